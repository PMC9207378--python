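import numpy as np
import pytest

from fvlsad.synthetic import CurveSpec, PageLayout, generate_curve, render_report


@pytest.fixture(scope="session")
def layout():
    return PageLayout()


@pytest.fixture(scope="session")
def templates(layout):
    """(label, digit_x, digit_y) glyph templates of the default layout."""
    digit_x, digit_y = layout.digit_templates(2)
    return layout.label_template(), digit_x, digit_y


@pytest.fixture(scope="session")
def default_curve_truth():
    """A noise-free piecewise-linear limb plus its closed-form indices."""
    return generate_curve(CurveSpec(flatten_theta_ab=60.0, flatten_theta_bc=40.0))


@pytest.fixture(scope="session")
def rendered_page(layout, default_curve_truth):
    curve, truth = default_curve_truth
    page, cal = render_report(curve, layout, source_id="fixture")
    return page, cal, curve, truth


def piecewise_curve(v_knots, f_knots, n=60, **kwargs):
    """Dense piecewise-linear curve through the given knots."""
    from fvlsad.curve import ExpiratoryCurve

    v = np.union1d(np.linspace(v_knots[0], v_knots[-1], n), v_knots)
    f = np.interp(v, v_knots, f_knots)
    return ExpiratoryCurve(v, f, source="synthetic", **kwargs)
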