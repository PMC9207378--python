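"""Late-expiratory flattening indices of the expiratory flow-volume limb.

The expiratory limb is reduced to three landmarks:

* **A** — the point of peak expiratory flow (PEF),
* **B** — the point after 75% of the expiratory vital capacity has been
  exhaled (the FEF75 locus), linearly interpolated between samples,
* **C** — the end of the limb on the volume axis, at (FVC, 0).

Ordinary least-squares lines are fitted to the A–B and B–C spans of the
curve and three indices are computed:

* ``angle_abc`` — the interior angle at B between the fitted A–B and
  B–C lines, in degrees.  Flattening of the late-expiratory portion
  (small-airway obstruction) makes the tail shallower relative to the
  A–B descent and shrinks this angle.
* ``angle_bcx`` — the inclination of the fitted B–C line against the
  volume axis, ``arctan(|slope|/aspect)`` in degrees.
* ``log_bc_over_ax`` — ``log10(|slope_BC| / PEF)``, the B–C slope
  normalized by the peak flow (the vertical distance from A to the
  volume axis).  The normalization makes the index invariant to a
  common rescaling of both axes.

Angles depend on how many L/s one plots per L of volume; the ``aspect``
parameter (L/s per L, default 1) fixes that convention and is exposed
on every angle operation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .curve import FLOW_EPSILON, ExpiratoryCurve
from .errors import (
    DegenerateCurveError,
    InsufficientPointsError,
    InvalidInputError,
    UndefinedRatioError,
)

#: fraction of the expiratory vital capacity exhaled at landmark B
B_FRACTION = 0.75


@dataclass(frozen=True)
class Landmarks:
    """Landmarks A (PEF), B (75% EVC) and C (end of limb) of a curve."""

    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]

    @property
    def fvc(self) -> float:
        return self.C[0]


@dataclass(frozen=True)
class SegmentFit:
    """OLS line fitted to a volume span of the curve, flow on volume."""

    slope: float
    intercept: float
    n_points: int
    rmse: float
    span: tuple[float, float]

    def flow_at(self, volume: float) -> float:
        return self.slope * volume + self.intercept


@dataclass(frozen=True)
class SadIndices:
    """The three flattening indices plus their ingredients."""

    angle_abc: float
    angle_bcx: float
    log_bc_over_ax: float
    peak_flow: float
    fvc: float
    fit_ab: SegmentFit
    fit_bc: SegmentFit
    aspect: float = 1.0
    source_id: str = ""

    def to_record(self) -> dict:
        """Flat JSON-serializable record, one row per curve."""
        return {
            "source_id": self.source_id,
            "angle_abc_deg": self.angle_abc,
            "angle_bcx_deg": self.angle_bcx,
            "log_bc_over_ax": self.log_bc_over_ax,
            "peak_flow_lps": self.peak_flow,
            "fvc_l": self.fvc,
            "aspect": self.aspect,
            "slope_ab": self.fit_ab.slope,
            "slope_bc": self.fit_bc.slope,
            "rmse_ab": self.fit_ab.rmse,
            "rmse_bc": self.fit_bc.rmse,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            **self.to_record(),
            "fit_ab": asdict(self.fit_ab),
            "fit_bc": asdict(self.fit_bc),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def locate_landmarks(curve: ExpiratoryCurve) -> Landmarks:
    """Find A (peak flow, first sample on ties), B (interpolated at
    75% of FVC) and C (last sample).

    Raises
    ------
    DegenerateCurveError
        If the peak lies at or beyond 75% of FVC, leaving no A-B
        segment to fit.
    """
    v, f = curve.volume, curve.flow
    i_a = int(np.argmax(f))  # first index attaining the maximum
    a = (float(v[i_a]), float(f[i_a]))
    c = (float(v[-1]), float(f[-1]))
    vb = B_FRACTION * c[0]
    if a[0] >= vb:
        raise DegenerateCurveError(
            f"peak flow at {a[0]:.3f} L is not before 75% of FVC ({vb:.3f} L)"
        )
    fb = float(np.interp(vb, v, f))
    return Landmarks(A=a, B=(vb, fb), C=c)


def fit_segment(curve: ExpiratoryCurve, v_start: float, v_end: float) -> SegmentFit:
    """OLS fit of flow on volume over samples with v_start <= v <= v_end."""
    if not v_start < v_end:
        raise InvalidInputError("v_start must be below v_end")
    sel = (curve.volume >= v_start) & (curve.volume <= v_end)
    n = int(np.count_nonzero(sel))
    if n < 2:
        raise InsufficientPointsError(
            f"only {n} samples in [{v_start:.3f}, {v_end:.3f}] L (need 2)"
        )
    x, y = curve.volume[sel], curve.flow[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return SegmentFit(
        slope=float(slope),
        intercept=float(intercept),
        n_points=n,
        rmse=float(np.sqrt(np.mean(resid**2))),
        span=(v_start, v_end),
    )


def _descent_inclination(slope: float, aspect: float) -> float:
    """Signed inclination of a descending line, degrees; positive when
    flow falls with volume."""
    return math.degrees(math.atan(-slope / aspect))


def angle_abc(fit_ab: SegmentFit, fit_bc: SegmentFit, aspect: float = 1.0) -> float:
    """Interior angle at B between the fitted A-B and B-C lines, degrees.

    Computed as 180° − (θ_AB − θ_BC) where θ is the signed descent
    inclination arctan(−slope/aspect); folded into (0, 180] so a tail
    steeper than the A-B descent still yields the interior angle.
    """
    if aspect <= 0:
        raise InvalidInputError("aspect must be positive")
    theta_ab = _descent_inclination(fit_ab.slope, aspect)
    theta_bc = _descent_inclination(fit_bc.slope, aspect)
    ang = 180.0 - (theta_ab - theta_bc)
    if ang > 180.0:
        ang = 360.0 - ang
    if not 0.0 < ang <= 180.0:
        raise InvalidInputError(f"angle {ang:.2f} outside (0, 180]")
    return ang


def angle_bcx(fit_bc: SegmentFit, aspect: float = 1.0) -> float:
    """Inclination of the fitted B-C line against the volume axis, in
    [0, 90) degrees."""
    if aspect <= 0:
        raise InvalidInputError("aspect must be positive")
    return math.degrees(math.atan(abs(fit_bc.slope) / aspect))


def log_bc_over_ax(fit_bc: SegmentFit, peak_flow: float) -> float:
    """log10 of |B-C slope| normalized by peak flow (A to x-axis)."""
    if peak_flow <= 0:
        raise InvalidInputError("peak flow must be positive")
    if fit_bc.slope == 0:
        raise UndefinedRatioError("B-C slope is zero; log ratio undefined")
    return math.log10(abs(fit_bc.slope) / peak_flow)


def compute_indices(
    curve: ExpiratoryCurve, aspect: float = 1.0
) -> SadIndices:
    """Landmarks, segment fits and all three indices for one curve."""
    lm = locate_landmarks(curve)
    fit_ab = fit_segment(curve, lm.A[0], lm.B[0])
    fit_bc = fit_segment(curve, lm.B[0], lm.C[0])
    peak = lm.A[1]
    if peak <= FLOW_EPSILON:
        raise DegenerateCurveError("peak flow not positive")
    return SadIndices(
        angle_abc=angle_abc(fit_ab, fit_bc, aspect),
        angle_bcx=angle_bcx(fit_bc, aspect),
        log_bc_over_ax=log_bc_over_ax(fit_bc, peak),
        peak_flow=peak,
        fvc=lm.fvc,
        fit_ab=fit_ab,
        fit_bc=fit_bc,
        aspect=aspect,
        source_id=curve.source_id,
    )
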