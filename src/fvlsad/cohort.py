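"""Cohort-level statistics: cutoff derivation, classification,
concordance and multi-rater agreement.

The flattening cutoff follows an expert-supervised convention: take the
index values of the subjects an expert called non-flattening and use
``mean − k·SD`` (k = 1 by default, roughly the 15th percentile of a
Gaussian).  The lower limit of normal (LLN) is also reported, both
parametric (``mean − 1.6449·SD``, the Gaussian 5th percentile) and as
the interpolated empirical percentile.

Inter-rater agreement over a subjects × raters matrix of binary calls
uses Fleiss' kappa with its large-sample standard error for the normal
95% CI; a seeded subject-resampling bootstrap CI is available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidInputError,
)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean: float
    sd: float
    k: float
    percentile: float
    cutoff_mean_minus_k_sd: float
    lln_parametric: float
    lln_empirical: float


@dataclass(frozen=True)
class ConcordanceResult:
    n_total: int
    n_concordant: int

    @property
    def rate(self) -> float:
        return self.n_concordant / self.n_total


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def summarize_cohort(
    values, k: float = 1.0, percentile: float = 0.05
) -> CohortSummary:
    """Mean, sample SD (n−1), mean − k·SD cutoff and LLN of a cohort.

    ``lln_parametric`` is mean − z(percentile)·SD with the Gaussian
    quantile z(0.05) = 1.6449; ``lln_empirical`` is the
    linearly-interpolated empirical percentile.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("values must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    z = float(stats.norm.ppf(1.0 - percentile))
    return CohortSummary(
        n=int(x.size),
        mean=mean,
        sd=sd,
        k=k,
        percentile=percentile,
        cutoff_mean_minus_k_sd=mean - k * sd,
        lln_parametric=mean - z * sd,
        lln_empirical=float(np.percentile(x, 100.0 * percentile)),
    )


def classify_flattening(index_value, cutoff: float):
    """True (flattening) iff the index is strictly below the cutoff.

    Accepts a scalar or an array; the boundary value itself is
    non-flattening.
    """
    arr = np.asarray(index_value, dtype=float)
    if not (np.all(np.isfinite(arr)) and np.isfinite(cutoff)):
        raise InvalidInputError("classification inputs must be finite")
    out = arr < cutoff
    return bool(out) if np.isscalar(index_value) else out


def concordance_rate(calls_a, calls_b) -> ConcordanceResult:
    """Fraction of paired binary assessments that agree."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("call lists must be 1-D and equally long")
    if a.size == 0:
        raise InvalidInputError("empty call lists")
    return ConcordanceResult(
        n_total=int(a.size), n_concordant=int(np.count_nonzero(a == b))
    )


def _category_counts(ratings: np.ndarray) -> np.ndarray:
    """Subjects × categories count table from a subjects × raters matrix."""
    cats = np.unique(ratings)
    return np.stack([(ratings == c).sum(axis=1) for c in cats], axis=1)


def fleiss_kappa(
    ratings,
    bootstrap: int = 0,
    seed: int | None = None,
) -> KappaResult:
    """Fleiss' kappa for a complete subjects × raters categorical matrix.

    κ = (P̄ − P̄e) / (1 − P̄e) with per-subject agreement
    P_i = (Σ_j n_ij² − n) / (n (n−1)) and chance agreement
    P̄e = Σ_j p_j².  The 95% CI is κ ± 1.96·SE with Fleiss'
    large-sample SE; pass ``bootstrap=N`` (with a seed) for a
    subject-resampling percentile CI instead.

    If every rater puts every subject in one single category, P̄e = 1
    and κ is returned as 1.0 with a degenerate [κ, κ] interval and
    ``degenerate=True``.
    """
    r = np.asarray(ratings)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise InvalidInputError("ratings must be >= 2 subjects x >= 2 raters")
    if r.dtype.kind == "f":
        if np.isnan(r.astype(float)).any():
            raise InvalidInputError("missing ratings are not allowed")
    n_subjects, n_raters = r.shape
    counts = _category_counts(r)
    kappa, se, degenerate = _fleiss_from_counts(counts)
    if degenerate:
        return KappaResult(
            kappa=kappa, se=0.0, ci_lower=kappa, ci_upper=kappa,
            n_subjects=n_subjects, n_raters=n_raters, degenerate=True,
        )
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, n_subjects, n_subjects)
            boots[b] = _fleiss_from_counts(_category_counts(r[idx]))[0]
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo, hi = kappa - 1.96 * se, kappa + 1.96 * se
    return KappaResult(
        kappa=kappa,
        se=se,
        ci_lower=float(min(lo, kappa)),
        ci_upper=float(max(hi, kappa)),
        n_subjects=n_subjects,
        n_raters=n_raters,
    )


def _fleiss_from_counts(counts: np.ndarray) -> tuple[float, float, bool]:
    """(kappa, large-sample SE, degenerate?) from a subject × category
    count table with a constant number of ratings per subject."""
    n_subjects, _ = counts.shape
    n = int(counts[0].sum())
    if not np.all(counts.sum(axis=1) == n):
        raise InvalidInputError("all subjects need the same number of ratings")
    p = counts.sum(axis=0) / (n_subjects * n)
    p_bar = float(((counts**2).sum(axis=1) - n).mean() / (n * (n - 1)))
    p_e = float((p**2).sum())
    if p_e >= 1.0:
        return 1.0, 0.0, True
    kappa = (p_bar - p_e) / (1.0 - p_e)
    q = 1.0 - p
    pq = float((p * q).sum())
    se = np.sqrt(2.0 / (n_subjects * n * (n - 1))) * np.sqrt(
        max(pq**2 - float((p * q * (q - p)).sum()), 0.0)
    ) / pq
    return float(kappa), float(se), False


def two_sample_t(values_a, values_b) -> tuple[float, float]:
    """Classical unpaired two-sided Student's t-test (equal variances).

    Provided for group-comparison report parity; returns (t, p).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "zero within-group variance in both groups"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
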