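"""Coincidence validation against independent sites.

A predicted-oak selection is compared with an independent set of known oak
woodland sites: a site counts as coincident when at least one selected
pixel centre falls inside it. The coincidence success rate — the model's
sensitivity, or true presence rate — is tested against a null proportion
with a two-sided exact binomial test (minimum-likelihood tail sum, the
convention of R's ``binom.test``) and bracketed by an exact Clopper-Pearson
confidence interval, which is the interval construction that reproduces
integer-percent rounding of the reference results (Wilson intervals do
not).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import shapely
from scipy import stats

from .filters import SelectionResult

__all__ = [
    "ValidationReport",
    "coincidence",
    "exact_binomial_test",
    "clopper_pearson_ci",
    "validate",
    "report_from_counts",
]


@dataclass
class ValidationReport:
    n_sites: int
    n_coincident: int
    rate: float  # percent
    ci_low: float  # percent
    ci_high: float  # percent
    p_value: float
    null_proportion: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_coincident <= self.n_sites:
            raise ValueError("need 0 <= n_coincident <= n_sites")

    def to_dict(self) -> dict:
        return asdict(self)


def coincidence(
    selection: SelectionResult, sites: list, buffer: float = 0.0
) -> tuple[int, int]:
    """Count validation sites touched by the selection.

    A site is coincident iff at least one selected pixel centre lies within
    its polygon (``buffer`` > 0 inflates each site first, for point-located
    sites). Returns ``(n_coincident, n_sites)``.
    """
    if not sites:
        raise ValueError("site list is empty")
    xs, ys = selection.grid.cell_centers(selection.rows, selection.cols)
    n_hit = 0
    for site in sites:
        geom = site.buffer(buffer) if buffer > 0 else site
        if len(xs) == 0:
            continue
        minx, miny, maxx, maxy = geom.bounds
        near = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
        if not near.any():
            continue
        shapely.prepare(geom)
        if shapely.contains_xy(geom, xs[near], ys[near]).any():
            n_hit += 1
    return n_hit, len(sites)


def exact_binomial_test(successes: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood method).

    Sums Pr(j | n, p0) over all outcomes j no more probable than the
    observed count; for p0 = 0.5 this is the symmetric two-tail sum.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binomtest(successes, n, p0).pvalue)


def clopper_pearson_ci(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles, on [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def validate(
    selection: SelectionResult,
    sites: list,
    p0: float = 0.5,
    confidence: float = 0.95,
    buffer: float = 0.0,
) -> ValidationReport:
    """Full coincidence validation of a selection against independent sites."""
    n_hit, n_sites = coincidence(selection, sites, buffer=buffer)
    return report_from_counts(n_hit, n_sites, p0=p0, confidence=confidence)


def report_from_counts(
    n_coincident: int, n_sites: int, p0: float = 0.5, confidence: float = 0.95
) -> ValidationReport:
    """Build a ValidationReport from raw coincidence counts."""
    low, high = clopper_pearson_ci(n_coincident, n_sites, confidence)
    return ValidationReport(
        n_sites=n_sites,
        n_coincident=n_coincident,
        rate=100.0 * n_coincident / n_sites,
        ci_low=100.0 * low,
        ci_high=100.0 * high,
        p_value=exact_binomial_test(n_coincident, n_sites, p0),
        null_proportion=p0,
    )
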