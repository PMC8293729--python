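"""Masking and inventory-constrained pixel selection.

The core post-processing of the pipeline: an ensemble habitat-probability
raster is masked to broadleaved-woodland stands, its eligible pixels are
ranked by probability, and pixels are then selected under two alternative
constraints —

* an *area filter*: accumulate ranked pixels up to a published regional
  stocked-oak area, and
* an *elevation filter*: within each 10 m elevation class, take the
  top-ranked pixels until the class count matches a reference histogram of
  surveyed oak stands.

The elevation filter is the corrective step: where historical management has
shifted real oak woodland away from the most ecologically suitable sites,
forcing the selection into the surveyed elevation distribution recovers
occupied sites that pure suitability ranking misses.

All selections are bit-reproducible: ties in probability are broken by
``(row, col)`` ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .grids import GridSpec

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .ensemble import ProbabilityRaster
    from .synthetic import StandPolygonLayer

__all__ = [
    "BROADLEAF_CATEGORIES",
    "ElevationHistogram",
    "MaskedRaster",
    "RankedPixels",
    "SelectionResult",
    "mask_to_broadleaf",
    "rank_pixels",
    "area_filter",
    "elevation_filter",
    "manual_adjust_check",
    "compare_selections_ks",
]

#: Indicative forest-type categories whose stands are eligible for selection.
BROADLEAF_CATEGORIES = (
    "broadleaved",
    "mixed-predominantly-broadleaved",
    "coppice",
    "coppice-with-standards",
)


@dataclass
class ElevationHistogram:
    """Counts of surveyed pixels (or plots) per half-open elevation class.

    Classes are ``[lower, lower + class_width)`` with lower bounds that are
    multiples of ``class_width`` (default 10 m, i.e. 0-9, 10-19, 20-29, ...).
    """

    counts: dict[float, int]
    class_width: float = 10.0

    def __post_init__(self) -> None:
        if self.class_width <= 0:
            raise ValueError("class_width must be > 0")
        clean: dict[float, int] = {}
        for lower, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative count {count} in class {lower}")
            snapped = np.floor(round(lower / self.class_width, 9)) * self.class_width
            if abs(snapped - lower) > 1e-6 * max(1.0, abs(lower)):
                raise ValueError(
                    f"class lower bound {lower} is not a multiple of {self.class_width}"
                )
            clean[float(snapped)] = int(count)
        self.counts = dict(sorted(clean.items()))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_values(
        cls, values: Iterable[float], class_width: float = 10.0
    ) -> "ElevationHistogram":
        values = np.asarray(list(values), dtype=float)
        lowers = np.floor(values / class_width) * class_width
        uniq, cnt = np.unique(lowers, return_counts=True)
        return cls({float(lo): int(c) for lo, c in zip(uniq, cnt)}, class_width)

    # -- queries -----------------------------------------------------------
    def class_of(self, values: np.ndarray) -> np.ndarray:
        """Lower bound of the class containing each value."""
        return np.floor(np.asarray(values, dtype=float) / self.class_width) * self.class_width

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def scaled_to_total(self, n: int) -> "ElevationHistogram":
        """Rescale counts so they sum to ``n`` (largest-remainder rounding).

        Used to lift a small-sample survey histogram to a regional pixel
        quota while preserving its shape.
        """
        if n < 0:
            raise ValueError("n must be >= 0")
        tot = self.total()
        if tot == 0:
            raise ValueError("cannot scale an empty histogram")
        lowers = list(self.counts)
        raw = np.array([self.counts[lo] for lo in lowers], dtype=float) * n / tot
        base = np.floor(raw).astype(int)
        remainder = n - int(base.sum())
        if remainder > 0:
            order = np.argsort(-(raw - base), kind="stable")
            base[order[:remainder]] += 1
        return ElevationHistogram(
            {lo: int(c) for lo, c in zip(lowers, base)}, self.class_width
        )


@dataclass
class MaskedRaster:
    """Probability raster after masking: values plus an eligibility mask."""

    values: np.ndarray
    eligible: np.ndarray
    grid: GridSpec


@dataclass
class RankedPixels:
    """Eligible pixels ordered by descending probability, ties (row, col)."""

    rows: np.ndarray
    cols: np.ndarray
    probs: np.ndarray
    grid: GridSpec

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SelectionResult:
    """Pixels chosen by a filter, with quota bookkeeping.

    ``achieved_area`` is always ``len(selected) * pixel_area``; for the
    elevation filter ``per_class_quota``/``per_class_achieved`` record the
    target histogram and what was actually available, and ``shortfalls``
    lists classes whose quota could not be met (deficits are never
    reallocated to other classes).
    """

    rows: np.ndarray
    cols: np.ndarray
    probs: np.ndarray
    grid: GridSpec
    target_area: float
    pixel_area: float
    per_class_quota: ElevationHistogram | None = None
    per_class_achieved: ElevationHistogram | None = None
    shortfalls: dict[float, int] = field(default_factory=dict)
    shortfall_area: float = 0.0

    @property
    def n_selected(self) -> int:
        return len(self.rows)

    @property
    def achieved_area(self) -> float:
        return self.n_selected * self.pixel_area

    @property
    def min_selected_probability(self) -> float:
        return float(self.probs.min()) if self.n_selected else float("nan")

    def mask(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        out[self.rows, self.cols] = True
        return out


# ---------------------------------------------------------------------------


def mask_to_broadleaf(
    prob: "ProbabilityRaster",
    stands: "StandPolygonLayer",
    categories: Sequence[str] = BROADLEAF_CATEGORIES,
) -> MaskedRaster:
    """Zero out and mark ineligible every pixel outside broadleaved stands.

    Pixels whose stand's indicative forest type is not in ``categories`` are
    set to 0 and excluded from ranking; NoData pixels (outside the raster's
    region) are likewise ineligible.
    """
    if prob.values.shape != stands.labels.shape:
        raise ValueError(
            f"raster shape {prob.values.shape} does not match stand layer "
            f"shape {stands.labels.shape}"
        )
    if prob.grid.pixel_size != stands.grid.pixel_size or prob.grid.origin != stands.grid.origin:
        raise ValueError("probability raster and stand layer are not co-registered")
    ok_ids = set(stands.table.index[stands.table["ift"].isin(categories)])
    in_cat = np.isin(stands.labels, sorted(ok_ids))
    finite = np.isfinite(prob.values)
    eligible = in_cat & finite
    values = np.where(eligible, prob.values, 0.0)
    return MaskedRaster(values=values, eligible=eligible, grid=stands.grid)


def rank_pixels(masked: MaskedRaster) -> RankedPixels:
    """Order eligible pixels from highest to lowest probability.

    Ties are broken by (row, col) ascending so the ranking — and everything
    downstream of it — is deterministic.
    """
    rows, cols = np.nonzero(masked.eligible)
    if len(rows) == 0:
        raise ValueError("no eligible pixels to rank")
    probs = masked.values[rows, cols]
    # np.lexsort: last key is primary
    order = np.lexsort((cols, rows, -probs))
    return RankedPixels(
        rows=rows[order], cols=cols[order], probs=probs[order], grid=masked.grid
    )


def area_filter(
    ranked: RankedPixels,
    target_area: float,
    pixel_area: float | None = None,
    mode: str = "floor",
) -> SelectionResult:
    """Accumulate ranked pixels up to a regional area target.

    ``mode='floor'`` (default) reads "up to" strictly: the largest selection
    whose area does not exceed the target. ``mode='nearest'`` rounds the
    pixel count to the nearest whole pixel instead. If the eligible pool is
    smaller than the target the whole pool is taken and the deficit recorded
    in ``shortfall_area``.
    """
    if target_area < 0:
        raise ValueError(f"target_area must be >= 0, got {target_area}")
    if pixel_area is None:
        pixel_area = ranked.grid.pixel_area_ha
    if mode == "floor":
        n = int(np.floor(target_area / pixel_area + 1e-9))
    elif mode == "nearest":
        n = int(round(target_area / pixel_area))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    shortfall_area = 0.0
    if n > len(ranked):
        shortfall_area = target_area - len(ranked) * pixel_area
        n = len(ranked)
    return SelectionResult(
        rows=ranked.rows[:n].copy(),
        cols=ranked.cols[:n].copy(),
        probs=ranked.probs[:n].copy(),
        grid=ranked.grid,
        target_area=float(target_area),
        pixel_area=pixel_area,
        shortfall_area=shortfall_area,
    )


def elevation_filter(
    ranked: RankedPixels,
    dem: np.ndarray,
    quota: ElevationHistogram,
) -> SelectionResult:
    """Fill each elevation class with its top-ranked pixels.

    Pixels are binned by the DEM value at their centre into half-open
    ``class_width`` classes; within every class the highest-probability
    pixels are taken until the class quota from the survey histogram is met.
    Classes with too few eligible pixels take everything available and the
    deficit is reported — never shifted into neighbouring classes, which
    would distort the target distribution.
    """
    if dem.shape != ranked.grid.shape:
        raise ValueError("DEM raster is not co-registered with the ranked pixels")
    classes = quota.class_of(dem[ranked.rows, ranked.cols])
    quota_map = quota.counts
    taken: dict[float, int] = {}
    keep = np.zeros(len(ranked), dtype=bool)
    for i, cls in enumerate(classes):
        cap = quota_map.get(float(cls), 0)
        got = taken.get(float(cls), 0)
        if got < cap:
            keep[i] = True
            taken[float(cls)] = got + 1
    achieved = ElevationHistogram(
        {lo: taken.get(lo, 0) for lo in quota_map}, quota.class_width
    )
    shortfalls = {
        lo: quota_map[lo] - achieved.counts[lo]
        for lo in quota_map
        if quota_map[lo] > achieved.counts[lo]
    }
    pixel_area = ranked.grid.pixel_area_ha
    return SelectionResult(
        rows=ranked.rows[keep].copy(),
        cols=ranked.cols[keep].copy(),
        probs=ranked.probs[keep].copy(),
        grid=ranked.grid,
        target_area=quota.total() * pixel_area,
        pixel_area=pixel_area,
        per_class_quota=quota,
        per_class_achieved=achieved,
        shortfalls=shortfalls,
        shortfall_area=sum(shortfalls.values()) * pixel_area,
    )


def manual_adjust_check(
    prob: "ProbabilityRaster",
    training_pixels: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, float]:
    """Force probability 1 at known (training) oak pixels; report the shift.

    Returns the adjusted raster and the signed mean of ``1 - p`` over the
    training pixels. A mean difference near zero means the model already
    ranks its own training stands at the top, i.e. the adjustment is a
    formality rather than a correction.
    """
    rows, cols = (np.asarray(training_pixels[0]), np.asarray(training_pixels[1]))
    grid = prob.grid
    if len(rows) and not np.all(grid.contains(rows, cols)):
        bad = np.flatnonzero(~grid.contains(rows, cols))
        raise ValueError(f"{len(bad)} training pixel(s) fall outside the grid")
    adjusted = prob.values.copy()
    if len(rows) == 0:
        return adjusted, 0.0
    original = prob.values[rows, cols]
    adjusted[rows, cols] = 1.0
    return adjusted, float(np.mean(1.0 - original))


def compare_selections_ks(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of probability samples.

    Returns ``(D, p)`` where D is the supremum ECDF distance and the p-value
    uses the asymptotic distribution.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(values_a, values_b, method="asymp")
    return float(res.statistic), float(res.pvalue)
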