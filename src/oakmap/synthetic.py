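"""Seeded synthetic landscapes with the statistical structure the analysis assumes.

The generator stands in for the confidential British forest datasets. It
produces, from a single integer seed:

* a co-registered stack of 50 m biophysical rasters (elevation plus
  climate, exposure, wetness and ordinal soil layers) with realistic
  spatial autocorrelation and the documented elevation couplings — warmth
  (AT) and moisture deficit (CMD) fall with elevation, wind exposure
  (DAMS) rises with it;
* a complete tessellation of the grid into 5-30 ha forest stands carrying
  an indicative forest type and species-composition percentages;
* a known "truth": a logistic suitability niche, stand-level oak occupancy
  derived from it, and inventory-style summary products (regional stocked
  areas, 10 m elevation histograms from a small stand sample, and held-out
  validation sites).

Occupancy is assigned in two ownership cohorts. "Public" (estate) stands
are occupied strictly by suitability rank and are the source of model
training data; "private" stands are occupied by a *bias-shifted* suitability
score — the niche evaluated as if every site sat ``management_bias`` metres
higher — and supply the validation sites and most of the survey histogram.
With a nonzero bias the truly occupied woodland therefore sits
systematically below the suitability optimum, which is exactly the
structure the elevation filter is designed to correct; with zero bias the
two cohorts collapse to plain top-suitability occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .filters import ElevationHistogram
from .grids import GridSpec

__all__ = [
    "BiophysicalStack",
    "StandPolygonLayer",
    "TruthModel",
    "InventoryProducts",
    "generate_biophysical",
    "generate_stands",
    "generate_truth_and_inventory",
    "suitability_surface",
]

# Deterministic elevation responses (per metre of elevation). The noise
# components of each layer scale with terrain relief, so a flat landscape
# (roughness 0) has spatially constant covariates.
_AT0, _AT_SLOPE = 1900.0, -2.5  # degree-days > 5 C
_CMD0, _CMD_SLOPE = 220.0, -0.45  # mm
_DAMS0, _DAMS_SLOPE = 9.0, 0.018  # exposure index
_DEFAULT_ROUGHNESS = 350.0  # m of relief

DEM_SLOPES = {"AT": _AT_SLOPE, "CMD": _CMD_SLOPE, "DAMS": _DAMS_SLOPE, "DEM": 1.0}

CONTINUOUS_LAYERS = ("AT", "CMD", "DAMS", "TWI", "DEM")
ORDINAL_LAYERS = ("SMR", "SNR")
ALL_LAYERS = CONTINUOUS_LAYERS + ORDINAL_LAYERS

BROADLEAF_SPECIES = ("oak", "birch", "ash", "beech", "sycamore")
CONIFER_SPECIES = ("scots_pine", "sitka_spruce", "larch")
ALL_SPECIES = BROADLEAF_SPECIES + CONIFER_SPECIES


@dataclass
class BiophysicalStack:
    """Co-registered biophysical rasters on a common grid.

    ``layers`` maps layer name to a float raster; SMR/SNR are ordinal
    integers stored as float. ``dem_slopes`` records the deterministic
    d(layer)/d(DEM) coefficients used by the generator, which lets the truth
    model evaluate the niche at an elevation offset.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    region_id: np.ndarray
    dem_slopes: dict[str, float] = field(default_factory=lambda: dict(DEM_SLOPES))

    def __post_init__(self) -> None:
        for name, layer in self.layers.items():
            if layer.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {layer.shape} != grid {self.grid.shape}")
            if not np.isfinite(layer).any():
                raise ValueError(f"layer {name!r} is entirely NoData")
        if self.region_id.shape != self.grid.shape:
            raise ValueError("region_id raster does not match the grid")

    @property
    def variable_names(self) -> list[str]:
        return [name for name in ALL_LAYERS if name in self.layers]

    def covariates_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Covariate table for pixel index arrays, columns in stack order."""
        data = {name: self.layers[name][rows, cols] for name in self.variable_names}
        return pd.DataFrame(data)

    def regions(self) -> list[int]:
        return sorted(int(r) for r in np.unique(self.region_id))


@dataclass
class StandPolygonLayer:
    """Forest stands as a label raster plus an attribute table.

    Stand boundaries follow pixel edges, so the label raster *is* the
    authoritative geometry; polygons are derived from it on demand. The
    table is indexed by stand id and carries region, indicative forest type,
    area, ownership, occupancy and integer species percentages (columns
    ``pct_<species>``) summing to 100.
    """

    grid: GridSpec
    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.labels.shape != self.grid.shape:
            raise ValueError("label raster does not match the grid")

    @property
    def stand_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def pixels_of(self, stand_ids) -> tuple[np.ndarray, np.ndarray]:
        mask = np.isin(self.labels, np.asarray(list(stand_ids)))
        return np.nonzero(mask)

    def polygon(self, stand_id: int):
        """Shapely polygon of a stand (union of its pixel squares)."""
        rows, cols = np.nonzero(self.labels == stand_id)
        if len(rows) == 0:
            raise KeyError(f"stand {stand_id} has no pixels")
        ps = self.grid.pixel_size
        x0, y0 = self.grid.origin
        boxes = [
            box(
                x0 + c * ps,
                y0 + (self.grid.n_rows - r - 1) * ps,
                x0 + (c + 1) * ps,
                y0 + (self.grid.n_rows - r) * ps,
            )
            for r, c in zip(rows, cols)
        ]
        return unary_union(boxes)

    def subset(self, stand_ids) -> "StandPolygonLayer":
        """Same rasters, attribute table restricted to ``stand_ids``."""
        return StandPolygonLayer(
            grid=self.grid, labels=self.labels, table=self.table.loc[list(stand_ids)]
        )


@dataclass
class TruthModel:
    """The known data-generating niche and its occupancy distortion.

    Suitability is ``sigmoid(intercept + sum_j beta_j z_j - ((DEM - opt)/tol)^2)``
    over standardized covariates z, i.e. a logistic niche with an explicit
    elevation optimum. ``management_bias`` (metres) shifts the elevation at
    which the *occupancy* score is evaluated, displacing occupied stands
    from the suitability optimum by a known, recoverable amount.
    """

    niche_coefficients: dict[str, float] = field(
        default_factory=lambda: {"AT": 1.5, "CMD": -0.5, "DAMS": -1.0, "TWI": 0.4, "SMR": 0.3, "SNR": 0.3}
    )
    intercept: float = 0.0
    dem_optimum: float = 150.0  # m
    dem_tolerance: float = 90.0  # m
    management_bias: float = 120.0  # m
    occupancy_area_fraction: float = 0.25  # of broadleaved stand area
    estate_fraction: float = 0.35  # share of stands that are public estate
    area_noise_sd: float = 0.0  # ha, optional noise on published area targets

    def __post_init__(self) -> None:
        if not 0 <= self.occupancy_area_fraction <= 1:
            raise ValueError("occupancy_area_fraction must be in [0, 1]")
        if not 0 <= self.estate_fraction <= 1:
            raise ValueError("estate_fraction must be in [0, 1]")
        if self.dem_tolerance <= 0:
            raise ValueError("dem_tolerance must be > 0")


@dataclass
class InventoryProducts:
    """Inventory-style summaries of the (hidden) occupancy truth."""

    regional_area_targets: dict[int, float]
    elevation_histograms: dict[int, ElevationHistogram]
    sample_fraction: float
    sampled_stand_ids: dict[int, list[int]]
    validation_stand_ids: list[int]
    validation_sites: list  # shapely polygons, same order as validation_stand_ids


# ---------------------------------------------------------------------------
# biophysical stack


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field from smoothed white noise."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_biophysical(
    grid: GridSpec, seed: int, roughness: float = _DEFAULT_ROUGHNESS
) -> BiophysicalStack:
    """Generate the covariate stack for a landscape.

    ``roughness`` is the approximate terrain relief in metres; it scales the
    DEM and every layer's stochastic component, so ``roughness=0`` yields a
    flat landscape with constant covariates. Identical ``(grid, seed,
    roughness)`` reproduce the stack bit-for-bit.
    """
    if roughness < 0:
        raise ValueError(f"roughness must be >= 0, got {roughness}")
    rng = np.random.default_rng(seed)
    shape = grid.shape
    sigma = max(min(shape) / 10.0, 1.0)

    base = _smooth_field(rng, shape, sigma)
    fine = _smooth_field(rng, shape, sigma / 3.0)
    terrain = base + 0.4 * fine
    span = terrain.max() - terrain.min()
    dem = roughness * (terrain - terrain.min()) / span if span > 0 else np.zeros(shape)

    # Noise amplitudes keep the layers correlated with elevation but not
    # collinear duplicates of it (pairwise |r| with DEM roughly 0.5-0.85,
    # as for real climate surfaces); they scale with relief so a flat
    # landscape has constant covariates.
    s = roughness / _DEFAULT_ROUGHNESS
    at = np.maximum(_AT0 + _AT_SLOPE * dem + 120.0 * s * _smooth_field(rng, shape, sigma), 0.0)
    cmd = np.maximum(_CMD0 + _CMD_SLOPE * dem + 60.0 * s * _smooth_field(rng, shape, sigma), 0.0)
    dams = np.maximum(_DAMS0 + _DAMS_SLOPE * dem + 2.5 * s * _smooth_field(rng, shape, sigma), 0.0)
    twi = np.maximum(6.0 + 2.2 * s * _smooth_field(rng, shape, sigma), 0.0)

    def ordinal(f: np.ndarray, n_classes: int = 5) -> np.ndarray:
        if f.max() == f.min():
            return np.ones_like(f)
        qs = np.quantile(f, np.linspace(0, 1, n_classes + 1)[1:-1])
        return (np.searchsorted(qs, f.ravel()).reshape(f.shape) + 1).astype(float)

    smr = ordinal(0.7 * _smooth_field(rng, shape, sigma) + 0.3 * s * (twi - twi.mean()))
    snr = ordinal(_smooth_field(rng, shape, sigma))

    # contiguous vertical bands
    cols = np.arange(grid.n_cols)
    band = np.minimum(
        (cols * grid.region_count) // grid.n_cols, grid.region_count - 1
    )
    region_id = np.broadcast_to(band, shape).astype(np.int32).copy()

    layers = {"AT": at, "CMD": cmd, "DAMS": dams, "TWI": twi, "DEM": dem, "SMR": smr, "SNR": snr}
    return BiophysicalStack(grid=grid, layers=layers, region_id=region_id)


# ---------------------------------------------------------------------------
# stand tessellation


def _serpentine_order(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Boustrophedon ordering of a pixel set (alternate column direction by row)."""
    key_cols = np.where(rows % 2 == 0, cols, -cols)
    return np.lexsort((key_cols, rows))


def _integer_percentages(rng: np.random.Generator, k: int, total: int = 100) -> np.ndarray:
    """Random integer composition summing to ``total`` (largest remainder)."""
    raw = rng.dirichlet(np.full(k, 1.5)) * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def generate_stands(
    stack: BiophysicalStack,
    seed: int,
    min_area: float = 5.0,
    max_area: float = 30.0,
) -> StandPolygonLayer:
    """Tessellate the landscape into contiguous 5-30 ha stands.

    Stands are grown along a serpentine pixel path within each region with
    randomized run lengths, which guarantees every stand is contiguous,
    every pixel belongs to exactly one stand, and all areas land inside
    ``[min_area, max_area]`` up to pixel quantization. Each stand receives
    an indicative forest type and integer species percentages summing to
    100; oak percentages stay below the presence threshold here — occupancy
    (and with it oak-dominated composition) is assigned by
    :func:`generate_truth_and_inventory`.
    """
    grid = stack.grid
    pa = grid.pixel_area_ha
    if not 0 < min_area <= max_area:
        raise ValueError("need 0 < min_area <= max_area")
    min_px = max(int(np.ceil(min_area / pa - 1e-9)), 1)
    max_px = int(np.floor(max_area / pa + 1e-9))
    if max_px < 1:
        raise ValueError(f"max_area {max_area} ha is smaller than one pixel ({pa} ha)")
    if max_px < min_px:
        raise ValueError("max_area rounds below min_area at this pixel size")

    rng = np.random.default_rng(seed)
    labels = np.full(grid.shape, -1, dtype=np.int32)
    records = []
    next_id = 0
    for region in stack.regions():
        rows, cols = np.nonzero(stack.region_id == region)
        order = _serpentine_order(rows, cols)
        rows, cols = rows[order], cols[order]
        pos, n = 0, len(rows)
        while pos < n:
            remaining = n - pos
            if remaining <= max_px:
                take = remaining
                if take < min_px and records and records[-1]["region_id"] == region:
                    # tiny tail: absorb into the previous stand
                    prev = records[-1]
                    labels[rows[pos:], cols[pos:]] = prev["stand_id"]
                    prev["n_pixels"] += take
                    prev["area_ha"] = prev["n_pixels"] * pa
                    break
            else:
                hi = min(max_px, remaining - min_px)
                take = int(rng.integers(min_px, hi + 1)) if hi >= min_px else min(remaining, max_px)
            sl = slice(pos, pos + take)
            labels[rows[sl], cols[sl]] = next_id
            records.append(
                {"stand_id": next_id, "region_id": region, "n_pixels": take, "area_ha": take * pa}
            )
            next_id += 1
            pos += take

    table = pd.DataFrame.from_records(records).set_index("stand_id")
    n_stands = len(table)
    ift = rng.choice(
        ["broadleaved", "conifer", "mixed-predominantly-broadleaved", "other"],
        size=n_stands,
        p=[0.55, 0.25, 0.12, 0.08],
    )
    table["ift"] = ift
    table["ownership"] = "private"  # assigned properly in the truth step
    table["occupied"] = False

    pct = np.zeros((n_stands, len(ALL_SPECIES)), dtype=int)
    sp_index = {sp: i for i, sp in enumerate(ALL_SPECIES)}
    for i, t in enumerate(ift):
        if t == "conifer":
            pool = CONIFER_SPECIES
        elif t == "other":
            pool = ("birch",)
        elif t == "mixed-predominantly-broadleaved":
            pool = BROADLEAF_SPECIES + CONIFER_SPECIES[:1]
        else:
            pool = BROADLEAF_SPECIES
        if "oak" in pool:
            # most non-oak-dominated broadleaved stands carry little or no
            # oak: draw the oak share from a zero-inflated mixture (absent /
            # minor / intermediate), then split the rest among the pool
            u = rng.random()
            if u < 0.55:
                oak = 0
            elif u < 0.80:
                oak = int(rng.integers(1, 11))
            else:
                oak = int(rng.integers(11, 56))
            rest = [sp for sp in pool if sp != "oak"]
            comp = _integer_percentages(rng, len(rest), total=100 - oak)
            pct[i, sp_index["oak"]] = oak
            for sp, v in zip(rest, comp):
                pct[i, sp_index[sp]] = v
        else:
            comp = _integer_percentages(rng, len(pool))
            for sp, v in zip(pool, comp):
                pct[i, sp_index[sp]] = v
    for sp in ALL_SPECIES:
        table[f"pct_{sp}"] = pct[:, sp_index[sp]]

    return StandPolygonLayer(grid=grid, labels=labels, table=table)


# ---------------------------------------------------------------------------
# truth + inventory


def suitability_surface(
    stack: BiophysicalStack, truth: TruthModel, dem_offset: float = 0.0
) -> np.ndarray:
    """Logistic suitability in [0, 1] per pixel.

    With ``dem_offset`` nonzero the niche is evaluated as if every pixel sat
    that many metres higher: DEM-coupled covariates are adjusted by their
    generator slopes and the elevation-optimum term is shifted, while the
    standardization constants of the *unshifted* landscape are kept so the
    offset acts as a pure displacement of the niche.
    """
    logit = np.full(stack.grid.shape, truth.intercept, dtype=float)
    for name, beta in truth.niche_coefficients.items():
        layer = stack.layers[name]
        mu, sd = float(layer.mean()), float(layer.std())
        shifted = layer + stack.dem_slopes.get(name, 0.0) * dem_offset
        z = (shifted - mu) / sd if sd > 0 else np.zeros_like(layer)
        logit += beta * z
    dem = stack.layers["DEM"] + dem_offset
    logit -= ((dem - truth.dem_optimum) / truth.dem_tolerance) ** 2
    return 1.0 / (1.0 + np.exp(-logit))


def _stand_means(values: np.ndarray, labels: np.ndarray, stand_ids: np.ndarray) -> np.ndarray:
    sums = ndimage.sum_labels(values, labels, index=stand_ids)
    counts = ndimage.sum_labels(np.ones_like(values), labels, index=stand_ids)
    return sums / counts


def generate_truth_and_inventory(
    stands: StandPolygonLayer,
    stack: BiophysicalStack,
    truth: TruthModel,
    seed: int,
    sample_fraction: float = 0.006,
    min_sample_stands: int = 20,
    n_validation_sites: int = 64,
) -> tuple[np.ndarray, InventoryProducts]:
    """Assign oak occupancy and derive the inventory summary products.

    Per region and ownership cohort, broadleaved stands are ranked by the
    occupancy score (pure suitability for public stands, bias-shifted
    suitability for private ones) and occupied from the top until
    ``occupancy_area_fraction`` of the cohort's broadleaved area is reached.
    Occupied stands get an oak composition of 60-95%; the stand table is
    updated in place. Returns the boolean occupancy raster and the
    inventory products: per-region stocked-oak areas (occupied pixels x
    pixel area, optionally noised), 10 m elevation histograms from a small
    sample of occupied stands (at least ``min_sample_stands`` per region, so
    the histogram keeps useful precision on reduced landscapes), and
    validation sites drawn from private occupied stands, geometrically
    disjoint from any public training stand by construction.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    table = stands.table
    grid = stands.grid
    pa = grid.pixel_area_ha

    ids = stands.stand_ids
    suit = suitability_surface(stack, truth, dem_offset=0.0)
    suit_biased = (
        suit
        if truth.management_bias == 0
        else suitability_surface(stack, truth, dem_offset=truth.management_bias)
    )
    mean_suit = pd.Series(_stand_means(suit, stands.labels, ids), index=ids)
    mean_biased = pd.Series(_stand_means(suit_biased, stands.labels, ids), index=ids)

    table["ownership"] = np.where(
        rng.random(len(table)) < truth.estate_fraction, "public", "private"
    )
    table["suitability"] = mean_suit
    table["occupancy_score"] = np.where(
        table["ownership"] == "public", mean_suit, mean_biased
    )
    table["occupied"] = False

    broad = table["ift"] == "broadleaved"
    if not broad.any():
        raise ValueError("no broadleaved stands available for occupancy")
    for (region, _own), group in table[broad].groupby(["region_id", "ownership"]):
        target = truth.occupancy_area_fraction * group["area_ha"].sum()
        ranked = group.sort_values("occupancy_score", ascending=False)
        cum = ranked["area_ha"].cumsum()
        chosen = ranked.index[cum <= target + 1e-9]
        table.loc[chosen, "occupied"] = True

    # occupied stands become oak-dominated; displaced percentage points are
    # taken from the other species proportionally (largest remainder)
    occupied_ids = table.index[table["occupied"]]
    pct_cols = [f"pct_{sp}" for sp in ALL_SPECIES]
    for sid in occupied_ids:
        oak_pct = int(rng.integers(60, 96))
        others = np.array(
            [table.at[sid, c] for c in pct_cols if c != "pct_oak"], dtype=float
        )
        if others.sum() > 0:
            raw = others / others.sum() * (100 - oak_pct)
            new = np.floor(raw).astype(int)
            short = (100 - oak_pct) - int(new.sum())
            if short > 0:
                order = np.argsort(-(raw - new), kind="stable")
                new[order[:short]] += 1
        else:
            new = np.zeros_like(others, dtype=int)
            new[0] = 100 - oak_pct
        table.at[sid, "pct_oak"] = oak_pct
        j = 0
        for c in pct_cols:
            if c != "pct_oak":
                table.at[sid, c] = int(new[j])
                j += 1

    occupancy = np.isin(stands.labels, occupied_ids.to_numpy())

    # regional stocked-oak area targets
    area_targets: dict[int, float] = {}
    for region in stack.regions():
        n_occ = int(np.count_nonzero(occupancy & (stack.region_id == region)))
        target = n_occ * pa
        if truth.area_noise_sd > 0:
            target = max(float(target + rng.normal(0, truth.area_noise_sd)), 0.0)
        area_targets[region] = float(target)

    # survey-style elevation histograms from a sample of occupied stands
    dem = stack.layers["DEM"]
    histograms: dict[int, ElevationHistogram] = {}
    sampled: dict[int, list[int]] = {}
    for region in stack.regions():
        occ_ids = table.index[(table["occupied"]) & (table["region_id"] == region)]
        if len(occ_ids) == 0:
            warnings.warn(f"region {region} has no occupied stands; empty histogram")
            histograms[region] = ElevationHistogram({0.0: 0})
            sampled[region] = []
            continue
        perm = rng.permutation(occ_ids.to_numpy())
        occ_area = table.loc[occ_ids, "area_ha"].sum()
        want_area = sample_fraction * occ_area
        chosen: list[int] = []
        got = 0.0
        for sid in perm:
            if got >= want_area and len(chosen) >= min(min_sample_stands, len(occ_ids)):
                break
            chosen.append(int(sid))
            got += table.at[sid, "area_ha"]
        rows, cols = stands.pixels_of(chosen)
        histograms[region] = ElevationHistogram.from_values(dem[rows, cols])
        sampled[region] = chosen

    # validation sites: private occupied stands, withheld from training
    private_occ = table.index[(table["occupied"]) & (table["ownership"] == "private")]
    n_sites = min(n_validation_sites, len(private_occ))
    if n_sites == 0:
        raise ValueError("no private occupied stands available for validation sites")
    site_ids = [int(s) for s in rng.choice(private_occ.to_numpy(), size=n_sites, replace=False)]
    site_polys = [stands.polygon(s) for s in site_ids]

    inventory = InventoryProducts(
        regional_area_targets=area_targets,
        elevation_histograms=histograms,
        sample_fraction=sample_fraction,
        sampled_stand_ids=sampled,
        validation_stand_ids=site_ids,
        validation_sites=site_polys,
    )
    return occupancy, inventory
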