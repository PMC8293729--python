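"""Presence/absence pixel tables and predictor screening.

Turns stand polygons plus the covariate stack into balanced training data:
presence pixels come from stands with an oak component of at least 60% of
the stand area, absence candidates from broadleaved stands where oak is
absent or a minor (<= 10%) component — stands in between belong to neither
class. Fifteen balanced pseudo-absence replicates per region keep the
prevalence at exactly 0.5 while sampling a wider environmental envelope
than any single absence set could.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .synthetic import BiophysicalStack, StandPolygonLayer

__all__ = [
    "PresenceAbsenceSet",
    "CollinearityReport",
    "extract_presence_pixels",
    "extract_absence_candidates",
    "sample_absence_replicates",
    "screen_collinearity",
    "build_presence_absence",
]

#: indicative forest types that count as broadleaved woodland for absences
ABSENCE_CATEGORIES = ("broadleaved",)


@dataclass
class PresenceAbsenceSet:
    """Balanced training data for one region.

    ``presence`` and each entry of ``absence_replicates`` are pixel tables
    with ``row``/``col`` columns plus one column per covariate; every
    replicate has exactly as many records as the presence table.
    """

    region_id: int
    presence: pd.DataFrame
    absence_replicates: list[pd.DataFrame]
    variable_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.presence)
        for i, rep in enumerate(self.absence_replicates):
            if len(rep) != n:
                raise ValueError(
                    f"absence replicate {i} has {len(rep)} records, expected {n}"
                )

    @property
    def n_presence(self) -> int:
        return len(self.presence)

    @property
    def k_replicates(self) -> int:
        return len(self.absence_replicates)

    def design(self, replicate: int) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) for the presence set stacked with one absence replicate."""
        xp = self.presence[self.variable_names].to_numpy(dtype=float)
        xa = self.absence_replicates[replicate][self.variable_names].to_numpy(dtype=float)
        X = np.vstack([xp, xa])
        y = np.concatenate([np.ones(len(xp), dtype=int), np.zeros(len(xa), dtype=int)])
        return X, y


@dataclass
class CollinearityReport:
    pairwise_correlations: pd.DataFrame
    vif_values: pd.Series  # VIFs of the retained variables, final pass
    removed: list[str]
    retained: list[str]
    r_threshold: float
    vif_threshold: float
    removal_log: list[dict] = field(default_factory=list)


def _pixel_table(
    stands: StandPolygonLayer,
    stack: BiophysicalStack,
    stand_ids,
) -> pd.DataFrame:
    rows, cols = stands.pixels_of(stand_ids)
    cov = stack.covariates_at(rows, cols)
    out = pd.DataFrame({"row": rows, "col": cols})
    out = pd.concat([out, cov], axis=1)
    finite = np.isfinite(out[stack.variable_names].to_numpy()).all(axis=1)
    n_dropped = int((~finite).sum())
    out = out.loc[finite].reset_index(drop=True)
    out.attrs["n_nodata_dropped"] = n_dropped
    return out


def extract_presence_pixels(
    stands: StandPolygonLayer,
    stack: BiophysicalStack,
    oak_min_pct: float = 60.0,
) -> pd.DataFrame:
    """All pixels of stands whose oak component is >= ``oak_min_pct``.

    Pixels with any NoData covariate are dropped; the count of dropped
    pixels is recorded in the result's ``attrs['n_nodata_dropped']``.
    """
    if "pct_oak" not in stands.table.columns:
        raise ValueError("stand table has no species-composition attribute 'pct_oak'")
    ids = stands.table.index[stands.table["pct_oak"] >= oak_min_pct]
    return _pixel_table(stands, stack, ids)


def extract_absence_candidates(
    stands: StandPolygonLayer,
    stack: BiophysicalStack,
    oak_max_pct: float = 10.0,
    categories=ABSENCE_CATEGORIES,
) -> pd.DataFrame:
    """Pixels of broadleaved stands where oak is absent or <= ``oak_max_pct``.

    Stands with an oak component strictly between the absence and presence
    thresholds contribute to neither class.
    """
    if "pct_oak" not in stands.table.columns:
        raise ValueError("stand table has no species-composition attribute 'pct_oak'")
    t = stands.table
    ids = t.index[t["ift"].isin(categories) & (t["pct_oak"] <= oak_max_pct)]
    return _pixel_table(stands, stack, ids)


def sample_absence_replicates(
    candidates: pd.DataFrame,
    n_presence: int,
    k: int = 15,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Draw ``k`` balanced pseudo-absence sets of size ``n_presence``.

    Each replicate is sampled without replacement from the candidate pool;
    replicates are independent draws and may overlap with each other.
    """
    if len(candidates) < n_presence:
        raise ValueError(
            f"absence candidate pool ({len(candidates)} pixels) is smaller than "
            f"the presence set ({n_presence}); short by {n_presence - len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(k):
        idx = rng.choice(len(candidates), size=n_presence, replace=False)
        reps.append(candidates.iloc[np.sort(idx)].reset_index(drop=True))
    return reps


def _vifs(X: np.ndarray) -> np.ndarray:
    if X.shape[1] < 2:
        return np.ones(X.shape[1])
    # center first: the auxiliary regressions need an intercept, which
    # variance_inflation_factor itself does not add
    Xc = X - X.mean(axis=0)
    return np.array([variance_inflation_factor(Xc, j) for j in range(Xc.shape[1])])


def screen_collinearity(
    table: np.ndarray | pd.DataFrame,
    variable_names: list[str] | None = None,
    r_threshold: float = 0.7,
    vif_threshold: float = 10.0,
    response: np.ndarray | None = None,
) -> CollinearityReport:
    """Iteratively prune collinear predictors.

    Repeats until every pairwise ``|r| <= r_threshold`` and every variance
    inflation factor ``<= vif_threshold``. At each step the offending
    variables are those in a too-correlated pair or above the VIF ceiling;
    when a binary ``response`` is supplied the offender explaining the least
    response variance (univariate R^2) is removed, otherwise the one with
    the largest VIF. Constant columns are flagged with a warning and removed
    first.
    """
    if isinstance(table, pd.DataFrame):
        if variable_names is None:
            variable_names = list(table.columns)
        X = table[variable_names].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        if variable_names is None:
            variable_names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need at least 2 variables and 3 records")

    names = list(variable_names)
    removed: list[str] = []
    log: list[dict] = []

    constant = [names[j] for j in range(X.shape[1]) if np.std(X[:, j]) == 0]
    if constant:
        warnings.warn(f"constant column(s) removed before screening: {constant}")
        for nm in constant:
            removed.append(nm)
            log.append({"variable": nm, "reason": "constant"})
        keep_idx = [j for j in range(X.shape[1]) if names[j] not in constant]
        X = X[:, keep_idx]
        names = [names[j] for j in keep_idx]

    full_corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=names, columns=names)

    def response_r2(j: int) -> float:
        x = X[:, j]
        r = np.corrcoef(x, response)[0, 1]
        return float(r * r) if np.isfinite(r) else 0.0

    while len(names) >= 2:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        vifs = _vifs(X)
        offenders = set()
        for a in range(len(names)):
            if vifs[a] > vif_threshold:
                offenders.add(a)
            for b in range(a + 1, len(names)):
                if abs(corr[a, b]) > r_threshold:
                    offenders.update((a, b))
        if not offenders:
            break
        if response is not None:
            victim = min(offenders, key=lambda j: (response_r2(j), -vifs[j]))
            reason = "least response R^2 among collinear set"
        else:
            victim = max(offenders, key=lambda j: vifs[j])
            reason = "highest VIF among collinear set"
        removed.append(names[victim])
        log.append(
            {"variable": names[victim], "reason": reason, "vif": float(vifs[victim])}
        )
        X = np.delete(X, victim, axis=1)
        names.pop(victim)

    final_vifs = pd.Series(_vifs(X) if len(names) >= 2 else np.ones(len(names)), index=names)
    return CollinearityReport(
        pairwise_correlations=full_corr,
        vif_values=final_vifs,
        removed=removed,
        retained=names,
        r_threshold=r_threshold,
        vif_threshold=vif_threshold,
        removal_log=log,
    )


def build_presence_absence(
    stands: StandPolygonLayer,
    stack: BiophysicalStack,
    region_id: int,
    seed: int,
    oak_min_pct: float = 60.0,
    oak_max_pct: float = 10.0,
    k: int = 15,
    presence_fraction: float = 0.5,
    variable_names: list[str] | None = None,
) -> PresenceAbsenceSet:
    """Assemble one region's balanced presence/pseudo-absence data.

    ``presence_fraction`` subsamples the presence pixels (default half),
    trading training-set size against spatial redundancy of neighbouring
    pixels in the same stand. The same pixel never appears in both classes.
    """
    region_stands = stands.subset(
        stands.table.index[stands.table["region_id"] == region_id]
    )
    presence = extract_presence_pixels(region_stands, stack, oak_min_pct)
    absence_pool = extract_absence_candidates(region_stands, stack, oak_max_pct)
    if len(presence) == 0:
        raise ValueError(f"region {region_id} has no presence pixels")
    rng = np.random.default_rng(seed)
    if presence_fraction < 1.0:
        n_keep = max(int(round(presence_fraction * len(presence))), 1)
        idx = np.sort(rng.choice(len(presence), size=n_keep, replace=False))
        presence = presence.iloc[idx].reset_index(drop=True)
    reps = sample_absence_replicates(
        absence_pool, len(presence), k=k, seed=int(rng.integers(2**31))
    )
    variables = variable_names if variable_names is not None else stack.variable_names
    cols = ["row", "col"] + list(variables)
    return PresenceAbsenceSet(
        region_id=region_id,
        presence=presence[cols],
        absence_replicates=[r[cols] for r in reps],
        variable_names=list(variables),
    )
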