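"""Areal dataset container, CSV I/O, and expected-count standardization.

The unit of analysis is a small areal polygon (e.g. a census dissemination
area).  For each area i and outcome k the dataset holds an observed count
O_ik, an expected count E_ik from (indirect) standardization, and a row of
covariates.  Expected counts enter the Poisson models as fixed offsets, so
they must be strictly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .spatial import AdjacencyGraph

__all__ = [
    "ArealDataset",
    "StratifiedTable",
    "read_areal_csv",
    "write_areal_csv",
    "expected_counts_overall",
    "expected_counts_indirect",
    "crude_sir",
    "write_results_csv",
    "standardize_covariates",
]

log = logging.getLogger(__name__)

#: floor applied to expected counts in zero-population areas so the Poisson
#: offset log E stays finite
DEFAULT_E_FLOOR = 0.1

RESULTS_COLUMNS = [
    "area_id",
    "rr_shared_mean",
    "rr_shared_lo95",
    "rr_shared_hi95",
    "pr_shared_gt1",
    "rr_specific_mean_k1",
    "pr_specific_gt1_k1",
    "hotspot_class",
]


@dataclass
class ArealDataset:
    """Observed/expected counts and covariates aligned with a graph.

    ``O`` and ``E`` have shape (n_areas, n_outcomes) with n_outcomes 1 or 2;
    outcome index 0 is the primary outcome (e.g. offenders), index 1 the
    secondary one (e.g. offenses).  Row order follows ``graph.area_ids``.
    """

    graph: AdjacencyGraph
    O: np.ndarray
    E: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.graph.n_areas
        self.O = np.asarray(self.O)
        self.E = np.asarray(self.E, dtype=float)
        if self.O.ndim == 1:
            self.O = self.O[:, None]
        if self.E.ndim == 1:
            self.E = self.E[:, None]
        self.X = np.asarray(self.X, dtype=float).reshape(n, -1)
        if self.O.shape != self.E.shape:
            raise ValueError("O and E must have the same shape")
        if self.O.shape[0] != n:
            raise ValueError("row count must equal graph.n_areas")
        if self.n_outcomes not in (1, 2):
            raise ValueError("n_outcomes must be 1 or 2")
        if np.any(self.O < 0) or not np.allclose(self.O, np.round(self.O)):
            raise ValueError("observed counts must be non-negative integers")
        self.O = np.round(self.O).astype(np.int64)
        if np.any(self.E <= 0):
            raise ValueError("expected counts must be strictly positive")
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.X.shape[1])]
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names length must match X columns")

    @property
    def n_areas(self) -> int:
        return self.graph.n_areas

    @property
    def n_outcomes(self) -> int:
        return self.O.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


@dataclass
class StratifiedTable:
    """Per-area, per-stratum populations for indirect standardization.

    ``pop`` has shape (n_areas, n_strata); strata are e.g. age-sex groups.
    """

    pop: np.ndarray

    def __post_init__(self) -> None:
        self.pop = np.asarray(self.pop, dtype=float).reshape(self.pop.shape[0], -1)
        if np.any(self.pop < 0):
            raise ValueError("stratum populations must be non-negative")
        if self.pop.sum() <= 0:
            raise ValueError("at least one stratum must have positive population")


DEFAULT_SCHEMA = {
    "area_id": "area_id",
    "obs_k1": "obs_k1",
    "obs_k2": "obs_k2",
    "exp_k1": "exp_k1",
    "exp_k2": "exp_k2",
}


def read_areal_csv(
    path: str | Path,
    graph: AdjacencyGraph,
    schema: dict[str, str] | None = None,
    covariate_columns: list[str] | None = None,
) -> ArealDataset:
    """Read a one-row-per-area CSV and align it to ``graph`` order.

    ``schema`` maps logical names (area_id, obs_k1, obs_k2, exp_k1, exp_k2)
    to actual column names; obs_k2/exp_k2 are optional (single-outcome
    data).  Remaining columns named in ``covariate_columns`` (default: all
    columns ``x1..xp`` present) become covariates.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path)
    idcol = sch["area_id"]
    if idcol not in df.columns:
        raise ValueError(f"missing area-id column {idcol!r}")
    df[idcol] = df[idcol].astype(str)
    dupes = df[idcol][df[idcol].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate area ids in {path}: {dupes}")
    missing = [a for a in graph.area_ids if a not in set(df[idcol])]
    if missing:
        raise ValueError(f"areas missing from {path}: {missing}")
    extra = [a for a in df[idcol] if a not in set(graph.area_ids)]
    if extra:
        raise ValueError(f"unknown areas in {path}: {extra}")
    df = df.set_index(idcol).loc[graph.area_ids]

    have_k2 = sch["obs_k2"] in df.columns and sch["exp_k2"] in df.columns
    obs_cols = [sch["obs_k1"]] + ([sch["obs_k2"]] if have_k2 else [])
    exp_cols = [sch["exp_k1"]] + ([sch["exp_k2"]] if have_k2 else [])
    for col in obs_cols + exp_cols:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    O = df[obs_cols].to_numpy()
    E = df[exp_cols].to_numpy(dtype=float)
    bad = np.where(O < 0)[0].tolist()
    if bad:
        raise ValueError(f"negative counts in rows (graph order) {bad}")
    bad = np.where(E <= 0)[0].tolist()
    if bad:
        raise ValueError(f"non-positive expected counts in rows (graph order) {bad}")
    if covariate_columns is None:
        covariate_columns = [c for c in df.columns if c not in obs_cols + exp_cols]
    X = df[covariate_columns].to_numpy(dtype=float) if covariate_columns else np.empty((len(df), 0))
    return ArealDataset(graph, O, E, X, list(covariate_columns))


def write_areal_csv(dataset: ArealDataset, path: str | Path) -> None:
    """Write an ArealDataset in the column layout read_areal_csv expects."""
    cols: dict[str, object] = {"area_id": dataset.graph.area_ids}
    for k in range(dataset.n_outcomes):
        cols[f"obs_k{k + 1}"] = dataset.O[:, k]
    for k in range(dataset.n_outcomes):
        cols[f"exp_k{k + 1}"] = dataset.E[:, k]
    for j, name in enumerate(dataset.covariate_names):
        cols[name] = dataset.X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def _floor_expected(E: np.ndarray, floor: float) -> np.ndarray:
    zero = E <= 0
    if np.any(zero):
        log.warning(
            "%d area(s) with zero population: expected count floored at %g", zero.sum(), floor
        )
        E = np.where(zero, floor, E)
    return E


def expected_counts_overall(
    pop: np.ndarray, O_total_by_area: np.ndarray, floor: float = DEFAULT_E_FLOOR
) -> np.ndarray:
    """Expected counts from the region-wide overall rate.

    E_i = (sum_j O_j / sum_j pop_j) * pop_i, i.e. the average regional trend
    multiplied by each area's residential population.  Conserves the total,
    sum(E) = sum(O), except in degenerate zero-population areas where E is
    floored so the log offset stays finite.
    """
    pop = np.asarray(pop, dtype=float)
    O = np.asarray(O_total_by_area, dtype=float)
    if pop.shape != O.shape:
        raise ValueError("pop and O must have the same length")
    if np.any(pop < 0) or np.any(O < 0):
        raise ValueError("pop and O must be non-negative")
    total_pop = pop.sum()
    if total_pop <= 0:
        raise ValueError("total population must be positive")
    rate = O.sum() / total_pop
    return _floor_expected(rate * pop, floor)


def expected_counts_indirect(
    strata: StratifiedTable,
    O_by_area_stratum: np.ndarray,
    floor: float = DEFAULT_E_FLOOR,
) -> np.ndarray:
    """Indirectly standardized expected counts.

    Reference rates r_g = sum_i O_ig / sum_i pop_ig per stratum g; then
    E_i = sum_g r_g * pop_ig.  With a single stratum this reduces to
    :func:`expected_counts_overall`.  Conserves sum(E) = sum(O).
    """
    O = np.asarray(O_by_area_stratum, dtype=float).reshape(strata.pop.shape[0], -1)
    if O.shape != strata.pop.shape:
        raise ValueError(
            f"O_by_area_stratum shape {O.shape} does not match populations {strata.pop.shape}"
        )
    if np.any(O < 0):
        raise ValueError("event counts must be non-negative")
    pop_g = strata.pop.sum(axis=0)
    events_g = O.sum(axis=0)
    bad = (events_g > 0) & (pop_g <= 0)
    if np.any(bad):
        raise ValueError(f"strata with events but zero population: {np.where(bad)[0].tolist()}")
    rates = np.divide(events_g, pop_g, out=np.zeros_like(events_g), where=pop_g > 0)
    return _floor_expected(strata.pop @ rates, floor)


def crude_sir(O: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Standardized incidence/risk ratio O_i / E_i (the crude relative risk)."""
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if O.shape != E.shape:
        raise ValueError("O and E must have the same shape")
    if np.any(E <= 0):
        raise ValueError("expected counts must be strictly positive")
    return O / E


def standardize_covariates(dataset: ArealDataset, scale: bool = False) -> ArealDataset:
    """Return a copy with mean-centred (optionally unit-variance) covariates."""
    if dataset.n_covariates == 0:
        return dataset
    X = dataset.X - dataset.X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    return replace(dataset, X=X)


def write_results_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write per-area posterior summaries with a fixed, documented column order.

    Columns not supplied are filled with NaN so downstream consumers always
    see the same header.
    """
    out = pd.DataFrame({c: table[c] if c in table.columns else np.nan for c in RESULTS_COLUMNS})
    out.to_csv(path, index=False, float_format="%.12g")
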