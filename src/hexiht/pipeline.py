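"""Orchestration: per-case indicator extraction and cohort-level modeling.

``run_case`` turns one cell table into the per-case indicator row: global
expression percentages (ER, PR, Ki67, HER2 2+/3+ in tumor; HIF1α per
compartment), immune-cell densities (CD8+ and CD8+SATB1+ per compartment),
and the hexagonal-grid heterogeneity set (five Haralick features plus
Ashman's D) for each heterogeneity marker. ``run_cohort`` joins indicator
rows with survival records and runs the statistical layer: correlation
pruning, per-indicator cutpoint + Kaplan–Meier/log-rank, and the two
multivariable Cox models (conventional covariates vs conventional +
heterogeneity/immune indicators), reporting likelihood-ratio statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cellmap import CellMap, cell_density, global_percent
from .errors import ConfigError, UndefinedIndicatorError
from .heterogeneity import compute_indicators
from .hexgrid import DEFAULT_MIN_CELLS, DEFAULT_SIDE_UM
from .survival import (
    CutoffResult,
    cox_fit,
    logrank_test,
    optimal_cutoff,
    prune_correlated,
)

logger = logging.getLogger("hexiht")

#: Markers for which heterogeneity indicators are extracted (sufficient
#: expression dynamic range); low-expression markers are summarized as
#: global percentages or densities instead.
HETEROGENEITY_MARKERS = ("er", "pr", "ki67")


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults match the published method."""

    markers: Sequence[str] = HETEROGENEITY_MARKERS
    side_um: float = DEFAULT_SIDE_UM
    min_cells: int = DEFAULT_MIN_CELLS
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_case(cellmap: CellMap, config: RunConfig | None = None) -> pd.Series:
    """Compute the full indicator row for one case.

    Indicators that are undefined on this case (marker absent, zero
    evaluable cells, too few hexagons) are reported as NaN and logged;
    the run continues for the remaining markers.
    """
    config = config or RunConfig()
    row: dict[str, float | str | int] = {"case_id": cellmap.case_id,
                                         "seed": config.seed}

    def attempt(key, fn, *args, **kwargs):
        try:
            row[key] = fn(*args, **kwargs)
        except (UndefinedIndicatorError, ConfigError) as err:
            row[key] = np.nan
            logger.warning("case %s: %s undefined (%s)", cellmap.case_id, key, err)

    for marker in ("er", "pr", "ki67", "her2"):
        attempt(f"{marker}_pct", global_percent, cellmap, marker, "tumor")
    for comp in ("tumor", "stroma"):
        suffix = "t" if comp == "tumor" else "s"
        attempt(f"hif1a_pct_{suffix}", global_percent, cellmap, "hif1a", comp)
        attempt(f"cd8_d_{suffix}", cell_density, cellmap, "cd8", comp)
        attempt(f"cd8_satb1_d_{suffix}", cell_density, cellmap, ["cd8", "satb1"], comp)

    rng = np.random.default_rng(config.seed)
    for marker in config.markers:
        sub_seed = int(rng.integers(2**31 - 1))
        try:
            ind = compute_indicators(
                cellmap, marker, side=config.side_um,
                min_cells=config.min_cells, seed=sub_seed,
            )
        except ConfigError as err:
            logger.warning("case %s: heterogeneity for %s failed (%s)",
                           cellmap.case_id, marker, err)
            continue
        for feat in ("contrast", "dissimilarity", "entropy", "energy",
                     "homogeneity", "ashman_d"):
            row[f"{marker}_{feat}"] = getattr(ind, feat)
        row[f"{marker}_n_hexagons"] = ind.n_hexagons
    return pd.Series(row)


@dataclass
class CohortReport:
    """Everything the statistical layer produces for one cohort."""

    retained_indicators: list[str]
    cutoffs: dict[str, CutoffResult]
    logrank: dict[str, tuple[float, float]]
    conventional_model: object
    extended_model: object
    config_hash: str

    @property
    def lr_gain(self) -> float:
        return self.extended_model.lr_statistic - self.conventional_model.lr_statistic

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, cut in self.cutoffs.items():
            stat, p = self.logrank[name]
            rows.append({
                "indicator": name, "cutoff": cut.cutoff,
                "n_low": cut.n_low, "n_high": cut.n_high,
                "hr_high_vs_low": cut.hazard_ratio,
                "logrank_statistic": stat, "logrank_p": p,
                "selection_biased": cut.selection_biased,
            })
        return pd.DataFrame(rows)


def run_cohort(
    data: pd.DataFrame,
    conventional: Sequence[str],
    extended: Sequence[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    prune_threshold: float = 0.90,
    prune_priority: Sequence[str] | None = None,
    min_group_fraction: float = 0.10,
    compute_cutoffs: bool = True,
    config: RunConfig | None = None,
) -> CohortReport:
    """Statistical layer over a joined indicator + survival table.

    ``conventional`` and ``extended`` name the covariate sets of the two
    Cox models (the extended set adds heterogeneity and immune-density
    indicators to the conventional clinicopathology + expression set).
    Correlation pruning is applied to each set before fitting.
    """
    config = config or RunConfig()
    if len(data) < 2:
        raise ConfigError("cohort analysis needs >= 2 cases")
    if int(data[event_col].sum()) < 1:
        raise ConfigError("cohort contains no observed events; "
                          "survival models cannot be fitted")
    all_covs = list(dict.fromkeys([*conventional, *extended]))
    missing = [c for c in all_covs if c not in data.columns]
    if missing:
        raise ConfigError(f"covariates missing from table: {missing}")

    retained = prune_correlated(
        data[all_covs], threshold=prune_threshold,
        priority=prune_priority if prune_priority is not None
        else [c for c in all_covs],
    )
    cutoffs: dict[str, CutoffResult] = {}
    logrank: dict[str, tuple[float, float]] = {}
    times = data[duration_col].to_numpy(dtype=float)
    events = data[event_col].to_numpy(dtype=int)
    for name in retained if compute_cutoffs else []:
        values = data[name].to_numpy(dtype=float)
        ok = ~np.isnan(values)
        try:
            cut = optimal_cutoff(values[ok], times[ok], events[ok],
                                 min_group_fraction=min_group_fraction)
        except UndefinedIndicatorError as err:
            logger.warning("indicator %s: no cutoff (%s)", name, err.reason)
            continue
        cutoffs[name] = cut
        high = (values[ok] > cut.cutoff).astype(int)
        logrank[name] = logrank_test(high, times[ok], events[ok])

    conv = [c for c in conventional if c in retained]
    ext = [c for c in extended if c in retained]
    conventional_model = cox_fit(data, conv, duration_col, event_col)
    extended_model = cox_fit(data, ext, duration_col, event_col)
    return CohortReport(
        retained_indicators=retained,
        cutoffs=cutoffs,
        logrank=logrank,
        conventional_model=conventional_model,
        extended_model=extended_model,
        config_hash=config.config_hash(),
    )
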