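"""Intratumoral heterogeneity indicators from a filtered hexagon lattice.

Per-hexagon positivity percentages are ranked linearly into ten intervals
(0–10%, >10–20%, …, >90–100%). Over all adjacent pairs of retained
hexagons a 10×10 symmetric co-occurrence matrix is accumulated and
normalized, from which five Haralick texture features are computed:

    contrast      Σ (i−j)²·P[i,j]
    dissimilarity Σ |i−j|·P[i,j]
    entropy       −Σ P[i,j]·ln P[i,j]          (0·ln 0 := 0)
    energy        Σ P[i,j]²                     (angular second moment)
    homogeneity   Σ P[i,j]/(1+(i−j)²)           (inverse difference moment)

Bimodality of the per-hexagon percentage distribution is summarized by
Ashman's D, computed from a two-component Gaussian mixture fitted by EM:

    D = √2·|μ1−μ2| / √(σ1²+σ2²)

D ≳ 2 indicates a clearly bimodal distribution. The mixture is fitted by
seeded multi-start EM (quantile initialization plus random perturbations)
with a variance floor and a minimum component weight, and the result is
accepted only if its BIC improves on a single Gaussian; otherwise the
distribution is treated as unimodal (coincident components, D = 0). Both
indicator families are undefined (not zero) when the lattice is too
sparse: no adjacent retained pair for the texture set, fewer than
``MIN_HEXAGONS_ASHD`` retained hexagons for Ashman's D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cellmap import CellMap
from .errors import ConfigError, UndefinedIndicatorError
from .hexgrid import (
    DEFAULT_MIN_CELLS,
    DEFAULT_SIDE_UM,
    HexLattice,
    assign_cells,
    build_grid,
    filter_hexes,
    neighbor_pairs,
)

N_BINS = 10
MIN_HEXAGONS_ASHD = 10

# EM settings for the mixture behind Ashman's D. The variance floor keeps
# components from collapsing onto single points; the weight floor keeps a
# component from shrinking onto a handful of outliers (either degeneracy
# would inflate D arbitrarily on unimodal data).
EM_RESTARTS = 5
EM_VARIANCE_FLOOR = 1e-4
EM_WEIGHT_FLOOR = 0.05
EM_TOL = 1e-8
EM_MAX_ITER = 500


def bin_percent(p: float | np.ndarray) -> np.ndarray | int:
    """Decile bin index in 1..10: bin 1 is [0, 10], bin k is (10(k−1), 10k]."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 100)).any():
        raise ConfigError("percentages must lie in [0, 100]")
    bins = np.ceil(arr / 10.0).astype(np.int64)
    bins = np.clip(bins, 1, N_BINS)
    return int(bins) if np.isscalar(p) or arr.ndim == 0 else bins


@dataclass(frozen=True)
class CoocMatrix:
    """Normalized symmetric 10×10 co-occurrence matrix over adjacent hexagons."""

    P: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        P = self.P
        if P.shape != (N_BINS, N_BINS):
            raise ConfigError(f"expected {N_BINS}x{N_BINS} matrix, got {P.shape}")
        if (P < 0).any() or not math.isclose(P.sum(), 1.0, abs_tol=1e-9):
            raise ConfigError("co-occurrence matrix must be non-negative and sum to 1")


@dataclass(frozen=True)
class MixtureFit:
    """Two-component univariate Gaussian mixture parameters."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float


@dataclass
class HeterogeneityIndicators:
    """The per-case heterogeneity set for one marker; NaN where undefined."""

    marker: str
    contrast: float = float("nan")
    dissimilarity: float = float("nan")
    entropy: float = float("nan")
    energy: float = float("nan")
    homogeneity: float = float("nan")
    ashman_d: float = float("nan")
    n_hexagons: int = 0
    n_pairs: int = 0
    seed: int | None = None
    reason: str | None = None


def cooccurrence(lattice: HexLattice) -> CoocMatrix:
    """Accumulate the decile co-occurrence matrix over retained adjacent pairs.

    Each unordered pair with bins (a, b) contributes equal mass to (a, b)
    and (b, a); a single normalization makes the entries probabilities.
    """
    pairs = neighbor_pairs(lattice)
    if not pairs:
        raise UndefinedIndicatorError(
            "no_adjacent_pairs", "no adjacent retained hexagon pairs"
        )
    ret = lattice.retained
    bins = {
        (int(q), int(r)): int(b)
        for q, r, b in zip(ret["q"], ret["r"], bin_percent(ret["percent"].to_numpy()))
    }
    P = np.zeros((N_BINS, N_BINS), dtype=float)
    for a_key, b_key in pairs:
        a, b = bins[a_key] - 1, bins[b_key] - 1
        P[a, b] += 1.0
        P[b, a] += 1.0
    P /= P.sum()
    return CoocMatrix(P=P, n_pairs=len(pairs))


def haralick(cooc: CoocMatrix | np.ndarray) -> tuple[float, float, float, float, float]:
    """(contrast, dissimilarity, entropy, energy, homogeneity) of a GLCM."""
    P = cooc.P if isinstance(cooc, CoocMatrix) else np.asarray(cooc, dtype=float)
    if P.shape[0] != P.shape[1]:
        raise ConfigError("co-occurrence matrix must be square")
    if (P < 0).any() or not math.isclose(P.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ConfigError("matrix must be normalized to sum 1 with entries >= 0")
    n = P.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = i - j
    contrast = float((d * d * P).sum())
    dissimilarity = float((np.abs(d) * P).sum())
    nz = P[P > 0]
    entropy = max(0.0, float(-(nz * np.log(nz)).sum()))
    energy = float((P * P).sum())
    homogeneity = float((P / (1.0 + d * d)).sum())
    return contrast, dissimilarity, entropy, energy, homogeneity


def _em_once(
    x: np.ndarray, mu: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """One EM run from the given mean initialization; returns (ll, mu, var, w)."""
    n = len(x)
    s2 = max(float(x.var()), EM_VARIANCE_FLOOR)
    var = np.full(2, max(s2 / 4.0, EM_VARIANCE_FLOOR))
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    ll = ll_old
    for _ in range(EM_MAX_ITER):
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2.0 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        ll = float((np.log(tot) + m).sum())
        resp = p / tot
        nk = resp.sum(axis=0)
        w = np.clip(nk / n, EM_WEIGHT_FLOOR, 1.0 - EM_WEIGHT_FLOOR)
        w = w / w.sum()
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, EM_VARIANCE_FLOOR)
        if abs(ll - ll_old) < EM_TOL * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    return ll, mu, var, w


def fit_mixture(values: np.ndarray, rng: np.random.Generator) -> MixtureFit:
    """Fit a two-component Gaussian mixture by seeded multi-start EM.

    Restarts start from the (25%, 75%) quantiles plus random perturbations;
    the best log-likelihood solution is kept. If BIC does not prefer two
    components over one Gaussian, the sample is treated as unimodal and the
    collapsed fit (coincident components) is returned.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    scale = float(x.std()) + 1e-12
    base = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for k in range(EM_RESTARTS):
        mu0 = base if k == 0 else base + rng.normal(0.0, 0.5 * scale, 2)
        result = _em_once(x, mu0.copy())
        if best is None or result[0] > best[0]:
            best = result
    ll2, mu, var, w = best
    # single-Gaussian reference: 2 free params vs the mixture's 5
    v1 = max(float(x.var()), EM_VARIANCE_FLOOR)
    ll1 = -0.5 * n * (math.log(2.0 * math.pi * v1) + 1.0)
    bic1 = -2.0 * ll1 + 2.0 * math.log(n)
    bic2 = -2.0 * ll2 + 5.0 * math.log(n)
    if bic1 <= bic2:
        m = float(x.mean())
        s = math.sqrt(v1)
        return MixtureFit(means=(m, m), sds=(s, s), weights=(0.5, 0.5),
                          log_likelihood=ll1)
    order = np.argsort(mu)
    return MixtureFit(
        means=tuple(float(m) for m in mu[order]),
        sds=tuple(float(s) for s in np.sqrt(var[order])),
        weights=tuple(float(v) for v in w[order]),
        log_likelihood=ll2,
    )


def ashman_d(
    percents: np.ndarray, rng: np.random.Generator
) -> tuple[float, MixtureFit]:
    """Ashman's D bimodality of the per-hexagon percentage distribution."""
    x = np.asarray(percents, dtype=float)
    if len(x) < MIN_HEXAGONS_ASHD:
        raise UndefinedIndicatorError(
            "too_few_hexagons",
            f"Ashman's D needs >= {MIN_HEXAGONS_ASHD} retained hexagons, got {len(x)}",
        )
    fit = fit_mixture(x, rng)
    mu1, mu2 = fit.means
    s1, s2 = fit.sds
    d = math.sqrt(2.0) * abs(mu1 - mu2) / math.sqrt(s1 * s1 + s2 * s2)
    return d, fit


def compute_indicators(
    cellmap: CellMap,
    marker: str,
    side: float = DEFAULT_SIDE_UM,
    min_cells: int = DEFAULT_MIN_CELLS,
    compartment: str = "tumor",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> HeterogeneityIndicators:
    """End-to-end heterogeneity set for one marker on one case.

    Builds a randomly placed grid, assigns and filters hexagons, then
    computes the Haralick set from the co-occurrence matrix and Ashman's D
    from the retained percentage vector. Undefined indicators propagate as
    NaN with a ``reason`` code rather than as zeros.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    grid = build_grid(cellmap.bounds, side=side, rng=rng)
    lattice = filter_hexes(assign_cells(cellmap, grid, marker, compartment), min_cells)
    out = HeterogeneityIndicators(
        marker=marker, n_hexagons=int(lattice.retained.shape[0]), seed=seed
    )
    try:
        cooc = cooccurrence(lattice)
        out.n_pairs = cooc.n_pairs
        (out.contrast, out.dissimilarity, out.entropy,
         out.energy, out.homogeneity) = haralick(cooc)
    except UndefinedIndicatorError as err:
        out.reason = err.reason
    try:
        out.ashman_d, _ = ashman_d(lattice.percents, rng)
    except UndefinedIndicatorError as err:
        out.reason = err.reason if out.reason is None else out.reason
    return out
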