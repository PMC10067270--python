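"""Global-epistasis scatters, least-squares fits, and slope decomposition.

For a focal mutation i, global epistasis is the systematic dependence of its
fitness effect ΔF_i = F_{B+i} − F_B on the fitness F_B of the background it
is added to.  This module computes, per focal mutation:

* the (F_B, ΔF) scatter over all usable backgrounds B(i);
* its ordinary least-squares fit (slope b_i, intercept a_i, R²);
* the microscopic prediction of the slope, truncated at pairwise epistasis,

      b_i ≈ Σ_{j≠i} ⟨ε_ij⟩·⟨δF_j⟩_B(i)  /  Σ_{j≠i} (⟨δF_j⟩_B(i))²
          = Σ_{j≠i} ω_ij·β_ij ,

  where ⟨ε_ij⟩ is the average four-corner epistasis of the pair over every
  background lacking both, ⟨δF_j⟩_B(i) the average fitness effect of partner
  j on the focal mutation's backgrounds, ω_ij = (⟨δF_j⟩)²/Σ(⟨δF_j⟩)² the
  weight of partner j, and β_ij = ⟨ε_ij⟩/⟨δF_j⟩ its individual slope
  contribution.  The predicted intercept is a_i = ⟨ΔF⟩ − b_i·⟨F_B⟩ with
  both averages over the focal scatter.  An equivalent form in Walsh
  coefficients, b_i ≈ 2·Σ f_ij(f_j − f_ij) / Σ (f_j − f_ij)², is exposed as
  ``mode="walsh"``; on complete pairwise-truncated landscapes the two modes
  agree exactly.

Averages use uniform weight per background.  On incomplete landscapes only
computable terms enter and every average reports the count used.  A partner
with ⟨δF_j⟩ = 0 but ⟨ε_ij⟩ ≠ 0 has an undefined β_ij (reported as NaN,
ω_ij = 0); the sum form of the slope stays well-defined and is
authoritative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .landscape import (
    Landscape,
    LandscapeError,
    backgrounds_of,
)
from .walsh import to_walsh

__all__ = [
    "GlobalEpistasisFit",
    "PartnerTerm",
    "SlopeDecomposition",
    "DecomposeResult",
    "scatter",
    "ols_fit",
    "avg_background_effect",
    "avg_pairwise_epistasis",
    "predicted_slope",
    "decompose_report",
    "classify_pattern",
    "fit_all",
    "house_of_cards_summary",
    "GlobalEpistasisRegression",
    "SlopeDecomposer",
]

PATTERN_LABELS = (
    "diminishing returns",
    "increasing returns",
    "increasing costs",
    "decreasing costs",
    "flat",
    "mixed-sign",
)


@dataclasses.dataclass
class GlobalEpistasisFit:
    """OLS fit of ΔF versus F_B for one focal mutation.

    ``degenerate`` flags scatters with zero variance in F_B (slope is NaN)
    or constant ΔF (slope 0, R² reported as 0 by convention).
    """

    focal: str
    points: np.ndarray  # (n, 2): columns F_B, ΔF
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    p_value: float
    degenerate: bool = False

    @property
    def mean_dF(self) -> float:
        return float(self.points[:, 1].mean())

    @property
    def mean_FB(self) -> float:
        return float(self.points[:, 0].mean())


def scatter(landscape: Landscape, focal: int | str) -> np.ndarray:
    """(F_B, ΔF) pairs for a focal mutation, one per usable background."""
    fi = landscape.locus_index(focal)
    if landscape.is_complete:
        dense = landscape.dense_fitness()
        idx = np.arange(2 ** landscape.n_loci)
        bg = idx[(idx >> fi) & 1 == 0]
        fb = dense[bg]
        df = dense[bg | (1 << fi)] - fb
        return np.column_stack([fb, df])
    bset = backgrounds_of(landscape, fi)
    if len(bset) == 0:
        raise LandscapeError(
            f"no usable background for focal locus {landscape.locus_names[fi]!r}"
        )
    points = np.empty((len(bset), 2))
    for row, b in enumerate(bset.backgrounds):
        plus = b.copy()
        plus[fi] = 1
        fb = landscape.fitness_of(b)
        points[row] = fb, landscape.fitness_of(plus) - fb
    return points


def ols_fit(points: np.ndarray, focal: str = "") -> GlobalEpistasisFit:
    """Ordinary least squares of ΔF on F_B.

    R² is the squared Pearson correlation (identical to the coefficient of
    determination for simple OLS); the p-value is the two-sided t-test of
    slope = 0.  Zero variance in F_B yields a flagged degenerate result
    rather than a crash; fewer than 3 points is an error.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (F_B, ΔF)")
    n = points.shape[0]
    if n < 3:
        raise ValueError(f"need ≥ 3 points for a fit, got {n}")
    x, y = points[:, 0], points[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx == 0.0:
        return GlobalEpistasisFit(
            focal, points, np.nan, np.nan, np.nan, n, np.nan, degenerate=True
        )
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    # a response whose spread sits at float-rounding scale is constant;
    # without this, an additive landscape's ~1e-16 ΔF jitter can fake a trend
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return GlobalEpistasisFit(
            focal, points, 0.0, float(y.mean()), 0.0, n, 1.0, degenerate=True
        )
    r_squared = sxy**2 / (sxx * syy)
    rss = syy - slope * sxy
    if rss <= 0.0:  # numerically perfect fit
        p_value = 0.0 if slope != 0.0 else 1.0
        r_squared = min(r_squared, 1.0)
    else:
        se = np.sqrt(rss / (n - 2) / sxx)
        t = slope / se
        p_value = 2.0 * stats.t.sf(abs(t), n - 2)
    return GlobalEpistasisFit(
        focal, points, float(slope), intercept, float(r_squared), n, float(p_value)
    )


def classify_pattern(fit: GlobalEpistasisFit, alpha: float = 0.05) -> str:
    """Name the global-epistasis pattern of a fitted scatter.

    The mutation is called beneficial/deleterious when every ΔF shares a
    sign, else mixed-sign; the slope is called nonzero when its two-sided
    t-test rejects at level ``alpha``.  Beneficial + negative slope is
    diminishing returns, beneficial + positive is increasing returns,
    deleterious + negative is increasing costs, deleterious + positive is
    decreasing costs; a non-rejected or degenerate slope is flat.
    """
    if fit.degenerate or not np.isfinite(fit.slope):
        return "flat"
    if fit.p_value >= alpha:
        return "flat"
    dF = fit.points[:, 1]
    if np.all(dF > 0):
        return "diminishing returns" if fit.slope < 0 else "increasing returns"
    if np.all(dF < 0):
        return "increasing costs" if fit.slope < 0 else "decreasing costs"
    return "mixed-sign"


# ---------------------------------------------------------------------------
# background-averaged microscopic quantities


def avg_background_effect(
    landscape: Landscape, j: int | str, focal: int | str
) -> tuple[float, int]:
    """⟨δF_j⟩_B(i): mean effect of partner j on the focal backgrounds.

    Averaged over every background lacking BOTH the focal locus and j for
    which both B and B+j are measured (adding j requires j absent; B(i)
    requires the focal absent).  Returns ``(mean, n_used)``.
    """
    ji = landscape.locus_index(j)
    fi = landscape.locus_index(focal)
    if ji == fi:
        raise LandscapeError("partner and focal locus must differ")
    total, n_used = 0.0, 0
    G = landscape.genotypes
    mask = (G[:, fi] == 0) & (G[:, ji] == 0)
    for g in G[mask]:
        plus = g.copy()
        plus[ji] = 1
        row = landscape.index_of(plus)
        if row >= 0:
            total += landscape.fitness[row] - landscape.fitness_of(g)
            n_used += 1
    if n_used == 0:
        raise LandscapeError(
            f"no background supports the effect of {landscape.locus_names[ji]!r} "
            f"on B({landscape.locus_names[fi]!r})"
        )
    return total / n_used, n_used


def avg_pairwise_epistasis(
    landscape: Landscape, i: int | str, j: int | str
) -> tuple[float, int]:
    """⟨ε_ij⟩: mean four-corner epistasis over every eligible background.

    A background is eligible when it lacks both loci and all four corner
    genotypes B, B+i, B+j, B+i+j are measured.  Returns ``(mean, n_used)``.
    """
    ii = landscape.locus_index(i)
    jj = landscape.locus_index(j)
    if ii == jj:
        raise LandscapeError("pairwise epistasis needs two distinct loci")
    total, n_used = 0.0, 0
    G = landscape.genotypes
    F = landscape.fitness
    mask = (G[:, ii] == 0) & (G[:, jj] == 0)
    for g in G[mask]:
        rows = []
        for bits in ((0, 0), (1, 0), (0, 1), (1, 1)):
            corner = g.copy()
            corner[ii], corner[jj] = bits
            rows.append(landscape.index_of(corner))
        if min(rows) < 0:
            continue
        f00, f10, f01, f11 = (F[r] for r in rows)
        total += f11 - f10 - f01 + f00
        n_used += 1
    if n_used == 0:
        raise LandscapeError(
            f"no complete quartet for pair "
            f"({landscape.locus_names[ii]!r}, {landscape.locus_names[jj]!r})"
        )
    return total / n_used, n_used


# ---------------------------------------------------------------------------
# slope decomposition


@dataclasses.dataclass
class PartnerTerm:
    """One partner mutation's contribution to a focal slope."""

    partner: str
    avg_epistasis: float  # ⟨ε_ij⟩
    n_epistasis_terms: int
    avg_effect: float  # ⟨δF_j⟩_B(i)
    n_effect_terms: int
    omega: float  # ω_ij, weight; Σ_j ω_ij = 1
    beta: float  # β_ij = ⟨ε_ij⟩/⟨δF_j⟩; NaN when avg_effect = 0
    product: float  # ⟨ε_ij⟩ × ⟨δF_j⟩_B(i)


@dataclasses.dataclass
class SlopeDecomposition:
    """Microscopic (pairwise-truncated) prediction of a focal slope."""

    focal: str
    partners: list[PartnerTerm]
    predicted_slope: float
    predicted_intercept: float
    mode: str
    degenerate: bool = False


@dataclasses.dataclass
class DecomposeResult:
    """Side-by-side microscopic prediction and least-squares fit."""

    decomposition: SlopeDecomposition
    fit: GlobalEpistasisFit


def predicted_slope(
    landscape: Landscape, focal: int | str, mode: str = "averages"
) -> SlopeDecomposition:
    """Predict a focal mutation's slope from pairwise microscopic terms.

    ``mode="averages"`` uses the background-averaged ⟨ε_ij⟩ and
    ⟨δF_j⟩_B(i) directly (works on incomplete landscapes, skipping
    unmeasurable terms); ``mode="walsh"`` uses the f-coefficient form,
    which requires a complete landscape.  On complete pairwise-truncated
    landscapes the two agree exactly.
    """
    fi = landscape.locus_index(focal)
    names = landscape.locus_names

    terms: list[tuple[str, float, int, float, int]] = []
    if mode == "averages":
        for j in range(landscape.n_loci):
            if j == fi:
                continue
            try:
                eps, n_eps = avg_pairwise_epistasis(landscape, fi, j)
                eff, n_eff = avg_background_effect(landscape, j, fi)
            except LandscapeError:
                continue
            terms.append((names[j], eps, n_eps, eff, n_eff))
    elif mode == "walsh":
        expansion = to_walsh(landscape, max_order=min(2, landscape.n_loci))
        n_bg = 2 ** max(landscape.n_loci - 2, 0)
        for j in range(landscape.n_loci):
            if j == fi:
                continue
            f_j = expansion.coefficient(j)
            f_ij = expansion.coefficient(fi, j)
            # identities on pairwise landscapes: ⟨ε_ij⟩ = 4·f_ij, ⟨δF_j⟩_B(i) = 2·(f_j − f_ij)
            terms.append((names[j], 4.0 * f_ij, n_bg, 2.0 * (f_j - f_ij), n_bg))
    else:
        raise LandscapeError(f"unknown prediction mode {mode!r}")

    if not terms:
        raise LandscapeError(
            f"no partner with computable terms for focal {names[fi]!r}"
        )

    denom = sum(eff**2 for _, _, _, eff, _ in terms)
    degenerate = denom == 0.0
    slope = (
        np.nan
        if degenerate
        else sum(eps * eff for _, eps, _, eff, _ in terms) / denom
    )
    partners = []
    for name, eps, n_eps, eff, n_eff in terms:
        omega = 0.0 if degenerate else eff**2 / denom
        beta = eps / eff if eff != 0.0 else np.nan
        partners.append(
            PartnerTerm(name, eps, n_eps, eff, n_eff, omega, beta, eps * eff)
        )

    points = scatter(landscape, fi)
    intercept = (
        np.nan
        if degenerate
        else float(points[:, 1].mean() - slope * points[:, 0].mean())
    )
    return SlopeDecomposition(
        names[fi], partners, float(slope), intercept, mode, degenerate
    )


def decompose_report(
    landscape: Landscape, focal: int | str, mode: str = "averages"
) -> DecomposeResult:
    """Per-focal table comparing the microscopic prediction with OLS."""
    decomposition = predicted_slope(landscape, focal, mode=mode)
    fit = ols_fit(scatter(landscape, focal), focal=decomposition.focal)
    return DecomposeResult(decomposition, fit)


def fit_all(
    landscape: Landscape, alpha: float = 0.05
) -> list[tuple[GlobalEpistasisFit, str]]:
    """OLS fit + pattern label for every locus (fits with < 3 points raise)."""
    out = []
    for name in landscape.locus_names:
        fit = ols_fit(scatter(landscape, name), focal=name)
        out.append((fit, classify_pattern(fit, alpha)))
    return out


def house_of_cards_summary(
    n_loci: int = 6,
    mean: float = 1.0,
    sd: float = 0.2,
    n_replicates: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Regression-to-the-mean statistics on replicate house-of-cards landscapes.

    Simulates ``n_replicates`` complete landscapes with genotype fitness
    iid Normal(mean, sd), fits every mutation's ΔF-vs-F_B scatter, and
    returns the grand means of slope, R² and intercept over all fits
    (expected near −1, 0.5 and the distribution mean respectively).
    """
    from .simulate import HoCSpec, simulate_hoc

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(2**31, size=n_replicates)
    slopes, r2s, intercepts = [], [], []
    names = tuple(f"m{k + 1}" for k in range(n_loci))
    for s in child_seeds:
        ls = simulate_hoc(HoCSpec(names, mean=mean, sd=sd, seed=int(s)))
        for name in names:
            fit = ols_fit(scatter(ls, name), focal=name)
            slopes.append(fit.slope)
            r2s.append(fit.r_squared)
            intercepts.append(fit.intercept)
    return {
        "slope": float(np.mean(slopes)),
        "r_squared": float(np.mean(r2s)),
        "intercept": float(np.mean(intercepts)),
        "n_fits": len(slopes),
    }


# ---------------------------------------------------------------------------
# estimator interfaces


class GlobalEpistasisRegression(BaseEstimator):
    """Per-mutation global-epistasis regression on (genotype matrix, fitness).

    ``fit(X, y)`` treats each row of the 0/1 matrix ``X`` as a measured
    genotype with fitness ``y`` and regresses, for every locus, the fitness
    effect ΔF against background fitness F_B over all usable backgrounds.

    Attributes (after fit): ``slopes_``, ``intercepts_``, ``r_squared_``,
    ``p_values_``, ``n_points_`` (arrays over loci), ``labels_`` (pattern
    names), ``fits_`` (full :class:`GlobalEpistasisFit` records).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        names = tuple(f"m{k + 1}" for k in range(X.shape[1]))
        landscape = Landscape(names, X, y)
        results = fit_all(landscape, alpha=self.alpha)
        self.fits_ = [fit for fit, _ in results]
        self.labels_ = [label for _, label in results]
        self.slopes_ = np.array([f.slope for f in self.fits_])
        self.intercepts_ = np.array([f.intercept for f in self.fits_])
        self.r_squared_ = np.array([f.r_squared for f in self.fits_])
        self.p_values_ = np.array([f.p_value for f in self.fits_])
        self.n_points_ = np.array([f.n_points for f in self.fits_])
        self.n_features_in_ = X.shape[1]
        return self


class SlopeDecomposer(BaseEstimator):
    """Microscopic slope decomposition for every locus of a landscape.

    ``fit(X, y)`` computes, per focal locus, the per-partner ⟨ε_ij⟩,
    ⟨δF_j⟩_B(i), ω_ij and β_ij terms and the predicted slope/intercept,
    alongside the OLS fit for comparison.

    Attributes: ``decompositions_`` (list of :class:`DecomposeResult`),
    ``predicted_slopes_``, ``ols_slopes_``.
    """

    def __init__(self, mode: str = "averages"):
        self.mode = mode

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        names = tuple(f"m{k + 1}" for k in range(X.shape[1]))
        landscape = Landscape(names, X, y)
        self.decompositions_ = [
            decompose_report(landscape, name, mode=self.mode) for name in names
        ]
        self.predicted_slopes_ = np.array(
            [d.decomposition.predicted_slope for d in self.decompositions_]
        )
        self.ols_slopes_ = np.array([d.fit.slope for d in self.decompositions_])
        self.n_features_in_ = X.shape[1]
        return self
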