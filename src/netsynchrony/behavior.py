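"""Brain-behavior screening: Spearman correlations with bootstrap CIs.

Cognitive measures are correlated with per-subject (scaled) eigenvalues
component by component.  Rank correlation accommodates non-normal score
distributions; 95% confidence intervals come from a seeded percentile
bootstrap over paired resamples.  A result is significant only when its
CI excludes zero AND its p-value survives multiple-comparison
correction over the full measure x component grid (Benjamini-Hochberg
by default, Bonferroni as a switch).  Scaled-eigenvalue screening
excludes component 1, whose scaled value is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_MEASURES",
    "CorrelationResult",
    "spearman_ci",
    "screen",
]

DEFAULT_MEASURES = (
    "cognitive_flexibility",
    "continuous_performance",
    "delay_discounting",
    "executive_inhibition",
    "working_memory",
    "episodic_memory",
    "language_comprehension",
    "processing_speed",
    "fluid_intelligence",
    "language_decoding",
    "spatial_orientation",
    "verbal_memory",
)


@dataclass
class CorrelationResult:
    measure: str
    component: int
    statistic: str      # "eigenvalue" | "scaled_eigenvalue"
    rho: float
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if np.isfinite(self.ci_low) and not (self.ci_low - 1e-12 <= self.rho <= self.ci_high + 1e-12):
            raise ValueError("rho must lie within its confidence interval")


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def spearman_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    measure: str = "",
    component: int = 0,
    statistic: str = "eigenvalue",
) -> CorrelationResult:
    """Spearman rho with a percentile-bootstrap 95% CI.

    Ties receive average ranks; the two-sided p-value uses the
    large-sample t approximation.  The bootstrap resamples (x, y) pairs
    with replacement, ``n_boot`` times, from a seeded stream; with
    ``n_boot=0`` the CI bounds are NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input")
    rho, p = stats.spearmanr(x, y)
    ci_low = ci_high = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        rx = _rank(x[idx])
        ry = _rank(y[idx])
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            boots = (rx * ry).sum(axis=1) / denom
        boots = boots[np.isfinite(boots)]
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        # the point estimate can fall a hair outside the percentile band
        ci_low = min(ci_low, rho)
        ci_high = max(ci_high, rho)
    return CorrelationResult(
        measure=measure,
        component=component,
        statistic=statistic,
        rho=float(rho),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(p),
    )


def screen(
    eigs: pd.DataFrame,
    behavior: pd.DataFrame,
    statistic: str = "eigenvalue",
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Correlate every measure with every component; select significant sets.

    ``eigs`` is a subjects x components table (integer column labels,
    1-based); ``behavior`` is indexed by the same subjects with one
    column per measure.  The correction family is the full
    measure x component grid.  Returns the grid as a DataFrame and, per
    measure, the sorted list of selected components.
    """
    if statistic not in ("eigenvalue", "scaled_eigenvalue"):
        raise ValueError("statistic must be 'eigenvalue' or 'scaled_eigenvalue'")
    if correction not in ("fdr_bh", "bonferroni"):
        raise ValueError("correction must be 'fdr_bh' or 'bonferroni'")
    if not eigs.index.equals(behavior.index):
        if set(eigs.index) != set(behavior.index):
            raise ValueError("eigenvalue and behavior tables are keyed by different subjects")
        behavior = behavior.loc[eigs.index]
    components = [int(c) for c in eigs.columns]
    if statistic == "scaled_eigenvalue":
        components = [c for c in components if c != 1]
    results: list[CorrelationResult] = []
    for measure in behavior.columns:
        y = behavior[measure].to_numpy(dtype=float)
        for comp in components:
            res = spearman_ci(
                eigs[comp].to_numpy(dtype=float),
                y,
                n_boot=n_boot,
                seed=_pair_seed(seed, measure, comp),
                measure=str(measure),
                component=comp,
                statistic=statistic,
            )
            results.append(res)
    pvals = np.array([r.p for r in results])
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=correction)
    for r, adj, rej in zip(results, p_adj, reject):
        r.p_adjusted = float(adj)
        ci_excludes_zero = (r.ci_low > 0) or (r.ci_high < 0)
        r.significant = bool(rej) and ci_excludes_zero
    grid = pd.DataFrame(
        {
            "measure": [r.measure for r in results],
            "component": [r.component for r in results],
            "statistic": [r.statistic for r in results],
            "rho": [r.rho for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )
    selected = {
        str(measure): sorted(
            grid.loc[(grid["measure"] == str(measure)) & grid["significant"], "component"].tolist()
        )
        for measure in behavior.columns
    }
    return grid, selected


def _pair_seed(seed: int, measure: str, comp: int) -> int:
    from ._seeds import derive_seed

    return derive_seed(seed, "spearman_boot", measure, comp)
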