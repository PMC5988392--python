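"""Eigenvalue-product network-interaction features and LASSO prediction.

The interaction of a subset S of screened components is quantified as
the product of their eigenvalues — geometrically the hypervolume of the
spanned eigensubspace.  All 2^k subsets of the k screened components
are enumerated (the empty subset carries the intercept and is never
penalized), a LASSO fitted on the training partition selects a sparse
set of products, and prediction quality is the Pearson correlation
between predicted and measured scores in the held-out test partition.

No information flows from test to training: screening, feature
standardization and penalty selection consume training rows only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from ._seeds import derive_seed

__all__ = [
    "InteractionFeatureSpec",
    "InteractionModel",
    "EvaluationResult",
    "split_cohort",
    "enumerate_subsets",
    "build_features",
    "fit_lasso",
    "evaluate",
    "run_prediction_experiment",
]


def subset_label(subset: tuple[int, ...]) -> str:
    return "intercept" if not subset else "x".join(str(k) for k in subset)


@dataclass(frozen=True)
class InteractionFeatureSpec:
    """Ordered list of component-index subsets; 2^k entries for k components.

    Subsets are sorted tuples, ordered by (size, lexicographic); the
    empty subset (intercept slot) comes first.
    """

    subsets: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(set(self.subsets)) != len(self.subsets):
            raise ValueError("subsets must be unique")
        if self.subsets and self.subsets[0] != ():
            raise ValueError("the empty subset must come first")

    @property
    def n_features(self) -> int:
        return len(self.subsets)

    @property
    def labels(self) -> list[str]:
        return [subset_label(s) for s in self.subsets]


@dataclass
class InteractionModel:
    """Sparse eigenvalue-product model on the original feature scale."""

    spec: InteractionFeatureSpec
    coefficients: dict[tuple[int, ...], float]
    intercept: float
    feature_means: dict[tuple[int, ...], float]
    feature_sds: dict[tuple[int, ...], float]
    penalty: float
    cv_folds: int
    seed: int

    @property
    def n_selected(self) -> int:
        return sum(1 for c in self.coefficients.values() if c != 0.0)

    @property
    def selected_subsets(self) -> list[tuple[int, ...]]:
        return [s for s, c in self.coefficients.items() if c != 0.0]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        pred = np.full(len(features), self.intercept, dtype=float)
        for subset, coef in self.coefficients.items():
            if coef != 0.0:
                pred += coef * features[subset_label(subset)].to_numpy(dtype=float)
        return pred

    def to_dict(self) -> dict:
        return {
            "subsets": [list(s) for s in self.spec.subsets],
            "coefficients": {subset_label(s): c for s, c in self.coefficients.items() if c != 0.0},
            "intercept": self.intercept,
            "penalty": self.penalty,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "n_selected": self.n_selected,
        }


@dataclass
class EvaluationResult:
    r: float
    p: float
    n_test: int
    r_defined: bool = True


def split_cohort(
    subject_ids: Sequence[str], n_train: int, seed: int
) -> tuple[list[str], list[str]]:
    """Seeded uniform random partition into disjoint train/test id lists."""
    ids = list(subject_ids)
    if not 0 < n_train < len(ids):
        raise ValueError(f"n_train must lie strictly between 0 and {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def enumerate_subsets(components: Sequence[int]) -> InteractionFeatureSpec:
    """All 2^k subsets of the screened components, intercept slot first."""
    comps = sorted(set(int(c) for c in components))
    if len(comps) != len(components):
        raise ValueError("component indices must be unique")
    subsets = []
    for size in range(len(comps) + 1):
        subsets.extend(itertools.combinations(comps, size))
    return InteractionFeatureSpec(tuple(subsets))


def build_features(spectra: pd.DataFrame, spec: InteractionFeatureSpec) -> pd.DataFrame:
    """Per subject, the product of eigenvalues over each subset.

    ``spectra`` is a subjects x components table (1-based integer
    columns); the empty-subset column is the constant 1.
    """
    available = {int(c) for c in spectra.columns}
    needed = {k for s in spec.subsets for k in s}
    missing = needed - available
    if missing:
        raise KeyError(f"spectra table lacks components {sorted(missing)}")
    out = {}
    for subset in spec.subsets:
        if not subset:
            out[subset_label(subset)] = np.ones(len(spectra))
        else:
            col = np.ones(len(spectra))
            for k in subset:
                col = col * spectra[k].to_numpy(dtype=float)
            out[subset_label(subset)] = col
    return pd.DataFrame(out, index=spectra.index)


def fit_lasso(
    features: pd.DataFrame,
    y: np.ndarray,
    spec: InteractionFeatureSpec,
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alphas: Sequence[float] | None = None,
    eps: float = 1e-2,
    max_iter: int = 10_000,
    tol: float = 1e-3,
) -> InteractionModel:
    """L1-penalized least squares with CV-selected penalty.

    Nonempty-subset columns are standardized to zero mean / unit SD
    using training statistics, the intercept stays unpenalized, and the
    penalty minimizing mean CV squared error over seeded k-fold splits
    is selected.  Coefficients are reported on the original scale.

    Nested eigenvalue products are strongly collinear, so the penalty
    grid stops at ``eps`` times the null-support penalty and coordinate
    descent runs with a capped iteration budget; near the unpenalized
    end of the path the solution is then only approximate, which CV
    never selects on such designs.
    """
    y = np.asarray(y, dtype=float)
    if len(features) != y.size:
        raise ValueError("feature rows and target length differ")
    if np.all(y == y[0]):
        raise ValueError("target is constant; fit is undefined")
    if len(features) < 2 * cv_folds:
        raise ValueError("need at least 2 rows per CV fold")
    penalized = [s for s in spec.subsets if s]
    X = np.column_stack([features[subset_label(s)].to_numpy(dtype=float) for s in penalized])
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds_safe = np.where(sds == 0, 1.0, sds)
    Xs = (X - means) / sds_safe
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=derive_seed(seed, "cv_folds"))
    # scikit-learn >= 1.9 takes the alpha-grid size through `alphas`
    model = LassoCV(cv=cv, alphas=n_alphas if alphas is None else alphas,
                    eps=eps, max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    coef_std = model.coef_
    coef_orig = coef_std / sds_safe
    coef_orig[sds == 0] = 0.0
    intercept = float(model.intercept_ - np.sum(coef_std * means / sds_safe))
    return InteractionModel(
        spec=spec,
        coefficients={s: float(c) for s, c in zip(penalized, coef_orig)},
        intercept=intercept,
        feature_means={s: float(m) for s, m in zip(penalized, means)},
        feature_sds={s: float(v) for s, v in zip(penalized, sds)},
        penalty=float(model.alpha_),
        cv_folds=cv_folds,
        seed=seed,
    )


def evaluate(model: InteractionModel, test_features: pd.DataFrame, y_test: np.ndarray) -> EvaluationResult:
    """Pearson correlation between predictions and measured test scores.

    Constant predictions (e.g., a fully shrunk model) yield an undefined
    correlation, flagged rather than raised.
    """
    y_test = np.asarray(y_test, dtype=float)
    if y_test.size < 3:
        raise ValueError("need at least 3 test subjects")
    pred = model.predict(test_features)
    if np.all(pred == pred[0]) or np.all(y_test == y_test[0]):
        return EvaluationResult(r=float("nan"), p=float("nan"), n_test=y_test.size, r_defined=False)
    r, p = stats.pearsonr(pred, y_test)
    return EvaluationResult(r=float(r), p=float(p), n_test=y_test.size)


@dataclass
class PredictionReport:
    target: str
    screened_components: list[int]
    screening_statistic: str
    n_train: int
    n_test: int
    n_candidate_subsets: int
    model: InteractionModel
    train_r: float
    test_result: EvaluationResult
    seed: int
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "screened_components": self.screened_components,
            "screening_statistic": self.screening_statistic,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_candidate_subsets": self.n_candidate_subsets,
            "n_selected": self.model.n_selected,
            "model": self.model.to_dict(),
            "train_r": self.train_r,
            "test_r": self.test_result.r,
            "test_p": self.test_result.p,
            "test_r_defined": self.test_result.r_defined,
            "seed": self.seed,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
        }


def _screened_feature_table(
    eigs: pd.DataFrame, scaled: pd.DataFrame, statistic: str, components: list[int]
) -> pd.DataFrame:
    """Per-component series in its screened form.

    'eigenvalue' / 'scaled_eigenvalue' use one table throughout; 'union'
    takes component 1 unscaled and every other component scaled.
    """
    cols = {}
    for c in components:
        if statistic == "eigenvalue":
            cols[c] = eigs[c]
        elif statistic == "scaled_eigenvalue":
            cols[c] = scaled[c]
        elif statistic == "union":
            cols[c] = eigs[c] if c == 1 else scaled[c]
        else:
            raise ValueError(f"unknown screening statistic {statistic!r}")
    return pd.DataFrame(cols, index=eigs.index)


def run_prediction_experiment(
    eigs: pd.DataFrame,
    scaled: pd.DataFrame,
    behavior: pd.DataFrame,
    target: str,
    statistic: str = "eigenvalue",
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    n_boot: int = 1000,
    n_train: int | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    screened_components: list[int] | None = None,
    max_components: int = 12,
) -> PredictionReport:
    """split -> screen (training rows only) -> enumerate -> build -> fit -> evaluate.

    Screening runs on the training partition only; when
    ``screened_components`` is given, screening is skipped and those
    components are used directly.  'union' screening merges the
    unscaled component-1 selection with the scaled selections for
    components 2+.
    """
    from .behavior import screen

    ids = list(eigs.index)
    if n_train is None:
        n_train = int(round(0.7 * len(ids)))
    train_ids, test_ids = split_cohort(ids, n_train, derive_seed(seed, "split"))
    eig_tr, eig_te = eigs.loc[train_ids], eigs.loc[test_ids]
    sc_tr, sc_te = scaled.loc[train_ids], scaled.loc[test_ids]
    y_tr = behavior.loc[train_ids, target].to_numpy(dtype=float)
    y_te = behavior.loc[test_ids, target].to_numpy(dtype=float)

    if screened_components is None:
        target_tbl = behavior.loc[train_ids, [target]]
        if statistic == "union":
            _, sel_e = screen(eig_tr, target_tbl, "eigenvalue", alpha, correction, n_boot,
                              derive_seed(seed, "screen_eig"))
            _, sel_s = screen(sc_tr, target_tbl, "scaled_eigenvalue", alpha, correction, n_boot,
                              derive_seed(seed, "screen_scaled"))
            comps = sorted(set(c for c in sel_e[target] if c == 1) | set(sel_s[target]))
        else:
            _, sel = screen(eig_tr if statistic == "eigenvalue" else sc_tr, target_tbl,
                            statistic, alpha, correction, n_boot, derive_seed(seed, "screen"))
            comps = sel[target]
    else:
        comps = sorted(set(screened_components))
    if len(comps) > max_components:
        raise ValueError(
            f"{len(comps)} screened components would enumerate 2^{len(comps)} subsets; "
            f"cap is 2^{max_components}"
        )
    spec = enumerate_subsets(comps)
    feat_tr = build_features(_screened_feature_table(eig_tr, sc_tr, statistic, comps), spec)
    feat_te = build_features(_screened_feature_table(eig_te, sc_te, statistic, comps), spec)
    if len(comps) == 0:
        # intercept-only model: nothing to penalize, prediction is the train mean
        model = InteractionModel(
            spec=spec, coefficients={}, intercept=float(np.mean(y_tr)),
            feature_means={}, feature_sds={}, penalty=float("inf"),
            cv_folds=cv_folds, seed=seed,
        )
        train_r = float("nan")
    else:
        model = fit_lasso(feat_tr, y_tr, spec, cv_folds=cv_folds, seed=derive_seed(seed, "lasso"))
        train_eval = evaluate(model, feat_tr, y_tr)
        train_r = train_eval.r
    test_result = evaluate(model, feat_te, y_te)
    return PredictionReport(
        target=target,
        screened_components=list(comps),
        screening_statistic=statistic,
        n_train=len(train_ids),
        n_test=len(test_ids),
        n_candidate_subsets=spec.n_features,
        model=model,
        train_r=train_r,
        test_result=test_result,
        seed=seed,
        train_ids=train_ids,
        test_ids=test_ids,
    )
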