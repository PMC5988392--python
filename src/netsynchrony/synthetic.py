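"""Synthetic cohorts with planted eigenstructure and brain-behavior coupling.

The generative model is the minimal one under which the downstream
eigen-analysis is well-posed and recoverable: each subject's
connectivity matrix (Fisher-z space) is a rank-K symmetric mixture

    C_i = sum_k lambda_ik * w_k w_k^T + E_i,       diag(C_i) = 0,

with shared unit-norm, mutually orthogonal component maps w_k whose
support overlaps spatially (every region loads on several components),
per-subject eigenvalues lambda_ik log-normal around a strictly
decreasing group spectrum, and i.i.d. symmetric Gaussian off-diagonal
noise.  Equivalently, region time series are generated as
X = W sqrt(Lambda) S + noise.  Behavior measures depend linearly on the
eigenvalues and/or on eigenvalue products, plus Gaussian residual
noise; all-zero weights give pure-noise null measures.

Every generator is a pure function of (configuration, seed); planted
loadings, spectra and coefficients are retained as ground truth for
recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._seeds import derive_rng, derive_seed
from .connectivity import (
    ConnectivityMatrix,
    Parcellation,
    RegionTimeSeries,
    synthetic_parcellation,
    write_connectivity,
    write_parcellation,
    write_timeseries,
)

__all__ = [
    "MeasureSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "make_truth",
    "default_truth",
    "draw_subject_spectra",
    "generate_connectivity",
    "generate_time_series",
    "generate_behavior",
    "make_cohort",
    "write_cohort",
    "plant_linear_measure",
    "plant_product_measure",
    "spearman_to_pearson",
    "eigenvalue_sd",
]


def spearman_to_pearson(rho: float) -> float:
    """Gaussian-copula map from a target Spearman rho to the Pearson r."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


@dataclass
class MeasureSpec:
    """Planted coefficients for one behavior measure."""

    intercept: float = 0.0
    linear: dict[int, float] = field(default_factory=dict)        # component (1-based) -> beta
    products: dict[tuple[int, ...], float] = field(default_factory=dict)  # subset -> gamma
    residual_sd: float = 1.0

    def is_null(self) -> bool:
        return not self.linear and not self.products


@dataclass
class SyntheticTruth:
    """Planted loadings, spectra, noise and behavior coefficients."""

    n_regions: int
    n_components: int
    loadings: np.ndarray            # (n_regions x K), unit-norm orthogonal columns
    group_spectrum: np.ndarray      # K positive reals, strictly decreasing
    subject_spectrum_sd: np.ndarray  # K nonnegative log-scale SDs
    noise_sd: float
    behavior_coefficients: dict[str, MeasureSpec]
    n_subjects: int
    n_runs: int
    n_timepoints: int
    seed: int

    def __post_init__(self) -> None:
        K = self.n_components
        if not (self.n_regions >= K >= 1):
            raise ValueError("need n_regions >= n_components >= 1")
        for name in ("n_subjects", "n_runs", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.group_spectrum = np.asarray(self.group_spectrum, dtype=float)
        self.subject_spectrum_sd = np.asarray(self.subject_spectrum_sd, dtype=float)
        if self.loadings.shape != (self.n_regions, K):
            raise ValueError("loadings must be n_regions x n_components")
        gram = self.loadings.T @ self.loadings
        if np.max(np.abs(gram - np.eye(K))) > 1e-10:
            raise ValueError("loading columns must be orthonormal within 1e-10")
        if self.group_spectrum.shape != (K,) or np.any(self.group_spectrum <= 0):
            raise ValueError("group spectrum must be K positive reals")
        if np.any(np.diff(self.group_spectrum) >= 0):
            raise ValueError("group spectrum must be strictly decreasing")
        if self.subject_spectrum_sd.shape != (K,) or np.any(self.subject_spectrum_sd < 0):
            raise ValueError("subject spectrum SDs must be K nonnegative reals")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name, spec in self.behavior_coefficients.items():
            comps = set(spec.linear) | {k for s in spec.products for k in s}
            bad = [k for k in comps if not 1 <= k <= K]
            if bad:
                raise ValueError(f"measure {name!r} references unknown components {bad}")
            if spec.residual_sd < 0:
                raise ValueError(f"measure {name!r} has negative residual SD")

    @property
    def measure_names(self) -> list[str]:
        return list(self.behavior_coefficients)

    @property
    def subject_ids(self) -> list[str]:
        width = len(str(self.n_subjects))
        return [f"sub-{i + 1:0{width}d}" for i in range(self.n_subjects)]


def eigenvalue_sd(truth: SyntheticTruth, component: int) -> float:
    """SD of the (log-normal) per-subject eigenvalue of one component."""
    g = truth.group_spectrum[component - 1]
    s2 = float(truth.subject_spectrum_sd[component - 1]) ** 2
    return g * math.sqrt(math.exp(s2) * (math.exp(s2) - 1.0))


def _product_sd(truth: SyntheticTruth, subset: tuple[int, ...]) -> float:
    g = float(np.prod([truth.group_spectrum[k - 1] for k in subset]))
    s2 = float(sum(truth.subject_spectrum_sd[k - 1] ** 2 for k in subset))
    return g * math.sqrt(math.exp(s2) * (math.exp(s2) - 1.0))


def plant_linear_measure(
    truth_params: dict, components: list[int], rho: float, intercept: float = 0.0
) -> MeasureSpec:
    """Linear coupling with a target marginal Spearman rho per component.

    Each beta is scaled so its component contributes unit variance; the
    residual SD is solved in closed form so every planted component's
    marginal Pearson correlation equals 2 sin(pi*rho/6), which a
    Gaussian copula maps back to Spearman rho.  Requires
    len(components) < 1/r^2.
    """
    r = spearman_to_pearson(abs(rho))
    m = len(components)
    if r <= 0 or m >= 1.0 / r**2:
        raise ValueError("target correlation too strong for this many components")
    sign = 1.0 if rho >= 0 else -1.0
    group = np.asarray(truth_params["group_spectrum"], dtype=float)
    sds = np.asarray(truth_params["subject_spectrum_sd"], dtype=float)
    linear = {}
    for k in components:
        g, s2 = group[k - 1], float(sds[k - 1]) ** 2
        sd_k = g * math.sqrt(math.exp(s2) * (math.exp(s2) - 1.0))
        linear[k] = sign / sd_k
    residual_sd = math.sqrt(1.0 / r**2 - m)
    return MeasureSpec(intercept=intercept, linear=linear, residual_sd=residual_sd)


def plant_product_measure(
    truth: SyntheticTruth, subset: tuple[int, ...], gamma: float, snr: float
) -> MeasureSpec:
    """Single product term with residual SD set by the signal-to-noise ratio."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    signal_sd = abs(gamma) * _product_sd(truth, subset)
    return MeasureSpec(products={tuple(sorted(subset)): gamma}, residual_sd=signal_sd / snr)


_DEFAULT_GROUP_BASE = 6.0
_DEFAULT_GROUP_RATIO = 0.82
_DEFAULT_SD_BASE = 0.08
_DEFAULT_SD_STEP = 0.012
_DEFAULT_NOISE_SD = 0.05


def _default_behavior(params: dict) -> dict[str, MeasureSpec]:
    """Default 12-measure battery mirroring a cognition test battery.

    Fluid intelligence couples positively to components 3-10 (marginal
    Spearman ~0.12 each); cognitive flexibility and processing speed
    couple negatively to the global component 1 (which also induces the
    positive scaled-eigenvalue correlations for components 2+);
    working/episodic memory and language comprehension carry weak
    couplings; the remaining six measures are pure-noise nulls.
    """
    K = params["n_components"]
    measures: dict[str, MeasureSpec] = {}
    if K >= 10:
        measures["fluid_intelligence"] = plant_linear_measure(params, list(range(3, 11)), 0.12)
        measures["cognitive_flexibility"] = plant_linear_measure(params, [1], -0.09)
        measures["processing_speed"] = plant_linear_measure(params, [1], -0.08)
        measures["working_memory"] = plant_linear_measure(params, [2, 5], 0.08)
        measures["episodic_memory"] = plant_linear_measure(params, [2], 0.08)
        measures["language_comprehension"] = plant_linear_measure(params, [2, 6], 0.07)
    from .behavior import DEFAULT_MEASURES

    # remaining battery measures (all of them, at K < 10) are pure noise
    for name in DEFAULT_MEASURES:
        measures.setdefault(name, MeasureSpec(residual_sd=1.0))
    return measures


def make_truth(config: dict | None = None, seed: int = 0, **overrides) -> SyntheticTruth:
    """Build a ground-truth object from configuration parameters.

    Loadings are K random spatially smoothed vectors (Gaussian kernel
    along the region index, circular boundary) orthonormalized by QR, so
    every region loads on several components (one-to-many overlap).
    Defaults: 60 regions, K=10, 200 subjects, 4 runs, 240 timepoints,
    geometric group spectrum 6.0 * 0.82^(k-1), log-scale subject SD
    increasing with component order, off-diagonal noise SD 0.05.
    """
    params = dict(config or {})
    params.update(overrides)
    n_regions = int(params.pop("n_regions", 60))
    K = int(params.pop("n_components", 10))
    n_subjects = int(params.pop("n_subjects", 200))
    n_runs = int(params.pop("n_runs", 4))
    n_timepoints = int(params.pop("n_timepoints", 240))
    noise_sd = float(params.pop("noise_sd", _DEFAULT_NOISE_SD))
    smooth_sigma = float(params.pop("smooth_sigma", 2.0))
    if n_regions < K or K < 1:
        raise ValueError("need n_regions >= n_components >= 1")
    group_spectrum = np.asarray(
        params.pop(
            "group_spectrum",
            _DEFAULT_GROUP_BASE * _DEFAULT_GROUP_RATIO ** np.arange(K),
        ),
        dtype=float,
    )
    if np.any(group_spectrum <= 0):
        raise ValueError("group spectrum must be positive")
    subject_spectrum_sd = np.asarray(
        params.pop(
            "subject_spectrum_sd",
            _DEFAULT_SD_BASE + _DEFAULT_SD_STEP * np.arange(K),
        ),
        dtype=float,
    )
    behavior = params.pop("behavior_coefficients", None)
    if params:
        raise ValueError(f"unknown configuration keys: {sorted(params)}")

    rng = derive_rng(seed, "loadings")
    raw = rng.standard_normal((n_regions, K))
    if smooth_sigma > 0:
        raw = gaussian_filter1d(raw, sigma=smooth_sigma, axis=0, mode="wrap")
    q, _ = np.linalg.qr(raw)
    loadings = q[:, :K]
    for k in range(K):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] = -loadings[:, k]

    truth_params = {
        "n_components": K,
        "group_spectrum": group_spectrum,
        "subject_spectrum_sd": subject_spectrum_sd,
    }
    if behavior is None:
        behavior = _default_behavior(truth_params)
    return SyntheticTruth(
        n_regions=n_regions,
        n_components=K,
        loadings=loadings,
        group_spectrum=group_spectrum,
        subject_spectrum_sd=subject_spectrum_sd,
        noise_sd=noise_sd,
        behavior_coefficients=behavior,
        n_subjects=n_subjects,
        n_runs=n_runs,
        n_timepoints=n_timepoints,
        seed=int(seed),
    )


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    return make_truth(seed=seed, **overrides)


def draw_subject_spectra(truth: SyntheticTruth) -> np.ndarray:
    """Per-subject eigenvalues: group value times exp(sd * z), z ~ N(0,1)."""
    rng = derive_rng(truth.seed, "subject_spectra")
    z = rng.standard_normal((truth.n_subjects, truth.n_components))
    return truth.group_spectrum[None, :] * np.exp(truth.subject_spectrum_sd[None, :] * z)


def generate_connectivity(
    truth: SyntheticTruth, subject_spectrum: np.ndarray, seed: int
) -> ConnectivityMatrix:
    """C = sum_k lambda_k w_k w_k^T + symmetric noise, zero diagonal."""
    lam = np.asarray(subject_spectrum, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("subject spectrum must be positive")
    W = truth.loadings
    C = (W * lam) @ W.T
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        E = rng.normal(0.0, truth.noise_sd, size=(truth.n_regions, truth.n_regions))
        E = np.triu(E, k=1)
        C = C + E + E.T
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 0.0)
    return ConnectivityMatrix(C, level="run")


def generate_time_series(
    truth: SyntheticTruth, subject_spectrum: np.ndarray, seed: int
) -> list[RegionTimeSeries]:
    """One regions x timepoints draw per run: X = W sqrt(Lambda) S + noise."""
    lam = np.asarray(subject_spectrum, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("subject spectrum must be positive")
    if truth.n_timepoints <= truth.n_components:
        raise ValueError("need more timepoints than components")
    out = []
    A = truth.loadings * np.sqrt(lam)
    for run in range(truth.n_runs):
        rng = derive_rng(seed, "run", run)
        S = rng.standard_normal((truth.n_components, truth.n_timepoints))
        X = A @ S
        if truth.noise_sd > 0:
            X = X + truth.noise_sd * rng.standard_normal((truth.n_regions, truth.n_timepoints))
        out.append(RegionTimeSeries("", f"run-{run + 1}", X))
    return out


def generate_behavior(truth: SyntheticTruth, subject_spectra: np.ndarray) -> pd.DataFrame:
    """y = intercept + sum beta_k lambda_k + sum gamma_S prod lambda_S + noise."""
    lam = np.asarray(subject_spectra, dtype=float)
    if lam.shape != (truth.n_subjects, truth.n_components):
        raise ValueError("subject_spectra must be n_subjects x n_components")
    rng = derive_rng(truth.seed, "behavior")
    data = {}
    for name, spec in truth.behavior_coefficients.items():
        y = np.full(truth.n_subjects, spec.intercept, dtype=float)
        for k, beta in spec.linear.items():
            y = y + beta * lam[:, k - 1]
        for subset, gamma in spec.products.items():
            y = y + gamma * np.prod(lam[:, [k - 1 for k in subset]], axis=1)
        if spec.residual_sd > 0:
            y = y + rng.normal(0.0, spec.residual_sd, size=truth.n_subjects)
        data[name] = y
    df = pd.DataFrame(data, index=truth.subject_ids)
    df.index.name = "subject_id"
    return df


@dataclass
class SyntheticCohort:
    """A drawn cohort plus its generating truth."""

    truth: SyntheticTruth
    subject_spectra: pd.DataFrame            # subjects x components (1-based columns)
    behavior: pd.DataFrame                   # subjects x measures
    parcellation: Parcellation
    connectivity: dict[str, list[ConnectivityMatrix]] = field(default_factory=dict)
    time_series: dict[str, list[RegionTimeSeries]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.subject_spectra.to_numpy() <= 0).any():
            raise ValueError("subject spectra must be positive")
        if self.behavior.isna().any().any():
            raise ValueError("behavior table has missing values")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subject_spectra.index)


def make_cohort(truth: SyntheticTruth, kind: str = "connectivity") -> SyntheticCohort:
    """Draw a full cohort: spectra, per-subject data, behavior table.

    ``kind`` selects connectivity matrices (one per subject/run) or raw
    region time series.  Each subject/run has its own derived stream.
    """
    if kind not in ("connectivity", "timeseries"):
        raise ValueError("kind must be 'connectivity' or 'timeseries'")
    spectra = draw_subject_spectra(truth)
    ids = truth.subject_ids
    parc = synthetic_parcellation(truth.n_regions)
    behavior = generate_behavior(truth, spectra)
    connectivity: dict[str, list[ConnectivityMatrix]] = {}
    time_series: dict[str, list[RegionTimeSeries]] = {}
    for i, sid in enumerate(ids):
        if kind == "connectivity":
            mats = []
            for run in range(truth.n_runs):
                cm = generate_connectivity(
                    truth, spectra[i], derive_seed(truth.seed, "conn", sid, run)
                )
                mats.append(
                    ConnectivityMatrix(
                        cm.values,
                        level="run",
                        provenance=(f"{sid}/run-{run + 1}",),
                        labels=tuple(parc.labels),
                    )
                )
            connectivity[sid] = mats
        else:
            runs = generate_time_series(truth, spectra[i], derive_seed(truth.seed, "ts", sid))
            for ts in runs:
                ts.subject_id = sid
                ts.parcellation = parc
            time_series[sid] = runs
    spectra_df = pd.DataFrame(
        spectra, index=ids, columns=np.arange(1, truth.n_components + 1)
    )
    spectra_df.index.name = "subject_id"
    return SyntheticCohort(
        truth=truth,
        subject_spectra=spectra_df,
        behavior=behavior,
        parcellation=parc,
        connectivity=connectivity,
        time_series=time_series,
    )


# ---------------------------------------------------------------------------
# Disk layout: TSV data + truth JSON


def truth_to_dict(truth: SyntheticTruth) -> dict:
    return {
        "n_regions": truth.n_regions,
        "n_components": truth.n_components,
        "loadings": truth.loadings.tolist(),
        "group_spectrum": truth.group_spectrum.tolist(),
        "subject_spectrum_sd": truth.subject_spectrum_sd.tolist(),
        "noise_sd": truth.noise_sd,
        "behavior_coefficients": {
            name: {
                "intercept": spec.intercept,
                "linear": {str(k): v for k, v in spec.linear.items()},
                "products": {"_".join(map(str, s)): v for s, v in spec.products.items()},
                "residual_sd": spec.residual_sd,
            }
            for name, spec in truth.behavior_coefficients.items()
        },
        "n_subjects": truth.n_subjects,
        "n_runs": truth.n_runs,
        "n_timepoints": truth.n_timepoints,
        "seed": truth.seed,
    }


def truth_from_dict(d: dict) -> SyntheticTruth:
    behavior = {
        name: MeasureSpec(
            intercept=spec["intercept"],
            linear={int(k): v for k, v in spec["linear"].items()},
            products={
                tuple(int(x) for x in s.split("_")): v for s, v in spec["products"].items()
            },
            residual_sd=spec["residual_sd"],
        )
        for name, spec in d["behavior_coefficients"].items()
    }
    return SyntheticTruth(
        n_regions=d["n_regions"],
        n_components=d["n_components"],
        loadings=np.asarray(d["loadings"], dtype=float),
        group_spectrum=np.asarray(d["group_spectrum"], dtype=float),
        subject_spectrum_sd=np.asarray(d["subject_spectrum_sd"], dtype=float),
        noise_sd=d["noise_sd"],
        behavior_coefficients=behavior,
        n_subjects=d["n_subjects"],
        n_runs=d["n_runs"],
        n_timepoints=d["n_timepoints"],
        seed=d["seed"],
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort as TSV data files plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_parcellation(cohort.parcellation, out / "parcellation.tsv")
    behavior = cohort.behavior.reset_index()
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False, float_format="%.17g")
    spectra = cohort.subject_spectra.reset_index()
    spectra.to_csv(out / "subject_spectra.tsv", sep="\t", index=False, float_format="%.17g")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_to_dict(cohort.truth), fh, indent=1)
    if cohort.time_series:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for sid, runs in cohort.time_series.items():
            for ts in runs:
                write_timeseries(ts, ts_dir / f"{sid}_{ts.run_id}.tsv")
    if cohort.connectivity:
        cm_dir = out / "connectivity"
        cm_dir.mkdir(exist_ok=True)
        for sid, mats in cohort.connectivity.items():
            for j, cm in enumerate(mats):
                write_connectivity(cm, cm_dir / f"{sid}_run-{j + 1}.tsv")
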