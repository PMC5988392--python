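"""Configuration and orchestration of the full analysis pipeline.

One master seed deterministically derives every per-stage stream, so a
single integer reproduces the whole study.  Each stage writes TSV/JSON
artifacts stamped with the configuration hash, and a log records every
seed and file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import connectivity as conn
from . import spectral
from ._seeds import derive_seed
from .behavior import screen
from .interaction import run_prediction_experiment
from .synthetic import make_cohort, make_truth, write_cohort

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger("netsynchrony")

_KNOWN_KEYS = {
    "out_dir", "timeseries_dir", "matrices_dir", "behavior_path", "parcellation_path",
    "simulate", "cohort", "m", "subject_m", "clip", "alpha", "n_boot", "correction",
    "statistic", "prediction_targets", "n_train", "cv_folds", "seed",
}


@dataclass
class PipelineConfig:
    """Stage parameters and paths for one pipeline run."""

    out_dir: str = "netsynchrony_out"
    timeseries_dir: str | None = None
    matrices_dir: str | None = None
    behavior_path: str | None = None
    parcellation_path: str | None = None
    simulate: bool = True
    cohort: dict = field(default_factory=dict)     # make_truth parameters
    m: int = 10                                    # group components retained
    subject_m: int = 20                            # subject components retained
    clip: float = conn.DEFAULT_CLIP
    alpha: float = 0.05
    n_boot: int = 1000
    correction: str = "fdr_bh"
    statistic: str = "eigenvalue"
    prediction_targets: dict = field(
        default_factory=lambda: {
            "fluid_intelligence": "eigenvalue",
            "cognitive_flexibility": "union",
        }
    )
    n_train: int | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.subject_m:
            raise ValueError("need 1 <= m <= subject_m")
        if not 0 < self.clip < 1:
            raise ValueError("clip must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 0 or self.cv_folds < 2:
            raise ValueError("n_boot must be >= 0 and cv_folds >= 2")
        if self.correction not in ("fdr_bh", "bonferroni"):
            raise ValueError("correction must be 'fdr_bh' or 'bonferroni'")
        if self.simulate:
            n_subjects = int(self.cohort.get("n_subjects", 200))
            if self.n_train is not None and not 0 < self.n_train < n_subjects:
                raise ValueError("n_train must lie strictly between 0 and n_subjects")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(obj: dict, path: Path, config_hash: str) -> None:
    obj = dict(obj)
    obj["config_hash"] = config_hash
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
    logger.info("wrote %s", path)


def run_all(config: PipelineConfig) -> Path:
    """simulate? -> connect -> decompose -> match -> correlate -> predict.

    Returns the artifact directory.  Any stage error aborts with a
    stage-named message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline start: hash=%s seed=%d", chash, config.seed)

    # --- stage: simulate (or load) ----------------------------------------
    try:
        if config.simulate:
            truth = make_truth(config.cohort, seed=derive_seed(config.seed, "simulate"))
            cohort = make_cohort(truth, kind="connectivity")
            write_cohort(cohort, out / "cohort")
            parc = cohort.parcellation
            run_matrices = cohort.connectivity
            behavior = cohort.behavior
        else:
            if config.matrices_dir is None or config.behavior_path is None:
                raise ValueError("without simulate, matrices_dir and behavior_path are required")
            parc = (
                conn.read_parcellation(config.parcellation_path)
                if config.parcellation_path
                else None
            )
            run_matrices = {}
            for path in sorted(Path(config.matrices_dir).glob("*.tsv")):
                sid = path.stem.split("_run")[0]
                run_matrices.setdefault(sid, []).append(
                    conn.read_connectivity(path, level="run", provenance=(path.stem,))
                )
            behavior = pd.read_csv(config.behavior_path, sep="\t", index_col="subject_id")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    # --- stage: connect (average runs -> subject, subjects -> group) ------
    try:
        subject_matrices = {
            sid: conn.average_matrices(mats, level="subject")
            for sid, mats in run_matrices.items()
        }
        group_mean = conn.average_matrices(list(subject_matrices.values()), level="group")
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        conn.write_connectivity(group_mean, conn_dir / "group_mean.tsv")
        logger.info("connect: %d subjects averaged", len(subject_matrices))
    except Exception as exc:
        raise RuntimeError(f"stage 'connect' failed: {exc}") from exc

    # --- stage: decompose + match -----------------------------------------
    try:
        group_profile = spectral.decompose(group_mean, m=config.m, owner="group")
        matched = []
        for sid, cm in subject_matrices.items():
            sp = spectral.decompose(cm, m=config.subject_m, owner=sid)
            matched.append(spectral.match_components(sp, group_profile))
        spec_dir = out / "spectral"
        spec_dir.mkdir(exist_ok=True)
        spectral.write_profile(
            group_profile, spec_dir / "group_loadings.tsv", spec_dir / "group_spectrum.tsv"
        )
        matched_frame = spectral.matched_profiles_frame(matched)
        matched_frame.to_csv(
            spec_dir / "matched_profiles.tsv", sep="\t", index=False, float_format="%.17g"
        )
        eigs = spectral.eigenvalue_table(matched, scaled=False)
        scaled = spectral.eigenvalue_table(matched, scaled=True)
        import numpy as np

        aligned = np.stack([p.aligned_loadings for p in matched], axis=0)
        rel = spectral.group_reliability(aligned, alpha=config.alpha)
        rel.to_frame(labels=list(parc.labels) if parc else None).to_csv(
            spec_dir / "reliability.tsv", sep="\t", index=False, float_format="%.17g"
        )
        if parc is not None and not parc.regions_of_class("subcortical").empty:
            spectral.subcortical_sign_table(rel, parc).to_csv(
                spec_dir / "subcortical_signs.tsv", sep="\t", index=False
            )
        logger.info("decompose: %d subjects matched to %d group components",
                    len(matched), config.m)
    except Exception as exc:
        raise RuntimeError(f"stage 'decompose' failed: {exc}") from exc

    # --- stage: correlate ---------------------------------------------------
    try:
        behavior = behavior.loc[eigs.index]
        corr_dir = out / "correlations"
        corr_dir.mkdir(exist_ok=True)
        selected_all = {}
        for statistic, table in (("eigenvalue", eigs), ("scaled_eigenvalue", scaled)):
            grid, selected = screen(
                table, behavior, statistic=statistic, alpha=config.alpha,
                correction=config.correction, n_boot=config.n_boot,
                seed=derive_seed(config.seed, "screen", statistic),
            )
            grid.to_csv(
                corr_dir / f"grid_{statistic}.tsv", sep="\t", index=False, float_format="%.17g"
            )
            selected_all[statistic] = selected
        _write_json(selected_all, corr_dir / "selected_components.json", chash)
        logger.info("correlate: %d measures screened", behavior.shape[1])
    except Exception as exc:
        raise RuntimeError(f"stage 'correlate' failed: {exc}") from exc

    # --- stage: predict -----------------------------------------------------
    try:
        pred_dir = out / "prediction"
        pred_dir.mkdir(exist_ok=True)
        for target, statistic in config.prediction_targets.items():
            if target not in behavior.columns:
                raise ValueError(f"prediction target {target!r} not in behavior table")
            report = run_prediction_experiment(
                eigs, scaled, behavior, target, statistic=statistic,
                alpha=config.alpha, correction=config.correction, n_boot=config.n_boot,
                n_train=config.n_train, cv_folds=config.cv_folds,
                seed=derive_seed(config.seed, "predict", target),
            )
            _write_json(report.to_dict(), pred_dir / f"report_{target}.json", chash)
            logger.info("predict %s: test r=%.3f (n_selected=%d)",
                        target, report.test_result.r, report.model.n_selected)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'predict' failed: {exc}") from exc

    _write_json({"seed": config.seed, "config": asdict(config)}, out / "manifest.json", chash)
    return out
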