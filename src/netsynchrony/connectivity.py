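"""Parcellated time series -> Fisher-z functional connectivity matrices.

Each subject's resting-state runs yield region-by-region Pearson
correlation matrices whose entries are variance-stabilized with the
Fisher r-to-z transform (arctanh).  Run-level matrices are averaged to
subject level and subject-level matrices to a group mean.  The diagonal
is set to exactly zero: arctanh(1) is infinite, and zeroing it makes the
decomposed object describe off-diagonal covariance structure only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "RegionTimeSeries",
    "ConnectivityMatrix",
    "default_parcellation",
    "fisher_z_connectivity",
    "average_matrices",
    "read_parcellation",
    "read_timeseries",
    "write_timeseries",
    "read_connectivity",
    "write_connectivity",
]

DEFAULT_CLIP = 1.0 - 1e-7

_SUBCORTICAL_STRUCTURES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

_LEVELS = ("run", "subject", "group")


@dataclass(frozen=True)
class Parcellation:
    """Ordered region manifest: id, label, class, hemisphere.

    Region ids are 0..R-1 and labels are unique.  Classes are
    cortical / subcortical / cerebellar; hemisphere is L, R or NA.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"id", "label", "region_class", "hemisphere"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"parcellation manifest missing columns: {sorted(missing)}")
        ids = t["id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(t))):
            raise ValueError("region ids must be contiguous 0..R-1")
        if t["label"].duplicated().any():
            dup = t.loc[t["label"].duplicated(), "label"].iloc[0]
            raise ValueError(f"duplicate region label: {dup!r}")
        bad = set(t["region_class"]) - {"cortical", "subcortical", "cerebellar"}
        if bad:
            raise ValueError(f"unknown region classes: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    def regions_of_class(self, region_class: str) -> pd.DataFrame:
        return self.table[self.table["region_class"] == region_class]


def default_parcellation() -> Parcellation:
    """Build the default 361-region manifest.

    333 functionally defined cortical regions, 14 subcortical regions
    (7 bilateral structures from subcortical segmentation) and 14
    cerebellar regions, mirroring the combined cortex + subcortex +
    cerebellum scheme used for whole-brain connectivity matrices.
    """
    rows: list[dict] = []
    for i in range(333):
        hemi = "L" if i % 2 == 0 else "R"
        rows.append(
            {"label": f"ctx_{i + 1:03d}_{hemi}", "region_class": "cortical", "hemisphere": hemi}
        )
    for name in _SUBCORTICAL_STRUCTURES:
        for hemi in ("L", "R"):
            rows.append(
                {"label": f"{name}_{hemi}", "region_class": "subcortical", "hemisphere": hemi}
            )
    for i in range(7):
        for hemi in ("L", "R"):
            rows.append(
                {
                    "label": f"cereb_{i + 1}_{hemi}",
                    "region_class": "cerebellar",
                    "hemisphere": hemi,
                }
            )
    table = pd.DataFrame(rows)
    table.insert(0, "id", np.arange(len(table)))
    return Parcellation(table)


def synthetic_parcellation(n_regions: int) -> Parcellation:
    """Minimal manifest for synthetic cohorts of arbitrary size.

    The last 14 regions (when available) are labeled as the 7 bilateral
    subcortical structures so sign-table code paths are exercised at
    desk scale.
    """
    n_sub = 14 if n_regions >= 28 else 0
    n_ctx = n_regions - n_sub
    rows = []
    for i in range(n_ctx):
        hemi = "L" if i % 2 == 0 else "R"
        rows.append(
            {"label": f"ctx_{i + 1:03d}_{hemi}", "region_class": "cortical", "hemisphere": hemi}
        )
    for name in _SUBCORTICAL_STRUCTURES[: n_sub // 2]:
        for hemi in ("L", "R"):
            rows.append(
                {"label": f"{name}_{hemi}", "region_class": "subcortical", "hemisphere": hemi}
            )
    table = pd.DataFrame(rows)
    table.insert(0, "id", np.arange(len(table)))
    return Parcellation(table)


@dataclass
class RegionTimeSeries:
    """One subject/run matrix of region signals (n_regions x n_timepoints)."""

    subject_id: str
    run_id: str
    values: np.ndarray
    parcellation: Parcellation | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D regions x timepoints array")
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.parcellation is not None and self.values.shape[0] != self.parcellation.n_regions:
            raise ValueError(
                f"time series has {self.values.shape[0]} regions, "
                f"parcellation has {self.parcellation.n_regions}"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix over regions, zero diagonal.

    ``level`` records the averaging level (run/subject/group) and
    ``provenance`` the subject/run ids that entered the average.
    """

    values: np.ndarray
    level: str = "run"
    provenance: tuple[str, ...] = field(default_factory=tuple)
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite values")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("connectivity matrix is not symmetric within 1e-12")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("connectivity diagonal must be exactly 0")
        if self.level not in _LEVELS:
            raise ValueError(f"level must be one of {_LEVELS}")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def fisher_z_connectivity(
    ts: RegionTimeSeries, clip: float = DEFAULT_CLIP
) -> ConnectivityMatrix:
    """Pairwise Pearson correlations, Fisher r-to-z, zero diagonal.

    Off-diagonal (i, j) = arctanh(clamp(pearson(row_i, row_j), -clip, clip)).
    Correlations are clipped at ``clip`` (default 1 - 1e-7) so degenerate
    near-duplicate regions stay finite.  A zero-variance region is a hard
    error naming the region.
    """
    if not 0.0 < clip < 1.0:
        raise ValueError("clip must lie in (0, 1)")
    x = ts.values
    # constant rows have std ~1e-16 from the mean subtraction, not exactly 0
    degenerate = np.ptp(x, axis=1) == 0.0
    if np.any(degenerate):
        idx = int(np.argmax(degenerate))
        label = ts.parcellation.labels[idx] if ts.parcellation is not None else str(idx)
        raise ValueError(f"region {label!r} has zero-variance time series")
    r = np.corrcoef(x)
    np.clip(r, -clip, clip, out=r)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    labels = tuple(ts.parcellation.labels) if ts.parcellation is not None else None
    return ConnectivityMatrix(
        z, level="run", provenance=(f"{ts.subject_id}/{ts.run_id}",), labels=labels
    )


def average_matrices(
    ms: Sequence[ConnectivityMatrix], level: str | None = None
) -> ConnectivityMatrix:
    """Entrywise mean of connectivity matrices, promoting the level.

    Runs average to a subject matrix, subjects to the group mean; no
    weighting is applied across runs or subjects.
    """
    if len(ms) == 0:
        raise ValueError("cannot average an empty list of matrices")
    n = ms[0].n_regions
    for m in ms:
        if m.n_regions != n:
            raise ValueError("matrices have mismatched dimensions")
    if level is None:
        idx = min(_LEVELS.index(ms[0].level) + 1, len(_LEVELS) - 1)
        level = _LEVELS[idx]
    mean = np.mean([m.values for m in ms], axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 0.0)
    provenance = tuple(p for m in ms for p in m.provenance)
    return ConnectivityMatrix(mean, level=level, provenance=provenance, labels=ms[0].labels)


# ---------------------------------------------------------------------------
# TSV I/O


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    parc.table.to_csv(path, sep="\t", index=False)


def read_parcellation(path: str | Path) -> Parcellation:
    return Parcellation(pd.read_csv(path, sep="\t"))


def write_timeseries(ts: RegionTimeSeries, path: str | Path) -> None:
    """Rows = regions, header = timepoint index (t0, t1, ...)."""
    df = pd.DataFrame(ts.values, columns=[f"t{j}" for j in range(ts.n_timepoints)])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(
    path: str | Path,
    subject_id: str,
    run_id: str,
    parcellation: Parcellation | None = None,
) -> RegionTimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return RegionTimeSeries(subject_id, run_id, df.to_numpy(dtype=float), parcellation)


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Dense TSV with a header row/column of region labels."""
    labels = list(cm.labels) if cm.labels is not None else [str(i) for i in range(cm.n_regions)]
    df = pd.DataFrame(cm.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", index=True, float_format="%.17g")


def read_connectivity(
    path: str | Path, level: str = "subject", provenance: Iterable[str] = ()
) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ConnectivityMatrix(
        df.to_numpy(dtype=float),
        level=level,
        provenance=tuple(provenance),
        labels=tuple(str(c) for c in df.columns),
    )
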