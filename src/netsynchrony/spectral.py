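"""Spectral decomposition of connectivity matrices and component matching.

A connectivity matrix is decomposed into ranked principal components
(eigenvectors) whose associated singular values measure network
synchrony: the persistence of within-network covariation.  Because the
input is symmetric, the decomposition is a symmetric eigendecomposition
with singular value = |eigenvalue|; the eigenvalue's sign is retained
separately so the matrix can be reconstructed exactly at full rank.
Negative eigenvalues — possible once the diagonal is zeroed — are
thereby ranked by magnitude.

Subject components are aligned to group components by maximal spatial
correlation.  Eigenvectors have an arbitrary sign, so matching uses
|r| and records the sign needed to align each subject map with its
group map.  A subject's scaled spectrum divides each matched eigenvalue
by the eigenvalue matched to group component 1 (the global synchrony
component), so scaled element 1 is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityMatrix, Parcellation

__all__ = [
    "SpectralProfile",
    "MatchedProfile",
    "ReliabilityMap",
    "decompose",
    "scaled_spectrum",
    "match_components",
    "group_reliability",
    "subcortical_sign_table",
]


@dataclass
class SpectralProfile:
    """Ranked components of one connectivity matrix.

    components: (R x m) unit-norm loading columns, ordered by descending
        singular value, each column's sign fixed so its largest-magnitude
        entry is positive.
    singular_values: |eigenvalue| per component, nonincreasing.
    eigen_signs: sign of the underlying eigenvalue (+1/-1), needed for
        exact reconstruction.
    """

    owner: str
    components: np.ndarray
    singular_values: np.ndarray
    eigen_signs: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        self.eigen_signs = np.asarray(self.eigen_signs, dtype=float)
        if self.components.shape[1] != self.singular_values.shape[0]:
            raise ValueError("component count does not match singular value count")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be nonincreasing")
        if np.any(self.singular_values < 0):
            raise ValueError("singular values must be nonnegative")

    @property
    def m(self) -> int:
        return self.singular_values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.components.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Sum of s_k * sign_k * v_k v_k^T over retained components."""
        weighted = self.components * (self.singular_values * self.eigen_signs)
        return weighted @ self.components.T


@dataclass
class MatchedProfile:
    """Alignment of one subject's components to the group components.

    For each group component k (0-based internally): the subject
    component index maximizing |spatial Pearson r| over the subject's
    retained components, the signed correlation, the alignment sign,
    the matched eigenvalue (singular value), and the scaled eigenvalue
    (matched eigenvalue / eigenvalue matched to group component 1).
    """

    subject_id: str
    matched_index: np.ndarray      # 0-based subject component index per group comp
    match_correlation: np.ndarray  # signed spatial r
    aligned_sign: np.ndarray       # +1/-1
    eigenvalue: np.ndarray
    scaled_eigenvalue: np.ndarray
    aligned_loadings: np.ndarray   # (R x n_group) subject maps, sign-aligned to group

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(1, len(self.matched_index) + 1)
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group_component": k,
                "matched_subject_component": self.matched_index + 1,
                "match_correlation": self.match_correlation,
                "aligned_sign": self.aligned_sign.astype(int),
                "eigenvalue": self.eigenvalue,
                "scaled_eigenvalue": self.scaled_eigenvalue,
            }
        )


@dataclass
class ReliabilityMap:
    """Per region x component one-sample t-test of aligned loadings.

    ``significant`` applies Bonferroni familywise control over all
    region x component tests at level alpha; ``sign`` is '+'/'-' for
    significant regions and 'ns' otherwise.
    """

    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    sign: np.ndarray
    alpha: float
    n_subjects: int

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        n_regions, n_comp = self.t.shape
        if labels is None:
            labels = [str(i) for i in range(n_regions)]
        rows = []
        for k in range(n_comp):
            for i in range(n_regions):
                rows.append(
                    {
                        "component": k + 1,
                        "region": labels[i],
                        "t": self.t[i, k],
                        "p": self.p[i, k],
                        "significant": bool(self.significant[i, k]),
                        "sign": self.sign[i, k],
                    }
                )
        return pd.DataFrame(rows)


def decompose(C: ConnectivityMatrix | np.ndarray, m: int, owner: str = "") -> SpectralProfile:
    """Rank the components of a symmetric connectivity matrix.

    Symmetric eigendecomposition; components are ordered by descending
    |eigenvalue| and the singular value is |eigenvalue|.  Each loading
    column's sign is fixed so its largest-magnitude entry is positive
    (a canonical, pre-matching convention).
    """
    values = C.values if isinstance(C, ConnectivityMatrix) else np.asarray(C, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    if np.max(np.abs(values - values.T)) > 1e-10:
        raise ValueError("input matrix is not symmetric")
    R = values.shape[0]
    if not 1 <= m <= R:
        raise ValueError(f"m must lie in 1..{R}")
    eigvals, eigvecs = np.linalg.eigh((values + values.T) / 2.0)
    order = np.argsort(-np.abs(eigvals), kind="stable")[:m]
    sv = np.abs(eigvals[order])
    signs = np.where(eigvals[order] >= 0, 1.0, -1.0)
    comps = eigvecs[:, order].copy()
    for k in range(m):
        col = comps[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            comps[:, k] = -col
    return SpectralProfile(owner=owner, components=comps, singular_values=sv, eigen_signs=signs)


def scaled_spectrum(singular_values: np.ndarray) -> np.ndarray:
    """Divide every eigenvalue by the first; element 1 is identically 1."""
    sv = np.asarray(singular_values, dtype=float)
    if sv.size == 0 or sv[0] <= 0:
        raise ValueError("degenerate spectrum: leading singular value must be positive")
    return sv / sv[0]


def _column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of a and every column of b."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    asd = np.sqrt((az**2).sum(axis=0))
    bsd = np.sqrt((bz**2).sum(axis=0))
    if np.any(asd == 0) or np.any(bsd == 0):
        raise ValueError("zero-variance loading vector")
    return (az.T @ bz) / np.outer(asd, bsd)


def match_components(
    subject: SpectralProfile,
    group: SpectralProfile,
    use_abs: bool = True,
    with_replacement: bool = True,
) -> MatchedProfile:
    """Match each group component to the best-correlated subject component.

    Selection maximizes |spatial Pearson r| by default (signed r via
    ``use_abs=False``); matching is with replacement unless disabled, in
    which case a greedy pass in group order consumes subject components.
    Ties in |r| break toward the lower subject index.
    """
    if subject.n_regions != group.n_regions:
        raise ValueError("subject and group profiles have different region counts")
    r = _column_corr(subject.components, group.components)  # (m_subj x m_group)
    score = np.abs(r) if use_abs else r
    n_group = group.m
    matched = np.empty(n_group, dtype=int)
    used: set[int] = set()
    for k in range(n_group):
        col = score[:, k].copy()
        if not with_replacement:
            for j in used:
                col[j] = -np.inf
        matched[k] = int(np.argmax(col))  # argmax returns the lowest tying index
        used.add(int(matched[k]))
    corr = r[matched, np.arange(n_group)]
    sign = np.where(corr >= 0, 1.0, -1.0)
    eig = subject.singular_values[matched]
    if eig[0] <= 0:
        raise ValueError("eigenvalue matched to group component 1 must be positive")
    aligned = subject.components[:, matched] * sign
    return MatchedProfile(
        subject_id=subject.owner,
        matched_index=matched,
        match_correlation=corr,
        aligned_sign=sign,
        eigenvalue=eig,
        scaled_eigenvalue=eig / eig[0],
        aligned_loadings=aligned,
    )


def group_reliability(aligned_loadings: np.ndarray, alpha: float = 0.05) -> ReliabilityMap:
    """One-sample t-tests of sign-aligned loadings across subjects.

    ``aligned_loadings`` has shape (n_subjects, n_regions, n_components).
    Bonferroni familywise correction over all region x component tests.
    Zero-variance nonzero-mean loadings are treated as infinitely
    reliable (t = inf, p = 0).
    """
    x = np.asarray(aligned_loadings, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (n_subjects, n_regions, n_components) array")
    n = x.shape[0]
    if n < 3:
        raise ValueError("group reliability needs at least 3 subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate & (mean != 0), np.inf * np.sign(mean), t)
    t = np.where(degenerate & (mean == 0), 0.0, t)
    p = np.where(degenerate & (mean != 0), 0.0, p)
    p = np.where(degenerate & (mean == 0), 1.0, p)
    n_tests = t.size
    significant = p <= alpha / n_tests
    sign = np.where(significant, np.where(mean > 0, "+", "-"), "ns")
    return ReliabilityMap(t=t, p=p, significant=significant, sign=sign, alpha=alpha, n_subjects=n)


def subcortical_sign_table(rel: ReliabilityMap, parcellation: Parcellation) -> pd.DataFrame:
    """Reliable loading sign per subcortical structure/hemisphere/component.

    Rows: (component, structure, hemisphere) with sign '+', '-' or 'ns'.
    Structure names are the region label minus its hemisphere suffix.
    """
    sub = parcellation.regions_of_class("subcortical")
    n_comp = rel.t.shape[1]
    rows = []
    for _, region in sub.iterrows():
        structure = str(region["label"]).rsplit("_", 1)[0]
        for k in range(n_comp):
            rows.append(
                {
                    "component": k + 1,
                    "structure": structure,
                    "hemisphere": region["hemisphere"],
                    "sign": rel.sign[int(region["id"]), k],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV I/O


def write_profile(profile: SpectralProfile, loadings_path: str | Path, spectrum_path: str | Path) -> None:
    cols = [f"PC{k + 1}" for k in range(profile.m)]
    pd.DataFrame(profile.components, columns=cols).to_csv(
        loadings_path, sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(
        {
            "component": np.arange(1, profile.m + 1),
            "singular_value": profile.singular_values,
            "eigen_sign": profile.eigen_signs.astype(int),
        }
    ).to_csv(spectrum_path, sep="\t", index=False, float_format="%.17g")


def matched_profiles_frame(profiles: list[MatchedProfile]) -> pd.DataFrame:
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


def eigenvalue_table(profiles: list[MatchedProfile], scaled: bool = False) -> pd.DataFrame:
    """Subjects x components table of matched (or scaled) eigenvalues."""
    data = {
        p.subject_id: (p.scaled_eigenvalue if scaled else p.eigenvalue) for p in profiles
    }
    n_comp = len(profiles[0].eigenvalue)
    df = pd.DataFrame(data).T
    df.columns = np.arange(1, n_comp + 1)
    df.index.name = "subject_id"
    return df
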