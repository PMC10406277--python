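"""Link-level test statistics from subject-level connectivity matrices.

FC matrices hold Pearson correlations (Fisher-Z transformed before testing);
SC matrices hold tractography fiber counts (cube-root transformed).  Each of
the R(R-1)/2 unique links is compared between groups with a heteroscedastic
(Welch) two-sample t test on the transformed values; optional subject-mean
centering removes a per-subject additive offset, approximating the random
subject intercept of a mixed-effects formulation, which with one observation
per subject per link reduces the between-group intercept contrast to a
two-sample location test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mixture import LinkStatsTable

__all__ = [
    "SubjectConnectivity",
    "fisher_z",
    "cube_root",
    "vectorize_links",
    "unvectorize_links",
    "link_group_stat",
    "welch_t",
    "build_link_stats",
    "link_stats_from_arrays",
    "load_subjects",
]

_SYM_TOL = 1e-8
_T_CAP = 1e6


@dataclass(frozen=True)
class SubjectConnectivity:
    """One subject's FC (correlations) and SC (fiber counts) matrices."""

    subject_id: str
    group: str
    fc: np.ndarray
    sc: np.ndarray

    def __post_init__(self):
        fc = np.asarray(self.fc, dtype=float)
        sc = np.asarray(self.sc, dtype=float)
        for name, mat in (("fc", fc), ("sc", sc)):
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
                raise ValueError(f"{name} must be a square matrix with R >= 2")
            if not np.allclose(mat, mat.T, atol=_SYM_TOL):
                raise ValueError(f"{name} must be symmetric")
        if np.any(np.abs(fc) > 1 + _SYM_TOL):
            raise ValueError("fc entries must be correlations in [-1, 1]")
        if np.any(sc < 0):
            raise ValueError("sc entries must be non-negative counts")
        object.__setattr__(self, "fc", fc)
        object.__setattr__(self, "sc", sc)

    @property
    def n_rois(self) -> int:
        return self.fc.shape[0]


def fisher_z(r):
    """Fisher's Z transform atanh(r); |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("correlations with |r| >= 1 clipped before Fisher Z")
        r = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    return np.arctanh(r)


def cube_root(x):
    """Cube-root transform for fiber counts; zeros map to zero."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("fiber counts must be non-negative")
    return np.cbrt(x)


def vectorize_links(matrix) -> np.ndarray:
    """Upper triangle (excluding diagonal) in row-major order."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(matrix, matrix.T, atol=_SYM_TOL):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def unvectorize_links(links, n_rois: int) -> np.ndarray:
    """Inverse of vectorize_links; diagonal is set to zero."""
    links = np.asarray(links, dtype=float)
    if links.size != n_rois * (n_rois - 1) // 2:
        raise ValueError("link vector length does not match n_rois")
    out = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    out[iu] = links
    return out + out.T


def link_labels(n_rois: int, names=None) -> list[tuple[str, str]]:
    """ROI pair labels matching the vectorize_links ordering."""
    names = names or [f"roi{i + 1}" for i in range(n_rois)]
    iu = np.triu_indices(n_rois, k=1)
    return [(names[a], names[b]) for a, b in zip(*iu)]


def welch_t(g1, g2) -> np.ndarray:
    """Welch two-sample t statistics, vectorized over the last axis.

    Zero-variance degeneracies: equal means give 0; unequal means give a
    large finite value of the correct sign (with a warning).
    """
    g1 = np.atleast_2d(np.asarray(g1, dtype=float))
    g2 = np.atleast_2d(np.asarray(g2, dtype=float))
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each group needs at least two subjects")
    diff = g1.mean(axis=0) - g2.mean(axis=0)
    se2 = g1.var(axis=0, ddof=1) / g1.shape[0] + g2.var(axis=0, ddof=1) / g2.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 == 0
    if np.any(degenerate & (diff != 0)):
        warnings.warn("zero within-group variance with unequal means; capping statistic")
    t = np.where(degenerate, np.sign(diff) * _T_CAP, t)
    return np.where(degenerate & (diff == 0), 0.0, t)


def link_group_stat(values_g1, values_g2) -> float:
    """Signed Welch t for one link; downstream models consume |t|."""
    return float(welch_t(np.asarray(values_g1)[:, None], np.asarray(values_g2)[:, None])[0])


def _center_subjects(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def link_stats_from_arrays(
    fc_links: np.ndarray,
    sc_links: np.ndarray,
    groups,
    *,
    disease_label: str = "disease",
    transform: bool = True,
    center_subjects: bool = False,
    labels=None,
) -> tuple[LinkStatsTable, np.ndarray, np.ndarray]:
    """Build the statistics table from pre-vectorized subject x link arrays.

    Returns the table of absolute statistics plus the signed FC and SC
    statistic vectors (the signed FC values are what tail-trimming and the
    covariate-free baseline operate on).
    """
    fc_links = np.asarray(fc_links, dtype=float)
    sc_links = np.asarray(sc_links, dtype=float)
    groups = np.asarray(groups)
    if fc_links.shape != sc_links.shape or fc_links.shape[0] != groups.size:
        raise ValueError("fc_links, sc_links and groups are inconsistent")
    is_dis = groups == disease_label
    if is_dis.sum() < 2 or (~is_dis).sum() < 2:
        raise ValueError("need at least two subjects per group")
    fc_t = fisher_z(fc_links) if transform else fc_links
    sc_t = cube_root(sc_links) if transform else sc_links
    if center_subjects:
        fc_t = _center_subjects(fc_t)
        sc_t = _center_subjects(sc_t)
    t_f = welch_t(fc_t[is_dis], fc_t[~is_dis])
    t_s = welch_t(sc_t[is_dis], sc_t[~is_dis])
    table = LinkStatsTable(np.abs(t_f), np.abs(t_s), labels)
    return table, t_f, t_s


def load_subjects(manifest_path) -> list[SubjectConnectivity]:
    """Read subject connectivity from a manifest file.

    The manifest is delimited text with columns ``subject_id, group,
    fc_path, sc_path``; each path points to one square delimited-text
    matrix (comma or whitespace separated).  Relative paths resolve
    against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "fc_path", "sc_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must contain columns {sorted(required)}")

    def read_matrix(rel):
        path = Path(rel)
        if not path.is_absolute():
            path = manifest_path.parent / path
        return np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)

    return [
        SubjectConnectivity(
            subject_id=str(row.subject_id),
            group=str(row.group),
            fc=read_matrix(row.fc_path),
            sc=read_matrix(row.sc_path),
        )
        for row in manifest.itertuples()
    ]


def build_link_stats(
    subjects,
    *,
    disease_label: str = "disease",
    center_subjects: bool = False,
) -> LinkStatsTable:
    """Full pipeline: transform, vectorize and test each link in both modalities."""
    subjects = list(subjects)
    if not subjects:
        raise ValueError("no subjects provided")
    n_rois = subjects[0].n_rois
    if any(s.n_rois != n_rois for s in subjects):
        raise ValueError("all subjects must share the same parcellation")
    groups = np.array([s.group for s in subjects])
    if disease_label not in groups:
        raise ValueError(f"no subjects labeled '{disease_label}'")
    fc = np.stack([vectorize_links(s.fc) for s in subjects])
    sc = np.stack([vectorize_links(s.sc) for s in subjects])
    table, _, _ = link_stats_from_arrays(
        fc, sc, groups,
        disease_label=disease_label,
        center_subjects=center_subjects,
        labels=link_labels(n_rois),
    )
    return table
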