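"""Unsupervised atrial/ventricular phenotype discrimination.

The pipeline mirrors common practice for small electrophysiology
cohorts: z-score the nine per-cell biomarkers, project to two principal
components, cluster with k-means (k = 2), then name the clusters from
their biomarker pattern (the cluster with the shorter mean APD90 is
atrial-like). Individual biomarkers are scored by ROC analysis with the
Youden index J = sensitivity + specificity − 1 choosing the operating
cutoff; the APD20/APD90 triangulation ratio with cutoff 0.44 is the
headline single-feature classifier (ratio < 0.44 → atrial-like,
≥ 0.44 → ventricular-like).

Group comparisons use the Mann–Whitney U test; equality of variance in
triangulation parameters uses Levene's test on deviations from group
means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .biomarkers import APBiomarkers

__all__ = [
    "FEATURE_COLUMNS",
    "APD_FAMILY",
    "ClusterResult",
    "ROCResult",
    "standardize_and_pca2",
    "kmeans2",
    "cluster_cohort",
    "roc_youden",
    "classify_by_cutoff",
    "mann_whitney_u",
    "levene_w",
]

logger = logging.getLogger(__name__)

#: The nine per-cell biomarker columns, in fixed order.
FEATURE_COLUMNS = [
    "Cm_pF",
    "Ediast_mV",
    "EdiastDC_mV",
    "APD90_ms",
    "APD50_ms",
    "APD20_ms",
    "APD20_APD90",
    "dVdtmax_Vps",
    "APA_mV",
]

#: Duration-family features expected to dominate PC1.
APD_FAMILY = ["APD90_ms", "APD50_ms", "APD20_ms", "APD20_APD90"]


@dataclass
class ClusterResult:
    """2-D projection, loadings and cluster labels of a cohort."""

    pc_scores: np.ndarray  # (n_cells, 2)
    loadings: pd.DataFrame  # features × [PC1, PC2]
    variance_explained: np.ndarray  # fractions, length 2
    labels: Optional[np.ndarray] = None  # {1, 2} per cell
    label_semantics: Dict[int, str] = field(default_factory=dict)

    def phenotype_calls(self) -> np.ndarray:
        """Per-cell 'atrial-like'/'ventricular-like' strings."""
        if self.labels is None or not self.label_semantics:
            raise ValueError("clustering/semantics not assigned yet")
        return np.array([self.label_semantics[int(l)] for l in self.labels])


@dataclass
class ROCResult:
    """Single-feature ROC summary with the Youden operating point."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # 'greater': value >= cutoff predicts the positive class
    youden_J: float


def _prepare_features(table: pd.DataFrame) -> pd.DataFrame:
    """Select, impute and validate the nine feature columns.

    A feature missing in more than half the cells is dropped; otherwise
    missing values are imputed by the cohort median (logged).
    """
    missing_cols = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks feature columns {missing_cols}")
    feats = table[FEATURE_COLUMNS].astype(float).copy()
    for c in FEATURE_COLUMNS:
        frac_na = feats[c].isna().mean()
        if frac_na > 0.5:
            logger.warning("feature %s missing in %.0f%% of cells; dropped", c, 100 * frac_na)
            feats = feats.drop(columns=c)
        elif frac_na > 0:
            med = feats[c].median()
            logger.warning("feature %s: imputing %d missing values by cohort median",
                           c, int(feats[c].isna().sum()))
            feats[c] = feats[c].fillna(med)
    return feats


def standardize_and_pca2(table: pd.DataFrame) -> ClusterResult:
    """Z-score the nine biomarkers and project the cells to 2-D.

    Constant features are dropped with a warning. The sign of each
    component is canonicalized so the APD90 loading on PC1 is ≥ 0 (and
    the largest-magnitude loading on PC2 is ≥ 0) — a flipped component
    is the same subspace.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 cells for PCA")
    feats = _prepare_features(table)
    sd = feats.std(ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        warnings.warn(f"constant features dropped before PCA: {const}", stacklevel=2)
        feats = feats.drop(columns=const)
        sd = sd.drop(index=const)
    z = (feats - feats.mean()) / sd
    pca = PCA(n_components=2)
    scores = pca.fit_transform(z.to_numpy())
    load = pca.components_.T.copy()  # features × 2
    # sign convention
    cols = list(feats.columns)
    if "APD90_ms" in cols and load[cols.index("APD90_ms"), 0] < 0:
        load[:, 0] *= -1
        scores[:, 0] *= -1
    if load[np.argmax(np.abs(load[:, 1])), 1] < 0:
        load[:, 1] *= -1
        scores[:, 1] *= -1
    return ClusterResult(
        pc_scores=scores,
        loadings=pd.DataFrame(load, index=cols, columns=["PC1", "PC2"]),
        variance_explained=pca.explained_variance_ratio_.copy(),
    )


def kmeans2(scores: np.ndarray, seed: int = 0) -> np.ndarray:
    """k-means with k = 2 on the PC scores; labels in {1, 2}.

    k-means++ seeding with 10 restarts, best inertia kept; deterministic
    under ``seed``. Raises on fewer than 2 points or all-identical
    points (degenerate clustering).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate clustering: all points identical")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    return km.fit_predict(scores) + 1


def cluster_cohort(table: pd.DataFrame, seed: int = 0) -> ClusterResult:
    """Full unsupervised pipeline: z-score → PCA(2) → k-means(2) → naming.

    Cluster semantics are assigned from the biomarker pattern: the
    cluster whose mean APD90 is lower is called atrial-like.
    """
    res = standardize_and_pca2(table)
    labels = kmeans2(res.pc_scores, seed=seed)
    apd90 = table["APD90_ms"].to_numpy(dtype=float)
    means = {l: float(np.nanmean(apd90[labels == l])) for l in (1, 2)}
    lo = min(means, key=means.get)
    res.labels = labels
    res.label_semantics = {lo: "atrial-like", 3 - lo: "ventricular-like"}
    return res


def roc_youden(values: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC of one feature against a binary label, with Youden cutoff.

    AUC is computed through the rank (Mann–Whitney) identity with tie
    handling, oriented so AUC ≥ 0.5 ('greater' when larger values
    predict the positive class, else 'less'). Candidate cutoffs are the
    midpoints between consecutive sorted unique values, so with perfect
    separation the cutoff falls strictly between the groups; ties in J
    break toward the lower cutoff. Sensitivity is the true-positive and
    specificity the true-negative rate at that cutoff.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(v)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    direction = "greater"
    if auc < 0.5:
        auc = 1.0 - auc
        direction = "less"
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([uniq[0]])
    best = None
    for c in mids:  # ascending: first max J is the lowest cutoff
        pred = (v >= c) if direction == "greater" else (v < c)
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    j, cutoff, sens, spec = best
    return ROCResult(
        auc=float(auc), cutoff=cutoff, sensitivity=sens, specificity=spec,
        direction=direction, youden_J=j,
    )


def classify_by_cutoff(
    bio: Union[APBiomarkers, float], cutoff: float = 0.44
) -> str:
    """Triangulation classifier: APD20/APD90 < cutoff → 'atrial-like',
    ≥ cutoff → 'ventricular-like' (the boundary is ventricular)."""
    ratio = bio.ratio_20_90 if isinstance(bio, APBiomarkers) else float(bio)
    if not np.isfinite(ratio):
        raise ValueError("APD20/APD90 ratio is not finite")
    return "atrial-like" if ratio < cutoff else "ventricular-like"


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when both groups have n ≤ 8 and no ties; the
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def levene_w(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classic Levene test (absolute deviations from the group mean)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrs):
        raise ValueError("each group needs at least 2 values")
    w, p = sps.levene(*arrs, center="mean")
    return float(w), float(p)
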