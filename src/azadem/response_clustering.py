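"""k-means clustering of methylation and expression response trajectories.

A trajectory summarizes one promoter (or gene) as two deltas relative to
untreated control: ``delta_acute`` and ``delta_recovery``. Methylation
trajectories are expressed in methylation-level units (negative =
demethylation, i.e. the negated angle-score change); expression
trajectories use log2 FPKM changes. Seven clusters are fit by design:
one no-change cluster plus three each for gain and loss of DNA
methylation, discriminating early (persistent), late (recovery-only) and
transient (acute-only) changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import ttest_ind
from sklearn.cluster import KMeans

__all__ = [
    "KMeansResult",
    "kmeans",
    "SEMANTIC_LABELS",
    "LOSS_LABELS",
    "GAIN_LABELS",
    "label_clusters",
    "ClusterReport",
    "proportion_report",
    "induction_calls",
    "differential_expression",
    "LinkedExpressionResult",
    "linked_expression_response",
]


@dataclass
class KMeansResult:
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float


def kmeans(points: np.ndarray, k: int, seed: int = 0, restarts: int = 25) -> KMeansResult:
    """Lloyd's k-means with k-means++ init, best of ``restarts`` runs by WCSS."""
    X = np.asarray(points, float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < k:
        raise ValueError(f"need at least k={k} points, got {len(X)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    return KMeansResult(labels, km.cluster_centers_, float(km.inertia_))


LOSS_LABELS = ("loss-early", "loss-late", "loss-transient")
GAIN_LABELS = ("gain-early", "gain-late", "gain-transient")
SEMANTIC_LABELS = ("no-change",) + GAIN_LABELS + LOSS_LABELS

# prototype sign patterns in (delta_acute, delta_recovery); loss of
# methylation is negative by the trajectory sign convention
_PROTOTYPES = {
    "loss-early": (-1.0, -1.0),
    "loss-late": (0.0, -1.0),
    "loss-transient": (-1.0, 0.0),
    "gain-early": (1.0, 1.0),
    "gain-late": (0.0, 1.0),
    "gain-transient": (1.0, 0.0),
}


def label_clusters(centroids: np.ndarray) -> list[str]:
    """Assign the seven semantic labels to seven cluster centroids.

    The centroid with the smallest L2 norm becomes "no-change"; the
    remaining six are matched one-to-one to the six prototype sign
    patterns by optimal assignment on Euclidean distance after scaling
    centroids to unit maximum magnitude. Each label is used exactly once.
    """
    C = np.asarray(centroids, float)
    if C.shape != (7, 2):
        raise ValueError(f"expected 7 centroids in 2-D, got shape {C.shape}")
    uniq = np.unique(np.round(C, 12), axis=0)
    if len(uniq) < 7:
        warnings.warn("duplicate centroids; label ties broken by cluster index",
                      stacklevel=2)
    norms = np.linalg.norm(C, axis=1)
    no_change = int(norms.argmin())
    rest = [i for i in range(7) if i != no_change]
    scale = np.abs(C[rest]).max()
    if scale == 0:
        scale = 1.0
    normed = C[rest] / scale
    labels_order = list(_PROTOTYPES)
    proto = np.array([_PROTOTYPES[l] for l in labels_order])
    cost = np.linalg.norm(normed[:, None, :] - proto[None, :, :], axis=-1)
    ri, cj = linear_sum_assignment(cost)
    out = [""] * 7
    out[no_change] = "no-change"
    for i, j in zip(ri, cj):
        out[rest[i]] = labels_order[j]
    return out


@dataclass
class ClusterReport:
    """Cluster assignments with semantic labels and unit proportions."""

    k: int
    assignments: pd.Series  # unit_id -> cluster index
    centroids: np.ndarray
    labels: list[str]  # per-cluster semantic label
    counts: dict[str, int] = field(default_factory=dict)
    proportions: dict[str, float] = field(default_factory=dict)  # percent of all units
    loss_total_pct: float = 0.0
    gain_total_pct: float = 0.0

    @property
    def n_units(self) -> int:
        return len(self.assignments)

    def units_with_labels(self, wanted: Sequence[str]) -> list:
        idx = [i for i, l in enumerate(self.labels) if l in wanted]
        return list(self.assignments.index[self.assignments.isin(idx)])

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_units": self.n_units,
            "counts": self.counts,
            "proportions_pct": {k: round(v, 4) for k, v in self.proportions.items()},
            "loss_total_pct": round(self.loss_total_pct, 4),
            "gain_total_pct": round(self.gain_total_pct, 4),
        }


def proportion_report(
    assignments: pd.Series, centroids: np.ndarray, labels: Sequence[str] | None = None
) -> ClusterReport:
    """Per-cluster percentages of all input units, plus loss/gain totals.

    Aggregates are computed from unit counts (not from rounded
    per-cluster percentages), so e.g. loss clusters holding 23.0%, 3.7%
    and 5.4% of units aggregate to exactly 32.1%.
    """
    assignments = pd.Series(assignments)
    k = len(centroids)
    if labels is None:
        labels = label_clusters(centroids)
    if len(labels) != k:
        raise ValueError("one semantic label per cluster required")
    n = len(assignments)
    counts = {}
    props = {}
    for ci in range(k):
        cnt = int((assignments == ci).sum())
        counts[labels[ci]] = counts.get(labels[ci], 0) + cnt
    for lbl, cnt in counts.items():
        props[lbl] = 100.0 * cnt / n if n else 0.0
    loss_n = sum(counts.get(l, 0) for l in LOSS_LABELS)
    gain_n = sum(counts.get(l, 0) for l in GAIN_LABELS)
    return ClusterReport(
        k=k,
        assignments=assignments,
        centroids=np.asarray(centroids, float),
        labels=list(labels),
        counts=counts,
        proportions=props,
        loss_total_pct=100.0 * loss_n / n if n else 0.0,
        gain_total_pct=100.0 * gain_n / n if n else 0.0,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def differential_expression(
    expression,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 0.1,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simple replicate-based differential expression calls.

    A deliberately plain rule used as plumbing around the methylation
    analyses: per-gene Welch t-test on log2(FPKM + pseudocount) across
    replicates, BH correction, and a fold-change floor. Returns a table
    with ``log2fc`` (b over a), ``p``, ``q`` and ``direction`` in
    {up, down, none}.
    """
    A = np.log2(expression.replicate_matrix(cond_a) + pseudocount)
    B = np.log2(expression.replicate_matrix(cond_b) + pseudocount)
    B = B.loc[A.index]
    lfc = B.mean(axis=1) - A.mean(axis=1)
    t, p = ttest_ind(B.to_numpy(), A.to_numpy(), axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = _bh_adjust(p)
    direction = np.where(
        (q < alpha) & (lfc >= lfc_min), "up",
        np.where((q < alpha) & (lfc <= -lfc_min), "down", "none"),
    )
    return pd.DataFrame(
        {"gene_id": A.index, "log2fc": lfc.to_numpy(), "p": p, "q": q,
         "direction": direction}
    ).set_index("gene_id")


def induction_calls(
    expression, cond_control: str, cond_treated: str, **kw
) -> pd.Series:
    """Boolean per-gene induction calls (up-regulation only)."""
    de = differential_expression(expression, cond_control, cond_treated, **kw)
    return de["direction"] == "up"


@dataclass
class LinkedExpressionResult:
    expression_report: ClusterReport | None
    induced_genes: list[str]
    induced_fraction_pct: float  # relative to ALL original units
    selected_units: list
    note: str = ""


def linked_expression_response(
    meth_report: ClusterReport,
    unit_gene: Mapping,
    expr_trajectories: pd.DataFrame,
    expression,
    cond_control: str,
    cond_acute: str,
    select_labels: Sequence[str] = LOSS_LABELS,
    k_expr: int = 4,
    seed: int = 0,
    restarts: int = 25,
) -> LinkedExpressionResult:
    """Expression response of genes linked to the greatest-loss clusters.

    Units in the selected methylation clusters are mapped to genes via
    ``unit_gene``; their expression trajectories (columns
    ``delta_acute, delta_recovery`` indexed by gene) are clustered with
    k-means (k = ``k_expr``), and the induced fraction is reported
    relative to the ORIGINAL unit count, so it is directly comparable
    with the methylation-cluster percentages.
    """
    units = meth_report.units_with_labels(select_labels)
    if not units:
        warnings.warn("no units in the selected methylation clusters", stacklevel=2)
        return LinkedExpressionResult(None, [], 0.0, [], "empty selection")
    genes = sorted({unit_gene[u] for u in units if u in unit_gene and unit_gene[u]})
    if not genes:
        raise ValueError("no linked genes for the selected clusters")
    traj = expr_trajectories.loc[expr_trajectories.index.intersection(genes)]
    report = None
    if len(traj) >= k_expr:
        res = kmeans(traj[["delta_acute", "delta_recovery"]].to_numpy(), k_expr,
                     seed=seed, restarts=restarts)
        assignments = pd.Series(res.assignments, index=traj.index)
        counts = {f"expr-cluster-{i}": int((res.assignments == i).sum()) for i in range(k_expr)}
        props = {k: 100.0 * v / meth_report.n_units for k, v in counts.items()}
        report = ClusterReport(
            k=k_expr, assignments=assignments, centroids=res.centroids,
            labels=[f"expr-cluster-{i}" for i in range(k_expr)],
            counts=counts, proportions=props,
        )
    induced = induction_calls(expression, cond_control, cond_acute)
    induced_genes = sorted(g for g in genes if induced.get(g, False))
    frac = 100.0 * len(induced_genes) / meth_report.n_units
    return LinkedExpressionResult(report, induced_genes, frac, units)
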