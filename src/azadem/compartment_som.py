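"""Genome compartmentalization with a self-organizing map (SOM).

The genome is tiled into 100-kb windows on a 50-kb lattice; each window
is described by control methylation, treated methylation (1.0 uM acute),
mean expression of genes whose TSS falls in the window, and the
cumulative CCGG (HpaII site) count. A batch-trained Kohonen map places
similar windows on nearby grid nodes; the U-matrix visualizes partition
boundaries, and quantile overlays quantify whether the windows with the
strongest demethylation response concentrate in the euchromatic
partition (top expression, top baseline methylation).

Quantile tags are quintiles (5 equal-frequency bins, tags 1..5, 5 = top).
The methylation quantile is computed on the methylation *level*
(100 - angle score), so tag 5 marks the most methylated windows; the
response quantile is computed on ``meth_treated - meth_control`` in
angle-score units (positive = demethylated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core_io import GeneModel, GenomicInterval

__all__ = [
    "WINDOW_SIZE",
    "WINDOW_STEP",
    "make_windows",
    "window_features",
    "zscore",
    "SomGrid",
    "train_som",
    "u_matrix",
    "EnrichmentResult",
    "overlay_enrichment",
    "node_label_density",
    "save_matrix_png",
]

WINDOW_SIZE = 100_000
WINDOW_STEP = 50_000

QUANTILE_COLS = {"methylation": "q_meth", "expression": "q_expr", "response": "q_response"}


def make_windows(
    chrom_sizes: Mapping[str, int],
    window: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> list[GenomicInterval]:
    """Sliding windows starting at 0, step, 2*step, ...

    Only fully contained windows are emitted; output is sorted by
    chromosome name and therefore invariant to input ordering.
    """
    out = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        if size <= 0:
            raise ValueError(f"non-positive size for {chrom}")
        start = 0
        while start + window <= size:
            out.append(GenomicInterval(chrom, start, start + window))
            start += step
    return out


def _window_index(pos: np.ndarray, n_windows: int, window: int, step: int) -> list[np.ndarray]:
    """For each overlap rank k, the window index containing each position."""
    hits = []
    n_per = window // step  # how many windows cover one position
    base = pos // step
    for k in range(n_per):
        w = base - k
        valid = (w >= 0) & (w < n_windows)
        hits.append((w, valid))
    return hits


def window_features(
    windows: Sequence[GenomicInterval],
    track_control: pd.DataFrame,
    track_treated: pd.DataFrame,
    expression_mean: pd.Series,
    gene_models: Sequence[GeneModel],
    ccgg_sites: pd.DataFrame,
    window: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """Per-window feature table for SOM training.

    ``track_*`` are angle tracks (chrom, pos, score); ``expression_mean``
    maps gene_id -> mean FPKM; ``ccgg_sites`` lists CCGG positions
    (chrom, pos). Windows lacking either HpaII sites or genes get missing
    features, are excluded from training (``excluded`` flag) and counted;
    quantile tags (quintiles 1..5) are computed over non-excluded windows.
    """
    if not windows:
        raise ValueError("no windows given")
    wdf = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
        }
    )
    n = len(wdf)
    sums = {k: np.zeros(n) for k in ("meth_c", "meth_t", "expr", "sites")}
    counts = {k: np.zeros(n) for k in ("meth_c", "meth_t", "expr")}

    # map window (chrom, start) -> row index; windows lie on the step lattice
    by_chrom: dict[str, dict[int, int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, {})[w.start] = i

    def _accumulate(chrom: str, pos: np.ndarray, val: np.ndarray, key: str, count_key=None):
        lattice = by_chrom.get(chrom, {})
        if not lattice:
            return
        base = pos // step
        for k in range(window // step):
            wstart = (base - k) * step
            for ws, v in zip(wstart, val):
                idx = lattice.get(int(ws))
                if idx is not None:
                    sums[key][idx] += v
                    if count_key:
                        counts[count_key][idx] += 1

    for track, key in ((track_control, "meth_c"), (track_treated, "meth_t")):
        for chrom, sub in track.groupby("chrom"):
            _accumulate(chrom, sub["pos"].to_numpy(), sub["score"].to_numpy(), key, key)

    tss_rows = []
    for g in gene_models:
        try:
            tss_rows.append((g.chrom, g.tss(), expression_mean.get(g.gene_id, np.nan)))
        except ValueError:
            continue  # unstranded gene: no TSS, not assignable
    if tss_rows:
        gdf = pd.DataFrame(tss_rows, columns=["chrom", "pos", "fpkm"]).dropna()
        for chrom, sub in gdf.groupby("chrom"):
            _accumulate(chrom, sub["pos"].to_numpy(), sub["fpkm"].to_numpy(), "expr", "expr")

    for chrom, sub in ccgg_sites.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        _accumulate(chrom, pos, np.ones(len(pos)), "sites")

    with np.errstate(invalid="ignore", divide="ignore"):
        wdf["meth_control"] = np.where(counts["meth_c"] > 0, sums["meth_c"] / np.maximum(counts["meth_c"], 1), np.nan)
        wdf["meth_treated"] = np.where(counts["meth_t"] > 0, sums["meth_t"] / np.maximum(counts["meth_t"], 1), np.nan)
        wdf["expr_mean"] = np.where(counts["expr"] > 0, sums["expr"] / np.maximum(counts["expr"], 1), np.nan)
    wdf["hpaii_sites"] = sums["sites"].astype(int)
    wdf["n_genes"] = counts["expr"].astype(int)

    feature_cols = ["meth_control", "meth_treated", "expr_mean"]
    wdf["excluded"] = wdf[feature_cols].isna().any(axis=1) | (wdf["hpaii_sites"] == 0)
    n_excluded = int(wdf["excluded"].sum())
    if n_excluded == n:
        raise ValueError("no window has both methylation and expression data")
    wdf.attrs["n_excluded"] = n_excluded

    ok = ~wdf["excluded"]
    wdf["response"] = wdf["meth_treated"] - wdf["meth_control"]
    # Precision-standardized response for the quantile tag: the raw
    # per-window delta has standard error proportional to
    # sqrt(1/n_control + 1/n_treated), so sparse (low-CCGG) windows would
    # otherwise dominate the response extremes through noise alone.
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(1.0 / np.maximum(counts["meth_c"], 1)
                     + 1.0 / np.maximum(counts["meth_t"], 1))
        wdf["response_z"] = wdf["response"] / se
    quant_src = {
        "q_meth": 100.0 - wdf["meth_control"],  # methylation level
        "q_expr": wdf["expr_mean"],
        "q_response": wdf["response_z"],
    }
    for col, series in quant_src.items():
        tags = pd.Series(np.nan, index=wdf.index)
        ranks = series[ok].rank(method="first")
        tags[ok] = np.ceil(ranks / len(ranks) * 5).clip(1, 5)
        wdf[col] = tags
    return wdf


def zscore(X: np.ndarray) -> np.ndarray:
    """Column-wise z-scaling; zero-variance columns map to zeros."""
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


@dataclass
class SomGrid:
    """A trained Kohonen map: node weights plus training metadata."""

    shape: tuple[int, int]
    weights: np.ndarray  # (rows*cols, dim)
    qe_history: list[float] = field(default_factory=list)
    epochs: int = 0
    seed: int = 0
    radius_schedule: tuple[float, float] = (0.0, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Best-matching unit (minimum Euclidean distance) per row of X."""
        d = ((np.asarray(X, float)[:, None, :] - self.weights[None, :, :]) ** 2).sum(-1)
        return d.argmin(axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        """Root-mean-square distance of each vector to its BMU."""
        d = ((np.asarray(X, float)[:, None, :] - self.weights[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d.min(axis=1).mean()))


def train_som(
    features: np.ndarray,
    grid_shape: tuple[int, int] = (20, 20),
    epochs: int = 100,
    seed: int = 0,
) -> SomGrid:
    """Batch-train a Kohonen SOM on (already scaled) feature vectors.

    Gaussian neighborhood on the rectangular lattice, radius decaying
    linearly from max(grid)/2 to ~0 across epochs (late epochs are
    therefore plain Lloyd steps). Nodes receiving no mass in an epoch
    keep their weights. Training is deterministic given the seed.

    A monotone-distortion safeguard keeps the recorded quantization
    error (RMS distance to the BMU) non-increasing: if a wide-radius
    batch update would raise it, the radius for that epoch is halved
    until the update is admissible, falling back to a plain Lloyd step
    (which cannot increase the distortion).
    """
    X = np.asarray(features, float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("features must be a non-empty 2-D array")
    if not np.isfinite(X).all():
        bad = np.where(~np.isfinite(X).all(axis=1))[0]
        raise ValueError(f"non-finite feature rows at indices {bad[:20].tolist()}")
    rows, cols = grid_shape
    n_nodes = rows * cols
    if len(X) < 5 * n_nodes:
        warnings.warn(
            f"only {len(X)} training vectors for {n_nodes} nodes "
            "(< 5 per node); the map may be under-determined",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.integers(0, len(X), size=n_nodes)
    W = X[init_idx].astype(float).copy()

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

    r0 = max(rows, cols) / 2.0
    r_end = 0.25

    def _batch_update(W, radius):
        d = ((X[:, None, :] - W[None, :, :]) ** 2).sum(-1)
        bmu = d.argmin(axis=1)
        if radius > 0:
            h = np.exp(-grid_d2[bmu] / (2.0 * radius * radius))  # (n, nodes)
            h[h < 1e-12] = 0.0
        else:  # pure Lloyd step: mass only at the BMU
            h = np.zeros((len(X), rows * cols))
            h[np.arange(len(X)), bmu] = 1.0
        mass = h.sum(axis=0)
        num = h.T @ X
        W_new = W.copy()
        upd = mass > 0
        W_new[upd] = num[upd] / mass[upd, None]
        return W_new

    def _qe(W):
        d = ((X[:, None, :] - W[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d.min(axis=1).mean()))

    qe_history = []
    qe_prev = _qe(W)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = r0 + (r_end - r0) * frac
        while True:
            W_new = _batch_update(W, radius)
            qe_new = _qe(W_new)
            if qe_new <= qe_prev + 1e-12 or radius <= 0:
                break
            radius = radius / 2.0 if radius > 1e-3 else 0.0
        W = W_new
        qe_prev = min(qe_prev, qe_new)
        qe_history.append(qe_new)
    return SomGrid(
        shape=(rows, cols),
        weights=W,
        qe_history=qe_history,
        epochs=epochs,
        seed=seed,
        radius_schedule=(r0, r_end),
    )


def u_matrix(grid: SomGrid) -> np.ndarray:
    """Per-node mean Euclidean distance to 4-connected lattice neighbors."""
    if grid.epochs == 0 or not len(grid.qe_history):
        raise ValueError("grid is untrained")
    rows, cols = grid.shape
    W = grid.weights.reshape(rows, cols, -1)
    um = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            ds = []
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    ds.append(np.linalg.norm(W[r, c] - W[rr, cc]))
            um[r, c] = float(np.mean(ds))
    return um


@dataclass
class EnrichmentResult:
    """2x2 cross-tabulation of two top-quantile labels over windows."""

    table: np.ndarray  # [[both, a_only], [b_only, neither]]
    odds_ratio: float
    p_value: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "note": self.note,
        }


def overlay_enrichment(
    features: pd.DataFrame,
    label_a: str,
    label_b: str,
    top_tag: int = 5,
) -> EnrichmentResult:
    """Association of two top-quantile window labels (Fisher exact test).

    ``label_a``/``label_b`` are "methylation", "expression" or
    "response". Windows excluded from training are ignored. The odds
    ratio is the sample odds ratio ad/bc, reported as ``inf`` when the
    off-diagonal product is zero but the diagonal is not, and undefined
    (nan) on degenerate margins.
    """
    cols = {k: QUANTILE_COLS.get(k, k) for k in (label_a, label_b)}
    for lbl, col in cols.items():
        if col not in features.columns:
            raise KeyError(f"no quantile column for label {lbl!r}")
    ok = ~features["excluded"] if "excluded" in features.columns else np.ones(len(features), bool)
    a = (features.loc[ok, cols[label_a]] == top_tag).to_numpy()
    b = (features.loc[ok, cols[label_b]] == top_tag).to_numpy()
    t11 = int((a & b).sum())
    t10 = int((a & ~b).sum())
    t01 = int((~a & b).sum())
    t00 = int((~a & ~b).sum())
    table = np.array([[t11, t10], [t01, t00]])
    note = ""
    if a.all() or (~a).all() or b.all() or (~b).all():
        return EnrichmentResult(table, float("nan"), 1.0, "degenerate margin: odds ratio undefined")
    _, p = fisher_exact(table, alternative="two-sided")
    if t10 * t01 == 0:
        oratio = float("inf") if t11 * t00 > 0 else float("nan")
        if np.isnan(oratio):
            note = "all-zero diagonal and off-diagonal"
    else:
        oratio = (t11 * t00) / (t10 * t01)
    return EnrichmentResult(table, float(oratio), float(p), note)


def node_label_density(grid: SomGrid, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-node count of masked windows (for dual-color overlay plots)."""
    bmu = grid.bmu(X)
    rows, cols = grid.shape
    out = np.zeros(rows * cols)
    np.add.at(out, bmu[np.asarray(mask, bool)], 1)
    return out.reshape(rows, cols)


def save_matrix_png(matrix: np.ndarray, path, cmap: str = "gray_r") -> None:
    """Render a node matrix (U-matrix or overlay density) as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(matrix, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
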