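"""Promoter categorization by CG dinucleotide observed/expected ratio.

Promoters (TSS +/- 1.5 kb by default, or ChIP peak summits +/- the same
flank) are scored by

    obs/exp CG = (#CG dinucleotides * L) / (#C * #G)

with N bases dropped from counts and from L. The distribution of ratios
over a promoter set is bimodal; a data-driven cutoff at the local
minimum of a kernel density estimate splits promoters into low-CG (LCG)
and high-CG (HCG) classes. The methylated-LCG subset isolates LCG
promoters whose methylation score falls below the lower bound of the
normal reference band of the HCG promoters (mean - 1.96 sd), i.e.
promoters distinctly more methylated than the HCG reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, mannwhitneyu

from .core_io import GeneModel, GenomicInterval

__all__ = [
    "attach_region_methylation",
    "cg_obs_exp",
    "UnimodalityError",
    "bimodal_cutoff",
    "CutoffDiagnostics",
    "promoter_records",
    "classify_promoters",
    "peak_promoters",
    "methylated_lcg_subset",
    "SubsetExpressionReport",
    "expression_of_subset",
]

DEFAULT_FLANK = 1500  # +/- 1.5 kb around the anchor -> 3 kb regions


def cg_obs_exp(sequence: str) -> float:
    """Observed/expected CG dinucleotide ratio of a nucleotide string.

    Counts CG pairs over all overlapping dinucleotide positions (both
    bases non-N); L is the number of non-N bases. Case-insensitive and
    invariant to appended runs of N. Returns 0 when the sequence lacks C
    or G; raises on empty / all-N input.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    n_c = seq.count("C")
    n_g = seq.count("G")
    L = len(seq) - seq.count("N")
    if L == 0:
        raise ValueError("all-N sequence")
    if n_c * n_g == 0:
        return 0.0
    n_cg = sum(1 for a, b in zip(seq, seq[1:]) if a == "C" and b == "G")
    return (n_cg * L) / (n_c * n_g)


class UnimodalityError(ValueError):
    """The ratio density has a single mode; carries its location."""

    def __init__(self, mode: float):
        self.mode = float(mode)
        super().__init__(
            f"density is unimodal (mode at {mode:.4f}); no data-driven cutoff "
            "(force a manual cutoff if appropriate)"
        )


@dataclass
class CutoffDiagnostics:
    cutoff: float
    modes: list[float]
    grid: np.ndarray
    density: np.ndarray
    multimodal_flag: bool  # True when more than two modes were found


def bimodal_cutoff(ratios: Sequence[float], n_grid: int = 512, full: bool = False):
    """Data-driven HCG/LCG cutoff at the valley of a bimodal KDE.

    Gaussian KDE with Silverman bandwidth, evaluated on a fixed lattice
    of ``n_grid`` points over [0, max(ratio)]; the cutoff is the lowest
    density point between the two highest modes. Raises
    :class:`UnimodalityError` when only one mode exists; a diagnostic
    flag is set when more than two modes are present.
    """
    x = np.asarray(ratios, float)
    if len(x) < 100:
        raise ValueError(f"need >= 100 ratios for a stable density, got {len(x)}")
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(0.0, float(x.max()), n_grid)
    dens = kde(grid)
    # interior local maxima (plateaus resolved leftward)
    is_max = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    max_idx = np.where(is_max)[0] + 1
    if len(max_idx) < 2:
        raise UnimodalityError(grid[int(dens.argmax())])
    top2 = max_idx[np.argsort(dens[max_idx])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(dens[lo : hi + 1].argmin())
    diag = CutoffDiagnostics(
        cutoff=float(grid[valley]),
        modes=[float(grid[i]) for i in sorted(max_idx, key=lambda i: -dens[i])],
        grid=grid,
        density=dens,
        multimodal_flag=len(max_idx) > 2,
    )
    if diag.multimodal_flag:
        warnings.warn(
            f"ratio density has {len(max_idx)} modes; cutoff taken between the "
            "two highest", stacklevel=2,
        )
    return diag if full else diag.cutoff


def _region(chrom: str, anchor: int, flank: int, chrom_size: int | None = None) -> GenomicInterval:
    start = max(0, anchor - flank)
    end = anchor + flank
    if chrom_size is not None:
        end = min(end, chrom_size)
    return GenomicInterval(chrom, start, end)


def promoter_records(
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    unstranded_as_plus: bool = False,
) -> pd.DataFrame:
    """TSS-anchored promoter records with CG obs/exp ratios.

    ``genome`` maps chromosome name to sequence (e.g. from
    :func:`azadem.core_io.read_fasta`).
    """
    rows = []
    for g in gene_models:
        tss = g.tss(unstranded_as_plus=unstranded_as_plus)
        seq = genome[g.chrom]
        region = _region(g.chrom, tss, flank, len(seq))
        rows.append(
            {
                "promoter_id": g.gene_id,
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "anchor": tss,
                "start": region.start,
                "end": region.end,
                "cg_ratio": cg_obs_exp(seq[region.start : region.end]),
            }
        )
    return pd.DataFrame(rows)


def attach_region_methylation(
    records: pd.DataFrame, track: pd.DataFrame, column: str
) -> pd.DataFrame:
    """Mean angle score of track sites within each record's region.

    Records without any site get NaN (absent, not zero).
    """
    out = records.copy()
    vals = np.full(len(out), np.nan)
    by_chrom = {c: s.sort_values("pos") for c, s in track.groupby("chrom")}
    for i, (_, r) in enumerate(out.iterrows()):
        sub = by_chrom.get(r["chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [r["start"], r["end"]])
        if hi > lo:
            vals[i] = float(sub["score"].to_numpy()[lo:hi].mean())
    out[column] = vals
    return out


def classify_promoters(records: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Assign HCG/LCG classes; a ratio exactly at the cutoff is HCG."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    out = records.copy()
    out["cg_class"] = np.where(out["cg_ratio"] >= cutoff, "HCG", "LCG")
    n = len(out)
    n_lcg = int((out["cg_class"] == "LCG").sum())
    out.attrs["class_counts"] = {"HCG": n - n_lcg, "LCG": n_lcg}
    out.attrs["lcg_fraction"] = n_lcg / n if n else float("nan")
    return out


def peak_promoters(
    peaks: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    link_dist: int = 2000,
) -> pd.DataFrame:
    """Peak-summit-anchored promoter records, gene-linked within link_dist.

    One record per peak; peaks with no TSS within ``link_dist`` keep an
    empty gene link.
    """
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in gene_models:
        try:
            tss_by_chrom.setdefault(g.chrom, []).append((g.tss(), g.gene_id))
        except ValueError:
            continue
    for lst in tss_by_chrom.values():
        lst.sort()
    rows = []
    for i, pk in peaks.iterrows():
        summit = int(pk["summit"]) if "summit" in pk and pd.notna(pk["summit"]) else int(
            (pk["start"] + pk["end"]) // 2
        )
        chrom = pk["chrom"]
        gene_id = ""
        cand = tss_by_chrom.get(chrom, [])
        if cand:
            pos = np.array([t for t, _ in cand])
            j = int(np.abs(pos - summit).argmin())
            if abs(int(pos[j]) - summit) <= link_dist:
                gene_id = cand[j][1]
        seq = genome[chrom]
        region = _region(chrom, summit, flank, len(seq))
        rows.append(
            {
                "promoter_id": pk.get("name", f"peak_{i}"),
                "gene_id": gene_id,
                "chrom": chrom,
                "anchor": summit,
                "start": region.start,
                "end": region.end,
                "cg_ratio": cg_obs_exp(seq[region.start : region.end]),
            }
        )
    return pd.DataFrame(rows)


def methylated_lcg_subset(
    records: pd.DataFrame,
    meth_col: str = "meth_control",
    min_hcg: int = 30,
) -> tuple[pd.DataFrame, float]:
    """LCG promoters more methylated than the HCG reference band.

    The threshold is ``mean - 1.96 sd`` of the HCG methylation scores
    (a normal reference band, not a CI of the mean). Because higher
    angle scores mean less methylation, LCG records with scores *below*
    the threshold are the distinctly methylated subset. Returns
    (subset, threshold); an empty subset is a valid outcome.
    """
    if "cg_class" not in records.columns:
        raise ValueError("records lack cg_class; run classify_promoters first")
    hcg = records.loc[records["cg_class"] == "HCG", meth_col].dropna()
    if len(hcg) < min_hcg:
        raise ValueError(f"only {len(hcg)} HCG records with methylation (need >= {min_hcg})")
    threshold = float(hcg.mean() - 1.96 * hcg.std(ddof=1))
    lcg = records[records["cg_class"] == "LCG"]
    subset = lcg[lcg[meth_col] < threshold].copy()
    subset.attrs["threshold"] = threshold
    return subset, threshold


@dataclass
class SubsetExpressionReport:
    p_value: float
    median_subset: float
    median_background: float
    n_subset: int
    n_background: int
    quantile_table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "median_subset": self.median_subset,
            "median_background": self.median_background,
            "n_subset": self.n_subset,
            "n_background": self.n_background,
        }


def expression_of_subset(
    subset_fpkm: Sequence[float], background_fpkm: Sequence[float]
) -> SubsetExpressionReport:
    """Compare subset vs background FPKM distributions (two-sided rank-sum).

    The report states the comparison; whether the two are "comparable"
    is left to the reader, not asserted.
    """
    a = np.asarray(subset_fpkm, float)
    b = np.asarray(background_fpkm, float)
    if len(a) == 0:
        raise ValueError("empty subset")
    if len(b) == 0:
        raise ValueError("empty background")
    _, p = mannwhitneyu(a, b, alternative="two-sided")
    qs = [0.1, 0.25, 0.5, 0.75, 0.9]
    qt = pd.DataFrame(
        {"quantile": qs, "subset": np.quantile(a, qs), "background": np.quantile(b, qs)}
    )
    return SubsetExpressionReport(
        p_value=float(p),
        median_subset=float(np.median(a)),
        median_background=float(np.median(b)),
        n_subset=len(a),
        n_background=len(b),
        quantile_table=qt,
    )
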