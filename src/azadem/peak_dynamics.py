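"""RNAPII ChIP-seq peak dynamics between conditions.

Treated peaks are classified concordant (overlap a control peak) or new,
control-only peaks lost; peaks are placed into mutually exclusive genic
contexts (promoter = TSS +/- 2 kb; intragenic = gene body minus the
promoter; intergenic otherwise, with priority promoter > intragenic >
intergenic). New intragenic peaks are tested for a paired methylation
shift and their host genes for loss of silent status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binomtest, wilcoxon

from .core_io import GeneModel

__all__ = [
    "PeakComparison",
    "compare_peaks",
    "classify_context",
    "MethylationShift",
    "methylation_shift_at",
    "SilentActivationReport",
    "silent_activation",
    "intragenic_enrichment",
]

PROMOTER_FLANK = 2000


def _trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        t = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            t.addi(int(s), int(e))
        trees[chrom] = t
    return trees


def _max_overlap(tree: IntervalTree | None, start: int, end: int) -> int:
    if tree is None:
        return 0
    best = 0
    for iv in tree.overlap(start, end):
        best = max(best, min(end, iv.end) - max(start, iv.begin))
    return best


@dataclass
class PeakComparison:
    treated: pd.DataFrame  # with status in {concordant, new}
    control_only: pd.DataFrame  # status == lost
    counts: dict[str, int] = field(default_factory=dict)


def compare_peaks(
    control: pd.DataFrame, treated: pd.DataFrame, min_overlap: int = 1
) -> PeakComparison:
    """Annotate treated peaks concordant/new and control-only peaks lost.

    A treated peak is concordant iff it overlaps any control peak by at
    least ``min_overlap`` bp. An assembly guard raises when two
    non-empty sets share no chromosome at all (listing the offending
    names); a partial chromosome mismatch only warns.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    c_chroms = set(control["chrom"]) if len(control) else set()
    t_chroms = set(treated["chrom"]) if len(treated) else set()
    if c_chroms and t_chroms:
        if not (c_chroms & t_chroms):
            raise ValueError(
                "peak sets share no chromosome; offending names: "
                f"control={sorted(c_chroms)}, treated={sorted(t_chroms)}"
            )
        diff = c_chroms ^ t_chroms
        if diff:
            warnings.warn(f"chromosomes present in only one set: {sorted(diff)}",
                          stacklevel=2)

    ctrees = _trees(control)
    ttrees = _trees(treated)
    treated = treated.copy()
    statuses = []
    for _, pk in treated.iterrows():
        ov = _max_overlap(ctrees.get(pk["chrom"]), int(pk["start"]), int(pk["end"]))
        statuses.append("concordant" if ov >= min_overlap else "new")
    treated["status"] = statuses
    control_only = control.copy()
    lost_mask = []
    for _, pk in control_only.iterrows():
        ov = _max_overlap(ttrees.get(pk["chrom"]), int(pk["start"]), int(pk["end"]))
        lost_mask.append(ov < min_overlap)
    control_only = control_only[np.asarray(lost_mask, bool) if len(control_only) else []]
    control_only = control_only.assign(status="lost") if len(control_only) else control_only
    counts = {
        "concordant": int((treated["status"] == "concordant").sum()),
        "new": int((treated["status"] == "new").sum()),
        "lost": int(len(control_only)),
        "n_treated": int(len(treated)),
        "n_control": int(len(control)),
    }
    return PeakComparison(treated, control_only, counts)


def classify_context(
    peaks: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    promoter_flank: int = PROMOTER_FLANK,
) -> pd.DataFrame:
    """Mutually exclusive genic context per peak.

    Judged by the summit when present, else by any-bp overlap of the
    whole peak. Priority promoter > intragenic > intergenic when a peak
    touches several contexts; the linked gene_id is that of the matched
    promoter or host gene body.
    """
    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        try:
            tss = g.tss()
        except ValueError:
            continue
        prom_trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, tss - promoter_flank), tss + promoter_flank, g.gene_id
        )
        body_trees.setdefault(g.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g.gene_id
        )

    out = peaks.copy()
    classes, gene_ids = [], []
    for _, pk in out.iterrows():
        chrom = pk["chrom"]
        if "summit" in pk and pd.notna(pk["summit"]):
            qs, qe = int(pk["summit"]), int(pk["summit"]) + 1
        else:
            qs, qe = int(pk["start"]), int(pk["end"])
        prom_hits = prom_trees.get(chrom, IntervalTree()).overlap(qs, qe)
        if prom_hits:
            classes.append("promoter")
            gene_ids.append(sorted(h.data for h in prom_hits)[0])
            continue
        body_hits = body_trees.get(chrom, IntervalTree()).overlap(qs, qe)
        if body_hits:
            classes.append("intragenic")
            gene_ids.append(sorted(h.data for h in body_hits)[0])
            continue
        classes.append("intergenic")
        gene_ids.append("")
    out["context"] = classes
    out["gene_id"] = gene_ids
    return out


@dataclass
class MethylationShift:
    deltas: pd.Series  # per-peak mean score delta (treated - control)
    p_value: float | None
    median_delta: float
    n_peaks_used: int
    n_peaks_empty: int
    note: str = ""


def methylation_shift_at(
    peaks: pd.DataFrame,
    track_control: pd.DataFrame,
    track_treated: pd.DataFrame,
    flank: int = 500,
) -> MethylationShift:
    """Paired angle-score shift at peak regions (one-sided Wilcoxon).

    Per peak, the mean score of sites within summit +/- ``flank`` is
    compared between conditions (sites present in both tracks); the
    alternative is delta > 0, i.e. demethylation. Peaks whose region
    holds no shared site are excluded and counted; a single usable peak
    skips the test with a warning but still reports the delta.
    """
    merged = track_control.merge(
        track_treated, on=["chrom", "pos"], suffixes=("_c", "_t")
    )
    if merged.empty:
        raise ValueError("methylation tracks share no sites")
    by_chrom = {c: s.sort_values("pos") for c, s in merged.groupby("chrom")}
    deltas = {}
    n_empty = 0
    for i, pk in peaks.iterrows():
        summit = int(pk["summit"]) if "summit" in pk and pd.notna(pk["summit"]) else int(
            (pk["start"] + pk["end"]) // 2
        )
        sub = by_chrom.get(pk["chrom"])
        if sub is None:
            n_empty += 1
            continue
        lo, hi = summit - flank, summit + flank
        sel = sub[(sub["pos"] >= lo) & (sub["pos"] <= hi)]
        if sel.empty:
            n_empty += 1
            continue
        deltas[pk.get("name", i)] = float(sel["score_t"].mean() - sel["score_c"].mean())
    if not deltas:
        raise ValueError("no peak region contains any methylation site")
    d = pd.Series(deltas)
    note = ""
    if len(d) < 2 or np.allclose(d, 0):
        warnings.warn("too few usable peaks for a signed-rank test", stacklevel=2)
        p = None
        note = "test skipped (insufficient peaks)"
    else:
        _, p = wilcoxon(d.to_numpy(), alternative="greater")
        p = float(p)
    return MethylationShift(
        deltas=d, p_value=p, median_delta=float(d.median()),
        n_peaks_used=len(d), n_peaks_empty=n_empty, note=note,
    )


@dataclass
class SilentActivationReport:
    fraction_silent_before: float
    fraction_silent_after: float
    activated_genes: list[str]  # silent before AND expressed after
    n_genes: int

    def to_dict(self) -> dict:
        return {
            "fraction_silent_before": self.fraction_silent_before,
            "fraction_silent_after": self.fraction_silent_after,
            "n_activated": len(self.activated_genes),
            "n_genes": self.n_genes,
        }


def silent_activation(
    gene_ids: Sequence[str],
    expression,
    cond_before: str,
    cond_after: str,
    silence_threshold: float = 0.5,
) -> SilentActivationReport:
    """Silent-gene fractions before/after treatment for a gene set.

    A gene is silent when ALL replicate FPKM values fall below
    ``silence_threshold``. The activated list holds genes silent before
    and no longer silent after.
    """
    genes = list(gene_ids)
    if not genes:
        raise ValueError("empty gene list")
    before = expression.replicate_matrix(cond_before).reindex(genes)
    after = expression.replicate_matrix(cond_after).reindex(genes)
    missing = before.index[before.isna().all(axis=1)]
    if len(missing):
        raise KeyError(f"genes missing from expression table: {list(missing[:5])}")
    silent_before = (before < silence_threshold).all(axis=1)
    silent_after = (after < silence_threshold).all(axis=1)
    activated = sorted(before.index[silent_before & ~silent_after])
    n = len(genes)
    return SilentActivationReport(
        fraction_silent_before=float(silent_before.sum() / n),
        fraction_silent_after=float(silent_after.sum() / n),
        activated_genes=[str(g) for g in activated],
        n_genes=n,
    )


def intragenic_enrichment(
    context: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    promoter_flank: int = PROMOTER_FLANK,
) -> tuple[float, float]:
    """Binomial test of intragenic peak placement vs a uniform null.

    The null probability is the fraction of the genome annotated as
    intragenic (gene bodies minus promoter flanks, clipped at zero).
    Returns (null_probability, p_value) for the one-sided alternative of
    intragenic enrichment.
    """
    genome = float(sum(chrom_sizes.values()))
    intra_bp = 0
    for g in gene_models:
        try:
            tss = g.tss()
        except ValueError:
            continue
        body = len(g.interval)
        prom_lo = max(g.interval.start, tss - promoter_flank)
        prom_hi = min(g.interval.end, tss + promoter_flank)
        intra_bp += max(0, body - max(0, prom_hi - prom_lo))
    p0 = intra_bp / genome
    n = len(context)
    k = int((context["context"] == "intragenic").sum())
    res = binomtest(k, n, p0, alternative="greater")
    return p0, float(res.pvalue)
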