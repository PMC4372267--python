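"""Synthetic genome and track generator with planted, recoverable effects.

The generator emulates the design of a demethylating-drug study in a
cultured human cell line: an untreated control, two drug doses sampled
acutely (3 days) and after a 30-day recovery, HpaII/MspI count tables
per condition, per-replicate FPKM, RNAPII promoter/intragenic peak sets
for control and the high acute dose, and LUMA pyrosequencing runs.

Planted structure (all knobs in :class:`SimulationConfig`):

* a two-compartment genome (contiguous domains): the euchromatic
  compartment carries BOTH the highest expression and the highest
  baseline methylation (lowest angle scores), and receives the bulk of
  the dose-dependent demethylation;
* partial, "imprinted" retention of the acute demethylation at
  recovery: a fraction of loci retain ``recovery_fraction`` of the
  acute shift, the rest remethylate almost completely (transient);
* ~1% of coding and ~3% of non-coding genes differentially expressed;
* bimodal promoter CG observed/expected content, with the high-CG
  component more frequent in euchromatin;
* treatment-only intragenic peaks planted in the bodies of silent
  genes (outside TSS +/- 2 kb), with local demethylation and, for a
  configurable fraction of host genes, expression activation.

Everything is deterministic given the seed: the same config generates
byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    write_fasta,
    write_peaks,
    write_site_counts,
    write_table,
)
from .intron_retention import GeneCoverage
from .methylation_scores import LumaRun

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "FixtureBundle",
    "generate",
    "luma_run_from_global",
    "make_trajectory_groups",
    "simulate_irs_coverage",
]

CONTROL = "control"
DOSES = (0.25, 1.0)
ACUTE = tuple(f"acute_{d}" for d in DOSES)
RECOVERY = tuple(f"recovery_{d}" for d in DOSES)
CONDITIONS = (CONTROL,) + ACUTE + RECOVERY


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic fixture.

    Methylation is parameterized on the angle-score scale (0-100,
    higher = less methylated); ``demeth_effect`` maps dose to the mean
    score *increase* in (euchromatin, heterochromatin).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    euchromatin_fraction: float = 0.4
    domain_size: int = 500_000
    # angle-score means by compartment (low score = heavily methylated)
    baseline_meth_eu: float = 30.0
    baseline_meth_het: float = 70.0
    demeth_effect: dict = field(default_factory=lambda: {0.25: (18.0, 3.0), 1.0: (32.0, 5.0)})
    recovery_fraction: float = 0.6
    imprinted_fraction: float = 0.6
    transient_recovery: float = 0.05
    site_sd: float = 8.0
    site_spacing_eu: int = 1500
    site_spacing_het: int = 4000
    mean_mspi: float = 30.0
    # gene architecture
    gene_spacing: int = 25_000
    n_exons: int = 4
    exon_length: int = 300
    intron_length: int = 1500
    coding_fraction: float = 0.85
    # expression
    expr_logmean_eu: float = math.log(20.0)
    expr_logsd_eu: float = 1.0
    expr_logmean_het: float = math.log(0.12)
    expr_logsd_het: float = 1.2
    n_replicates: int = 4
    replicate_logsd: float = 0.15
    de_fraction_coding: float = 0.01
    de_fraction_lnc: float = 0.03
    de_fold: float = 4.0
    couple_expression_to_demethylation: bool = False
    silence_threshold: float = 0.5
    # peaks
    n_new_intragenic_peaks: int = 30
    activated_fraction: float = 0.5
    activated_fpkm: float = 5.0
    peak_demeth_shift: float = 35.0
    peak_halfwidth: int = 200
    active_peak_fpkm: float = 1.0
    # promoter CG mixture (low, high components)
    cg_means: tuple = (0.2, 0.6)
    cg_sds: tuple = (0.05, 0.05)
    p_hcg_eu: float = 0.85
    p_hcg_het: float = 0.35
    # promoter-site baseline angle scores: HCG promoters are unmethylated
    # regardless of compartment; a fraction of LCG promoters is heavily
    # methylated (the methylated-LCG subset)
    prom_score_hcg: float = 82.0
    prom_score_lcg_unmeth: float = 75.0
    prom_score_lcg_meth: float = 35.0
    lcg_meth_fraction: float = 0.4
    # LUMA
    luma_baseline: float = 68.0
    luma_noise_sd: float = 1.0
    luma_replicates: int = 3

    def __post_init__(self):
        fracs = {
            "euchromatin_fraction": self.euchromatin_fraction,
            "recovery_fraction": self.recovery_fraction,
            "imprinted_fraction": self.imprinted_fraction,
            "transient_recovery": self.transient_recovery,
            "coding_fraction": self.coding_fraction,
            "de_fraction_coding": self.de_fraction_coding,
            "de_fraction_lnc": self.de_fraction_lnc,
            "activated_fraction": self.activated_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        prev = None
        for dose in sorted(self.demeth_effect):
            eff = tuple(self.demeth_effect[dose])
            if prev is not None and (eff[0] < prev[0] or eff[1] < prev[1]):
                raise ValueError("demeth_effect must be monotone non-decreasing in dose")
            prev = eff

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["demeth_effect"] = {str(k): list(v) for k, v in self.demeth_effect.items()}
        d["cg_means"] = list(self.cg_means)
        d["cg_sds"] = list(self.cg_sds)
        return d


@dataclass
class GroundTruth:
    """What was planted, exactly as generated."""

    genes: pd.DataFrame  # gene_id, compartment, biotype, de flags, cg component, ...
    domains: pd.DataFrame  # chrom, start, end, compartment
    new_peaks: pd.DataFrame  # planted treatment-only intragenic peaks
    luma_percent: dict  # condition -> planted global methylation percent

    def window_compartment(self, windows) -> pd.Series:
        """Planted compartment label per window (by midpoint domain)."""
        dom = self.domains
        labels = []
        for w in windows:
            mid = (w.start + w.end) // 2
            hit = dom[(dom["chrom"] == w.chrom) & (dom["start"] <= mid) & (dom["end"] > mid)]
            labels.append(hit["compartment"].iloc[0] if len(hit) else "NA")
        return pd.Series(labels)


@dataclass
class FixtureBundle:
    config: SimulationConfig
    chrom_sizes: dict
    gene_models: list
    site_tables: dict  # condition -> DataFrame(chrom, pos, hpaii_count, mspi_count)
    expression: ExpressionTable
    peak_sets: dict  # condition -> peak DataFrame
    luma_runs: dict  # condition -> list[LumaRun]
    truth: GroundTruth
    genome: dict | None = None  # chrom -> sequence (optional)
    promoter_cg_ratio: pd.Series | None = None  # planted per-gene target ratios

    def site_positions(self) -> pd.DataFrame:
        df = self.site_tables[CONTROL]
        return df[["chrom", "pos"]].copy()

    def angle_tracks(self, min_mspi: int = 1) -> dict:
        """Angle-score tracks per condition.

        Synthetic libraries are depth-matched against the MspI reference
        by construction, so equal library sizes are used: the score is
        the angle of the raw HpaII/MspI count ratio.
        """
        from .methylation_scores import angle_track

        out = {}
        for cond, df in self.site_tables.items():
            track, _ = angle_track(df, hpaii_libsize=1.0, mspi_libsize=1.0,
                                   min_mspi=min_mspi)
            out[cond] = track
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.genome is not None:
            write_fasta(self.genome, outdir / "genome.fa")
        biotypes = dict(zip(self.truth.genes["gene_id"], self.truth.genes["biotype"]))
        _write_gtf(self.gene_models, biotypes, outdir / "genes.gtf")
        for cond, df in self.site_tables.items():
            write_site_counts(df, outdir / f"sites_{cond}.tsv")
        self.expression.to_tsv(outdir / "expression.tsv")
        for cond, df in self.peak_sets.items():
            write_peaks(df, outdir / f"peaks_{cond}.bed")
        luma_rows = []
        for cond in CONDITIONS:
            for i, run in enumerate(self.luma_runs[cond]):
                luma_rows.append({"condition": cond, "replicate": i,
                                  "hpaii_cg": run.hpaii_cg, "hpaii_norm": run.hpaii_norm,
                                  "mspi_cg": run.mspi_cg, "mspi_norm": run.mspi_norm})
        write_table(pd.DataFrame(luma_rows), outdir / "luma.tsv")
        write_table(self.truth.genes, outdir / "truth_genes.tsv")
        write_table(self.truth.domains, outdir / "truth_domains.tsv")
        write_table(self.truth.new_peaks, outdir / "truth_new_peaks.tsv")
        with open(outdir / "truth.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump({"luma_percent": self.truth.luma_percent,
                       "chrom_sizes": self.chrom_sizes}, fh, sort_keys=True, indent=1)
        with open(outdir / "config.yaml", "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)


def _write_gtf(gene_models, biotypes: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in gene_models:
            bt = "protein_coding" if biotypes.get(g.gene_id, "coding") == "coding" else "lincRNA"
            for ex in g.exons:
                # internal 0-based half-open -> GTF 1-based closed
                fh.write(
                    f"{g.chrom}\tazadem\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1"; '
                    f'gene_biotype "{bt}";\n'
                )


def luma_run_from_global(meth_percent: float, noise_sd: float, seed) -> LumaRun:
    """Invert the LUMA formula: a run whose forward score is ``meth_percent``.

    With ``noise_sd`` = 0 the forward computation recovers the input
    exactly; with noise, within ~3 * noise_sd.
    """
    if not 0.0 <= meth_percent <= 100.0:
        raise ValueError(f"meth_percent must be in [0, 100], got {meth_percent}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hpaii_norm = mspi_norm = 50.0
    mspi_cg = 100.0
    hpaii_cg = (1.0 - meth_percent / 100.0) * (mspi_cg / mspi_norm) * hpaii_norm
    if noise_sd > 0:
        hpaii_cg = max(0.0, hpaii_cg + rng.normal(0.0, noise_sd))
        mspi_cg = max(1e-6, mspi_cg + rng.normal(0.0, noise_sd))
    return LumaRun(hpaii_cg, hpaii_norm, mspi_cg, mspi_norm)


# ---------------------------------------------------------------------------
# generation internals


def _make_domains(cfg: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        start = 0
        while start < cfg.chrom_length:
            end = min(start + cfg.domain_size, cfg.chrom_length)
            rows.append({"chrom": chrom, "start": start, "end": end})
            start = end
    dom = pd.DataFrame(rows)
    n_eu = int(round(cfg.euchromatin_fraction * len(dom)))
    labels = np.array(["het"] * len(dom), dtype=object)
    labels[rng.permutation(len(dom))[:n_eu]] = "eu"
    dom["compartment"] = labels
    return dom


def _compartment_lookup(dom: pd.DataFrame, cfg: SimulationConfig):
    table = {}
    for chrom, sub in dom.groupby("chrom"):
        arr = sub.sort_values("start")["compartment"].to_numpy()
        table[chrom] = arr

    def look(chrom: str, pos) -> np.ndarray:
        idx = np.minimum(np.atleast_1d(pos) // cfg.domain_size, len(table[chrom]) - 1)
        return table[chrom][idx]

    return look


def _make_genes(cfg: SimulationConfig, rng, compartment_at) -> tuple[list, pd.DataFrame]:
    gene_len = cfg.n_exons * cfg.exon_length + (cfg.n_exons - 1) * cfg.intron_length
    models, rows = [], []
    gid = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        start = 10_000
        while start + gene_len + 2_000 <= cfg.chrom_length:
            gid += 1
            gene_id = f"g{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for _ in range(cfg.n_exons):
                exons.append(GenomicInterval(chrom, pos, pos + cfg.exon_length, strand))
                pos += cfg.exon_length + cfg.intron_length
            end = exons[-1].end
            interval = GenomicInterval(chrom, start, end, strand)
            biotype = "coding" if rng.random() < cfg.coding_fraction else "lncRNA"
            gm = GeneModel(gene_id, biotype, interval, tuple(exons))
            models.append(gm)
            comp = str(compartment_at(chrom, gm.tss())[0])
            rows.append({"gene_id": gene_id, "chrom": chrom, "start": start,
                         "end": end, "strand": strand, "tss": gm.tss(),
                         "biotype": biotype, "compartment": comp})
            start += cfg.gene_spacing
    return models, pd.DataFrame(rows)


def _plan_expression(cfg: SimulationConfig, rng, genes: pd.DataFrame) -> pd.DataFrame:
    g = genes.copy()
    eu = (g["compartment"] == "eu").to_numpy()
    logmean = np.where(eu, cfg.expr_logmean_eu, cfg.expr_logmean_het)
    logsd = np.where(eu, cfg.expr_logsd_eu, cfg.expr_logsd_het)
    g["control_fpkm"] = np.exp(rng.normal(logmean, logsd))

    # peak-host genes must be robustly silent at baseline
    eligible = g.index[g["control_fpkm"] < cfg.silence_threshold / 2.0].to_numpy()
    if len(eligible) < cfg.n_new_intragenic_peaks:
        raise ValueError(
            f"infeasible config: {cfg.n_new_intragenic_peaks} new intragenic peaks "
            f"requested but only {len(eligible)} robustly silent host genes exist"
        )
    hosts = rng.choice(eligible, size=cfg.n_new_intragenic_peaks, replace=False)
    g["peak_host"] = False
    g.loc[hosts, "peak_host"] = True
    n_act = int(round(cfg.activated_fraction * len(hosts)))
    activated = rng.permutation(hosts)[:n_act]
    g["activated"] = False
    g.loc[activated, "activated"] = True

    g["de_flag"] = False
    g["de_direction"] = ""
    for biotype, frac in (("coding", cfg.de_fraction_coding), ("lncRNA", cfg.de_fraction_lnc)):
        pool = g.index[(g["biotype"] == biotype) & ~g["peak_host"]].to_numpy()
        n_de = int(round(frac * len(pool)))
        chosen = rng.choice(pool, size=n_de, replace=False)
        g.loc[chosen, "de_flag"] = True
        dirs = np.where(rng.random(n_de) < 0.5, "up", "down")
        g.loc[chosen, "de_direction"] = dirs

    g["imprinted"] = rng.random(len(g)) < cfg.imprinted_fraction

    # promoter CG class from the compartment-weighted two-component
    # mixture, plus the promoter-site baseline methylation it implies
    comp_hcg = np.where(g["compartment"] == "eu", cfg.p_hcg_eu, cfg.p_hcg_het)
    is_hcg = rng.random(len(g)) < comp_hcg
    mu = np.where(is_hcg, cfg.cg_means[1], cfg.cg_means[0])
    sd = np.where(is_hcg, cfg.cg_sds[1], cfg.cg_sds[0])
    g["cg_component"] = np.where(is_hcg, "HCG", "LCG")
    g["cg_ratio_target"] = np.clip(rng.normal(mu, sd), 0.02, None)
    lcg_meth = ~is_hcg & (rng.random(len(g)) < cfg.lcg_meth_fraction)
    g["promoter_methylated"] = lcg_meth
    g["prom_base_score"] = np.where(
        is_hcg, cfg.prom_score_hcg,
        np.where(lcg_meth, cfg.prom_score_lcg_meth, cfg.prom_score_lcg_unmeth),
    )
    return g


def _expression_table(cfg: SimulationConfig, rng, genes: pd.DataFrame) -> ExpressionTable:
    rows = []
    base = genes["control_fpkm"].to_numpy()
    for cond in CONDITIONS:
        mean = base.copy()
        if cond != CONTROL:
            up = (genes["de_direction"] == "up").to_numpy()
            dn = (genes["de_direction"] == "down").to_numpy()
            mean[up] *= cfg.de_fold
            mean[dn] /= cfg.de_fold
            if cfg.couple_expression_to_demethylation:
                mean[(genes["compartment"] == "eu").to_numpy()] *= cfg.de_fold
            mean[genes["activated"].to_numpy()] = cfg.activated_fpkm
        for rep in range(cfg.n_replicates):
            noise = np.exp(rng.normal(0.0, cfg.replicate_logsd, size=len(mean)))
            rows.append(pd.DataFrame({
                "gene_id": genes["gene_id"], "condition": cond,
                "replicate": rep, "fpkm": mean * noise,
            }))
    return ExpressionTable(pd.concat(rows, ignore_index=True))


def _site_layout(cfg: SimulationConfig, rng, dom: pd.DataFrame, genes: pd.DataFrame,
                 new_peaks: pd.DataFrame) -> pd.DataFrame:
    """Site positions with per-site compartment / imprint / peak flags."""
    rows = []
    for d in dom.itertuples(index=False):
        spacing = cfg.site_spacing_eu if d.compartment == "eu" else cfg.site_spacing_het
        pos = np.arange(d.start + spacing // 2, d.end - 4, spacing)
        jitter = rng.integers(-spacing // 4, spacing // 4 + 1, size=len(pos))
        pos = np.clip(pos + jitter, d.start, d.end - 5)
        for p in pos:
            rows.append((d.chrom, int(p), d.compartment, "domain", ""))
    for g in genes.itertuples(index=False):
        for off in (-500, 500):
            p = g.tss + off
            if 0 <= p < cfg.chrom_length - 4:
                rows.append((g.chrom, int(p), g.compartment, "promoter", g.gene_id))
    for pk in new_peaks.itertuples(index=False):
        for off in (-400, 0, 400):
            rows.append((pk.chrom, int(pk.summit + off), pk.compartment, "peak", pk.gene_id))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "compartment", "kind", "gene_id"])
    df = df.drop_duplicates(subset=["chrom", "pos"]).sort_values(["chrom", "pos"])
    return df.reset_index(drop=True)


def _plan_new_peaks(cfg: SimulationConfig, rng, genes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    hosts = genes[genes["peak_host"]]
    gene_len = cfg.n_exons * cfg.exon_length + (cfg.n_exons - 1) * cfg.intron_length
    lo, hi = 2_000 + cfg.peak_halfwidth + 100, gene_len - cfg.peak_halfwidth - 100
    for i, g in enumerate(hosts.itertuples(index=False)):
        off = int(rng.integers(lo, hi))
        summit = g.tss + off if g.strand == "+" else g.tss - off
        rows.append({"name": f"newpeak_{i:03d}", "chrom": g.chrom,
                     "start": summit - cfg.peak_halfwidth,
                     "end": summit + cfg.peak_halfwidth, "summit": summit,
                     "score": 100, "strand": ".", "gene_id": g.gene_id,
                     "compartment": g.compartment, "activated": bool(g.activated)})
    cols = ["name", "chrom", "start", "end", "summit", "score", "strand",
            "gene_id", "compartment", "activated"]
    return pd.DataFrame(rows, columns=cols)


def _site_tables(cfg: SimulationConfig, rng, layout: pd.DataFrame,
                 genes: pd.DataFrame) -> dict:
    eu = (layout["compartment"] == "eu").to_numpy()
    base = np.where(eu, cfg.baseline_meth_eu, cfg.baseline_meth_het)
    # promoter sites carry CG-class-driven baselines instead
    prom_base = dict(zip(genes["gene_id"], genes["prom_base_score"]))
    is_prom = (layout["kind"] == "promoter").to_numpy()
    prom_vals = np.array([prom_base.get(gid, np.nan) for gid in layout["gene_id"]])
    base = np.where(is_prom & ~np.isnan(prom_vals), prom_vals, base)

    imprint_by_gene = dict(zip(genes["gene_id"], genes["imprinted"]))
    site_imprint = np.array([
        bool(imprint_by_gene.get(gid))
        if kind in ("promoter", "peak") and gid in imprint_by_gene
        else bool(r < cfg.imprinted_fraction)
        for kind, gid, r in zip(layout["kind"], layout["gene_id"],
                                rng.random(len(layout)))
    ])
    retention = np.where(site_imprint, cfg.recovery_fraction, cfg.transient_recovery)
    is_peak = (layout["kind"] == "peak").to_numpy()

    tables = {}
    for cond in CONDITIONS:
        if cond == CONTROL:
            mean = base.copy()
        else:
            stage, dose_s = cond.split("_")
            eff_eu, eff_het = cfg.demeth_effect[float(dose_s)]
            shift = np.where(eu, eff_eu, eff_het)
            shift = np.where(is_peak, np.maximum(shift, cfg.peak_demeth_shift), shift)
            if stage == "recovery":
                shift = shift * retention
            mean = base + shift
        true_score = np.clip(rng.normal(mean, cfg.site_sd), 0.5, 99.5)
        ratio = np.tan(true_score * np.pi / 200.0)
        mspi = rng.poisson(cfg.mean_mspi, size=len(layout))
        hpaii = rng.poisson(cfg.mean_mspi * ratio)
        tables[cond] = pd.DataFrame({
            "chrom": layout["chrom"].to_numpy(), "pos": layout["pos"].to_numpy(),
            "hpaii_count": hpaii.astype(int), "mspi_count": mspi.astype(int),
        })
    return tables


def _peak_sets(cfg: SimulationConfig, rng, genes: pd.DataFrame,
               new_peaks: pd.DataFrame) -> dict:
    active = genes[genes["control_fpkm"] >= cfg.active_peak_fpkm]
    rows = []
    for i, g in enumerate(active.itertuples(index=False)):
        rows.append({"chrom": g.chrom, "start": max(0, g.tss - cfg.peak_halfwidth),
                     "end": g.tss + cfg.peak_halfwidth, "name": f"ctrlpeak_{i:04d}",
                     "score": 100, "strand": ".", "summit": g.tss})
    control = pd.DataFrame(rows)
    jitter = rng.integers(-30, 31, size=len(control))
    treated_conc = control.copy()
    treated_conc["start"] = np.maximum(0, treated_conc["start"] + jitter)
    treated_conc["end"] = treated_conc["end"] + jitter
    treated_conc["name"] = [f"trtpeak_{i:04d}" for i in range(len(treated_conc))]
    new_cols = ["chrom", "start", "end", "name", "score", "strand", "summit"]
    treated = pd.concat([treated_conc, new_peaks[new_cols]], ignore_index=True)
    order = ["chrom", "start", "end", "name", "score", "strand", "summit"]
    return {
        CONTROL: control[order].sort_values(["chrom", "start"]).reset_index(drop=True),
        "acute_1.0": treated[order].sort_values(["chrom", "start"]).reset_index(drop=True),
    }


def _luma_truth(cfg: SimulationConfig) -> dict:
    f_eu = cfg.euchromatin_fraction
    exp_ret = (cfg.imprinted_fraction * cfg.recovery_fraction
               + (1 - cfg.imprinted_fraction) * cfg.transient_recovery)

    def level(cond: str) -> float:
        if cond == CONTROL:
            s_eu, s_het = cfg.baseline_meth_eu, cfg.baseline_meth_het
        else:
            stage, dose_s = cond.split("_")
            eff_eu, eff_het = cfg.demeth_effect[float(dose_s)]
            ret = exp_ret if stage == "recovery" else 1.0
            s_eu = cfg.baseline_meth_eu + ret * eff_eu
            s_het = cfg.baseline_meth_het + ret * eff_het
        return f_eu * (100.0 - s_eu) + (1 - f_eu) * (100.0 - s_het)

    scale = cfg.luma_baseline / level(CONTROL)
    return {cond: float(np.clip(scale * level(cond), 0.0, 100.0)) for cond in CONDITIONS}


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _scrub_ccgg(seq: str) -> str:
    while "CCGG" in seq:
        seq = seq.replace("CCGG", "CCAG")
    return seq


def _promoter_sequence(rng, length: int, target_ratio: float) -> str:
    """A sequence whose CG obs/exp ratio approximates ``target_ratio``.

    i.i.d. uniform bases, all CG dinucleotides removed, then CG pairs
    planted at non-overlapping even offsets. Scrubbing depletes G, which
    inflates the realized obs/exp ratio, so one calibration pass rescales
    the planted pair count against the measured ratio.
    """
    arr = rng.integers(0, 4, size=length)
    backbone = list(_BASES[arr].tobytes().decode())
    for i in range(length - 1):
        if backbone[i] == "C" and backbone[i + 1] == "G":
            backbone[i + 1] = "T"
    slots = np.arange(0, length - 1, 2)

    def realize(n_cg: int) -> list[str]:
        s = backbone.copy()
        chosen = rng.choice(slots, size=min(n_cg, len(slots)), replace=False)
        for p in chosen:
            s[p] = "C"
            s[p + 1] = "G"
        return s

    def ratio_of(s: list[str]) -> float:
        st = "".join(s)
        n_c, n_g = st.count("C"), st.count("G")
        if n_c * n_g == 0:
            return 0.0
        return st.count("CG") * length / (n_c * n_g)

    n0 = max(1, int(round(target_ratio * length / 16.0)))
    s = realize(n0)
    r0 = ratio_of(s)
    if r0 > 0:
        n1 = max(1, min(len(slots), int(round(n0 * target_ratio / r0))))
        if n1 != n0:
            s = realize(n1)
    return "".join(s)


def _make_genome(cfg: SimulationConfig, rng, genes: pd.DataFrame,
                 cg_target: pd.Series, site_layout: pd.DataFrame) -> dict:
    genome = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = rng.choice(4, size=cfg.chrom_length, p=[0.3, 0.2, 0.2, 0.3])
        seq = _scrub_ccgg(_BASES[arr].tobytes().decode())
        seq = list(seq)
        for g in genes[genes["chrom"] == chrom].itertuples(index=False):
            lo = max(0, g.tss - 1500)
            hi = min(cfg.chrom_length, g.tss + 1500)
            block = _promoter_sequence(rng, hi - lo, float(cg_target[g.gene_id]))
            seq[lo:hi] = block
        for p in site_layout.loc[site_layout["chrom"] == chrom, "pos"]:
            seq[p : p + 4] = "CCGG"
        genome[chrom] = "".join(seq)
    return genome


def generate(config: SimulationConfig | None = None, include_sequence: bool = True) -> FixtureBundle:
    """Generate the full fixture bundle for one simulated study.

    ``include_sequence=False`` skips genome/promoter sequence synthesis
    (the slowest step) for analyses that only need tracks and tables.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}

    domains = _make_domains(cfg, rng)
    compartment_at = _compartment_lookup(domains, cfg)
    models, genes = _make_genes(cfg, rng, compartment_at)
    genes = _plan_expression(cfg, rng, genes)
    new_peaks = _plan_new_peaks(cfg, rng, genes)
    expression = _expression_table(cfg, rng, genes)
    layout = _site_layout(cfg, rng, domains, genes, new_peaks)
    site_tables = _site_tables(cfg, rng, layout, genes)
    peak_sets = _peak_sets(cfg, rng, genes, new_peaks)
    cg_target = pd.Series(genes["cg_ratio_target"].to_numpy(),
                          index=genes["gene_id"])

    luma_percent = _luma_truth(cfg)
    luma_runs = {
        cond: [luma_run_from_global(luma_percent[cond], cfg.luma_noise_sd, rng)
               for _ in range(cfg.luma_replicates)]
        for cond in CONDITIONS
    }

    genome = None
    if include_sequence:
        genome = _make_genome(cfg, rng, genes, cg_target, layout)

    truth = GroundTruth(genes=genes, domains=domains, new_peaks=new_peaks,
                        luma_percent=luma_percent)
    return FixtureBundle(
        config=cfg, chrom_sizes=chrom_sizes, gene_models=models,
        site_tables=site_tables, expression=expression, peak_sets=peak_sets,
        luma_runs=luma_runs, truth=truth, genome=genome,
        promoter_cg_ratio=cg_target,
    )


# ---------------------------------------------------------------------------
# small stand-alone simulators for the clustering and IRS analyses


def make_trajectory_groups(
    centroids: Sequence[Sequence[float]], n_per_group: int, sd: float, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Well-separated planted trajectory groups for cluster recovery tests."""
    rng = np.random.default_rng(seed)
    C = np.asarray(centroids, float)
    pts, labels = [], []
    for i, c in enumerate(C):
        pts.append(rng.normal(c, sd, size=(n_per_group, C.shape[1])))
        labels.extend([i] * n_per_group)
    X = np.vstack(pts)
    df = pd.DataFrame(X, columns=["delta_acute", "delta_recovery"])
    df.index = [f"unit_{i:05d}" for i in range(len(df))]
    return df, np.asarray(labels)


def simulate_irs_coverage(
    n_genes: int,
    seed: int = 0,
    planted_fraction: float = 0.0,
    planted_factor: float = 5.0,
    base_retention: float = 0.05,
    exon_density_mean: float = 50.0,
    nb_dispersion: float = 10.0,
    min_exons: int = 2,
    max_exons: int = 6,
):
    """Paired control/treated gene coverages with optional planted retention.

    Per-feature summed depth is negative binomial with mean =
    density * length; intron density = retention * exon density, where a
    ``planted_fraction`` of genes has ``planted_factor``-fold retention
    in the treated condition only. Returns (control, treated, planted_ids).
    """
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_fraction * n_genes))
    planted = set(rng.choice(n_genes, size=n_planted, replace=False).tolist())

    def nb(mean):
        mean = np.maximum(mean, 1e-9)
        p = nb_dispersion / (nb_dispersion + mean)
        return rng.negative_binomial(nb_dispersion, p)

    control, treated, planted_ids = [], [], []
    for i in range(n_genes):
        gene_id = f"ir{i:05d}"
        n_ex = int(rng.integers(min_exons, max_exons + 1))
        ex_len = rng.integers(100, 500, size=n_ex)
        in_len = rng.integers(500, 3000, size=n_ex - 1)
        dens = exon_density_mean * np.exp(rng.normal(0, 0.5))
        for cond, records in (("control", control), ("treated", treated)):
            ret = base_retention
            if cond == "treated" and i in planted:
                ret = base_retention * planted_factor
            ex_cov = np.array([nb(dens * l) for l in ex_len], float)
            in_cov = np.array([nb(ret * dens * l) for l in in_len], float)
            records.append(GeneCoverage(
                gene_id=gene_id,
                exon_lengths=tuple(int(x) for x in ex_len),
                exon_coverage=tuple(float(x) for x in ex_cov),
                intron_lengths=tuple(int(x) for x in in_len),
                intron_coverage=tuple(float(x) for x in in_cov),
                condition=cond,
            ))
        if i in planted:
            planted_ids.append(gene_id)
    return control, treated, planted_ids
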