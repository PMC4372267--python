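"""End-to-end orchestration: simulate -> scores -> som -> promoters ->
cluster -> peaks -> irs, with per-stage outputs, structured stderr
logging, resumable stages and a single combined summary JSON.

One global seed in the run configuration fans out to per-stage seeds via
``derive_seed`` (seed + CRC32 of the stage name, mod 2^31), so a stage
rerun in isolation reproduces its in-pipeline behavior.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    compartment_som as csom,
    intron_retention as ir,
    methylation_scores as ms,
    peak_dynamics as pkd,
    promoter_cg as pcg,
    response_clustering as rc,
    synthetic_data as sd,
)
from .core_io import write_bedgraph, write_table

__all__ = ["RunConfig", "derive_seed", "run_all", "validate_summary", "STAGES",
           "promoter_trajectories", "expression_trajectories"]

STAGES = ("simulate", "scores", "som", "promoters", "cluster", "peaks", "irs")


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed (stable, < 2^31)."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Module-level defaults are scaled to the bundled synthetic fixture
    (a 2 x 5 Mb genome with ~800 genes and ~200 windows); every knob is
    overridable here or via YAML.
    """

    seed: int = 7
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    include_sequence: bool = True
    min_mspi: int = 1
    # SOM
    grid_shape: tuple = (8, 8)
    som_epochs: int = 50
    # promoters
    promoter_flank: int = 1500
    link_dist: int = 2000
    # clustering
    k_meth: int = 7
    k_expr: int = 4
    kmeans_restarts: int = 25
    # peaks
    min_overlap: int = 1
    peak_meth_flank: int = 500
    silence_threshold: float = 0.5
    # IRS
    irs_n_genes: int = 2000
    irs_planted_fraction: float = 0.01
    irs_planted_factor: float = 5.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def _stage_cached(outdir: Path, stage: str, conf_hash: str) -> dict | None:
    f = outdir / f"{stage}.json"
    if not f.exists():
        return None
    try:
        payload = json.loads(f.read_text())
    except json.JSONDecodeError:
        return None
    if payload.get("_config_hash") != conf_hash:
        return None
    return payload


def _write_stage(outdir: Path, stage: str, conf_hash: str, payload: dict) -> dict:
    payload = dict(payload)
    payload["_config_hash"] = conf_hash
    with open(outdir / f"{stage}.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1, default=_jsonable)
    return payload


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _simulate(config: RunConfig):
    sim_kw = dict(config.simulation)
    sim_kw.setdefault("seed", derive_seed(config.seed, "simulate"))
    return sd.generate(sd.SimulationConfig(**sim_kw),
                       include_sequence=config.include_sequence)


def promoter_trajectories(bundle, tracks, flank: int) -> pd.DataFrame:
    """Promoter methylation trajectories in methylation-level units.

    delta = -(score_condition - score_control): loss of methylation is
    negative, matching the trajectory sign convention.
    """
    recs = []
    for g in bundle.gene_models:
        tss = g.tss()
        recs.append({"promoter_id": g.gene_id, "gene_id": g.gene_id,
                     "chrom": g.chrom, "start": max(0, tss - flank),
                     "end": tss + flank})
    df = pd.DataFrame(recs)
    for cond, col in (("control", "s_control"), ("acute_1.0", "s_acute"),
                      ("recovery_1.0", "s_recovery")):
        df = pcg.attach_region_methylation(df, tracks[cond], col)
    df = df.dropna(subset=["s_control", "s_acute", "s_recovery"])
    df["delta_acute"] = -(df["s_acute"] - df["s_control"])
    df["delta_recovery"] = -(df["s_recovery"] - df["s_control"])
    return df.set_index("promoter_id")


def expression_trajectories(bundle, pseudocount: float = 0.1) -> pd.DataFrame:
    e = bundle.expression
    ctrl = np.log2(e.condition_mean("control") + pseudocount)
    acute = np.log2(e.condition_mean("acute_1.0") + pseudocount)
    rec = np.log2(e.condition_mean("recovery_1.0") + pseudocount)
    return pd.DataFrame({"delta_acute": acute - ctrl, "delta_recovery": rec - ctrl})


def run_all(config: RunConfig, outdir, resume: bool = True) -> dict:
    """Execute all stages in dependency order and write the summary.

    Stage outputs live under ``outdir``; a stage whose output exists and
    whose configuration hash is unchanged is loaded instead of
    recomputed (``resume=False`` forces full recomputation).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conf_hash = config.content_hash()
    with open(outdir / "run_config.yaml", "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # --- simulate (the bundle is needed in memory by every later stage;
    # regeneration is deterministic and cheap, so resume only skips the
    # fixture-file writes)
    bundle = _simulate(config)
    fixtures = outdir / "fixtures"
    if resume and _stage_cached(outdir, "simulate", conf_hash):
        _log("simulate", "skip (cached fixtures up to date)")
    else:
        _log("simulate", f"writing fixtures to {fixtures}")
        bundle.write(fixtures)
        _write_stage(outdir, "simulate", conf_hash, {
            "n_genes": len(bundle.gene_models),
            "n_sites": int(len(bundle.site_tables["control"])),
            "conditions": list(sd.CONDITIONS),
        })

    tracks = bundle.angle_tracks(min_mspi=config.min_mspi)
    summary: dict = {"seed": config.seed, "config_hash": conf_hash}

    # --- scores
    cached = _stage_cached(outdir, "scores", conf_hash) if resume else None
    if cached:
        _log("scores", "skip (cached)")
        scores_payload = cached
    else:
        _log("scores", "global methylation and angle tracks")
        luma_by_cond = {c: ms.luma_mean(r) for c, r in bundle.luma_runs.items()}
        acute_resp = ms.dose_response(
            {d: bundle.luma_runs[f"acute_{d}"] for d in sd.DOSES}
            | {0.0: bundle.luma_runs["control"]}
        )
        for cond, tr in tracks.items():
            write_bedgraph(
                tr.assign(start=tr["pos"], end=tr["pos"] + 4)[
                    ["chrom", "start", "end", "score"]
                ],
                outdir / f"angle_{cond}.bedgraph",
            )
        scores_payload = _write_stage(outdir, "scores", conf_hash, {
            "luma_percent_by_condition": luma_by_cond,
            "acute_dose_response": acute_resp.to_dict(orient="list"),
            "mean_angle_score_by_condition": {
                c: float(t["score"].mean()) for c, t in tracks.items()
            },
        })
    summary["global_methylation"] = {
        k: scores_payload[k]
        for k in ("luma_percent_by_condition", "acute_dose_response")
    }

    # --- som
    cached = _stage_cached(outdir, "som", conf_hash) if resume else None
    if cached:
        _log("som", "skip (cached)")
        som_payload = cached
    else:
        _log("som", f"window features + SOM {config.grid_shape}")
        windows = csom.make_windows(bundle.chrom_sizes)
        feats = csom.window_features(
            windows, tracks["control"], tracks["acute_1.0"],
            bundle.expression.condition_mean("control"), bundle.gene_models,
            bundle.site_positions(),
        )
        write_table(feats, outdir / "window_features.tsv")
        ok = ~feats["excluded"]
        X = csom.zscore(feats.loc[ok, ["meth_control", "meth_treated",
                                       "expr_mean", "hpaii_sites"]].to_numpy())
        grid = csom.train_som(X, grid_shape=tuple(config.grid_shape),
                              epochs=config.som_epochs,
                              seed=derive_seed(config.seed, "som"))
        um = csom.u_matrix(grid)
        np.savetxt(outdir / "u_matrix.tsv", um, delimiter="\t", fmt="%.6g")
        csom.save_matrix_png(um, outdir / "u_matrix.png")
        enr_expr = csom.overlay_enrichment(feats, "response", "expression")
        enr_meth = csom.overlay_enrichment(feats, "response", "methylation")
        som_payload = _write_stage(outdir, "som", conf_hash, {
            "n_windows": int(len(feats)),
            "n_excluded": int(feats.attrs["n_excluded"]),
            "quantization_error_final": grid.qe_history[-1],
            "enrichment_response_x_expression": enr_expr.to_dict(),
            "enrichment_response_x_methylation": enr_meth.to_dict(),
        })
    summary["compartments"] = {
        k: som_payload[k]
        for k in ("enrichment_response_x_expression",
                  "enrichment_response_x_methylation", "n_windows")
    }

    # --- promoters
    cached = _stage_cached(outdir, "promoters", conf_hash) if resume else None
    if cached:
        _log("promoters", "skip (cached)")
        prom_payload = cached
    else:
        _log("promoters", "CG ratios, cutoff, classes, methylated-LCG subset")
        if bundle.genome is not None:
            recs = pcg.promoter_records(bundle.gene_models, bundle.genome,
                                        flank=config.promoter_flank)
        else:
            # sequence-free run: use the generator's planted target ratios
            recs = pd.DataFrame({
                "promoter_id": bundle.promoter_cg_ratio.index,
                "gene_id": bundle.promoter_cg_ratio.index,
                "chrom": [g.chrom for g in bundle.gene_models],
                "anchor": [g.tss() for g in bundle.gene_models],
                "start": [max(0, g.tss() - config.promoter_flank) for g in bundle.gene_models],
                "end": [g.tss() + config.promoter_flank for g in bundle.gene_models],
                "cg_ratio": bundle.promoter_cg_ratio.to_numpy(),
            })
        cutoff = pcg.bimodal_cutoff(recs["cg_ratio"])
        recs = pcg.classify_promoters(recs, cutoff)
        recs = pcg.attach_region_methylation(recs, tracks["control"], "meth_control")
        subset, threshold = pcg.methylated_lcg_subset(recs)
        ctrl_mean = bundle.expression.condition_mean("control")
        if len(subset):
            expr_rep = pcg.expression_of_subset(
                ctrl_mean.reindex(subset["gene_id"]).dropna(),
                ctrl_mean,
            ).to_dict()
        else:
            expr_rep = {"p_value": None, "note": "empty subset"}
        write_table(recs, outdir / "promoters.tsv")
        prom_payload = _write_stage(outdir, "promoters", conf_hash, {
            "cg_cutoff": float(cutoff),
            "class_counts": recs.attrs["class_counts"],
            "lcg_fraction": recs.attrs["lcg_fraction"],
            "methylated_lcg_threshold": threshold,
            "n_methylated_lcg": int(len(subset)),
            "subset_expression": expr_rep,
        })
    summary["promoters"] = {
        k: prom_payload[k]
        for k in ("cg_cutoff", "class_counts", "lcg_fraction", "n_methylated_lcg")
    }

    # --- cluster
    cached = _stage_cached(outdir, "cluster", conf_hash) if resume else None
    if cached:
        _log("cluster", "skip (cached)")
        clus_payload = cached
    else:
        _log("cluster", f"k-means trajectories (k={config.k_meth})")
        traj = promoter_trajectories(bundle, tracks, config.promoter_flank)
        res = rc.kmeans(traj[["delta_acute", "delta_recovery"]].to_numpy(),
                        config.k_meth, seed=derive_seed(config.seed, "cluster"),
                        restarts=config.kmeans_restarts)
        assignments = pd.Series(res.assignments, index=traj.index)
        report = rc.proportion_report(assignments, res.centroids)
        linked = rc.linked_expression_response(
            report, dict(zip(traj.index, traj["gene_id"])),
            expression_trajectories(bundle), bundle.expression,
            "control", "acute_1.0", k_expr=config.k_expr,
            seed=derive_seed(config.seed, "cluster-expr"),
            restarts=config.kmeans_restarts,
        )
        write_table(traj.reset_index().assign(cluster=res.assignments),
                    outdir / "trajectories.tsv")
        clus_payload = _write_stage(outdir, "cluster", conf_hash, {
            "methylation_clusters": report.to_dict(),
            "induced_fraction_pct": linked.induced_fraction_pct,
            "n_induced": len(linked.induced_genes),
        })
    summary["response_clusters"] = clus_payload["methylation_clusters"]
    summary["induced_fraction_pct"] = clus_payload["induced_fraction_pct"]

    # --- peaks
    cached = _stage_cached(outdir, "peaks", conf_hash) if resume else None
    if cached:
        _log("peaks", "skip (cached)")
        peaks_payload = cached
    else:
        _log("peaks", "peak comparison, genic context, silent activation")
        comp = pkd.compare_peaks(bundle.peak_sets["control"],
                                 bundle.peak_sets["acute_1.0"],
                                 min_overlap=config.min_overlap)
        ctx = pkd.classify_context(comp.treated, bundle.gene_models)
        new_intra = ctx[(ctx["status"] == "new") & (ctx["context"] == "intragenic")]
        shift = pkd.methylation_shift_at(new_intra, tracks["control"],
                                         tracks["acute_1.0"],
                                         flank=config.peak_meth_flank)
        host_genes = sorted(set(new_intra["gene_id"]) - {""})
        act = pkd.silent_activation(host_genes, bundle.expression,
                                    "control", "acute_1.0",
                                    silence_threshold=config.silence_threshold)
        p0, p_enrich = pkd.intragenic_enrichment(
            ctx[ctx["status"] == "new"], bundle.gene_models, bundle.chrom_sizes)
        write_table(ctx, outdir / "peaks_classified.tsv")
        peaks_payload = _write_stage(outdir, "peaks", conf_hash, {
            "counts": comp.counts,
            "new_peak_context_counts": ctx[ctx["status"] == "new"]["context"]
                .value_counts().to_dict(),
            "new_intragenic_meth_shift": {
                "median_delta": shift.median_delta, "p_value": shift.p_value,
                "n_peaks_used": shift.n_peaks_used,
            },
            "silent_activation": act.to_dict(),
            "intragenic_enrichment": {"null_p": p0, "p_value": p_enrich},
        })
    summary["peaks"] = {k: v for k, v in peaks_payload.items()
                        if not k.startswith("_")}

    # --- irs
    cached = _stage_cached(outdir, "irs", conf_hash) if resume else None
    if cached:
        _log("irs", "skip (cached)")
        irs_payload = cached
    else:
        _log("irs", f"intron retention ({config.irs_n_genes} genes)")
        ctrl, trt, planted = sd.simulate_irs_coverage(
            config.irs_n_genes, seed=derive_seed(config.seed, "irs"),
            planted_fraction=config.irs_planted_fraction,
            planted_factor=config.irs_planted_factor,
        )
        resp = ir.irs_response(ir.irs_table(ctrl), ir.irs_table(trt))
        rep = ir.shift_test(resp)
        flagged_up = set(resp.index[resp["flag"] == "increased"])
        recov = (len(flagged_up & set(planted)) / len(planted)) if planted else None
        write_table(resp.reset_index(), outdir / "irs.tsv")
        irs_payload = _write_stage(outdir, "irs", conf_hash, {
            "shift_report": rep.to_dict(),
            "n_genes": int(len(resp)),
            "planted_recovery": recov,
        })
    summary["intron_retention"] = {
        k: v for k, v in irs_payload.items() if not k.startswith("_")
    }

    with open(outdir / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1, default=_jsonable)
    _log("run-all", f"summary written to {outdir / 'summary.json'}")
    return summary


_SUMMARY_REQUIRED = {
    "seed": (int,),
    "global_methylation": (dict,),
    "compartments": (dict,),
    "promoters": (dict,),
    "response_clusters": (dict,),
    "induced_fraction_pct": (int, float),
    "peaks": (dict,),
    "intron_retention": (dict,),
}


def validate_summary(summary: dict) -> None:
    """Check the combined summary against the bundled schema.

    Raises ValueError on a missing key or a wrong type; the formal
    schema document ships in docs/summary.schema.json.
    """
    for key, types in _SUMMARY_REQUIRED.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], types):
            raise ValueError(f"summary[{key!r}] has type {type(summary[key]).__name__}")
    comp = summary["compartments"]
    for k in ("enrichment_response_x_expression", "enrichment_response_x_methylation"):
        if k not in comp:
            raise ValueError(f"compartments missing {k!r}")
    if "cg_cutoff" not in summary["promoters"]:
        raise ValueError("promoters missing cg_cutoff")
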