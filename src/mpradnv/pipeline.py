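"""Stage-wise pipeline: simulate -> design -> associate -> count -> alpha ->
test -> enrich -> motifs -> report.

Each stage reads its inputs from the run directory and writes its outputs
there, so a run can be resumed: with ``resume=True`` a stage is skipped when
all its output files exist and no earlier stage was re-run; regenerating an
upstream output forces every downstream stage to run again.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Dict, List

import numpy as np
import pandas as pd
import yaml

from . import barcodes, design, differential, enrichment, motifs, simulate
from .activity import TranscriptionRateModel, estimate_size_factors
from .config import PipelineConfig
from .errors import PipelineError, SamplingError

logger = logging.getLogger(__name__)


def bundled_motif_file():
    return resources.files("mpradnv.data") / "toy_motifs.meme"


def demo_config_file():
    return resources.files("mpradnv.data") / "demo_config.yaml"


@dataclass
class RunResult:
    out_dir: Path
    stages_run: List[str]
    summary: dict


def _paths(out: Path, reps: List[str]) -> Dict[str, Path]:
    p = {
        "variants": out / "sim" / "variants.tsv",
        "truth": out / "sim" / "truth.tsv",
        "genome": out / "sim" / "genome.fa",
        "assoc_reads": out / "sim" / "association_reads.tsv",
        "h3k27ac": out / "sim" / "h3k27ac.bed",
        "atac": out / "sim" / "atac.bed",
        "tss": out / "sim" / "tss.tsv",
        "sim_config": out / "sim" / "sim_config.yaml",
        "library": out / "design" / "library.fa",
        "manifest": out / "design" / "manifest.tsv",
        "assignments": out / "assoc" / "assignments.tsv",
        "assoc_qc": out / "assoc" / "association_qc.json",
        "count_qc": out / "counts" / "count_qc.json",
        "alphas": out / "alpha" / "alphas.tsv",
        "size_factors": out / "alpha" / "size_factors.tsv",
        "activity": out / "alpha" / "activity.tsv",
        "differential": out / "differential" / "differential.tsv",
        "contrast": out / "differential" / "contrast.json",
        "volcano": out / "differential" / "volcano.tsv",
        "anno_enrichment": out / "enrichment" / "annotation_enrichment.tsv",
        "peak_enrichment": out / "enrichment" / "peak_enrichment.tsv",
        "gc": out / "enrichment" / "gc.json",
        "gc_table": out / "enrichment" / "gc_per_variant.tsv",
        "motif_hits": out / "motifs" / "variant_hits.tsv",
        "disruption": out / "motifs" / "disruption.tsv",
        "motif_contrast": out / "motifs" / "motif_contrast.json",
        "summary_json": out / "summary.json",
        "summary_md": out / "summary.md",
    }
    for rep in reps:
        p[f"dna_{rep}"] = out / "sim" / f"{rep}_dna_library.tsv"
        p[f"rna_{rep}"] = out / "sim" / f"{rep}_rna_library.tsv"
        p[f"counts_{rep}"] = out / "counts" / f"{rep}.tsv"
    return p


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def _read_json(path: Path):
    with open(path) as fh:
        return json.load(fh)


def _tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, P, ctx) -> None:
    sc = cfg.sim_config()
    sim = simulate.simulate_variants(sc)
    counts = simulate.simulate_counts(sim.truth, sc)
    reads = simulate.simulate_association_reads(counts.barcode_map, sc)
    epi = simulate.simulate_epigenome(sim.genome, sc)

    P["variants"].parent.mkdir(parents=True, exist_ok=True)
    _tsv(sim.variants, P["variants"])
    _tsv(sim.truth, P["truth"])
    simulate.write_genome_fasta(sim.genome, P["genome"])
    _tsv(reads, P["assoc_reads"])
    enrichment.write_bed(epi.h3k27ac, P["h3k27ac"])
    enrichment.write_bed(epi.atac, P["atac"])
    _tsv(epi.tss, P["tss"])
    simulate.write_config_yaml(sc, P["sim_config"])
    for rep, libs in counts.library_tables.items():
        _tsv(libs["dna"], P[f"dna_{rep}"])
        _tsv(libs["rna"], P[f"rna_{rep}"])
    logger.info("simulate: %d variants, %d barcodes",
                len(sim.variants), len(counts.barcode_map))


def _stage_design(cfg: PipelineConfig, P, ctx) -> None:
    sc = cfg.sim_config()
    variants = pd.read_csv(P["variants"], sep="\t")
    genome = design.read_genome_fasta(P["genome"])
    pairs = design.build_crs_pairs(variants, genome)
    origins = dict(zip(variants["variant_id"], variants["origin"]))
    n_case_neg = sc.n_neg_controls // 2
    negatives = design.scramble_negatives(
        pairs, origins, n_case_neg, sc.n_neg_controls - n_case_neg,
        seed=[cfg.seed, 4])
    h3 = enrichment.read_bed(P["h3k27ac"], min_cols=5)
    atac = enrichment.read_bed(P["atac"], min_cols=5)
    tss = pd.read_csv(P["tss"], sep="\t")
    positives, _ = design.select_positive_controls(
        h3, atac, tss, genome, n=sc.n_pos_controls)
    if len(positives) < sc.n_pos_controls:
        raise SamplingError(
            f"only {len(positives)} positive controls pass the filters; "
            f"{sc.n_pos_controls} requested")
    design.emit_library(pairs, positives + negatives, P["library"], P["manifest"])
    logger.info("design: %d library sequences", 2 * len(pairs) + len(positives)
                + len(negatives))


def _stage_associate(cfg: PipelineConfig, P, ctx) -> None:
    reads = pd.read_csv(P["assoc_reads"], sep="\t")
    result = barcodes.associate(reads)
    _tsv(result.assignments, P["assignments"])
    n = len(result.assignments)
    conf = int((result.assignments["status"] == "confident").sum())
    qc = {"n_barcodes": n, "n_confident": conf,
          "frac_confident": conf / n if n else 0.0,
          "n_skipped_reads": result.n_skipped}
    _write_json(qc, P["assoc_qc"])
    logger.info("associate: %d/%d barcodes confident", conf, n)


def _stage_count(cfg: PipelineConfig, P, ctx) -> None:
    assignments = pd.read_csv(P["assignments"], sep="\t")
    qcs = {}
    for rep in ctx["reps"]:
        dna = pd.read_csv(P[f"dna_{rep}"], sep="\t")
        rna = pd.read_csv(P[f"rna_{rep}"], sep="\t")
        table, qc = barcodes.count_barcodes(dna, rna, assignments, rep)
        _tsv(table, P[f"counts_{rep}"])
        qcs[rep] = qc
    _write_json(qcs, P["count_qc"])


def _load_model(cfg: PipelineConfig, P, ctx) -> TranscriptionRateModel:
    tables = {rep: pd.read_csv(P[f"counts_{rep}"], sep="\t")
              for rep in ctx["reps"]}
    manifest = pd.read_csv(P["manifest"], sep="\t")
    return TranscriptionRateModel(tables, manifest)


def _get_results(cfg: PipelineConfig, P, ctx):
    if "results" not in ctx:
        model = _load_model(cfg, P, ctx)
        ctx["results"] = model.fit()
    return ctx["results"]


def _stage_alpha(cfg: PipelineConfig, P, ctx) -> None:
    res = _get_results(cfg, P, ctx)
    _tsv(res.alphas.reset_index(), P["alphas"])
    _tsv(res.size_factors.reset_index(), P["size_factors"])
    activity = res.classify_active(fdr=cfg.activity_fdr)
    _tsv(activity, P["activity"])
    logger.info("alpha: %d sequences fitted, %d active",
                len(res.alphas), int(activity["active"].sum()))


def _stage_test(cfg: PipelineConfig, P, ctx) -> None:
    res = _get_results(cfg, P, ctx)
    allelic = res.test_allelic_effects(hcdnv_fdr=cfg.hcdnv_fdr,
                                       hcdnv_abs_lfc=cfg.hcdnv_abs_lfc)
    _tsv(allelic.frame, P["differential"])
    _tsv(allelic.volcano_table(), P["volcano"])
    variants = pd.read_csv(P["variants"], sep="\t")
    origins = dict(zip(variants["variant_id"], variants["origin"]))
    contrast = allelic.case_control_contrast(origins)
    _write_json({"contrast": contrast.to_dict(),
                 "hcdnv": allelic.hcdnv_summary(),
                 "n_excluded": len(allelic.excluded)}, P["contrast"])
    logger.info("test: %s", allelic.summary().replace("\n", "; "))


def _stage_enrich(cfg: PipelineConfig, P, ctx) -> None:
    variants = pd.read_csv(P["variants"], sep="\t")
    diff = pd.read_csv(P["differential"], sep="\t")
    tested = variants[variants["variant_id"].isin(diff["variant_id"])].reset_index(drop=True)
    hcdnv = tested["variant_id"].map(
        diff.set_index("variant_id")["hcdnv"]).astype(bool)

    anno = enrichment.enrich_categories(
        tested, hcdnv, family_size=cfg.annotation_family_size)
    _tsv(anno, P["anno_enrichment"])

    peak_rows = []
    for name in ("atac", "h3k27ac"):
        peaks = enrichment.read_bed(P[name], min_cols=5)
        ov = enrichment.peak_overlap(tested, peaks, peak_set=name)
        res = enrichment.fet_enrich(hcdnv, ov["overlaps"], category=name,
                                    family_size=2)
        (a, b), (c, d) = res.table
        peak_rows.append({"peak_set": name, "a": a, "b": b, "c": c, "d": d,
                          "odds_ratio": res.odds_ratio, "p": res.p})
    _tsv(pd.DataFrame(peak_rows), P["peak_enrichment"])

    library = design.read_library_fasta(P["library"])
    ref_seqs = {vid: library[f"{vid}_ref"] for vid in tested["variant_id"]}
    flags = dict(zip(tested["variant_id"], hcdnv))
    gc, gc_p = enrichment.gc_compare(ref_seqs, flags)
    gc_df = pd.DataFrame({"variant_id": gc.index, "gc": gc.to_numpy(),
                          "hcdnv": [flags[v] for v in gc.index]})
    _tsv(gc_df, P["gc_table"])
    _write_json({"gc_hcdnv_mean": float(gc_df.loc[gc_df["hcdnv"], "gc"].mean()),
                 "gc_background_mean": float(gc_df.loc[~gc_df["hcdnv"], "gc"].mean()),
                 "wilcoxon_p": gc_p}, P["gc"])


def _stage_motifs(cfg: PipelineConfig, P, ctx) -> None:
    library = design.read_library_fasta(P["library"])
    diff = pd.read_csv(P["differential"], sep="\t")
    motif_file = cfg.motif_file or bundled_motif_file()
    pwms = motifs.read_meme(motif_file)

    ref_seqs = {f"{v}_ref": library[f"{v}_ref"] for v in diff["variant_id"]}
    alt_seqs = {f"{v}_alt": library[f"{v}_alt"] for v in diff["variant_id"]}
    kwargs = dict(p_threshold=cfg.motif_p, granularity=cfg.motif_granularity,
                  variant_offset=design.VARIANT_OFFSET)
    ref_hits = motifs.scan_library(ref_seqs, pwms, **kwargs)
    alt_hits = motifs.scan_library(alt_seqs, pwms, **kwargs)
    hits = pd.concat([ref_hits.assign(allele="ref"), alt_hits.assign(allele="alt")],
                     ignore_index=True)
    _tsv(hits[hits["covers_variant"]], P["motif_hits"])

    variant_of = {f"{v}_ref": v for v in diff["variant_id"]}
    variant_of.update({f"{v}_alt": v for v in diff["variant_id"]})
    table = motifs.disruption_table(ref_hits, alt_hits, variant_of)
    _tsv(table, P["disruption"])
    flags = dict(zip(diff["variant_id"], diff["hcdnv"].astype(bool)))
    contrast = motifs.disruption_contrast(table, flags)
    _write_json(contrast, P["motif_contrast"])


def _stage_report(cfg: PipelineConfig, P, ctx) -> None:
    contrast = _read_json(P["contrast"])
    activity = pd.read_csv(P["activity"], sep="\t")
    manifest = pd.read_csv(P["manifest"], sep="\t")
    role = manifest.set_index("sequence_id")["role"]
    act = activity.set_index("sequence_id")
    act_role = role.reindex(act.index)
    anno = pd.read_csv(P["anno_enrichment"], sep="\t")
    hc = contrast["hcdnv"]
    summary = {
        "config": cfg.to_dict(),
        "counts": {
            "n_sequences_fitted": int(len(act)) + 0,
            "n_active_reference": int(act.loc[act_role == "reference", "active"].sum()),
            "n_active_alternate": int(act.loc[act_role == "alternate", "active"].sum()),
            **hc,
        },
        "case_control": contrast["contrast"],
        "annotation_enrichment_significant": anno.loc[
            anno["bonferroni_significant"], "category"].tolist(),
        "gc": _read_json(P["gc"]),
        "motifs": _read_json(P["motif_contrast"]),
        "qc": {"association": _read_json(P["assoc_qc"]),
               "counting": _read_json(P["count_qc"])},
    }
    # internal consistency
    assert hc["n_hcdnv"] == hc["n_activator"] + hc["n_inhibitor"]
    assert hc["n_tested"] == hc["n_hcdnv"] + hc["n_background"]
    _write_json(summary, P["summary_json"])

    md = [
        "# MPRA pipeline summary", "",
        f"- variants tested: {hc['n_tested']}",
        f"- HcDNV: {hc['n_hcdnv']} (activators {hc['n_activator']}, "
        f"inhibitors {hc['n_inhibitor']})",
        f"- background: {hc['n_background']} ({hc['background_pct']:.1f}%)",
        f"- active reference / alternate sequences: "
        f"{summary['counts']['n_active_reference']} / "
        f"{summary['counts']['n_active_alternate']}",
        f"- case/control FET: OR = {contrast['contrast']['odds_ratio']:.2f}, "
        f"p = {contrast['contrast']['fet_p']:.3g}",
        f"- GC (HcDNV vs background): "
        f"{summary['gc']['gc_hcdnv_mean']:.3f} vs "
        f"{summary['gc']['gc_background_mean']:.3f}",
        f"- significant annotation categories (Bonferroni): "
        f"{', '.join(summary['annotation_enrichment_significant']) or 'none'}",
    ]
    P["summary_md"].write_text("\n".join(md) + "\n")


STAGE_ORDER = ["simulate", "design", "associate", "count", "alpha", "test",
               "enrich", "motifs", "report"]

_STAGE_FNS: Dict[str, Callable] = {
    "simulate": _stage_simulate,
    "design": _stage_design,
    "associate": _stage_associate,
    "count": _stage_count,
    "alpha": _stage_alpha,
    "test": _stage_test,
    "enrich": _stage_enrich,
    "motifs": _stage_motifs,
    "report": _stage_report,
}


def _stage_outputs(name: str, P, reps) -> List[Path]:
    out = {
        "simulate": ["variants", "truth", "genome", "assoc_reads", "h3k27ac",
                     "atac", "tss", "sim_config"]
        + [f"dna_{r}" for r in reps] + [f"rna_{r}" for r in reps],
        "design": ["library", "manifest"],
        "associate": ["assignments", "assoc_qc"],
        "count": ["count_qc"] + [f"counts_{r}" for r in reps],
        "alpha": ["alphas", "size_factors", "activity"],
        "test": ["differential", "contrast", "volcano"],
        "enrich": ["anno_enrichment", "peak_enrichment", "gc", "gc_table"],
        "motifs": ["motif_hits", "disruption", "motif_contrast"],
        "report": ["summary_json", "summary_md"],
    }[name]
    return [P[k] for k in out]


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> RunResult:
    """Run all stages in dependency order.

    A stage failure raises PipelineError naming the stage; outputs of
    completed stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reps = [f"rep{t + 1}" for t in range(cfg.sim_config().n_replicates)]
    P = _paths(out, reps)
    ctx = {"reps": reps}

    stages_run = []
    upstream_ran = False
    for name in STAGE_ORDER:
        outputs = _stage_outputs(name, P, reps)
        if resume and not upstream_ran and all(p.exists() for p in outputs):
            logger.info("stage %s: outputs present, skipped", name)
            continue
        logger.info("stage %s: running", name)
        for p in outputs:
            p.parent.mkdir(parents=True, exist_ok=True)
        try:
            _STAGE_FNS[name](cfg, P, ctx)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        stages_run.append(name)
        upstream_ran = True

    summary = _read_json(P["summary_json"])
    return RunResult(out, stages_run, summary)
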