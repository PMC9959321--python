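"""Synthetic MPRA data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a library of paired reference/alternate 200-nt candidate regulatory
sequences tagged by ~125 barcodes each, observed in three biological
replicates, with gamma-distributed construct (DNA) abundances and
negative-binomial RNA counts whose mean is proportional to a per-sequence
transcription rate ("alpha").  A configurable fraction of variants carries a
planted allelic effect; effect variants are drawn with higher window GC and
enriched annotation flags, mirroring the structure the analysis is meant to
detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Dict

import numpy as np
import pandas as pd

from ._util import BASES, encode_barcode, gmean
from .errors import ConfigError

FLANK = 200  # genome padding on each side of the variant block


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe the assayed design: 3600 variants with a 1888/1712
    case/control split, three replicates, ~125 barcodes per library sequence,
    150 positive and 150 scrambled negative controls, and window GC drawn
    around 0.63 for effect variants vs 0.50 for null variants.
    """

    n_variants: int = 3600
    frac_case: float = 1888 / 3600
    frac_true_effect: float = 0.05
    effect_size_log: float = 0.5
    n_replicates: int = 3
    barcodes_per_seq_mean: float = 125.0
    dna_gamma_shape: float = 4.0
    dna_gamma_scale: float = 12.5
    rna_dispersion: float = 10.0
    baseline_alpha: float = 1.0
    positive_alpha_mult: float = 8.0
    n_pos_controls: int = 150
    n_neg_controls: int = 150
    seed: int = 0
    # genome / variant structure
    window: int = 200
    spacing: int = 300
    frac_snv: float = 0.8
    max_indel: int = 3
    # planted correlates
    gc_effect_target: float = 0.63
    gc_null_target: float = 0.50
    gc_sd: float = 0.04
    alpha_log_sd: float = 0.25
    n_annotation_categories: int = 28
    n_enriched_categories: int = 10
    flag_base_rate: float = 0.15
    flag_effect_rate: float = 0.35
    assoc_ambiguous_frac: float = 0.05
    assoc_umi_mean: float = 10.0

    def validate(self) -> None:
        counts = [
            "n_variants", "n_replicates", "n_pos_controls", "n_neg_controls",
            "n_annotation_categories", "n_enriched_categories", "max_indel",
        ]
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        fractions = [
            "frac_case", "frac_true_effect", "frac_snv", "gc_effect_target",
            "gc_null_target", "flag_base_rate", "flag_effect_rate",
            "assoc_ambiguous_frac",
        ]
        for name in fractions:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        positive = [
            "effect_size_log", "barcodes_per_seq_mean", "dna_gamma_shape",
            "dna_gamma_scale", "rna_dispersion", "baseline_alpha",
            "positive_alpha_mult", "window", "spacing", "assoc_umi_mean",
        ]
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be positive, got {v!r}")
        if self.positive_alpha_mult <= 1:
            raise ConfigError(
                f"positive_alpha_mult must exceed 1, got {self.positive_alpha_mult!r}")
        if self.gc_sd < 0 or self.alpha_log_sd < 0:
            raise ConfigError("gc_sd and alpha_log_sd must be non-negative")
        if self.n_replicates == 0:
            raise ConfigError("n_replicates must be at least 1")
        if self.spacing < self.window + 20:
            raise ConfigError("spacing must exceed window + 20")
        if self.n_enriched_categories > self.n_annotation_categories:
            raise ConfigError(
                "n_enriched_categories cannot exceed n_annotation_categories")

    def to_dict(self) -> dict:
        return asdict(self)


def annotation_columns(cfg: SimConfig) -> list:
    return [f"anno_{i + 1:02d}" for i in range(cfg.n_annotation_categories)]


@dataclass
class SimulatedVariants:
    variants: pd.DataFrame
    truth: pd.DataFrame
    genome: Dict[str, str]


def _draw_window(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=p)


def simulate_variants(cfg: SimConfig) -> SimulatedVariants:
    """Generate a variant table, ground truth, and a synthetic genome.

    Variant windows are laid out non-overlapping on a single synthetic
    chromosome, each variant sitting at 0-based offset 99 of its 200-nt
    window.  Exactly ``round(frac_case * n)`` variants are labelled case and
    ``round(frac_true_effect * n)`` carry a planted allelic effect, split
    alternately between activator loci (alt allele lowers alpha) and
    inhibitor loci (alt allele raises alpha).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_variants
    anno_cols = annotation_columns(cfg)

    if n == 0:
        variants = pd.DataFrame(columns=[
            "variant_id", "chrom", "pos", "ref_allele", "alt_allele",
            "origin", "subset", "nearest_gene", *anno_cols])
        truth = pd.DataFrame(columns=[
            "variant_id", "true_alpha_ref", "true_alpha_alt", "is_effect",
            "effect_class", "gc_target"])
        genome = {"chr1": "".join(BASES[b] for b in rng.integers(0, 4, 2 * FLANK))}
        return SimulatedVariants(variants, truth, genome)

    # labels -------------------------------------------------------------
    n_case = int(round(cfg.frac_case * n))
    origin = np.array(["control"] * n, dtype=object)
    origin[rng.permutation(n)[:n_case]] = "case"

    n_eff = int(round(cfg.frac_true_effect * n))
    is_effect = np.zeros(n, dtype=bool)
    eff_idx = np.sort(rng.permutation(n)[:n_eff])
    is_effect[eff_idx] = True
    effect_class = np.array(["null"] * n, dtype=object)
    effect_class[eff_idx[0::2]] = "activator_locus"
    effect_class[eff_idx[1::2]] = "inhibitor_locus"

    gc_target = np.where(
        is_effect,
        rng.normal(cfg.gc_effect_target, cfg.gc_sd, n),
        rng.normal(cfg.gc_null_target, cfg.gc_sd, n),
    ).clip(0.2, 0.9)

    n_snv = int(round(cfg.frac_snv * n))
    vtype = np.array(["snv"] * n, dtype=object)
    other = rng.permutation(n)[: n - n_snv]
    vtype[other[0::2]] = "insertion"
    vtype[other[1::2]] = "deletion"

    # genome --------------------------------------------------------------
    total = 2 * FLANK + n * cfg.spacing
    genome_arr = rng.integers(0, 4, total)
    margin = (cfg.spacing - cfg.window) // 2
    w0 = FLANK + np.arange(n) * cfg.spacing + margin
    for i in range(n):
        genome_arr[w0[i]:w0[i] + cfg.window] = _draw_window(rng, cfg.window, gc_target[i])
    pos0 = w0 + 99          # 0-based variant start
    pos = pos0 + 1          # 1-based

    # alleles --------------------------------------------------------------
    ref_alleles, alt_alleles = [], []
    for i in range(n):
        b = genome_arr[pos0[i]]
        if vtype[i] == "snv":
            ref_alleles.append(BASES[b])
            alt_alleles.append(BASES[(b + rng.integers(1, 4)) % 4])
        elif vtype[i] == "insertion":
            k = int(rng.integers(1, cfg.max_indel + 1))
            ins = "".join(BASES[j] for j in rng.integers(0, 4, k))
            ref_alleles.append(BASES[b])
            alt_alleles.append(BASES[b] + ins)
        else:  # deletion of k bases after the anchor
            k = int(rng.integers(1, cfg.max_indel + 1))
            span = genome_arr[pos0[i]:pos0[i] + 1 + k]
            ref_alleles.append("".join(BASES[j] for j in span))
            alt_alleles.append(BASES[b])

    # alphas ----------------------------------------------------------------
    alpha_ref = cfg.baseline_alpha * np.exp(rng.normal(0.0, cfg.alpha_log_sd, n))
    shift = np.where(effect_class == "activator_locus", -cfg.effect_size_log,
                     np.where(effect_class == "inhibitor_locus", cfg.effect_size_log, 0.0))
    alpha_alt = alpha_ref * np.exp(shift)

    # annotation flags: the first n_enriched categories are enriched among
    # effect variants
    rates = np.full((n, cfg.n_annotation_categories), cfg.flag_base_rate)
    rates[np.ix_(is_effect, np.arange(cfg.n_enriched_categories))] = cfg.flag_effect_rate
    flags = (rng.random((n, cfg.n_annotation_categories)) < rates).astype(int)

    vid = [f"v{i:05d}" for i in range(n)]
    subset = np.where(rng.random(n) < 923 / 3600, "conserved", "model_prioritized")
    variants = pd.DataFrame({
        "variant_id": vid,
        "chrom": "chr1",
        "pos": pos,
        "ref_allele": ref_alleles,
        "alt_allele": alt_alleles,
        "origin": origin,
        "subset": subset,
        "nearest_gene": [f"GENE{i:05d}" for i in range(n)],
    })
    for j, c in enumerate(anno_cols):
        variants[c] = flags[:, j]

    truth = pd.DataFrame({
        "variant_id": vid,
        "true_alpha_ref": alpha_ref,
        "true_alpha_alt": alpha_alt,
        "is_effect": is_effect,
        "effect_class": effect_class,
        "gc_target": gc_target,
    })
    genome = {"chr1": "".join(BASES[b] for b in genome_arr)}
    return SimulatedVariants(variants, truth, genome)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCounts:
    """Barcode-level counts plus the latent quantities that produced them.

    ``tables`` holds one post-intersection BarcodeTable per replicate
    (barcode, sequence_id, dna_count, rna_count; both counts >= 1);
    ``library_tables`` holds the raw per-library (barcode, count) views that
    feed the counting stage; ``barcode_map`` is the ground-truth
    barcode -> sequence assignment.
    """
    tables: Dict[str, pd.DataFrame]
    library_tables: Dict[str, Dict[str, pd.DataFrame]]
    barcode_map: pd.DataFrame
    sequence_alphas: pd.Series
    dna_size_factors: np.ndarray
    rna_size_factors: np.ndarray


def sequence_ids_for(truth: pd.DataFrame, cfg: SimConfig):
    """Per-sequence ids in library order: ref/alt pairs, then controls."""
    ids = []
    for vid in truth["variant_id"]:
        ids.append(f"{vid}_ref")
        ids.append(f"{vid}_alt")
    ids += [f"pos_{i:03d}" for i in range(cfg.n_pos_controls)]
    ids += [f"neg_{i:03d}" for i in range(cfg.n_neg_controls)]
    return ids


def simulate_counts(truth: pd.DataFrame, cfg: SimConfig) -> SimulatedCounts:
    """Generate per-replicate barcode-level DNA/RNA counts.

    For each sequence *s* and barcode *b*: a latent construct abundance
    d_sb ~ Gamma(shape, scale) shared across replicates; observed DNA count
    round(d_sb * dna_size_factor_t); RNA count ~ NB(mean = alpha_s * d_sb *
    rna_size_factor_t, size = rna_dispersion).  Barcode numbers per sequence
    are Poisson(barcodes_per_seq_mean) truncated at 1.  True size factors are
    drawn log-uniform in [0.5, 2] and renormalised to geometric mean 1 per
    library type (the identifiability convention the estimator uses).
    """
    cfg.validate()
    if truth is None or len(truth) == 0:
        if cfg.n_pos_controls == 0 and cfg.n_neg_controls == 0:
            raise ConfigError("truth table is empty and no controls requested")
    rng = np.random.default_rng([cfg.seed, 1])

    seq_ids = sequence_ids_for(truth, cfg)
    alphas = []
    for _, row in truth.iterrows():
        alphas.append(row["true_alpha_ref"])
        alphas.append(row["true_alpha_alt"])
    alphas += list(cfg.baseline_alpha * cfg.positive_alpha_mult
                   * np.exp(rng.normal(0.0, cfg.alpha_log_sd, cfg.n_pos_controls)))
    alphas += list(cfg.baseline_alpha
                   * np.exp(rng.normal(0.0, cfg.alpha_log_sd, cfg.n_neg_controls)))
    alpha = pd.Series(alphas, index=seq_ids, name="true_alpha")
    n_seq = len(seq_ids)

    # truncated-Poisson barcode counts
    n_b = rng.poisson(cfg.barcodes_per_seq_mean, n_seq)
    while np.any(n_b == 0):
        zero = n_b == 0
        n_b[zero] = rng.poisson(cfg.barcodes_per_seq_mean, int(zero.sum()))
    total_b = int(n_b.sum())

    barcode = np.array([encode_barcode(i) for i in range(total_b)], dtype=object)
    seq_of_b = np.repeat(np.array(seq_ids, dtype=object), n_b)
    alpha_of_b = np.repeat(alpha.to_numpy(), n_b)
    d = rng.gamma(cfg.dna_gamma_shape, cfg.dna_gamma_scale, total_b)

    def _factors():
        f = np.exp(rng.uniform(np.log(0.5), np.log(2.0), cfg.n_replicates))
        return f / gmean(f)

    dna_sf = _factors()
    rna_sf = _factors()

    tables, library_tables = {}, {}
    r = cfg.rna_dispersion
    for t in range(cfg.n_replicates):
        rep = f"rep{t + 1}"
        dna = np.rint(d * dna_sf[t]).astype(np.int64)
        mu = alpha_of_b * d * rna_sf[t]
        rna = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
        library_tables[rep] = {
            "dna": pd.DataFrame({"barcode": barcode[dna > 0], "count": dna[dna > 0]}),
            "rna": pd.DataFrame({"barcode": barcode[rna > 0], "count": rna[rna > 0]}),
        }
        both = (dna > 0) & (rna > 0)
        tables[rep] = pd.DataFrame({
            "barcode": barcode[both],
            "sequence_id": seq_of_b[both],
            "dna_count": dna[both],
            "rna_count": rna[both],
        })

    barcode_map = pd.DataFrame({"barcode": barcode, "sequence_id": seq_of_b})
    return SimulatedCounts(tables, library_tables, barcode_map, alpha, dna_sf, rna_sf)


def simulate_association_reads(barcode_map: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """(barcode, umi, sequence_id) triples emulating the association library.

    Every barcode receives at least 3 unique UMIs mapping to its true
    sequence; a fraction ``assoc_ambiguous_frac`` of barcodes additionally
    receives an equal number of UMIs mapping to a random other sequence,
    which drives their support fraction to ~0.5 and makes them ambiguous.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    nb = len(barcode_map)
    lam = max(cfg.assoc_umi_mean - 3.0, 0.0)
    n_umi = 3 + rng.poisson(lam, nb)
    contaminated = rng.random(nb) < cfg.assoc_ambiguous_frac
    seqs = barcode_map["sequence_id"].to_numpy()
    uniq_seqs = pd.unique(seqs)

    barcodes_out, umis_out, seqs_out = [], [], []
    for i, (bc, sid) in enumerate(zip(barcode_map["barcode"], seqs)):
        k = int(n_umi[i])
        barcodes_out.extend([bc] * k)
        umis_out.extend(f"u{j:04d}" for j in range(k))
        seqs_out.extend([sid] * k)
        if contaminated[i] and len(uniq_seqs) > 1:
            other = uniq_seqs[int(rng.integers(len(uniq_seqs)))]
            if other == sid:
                other = uniq_seqs[0] if sid != uniq_seqs[0] else uniq_seqs[1]
            barcodes_out.extend([bc] * k)
            umis_out.extend(f"u{j:04d}" for j in range(k, 2 * k))
            seqs_out.extend([other] * k)
    return pd.DataFrame({"barcode": barcodes_out, "umi": umis_out,
                         "sequence_id": seqs_out})


# ---------------------------------------------------------------------------
# synthetic epigenome for positive-control selection
# ---------------------------------------------------------------------------

@dataclass
class Epigenome:
    h3k27ac: pd.DataFrame
    atac: pd.DataFrame
    tss: pd.DataFrame


def simulate_epigenome(genome: Dict[str, str], cfg: SimConfig,
                       n_peaks: int | None = None) -> Epigenome:
    """Random H3K27ac/ATAC peak pairs with nearby expressed TSSs.

    Each H3K27ac peak contains one ATAC peak; TSS distances and expression
    are drawn so that roughly half the peaks survive the positive-control
    filters (distance 150-2000 bp, RPKM >= 2).
    """
    rng = np.random.default_rng([cfg.seed, 3])
    chrom = next(iter(genome))
    length = len(genome[chrom])
    if n_peaks is None:
        n_peaks = max(4 * cfg.n_pos_controls, 40)
    lo, hi = 2600, max(length - 2600, 2700)
    starts = np.sort(rng.integers(lo, hi, n_peaks))
    h_width = rng.integers(800, 1500, n_peaks)
    h_score = rng.gamma(3.0, 20.0, n_peaks)
    a_width = rng.integers(150, 260, n_peaks)
    a_off = np.array([rng.integers(0, max(hw - aw, 1))
                      for hw, aw in zip(h_width, a_width)])
    a_start = starts + a_off
    a_score = rng.gamma(3.0, 10.0, n_peaks)

    mid = a_start + a_width // 2
    dist = rng.integers(120, 2400, n_peaks)
    sign = rng.choice([-1, 1], n_peaks)
    tss_pos = np.clip(mid + sign * dist, 1, length - 1)
    expr = np.exp(rng.normal(1.2, 1.0, n_peaks))

    h3 = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + h_width,
                       "name": [f"h3_{i:04d}" for i in range(n_peaks)],
                       "score": h_score})
    atac = pd.DataFrame({"chrom": chrom, "start": a_start, "end": a_start + a_width,
                         "name": [f"atac_{i:04d}" for i in range(n_peaks)],
                         "score": a_score})
    tss = pd.DataFrame({"gene": [f"GENEP{i:04d}" for i in range(n_peaks)],
                        "chrom": chrom, "pos": tss_pos, "expression": expr})
    return Epigenome(h3, atac, tss)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_config_yaml(cfg: SimConfig, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
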