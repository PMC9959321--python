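"""Candidate-regulatory-sequence (CRS) library design.

Builds paired reference/alternate 200-nt windows around each variant (the
variant base at 0-based offset 99, i.e. the 100th bp), scrambled negative
controls, epigenetically ranked positive controls, and the library FASTA plus
manifest.

Coordinate conventions: variant positions are 1-based on input (VCF style);
all intervals are handled internally as 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import BASES
from .errors import (BoundaryError, FormatError, ManifestError,
                     ReferenceMismatchError, SamplingError)

WINDOW = 200
VARIANT_OFFSET = 99  # 0-based: the "100th bp" of the window


@dataclass(frozen=True)
class CRSPair:
    """Reference and alternate candidate regulatory sequences for a variant."""
    variant_id: str
    ref_seq: str
    alt_seq: str
    window: Tuple[str, int, int]  # chrom, 0-based half-open
    variant_offset: int = VARIANT_OFFSET


@dataclass(frozen=True)
class ControlSeq:
    control_id: str
    klass: str  # "positive" | "negative"
    seq: str
    source_variant_id: str | None = None
    source_origin: str | None = None


def _chrom_len(genome, chrom: str) -> int:
    return len(genome[chrom])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """0-based half-open slice from a dict-of-strings or pyfaidx.Fasta."""
    return str(genome[chrom][start:end]).upper()


def build_crs_pair(variant: Mapping, genome, *, window: int = WINDOW,
                   offset: int = VARIANT_OFFSET) -> CRSPair:
    """Build the reference/alternate sequence pair for one variant.

    The allele whose sequence is genomic (reference for SNVs and deletions,
    alternate for insertions) is exactly ``window`` nt long with the variant
    start at ``offset``; the partner is obtained by allele substitution, so
    indel pairs differ in length by the indel size.
    """
    chrom = variant["chrom"]
    pos0 = int(variant["pos"]) - 1
    ref_a = str(variant["ref_allele"]).upper()
    alt_a = str(variant["alt_allele"]).upper()
    vid = variant["variant_id"]
    for allele, label in ((ref_a, "ref_allele"), (alt_a, "alt_allele")):
        if not allele or any(b not in BASES for b in allele):
            raise FormatError(f"{vid}: {label} {allele!r} is not a non-empty ACGT string")

    clen = _chrom_len(genome, chrom)
    observed = _fetch(genome, chrom, pos0, pos0 + len(ref_a))
    if observed != ref_a:
        raise ReferenceMismatchError(
            f"{vid}: reference allele mismatch at {chrom}:{pos0 + 1}: "
            f"expected {ref_a!r}, observed {observed!r}")

    if len(alt_a) > len(ref_a):
        # insertion: the alternate sequence is the 200-nt member
        right_len = window - offset - len(alt_a)
        start = pos0 - offset
        end = pos0 + len(ref_a) + right_len
        if start < 0 or end > clen or right_len < 0:
            raise BoundaryError(f"{vid}: window [{start}, {end}) outside {chrom} "
                                f"(length {clen})")
        left = _fetch(genome, chrom, start, pos0)
        right = _fetch(genome, chrom, pos0 + len(ref_a), end)
        ref_seq = left + ref_a + right
        alt_seq = left + alt_a + right
    else:
        # SNV / deletion: the reference sequence is the 200-nt member
        start = pos0 - offset
        end = start + window
        if start < 0 or end > clen:
            raise BoundaryError(f"{vid}: window [{start}, {end}) outside {chrom} "
                                f"(length {clen})")
        ref_seq = _fetch(genome, chrom, start, end)
        alt_seq = ref_seq[:offset] + alt_a + ref_seq[offset + len(ref_a):]
    return CRSPair(vid, ref_seq, alt_seq, (chrom, start, end), offset)


def build_crs_pairs(variants: pd.DataFrame, genome) -> List[CRSPair]:
    return [build_crs_pair(row, genome) for _, row in variants.iterrows()]


def scramble_negatives(pairs: Sequence[CRSPair], origins: Mapping[str, str],
                       n_case: int, n_control: int, seed) -> List[ControlSeq]:
    """Scrambled negative controls: uniform permutations of randomly chosen
    reference sequences, preserving the case/control source composition."""
    rng = np.random.default_rng(seed)
    by_origin = {"case": [], "control": []}
    for p in pairs:
        o = origins.get(p.variant_id)
        if o in by_origin:
            by_origin[o].append(p)
    for want, o in ((n_case, "case"), (n_control, "control")):
        if want > len(by_origin[o]):
            raise SamplingError(
                f"requested {want} {o} negatives but only {len(by_origin[o])} "
                f"{o} pairs are available")
    out: List[ControlSeq] = []
    for o, want in (("case", n_case), ("control", n_control)):
        pool = by_origin[o]
        chosen = rng.choice(len(pool), size=want, replace=False)
        for j in sorted(chosen):
            p = pool[j]
            perm = rng.permutation(len(p.ref_seq))
            seq = "".join(p.ref_seq[k] for k in perm)
            out.append(ControlSeq(f"neg_{len(out):03d}", "negative", seq,
                                  p.variant_id, o))
    return out


def select_positive_controls(h3k27ac: pd.DataFrame, atac: pd.DataFrame,
                             tss: pd.DataFrame, genome, *, n: int | None = 150,
                             top_h3k27ac: int = 5000, min_dist: int = 150,
                             max_dist: int = 2000, min_expression: float = 2.0,
                             window: int = WINDOW) -> Tuple[List[ControlSeq], pd.DataFrame]:
    """Rank candidate positive controls through the five-step filter.

    (1) top ``top_h3k27ac`` H3K27ac peaks by score; (2) the maximum-score
    ATAC peak contained in each; (3) keep peaks whose midpoint lies between
    ``min_dist`` and ``max_dist`` bp (inclusive) from a TSS; (4) require that
    TSS's transcript expression >= ``min_expression``; (5) a ``window``-bp
    sequence centred on the retained ATAC-peak midpoint.  Candidates are
    ranked by ATAC score (ties by chrom, start) and truncated to ``n``.
    """
    for name, df in (("h3k27ac", h3k27ac), ("atac", atac)):
        if "score" not in df.columns:
            raise FormatError(f"{name} peak table lacks a 'score' column")
    for col in ("chrom", "start", "end"):
        if col not in h3k27ac.columns or col not in atac.columns:
            raise FormatError("peak tables need chrom/start/end columns")
    if not {"chrom", "pos", "expression"}.issubset(tss.columns):
        raise FormatError("tss table needs chrom/pos/expression columns")

    top = h3k27ac.sort_values(["score", "chrom", "start"],
                              ascending=[False, True, True]).head(top_h3k27ac)
    rows = []
    for _, h in top.iterrows():
        contained = atac[(atac["chrom"] == h["chrom"])
                         & (atac["start"] >= h["start"])
                         & (atac["end"] <= h["end"])]
        if contained.empty:
            continue
        best = contained.sort_values(["score", "chrom", "start"],
                                     ascending=[False, True, True]).iloc[0]
        mid = int((int(best["start"]) + int(best["end"])) // 2)
        near = tss[tss["chrom"] == best["chrom"]].copy()
        near["dist"] = (near["pos"] - mid).abs()
        ok = near[(near["dist"] >= min_dist) & (near["dist"] <= max_dist)
                  & (near["expression"] >= min_expression)]
        if ok.empty:
            continue
        rows.append({"chrom": best["chrom"], "start": int(best["start"]),
                     "end": int(best["end"]), "score": float(best["score"]),
                     "mid": mid})
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "mid"])
    if not table.empty:
        table = (table.drop_duplicates(["chrom", "start", "end"])
                 .sort_values(["score", "chrom", "start"],
                              ascending=[False, True, True])
                 .reset_index(drop=True))
        if n is not None:
            table = table.head(n)
    controls = []
    for i, row in table.iterrows():
        start = int(row["mid"]) - window // 2
        seq = _fetch(genome, row["chrom"], start, start + window)
        controls.append(ControlSeq(f"pos_{i:03d}", "positive", seq))
    return controls, table


def emit_library(pairs: Sequence[CRSPair], controls: Sequence[ControlSeq],
                 fasta_path, manifest_path=None) -> pd.DataFrame:
    """Write one FASTA record per library sequence and return the manifest."""
    records, rows, seen = [], [], set()

    def _add(seq_id, seq, role, variant_id):
        if seq_id in seen:
            raise ManifestError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        records.append(SeqRecord(Seq(seq), id=seq_id, description=""))
        rows.append({"sequence_id": seq_id, "role": role,
                     "variant_id": variant_id or ""})

    for p in pairs:
        _add(f"{p.variant_id}_ref", p.ref_seq, "reference", p.variant_id)
        _add(f"{p.variant_id}_alt", p.alt_seq, "alternate", p.variant_id)
    for c in controls:
        _add(c.control_id, c.seq, c.klass, c.source_variant_id)

    SeqIO.write(records, str(fasta_path), "fasta")
    manifest = pd.DataFrame(rows, columns=["sequence_id", "role", "variant_id"])
    if manifest_path is not None:
        manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest


def read_library_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_genome_fasta(path) -> Dict[str, str]:
    return read_library_fasta(path)
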