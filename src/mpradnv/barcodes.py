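"""Barcode-to-sequence association and per-replicate count tables.

A barcode is confidently assigned to a library sequence when at least
``min_umis`` unique UMIs support the assignment and the supporting UMIs make
up at least ``min_fraction`` of all UMIs seen for that barcode (both
thresholds inclusive).  Downstream count tables keep only confidently
assigned barcodes observed in both the DNA and RNA library of the same
replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from ._util import as_count_series
from .errors import PipelineError

logger = logging.getLogger(__name__)

BARCODE_LENGTH = 15
UNMAPPED = "*"


@dataclass
class AssociationResult:
    assignments: pd.DataFrame  # barcode, sequence_id, n_support_umis, support_fraction, status
    n_skipped: int

    @property
    def confident(self) -> pd.DataFrame:
        return self.assignments[self.assignments["status"] == "confident"]


def associate(reads, *, min_umis: int = 3, min_fraction: float = 0.8,
              barcode_length: int = BARCODE_LENGTH) -> AssociationResult:
    """Assign barcodes to sequences from (barcode, umi, sequence_id) triples.

    Support is computed over unique UMIs; reads mapping nowhere
    (sequence_id ``*``) count in the denominator but support no sequence.
    Barcodes of the wrong length are skipped with a logged count.  Ties for
    the best-supported sequence are labelled ambiguous.
    """
    df = pd.DataFrame(reads, columns=["barcode", "umi", "sequence_id"]) \
        if not isinstance(reads, pd.DataFrame) else reads
    bad = df["barcode"].str.len() != barcode_length
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("skipped %d reads with malformed barcodes", n_skipped)
        df = df[~bad]

    if df.empty:
        cols = ["barcode", "sequence_id", "n_support_umis", "support_fraction", "status"]
        return AssociationResult(pd.DataFrame(columns=cols), n_skipped)

    triples = df.drop_duplicates(["barcode", "umi", "sequence_id"])
    total = triples.groupby("barcode")["umi"].nunique()

    mapped = triples[triples["sequence_id"] != UNMAPPED]
    support = (mapped.groupby(["barcode", "sequence_id"])["umi"].nunique()
               .reset_index(name="n_support_umis")
               .sort_values(["barcode", "n_support_umis", "sequence_id"],
                            ascending=[True, False, True]))
    grouped = support.groupby("barcode", sort=False)
    top = grouped.nth(0).set_index("barcode")
    runner = grouped.nth(1).set_index("barcode")
    tied = set(runner.index[
        runner["n_support_umis"].eq(
            top["n_support_umis"].reindex(runner.index))])

    rows = []
    for bc, n_total in total.items():
        if bc in top.index:
            sid = top.loc[bc, "sequence_id"]
            n_sup = int(top.loc[bc, "n_support_umis"])
        else:
            sid, n_sup = UNMAPPED, 0
        frac = n_sup / n_total if n_total else 0.0
        confident = (bc not in tied and sid != UNMAPPED
                     and n_sup >= min_umis and frac >= min_fraction)
        rows.append({"barcode": bc, "sequence_id": sid,
                     "n_support_umis": n_sup, "support_fraction": frac,
                     "status": "confident" if confident else "ambiguous"})
    assignments = pd.DataFrame(rows).sort_values("barcode").reset_index(drop=True)
    return AssociationResult(assignments, n_skipped)


def count_barcodes(dna_counts, rna_counts, assignments: pd.DataFrame,
                   replicate: str) -> Tuple[pd.DataFrame, dict]:
    """Intersect DNA/RNA library barcode counts with confident assignments.

    Returns the per-replicate BarcodeTable (barcode, sequence_id, dna_count,
    rna_count; confident barcodes present in both libraries) plus a QC dict
    with read-weighted fractions of confident / ambiguous / unobserved
    barcodes and the mean number of barcodes per sequence.
    """
    dna = as_count_series(dna_counts)
    rna = as_count_series(rna_counts)
    status = assignments.set_index("barcode")["status"]
    confident = status[status == "confident"].index
    if len(confident) == 0:
        raise PipelineError("no confidently assigned barcodes available")
    seq_of = assignments.set_index("barcode")["sequence_id"]

    def _tally(counts: pd.Series):
        known = counts.index.isin(status.index)
        conf = counts.index.isin(confident)
        return (float(counts[conf].sum()),
                float(counts[known & ~conf].sum()),
                float(counts[~known].sum()))

    c1, a1, u1 = _tally(dna)
    c2, a2, u2 = _tally(rna)
    tot = c1 + a1 + u1 + c2 + a2 + u2
    qc = {
        "replicate": replicate,
        "frac_confident": (c1 + c2) / tot if tot else 0.0,
        "frac_ambiguous": (a1 + a2) / tot if tot else 0.0,
        "frac_unobserved": (u1 + u2) / tot if tot else 0.0,
    }

    keep = dna.index.intersection(rna.index).intersection(confident)
    table = pd.DataFrame({
        "barcode": keep,
        "sequence_id": seq_of.loc[keep].to_numpy(),
        "dna_count": dna.loc[keep].to_numpy(),
        "rna_count": rna.loc[keep].to_numpy(),
    })
    table = table[(table["dna_count"] >= 1) & (table["rna_count"] >= 1)]
    table = table.sort_values(["sequence_id", "barcode"]).reset_index(drop=True)
    per_seq = table.groupby("sequence_id").size()
    qc["mean_barcodes_per_sequence"] = float(per_seq.mean()) if len(per_seq) else 0.0
    qc["n_barcodes"] = int(len(table))
    qc["n_sequences"] = int(len(per_seq))
    return table, qc
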