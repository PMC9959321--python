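"""Fisher's-exact enrichment, peak overlap, and GC-content comparison.

All 2x2 tables are oriented with the double-positive count in the upper-left
and the double-negative in the lower-right, so the odds ratio reads as
enrichment of the category among the flagged group.  Annotation families are
Bonferroni-corrected over the number of categories tested (28 for the
standard annotation family).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._util import gc_fraction
from .errors import FormatError, MpraError
from .differential import sample_odds_ratio


@dataclass
class EnrichmentResult:
    category: str
    table: list  # [[a, b], [c, d]], double-positive upper-left
    odds_ratio: float
    p: float
    bonferroni_significant: bool
    family_size: int

    def to_dict(self) -> dict:
        return asdict(self)


def fet_enrich(group_flag, category_flag, *, category: str = "",
               family_size: int = 1, alpha: float = 0.05) -> EnrichmentResult:
    """Two-sided Fisher's exact test of a category against a group flag.

    ``group_flag`` and ``category_flag`` are boolean vectors over the same
    variant universe (e.g. HcDNV membership vs an annotation flag).
    """
    g = np.asarray(group_flag, dtype=bool)
    c = np.asarray(category_flag, dtype=bool)
    if g.size == 0:
        raise MpraError("empty variant universe")
    if g.shape != c.shape:
        raise MpraError("group and category flags must have equal length")
    a = int(np.sum(g & c))
    b = int(np.sum(~g & c))
    cc = int(np.sum(g & ~c))
    d = int(np.sum(~g & ~c))
    table = np.array([[a, b], [cc, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        category=category,
        table=table.tolist(),
        odds_ratio=sample_odds_ratio(table),
        p=float(p),
        bonferroni_significant=bool(p * family_size <= alpha),
        family_size=family_size,
    )


def enrich_categories(variants: pd.DataFrame, group_flag,
                      categories: Sequence[str] | None = None,
                      family_size: int | None = None) -> pd.DataFrame:
    """FET enrichment of each annotation column against a group flag.

    Category membership is data-driven: any column named ``anno_*`` is used
    when ``categories`` is not given, and the Bonferroni family size adapts
    to the number tested.
    """
    if categories is None:
        categories = [c for c in variants.columns if c.startswith("anno_")]
    if family_size is None:
        family_size = len(categories)
    rows = []
    for cat in categories:
        res = fet_enrich(group_flag, variants[cat].astype(bool),
                         category=cat, family_size=family_size)
        (a, b), (c, d) = res.table
        rows.append({"category": cat, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": res.odds_ratio, "p": res.p,
                     "bonferroni_significant": res.bonferroni_significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peak overlap
# ---------------------------------------------------------------------------

def read_bed(path, min_cols: int = 3) -> pd.DataFrame:
    """Parse a BED file (3-5 columns), reporting malformed lines by number."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise FormatError(f"{path}: line {i}: expected >= {min_cols} "
                                  f"columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}: line {i}: end < start")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                try:
                    row["score"] = float(parts[4])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {i}: non-numeric score") from exc
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def variant_intervals(variants: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open interval per variant: a point for SNVs and
    insertions, the deleted span for deletions."""
    start = variants["pos"].astype(int) - 1
    ref_len = variants["ref_allele"].str.len()
    alt_len = variants["alt_allele"].str.len()
    length = np.where(ref_len > alt_len, ref_len, 1)
    return pd.DataFrame({"variant_id": variants["variant_id"],
                         "chrom": variants["chrom"],
                         "start": start, "end": start + length})


def peak_overlap(variants: pd.DataFrame, peaks: pd.DataFrame,
                 peak_set: str = "peaks") -> pd.DataFrame:
    """Flag each variant that intersects >= 1 peak (0-based half-open,
    any overlap) -- bedtools intersect -u / -v semantics."""
    trees: dict[str, IntervalTree] = {}
    for _, p in peaks.iterrows():
        if p["end"] > p["start"]:
            trees.setdefault(p["chrom"], IntervalTree()).addi(
                int(p["start"]), int(p["end"]))
    iv = variant_intervals(variants)
    flags = [
        bool(trees.get(row["chrom"], IntervalTree()).overlap(row["start"], row["end"]))
        for _, row in iv.iterrows()
    ]
    return pd.DataFrame({"variant_id": iv["variant_id"],
                         "peak_set": peak_set, "overlaps": flags})


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_compare(ref_seqs: Mapping[str, str] | pd.Series, group_flag: Mapping[str, bool]):
    """Per-variant GC of the reference library sequence and a two-sided
    Wilcoxon rank-sum test between the two groups.

    Returns (gc Series indexed like ref_seqs, rank-sum p-value).
    """
    seqs = pd.Series(dict(ref_seqs)) if not isinstance(ref_seqs, pd.Series) else ref_seqs
    gc = seqs.map(gc_fraction)
    flag = pd.Series(dict(group_flag)).reindex(gc.index)
    x = gc[flag == True]  # noqa: E712  (NaN-safe boolean comparison)
    y = gc[flag == False]  # noqa: E712
    if len(x) == 0 or len(y) == 0:
        return gc, float("nan")
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return gc, p
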