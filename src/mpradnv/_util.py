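"""Small shared helpers: sequence ops, multiple testing, barcode codec."""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence; ambiguous (N) bases are excluded from both
    numerator and denominator."""
    seq = seq.upper()
    n_valid = sum(seq.count(b) for b in BASES)
    if n_valid == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / n_valid


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def gmean(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(x))))


def encode_barcode(index: int, length: int = 15) -> str:
    """Deterministically encode an integer as a unique DNA barcode."""
    digits = []
    for _ in range(length):
        digits.append(BASES[index % 4])
        index //= 4
    return "".join(digits)


def as_count_series(counts) -> pd.Series:
    """Coerce a (barcode, count) table, Series or mapping to a Series."""
    if isinstance(counts, pd.Series):
        return counts
    if isinstance(counts, pd.DataFrame):
        if not {"barcode", "count"}.issubset(counts.columns):
            raise ValueError("count table needs 'barcode' and 'count' columns")
        return counts.set_index("barcode")["count"]
    return pd.Series(dict(counts))
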