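"""PWM motif scanning with exact null p-values and disruption calls.

Sequences are scored on both strands with log2-odds against a background
model; the p-value of a window score is computed from the *exact* null score
distribution under the background, obtained by dynamic programming over
integer-discretised per-position scores (default granularity 1/1000 bit).
Hits are thresholded at p < 1e-5 and restricted to windows covering the
variant base (the 100th bp of a 200-nt library sequence) before
unchanged/disrupted/gained classification.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .errors import FormatError
from .differential import sample_odds_ratio

logger = logging.getLogger(__name__)

P_THRESHOLD = 1e-5
GRANULARITY = 1e-3      # bits per integer score unit
SCORE_FLOOR = -30.0     # bits; replaces log2(0) for zero-probability entries
VARIANT_OFFSET = 99

_BASE_IDX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_IDX[ord(_b)] = _i
    _BASE_IDX[ord(_b.lower())] = _i


@dataclass
class PWM:
    """Position probability matrix with background and pseudocount."""
    motif_id: str
    matrix: np.ndarray          # width x 4, rows sum to 1
    background: np.ndarray      # length 4
    pseudocount: float = 0.1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise FormatError(f"{self.motif_id}: matrix must be width x 4 with width >= 1")
        if np.any(np.abs(self.matrix.sum(axis=1) - 1.0) > 1e-3):
            raise FormatError(f"{self.motif_id}: matrix rows must sum to 1")
        self.matrix = self.matrix / self.matrix.sum(axis=1, keepdims=True)
        self.background = self.background / self.background.sum()
        if self.pseudocount < 0:
            raise FormatError(f"{self.motif_id}: pseudocount must be non-negative")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2((p + pc*bg) / ((1+pc)*bg)); zero-probability entries floored."""
        padj = (self.matrix + self.pseudocount * self.background) / (1 + self.pseudocount)
        with np.errstate(divide="ignore"):
            lo = np.log2(padj / self.background)
        return np.maximum(lo, SCORE_FLOOR)

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1].copy(),
                   self.background[::-1].copy(), self.pseudocount)


# ---------------------------------------------------------------------------
# MEME minimal format I/O
# ---------------------------------------------------------------------------

def read_meme(path, pseudocount: float = 0.1) -> List[PWM]:
    """Parse a MEME minimal-format motif file; background defaults to
    uniform 0.25 when the file has no background line."""
    with open(path) as fh:
        text = fh.read()
    if not any(line.lower().startswith("background letter frequencies")
               for line in text.splitlines()):
        # no background section: default to uniform 0.25
        head, sep, tail = text.partition("\nMOTIF")
        text = (head + "\nBackground letter frequencies\n"
                "A 0.25 C 0.25 G 0.25 T 0.25\n" + sep + tail)
    try:
        records = list(bio_motifs.parse(io.StringIO(text), "minimal"))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse MEME minimal file: {exc}") from exc
    pwms = []
    for m in records:
        name = m.name or getattr(m, "id", "") or f"motif_{len(pwms)}"
        bg = m.background or {}
        background = np.array([bg.get(b, 0.25) for b in "ACGT"], dtype=float)
        matrix = np.column_stack([np.asarray(m.pwm[b], dtype=float) for b in "ACGT"])
        try:
            pwms.append(PWM(name, matrix, background, pseudocount))
        except FormatError as exc:
            raise FormatError(f"{path}: motif {name!r}: {exc}") from exc
    return pwms


def write_meme(pwms: Sequence[PWM], path) -> None:
    """Write motifs in MEME minimal format (probabilities to 6 d.p.)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write("A %.6f C %.6f G %.6f T %.6f\n\n" % tuple(bg))
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            # large nsites so parsers that round-trip through integer counts
            # keep 6-decimal precision
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width} "
                     f"nsites= 1000000 E= 0\n")
            for row in p.matrix:
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# exact null distribution
# ---------------------------------------------------------------------------

def discretize_scores(log_odds: np.ndarray, granularity: float = GRANULARITY) -> np.ndarray:
    """Integer per-position scores: round(log2-odds / granularity)."""
    return np.rint(log_odds / granularity).astype(np.int64)

def exact_null_tail(int_scores: np.ndarray, background: np.ndarray):
    """Exact distribution of the window score under the background model.

    Returns (min_sum, tail) where tail[k] = P(S >= min_sum + k) for the
    integer score S of a random background window.
    """
    mins = int_scores.min(axis=1)
    maxs = int_scores.max(axis=1)
    min_sum = int(mins.sum())
    dist = np.array([1.0])
    offset = 0  # dist[j] = P(partial sum == offset + j)
    for i in range(int_scores.shape[0]):
        lo, hi = int(mins[i]), int(maxs[i])
        new = np.zeros(len(dist) + hi - lo)
        for a in range(4):
            s = int(int_scores[i, a]) - lo
            new[s:s + len(dist)] += background[a] * dist
        dist = new
        offset += lo
    tail = np.cumsum(dist[::-1])[::-1]
    return min_sum, tail


def _tail_p(score_int: int, min_sum: int, tail: np.ndarray) -> float:
    idx = score_int - min_sum
    if idx <= 0:
        return 1.0
    if idx >= len(tail):
        return 0.0
    return float(tail[idx])


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return _BASE_IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan(seq: str, pwm: PWM, *, sequence_id: str = "",
         p_threshold: float = P_THRESHOLD, granularity: float = GRANULARITY,
         both_strands: bool = True, variant_offset: int | None = None,
         variant_len: int = 1) -> pd.DataFrame:
    """Scan one sequence with one PWM; report hits with p < ``p_threshold``.

    Windows containing ambiguous bases are skipped (logged).  ``covers_variant``
    flags hits whose interval intersects [variant_offset, variant_offset +
    variant_len).
    """
    w = pwm.width
    enc = _encode(seq)
    cols = ["motif_id", "sequence_id", "start", "end", "strand", "score", "p",
            "covers_variant"]
    if len(enc) < w:
        return pd.DataFrame(columns=cols)

    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("%s: skipped %d windows containing N", sequence_id, n_skipped)

    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))

    rows = []
    pos_idx = np.arange(w)
    for strand, mat in strands:
        ints = discretize_scores(mat.log_odds(), granularity)
        min_sum, tail = exact_null_tail(ints, mat.background)
        starts = np.nonzero(valid)[0]
        if len(starts) == 0:
            continue
        scores = ints[pos_idx[None, :], windows[valid]].sum(axis=1)
        for start, s in zip(starts, scores):
            p = _tail_p(int(s), min_sum, tail)
            if p < p_threshold:
                end = int(start) + w
                covers = (variant_offset is not None
                          and start < variant_offset + variant_len
                          and variant_offset < end)
                rows.append((pwm.motif_id, sequence_id, int(start), end, strand,
                             float(s) * granularity, p, bool(covers)))
    return pd.DataFrame(rows, columns=cols)


def scan_library(sequences: Mapping[str, str], pwms: Sequence[PWM],
                 **kwargs) -> pd.DataFrame:
    frames = [scan(seq, pwm, sequence_id=sid, **kwargs)
              for sid, seq in sequences.items() for pwm in pwms]
    empty = scan("ACGT", PWM("empty", np.full((1, 4), 0.25), np.full(4, 0.25))).iloc[:0]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return empty
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# disruption classification
# ---------------------------------------------------------------------------

def classify_disruption(ref_motifs: Iterable[str], alt_motifs: Iterable[str]) -> Tuple[int, int, int]:
    """(unchanged, disrupted, gained) counts keyed by motif identity."""
    ref, alt = set(ref_motifs), set(alt_motifs)
    return len(ref & alt), len(ref - alt), len(alt - ref)


def disruption_table(ref_hits: pd.DataFrame, alt_hits: pd.DataFrame,
                     variant_of: Mapping[str, str]) -> pd.DataFrame:
    """Per-variant unchanged/disrupted/gained counts from variant-covering
    hits on the reference and alternate sequences."""
    def _sets(hits):
        if hits.empty:
            return {}
        h = hits[hits["covers_variant"]]
        out: Dict[str, set] = {}
        for sid, grp in h.groupby("sequence_id"):
            vid = variant_of.get(sid)
            if vid is not None:
                out.setdefault(vid, set()).update(grp["motif_id"])
        return out

    ref_sets, alt_sets = _sets(ref_hits), _sets(alt_hits)
    vids = sorted(set(variant_of.values()))
    rows = []
    for vid in vids:
        u, d, g = classify_disruption(ref_sets.get(vid, ()), alt_sets.get(vid, ()))
        rows.append({"variant_id": vid, "unchanged": u, "disrupted": d, "gained": g})
    return pd.DataFrame(rows)


def disruption_contrast(summary: pd.DataFrame, group_flag: Mapping[str, bool]) -> dict:
    """Compare disrupted vs unchanged motif proportions between two variant
    groups (FET on the pooled counts) and report motifs-per-variant ratios."""
    df = summary.copy()
    df["group"] = df["variant_id"].map(dict(group_flag))
    df = df[df["group"].notna()]
    out = {}
    table = np.zeros((2, 2), dtype=int)
    for gi, gname in ((True, "group"), (False, "background")):
        sub = df[df["group"] == gi]
        n_var = len(sub)
        ref_motifs = int((sub["unchanged"] + sub["disrupted"]).sum())
        disrupted = int(sub["disrupted"].sum())
        out[f"{gname}_n_variants"] = n_var
        out[f"{gname}_motifs_per_variant"] = ref_motifs / n_var if n_var else float("nan")
        out[f"{gname}_disrupted_fraction"] = (disrupted / ref_motifs
                                              if ref_motifs else float("nan"))
        row = 0 if gi else 1
        table[row, 0] = disrupted
        table[row, 1] = ref_motifs - disrupted
    from scipy import stats
    if table.sum() > 0:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        p = float("nan")
    out["table_disrupted_undisrupted"] = table.tolist()
    out["fet_p"] = float(p)
    out["odds_ratio"] = sample_odds_ratio(table)
    return out
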