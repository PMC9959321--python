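"""Allelic differential-activity testing and case/control contrasts.

Each variant's reference and alternate barcode counts are compared by a
likelihood-ratio test between nested NB GLMs: the full model fits one alpha
per replicate plus a shared allelic log fold change, the null model drops the
allelic term (df = 1, chi-square reference).  BH FDR is applied across the
tested variants; high-confidence variants (HcDNVs) satisfy FDR <= 0.2 and
|ln fold change| >= 0.1 (both inclusive), split into activator loci
(reference alpha above alternate) and inhibitor loci (the reverse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

from ._nbglm import fit_nb_glm
from ._util import bh_adjust
from .errors import PipelineError

logger = logging.getLogger(__name__)

HCDNV_FDR = 0.2
HCDNV_ABS_LFC = 0.1


def allelic_lrt(y, offset, rep_idx, is_alt, n_reps: int):
    """LRT p-value for an allele-specific rate, plus the fitted allelic
    log fold change ln(alt/ref)."""
    y = np.asarray(y, float)
    log_o = np.log(np.asarray(offset, float))
    rep_idx = np.asarray(rep_idx)
    is_alt = np.asarray(is_alt, float)
    present = np.unique(rep_idx)
    X_null = (rep_idx[:, None] == present[None, :]).astype(float)
    X_full = np.column_stack([X_null, is_alt])

    full = fit_nb_glm(y, log_o, X_full)
    null = fit_nb_glm(y, log_o, X_null, dispersion=full.dispersion)
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    beta = float(full.theta[-1])
    return p, beta, stat


def sample_odds_ratio(table: np.ndarray) -> float:
    a, b, c, d = np.asarray(table, float).ravel()
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


@dataclass
class ContrastReport:
    """Case/control contrast: FET on (HcDNV vs background) x (case vs
    control), plus Wilcoxon rank-sum effect-size comparisons within strata."""
    contingency: list
    odds_ratio: float                 # sample OR (a*d)/(b*c), double-positive upper-left
    conditional_odds_ratio: float     # exact-test conditional MLE
    ci95: tuple
    fet_p: float
    hcdnv_case_pct: float
    background_case_pct: float
    wilcoxon_p: Dict[str, float] = field(default_factory=dict)
    strata_p: Dict[str, float] = field(default_factory=dict)
    strata_p_bonferroni: Dict[str, float] = field(default_factory=dict)
    skipped: Dict[str, str] = field(default_factory=dict)
    multiple_testing_note: str = (
        "strata p-values Bonferroni-corrected for the 4 equivalent conditions")

    def to_dict(self) -> dict:
        return asdict(self)


def case_control_contrast(frame: pd.DataFrame, origins: Mapping[str, str],
                          metrics=("lfc", "abs_lfc", "deviation", "fdr")) -> ContrastReport:
    """Contrast HcDNVs vs background across case/control origin."""
    df = frame.copy()
    if "hcdnv" not in df.columns:
        raise PipelineError("call_hcdnv must run before the case/control contrast")
    df["origin"] = df["variant_id"].map(dict(origins))
    df = df[df["origin"].isin(["case", "control"])]
    df["abs_lfc"] = df["lfc"].abs()

    a = int(((df["hcdnv"]) & (df["origin"] == "case")).sum())
    b = int(((df["hcdnv"]) & (df["origin"] == "control")).sum())
    c = int(((~df["hcdnv"]) & (df["origin"] == "case")).sum())
    d = int(((~df["hcdnv"]) & (df["origin"] == "control")).sum())
    table = np.array([[a, b], [c, d]])
    _, fet_p = stats.fisher_exact(table, alternative="two-sided")
    cond = _conditional_or(table)
    ci = cond.confidence_interval(0.95)

    hc = df[df["hcdnv"]]
    wil = {}
    for m in metrics:
        x = hc.loc[hc["origin"] == "case", m].to_numpy()
        y = hc.loc[hc["origin"] == "control", m].to_numpy()
        if len(x) == 0 or len(y) == 0:
            wil[m] = float("nan")
            continue
        wil[m] = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)

    strata = {
        "hcdnv_abs_lfc": hc,
        "activators_abs_lfc": hc[hc["effect_class"] == "activator"],
        "inhibitors_abs_lfc": hc[hc["effect_class"] == "inhibitor"],
        "background_abs_lfc": df[~df["hcdnv"]],
    }
    strata_p, skipped = {}, {}
    for name, sub in strata.items():
        x = sub.loc[sub["origin"] == "case", "abs_lfc"].to_numpy()
        y = sub.loc[sub["origin"] == "control", "abs_lfc"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            skipped[name] = "empty case or control stratum"
            continue
        strata_p[name] = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    m = 4
    strata_bonf = {k: min(v * m, 1.0) for k, v in strata_p.items()}

    n_hc, n_bg = a + b, c + d
    return ContrastReport(
        contingency=table.tolist(),
        odds_ratio=sample_odds_ratio(table),
        conditional_odds_ratio=float(cond.statistic),
        ci95=(float(ci.low), float(ci.high)),
        fet_p=float(fet_p),
        hcdnv_case_pct=100.0 * a / n_hc if n_hc else float("nan"),
        background_case_pct=100.0 * c / n_bg if n_bg else float("nan"),
        wilcoxon_p=wil,
        strata_p=strata_p,
        strata_p_bonferroni=strata_bonf,
        skipped=skipped,
    )


def call_hcdnv(frame: pd.DataFrame, fdr: float = HCDNV_FDR,
               abs_lfc: float = HCDNV_ABS_LFC) -> pd.DataFrame:
    """Flag high-confidence variants (inclusive thresholds) and label
    activator/inhibitor loci."""
    df = frame.copy()
    df["hcdnv"] = (df["fdr"] <= fdr) & (df["lfc"].abs() >= abs_lfc)
    df["effect_class"] = np.where(
        ~df["hcdnv"], "background",
        np.where(df["alpha_ref"] > df["alpha_alt"], "activator", "inhibitor"))
    return df


def hcdnv_summary(frame: pd.DataFrame) -> dict:
    n = len(frame)
    n_hc = int(frame["hcdnv"].sum())
    n_act = int((frame["effect_class"] == "activator").sum())
    n_inh = int((frame["effect_class"] == "inhibitor").sum())
    n_bg = n - n_hc
    return {
        "n_tested": n,
        "n_hcdnv": n_hc,
        "n_activator": n_act,
        "n_inhibitor": n_inh,
        "n_background": n_bg,
        "background_pct": 100.0 * n_bg / n if n else float("nan"),
    }


class AllelicEffectResults:
    """Per-variant allelic differential results with HcDNV bookkeeping."""

    def __init__(self, frame: pd.DataFrame, excluded=None):
        self.frame = frame
        self.excluded = list(excluded or [])

    @classmethod
    def from_results(cls, results, pairs: Optional[pd.DataFrame] = None,
                     hcdnv_fdr: float = HCDNV_FDR,
                     hcdnv_abs_lfc: float = HCDNV_ABS_LFC):
        """Test every variant with both alleles fitted.

        ``pairs`` maps variant_id -> (ref sequence id, alt sequence id); when
        omitted it is derived from the model manifest or from ``_ref``/``_alt``
        id suffixes.
        """
        if pairs is None:
            pairs = derive_pairs(results)
        alphas = results.alphas
        rows, excluded = [], []
        n_reps = len(results.model.replicates)
        for _, pr in pairs.iterrows():
            vid, rid, aid = pr["variant_id"], pr["ref_id"], pr["alt_id"]
            if rid not in results._seq_data or aid not in results._seq_data:
                excluded.append(vid)
                continue
            yr, orr, rr = results._seq_data[rid]
            ya, oa, ra = results._seq_data[aid]
            y = np.concatenate([yr, ya])
            o = np.concatenate([orr, oa])
            rep = np.concatenate([rr, ra])
            is_alt = np.concatenate([np.zeros(len(yr)), np.ones(len(ya))])
            p, beta, stat = allelic_lrt(y, o, rep, is_alt, n_reps)
            a_ref = float(alphas.loc[rid, "alpha_mean"])
            a_alt = float(alphas.loc[aid, "alpha_mean"])
            rows.append({
                "variant_id": vid,
                "alpha_ref": a_ref,
                "alpha_alt": a_alt,
                "lfc": float(np.log(a_ref / a_alt)),
                "deviation": abs(a_ref - a_alt) / a_alt,
                "p": p,
                "lrt_stat": stat,
            })
        if excluded:
            logger.info("excluded %d variants lacking a fitted allele", len(excluded))
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame["fdr"] = bh_adjust(frame["p"])
            frame = call_hcdnv(frame, hcdnv_fdr, hcdnv_abs_lfc)
        return cls(frame, excluded)

    def call_hcdnv(self, fdr: float = HCDNV_FDR, abs_lfc: float = HCDNV_ABS_LFC):
        return AllelicEffectResults(call_hcdnv(self.frame, fdr, abs_lfc),
                                    self.excluded)

    def hcdnv_summary(self) -> dict:
        return hcdnv_summary(self.frame)

    def case_control_contrast(self, origins: Mapping[str, str]) -> ContrastReport:
        return case_control_contrast(self.frame, origins)

    def volcano_table(self) -> pd.DataFrame:
        df = self.frame
        return pd.DataFrame({
            "variant_id": df["variant_id"],
            "lfc": df["lfc"],
            "neglog10_fdr": -np.log10(df["fdr"].clip(lower=1e-300)),
        })

    def summary(self) -> str:
        s = self.hcdnv_summary()
        return ("Allelic differential activity\n"
                f"  tested variants: {s['n_tested']}"
                f" (excluded: {len(self.excluded)})\n"
                f"  HcDNV: {s['n_hcdnv']}"
                f" (activators {s['n_activator']}, inhibitors {s['n_inhibitor']})\n"
                f"  background: {s['n_background']} ({s['background_pct']:.1f}%)")


def derive_pairs(results) -> pd.DataFrame:
    """variant_id -> (ref_id, alt_id) from the manifest or id suffixes."""
    m = results.model.manifest
    if m is not None and {"role", "variant_id"}.issubset(m.columns):
        ref = m[m["role"] == "reference"].set_index("variant_id")["sequence_id"]
        alt = m[m["role"] == "alternate"].set_index("variant_id")["sequence_id"]
        vids = ref.index.intersection(alt.index)
        return pd.DataFrame({"variant_id": vids, "ref_id": ref.loc[vids].to_numpy(),
                             "alt_id": alt.loc[vids].to_numpy()})
    ids = results.alphas.index
    vids = sorted({i[:-4] for i in ids if i.endswith("_ref")}
                  & {i[:-4] for i in ids if i.endswith("_alt")})
    return pd.DataFrame({"variant_id": vids,
                         "ref_id": [f"{v}_ref" for v in vids],
                         "alt_id": [f"{v}_alt" for v in vids]})
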