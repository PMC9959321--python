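import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from mpradnv import differential
from mpradnv.differential import (allelic_lrt, call_hcdnv, case_control_contrast,
                                  hcdnv_summary, sample_odds_ratio)
from mpradnv.simulate import SimConfig, simulate_counts, simulate_variants
from mpradnv.activity import TranscriptionRateModel

# the published contingency table: rows HcDNV/background, cols case/control
PRINTED = np.array([[78, 87], [1554, 1371]])


def _hand_counts(alpha_ref, alpha_alt, n=60, seed=5, r=10.0):
    rng = np.random.default_rng(seed)
    d = rng.gamma(4.0, 12.5, 2 * n)
    y_ref = rng.negative_binomial(r, r / (r + alpha_ref * d[:n]))
    y_alt = rng.negative_binomial(r, r / (r + alpha_alt * d[n:]))
    y = np.concatenate([y_ref, y_alt]).astype(float)
    o = d
    rep = np.zeros(2 * n, dtype=int)
    is_alt = np.concatenate([np.zeros(n), np.ones(n)])
    return y, o, rep, is_alt


def test_identical_alleles_null():
    rng = np.random.default_rng(3)
    d = rng.gamma(4.0, 12.5, 50)
    y = rng.negative_binomial(10, 10 / (10 + d)).astype(float)
    yy = np.concatenate([y, y])
    oo = np.concatenate([d, d])
    rep = np.zeros(100, dtype=int)
    is_alt = np.concatenate([np.zeros(50), np.ones(50)])
    p, beta, stat = allelic_lrt(yy, oo, rep, is_alt, 1)
    assert abs(beta) < 1e-6
    assert stat < 1e-8
    assert p > 0.999


def test_lrt_antisymmetry():
    y, o, rep, is_alt = _hand_counts(1.0, 1.8)
    p1, b1, _ = allelic_lrt(y, o, rep, is_alt, 1)
    p2, b2, _ = allelic_lrt(y, o, rep, 1 - is_alt, 1)
    assert b1 == pytest.approx(-b2, abs=1e-4)
    assert p1 == pytest.approx(p2, rel=1e-3)


def test_lrt_detects_large_effect():
    y, o, rep, is_alt = _hand_counts(1.0, 2.5)
    p, beta, _ = allelic_lrt(y, o, rep, is_alt, 1)
    assert p < 1e-6
    assert beta == pytest.approx(np.log(2.5), abs=0.25)


def test_hcdnv_thresholds_inclusive():
    frame = pd.DataFrame({
        "variant_id": ["a", "b", "c", "d"],
        "alpha_ref": [1.5, 1.5, 1.0, 1.0],
        "alpha_alt": [1.0, 1.0, 1.5, 1.0],
        "lfc": [0.1, 0.0999999, -0.1, 0.5],
        "fdr": [0.2, 0.2, 0.2000001, 0.2],
    })
    out = call_hcdnv(frame)
    assert out.set_index("variant_id")["hcdnv"].to_dict() == {
        "a": True, "b": False, "c": False, "d": True}
    assert out.set_index("variant_id")["effect_class"].to_dict() == {
        "a": "activator", "b": "background", "c": "background",
        "d": "background" if False else "inhibitor"}


def test_hcdnv_activator_inhibitor_labels():
    frame = pd.DataFrame({
        "variant_id": ["act", "inh"],
        "alpha_ref": [2.0, 1.0],
        "alpha_alt": [1.0, 2.0],
        "lfc": [np.log(2), -np.log(2)],
        "fdr": [0.01, 0.01],
    })
    out = call_hcdnv(frame).set_index("variant_id")
    assert out.loc["act", "effect_class"] == "activator"
    assert out.loc["inh", "effect_class"] == "inhibitor"


def test_hcdnv_count_monotone_in_fdr():
    rng = np.random.default_rng(9)
    n = 300
    frame = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "alpha_ref": np.exp(rng.normal(0, 0.3, n)),
        "alpha_alt": np.exp(rng.normal(0, 0.3, n)),
        "fdr": rng.uniform(0, 1, n),
    })
    frame["lfc"] = np.log(frame["alpha_ref"] / frame["alpha_alt"])
    counts = [int(call_hcdnv(frame, fdr=q)["hcdnv"].sum())
              for q in (0.05, 0.1, 0.2, 0.5, 1.0)]
    assert counts == sorted(counts)


def test_hcdnv_summary_printed_arithmetic():
    frame = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(3090)],
        "hcdnv": [True] * 165 + [False] * 2925,
        "effect_class": ["activator"] * 83 + ["inhibitor"] * 82
        + ["background"] * 2925,
    })
    s = hcdnv_summary(frame)
    assert s["n_tested"] == 3090
    assert s["n_hcdnv"] == 165
    assert s["n_background"] == 2925
    assert round(s["background_pct"], 1) == 94.7


def _printed_frame():
    rows = []
    spec = [(True, "case", 78), (True, "control", 87),
            (False, "case", 1554), (False, "control", 1371)]
    rng = np.random.default_rng(0)
    i = 0
    origins = {}
    for hc, orig, n in spec:
        for _ in range(n):
            vid = f"v{i:05d}"
            if hc:
                lfc = (0.3 + rng.uniform(0, 0.4)) * (1 if i % 2 else -1)
                fdr = rng.uniform(0, 0.19)
            else:
                lfc = rng.uniform(-0.09, 0.09)
                fdr = rng.uniform(0.21, 1.0)
            rows.append({"variant_id": vid,
                         "alpha_ref": np.exp(lfc / 2),
                         "alpha_alt": np.exp(-lfc / 2),
                         "lfc": lfc, "deviation": abs(np.expm1(lfc)),
                         "fdr": fdr})
            origins[vid] = orig
            i += 1
    frame = call_hcdnv(pd.DataFrame(rows))  # recompute labels consistently
    return frame, origins


def test_case_control_contrast_printed_table():
    frame, origins = _printed_frame()
    rep = case_control_contrast(frame, origins)
    assert rep.contingency == PRINTED.tolist()
    assert round(rep.odds_ratio, 2) == 0.79
    # published p-value is the truncation of 0.1496 to two decimals
    assert int(rep.fet_p * 100) / 100 == 0.14
    assert rep.fet_p == pytest.approx(
        stats.fisher_exact(PRINTED, "two-sided")[1], rel=1e-12)
    assert (round(rep.ci95[0], 2), round(rep.ci95[1], 2)) == (0.57, 1.10)
    assert rep.hcdnv_case_pct == pytest.approx(100 * 78 / 165)
    assert rep.background_case_pct == pytest.approx(100 * 1554 / 2925)
    # truncated to one decimal these are the published proportions
    assert int(rep.hcdnv_case_pct * 10) / 10 == 47.2
    assert int(rep.background_case_pct * 10) / 10 == 53.1
    assert set(rep.strata_p_bonferroni.values()) <= {min(v * 4, 1.0)
                                                     for v in rep.strata_p.values()}


def hypergeom_fet_p(table):
    """From-scratch two-sided FET p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def logpmf(x):
        return (gammaln(row1 + 1) - gammaln(x + 1) - gammaln(row1 - x + 1)
                + gammaln(n - row1 + 1) - gammaln(col1 - x + 1)
                - gammaln(n - row1 - col1 + x + 1)
                - gammaln(n + 1) + gammaln(col1 + 1) + gammaln(n - col1 + 1))

    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    pmf = np.exp([logpmf(x) for x in xs])
    p_obs = np.exp(logpmf(a))
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def test_fet_matches_hypergeometric_oracle():
    for table in (PRINTED, np.array([[3, 1], [1, 3]]),
                  np.array([[10, 0], [5, 12]])):
        scipy_p = stats.fisher_exact(table, "two-sided")[1]
        assert scipy_p == pytest.approx(hypergeom_fet_p(table), rel=1e-9)


def test_sample_odds_ratio_edge_cases():
    assert sample_odds_ratio(np.array([[2, 3], [4, 5]])) == pytest.approx(10 / 12)
    assert sample_odds_ratio(np.array([[2, 0], [4, 5]])) == float("inf")
    assert np.isnan(sample_odds_ratio(np.array([[0, 0], [0, 5]])))


def test_null_log_odds_centred():
    # tables drawn under independence at the study margins: mean log
    # conditional OR ~ 0
    rng = np.random.default_rng(12)
    n, row1, col1 = 3090, 165, 1632
    logors = []
    for _ in range(300):
        a = rng.hypergeometric(col1, n - col1, row1)
        t = np.array([[a, row1 - a], [col1 - a, n - row1 - col1 + a]])
        logors.append(np.log(sample_odds_ratio(t)))
    logors = np.asarray(logors)
    se = logors.std() / np.sqrt(len(logors))
    assert abs(logors.mean()) < 4 * se + 0.01


def test_fet_p_superuniform_under_null():
    # P(p <= alpha) <= alpha + 3 MC SE for the discrete FET null
    rng = np.random.default_rng(13)
    n, row1, col1 = 3090, 165, 1632
    ps = []
    for _ in range(400):
        a = rng.hypergeometric(col1, n - col1, row1)
        t = np.array([[a, row1 - a], [col1 - a, n - row1 - col1 + a]])
        ps.append(stats.fisher_exact(t, "two-sided")[1])
    ps = np.asarray(ps)
    for alpha in (0.05, 0.1, 0.2, 0.5):
        frac = (ps <= alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / len(ps))
        assert frac <= alpha + 3 * se


def test_end_to_end_power_smoke(small_sim, small_results):
    cfg, sim, counts = small_sim
    allelic = small_results.test_allelic_effects()
    truth = sim.truth.set_index("variant_id")
    df = allelic.frame.set_index("variant_id")
    eff = truth["is_effect"].reindex(df.index)
    assert df.loc[eff, "hcdnv"].mean() >= 0.5
    # lfc sign matches the planted direction
    planted = truth.loc[eff[eff].index]
    got = df.loc[eff[eff].index, "lfc"]
    want_sign = np.where(planted["effect_class"] == "activator_locus", 1, -1)
    assert (np.sign(got) == want_sign).all()


def test_excluded_variants_reported(small_results):
    pairs = differential.derive_pairs(small_results)
    pairs = pd.concat([pairs, pd.DataFrame([{"variant_id": "ghost",
                                             "ref_id": "nope_ref",
                                             "alt_id": "nope_alt"}])],
                      ignore_index=True)
    res = differential.AllelicEffectResults.from_results(small_results, pairs)
    assert res.excluded == ["ghost"]
    assert "ghost" not in set(res.frame["variant_id"])
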