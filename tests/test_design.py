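import numpy as np
import pandas as pd
import pytest

from mpradnv import design
from mpradnv.errors import (BoundaryError, FormatError, ManifestError,
                            ReferenceMismatchError, SamplingError)
from mpradnv.simulate import SimConfig, simulate_epigenome, simulate_variants


def _genome(n=600, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join("ACGT"[b] for b in rng.integers(0, 4, n))}


def _variant(genome, pos, ref_len=1, alt="A", vid="v1"):
    g = genome["chr1"]
    return {"variant_id": vid, "chrom": "chr1", "pos": pos,
            "ref_allele": g[pos - 1:pos - 1 + ref_len], "alt_allele": alt}


def test_snv_pair():
    genome = _genome()
    g = genome["chr1"]
    ref_base = g[149]
    alt_base = "A" if ref_base != "A" else "C"
    v = _variant(genome, 150, 1, alt_base)
    pair = design.build_crs_pair(v, genome)
    assert len(pair.ref_seq) == 200 and len(pair.alt_seq) == 200
    assert pair.ref_seq == g[50:250]
    assert pair.ref_seq[99] == ref_base
    assert pair.alt_seq[99] == alt_base
    assert pair.alt_seq[:99] == pair.ref_seq[:99]
    assert pair.alt_seq[100:] == pair.ref_seq[100:]


def test_deletion_pair():
    genome = _genome()
    g = genome["chr1"]
    v = _variant(genome, 150, ref_len=3, alt=g[149], vid="vdel")
    pair = design.build_crs_pair(v, genome)
    assert len(pair.ref_seq) == 200
    assert len(pair.alt_seq) == 198
    assert pair.ref_seq == g[50:250]
    assert pair.alt_seq == g[50:150] + g[152:250]


def test_insertion_pair():
    genome = _genome()
    g = genome["chr1"]
    v = _variant(genome, 150, ref_len=1, alt=g[149] + "GG", vid="vins")
    pair = design.build_crs_pair(v, genome)
    # the alternate (insertion-carrying) sequence is the 200-nt member
    assert len(pair.alt_seq) == 200
    assert len(pair.ref_seq) == 198
    assert pair.alt_seq[99:102] == g[149] + "GG"
    assert pair.alt_seq == g[50:150] + "GG" + g[150:248]
    assert pair.ref_seq == g[50:248]


def test_reference_mismatch_error():
    genome = _genome()
    g = genome["chr1"]
    wrong = "A" if g[149] != "A" else "C"
    v = {"variant_id": "vx", "chrom": "chr1", "pos": 150,
         "ref_allele": wrong, "alt_allele": "G"}
    with pytest.raises(ReferenceMismatchError) as exc:
        design.build_crs_pair(v, genome)
    assert wrong in str(exc.value) and g[149] in str(exc.value)


def test_boundary_error():
    genome = _genome()
    v = _variant(genome, 50)  # window would start at -50
    with pytest.raises(BoundaryError):
        design.build_crs_pair(v, genome)
    v2 = _variant(genome, 580)  # window would end past the chromosome
    with pytest.raises(BoundaryError):
        design.build_crs_pair(v2, genome)


def test_bad_allele_format():
    genome = _genome()
    v = {"variant_id": "vb", "chrom": "chr1", "pos": 150,
         "ref_allele": genome["chr1"][149], "alt_allele": "NX"}
    with pytest.raises(FormatError):
        design.build_crs_pair(v, genome)


def test_variant_recovery_over_simulated_variants():
    cfg = SimConfig(n_variants=40, seed=12)
    sim = simulate_variants(cfg)
    pairs = design.build_crs_pairs(sim.variants, sim.genome)
    for pair, (_, v) in zip(pairs, sim.variants.iterrows()):
        ref_a, alt_a = v["ref_allele"], v["alt_allele"]
        if len(alt_a) > len(ref_a):  # insertion: alt is the 200-nt member
            assert pair.alt_seq[99:99 + len(alt_a)] == alt_a
            assert len(pair.alt_seq) == 200
        else:
            assert pair.ref_seq[99:99 + len(ref_a)] == ref_a
            assert len(pair.ref_seq) == 200
            assert pair.alt_seq[99:99 + len(alt_a)] == alt_a
        # substituting back recovers the partner sequence
        off = pair.variant_offset
        assert (pair.ref_seq[:off] + alt_a + pair.ref_seq[off + len(ref_a):]
                == pair.alt_seq)


def _pairs_and_origins(n=30, seed=5):
    cfg = SimConfig(n_variants=n, seed=seed)
    sim = simulate_variants(cfg)
    pairs = design.build_crs_pairs(sim.variants, sim.genome)
    origins = dict(zip(sim.variants["variant_id"], sim.variants["origin"]))
    return pairs, origins


def test_scramble_preserves_multiset_and_composition():
    pairs, origins = _pairs_and_origins()
    negs = design.scramble_negatives(pairs, origins, 4, 5, seed=1)
    assert len(negs) == 9
    assert sum(1 for c in negs if c.source_origin == "case") == 4
    assert sum(1 for c in negs if c.source_origin == "control") == 5
    src = {p.variant_id: p.ref_seq for p in pairs}
    for c in negs:
        assert sorted(c.seq) == sorted(src[c.source_variant_id])
        assert c.seq != src[c.source_variant_id] or len(set(c.seq)) == 1


def test_scramble_homopolymer_fixed_point():
    pair = design.CRSPair("vh", "A" * 200, "A" * 200, ("chr1", 0, 200))
    negs = design.scramble_negatives([pair], {"vh": "case"}, 1, 0, seed=0)
    assert negs[0].seq == "A" * 200


def test_scramble_deterministic_and_insufficient_pool():
    pairs, origins = _pairs_and_origins()
    a = design.scramble_negatives(pairs, origins, 3, 3, seed=7)
    b = design.scramble_negatives(pairs, origins, 3, 3, seed=7)
    assert [c.seq for c in a] == [c.seq for c in b]
    with pytest.raises(SamplingError):
        design.scramble_negatives(pairs, origins, 10 ** 6, 0, seed=0)


# ---------------------------------------------------------------------------
# positive controls
# ---------------------------------------------------------------------------

def _oracle_positive(h3, atac, tss, n, top_h3k27ac=5000, min_dist=150,
                     max_dist=2000, min_expr=2.0):
    """Independent brute-force reimplementation of the five-step filter."""
    ranked = sorted(h3.to_dict("records"),
                    key=lambda r: (-r["score"], r["chrom"], r["start"]))
    rows = []
    for h in ranked[:top_h3k27ac]:
        inside = [a for a in atac.to_dict("records")
                  if a["chrom"] == h["chrom"] and a["start"] >= h["start"]
                  and a["end"] <= h["end"]]
        if not inside:
            continue
        best = sorted(inside, key=lambda r: (-r["score"], r["chrom"], r["start"]))[0]
        mid = (best["start"] + best["end"]) // 2
        keep = False
        for _, t in tss.iterrows():
            if t["chrom"] != best["chrom"]:
                continue
            d = abs(t["pos"] - mid)
            if min_dist <= d <= max_dist and t["expression"] >= min_expr:
                keep = True
        if keep:
            rows.append((best["chrom"], best["start"], best["end"],
                         best["score"], mid))
    seen, out = set(), []
    for r in sorted(rows, key=lambda r: (-r[3], r[0], r[1])):
        if r[:3] not in seen:
            seen.add(r[:3])
            out.append(r)
    return out[:n]


def test_positive_controls_match_bruteforce_oracle():
    cfg = SimConfig(n_variants=30, n_pos_controls=8, seed=19)
    sim = simulate_variants(cfg)
    epi = simulate_epigenome(sim.genome, cfg, n_peaks=20)
    controls, table = design.select_positive_controls(
        epi.h3k27ac, epi.atac, epi.tss, sim.genome, n=8)
    oracle = _oracle_positive(epi.h3k27ac, epi.atac, epi.tss, 8)
    got = list(table[["chrom", "start", "end", "score", "mid"]]
               .itertuples(index=False, name=None))
    assert got == oracle
    for c, row in zip(controls, oracle):
        mid = row[4]
        assert c.seq == sim.genome["chr1"][mid - 100:mid + 100]
        assert len(c.seq) == 200


def test_positive_controls_row_order_invariance():
    cfg = SimConfig(n_variants=30, n_pos_controls=8, seed=19)
    sim = simulate_variants(cfg)
    epi = simulate_epigenome(sim.genome, cfg, n_peaks=20)
    _, table1 = design.select_positive_controls(
        epi.h3k27ac, epi.atac, epi.tss, sim.genome, n=8)
    rng = np.random.default_rng(0)
    h3s = epi.h3k27ac.sample(frac=1, random_state=3).reset_index(drop=True)
    atacs = epi.atac.sample(frac=1, random_state=4).reset_index(drop=True)
    _, table2 = design.select_positive_controls(
        h3s, atacs, epi.tss, sim.genome, n=8)
    pd.testing.assert_frame_equal(table1, table2)


def test_positive_control_boundaries_inclusive():
    genome = {"chr1": "ACGT" * 2000}
    h3 = pd.DataFrame({"chrom": "chr1", "start": [1000], "end": [2000],
                       "score": [50.0]})
    atac = pd.DataFrame({"chrom": "chr1", "start": [1400], "end": [1600],
                         "score": [10.0]})
    mid = 1500

    def run(dist, expr):
        tss = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"],
                            "pos": [mid + dist], "expression": [expr]})
        _, table = design.select_positive_controls(h3, atac, tss, genome, n=5)
        return len(table)

    assert run(150, 2.0) == 1       # both boundaries inclusive
    assert run(2000, 2.0) == 1
    assert run(149, 2.0) == 0
    assert run(2001, 2.0) == 0
    assert run(500, 1.999) == 0


def test_emit_library_roundtrip_and_duplicates(tmp_path):
    pairs, origins = _pairs_and_origins(n=6, seed=2)
    negs = design.scramble_negatives(pairs, origins, 1, 1, seed=0)
    fa = tmp_path / "lib.fa"
    man = tmp_path / "manifest.tsv"
    manifest = design.emit_library(pairs, negs, fa, man)
    assert len(manifest) == 2 * 6 + 2
    assert manifest["role"].value_counts().to_dict() == {
        "reference": 6, "alternate": 6, "negative": 2}
    lib = design.read_library_fasta(fa)
    assert len(lib) == 14
    for p in pairs:
        assert lib[f"{p.variant_id}_ref"] == p.ref_seq
        assert lib[f"{p.variant_id}_alt"] == p.alt_seq
    with pytest.raises(ManifestError):
        design.emit_library(pairs + [pairs[0]], negs, tmp_path / "x.fa")
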