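import numpy as np
import pandas as pd
import pytest

from mpradnv.activity import TranscriptionRateModel
from mpradnv.simulate import SimConfig, simulate_counts, simulate_variants


@pytest.fixture(scope="session")
def small_sim():
    """60 variant pairs at default barcode density, with controls."""
    cfg = SimConfig(n_variants=60, n_pos_controls=25, n_neg_controls=25, seed=3)
    sim = simulate_variants(cfg)
    counts = simulate_counts(sim.truth, cfg)
    return cfg, sim, counts


@pytest.fixture(scope="session")
def small_results(small_sim):
    cfg, sim, counts = small_sim
    manifest_rows = []
    for vid in sim.truth["variant_id"]:
        manifest_rows.append({"sequence_id": f"{vid}_ref", "role": "reference",
                              "variant_id": vid})
        manifest_rows.append({"sequence_id": f"{vid}_alt", "role": "alternate",
                              "variant_id": vid})
    for i in range(cfg.n_pos_controls):
        manifest_rows.append({"sequence_id": f"pos_{i:03d}", "role": "positive",
                              "variant_id": ""})
    for i in range(cfg.n_neg_controls):
        manifest_rows.append({"sequence_id": f"neg_{i:03d}", "role": "negative",
                              "variant_id": ""})
    manifest = pd.DataFrame(manifest_rows)
    model = TranscriptionRateModel(counts.tables, manifest)
    return model.fit()


def exact_ratio_tables(alpha=3.0, n_barcodes=40, n_reps=3):
    """Count tables where rna = alpha * dna exactly, identical across reps."""
    rng = np.random.default_rng(17)
    dna = rng.integers(5, 60, n_barcodes)
    tables = {}
    for t in range(n_reps):
        tables[f"rep{t + 1}"] = pd.DataFrame({
            "barcode": [f"B{i:03d}" for i in range(n_barcodes)],
            "sequence_id": "seqX",
            "dna_count": dna,
            "rna_count": (alpha * dna).astype(int),
        })
    return tables
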