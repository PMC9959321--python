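"""Transcription-rate ("alpha") estimation and activity classification.

The estimator mirrors the nested-GLM idea behind MPRA rate quantification:
latent construct abundances are the gamma-likelihood maximisers of the
normalised DNA counts (with one observation per barcode this is the
normalised count itself), and each sequence's per-replicate alpha maximises a
negative-binomial likelihood of the RNA counts with mean
alpha * d_hat_b * rna_size_factor.  The NB dispersion is shared across a
sequence's barcodes and profiled.  Library size factors are median-of-ratios
across replicates, constrained to multiply to one within each library type,
so alpha's absolute scale is set by the data's overall RNA-to-DNA ratio.
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from ._nbglm import fit_nb_glm
from ._util import bh_adjust
from .errors import DegenerateNullError, NormalizationError, SamplingError

logger = logging.getLogger(__name__)

MIN_NEGATIVES = 20  # minimum usable empirical null


def _totals(tables: Mapping[str, pd.DataFrame], column: str) -> pd.DataFrame:
    per_rep = {rep: t.groupby("sequence_id")[column].sum()
               for rep, t in tables.items()}
    return pd.DataFrame(per_rep)


def _median_of_ratios(mat: pd.DataFrame) -> np.ndarray:
    mat = mat.dropna()
    mat = mat[(mat > 0).all(axis=1)]
    if mat.empty:
        raise NormalizationError("no sequence has positive counts in every replicate")
    logk = np.log(mat.to_numpy(dtype=float))
    ratios = logk - logk.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(ratios, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def estimate_size_factors(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Median-of-ratios DNA and RNA size factors, one pair per replicate.

    Factors are normalised to geometric mean one within each library type
    (the scale-identifiability convention).
    """
    if not tables:
        raise NormalizationError("no count tables supplied")
    for rep, t in tables.items():
        if t.empty or (t[["dna_count", "rna_count"]].to_numpy().sum() == 0):
            raise NormalizationError(f"replicate {rep!r} has no positive counts")
    reps = list(tables)
    dna = _median_of_ratios(_totals(tables, "dna_count"))
    rna = _median_of_ratios(_totals(tables, "rna_count"))
    return pd.DataFrame({"dna": dna, "rna": rna}, index=pd.Index(reps, name="replicate"))


class TranscriptionRateModel:
    """Per-sequence transcription-rate model over barcode count tables.

    Parameters
    ----------
    tables
        Mapping replicate label -> BarcodeTable with columns
        (barcode, sequence_id, dna_count, rna_count).
    manifest
        Optional library manifest (sequence_id, role, variant_id); used to
        locate negative controls and reference/alternate pairs.
    """

    def __init__(self, tables: Mapping[str, pd.DataFrame],
                 manifest: Optional[pd.DataFrame] = None):
        self.tables = dict(tables)
        self.replicates = list(self.tables)
        self.manifest = manifest

    @classmethod
    def from_files(cls, count_paths: Mapping[str, str], manifest_path=None):
        tables = {rep: pd.read_csv(p, sep="\t") for rep, p in count_paths.items()}
        manifest = pd.read_csv(manifest_path, sep="\t") if manifest_path else None
        return cls(tables, manifest)

    # -- data assembly -----------------------------------------------------
    def _long(self, size_factors: pd.DataFrame) -> pd.DataFrame:
        frames = []
        for t, rep in enumerate(self.replicates):
            df = self.tables[rep]
            sf_dna = size_factors.loc[rep, "dna"]
            sf_rna = size_factors.loc[rep, "rna"]
            frames.append(pd.DataFrame({
                "sequence_id": df["sequence_id"].to_numpy(),
                "rep_idx": t,
                "y": df["rna_count"].to_numpy(dtype=float),
                # latent construct estimate: gamma MLE with one observation
                # per barcode is the normalised DNA count
                "offset": df["dna_count"].to_numpy(dtype=float) / sf_dna * sf_rna,
            }))
        return pd.concat(frames, ignore_index=True)

    def fit(self, size_factors: Optional[pd.DataFrame] = None) -> "TranscriptionRateResults":
        if size_factors is None:
            size_factors = estimate_size_factors(self.tables)
        long = self._long(size_factors)
        n_reps = len(self.replicates)

        rows = {}
        seq_data = {}
        for sid, grp in long.groupby("sequence_id", sort=True):
            y = grp["y"].to_numpy()
            o = grp["offset"].to_numpy()
            rep_idx = grp["rep_idx"].to_numpy()
            present = np.unique(rep_idx)
            X = (rep_idx[:, None] == present[None, :]).astype(float)
            fit = fit_nb_glm(y, np.log(o), X)
            alphas = np.full(n_reps, np.nan)
            alphas[present] = np.exp(fit.theta)
            rows[sid] = (*alphas, fit.dispersion, len(y), fit.converged)
            seq_data[sid] = (y, o, rep_idx)
            if not fit.converged:
                logger.warning("alpha fit did not converge for %s", sid)

        alpha_cols = [f"alpha_{rep}" for rep in self.replicates]
        frame = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=[*alpha_cols, "dispersion", "n_observations", "converged"])
        frame.index.name = "sequence_id"
        n_bc = (pd.concat(self.tables.values())
                .groupby("sequence_id")["barcode"].nunique())
        frame["n_barcodes"] = n_bc.reindex(frame.index).fillna(0).astype(int)
        frame["alpha_mean"] = frame[alpha_cols].mean(axis=1)
        return TranscriptionRateResults(self, frame, size_factors, seq_data)


class TranscriptionRateResults:
    """Fitted per-sequence, per-replicate transcription rates."""

    def __init__(self, model, alphas: pd.DataFrame, size_factors: pd.DataFrame,
                 seq_data: Dict[str, tuple]):
        self.model = model
        self.alphas = alphas
        self.size_factors = size_factors
        self._seq_data = seq_data

    @property
    def alpha_columns(self):
        return [f"alpha_{rep}" for rep in self.model.replicates]

    def _negative_ids(self, negatives=None):
        if negatives is not None:
            return set(negatives)
        if self.model.manifest is None:
            raise SamplingError("no negative-control ids supplied and no manifest")
        m = self.model.manifest
        return set(m.loc[m["role"] == "negative", "sequence_id"])

    def classify_active(self, negatives=None, fdr: float = 0.05) -> pd.DataFrame:
        """MAD-normalise alphas against the scrambled-negative null and call
        active sequences by empirical upper-tail p-values with BH FDR."""
        neg_ids = self._negative_ids(negatives)
        neg_ids &= set(self.alphas.index)
        if len(neg_ids) < MIN_NEGATIVES:
            raise SamplingError(
                f"need at least {MIN_NEGATIVES} negative controls for an "
                f"empirical null, got {len(neg_ids)}")
        neg = self.alphas.loc[sorted(neg_ids), "alpha_mean"].to_numpy()
        med = float(np.median(neg))
        mad = float(np.median(np.abs(neg - med)))
        if mad == 0:
            raise DegenerateNullError("negative-control alpha MAD is zero")

        tested = self.alphas.index[~self.alphas.index.isin(neg_ids)]
        a = self.alphas.loc[tested, "alpha_mean"].to_numpy()
        mad_z = (a - med) / (1.4826 * mad)
        # add-one empirical upper-tail p-value
        p = (1.0 + (neg[None, :] >= a[:, None]).sum(axis=1)) / (1.0 + len(neg))
        out = pd.DataFrame({
            "sequence_id": tested,
            "alpha": a,
            "alpha_mad_z": mad_z,
            "empirical_p": p,
            "fdr": bh_adjust(p),
        })
        out["active"] = out["fdr"] <= fdr
        return out

    def test_allelic_effects(self, pairs: Optional[pd.DataFrame] = None,
                             **kwargs):
        from .differential import AllelicEffectResults
        return AllelicEffectResults.from_results(self, pairs, **kwargs)

    def summary(self) -> str:
        lines = ["Transcription-rate model",
                 f"  replicates: {', '.join(self.model.replicates)}",
                 f"  sequences fitted: {len(self.alphas)}",
                 f"  median alpha: {self.alphas['alpha_mean'].median():.4g}",
                 f"  non-converged fits: {int((~self.alphas['converged']).sum())}"]
        if self.model.manifest is not None:
            roles = self.model.manifest.set_index("sequence_id")["role"]
            med = (self.alphas["alpha_mean"]
                   .groupby(roles.reindex(self.alphas.index)).median())
            for role, v in med.items():
                lines.append(f"  median alpha ({role}): {v:.4g}")
        return "\n".join(lines)
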