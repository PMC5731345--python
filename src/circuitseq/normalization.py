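"""Between-sample normalization and gene-level expression summaries.

RNA-seq measures fractional, not absolute, abundance, so samples are put
on a common scale with trimmed-mean-of-M-values (TMM) factors before
profiles or FPKM values are compared.  The TMM implementation follows the
original description (Robinson & Oshlack 2010, Genome Biology) and the
conventions of its reference implementation: per-gene log-ratios (M) and
log-intensities (A) against a reference sample, double trimming (30% on M,
5% on A), inverse-variance weighting, and centering of the factors to
geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneCountTable, Part, TranscriptionProfile

__all__ = [
    "NormalizationFactors",
    "ExpressionTable",
    "tmm_factors",
    "fpkm",
    "gene_expression_au",
    "normalize_profiles",
]


@dataclass
class NormalizationFactors:
    factors: pd.Series              # sample -> TMM factor, geometric mean 1
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_mean = np.log(self.factors).mean()
        if abs(log_mean) > 1e-6:
            raise ValueError("TMM factors must have geometric mean 1")

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])

    def to_tsv(self, path) -> None:
        frame = self.factors.rename("tmm_factor").to_frame()
        frame["reference_sample"] = self.reference_sample
        frame.to_csv(path, sep="\t", index_label="sample")


@dataclass
class ExpressionTable:
    """Gene x sample expression; FPKM and/or profile-height (au) units."""

    fpkm: pd.DataFrame | None = None
    au: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for frame in (self.fpkm, self.au):
            if frame is not None and (frame.values < 0).any():
                raise ValueError("expression values must be non-negative")


def _pairwise_tmm(obs: np.ndarray, ref: np.ndarray,
                  n_obs: float, n_ref: float,
                  trim_logratio: float, trim_intensity: float) -> float:
    """log2 TMM factor of the observed sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    M = np.log2((obs / n_obs) / (ref / n_ref))
    A = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic variance of M by the delta method; weights are 1/variance
    variance = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.allclose(M, M[0]):
        # constant log-ratio: trimming is a no-op, avoid rank edge cases
        return float(M[0])
    n = M.size
    lo_m = np.floor(n * trim_logratio) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_intensity) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    weights = 1.0 / variance[keep]
    return float(np.sum(weights * M[keep]) / np.sum(weights))


def tmm_factors(counts: GeneCountTable,
                trim_logratio: float = 0.30,
                trim_intensity: float = 0.05) -> NormalizationFactors:
    """TMM scale factor per sample, centered to geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions across samples.  Genes with a
    zero count in either member of a pair are excluded from that pair's
    M/A values.
    """
    matrix = counts.counts
    totals = counts.total_fragments
    for sample in matrix.columns:
        if matrix[sample].sum() == 0:
            raise ValueError(f"sample {sample} has all-zero counts")
    if matrix.shape[1] == 1:
        only = matrix.columns[0]
        return NormalizationFactors(pd.Series({only: 1.0}), reference_sample=only)
    f75 = {}
    for sample in matrix.columns:
        f75[sample] = np.quantile(matrix[sample] / totals[sample], 0.75)
    f75 = pd.Series(f75)
    reference = (f75 - f75.mean()).abs().idxmin()
    log2_factors = {}
    ref = matrix[reference].to_numpy()
    n_ref = float(totals[reference])
    for sample in matrix.columns:
        if sample == reference:
            log2_factors[sample] = 0.0
            continue
        log2_factors[sample] = _pairwise_tmm(
            matrix[sample].to_numpy(), ref, float(totals[sample]), n_ref,
            trim_logratio, trim_intensity)
    factors = pd.Series({s: 2.0 ** f for s, f in log2_factors.items()})
    factors /= np.exp(np.log(factors).mean())
    return NormalizationFactors(factors, reference_sample=reference)


def fpkm(counts: GeneCountTable,
         factors: NormalizationFactors | None = None) -> ExpressionTable:
    """Fragments per kilobase of gene per million mapped fragments.

    FPKM(g, s) = count / (gene length in kb * effective library size in
    millions), with effective library size = total mapped fragments *
    the sample's TMM factor.
    """
    matrix = counts.counts
    length_kb = counts.gene_lengths / 1000.0
    if (length_kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    values = pd.DataFrame(index=matrix.index, columns=matrix.columns,
                          dtype=float)
    for sample in matrix.columns:
        factor = 1.0 if factors is None else factors[sample]
        effective = counts.total_fragments[sample] * factor / 1e6
        if effective <= 0:
            raise ValueError(f"sample {sample}: zero effective library size")
        values[sample] = matrix[sample] / (length_kb.loc[matrix.index] * effective)
    return ExpressionTable(fpkm=values)


def gene_expression_au(profile: TranscriptionProfile, gene: Part) -> float:
    """Gene expression in profile units: mean height over the gene body."""
    if gene.length <= 0:
        raise ValueError(f"gene {gene.name} has zero length")
    if gene.start < 0 or gene.end > len(profile):
        raise ValueError(f"gene {gene.name} outside profile bounds")
    return profile.mean_over(gene.start, gene.end)


def normalize_profiles(profile: TranscriptionProfile,
                       factor: float,
                       total_fragments: float) -> TranscriptionProfile:
    """Scale a raw count profile by the effective library size.

    Every value is divided by (factor * total_fragments / 1e6), the same
    effective-library-size convention FPKM uses, making profiles
    comparable across samples.
    """
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    if total_fragments <= 0:
        raise ValueError("total fragment count must be positive")
    scale = 1.0 / (factor * total_fragments / 1e6)
    return profile.scaled(scale)
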