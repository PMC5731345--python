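"""Transcript-end coverage bias correction.

Counting fragments that map exclusively within a transcription unit
depresses coverage near the unit ends: a position x nucleotides from an
end can only be covered by fragment placements that fit between x and the
boundary.  The expected shape of that curvature depends only on the
fragment-length distribution, so it can be reconstructed by Monte Carlo:
fragments with lengths drawn from the empirical distribution are placed
uniformly at random inside a hypothetical 2,000-nt unit, the resulting
pile-up T(x) is max-normalized over its first 500 nt to give a correction
factor profile C(x), and observed unit profiles are divided by C at both
ends.  The correction knows nothing about sequence, so the same C serves
the 5' and 3' ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import (SENSE, CircuitAnnotation, FragmentAlignment,
                 FragmentLengthDistribution, PartType, TranscriptionProfile,
                 build_strand_profiles)

__all__ = [
    "HypotheticalProfile",
    "CorrectionFactorProfile",
    "analytic_end_coverage",
    "hypothetical_profile",
    "correction_factor",
    "apply_correction",
    "transcription_units",
    "correct_circuit_profile",
]

#: Window (nt) at each transcript end inside which curvature is corrected.
END_WINDOW = 500

#: Length of the hypothetical transcription unit used for the Monte Carlo.
DEFAULT_UNIT_LENGTH = 2000

DEFAULT_DRAWS = 1_000_000
DEFAULT_SEED = 20170901


@dataclass
class HypotheticalProfile:
    """Monte-Carlo pile-up T(x) over the hypothetical transcription unit."""

    values: np.ndarray
    draws: int
    seed: int
    unit_length: int


@dataclass
class CorrectionFactorProfile:
    """C(x) for x = 1..500 (1-based distance from a transcript end)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != END_WINDOW:
            raise ValueError(f"expected {END_WINDOW} values, got {len(self.values)}")
        if not np.isclose(self.values.max(), 1.0):
            raise ValueError("correction factors must be max-normalized to 1")
        if np.any(self.values <= 0):
            raise ValueError("correction factors must be positive")

    def at(self, distance: int) -> float:
        """C at a 1-based distance from the transcript end."""
        if not 1 <= distance <= END_WINDOW:
            raise ValueError(f"distance {distance} outside 1..{END_WINDOW}")
        return float(self.values[distance - 1])


def analytic_end_coverage(x: int, L: int, N: int) -> int:
    """Number of valid placements of an L-nt fragment covering position x
    (1-based) in an N-nt unit: min(x, L, N-x+1, N-L+1).

    Serves as the closed-form oracle for the Monte-Carlo pile-up.
    """
    if not 1 <= x <= N:
        raise ValueError(f"x={x} outside 1..{N}")
    if not 1 <= L <= N:
        raise ValueError(f"L={L} outside 1..{N}")
    return min(x, L, N - x + 1, N - L + 1)


def expected_end_coverage(fld: FragmentLengthDistribution,
                          unit_length: int = DEFAULT_UNIT_LENGTH) -> np.ndarray:
    """Mixture over the FLD of the analytic placement counts, normalized to
    probabilities of covering each position per draw."""
    x = np.arange(1, unit_length + 1)
    expected = np.zeros(unit_length)
    for L, p in zip(fld.lengths, fld.probabilities):
        counts = np.minimum.reduce([x, np.full_like(x, L),
                                    unit_length - x + 1,
                                    np.full_like(x, unit_length - L + 1)])
        expected += p * counts / (unit_length - L + 1)
    return expected


def hypothetical_profile(fld: FragmentLengthDistribution,
                         unit_length: int = DEFAULT_UNIT_LENGTH,
                         draws: int = DEFAULT_DRAWS,
                         seed: int = DEFAULT_SEED) -> HypotheticalProfile:
    """Monte-Carlo pile-up of ``draws`` fragments inside the hypothetical unit.

    For each draw a length L is sampled from the FLD and a start uniform
    over the valid starts; T(x) counts covering fragments.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if fld.max_length > unit_length:
        raise ValueError(f"fragment length {fld.max_length} exceeds the "
                         f"{unit_length}-nt hypothetical unit")
    rng = np.random.default_rng(seed)
    lengths = fld.sample(draws, rng)
    diff = np.zeros(unit_length + 1)
    for L in np.unique(lengths):
        n = int((lengths == L).sum())
        starts = rng.integers(0, unit_length - L + 1, size=n)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, starts + L, -1.0)
    values = np.cumsum(diff[:-1])
    return HypotheticalProfile(values=values, draws=draws, seed=seed,
                               unit_length=unit_length)


def correction_factor(hyp: HypotheticalProfile) -> CorrectionFactorProfile:
    """Extract the first 500 nt of T(x) and normalize by its maximum."""
    region = hyp.values[:END_WINDOW]
    peak = region.max()
    if peak <= 0:
        raise ValueError("hypothetical profile is zero over the end window; "
                         "increase the number of Monte-Carlo draws")
    return CorrectionFactorProfile(values=region / peak)


def apply_correction(profile: TranscriptionProfile,
                     unit: tuple[int, int],
                     C: CorrectionFactorProfile) -> TranscriptionProfile:
    """Divide P(x) by C(x_n) over the first/last 500 nt of the unit.

    x_n is the 1-based distance to the *nearest* unit end; positions
    farther than 500 nt from both ends are returned bit-identical.  The
    profile must have been built from fragments mapping exclusively within
    the unit boundaries.
    """
    start, end = unit
    if not (0 <= start < end <= len(profile)):
        raise ValueError(f"unit [{start}, {end}) outside profile bounds")
    values = profile.values.copy()
    positions = np.arange(start, end)
    dist5 = positions - start + 1
    dist3 = end - positions
    nearest = np.minimum(dist5, dist3)
    in_window = nearest <= END_WINDOW
    factors = C.values[nearest[in_window] - 1]
    if np.any(factors <= 0):
        raise ValueError("zero correction factor; insufficient Monte-Carlo depth")
    values[positions[in_window]] = values[positions[in_window]] / factors
    return TranscriptionProfile(profile.reference_id, profile.strand_class,
                                values, profile.sample_id)


def transcription_units(annotation: CircuitAnnotation) -> list[tuple[int, int]]:
    """Annotated transcript intervals internal to the circuit.

    Each unit runs from where its transcript's observable 5' end lies — the
    cut site of an insulating ribozyme, or the promoter TSS when there is
    no ribozyme — to the end of the next downstream terminator.  These are
    the only regions the end correction is applied to; read-through
    between units, antisense and host transcription stay uncorrected.
    """
    sense_parts = [p for p in annotation.parts if p.strand == "+"]
    terminator_ends = sorted(p.end for p in sense_parts
                             if p.part_type is PartType.TERMINATOR)
    from .prediction import _assign_ribozymes

    ribozyme_for = _assign_ribozymes(sense_parts)
    starts: set[int] = set()
    for part in sense_parts:
        if part.part_type is PartType.PROMOTER:
            ribozyme = ribozyme_for.get(part.name)
            if ribozyme is not None:
                cut = ribozyme.cut_site
                starts.add(cut if cut is not None else ribozyme.end)
            elif part.tss is not None:
                starts.add(part.tss)
    units = []
    for start in sorted(starts):
        end = next((e for e in terminator_ends if e > start),
                   annotation.reference_length)
        if end > start:
            units.append((start, min(end, annotation.reference_length)))
    # tandem promoters share a unit; drop duplicates, keep sorted order
    return sorted(set(units))


def correct_circuit_profile(fragments: Sequence[FragmentAlignment],
                            annotation: CircuitAnnotation,
                            C: CorrectionFactorProfile,
                            strand_class: str = SENSE,
                            units: Sequence[tuple[int, int]] | None = None,
                            sample_id: str | None = None,
                            ) -> TranscriptionProfile:
    """End-corrected circuit profile assembled unit by unit.

    For each transcription unit, a local profile is rebuilt from the
    fragments wholly contained in the unit, end-corrected, and spliced into
    the output track.  Regions outside every unit keep their raw pile-up
    (read-through and antisense regions are deliberately left uncorrected).
    """
    length = annotation.reference_length
    if units is None:
        units = transcription_units(annotation)
    strand_fragments = [f for f in fragments if f.strand_class == strand_class]
    sense, antisense = build_strand_profiles(strand_fragments, length,
                                             annotation.reference_id, sample_id)
    raw = sense if strand_class == SENSE else antisense
    out = raw.values.copy()
    for start, end in units:
        local = [f for f in strand_fragments
                 if f.start >= start and f.end <= end]
        if not local:
            continue
        local_sense, local_anti = build_strand_profiles(
            local, length, annotation.reference_id, sample_id)
        local_profile = local_sense if strand_class == SENSE else local_anti
        corrected = apply_correction(local_profile, (start, end), C)
        out[start:end] = corrected.values[start:end]
    return TranscriptionProfile(annotation.reference_id, strand_class, out,
                                sample_id)
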