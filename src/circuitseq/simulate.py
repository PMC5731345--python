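"""Forward simulator for circuit RNA-seq experiments.

Generates the data the characterization pipeline consumes, from known
part parameters: steady-state expected profiles M(x) = J(x)/gamma traced
along the circuit with the same rules the prediction module uses, and
strand-specific fragment sets sampled from those profiles with a chosen
fragment-length distribution.  Fragments are placed uniformly over the
valid starts inside plateau-level transcription units, which reproduces
the end curvature the correction model expects.  Noise enters in two
places only: multiplicative lognormal jitter on promoter activities, and
the fragment sampling itself — exactly the statistical structure the
part-quantification models assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import (ANTISENSE, SENSE, CircuitAnnotation, FragmentAlignment,
                 FragmentLengthDistribution, PartType, TranscriptionProfile)
from .prediction import trace_profile

__all__ = [
    "AntisensePromoter",
    "GroundTruth",
    "SyntheticExperiment",
    "default_fld",
    "simulate_expected_profile",
    "transcript_species",
    "antisense_species",
    "sample_fragments",
    "simulate_experiment",
]


@dataclass(frozen=True)
class AntisensePromoter:
    """A reverse promoter internal to the circuit: transcribes from its
    TSS toward the reference start (down to ``stop``)."""

    name: str
    tss: int                       # 0-based; transcription covers [stop, tss]
    activity: float                # delta J in au/s
    stop: int = 0

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("antisense promoter activity must be >= 0")
        if not 0 <= self.stop <= self.tss:
            raise ValueError("require 0 <= stop <= tss")


@dataclass
class GroundTruth:
    """Known part parameters a synthetic experiment is generated from."""

    promoter_activities: Mapping[str, Mapping[str, float]]  # state -> name -> au/s
    terminator_ts: Mapping[str, float] = field(default_factory=dict)
    ribozyme_pc: Mapping[str, float] = field(default_factory=dict)
    antisense_promoters: Sequence[AntisensePromoter] = field(default_factory=tuple)
    gamma: float = 0.0067
    read_through_in: float = 0.0       # au/s entering the circuit 5' end
    noise_sigma: float = 0.0           # lognormal sigma on activities

    def __post_init__(self) -> None:
        for state, activities in self.promoter_activities.items():
            for name, value in activities.items():
                if value < 0:
                    raise ValueError(f"{state}/{name}: activity must be >= 0")
        for name, ts in self.terminator_ts.items():
            if ts < 1:
                raise ValueError(f"terminator {name}: Ts must be >= 1")
        for name, pc in self.ribozyme_pc.items():
            if not 0 <= pc <= 1:
                raise ValueError(f"ribozyme {name}: p_c must be in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class SyntheticExperiment:
    """Bundle of generated fragments, expected profiles and the truth used."""

    annotation: CircuitAnnotation
    states: list[str]
    fragments: dict                 # state -> list[FragmentAlignment]
    true_profiles: dict             # state -> (sense, antisense) in au
    realized_activities: dict       # state -> name -> au/s after noise
    truth: GroundTruth
    fld: FragmentLengthDistribution
    depth: int
    seed: int

    def true_mass(self, state: str) -> float:
        """Total expected profile mass (sum of au over both strands); the
        anchor for calibrating recovered count profiles onto the au scale."""
        sense, antisense = self.true_profiles[state]
        return float(sense.values.sum() + antisense.values.sum())


def default_fld(mean: int = 150, sd: int = 30,
                lo: int = 60, hi: int = 300) -> FragmentLengthDistribution:
    """Discretized truncated-normal fragment-length distribution.

    Defaults emulate a typical size-selected bacterial RNA-seq library
    (~150 nt inserts).
    """
    lengths = np.arange(lo, hi + 1)
    weights = np.exp(-0.5 * ((lengths - mean) / sd) ** 2)
    return FragmentLengthDistribution(lengths, weights / weights.sum())


def simulate_expected_profile(annotation: CircuitAnnotation,
                              truth: GroundTruth,
                              state: str,
                              activities: Mapping[str, float] | None = None,
                              ) -> tuple[TranscriptionProfile, TranscriptionProfile]:
    """Deterministic expected (sense, antisense) profiles in au for a state.

    M(x) = J(x)/gamma with fluxes traced 5'->3' using the prediction-module
    rules; antisense promoters are traced 3'->5' on the minus strand.
    """
    if activities is None:
        if state not in truth.promoter_activities:
            raise ValueError(f"state {state!r} absent from the ground truth")
        activities = truth.promoter_activities[state]
    strengths_au = {name: dj / truth.gamma for name, dj in activities.items()}
    sense_values = trace_profile(
        annotation, strengths_au, truth.terminator_ts, truth.ribozyme_pc,
        read_through_in=truth.read_through_in / truth.gamma)
    anti_values = np.zeros(annotation.reference_length)
    for promoter in truth.antisense_promoters:
        if promoter.tss >= annotation.reference_length:
            raise ValueError(f"antisense promoter {promoter.name} TSS outside "
                             "the reference")
        anti_values[promoter.stop:promoter.tss + 1] += \
            promoter.activity / truth.gamma
    sense = TranscriptionProfile(annotation.reference_id, SENSE,
                                 sense_values, sample_id=state)
    antisense = TranscriptionProfile(annotation.reference_id, ANTISENSE,
                                     anti_values, sample_id=state)
    return sense, antisense


def _plateau_units(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal constant nonzero runs of an expected profile."""
    boundaries = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(values)]))
    return [(int(a), int(b), float(values[a]))
            for a, b in zip(starts, ends) if values[a] > 0]


_MIN_ABUNDANCE = 1e-12


def transcript_species(annotation: CircuitAnnotation,
                       truth: GroundTruth,
                       activities: Mapping[str, float],
                       ) -> list[tuple[int, int, float]]:
    """Sense-strand transcript species (start, end, abundance in au).

    Walks the circuit 5'->3' tracking active RNAP streams.  A promoter
    starts an uncleaved stream of abundance s*(1-p_c) at its TSS; at a
    ribozyme cut site the cleaved 3' products of its promoters appear as a
    stream of abundance sum(s_i)*p_c (the cleaved 5' leaders are removed
    during library preparation and never become species).  A terminator
    ends the fraction (1 - 1/Ts) of every active stream and lets 1/Ts read
    through as the same long molecule.  Overlaying the species reproduces
    the traced expected profile exactly.
    """
    from .prediction import _assign_ribozymes

    length = annotation.reference_length
    sense_parts = [p for p in annotation.parts if p.strand == "+"]
    ribozyme_for = _assign_ribozymes(sense_parts)
    cleaved_strength: dict[str, float] = {}
    events = []
    for part in sense_parts:
        if part.part_type is PartType.PROMOTER:
            strength_au = float(activities.get(part.name, 0.0)) / truth.gamma
            ribozyme = ribozyme_for.get(part.name)
            p_c = (float(truth.ribozyme_pc.get(ribozyme.name, 0.0))
                   if ribozyme is not None else 0.0)
            events.append((part.tss, 0, "promoter",
                           strength_au * (1.0 - p_c)))
            if ribozyme is not None:
                cleaved_strength[ribozyme.name] = (
                    cleaved_strength.get(ribozyme.name, 0.0)
                    + strength_au * p_c)
        elif part.part_type is PartType.RIBOZYME:
            cut = part.cut_site if part.cut_site is not None else part.end
            events.append((cut, 1, "ribozyme", part.name))
        elif part.part_type is PartType.TERMINATOR:
            ts = max(float(truth.terminator_ts.get(part.name, 1.0)), 1.0)
            events.append((part.end, 2, "terminator", ts))
    events.sort(key=lambda e: (e[0], e[1]))

    streams: list[tuple[int, float]] = []
    if truth.read_through_in > 0:
        streams.append((0, truth.read_through_in / truth.gamma))
    species: list[tuple[int, int, float]] = []
    for coord, _, kind, payload in events:
        coord = min(max(int(coord), 0), length)
        if kind == "promoter":
            if payload > _MIN_ABUNDANCE:
                streams.append((coord, payload))
        elif kind == "ribozyme":
            cleaved = cleaved_strength.get(payload, 0.0)
            if cleaved > _MIN_ABUNDANCE:
                streams.append((coord, cleaved))
        else:
            ts = payload
            surviving = []
            for start, abundance in streams:
                terminated = abundance * (1.0 - 1.0 / ts)
                if terminated > _MIN_ABUNDANCE and coord > start:
                    species.append((start, coord, terminated))
                passed = abundance / ts
                if passed > _MIN_ABUNDANCE:
                    surviving.append((start, passed))
            streams = surviving
    for start, abundance in streams:
        if length > start:
            species.append((start, length, abundance))
    return species


def antisense_species(annotation: CircuitAnnotation,
                      truth: GroundTruth) -> list[tuple[int, int, float]]:
    """Antisense transcript species: each reverse promoter transcribes from
    its TSS down to its stop position."""
    species = []
    for promoter in truth.antisense_promoters:
        if promoter.tss >= annotation.reference_length:
            raise ValueError(f"antisense promoter {promoter.name} TSS outside "
                             "the reference")
        abundance = promoter.activity / truth.gamma
        if abundance > _MIN_ABUNDANCE:
            species.append((promoter.stop, promoter.tss + 1, abundance))
    return species


def _overlay(species: Sequence[tuple[int, int, float]],
             length: int) -> np.ndarray:
    values = np.zeros(length + 1)
    for start, end, abundance in species:
        values[start] += abundance
        values[end] -= abundance
    return np.cumsum(values[:-1])


def sample_fragments(true_profile: TranscriptionProfile,
                     fld: FragmentLengthDistribution,
                     depth: int,
                     seed: int,
                     units: Sequence[tuple[int, int, float]] | None = None,
                     ) -> list[FragmentAlignment]:
    """Sample ``depth`` fragments from an expected profile.

    The profile is decomposed into plateau-level transcription units
    (maximal constant nonzero runs unless explicit units are given).  For
    each fragment a length L is drawn from the FLD, a unit is drawn with
    probability proportional to abundance x (unit length - L + 1) — the
    number of valid placements, so that interior coverage is proportional
    to abundance — and the start is uniform over the valid starts.
    Fragment lengths that fit no unit are rejected and redrawn.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if units is None:
        units = _plateau_units(true_profile.values)
    if not units:
        raise ValueError("expected profile is identically zero; nothing to sample")
    u_start = np.array([u[0] for u in units])
    u_len = np.array([u[1] - u[0] for u in units])
    u_abundance = np.array([u[2] for u in units], dtype=float)
    if fld.lengths.min() > u_len.max():
        raise ValueError("every fragment length exceeds every unit length")
    rng = np.random.default_rng(seed)
    starts_out: list[np.ndarray] = []
    lengths_out: list[np.ndarray] = []
    remaining = depth
    guard = 0
    while remaining > 0:
        guard += 1
        if guard > 1000:
            raise RuntimeError("fragment sampling failed to converge")
        lengths = fld.sample(remaining, rng)
        accepted = 0
        for L in np.unique(lengths):
            n_draws = int((lengths == L).sum())
            placements = np.maximum(u_len - int(L) + 1, 0)
            weights = u_abundance * placements
            total = weights.sum()
            if total == 0:
                continue  # no unit fits this length; redrawn next round
            unit_idx = rng.choice(len(units), size=n_draws, p=weights / total)
            offsets = rng.integers(0, placements[unit_idx])
            starts_out.append(u_start[unit_idx] + offsets)
            lengths_out.append(np.full(n_draws, int(L)))
            accepted += n_draws
        remaining -= accepted
    starts = np.concatenate(starts_out)
    lengths = np.concatenate(lengths_out)
    return [FragmentAlignment(true_profile.reference_id, int(s), int(s + L),
                              true_profile.strand_class)
            for s, L in zip(starts, lengths)]


def simulate_experiment(annotation: CircuitAnnotation,
                        truth: GroundTruth,
                        states: Sequence[str],
                        fld: FragmentLengthDistribution | None = None,
                        depth: int = 1_000_000,
                        seed: int = 0) -> SyntheticExperiment:
    """Generate a complete multi-state synthetic experiment.

    Per state: promoter activities receive lognormal noise (sigma from the
    truth record), expected profiles are traced, and ``depth`` fragments
    are sampled, split between strands in proportion to expected profile
    mass.  The same seed regenerates the experiment bit-identically.
    """
    if len(states) == 0:
        raise ValueError("state list is empty")
    if fld is None:
        fld = default_fld()
    root = np.random.SeedSequence(seed)
    state_seeds = root.spawn(len(states))
    fragments: dict[str, list[FragmentAlignment]] = {}
    profiles: dict[str, tuple[TranscriptionProfile, TranscriptionProfile]] = {}
    realized: dict[str, dict[str, float]] = {}
    for state, seed_seq in zip(states, state_seeds):
        rng = np.random.default_rng(seed_seq)
        base = truth.promoter_activities[state]
        if truth.noise_sigma > 0:
            noise = rng.lognormal(0.0, truth.noise_sigma, size=len(base))
            activities = {name: dj * float(z)
                          for (name, dj), z in zip(base.items(), noise)}
        else:
            activities = dict(base)
        realized[state] = activities
        sense, antisense = simulate_expected_profile(
            annotation, truth, state, activities=activities)
        profiles[state] = (sense, antisense)
        sense_species = transcript_species(annotation, truth, activities)
        anti_species = antisense_species(annotation, truth)
        mass_s = sum(a * (e - s) for s, e, a in sense_species)
        mass_a = sum(a * (e - s) for s, e, a in anti_species)
        total_mass = mass_s + mass_a
        if total_mass == 0:
            fragments[state] = []
            continue
        depth_s = int(round(depth * mass_s / total_mass))
        depth_a = depth - depth_s
        state_fragments: list[FragmentAlignment] = []
        sub_seeds = seed_seq.spawn(2)
        if depth_s > 0 and mass_s > 0:
            state_fragments += sample_fragments(
                sense, fld, depth_s,
                seed=int(sub_seeds[0].generate_state(1)[0] % (2 ** 31)),
                units=sense_species)
        if depth_a > 0 and mass_a > 0:
            state_fragments += sample_fragments(
                antisense, fld, depth_a,
                seed=int(sub_seeds[1].generate_state(1)[0] % (2 ** 31)),
                units=anti_species)
        fragments[state] = state_fragments
    return SyntheticExperiment(
        annotation=annotation, states=list(states), fragments=fragments,
        true_profiles=profiles, realized_activities=realized, truth=truth,
        fld=fld, depth=depth, seed=seed)
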