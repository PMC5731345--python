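"""End-to-end orchestration: fragments -> corrected profile -> part table.

Ties the modules together the way the command-line interface and the
recovery tests use them.  Promoters sharing an insulating ribozyme are
measured as one combined tandem part (their individual rises cannot be
separated in the profile; deconvolution across states is the devices
module's job).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .correction import (CorrectionFactorProfile, correct_circuit_profile,
                         correction_factor, hypothetical_profile)
from .io import (SENSE, CircuitAnnotation, FragmentAlignment,
                 FragmentLengthDistribution, PartType, TranscriptionProfile,
                 fragment_length_distribution)
from .parts import (AnalysisConfig, PartMeasurement, promoter_activity,
                    promoter_boundaries, ribozyme_cleavage_efficiency,
                    terminator_strength)
from .prediction import _assign_ribozymes

__all__ = [
    "CircuitMeasurement",
    "recover_profile",
    "measure_parts",
    "measurements_to_frame",
]


@dataclass
class CircuitMeasurement:
    profile: TranscriptionProfile
    measurements: list[PartMeasurement]
    correction: CorrectionFactorProfile
    fld: FragmentLengthDistribution


def recover_profile(fragments: Sequence[FragmentAlignment],
                    annotation: CircuitAnnotation,
                    strand_class: str = SENSE,
                    C: CorrectionFactorProfile | None = None,
                    fld: FragmentLengthDistribution | None = None,
                    draws: int = 1_000_000,
                    seed: int = 20170901,
                    calibration_mass: float | None = None,
                    ) -> tuple[TranscriptionProfile, CorrectionFactorProfile,
                               FragmentLengthDistribution]:
    """Build the end-corrected profile for one strand of one sample.

    The fragment-length distribution is estimated from the fragments
    themselves unless given; the correction factor profile is built by
    Monte Carlo from that distribution.  If ``calibration_mass`` is given
    the corrected profile is rescaled so its total equals it (putting raw
    counts onto a chosen au scale).
    """
    if fld is None:
        fld = fragment_length_distribution(list(fragments))
    if C is None:
        C = correction_factor(hypothetical_profile(fld, draws=draws, seed=seed))
    profile = correct_circuit_profile(fragments, annotation, C,
                                      strand_class=strand_class)
    if calibration_mass is not None:
        total = profile.values.sum()
        if total > 0:
            profile = profile.scaled(calibration_mass / total)
    return profile, C, fld


def measure_parts(profile: TranscriptionProfile,
                  annotation: CircuitAnnotation,
                  config: AnalysisConfig = AnalysisConfig(),
                  state: str = "state",
                  C: CorrectionFactorProfile | None = None,
                  ) -> list[PartMeasurement]:
    """Quantify every promoter, ribozyme and terminator on the sense strand.

    Ribozymes are measured first so promoter activities can also be
    reported corrected for incomplete cleavage (delta_J divided by the
    estimated p_c appears under ``extras['delta_J_cleavage_corrected']``).
    """
    sense_parts = [p for p in annotation.parts if p.strand == "+"]
    promoters = [p for p in sense_parts if p.part_type is PartType.PROMOTER]
    ribozyme_for = _assign_ribozymes(sense_parts)
    measurements: list[PartMeasurement] = []

    pc_for_ribozyme: dict[str, PartMeasurement] = {}
    for ribozyme in (p for p in sense_parts if p.part_type is PartType.RIBOZYME):
        driving = [p for p in promoters
                   if ribozyme_for.get(p.name) is ribozyme]
        if not driving:
            continue
        tss = min(p.tss for p in driving)
        m = ribozyme_cleavage_efficiency(profile, ribozyme, tss, config,
                                         state, C=C)
        pc_for_ribozyme[ribozyme.name] = m
        measurements.append(m)

    # promoters grouped by shared ribozyme = tandem parts measured jointly
    grouped: dict[str | None, list] = {}
    for promoter in promoters:
        ribozyme = ribozyme_for.get(promoter.name)
        key = ribozyme.name if ribozyme is not None else promoter.name
        grouped.setdefault(key, []).append((promoter, ribozyme))
    for group in grouped.values():
        promoter, ribozyme = group[0]
        name = "-".join(p.name for p, _ in group)
        boundary_up, boundary_down = promoter_boundaries(promoter, ribozyme)
        dj = promoter_activity(profile, boundary_up, boundary_down, config)
        extras = {}
        if ribozyme is not None:
            pc = pc_for_ribozyme.get(ribozyme.name)
            if pc is not None and not pc.filtered and pc.value > 0.05:
                extras["delta_J_cleavage_corrected"] = dj / pc.value
        measurements.append(PartMeasurement(name, state, "delta_J", dj,
                                            "au/s", extras=extras))

    for terminator in (p for p in sense_parts
                       if p.part_type is PartType.TERMINATOR):
        measurements.append(terminator_strength(profile, terminator, config,
                                                state))
    return measurements


def measurements_to_frame(measurements: Sequence[PartMeasurement]) -> pd.DataFrame:
    rows = [{"part": m.part, "state": m.state, "metric": m.metric,
             "value": m.value, "units": m.units, "filtered": m.filtered,
             "reason": m.reason or ""} for m in measurements]
    return pd.DataFrame(rows, columns=["part", "state", "metric", "value",
                                       "units", "filtered", "reason"])
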