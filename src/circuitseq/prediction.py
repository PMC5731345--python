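"""Predicted transcription profiles from design-tool part parameters.

Design tools report promoter strengths in relative promoter units (RPU)
from fluorescent-reporter assays; a proportional conversion fitted
against the measured output-gene profile puts them on the profile au
scale.  The predicted profile is then traced 5'->3' along the circuit: a
promoter raises the height at its TSS by its strength times (1 - p_c) of
the next downstream ribozyme (the cleaved fraction loses its 5' leader),
a ribozyme resets the height to the combined strength of the promoters
driving it plus terminator read-through, and passing a terminator end
divides the height by its strength Ts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import (SENSE, CircuitAnnotation, Part, PartType,
                 TranscriptionProfile)

__all__ = [
    "DesignPrediction",
    "RpuConversion",
    "fit_rpu_conversion",
    "trace_profile",
    "predict_profile",
    "compare_predicted_observed",
]


@dataclass
class DesignPrediction:
    """Per-state promoter strengths (RPU) and part parameters from a
    circuit design tool."""

    promoter_rpu: Mapping[str, Mapping[str, float]]   # state -> promoter -> RPU
    terminator_ts: Mapping[str, float]                # terminator -> fold
    ribozyme_pc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for state, strengths in self.promoter_rpu.items():
            for name, rpu in strengths.items():
                if rpu < 0:
                    raise ValueError(f"{state}/{name}: RPU must be >= 0")
        for name, ts in self.terminator_ts.items():
            if ts < 1:
                raise ValueError(f"terminator {name}: Ts must be >= 1")
        for name, pc in self.ribozyme_pc.items():
            if not 0 <= pc <= 1:
                raise ValueError(f"ribozyme {name}: p_c must be in [0, 1]")


@dataclass
class RpuConversion:
    slope: float                     # au per RPU
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("conversion slope must be positive")

    def to_au(self, rpu: float) -> float:
        return self.slope * rpu


def fit_rpu_conversion(rpu: Sequence[float],
                       mean_au: Sequence[float]) -> RpuConversion:
    """Zero-intercept least-squares slope between RPU and profile au.

    A conversion factor is a proportionality, so the regression is forced
    through the origin; R-squared against the zero-intercept fit is
    reported for diagnostics.
    """
    x = np.asarray(rpu, dtype=float)
    y = np.asarray(mean_au, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rpu and au vectors differ in length")
    usable = (x > 0) | (y > 0)
    if usable.sum() < 2:
        raise ValueError("need >= 2 states with nonzero values")
    denominator = np.sum(x ** 2)
    if denominator == 0:
        raise ValueError("all RPU values are zero")
    slope = float(np.sum(x * y) / denominator)
    residual = y - slope * x
    total = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(residual ** 2) / total) if total > 0 else 1.0
    return RpuConversion(slope=slope, r_squared=r2)


def trace_profile(annotation: CircuitAnnotation,
                  strengths_au: Mapping[str, float],
                  terminator_ts: Mapping[str, float],
                  ribozyme_pc: Mapping[str, float],
                  read_through_in: float = 0.0) -> np.ndarray:
    """Trace the expected piecewise-constant sense profile in au.

    Scans parts 5'->3'.  Change points are promoter TSSs (height +=
    strength * (1 - p_c of the assigned downstream ribozyme)), ribozyme
    cut sites (height reset to combined assigned promoter strengths plus
    read-through from the nearest upstream terminator) and terminator ends
    (height /= Ts).  Promoters with no downstream ribozyme before the next
    terminator are traced with p_c = 0 (warning).
    """
    length = annotation.reference_length
    events = []    # (coordinate, order, kind, payload)
    sense_parts = [p for p in annotation.parts if p.strand == "+"]
    ribozyme_for = _assign_ribozymes(sense_parts)
    for part in sense_parts:
        if part.part_type is PartType.PROMOTER:
            strength = float(strengths_au.get(part.name, 0.0))
            ribozyme = ribozyme_for.get(part.name)
            if ribozyme is None:
                p_c = 0.0
                if not _terminator_downstream(sense_parts, part):
                    warnings.warn(
                        f"promoter {part.name} has no downstream ribozyme or "
                        "terminator; traced with p_c = 0")
            else:
                p_c = float(ribozyme_pc.get(ribozyme.name, 0.0))
            events.append((part.tss, 0, "promoter", (strength, p_c)))
        elif part.part_type is PartType.RIBOZYME:
            cut = part.cut_site if part.cut_site is not None else part.end
            events.append((cut, 1, "ribozyme", part.name))
        elif part.part_type is PartType.TERMINATOR:
            ts = float(terminator_ts.get(part.name, 1.0))
            events.append((part.end, 2, "terminator", max(ts, 1.0)))
    events.sort(key=lambda e: (e[0], e[1]))

    profile = np.zeros(length)
    height = read_through_in
    read_through = read_through_in        # level after the last terminator
    pending: list[float] = []             # full strengths since last terminator
    cursor = 0
    for coord, _, kind, payload in events:
        coord = min(max(coord, 0), length)
        profile[cursor:coord] = height
        cursor = coord
        if kind == "promoter":
            strength, p_c = payload
            pending.append(strength)
            height += strength * (1.0 - p_c)
        elif kind == "ribozyme":
            height = read_through + sum(pending)
        else:
            height /= payload
            read_through = height
            pending = []
    profile[cursor:length] = height
    return profile


def _assign_ribozymes(sense_parts: Sequence[Part]) -> dict[str, Part]:
    """Each promoter between a terminator and the next ribozyme is driven
    through (assigned to) that ribozyme."""
    assignment: dict[str, Part] = {}
    pending: list[Part] = []
    for part in sense_parts:
        if part.part_type is PartType.PROMOTER:
            pending.append(part)
        elif part.part_type is PartType.RIBOZYME:
            for promoter in pending:
                assignment[promoter.name] = part
            pending = []
        elif part.part_type is PartType.TERMINATOR:
            pending = []
    return assignment


def _terminator_downstream(sense_parts: Sequence[Part], promoter: Part) -> bool:
    return any(p.part_type is PartType.TERMINATOR and p.start >= promoter.end
               for p in sense_parts)


def predict_profile(annotation: CircuitAnnotation,
                    prediction: DesignPrediction,
                    conversion: RpuConversion,
                    state: str,
                    read_through_in: float = 0.0) -> TranscriptionProfile:
    """Predicted sense-strand profile for one state, in au."""
    if state not in prediction.promoter_rpu:
        raise ValueError(f"state {state!r} absent from the prediction")
    strengths_au = {name: conversion.to_au(rpu)
                    for name, rpu in prediction.promoter_rpu[state].items()}
    values = trace_profile(annotation, strengths_au,
                           prediction.terminator_ts, prediction.ribozyme_pc,
                           read_through_in)
    return TranscriptionProfile(annotation.reference_id, SENSE, values,
                                sample_id=state)


def compare_predicted_observed(predicted: Mapping[str, TranscriptionProfile],
                               observed: Mapping[str, TranscriptionProfile],
                               genes: Sequence[Part],
                               floor: float = 1.0):
    """Per-gene/state comparison of predicted and observed expression.

    Returns (table, summary): the table holds mean predicted au, mean
    observed au and their log10 ratio per gene and state; the summary
    holds the zero-intercept slope (observed vs predicted, linear scale)
    and the squared correlation of the log10 values.  Values are floored
    at ``floor`` au before logging.
    """
    import pandas as pd

    if len(genes) == 0:
        raise ValueError("empty gene list")
    rows = []
    for state, pred in predicted.items():
        obs = observed[state]
        if obs.reference_id != pred.reference_id:
            raise ValueError(
                f"state {state}: predicted profile on {pred.reference_id!r} "
                f"but observed on {obs.reference_id!r}")
        for gene in genes:
            p = pred.mean_over(gene.start, gene.end)
            o = obs.mean_over(gene.start, gene.end)
            rows.append({"gene": gene.name, "state": state,
                         "predicted_au": p, "observed_au": o,
                         "log10_ratio": float(np.log10(max(o, floor))
                                              - np.log10(max(p, floor)))})
    table = pd.DataFrame(rows)
    x = table["predicted_au"].to_numpy()
    y = table["observed_au"].to_numpy()
    slope = float(np.sum(x * y) / np.sum(x ** 2)) if np.any(x > 0) else np.nan
    log_x = np.log10(np.maximum(x, floor))
    log_y = np.log10(np.maximum(y, floor))
    if np.std(log_x) > 0 and np.std(log_y) > 0:
        r2 = float(np.corrcoef(log_x, log_y)[0, 1] ** 2)
    else:
        r2 = float("nan")
    summary = {"slope": slope, "log_r_squared": r2}
    return table, summary
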