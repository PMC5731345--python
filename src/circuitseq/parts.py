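"""Biophysical part quantification from transcription profiles.

At steady state the RNAP flux past a position is J(x) = gamma * M(x),
where M(x) is the profile height and gamma the bulk mRNA degradation
rate.  Promoter activity is the background-subtracted step in flux across
the part (or across the cleavage site of its insulating ribozyme),
terminator strength the fold drop in profile height across the part, and
ribozyme cleavage efficiency the fraction of transcripts whose 5' end was
removed, read from the step at the cut site.  Averaging windows of n
nucleotides immediately flanking the measured boundaries damp
single-position noise.  Measurements made where almost no RNAP enters a
part are unreliable, so they are flagged rather than reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import Part, TranscriptionProfile

__all__ = [
    "AnalysisConfig",
    "PartMeasurement",
    "rnap_flux_at",
    "promoter_activity",
    "terminator_strength",
    "ribozyme_cleavage_efficiency",
    "antisense_activity",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the part-quantification model.

    gamma : bulk mRNA degradation rate (1/s).  The default 0.0067 1/s
        corresponds to a ~1.7 min mRNA half-life in fast-growing E. coli.
    window_n : averaging window length in nt on each side of a boundary.
    min_flux_filter : measurements with less than this RNAP flux (au/s)
        entering a terminator or leaving a ribozyme are flagged.
    """

    gamma: float = 0.0067
    window_n: int = 10
    min_flux_filter: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")
        if self.min_flux_filter < 0:
            raise ValueError("min_flux_filter must be >= 0")


@dataclass
class PartMeasurement:
    """One quantified metric for one part in one sample/state."""

    part: str
    state: str
    metric: str                 # delta_J | Ts | p_c | antisense_J
    value: float
    units: str
    filtered: bool = False
    reason: str | None = None
    extras: dict = field(default_factory=dict)


def rnap_flux_at(profile: TranscriptionProfile, x: int,
                 config: AnalysisConfig = AnalysisConfig()) -> float:
    """Steady-state RNAP flux gamma*M(x) in au/s."""
    if not 0 <= x < len(profile):
        raise ValueError(f"position {x} outside profile bounds [0, {len(profile)})")
    return config.gamma * float(profile.values[x])


def _window_mean(profile: TranscriptionProfile, start: int, end: int) -> float:
    if not (0 <= start < end <= len(profile)):
        raise ValueError(f"averaging window [{start}, {end}) out of bounds "
                         f"for profile of length {len(profile)}")
    return profile.mean_over(start, end)


def promoter_activity(profile: TranscriptionProfile,
                      boundary_up: int,
                      boundary_down: int,
                      config: AnalysisConfig = AnalysisConfig()) -> float:
    """Promoter activity dJ (au/s): flux step across the part boundaries.

    The upstream window covers the n positions ending just before
    ``boundary_up`` and the downstream window the n positions starting at
    ``boundary_down``; the upstream mean is subtracted as background so
    only flux originating from the promoter is counted.  For a promoter
    insulated by a ribozyme, pass the cleavage site as both boundaries so
    the windows flank the cut, where the profile step actually appears.
    """
    n = config.window_n
    up = _window_mean(profile, boundary_up - n, boundary_up)
    down = _window_mean(profile, boundary_down, boundary_down + n)
    return config.gamma * (down - up)


def promoter_boundaries(promoter: Part, ribozyme: Part | None) -> tuple[int, int]:
    """Measurement boundaries for a promoter: its part boundaries, or the
    cleavage site of the insulating ribozyme when one is present."""
    if ribozyme is not None:
        cut = ribozyme.cut_site
        if cut is None:
            raise ValueError(f"ribozyme {ribozyme.name} lacks a cut_site attribute")
        return cut, cut
    return promoter.start, promoter.end


def terminator_strength(profile: TranscriptionProfile, part: Part,
                        config: AnalysisConfig = AnalysisConfig(),
                        state: str = "state") -> PartMeasurement:
    """Terminator strength Ts: fold decrease in profile height across the part.

    Ts = mean M over the n nt upstream of the part start divided by the
    mean over the n nt downstream of the part end.  If the flux entering
    the terminator is below the filter threshold the measurement is
    flagged ("low input flux"); a zero downstream window yields an
    infinite-strength sentinel with a flag.
    """
    n = config.window_n
    up = _window_mean(profile, part.start - n, part.start)
    down = _window_mean(profile, part.end, part.end + n)
    incoming_flux = config.gamma * up
    if down == 0:
        return PartMeasurement(part.name, state, "Ts", math.inf, "fold",
                               filtered=True, reason="zero downstream window",
                               extras={"incoming_flux": incoming_flux})
    measurement = PartMeasurement(part.name, state, "Ts", up / down, "fold",
                                  extras={"incoming_flux": incoming_flux})
    if incoming_flux < config.min_flux_filter:
        measurement.filtered = True
        measurement.reason = "low input flux"
    return measurement


def ribozyme_cleavage_efficiency(profile: TranscriptionProfile,
                                 ribozyme: Part,
                                 tss: int,
                                 config: AnalysisConfig = AnalysisConfig(),
                                 state: str = "state",
                                 C=None) -> PartMeasurement:
    """Cleavage efficiency p_c of a self-cleaving ribozyme insulator.

    Cleaved transcripts lose their 5' leader (the small RNA is removed
    during library preparation), so coverage upstream of the cut site comes
    only from the uncleaved fraction.  With the read-through background
    measured just upstream of the promoter TSS subtracted from both sides,

        p_c = 1 - (net flux upstream of cut) / (net flux downstream of cut),

    clamped to [0, 1].  The uncleaved leader is itself a transcript 5' end,
    so its coverage in the upstream window carries the usual end bias;
    passing a correction factor profile ``C`` divides the net upstream flux
    by C at the window's distance from the TSS (assuming a locally flat
    background).  Flagged when the flux leaving the ribozyme is below the
    filter threshold, or when there is no net downstream flux.
    """
    cut = ribozyme.cut_site
    if cut is None:
        raise ValueError(f"ribozyme {ribozyme.name} has no cut_site attribute")
    n = config.window_n
    background = config.gamma * _window_mean(profile, tss - n, tss)
    flux_up = config.gamma * _window_mean(profile, cut - n, cut)
    flux_down = config.gamma * _window_mean(profile, cut, cut + n)
    net_up = flux_up - background
    if C is not None:
        # mean C over the window positions' 1-based distances from the TSS
        distances = [pos - tss + 1 for pos in range(cut - n, cut)]
        usable = [d for d in distances if 1 <= d <= len(C.values)]
        if usable:
            mean_c = float(np.mean([C.at(d) for d in usable]))
            if mean_c > 0:
                net_up /= mean_c
    net_down = flux_down - background
    extras = {"flux_leaving": flux_down, "background": background}
    if flux_down < config.min_flux_filter:
        return PartMeasurement(ribozyme.name, state, "p_c", math.nan,
                               "fraction", filtered=True,
                               reason="low flux leaving ribozyme",
                               extras=extras)
    if net_down <= 0:
        return PartMeasurement(ribozyme.name, state, "p_c", math.nan,
                               "fraction", filtered=True,
                               reason="no net flux across cut site",
                               extras=extras)
    p_c = 1.0 - net_up / net_down
    p_c = min(1.0, max(0.0, p_c))
    return PartMeasurement(ribozyme.name, state, "p_c", p_c, "fraction",
                           extras=extras)


def antisense_activity(antisense_profile: TranscriptionProfile,
                       region: tuple[int, int],
                       config: AnalysisConfig = AnalysisConfig()) -> float:
    """Mean antisense RNAP flux (au/s) over a region of interest."""
    start, end = region
    if start >= end:
        raise ValueError(f"empty region [{start}, {end})")
    return config.gamma * _window_mean(antisense_profile, start, end)
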