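"""Sensor and gate characterization across circuit states.

A sensor is summarized by its output promoter activity with and without
its inducer (dJ_on, dJ_off).  A NOT gate maps total input RNAP flux J_in
to output promoter activity through a repressing Hill function

    dJ_out = dJ_min + (dJ_max - dJ_min) * K^n / (K^n + J_in^n),

with threshold K and cooperativity n; NOR gates are the same device with
J_in summed over their input promoters plus upstream read-through.
Parameters are fit by minimizing a least-squares error on log activities
(E1), and promoters measured jointly in series are deconvolved with an
adapted error on the log of the summed expected activities (E2), then the
measured combined activity is split by each promoter's expected fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ResponseFunction",
    "SensorResponse",
    "GateObservation",
    "FitResult",
    "eval_response_function",
    "sensor_response",
    "gate_input_flux",
    "fit_gate_response",
    "SeriesSensor",
    "SeriesGate",
    "fit_series",
    "split_series_activity",
    "DEFAULT_LOG_FLOOR",
]

#: Activities at or below this value (au/s) are replaced by it before
#: logging; off states can measure exactly 0 and logs need positivity.
DEFAULT_LOG_FLOOR = 1e-2

_N_COOP_BOUNDS = (0.1, 8.0)


@dataclass
class ResponseFunction:
    """Hill-form response of a NOT/NOR gate."""

    dJ_min: float
    dJ_max: float
    K: float
    n_coop: float

    def __post_init__(self) -> None:
        if not 0 <= self.dJ_min < self.dJ_max:
            raise ValueError("require 0 <= dJ_min < dJ_max")
        if self.K <= 0:
            raise ValueError("threshold K must be positive")
        if self.n_coop <= 0:
            raise ValueError("cooperativity must be positive")

    def __call__(self, J_in: float) -> float:
        return eval_response_function(self, J_in)


@dataclass
class SensorResponse:
    dJ_off: float
    dJ_on: float
    off_states: list[str] = field(default_factory=list)
    on_states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dJ_off < 0 or self.dJ_on < 0:
            raise ValueError("sensor activities must be non-negative")


@dataclass
class GateObservation:
    """One state's (input flux, output activity) pair for a gate."""

    state: str
    J_in: float
    dJ_out: float
    J0: float = 0.0

    def __post_init__(self) -> None:
        if self.J_in < 0:
            raise ValueError("input flux must be non-negative")


@dataclass
class FitResult:
    response: ResponseFunction | None
    error: float
    converged: bool
    degenerate: bool = False
    message: str = ""


def eval_response_function(rf: ResponseFunction, J_in: float) -> float:
    """dJ_out = dJ_min + (dJ_max - dJ_min) * K^n / (K^n + J_in^n)."""
    if J_in < 0:
        raise ValueError("input flux must be non-negative")
    kn = rf.K ** rf.n_coop
    return rf.dJ_min + (rf.dJ_max - rf.dJ_min) * kn / (kn + J_in ** rf.n_coop)


def sensor_response(activities: Mapping[str, float],
                    on_states: Mapping[str, bool]) -> SensorResponse:
    """Average the output promoter activity over on and over off states."""
    on = [s for s in activities if on_states[s]]
    off = [s for s in activities if not on_states[s]]
    if not on or not off:
        raise ValueError("need at least one on state and one off state")
    return SensorResponse(
        dJ_off=float(np.mean([activities[s] for s in off])),
        dJ_on=float(np.mean([activities[s] for s in on])),
        off_states=off, on_states=on)


def gate_input_flux(input_activities: Sequence[float], J0: float = 0.0) -> float:
    """Total input flux: sum of input promoter activities plus read-through."""
    return float(sum(input_activities) + J0)


def _floor(values: np.ndarray, floor: float) -> np.ndarray:
    return np.maximum(values, floor)


def _e1(theta: np.ndarray, J_in: np.ndarray, log_measured: np.ndarray) -> float:
    # theta = (log dJ_min, log(dJ_max - dJ_min), log K, n)
    dj_min = math.exp(theta[0])
    dj_span = math.exp(theta[1])
    K = math.exp(theta[2])
    n = theta[3]
    kn = K ** n
    expected = dj_min + dj_span * kn / (kn + J_in ** n)
    return float(np.sum((np.log(expected) - log_measured) ** 2))


def fit_gate_response(observations: Sequence[GateObservation],
                      floor: float = DEFAULT_LOG_FLOOR) -> FitResult:
    """Fit the Hill response to (J_in, dJ_out) observations by minimizing
    E1 = sum_i [log(dJ_i) - log(dJ_out(J_in_i))]^2.

    Needs at least four observations (four free parameters).  Measured
    outputs at or below ``floor`` are floored before logging.  A constrained
    local minimization (SLSQP) is started from a small grid (K at the input
    quantiles, cooperativity in {1, 2, 4}); the lowest error wins, ties
    going to the smaller cooperativity.  Non-convergence and degenerate
    (flat-output) data are flagged in the result, not raised.
    """
    if len(observations) < 4:
        raise ValueError(f"need >= 4 observations to fit 4 parameters, "
                         f"got {len(observations)}")
    J_in = np.array([o.J_in for o in observations], dtype=float)
    measured = _floor(np.array([o.dJ_out for o in observations]), floor)
    log_measured = np.log(measured)
    if np.allclose(measured, measured[0]):
        flat = float(measured[0])
        rf = None
        if flat > 0:
            rf = ResponseFunction(dJ_min=flat * (1 - 1e-9), dJ_max=flat,
                                  K=max(np.median(J_in), floor), n_coop=1.0)
        return FitResult(response=rf, error=0.0, converged=False,
                         degenerate=True,
                         message="all outputs identical; K unidentifiable")
    lo = math.log(floor) - 2
    bounds = [(lo, 25.0), (lo, 25.0), (math.log(1e-6), 25.0), _N_COOP_BOUNDS]
    positive_inputs = J_in[J_in > 0]
    if positive_inputs.size == 0:
        positive_inputs = np.array([floor])
    k_starts = np.unique(np.quantile(positive_inputs, [0.25, 0.5, 0.75]))
    dj_min0 = max(measured.min(), floor)
    dj_span0 = max(measured.max() - dj_min0, floor)
    best: FitResult | None = None
    for k0 in k_starts:
        for n0 in (1.0, 2.0, 4.0):
            theta0 = np.array([math.log(dj_min0), math.log(dj_span0),
                               math.log(k0), n0])
            res = minimize(_e1, theta0, args=(J_in, log_measured),
                           method="SLSQP", bounds=bounds,
                           options={"maxiter": 500, "ftol": 1e-14})
            candidate = _result_from_theta(res, floor)
            if _better(candidate, best):
                best = candidate
    return best


def _result_from_theta(res, floor: float) -> FitResult:
    dj_min = math.exp(res.x[0])
    dj_span = math.exp(res.x[1])
    rf = ResponseFunction(dJ_min=dj_min, dJ_max=dj_min + dj_span,
                          K=math.exp(res.x[2]), n_coop=float(res.x[3]))
    return FitResult(response=rf, error=float(res.fun),
                     converged=bool(res.success), message=res.message)


def _better(candidate: FitResult, incumbent: FitResult | None) -> bool:
    if incumbent is None:
        return True
    if not math.isclose(candidate.error, incumbent.error,
                        rel_tol=1e-9, abs_tol=1e-12):
        return candidate.error < incumbent.error
    return candidate.response.n_coop < incumbent.response.n_coop


# ---------------------------------------------------------------------------
# Promoters in series


@dataclass
class SeriesSensor:
    """Series member whose expected activity is dJ_on or dJ_off per state."""

    name: str
    on_states: Mapping[str, bool]      # state -> inducer present

    n_params = 2

    def expected(self, params: np.ndarray, state: str) -> float:
        dj_off, dj_on = params
        return dj_on if self.on_states[state] else dj_off

    def pack_result(self, params: np.ndarray) -> SensorResponse:
        off = [s for s, on in self.on_states.items() if not on]
        on = [s for s, v in self.on_states.items() if v]
        return SensorResponse(dJ_off=float(params[0]), dJ_on=float(params[1]),
                              off_states=off, on_states=on)


@dataclass
class SeriesGate:
    """Series member whose expected activity is the Hill response of its
    per-state input flux."""

    name: str
    J_in: Mapping[str, float]          # state -> total input flux

    n_params = 4

    def expected(self, params: np.ndarray, state: str) -> float:
        dj_min, dj_span, K, n = params
        j = self.J_in[state]
        kn = K ** n
        return dj_min + dj_span * kn / (kn + j ** n)

    def pack_result(self, params: np.ndarray) -> ResponseFunction:
        dj_min, dj_span, K, n = params
        return ResponseFunction(dJ_min=float(dj_min),
                                dJ_max=float(dj_min + dj_span),
                                K=float(K), n_coop=float(n))


def _check_identifiable(devices, states: Sequence[str]) -> None:
    sensors = [d for d in devices if isinstance(d, SeriesSensor)]
    if len(sensors) == 2:
        pat1 = tuple(sensors[0].on_states[s] for s in states)
        pat2 = tuple(sensors[1].on_states[s] for s in states)
        if pat1 == pat2:
            raise ValueError(
                f"sensors {sensors[0].name} and {sensors[1].name} are "
                "confounded: identical on/off pattern across all states")
        combos = set(zip(pat1, pat2))
        if len(combos) < 4:
            raise ValueError(
                "underdetermined: two-sensor series needs all four "
                f"inducer combinations, observed only {len(combos)}")
    n_params = sum(d.n_params for d in devices)
    if len(states) < n_params:
        raise ValueError(f"underdetermined: {len(states)} states for "
                         f"{n_params} free parameters")


def fit_series(measured: Mapping[str, float],
               devices: Sequence[SeriesSensor | SeriesGate],
               floor: float = DEFAULT_LOG_FLOOR):
    """Deconvolve two promoters measured jointly in series.

    Minimizes E2 = sum_i [log(dJ_{1+2,i}) - log(dJ_1,i + dJ_2,i)]^2 over
    the union of both devices' parameters, where each expected individual
    activity comes from the device's model (on/off level for a sensor,
    Hill response of that state's input flux for a gate).  Returns
    (per-device fitted objects, FitResult-style diagnostics dict).
    """
    if len(devices) != 2:
        raise ValueError("series fitting expects exactly two devices")
    states = list(measured)
    _check_identifiable(devices, states)
    y = _floor(np.array([measured[s] for s in states], dtype=float), floor)
    log_y = np.log(y)
    slices = []
    offset = 0
    for dev in devices:
        slices.append(slice(offset, offset + dev.n_params))
        offset += dev.n_params

    def unpack(theta):
        # all magnitude parameters live in log space; cooperativity linear
        params = []
        for dev, sl in zip(devices, slices):
            t = theta[sl]
            if isinstance(dev, SeriesSensor):
                params.append(np.exp(t))
            else:
                params.append(np.array([math.exp(t[0]), math.exp(t[1]),
                                        math.exp(t[2]), t[3]]))
        return params

    def e2(theta):
        params = unpack(theta)
        expected = np.empty(len(states))
        for i, state in enumerate(states):
            expected[i] = sum(dev.expected(p, state)
                              for dev, p in zip(devices, params))
        expected = np.maximum(expected, 1e-300)
        return float(np.sum((np.log(expected) - log_y) ** 2))

    starts = _series_starts(measured, devices, floor)
    lo = math.log(floor) - 4
    bounds = []
    for dev in devices:
        if isinstance(dev, SeriesSensor):
            bounds += [(lo, 25.0)] * 2
        else:
            bounds += [(lo, 25.0), (lo, 25.0), (math.log(1e-6), 25.0),
                       _N_COOP_BOUNDS]
    best = None
    for theta0 in starts:
        res = minimize(e2, theta0, method="SLSQP", bounds=bounds,
                       options={"maxiter": 1000, "ftol": 1e-16})
        if best is None or res.fun < best.fun:
            best = res
    params = _fix_gauge(devices, unpack(best.x), floor)
    fitted = [dev.pack_result(p) for dev, p in zip(devices, params)]
    diagnostics = {"error": float(best.fun), "converged": bool(best.success),
                   "message": best.message}
    return fitted, diagnostics


def _fix_gauge(devices, params, floor):
    """Pin the additive exchange degeneracy of a series fit.

    Adding a constant c to every output level of one device (both sensor
    levels, or a gate's dJ_min and dJ_max) and subtracting it from the
    other leaves every state's predicted sum — and hence E2 — unchanged,
    so a series pair is only identifiable up to this exchange.  The gauge
    is fixed by the convention that the first device's minimal output
    level sits at the log floor (engineered sensors and gates are tight in
    their off state; residual leakiness is attributed to the second
    device), clipped so the second device's levels stay at or above the
    floor.
    """
    p1, p2 = (p.copy() for p in params)
    min1 = p1.min() if isinstance(devices[0], SeriesSensor) else p1[0]
    min2 = p2.min() if isinstance(devices[1], SeriesSensor) else p2[0]
    c = min1 - floor                   # shift device 1 down by c ...
    c = min(c, 10 ** 12) if c >= 0 else max(c, -(min2 - floor))
    if isinstance(devices[0], SeriesSensor):
        p1 -= c
    else:
        p1[0] -= c                     # dJ_min; the span is untouched
    if isinstance(devices[1], SeriesSensor):
        p2 += c
    else:
        p2[0] += c
    return [p1, p2]


def _series_starts(measured, devices, floor):
    """Data-driven starting points; for sensor pairs, a linear least-squares
    solve of the on/off sum equations seeds the optimizer."""
    states = list(measured)
    y = np.array([max(measured[s], floor) for s in states])
    starts = []
    if all(isinstance(d, SeriesSensor) for d in devices):
        design = np.zeros((len(states), 4))
        for i, state in enumerate(states):
            design[i, 0 if not devices[0].on_states[state] else 1] = 1
            design[i, 2 if not devices[1].on_states[state] else 3] = 1
        solution, *_ = np.linalg.lstsq(design, y, rcond=None)
        solution = np.maximum(solution, floor)
        starts.append(np.log(solution))
    base = []
    lo_guess = max(y.min() / 2, floor)
    hi_guess = max(y.max() / 2, floor * 2)
    for dev in devices:
        if isinstance(dev, SeriesSensor):
            base += [math.log(lo_guess), math.log(hi_guess)]
        else:
            j = np.array([v for v in dev.J_in.values() if v > 0])
            k0 = np.median(j) if j.size else 1.0
            base += [math.log(lo_guess), math.log(hi_guess), math.log(k0), 2.0]
    starts.append(np.array(base))
    # perturbed variants guard against a poor single basin
    rng = np.random.default_rng(0)
    for _ in range(4):
        starts.append(np.array(base) + rng.normal(0, 0.5, size=len(base)))
    return starts


def split_series_activity(measured_total: float,
                          expected_1: float,
                          expected_2: float) -> tuple[float, float]:
    """Split a combined tandem-promoter measurement by expected fractions.

    dJ1_est = measured * expected_1 / (expected_1 + expected_2), and
    analogously for promoter 2; the two estimates sum to the measurement
    exactly.
    """
    total_expected = expected_1 + expected_2
    if total_expected <= 0:
        raise ValueError("expected activities sum to zero; cannot split")
    frac = expected_1 / total_expected
    part1 = measured_total * frac
    return part1, measured_total - part1
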