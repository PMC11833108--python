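"""Reduced order model of the ligament's ramp-and-hold force response.

The specimen-level model has one degree of freedom, the actuator
displacement x(t).  The elastic backbone F(x) comes from the one-term
compressible hyperelastic law through the proportional stress/strain
mapping (:mod:`pdlrom.hyperelastic`); relaxation is carried by the
three-branch Prony function G(t) (:mod:`pdlrom.relaxation`).

Two response modes are first-class:

``separable``
    Y(t) = F(x(t)) * G(t), the product (separation-of-variables) form
    appropriate for a single test.

``hereditary``
    Y(t) = sum_i dF_i * G(t - t_i), the discrete quasi-linear
    superposition of force increments dF_i = F(x(t_i)) - F(x(t_{i-1}))
    on a fine uniform grid — the step-response sum written out.

The augmented response adds a ramp-rise-time (strain-rate) term
H = p10 * x * exp(-p11 * t_ramp) and a prior-test history term K built
from rectangular displacement pulses of the earlier tests, carried by
the slowest Prony branch only (the faster branches have decayed by more
than e^-C across any rest period).  K(0) is subtracted because the
measured force is tared at the start of each test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import lfilter

from .hyperelastic import HyperfoamParams, StressStrainMapping, force_from_displacement
from .protocols import MeasurementRecord, TestProtocol, _displacement_profile
from .relaxation import PronySeries, relaxation_modulus

__all__ = [
    "RomParams",
    "HistoryPulse",
    "PeakForce",
    "rate_term",
    "history_term",
    "campaign_pulses",
    "simulate_response",
    "peak_force",
    "goodness_r2",
    "default_dt",
]


@dataclass(frozen=True)
class RomParams:
    """Full augmented reduced-order-model parameter set.

    Composes the hyperelastic backbone, the force/displacement mapping,
    the Prony relaxation function, and the rate-term parameters
    ``p10`` (N/mm) and ``p11`` (1/s; tau_H = 1/p11).
    """

    hyper: HyperfoamParams
    mapping: StressStrainMapping
    prony: PronySeries
    p10: float = 0.0
    p11: float = 1.0

    def __post_init__(self) -> None:
        if self.p10 < 0:
            raise ValueError("p10 must be non-negative")
        if self.p11 <= 0:
            raise ValueError("p11 must be positive")
        if abs(self.prony.weight_sum() - 1.0) > 1e-9:
            raise ValueError("Prony weights must sum to 1 within 1e-9")

    @property
    def tau_rate(self) -> float:
        """e-folding ramp rise time of the rate term, 1/p11 in s."""
        return 1.0 / self.p11

    def elastic_force(self, x):
        """Elastic backbone force F(x) in N."""
        return force_from_displacement(self.hyper, self.mapping, x)


@dataclass(frozen=True)
class HistoryPulse:
    """Rectangular displacement pulse approximating one earlier test.

    Times are on the campaign clock (seconds since the first test
    started): the pulse holds ``d_ramp`` mm between ``t_ps`` (end of
    that test's ramp) and ``t_pe`` (end of that test's record).
    """

    t_ps: float
    t_pe: float
    d_ramp: float

    def __post_init__(self) -> None:
        if self.t_ps < 0 or self.t_pe <= self.t_ps:
            raise ValueError("need t_pe > t_ps >= 0")
        if self.d_ramp <= 0:
            raise ValueError("pulse height must be positive")


def campaign_pulses(protocols: Sequence[TestProtocol],
                    before_test_id: int) -> list[HistoryPulse]:
    """History pulses of all campaign tests preceding ``before_test_id``.

    One pulse per prior test: start at (test start + ramp time), end at
    (test start + record duration), height d_ramp.  Discarded tests are
    included — they loaded the specimen regardless.
    """
    return [
        HistoryPulse(t_ps=p.start_offset + p.t_ramp,
                     t_pe=p.start_offset + p.t_max,
                     d_ramp=p.d_ramp)
        for p in protocols
        if p.test_id < before_test_id
    ]


def rate_term(params: RomParams, x, t_ramp: float):
    """Ramp-rise-time force contribution H in N.

    H = p10 * x * exp(-p11 * t_ramp): proportional to the actuator
    displacement and decaying exponentially with ramp rise time (fast
    ramps harden the response).  For fixed x it does not vary with time
    within a test.
    """
    if t_ramp <= 0:
        raise ValueError("t_ramp must be positive")
    return params.p10 * np.asarray(x, dtype=float) * np.exp(-params.p11 * t_ramp)


def history_term(params: RomParams, pulses: Sequence[HistoryPulse],
                 t_start: float, t):
    """Residual-strain force contribution K(t) of earlier tests, in N.

    Each prior pulse of height d enters through the slowest Prony branch
    as F(d) * p6 * (e^(-p7 (t_start - t_ps + t)) - e^(-p7 (t_start -
    t_pe + t))), with t the current test's own clock.  Only the
    baseline-corrected K(t) - K(0) enters the response.

    Raises
    ------
    ValueError
        If any pulse ends at or after the current test start.
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros_like(t_arr, dtype=float)
    p6, p7 = params.prony.p6, params.prony.p7
    for pulse in pulses:
        if pulse.t_pe > t_start:
            raise ValueError(
                f"pulse ending at {pulse.t_pe} s overlaps test start {t_start} s")
        f_d = float(params.elastic_force(pulse.d_ramp))
        out += f_d * p6 * (np.exp(-p7 * (t_start - pulse.t_ps + t_arr))
                           - np.exp(-p7 * (t_start - pulse.t_pe + t_arr)))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def default_dt(protocol: TestProtocol) -> float:
    """Default fine-grid step: min(t_sample, t_ramp / 200)."""
    return min(protocol.t_sample, protocol.t_ramp / 200.0)


def _fine_grid(protocol: TestProtocol, dt: float) -> np.ndarray:
    n = int(np.ceil(protocol.t_max / dt))
    return np.arange(n + 1) * dt


def _response_on_grid(params: RomParams, protocol: TestProtocol,
                      pulses: Sequence[HistoryPulse], mode: str,
                      times: np.ndarray, dt: float) -> np.ndarray:
    """Augmented response Y on a uniform fine grid."""
    x = _displacement_profile(protocol, times)
    f = params.elastic_force(x)
    prony = params.prony
    if mode == "separable":
        visc = f * relaxation_modulus(prony, times)
    elif mode == "hereditary":
        # Sum of step responses dF_i * G(t - t_i).  With G a sum of
        # exponentials this is an exact one-pole recursion per branch:
        # S_b[j] = exp(-r_b dt) S_b[j-1] + w_b dF_j.
        df = np.diff(f, prepend=0.0)
        visc = prony.p1 * f
        for w, r in zip(prony.branch_weights, prony.rates):
            visc = visc + lfilter([w], [1.0, -np.exp(-r * dt)], df)
    else:
        raise ValueError("mode must be 'hereditary' or 'separable'")
    y = visc + rate_term(params, x, protocol.t_ramp)
    if pulses:
        k = history_term(params, pulses, protocol.start_offset, times)
        y = y + k - k[0]
    return y


def simulate_response(params: RomParams, protocol: TestProtocol,
                      pulses: Sequence[HistoryPulse] = (),
                      mode: str = "hereditary",
                      dt: float | None = None) -> MeasurementRecord:
    """Simulate the augmented model response of one test.

    The response is evaluated on a uniform fine grid of step ``dt``
    (default :func:`default_dt`) and linearly interpolated onto the
    protocol's sampling grid.  ``mode`` selects the hereditary
    superposition or the separable product form; both satisfy Y(0) = 0.

    Returns a :class:`~pdlrom.protocols.MeasurementRecord` whose
    displacements are the ideal actuator waveform.
    """
    if dt is None:
        dt = default_dt(protocol)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > protocol.t_sample:
        raise ValueError("dt must not exceed the protocol's t_sample")
    times = _fine_grid(protocol, dt)
    y = _response_on_grid(params, protocol, pulses, mode, times, dt)
    ts = protocol.sample_times
    return MeasurementRecord(
        protocol=protocol,
        times=ts,
        displacements=_displacement_profile(protocol, ts),
        forces=np.interp(ts, times, y),
    )


class PeakForce(NamedTuple):
    f_max: float
    t_peak: float


def peak_force(record: MeasurementRecord) -> PeakForce:
    """Maximum force and its time; ties broken by the earliest time."""
    if record.forces.size == 0:
        raise ValueError("empty record")
    idx = int(np.argmax(record.forces))
    return PeakForce(f_max=float(record.forces[idx]),
                     t_peak=float(record.times[idx]))


def goodness_r2(predicted: Sequence[MeasurementRecord],
                measured: Sequence[MeasurementRecord]) -> float:
    """Pooled coefficient of determination of predicted vs measured force.

    R^2 = 1 - SS_res / SS_tot with the residual and total sums pooled
    over every sample of every record and SS_tot taken about the pooled
    mean of the measured forces.  Every sample counts equally, so long
    records dominate.
    """
    if len(predicted) != len(measured) or not measured:
        raise ValueError("need equally many predicted and measured records")
    pred_all, meas_all = [], []
    for pred, meas in zip(predicted, measured):
        if pred.times.shape != meas.times.shape or not np.allclose(
                pred.times, meas.times):
            raise ValueError("predicted/measured sample grids differ")
        pred_all.append(pred.forces)
        meas_all.append(meas.forces)
    pred_vec = np.concatenate(pred_all)
    meas_vec = np.concatenate(meas_all)
    ss_res = float(np.sum((meas_vec - pred_vec) ** 2))
    ss_tot = float(np.sum((meas_vec - meas_vec.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot
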