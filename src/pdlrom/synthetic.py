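"""Synthetic measurement records and campaigns from known model parameters.

The generator wraps the reduced-order simulator: it produces records
with the statistical structure the identification stage assumes —
additive i.i.d. Gaussian force noise, scaled to each record's noiseless
peak, with the t = 0 sample re-zeroed to mimic the taring of the force
transducer at test start.  Whole campaigns are generated sequentially so
that every test inherits the residual-strain history of its
predecessors, exactly as the augmented model's history term prescribes.

Per-record random streams are derived deterministically from one master
seed and the test id, so single records and campaign members coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .protocols import MeasurementRecord, TestProtocol
from .rom import HistoryPulse, RomParams, simulate_response

__all__ = ["NoiseModel", "generate_record", "generate_campaign"]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise.

    ``relative_sd`` is the noise standard deviation as a fraction of the
    record's noiseless peak force (homoscedastic within a record);
    ``seed`` is the master seed from which per-record streams derive.
    """

    relative_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be non-negative")


def _record_rng(noise: NoiseModel, test_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(noise.seed), spawn_key=(int(test_id),)))


def generate_record(params: RomParams, protocol: TestProtocol,
                    pulses: Sequence[HistoryPulse] = (),
                    noise: NoiseModel = NoiseModel(),
                    mode: str = "hereditary",
                    dt: float | None = None) -> MeasurementRecord:
    """One simulated record with measurement noise and start-of-test taring.

    With ``relative_sd = 0`` the output equals the noiseless simulation.
    The same (seed, test_id) pair always yields the same record.
    """
    record = simulate_response(params, protocol, pulses, mode=mode, dt=dt)
    if noise.relative_sd == 0.0:
        return record
    rng = _record_rng(noise, protocol.test_id)
    sd = noise.relative_sd * float(np.max(np.abs(record.forces)))
    forces = record.forces + rng.normal(0.0, sd, size=record.forces.shape)
    # Taring nulls the static transducer offset at test start, so the
    # record begins exactly at zero; it does not shift later readings.
    forces[0] = 0.0
    return MeasurementRecord(protocol=protocol, times=record.times,
                             displacements=record.displacements, forces=forces)


def generate_campaign(params: RomParams, protocols: Sequence[TestProtocol],
                      noise: NoiseModel = NoiseModel(),
                      mode: str = "hereditary",
                      dt: float | None = None) -> list[MeasurementRecord]:
    """Sequentially simulate a whole campaign with accumulated history.

    Each test receives one history pulse per preceding test (including
    discarded ones).  Tests must not overlap in campaign time.
    """
    ordered = sorted(protocols, key=lambda p: p.start_offset)
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.start_offset + prev.t_max > nxt.start_offset:
            raise ValueError(
                f"tests {prev.test_id} and {nxt.test_id} overlap in time")
    records: list[MeasurementRecord] = []
    pulses: list[HistoryPulse] = []
    for protocol in ordered:
        records.append(generate_record(params, protocol, tuple(pulses),
                                       noise=noise, mode=mode, dt=dt))
        pulses.append(HistoryPulse(t_ps=protocol.start_offset + protocol.t_ramp,
                                   t_pe=protocol.start_offset + protocol.t_max,
                                   d_ramp=protocol.d_ramp))
    return records
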