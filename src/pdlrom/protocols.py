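"""Ramp-and-hold test protocols and sampled force records.

A relaxation test drives the actuator at constant speed ``v_ramp =
d_ramp / t_ramp`` up to the plateau displacement ``d_ramp`` and holds it
there while the reaction force decays.  A campaign is a sequence of such
tests on one specimen, each starting at a known clock time, so that
residual strains of earlier tests can be accounted for.

The module ships the 14-test reference campaign measured on a porcine
mandibular premolar specimen (buccal-lingual crown loading) together
with the recorded peak forces, and reads/writes sampled records as
delimited text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TestProtocol",
    "MeasurementRecord",
    "RecordFormatError",
    "actuator_displacement",
    "builtin_test_table",
    "campaign_table",
    "recorded_peaks",
    "read_record",
    "write_record",
    "save_campaign",
    "load_campaign",
]


class RecordFormatError(ValueError):
    """Raised when a record file does not conform to the CSV dialect."""


@dataclass(frozen=True)
class TestProtocol:
    """Timing and displacement parameters of one ramp-and-hold test.

    Parameters
    ----------
    test_id
        Integer label of the test within its campaign.
    t_ramp
        Ramp rise time in s.
    d_ramp
        Plateau actuator displacement in mm.
    t_sample
        Sampling interval of the recorded force in s.
    t_max
        Record duration in s (ramp plus hold).
    t_rest
        Rest time in s between the end of the previous test and the
        start of this one; ``None`` for the first test of a campaign.
    start_clock
        Time of day ("hh:mm") at which the test started, if known.
    start_offset
        Test start in seconds since the campaign reference time
        (start of the first test).
    discarded
        True if the measured record was discarded due to a protocol
        issue.  Discarded tests still contribute residual-strain
        history, so they remain part of the campaign description.
    """

    test_id: int
    t_ramp: float
    d_ramp: float
    t_sample: float
    t_max: float
    t_rest: float | None = None
    start_clock: str | None = None
    start_offset: float = 0.0
    discarded: bool = False

    def __post_init__(self) -> None:
        if self.t_ramp <= 0:
            raise ValueError("t_ramp must be positive")
        if self.d_ramp <= 0:
            raise ValueError("d_ramp must be positive")
        if not 0 < self.t_sample <= self.t_ramp:
            raise ValueError("t_sample must satisfy 0 < t_sample <= t_ramp")
        if self.t_max <= self.t_ramp:
            raise ValueError("t_max must exceed t_ramp")
        if self.start_offset < 0:
            raise ValueError("start_offset must be non-negative")

    @property
    def v_ramp(self) -> float:
        """Ramp speed in mm/s."""
        return self.d_ramp / self.t_ramp

    @property
    def sample_times(self) -> np.ndarray:
        """Uniform sampling grid 0, t_sample, ... up to t_max."""
        n = int(math.floor(self.t_max / self.t_sample)) + 1
        return np.arange(n) * self.t_sample


def actuator_displacement(protocol: TestProtocol, t):
    """Actuator displacement x(t) in mm of the ramp-and-hold waveform.

    Rises linearly at ``v_ramp`` until ``t_ramp``, then stays at
    ``d_ramp`` until ``t_max``.  Accepts a scalar or an array of times.

    Raises
    ------
    ValueError
        If any time lies outside [0, t_max].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > protocol.t_max):
        raise ValueError(f"time outside [0, {protocol.t_max}] s")
    x = _displacement_profile(protocol, t_arr)
    return float(x) if np.isscalar(t) or t_arr.ndim == 0 else x


def _displacement_profile(protocol: TestProtocol, t_arr: np.ndarray) -> np.ndarray:
    """Like :func:`actuator_displacement` but tolerant of t > t_max.

    Internal fine grids may overshoot t_max by less than one step; the
    hold value is returned there.
    """
    return protocol.v_ramp * np.minimum(t_arr, protocol.t_ramp)


@dataclass
class MeasurementRecord:
    """Sampled (time, actuator displacement, force) series of one test."""

    protocol: TestProtocol
    times: np.ndarray
    displacements: np.ndarray
    forces: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        n = self.times.size
        if n < 2 or self.displacements.size != n or self.forces.size != n:
            raise ValueError("record vectors must have equal length >= 2")
        if self.times[0] != 0.0:
            raise ValueError("record must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def peak_force(self) -> float:
        """Maximum recorded force in N."""
        return float(np.max(self.forces))

    @property
    def t_peak(self) -> float:
        """Time of the (earliest) maximum force in s."""
        return float(self.times[int(np.argmax(self.forces))])


# ---------------------------------------------------------------------------
# Reference campaign: 14 sequential ramp-and-hold tests on one porcine
# mandibular premolar specimen.  Columns: test id, start clock (hh:mm),
# t_ramp s, d_ramp mm, t_sample s, t_max s, t_Fmax s, F_max N, t_rest s
# (rest before the test; None for the first).  Tests 1 and 13 were
# discarded due to protocol issues but remain listed — they happened
# physically and load the specimen's strain history.
# ---------------------------------------------------------------------------
_CAMPAIGN_ROWS = [
    (1, "10:59", 5.0, 0.1, 0.2, 605.1, 5.4, 2.5, None, True),
    (2, "11:20", 5.0, 0.2, 0.2, 605.1, 6.4, 9.5, 655.0, False),
    (3, "12:21", 10.0, 0.1, 0.2, 610.1, 10.6, 1.6, 3055.0, False),
    (4, "12:36", 10.0, 0.2, 0.2, 610.1, 10.4, 8.1, 290.0, False),
    (5, "12:54", 20.0, 0.1, 0.2, 620.1, 21.0, 1.0, 470.0, False),
    (6, "13:14", 20.0, 0.2, 0.2, 620.1, 20.6, 6.7, 580.0, False),
    (7, "13:31", 30.0, 0.1, 0.2, 630.1, 30.6, 0.9, 400.0, False),
    (8, "13:49", 30.0, 0.2, 0.2, 630.1, 30.8, 5.9, 450.0, False),
    (9, "14:07", 60.0, 0.1, 0.2, 660.2, 60.5, 0.7, 450.0, False),
    (10, "14:30", 60.0, 0.2, 0.2, 660.1, 61.9, 4.6, 720.0, False),
    (11, "14:50", 120.0, 0.1, 0.5, 720.0, 120.2, 0.5, 540.0, False),
    (12, "15:12", 120.0, 0.2, 0.5, 720.0, 123.2, 4.3, 600.0, False),
    (13, "15:32", 300.0, 0.1, 0.5, 900.3, 191.3, 0.4, 480.0, True),
    (14, "15:57", 300.0, 0.2, 0.5, 900.3, 305.4, 3.8, 600.0, False),
]


def _clock_to_seconds(clock: str) -> int:
    hh, mm = clock.split(":")
    return (int(hh) * 60 + int(mm)) * 60


def builtin_test_table() -> list[TestProtocol]:
    """The packaged 14-test reference campaign.

    Start offsets are computed from the hh:mm clock column relative to
    the first test (10:59 -> 0 s).  Tests 1 and 13 carry
    ``discarded=True``.
    """
    ref = _clock_to_seconds(_CAMPAIGN_ROWS[0][1])
    protocols = []
    for (tid, clock, t_ramp, d_ramp, t_sample, t_max, _t_fmax, _f_max,
         t_rest, discarded) in _CAMPAIGN_ROWS:
        protocols.append(
            TestProtocol(
                test_id=tid,
                t_ramp=t_ramp,
                d_ramp=d_ramp,
                t_sample=t_sample,
                t_max=t_max,
                t_rest=t_rest,
                start_clock=clock,
                start_offset=float(_clock_to_seconds(clock) - ref),
                discarded=discarded,
            )
        )
    return protocols


def recorded_peaks() -> dict[int, tuple[float, float]]:
    """Measured peak forces of the reference campaign.

    Returns a mapping test_id -> (F_max in N, t_Fmax in s).
    """
    return {row[0]: (row[7], row[6]) for row in _CAMPAIGN_ROWS}


def campaign_table() -> pd.DataFrame:
    """The reference campaign as a tidy DataFrame (one row per test)."""
    protocols = builtin_test_table()
    peaks = recorded_peaks()
    rows = []
    for p in protocols:
        f_max, t_fmax = peaks[p.test_id]
        rows.append(
            {
                "test": p.test_id,
                "start_clock": p.start_clock,
                "start_offset_s": p.start_offset,
                "t_ramp_s": p.t_ramp,
                "d_ramp_mm": p.d_ramp,
                "t_sample_s": p.t_sample,
                "t_max_s": p.t_max,
                "t_Fmax_s": t_fmax,
                "F_max_N": f_max,
                "t_rest_s": p.t_rest,
                "discarded": p.discarded,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Record I/O: comma-separated, header `time_s,displacement_mm,force_N`,
# decimal point, UTF-8.
# ---------------------------------------------------------------------------
_COLUMNS = ["time_s", "displacement_mm", "force_N"]


def write_record(record: MeasurementRecord, path) -> None:
    """Write a record as CSV with full double precision."""
    df = pd.DataFrame(
        {
            "time_s": record.times,
            "displacement_mm": record.displacements,
            "force_N": record.forces,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_record(path, protocol: TestProtocol | None = None) -> MeasurementRecord:
    """Read a record written by :func:`write_record`.

    If no protocol is given, a minimal one is inferred from the data
    (plateau displacement, first time the plateau is reached, first
    sampling step, record duration).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise RecordFormatError(f"{path}: empty file") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise RecordFormatError(f"{path}: need at least 2 samples")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise RecordFormatError(f"{path}: time column not strictly increasing")
    disp = df["displacement_mm"].to_numpy(dtype=float)
    forces = df["force_N"].to_numpy(dtype=float)
    if protocol is None:
        protocol = _infer_protocol(times, disp)
    return MeasurementRecord(protocol=protocol, times=times,
                             displacements=disp, forces=forces)


def _infer_protocol(times: np.ndarray, disp: np.ndarray) -> TestProtocol:
    d_ramp = float(np.max(disp))
    at_plateau = np.nonzero(disp >= d_ramp * (1 - 1e-9))[0]
    t_ramp = float(times[at_plateau[0]]) if at_plateau.size else float(times[-1])
    t_ramp = max(t_ramp, float(times[1]))
    t_sample = float(times[1] - times[0])
    return TestProtocol(
        test_id=0,
        t_ramp=t_ramp,
        d_ramp=d_ramp if d_ramp > 0 else 1.0,
        t_sample=min(t_sample, t_ramp),
        t_max=float(times[-1]) if times[-1] > t_ramp else float(times[-1]) + t_sample,
    )


# ---------------------------------------------------------------------------
# Campaign descriptions as YAML config files.
# ---------------------------------------------------------------------------

def save_campaign(protocols: Sequence[TestProtocol], path) -> None:
    """Write a campaign description as a YAML file mirroring the schema."""
    payload = {
        "tests": [
            {
                "test_id": p.test_id,
                "start_clock": p.start_clock,
                "start_offset_s": p.start_offset,
                "t_ramp_s": p.t_ramp,
                "d_ramp_mm": p.d_ramp,
                "t_sample_s": p.t_sample,
                "t_max_s": p.t_max,
                "t_rest_s": p.t_rest,
                "discarded": p.discarded,
            }
            for p in protocols
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_campaign(path) -> list[TestProtocol]:
    """Read a campaign description written by :func:`save_campaign`."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not payload or "tests" not in payload:
        raise RecordFormatError(f"{path}: no 'tests' section")
    return [
        TestProtocol(
            test_id=int(row["test_id"]),
            t_ramp=float(row["t_ramp_s"]),
            d_ramp=float(row["d_ramp_mm"]),
            t_sample=float(row["t_sample_s"]),
            t_max=float(row["t_max_s"]),
            t_rest=None if row.get("t_rest_s") is None else float(row["t_rest_s"]),
            start_clock=row.get("start_clock"),
            start_offset=float(row.get("start_offset_s", 0.0)),
            discarded=bool(row.get("discarded", False)),
        )
        for row in payload["tests"]
    ]
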