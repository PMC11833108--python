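"""Two-stage parameter identification for the reduced order model.

Stage one is a full-factorial scan of the admissible parameter box: the
pooled R² of the simulated response against the records is evaluated at
every grid point and points clearing a gate (default 0.8) are ranked.
Stage two refines a candidate by damped nonlinear least squares
(Levenberg-Marquardt-type trust-region iterations on the pooled force
residual) under the relaxation-function constraints.

Constraints are enforced by construction rather than penalised where
possible:

* the weight simplex p1 + p2 + p4 + p6 = 1 holds exactly through a
  softmax map of three unconstrained logits;
* rate positivity and the separation factor C hold through the
  parameters (log p3, log(p3/(C p5)), log(p5/(C p7))) with box bounds
  log p3 <= log(1/t_min) and non-negative log-ratio excesses;
* the remaining bound p7 >= 1/t_max enters as a smooth hinge penalty
  residual (it is far from active for the campaigns of interest) and is
  verified on the returned parameters.

Identifiability: the backbone force scales as mu / p8, so when both are
requested free, mu is held at its start value, p8 absorbs the scale and
the composite mu/p8 is what the fit actually determines
(:attr:`FitResult.composite_scale`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .hyperelastic import HyperfoamParams, StressStrainMapping, beta_from_nu
from .protocols import MeasurementRecord
from .relaxation import ConstraintReport, PronySeries, validate_constraints
from .rom import (HistoryPulse, RomParams, _fine_grid, _response_on_grid,
                  campaign_pulses, default_dt)

__all__ = [
    "GridAxis",
    "GridSpec",
    "FitResult",
    "factorial_scan",
    "constrained_fit",
    "fit_individual",
    "parameter_stats",
    "fit_results_table",
]

#: parameter names accepted in free sets and grid axes
PARAM_NAMES = ("mu", "alpha", "nu", "p8", "p9", "prony_weights",
               "prony_rates", "p10", "p11")


# ---------------------------------------------------------------------------
# Record preparation: cache fine grids and sampled data once per fit.
# ---------------------------------------------------------------------------

@dataclass
class _PreparedRecord:
    record: MeasurementRecord
    pulses: tuple[HistoryPulse, ...]
    dt: float
    fine_times: np.ndarray

    def simulate(self, params: RomParams, mode: str) -> np.ndarray:
        y = _response_on_grid(params, self.record.protocol, self.pulses,
                              mode, self.fine_times, self.dt)
        return np.interp(self.record.times, self.fine_times, y)


def _prepare(records: Sequence[MeasurementRecord],
             pulses_per_record: Sequence[Sequence[HistoryPulse]] | None,
             dt: float | None) -> list[_PreparedRecord]:
    prepared = []
    for i, rec in enumerate(records):
        pulses = tuple(pulses_per_record[i]) if pulses_per_record else ()
        step = dt if dt is not None else default_dt(rec.protocol)
        prepared.append(_PreparedRecord(
            record=rec, pulses=pulses, dt=step,
            fine_times=_fine_grid(rec.protocol, step)))
    return prepared


def _pooled_r2(prepared: Sequence[_PreparedRecord], params: RomParams,
               mode: str) -> tuple[float, list[float]]:
    res, tot_meas = [], []
    per_test = []
    for p in prepared:
        pred = p.simulate(params, mode)
        meas = p.record.forces
        res.append(meas - pred)
        tot_meas.append(meas)
        ss_res = float(np.sum((meas - pred) ** 2))
        ss_tot = float(np.sum((meas - meas.mean()) ** 2))
        per_test.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0)
    res_vec = np.concatenate(res)
    meas_vec = np.concatenate(tot_meas)
    ss_tot = float(np.sum((meas_vec - meas_vec.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res_vec**2)) / ss_tot if ss_tot > 0 else 1.0
    return r2, per_test


# ---------------------------------------------------------------------------
# Factorial scan.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridAxis:
    """One scanned parameter: bounds, level count and spacing."""

    low: float
    high: float
    levels: int = 5
    log: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("bounds must be finite")
        if self.low >= self.high:
            raise ValueError("need low < high")
        if self.levels < 2:
            raise ValueError("need at least 2 levels")
        if self.log and self.low <= 0:
            raise ValueError("log axes need positive bounds")

    def values(self) -> np.ndarray:
        if self.log:
            return np.geomspace(self.low, self.high, self.levels)
        return np.linspace(self.low, self.high, self.levels)


@dataclass(frozen=True)
class GridSpec:
    """Scan specification: one axis per free scalar, plus the R² gate."""

    axes: dict[str, GridAxis]
    r2_gate: float = 0.8


def _with_updates(base: RomParams, updates: dict[str, float]) -> RomParams:
    """Rebuild RomParams with named scalar overrides.

    Scalars: mu, alpha, nu, p8, p9, p10, p11, tau1..tau3 (rates via
    1/tau), and individual weights are not scanned — the weight simplex
    is scanned through the fit stage only.
    """
    hyper = base.hyper
    mu = updates.get("mu", hyper.mu)
    alpha = updates.get("alpha", hyper.alpha)
    nu = updates.get("nu", hyper.nu)
    mapping = StressStrainMapping(p8=updates.get("p8", base.mapping.p8),
                                  p9=updates.get("p9", base.mapping.p9))
    pr = base.prony
    prony = PronySeries.from_taus(
        pr.p1, pr.p2, updates.get("tau1", pr.tau1),
        pr.p4, updates.get("tau2", pr.tau2),
        pr.p6, updates.get("tau3", pr.tau3), C=pr.C)
    return RomParams(
        hyper=HyperfoamParams(mu=mu, alpha=alpha, beta=beta_from_nu(nu)),
        mapping=mapping,
        prony=prony,
        p10=updates.get("p10", base.p10),
        p11=updates.get("p11", base.p11),
    )


def factorial_scan(records: Sequence[MeasurementRecord], grid: GridSpec,
                   base: RomParams, mode: str = "hereditary",
                   pulses_per_record=None, dt: float | None = None
                   ) -> list[tuple[dict[str, float], float]]:
    """Evaluate pooled R² on the full factorial grid and rank the survivors.

    Every combination of axis levels overrides the corresponding fields
    of ``base``; combinations with pooled R² above the gate are returned
    as (overrides, r2) sorted by descending R².  Deterministic; an empty
    admissible set yields an empty list.
    """
    if not records:
        raise ValueError("need at least one record")
    prepared = _prepare(records, pulses_per_record, dt)
    names = list(grid.axes)
    survivors = []
    for combo in itertools.product(*(grid.axes[n].values() for n in names)):
        updates = dict(zip(names, (float(v) for v in combo)))
        try:
            params = _with_updates(base, updates)
        except ValueError:
            continue
        r2, _ = _pooled_r2(prepared, params, mode)
        if r2 > grid.r2_gate:
            survivors.append((updates, r2))
    survivors.sort(key=lambda item: item[1], reverse=True)
    return survivors


# ---------------------------------------------------------------------------
# Constrained refinement.
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a constrained refinement."""

    params: RomParams
    r2: float
    per_test_r2: list[float]
    converged: bool
    constraint_report: ConstraintReport
    objective_history: list[float] = field(default_factory=list)
    nfev: int = 0
    free: tuple[str, ...] = ()
    composite_scale: float | None = None

    @property
    def mu_over_p8(self) -> float:
        """Composite backbone scale mu/p8 (N), the identifiable quantity."""
        return self.params.hyper.mu / self.params.mapping.p8


class _Transform:
    """Map between named free parameters and the optimizer vector."""

    def __init__(self, start: RomParams, free: Sequence[str],
                 t_min: float, t_max: float):
        unknown = set(free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
        self.free = tuple(free)
        self.start = start
        self.t_min = t_min
        self.t_max = t_max
        self.fit_scale_via_p8 = "mu" in self.free and "p8" in self.free
        self.names: list[str] = []
        x0, lo, hi = [], [], []

        def add(name, value, low=-np.inf, high=np.inf):
            self.names.append(name)
            x0.append(value)
            lo.append(low)
            hi.append(high)

        pr = start.prony
        if "prony_weights" in self.free:
            # three logits relative to p1; softmax restores the simplex
            for tag, w in (("z2", pr.p2), ("z4", pr.p4), ("z6", pr.p6)):
                add(tag, math.log(w / pr.p1))
        if "prony_rates" in self.free:
            add("log_p3", math.log(pr.p3), high=math.log(1.0 / t_min))
            add("s12", math.log(pr.p3 / (pr.C * pr.p5)), low=0.0)
            add("s23", math.log(pr.p5 / (pr.C * pr.p7)), low=0.0)
        if "mu" in self.free and not self.fit_scale_via_p8:
            add("log_mu", math.log(start.hyper.mu))
        if "alpha" in self.free:
            add("log_alpha", math.log(start.hyper.alpha))
        if "nu" in self.free:
            nu = start.hyper.nu
            add("logit_2nu", math.log(2 * nu / (1 - 2 * nu)))
        if "p8" in self.free or self.fit_scale_via_p8:
            add("log_p8", math.log(start.mapping.p8))
        if "p9" in self.free:
            add("log_p9", math.log(start.mapping.p9))
        if "p10" in self.free:
            add("log_p10", math.log(max(start.p10, 1e-12)))
        if "p11" in self.free:
            add("log_p11", math.log(start.p11))
        self.x0 = np.array(x0)
        self.bounds = (np.array(lo), np.array(hi))

    def _get(self, values: dict[str, float], name: str, fallback: float) -> float:
        return values.get(name, fallback)

    def unpack(self, x: np.ndarray) -> RomParams:
        v = dict(zip(self.names, x))
        start, pr = self.start, self.start.prony
        if "z2" in v:
            logits = np.array([0.0, v["z2"], v["z4"], v["z6"]])
            logits -= logits.max()
            w = np.exp(logits)
            w /= w.sum()
            p1, p2, p4, p6 = (float(wi) for wi in w)
        else:
            p1, p2, p4, p6 = pr.p1, pr.p2, pr.p4, pr.p6
        if "log_p3" in v:
            p3 = math.exp(v["log_p3"])
            p5 = p3 / (pr.C * math.exp(v["s12"]))
            p7 = p5 / (pr.C * math.exp(v["s23"]))
        else:
            p3, p5, p7 = pr.p3, pr.p5, pr.p7
        prony = PronySeries(p1=p1, p2=p2, p3=p3, p4=p4, p5=p5, p6=p6,
                            p7=p7, C=pr.C)
        mu = math.exp(v["log_mu"]) if "log_mu" in v else start.hyper.mu
        alpha = math.exp(v["log_alpha"]) if "log_alpha" in v else start.hyper.alpha
        if "logit_2nu" in v:
            nu = 0.5 / (1.0 + math.exp(-v["logit_2nu"]))
        else:
            nu = start.hyper.nu
        mapping = StressStrainMapping(
            p8=math.exp(v["log_p8"]) if "log_p8" in v else start.mapping.p8,
            p9=math.exp(v["log_p9"]) if "log_p9" in v else start.mapping.p9)
        return RomParams(
            hyper=HyperfoamParams(mu=mu, alpha=alpha, beta=beta_from_nu(nu)),
            mapping=mapping,
            prony=prony,
            p10=math.exp(v["log_p10"]) if "log_p10" in v else start.p10,
            p11=math.exp(v["log_p11"]) if "log_p11" in v else start.p11,
        )

    def penalty(self, params: RomParams, scale: float) -> np.ndarray:
        """Smooth hinge on the remaining bound p7 >= 1/t_max."""
        gap = math.log(1.0 / (params.prony.p7 * self.t_max))
        return np.array([scale * max(0.0, gap)])


def constrained_fit(records: Sequence[MeasurementRecord], start: RomParams,
                    free: Sequence[str] = ("prony_weights", "prony_rates",
                                           "p8", "p9"),
                    mode: str = "hereditary",
                    pulses_per_record=None,
                    t_min: float | None = None, t_max: float | None = None,
                    dt: float | None = None,
                    max_nfev: int | None = None) -> FitResult:
    """Refine ``start`` by constrained damped least squares.

    Minimises the pooled squared force residual over the requested free
    parameters (names from ``PARAM_NAMES``).  ``t_min``/``t_max``
    default to the smallest sampling interval and the longest record
    duration among the records.  Non-convergence returns the
    best-so-far with ``converged=False`` rather than raising.
    """
    if not records:
        raise ValueError("need at least one record")
    if t_min is None:
        t_min = min(r.protocol.t_sample for r in records)
    if t_max is None:
        t_max = max(r.protocol.t_max for r in records)
    prepared = _prepare(records, pulses_per_record, dt)
    start_report = validate_constraints(start.prony, t_min, t_max)
    if not start_report.all_pass:
        raise ValueError("start parameters violate the relaxation constraints")
    transform = _Transform(start, free, t_min, t_max)
    force_scale = max(float(np.max(np.abs(p.record.forces)))
                      for p in prepared)
    history: list[float] = []

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            params = transform.unpack(x)
        except (ValueError, OverflowError):
            return np.full(_n_res, 1e3 * force_scale)
        parts = [p.simulate(params, mode) - p.record.forces for p in prepared]
        parts.append(transform.penalty(params, 10.0 * force_scale))
        res = np.concatenate(parts)
        cost = float(np.sum(res**2))
        if not history or cost < history[-1]:
            history.append(cost)
        return res

    _n_res = sum(p.record.forces.size for p in prepared) + 1
    if transform.x0.size == 0:
        params = start
        r2, per_test = _pooled_r2(prepared, params, mode)
        return FitResult(params=params, r2=r2, per_test_r2=per_test,
                         converged=True,
                         constraint_report=start_report,
                         objective_history=history, nfev=0,
                         free=tuple(free))
    sol = least_squares(residuals, transform.x0, bounds=transform.bounds,
                        method="trf", x_scale="jac",
                        ftol=1e-12, xtol=1e-12, gtol=1e-12,
                        max_nfev=max_nfev)
    params = transform.unpack(sol.x)
    r2, per_test = _pooled_r2(prepared, params, mode)
    report = validate_constraints(params.prony, t_min, t_max)
    composite = (params.hyper.mu / params.mapping.p8
                 if transform.fit_scale_via_p8 else None)
    return FitResult(params=params, r2=r2, per_test_r2=per_test,
                     converged=bool(sol.success) and report.all_pass,
                     constraint_report=report,
                     objective_history=history, nfev=int(sol.nfev),
                     free=tuple(free), composite_scale=composite)


def fit_individual(record: MeasurementRecord,
                   fixed_hyper: HyperfoamParams,
                   start: RomParams | None = None,
                   mode: str = "separable",
                   dt: float | None = None,
                   max_nfev: int | None = None) -> FitResult:
    """Fit the product-form model to a single record.

    The constitutive parameters stay frozen at ``fixed_hyper``; free are
    the relaxation weights and rates and the mapping scales p8, p9.  No
    rate or history term is used (p10 = 0, single-test setting).
    """
    if start is None:
        proto = record.protocol
        tau1 = max(4.0, 2.0 * proto.t_sample)
        start = RomParams(
            hyper=fixed_hyper,
            mapping=StressStrainMapping(p8=0.01, p9=0.8),
            prony=PronySeries.from_taus(0.35, 0.25, tau1, 0.15, 10.0 * tau1,
                                        0.25, 100.0 * tau1),
            p10=0.0, p11=1.0,
        )
    else:
        start = RomParams(hyper=fixed_hyper, mapping=start.mapping,
                          prony=start.prony, p10=0.0, p11=start.p11)
    return constrained_fit([record], start,
                           free=("prony_weights", "prony_rates", "p8", "p9"),
                           mode=mode, dt=dt, max_nfev=max_nfev)


# ---------------------------------------------------------------------------
# Summary statistics.
# ---------------------------------------------------------------------------

def fit_results_table(results: Sequence[FitResult]):
    """Tabulate named parameters of several fits (one row per fit)."""
    import pandas as pd

    rows = []
    for res in results:
        p, pr = res.params, res.params.prony
        rows.append({
            "p1": pr.p1, "p2": pr.p2, "tau1": pr.tau1,
            "p4": pr.p4, "tau2": pr.tau2, "p6": pr.p6, "tau3": pr.tau3,
            "p8": p.mapping.p8, "p9": p.mapping.p9, "r2": res.r2,
        })
    return pd.DataFrame(rows)


def parameter_stats(table) -> "pd.DataFrame":
    """Column-wise mean and sample standard deviation (n-1 denominator).

    Accepts a DataFrame of per-fit parameters (or a sequence of
    :class:`FitResult`, tabulated first).  Requires at least two rows.
    """
    import pandas as pd

    if not isinstance(table, pd.DataFrame):
        table = fit_results_table(table)
    if len(table) < 2:
        raise ValueError("need at least two rows for a standard deviation")
    numeric = table.select_dtypes("number")
    return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=1)}).T
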