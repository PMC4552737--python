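"""Stochastic per-case simulator of the FNAB sampling process.

This module replays the sampling model event by event — Bernoulli needle
passes, imperfect on-site adequacy calls, repeat procedures — and serves
as the brute-force cross-check for every closed form in
:mod:`rosecost.sampling` and :mod:`rosecost.economics`, as well as the
package's synthetic-data generator.

Event semantics (ROSE): each pass yields truly adequate material with
probability p; the cytologist calls it adequate with probability sn if it
is, and with probability 1-sp if it is not.  Sampling stops at the
n_rose-th positive call.  The procedure succeeds iff at least one
*collected* sample is truly adequate — an adequate sample miscalled
negative still rescues the case once the laboratory processes it.  Fixed
protocol: exactly n_fixed passes, success iff any is adequate.  Failed
procedures repeat until success or the safety cap.

Scalar entry points (:func:`simulate_procedure`, :func:`simulate_case`)
keep a per-pass event log; the bulk entry points vectorize over many
cases for Monte Carlo summaries and are what the oracle tests use.  One
explicitly seeded generator drives each run; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .economics import CostInputs, OperationalInputs, variable_rate
from .sampling import FIXED, ROSE, TechnicalInputs, PROTOCOLS

DEFAULT_MAX_PASSES = 10_000
DEFAULT_MAX_PROCEDURES = 1_000

__all__ = [
    "SimConfig",
    "CaseRecord",
    "ProcedureResult",
    "SamplingSummary",
    "EmpiricalPolicy",
    "simulate_procedure",
    "simulate_case",
    "simulate_sampling",
    "simulate_policy_cost",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run.

    The safety caps only exist to bound degenerate parameter choices; at
    default settings truncation is vanishingly rare (< 1e-6) and is
    counted and reported, never silent.
    """

    technical: TechnicalInputs
    protocol: str
    n_cases: int
    seed: int
    max_passes_per_procedure: int = DEFAULT_MAX_PASSES
    max_procedures_per_case: int = DEFAULT_MAX_PROCEDURES

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.max_passes_per_procedure < 1 or self.max_procedures_per_case < 1:
            raise ValueError("safety caps must be >= 1")


class ProcedureResult(NamedTuple):
    success: bool
    passes: int
    truncated: bool
    #: per-pass (truly_adequate, called_positive) events; empty unless record=True
    log: tuple[tuple[bool, bool], ...]


@dataclass(frozen=True)
class CaseRecord:
    """Outcome of one simulated case (procedures repeated until success)."""

    passes_total: int
    procedures: int
    adequate_obtained: bool
    truncated: bool
    log: tuple[tuple[bool, bool], ...]

    def __post_init__(self) -> None:
        assert self.procedures >= 1 and self.passes_total >= self.procedures


def simulate_procedure(
    t: TechnicalInputs,
    protocol: str,
    rng: np.random.Generator,
    max_passes: int = DEFAULT_MAX_PASSES,
    record: bool = False,
) -> ProcedureResult:
    """Simulate a single procedure pass by pass."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")
    log: list[tuple[bool, bool]] = []
    any_adequate = False
    passes = 0
    positive_calls = 0
    while True:
        passes += 1
        adequate = bool(rng.random() < t.p)
        if adequate:
            called = bool(rng.random() < t.sn)
        else:
            called = bool(rng.random() < 1.0 - t.sp)
        any_adequate = any_adequate or adequate
        if record:
            log.append((adequate, called))
        if protocol == FIXED:
            if passes >= t.n_fixed:
                return ProcedureResult(any_adequate, passes, False, tuple(log))
        else:
            positive_calls += called
            if positive_calls >= t.n_rose:
                return ProcedureResult(any_adequate, passes, False, tuple(log))
        if passes >= max_passes:
            return ProcedureResult(any_adequate, passes, True, tuple(log))


def simulate_case(
    t: TechnicalInputs,
    protocol: str,
    rng: np.random.Generator,
    max_passes: int = DEFAULT_MAX_PASSES,
    max_procedures: int = DEFAULT_MAX_PROCEDURES,
    record: bool = False,
) -> CaseRecord:
    """Repeat simulated procedures until one succeeds (or the case cap)."""
    passes_total = 0
    procedures = 0
    truncated = False
    log: list[tuple[bool, bool]] = []
    while True:
        result = simulate_procedure(t, protocol, rng, max_passes=max_passes, record=record)
        procedures += 1
        passes_total += result.passes
        truncated = truncated or result.truncated
        log.extend(result.log)
        if result.success:
            return CaseRecord(passes_total, procedures, True, truncated, tuple(log))
        if procedures >= max_procedures:
            return CaseRecord(passes_total, procedures, False, True, tuple(log))


def _bulk_procedures_fixed(
    t: TechnicalInputs, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    adequate = rng.random((n, t.n_fixed)) < t.p
    success = adequate.any(axis=1)
    passes = np.full(n, t.n_fixed, dtype=np.int64)
    return success, passes, 0


def _bulk_procedures_rose(
    t: TechnicalInputs, n: int, rng: np.random.Generator, max_passes: int
) -> tuple[np.ndarray, np.ndarray, int]:
    passes = np.zeros(n, dtype=np.int64)
    positive = np.zeros(n, dtype=np.int64)
    any_adequate = np.zeros(n, dtype=bool)
    active = np.arange(n)
    truncated = 0
    while active.size:
        m = active.size
        adequate = rng.random(m) < t.p
        u = rng.random(m)
        called = np.where(adequate, u < t.sn, u < 1.0 - t.sp)
        passes[active] += 1
        any_adequate[active] |= adequate
        positive[active] += called
        done = positive[active] >= t.n_rose
        capped = passes[active] >= max_passes
        truncated += int(np.count_nonzero(capped & ~done))
        active = active[~(done | capped)]
    return any_adequate, passes, truncated


@dataclass(frozen=True)
class _RunArrays:
    """Raw per-case arrays plus per-procedure aggregates for one run."""

    procedures: np.ndarray
    passes_total: np.ndarray
    success: np.ndarray
    n_procedures: int
    n_successes: int
    sum_passes: float
    sumsq_passes: float
    truncated_procedures: int
    truncated_cases: int


def _run(cfg: SimConfig) -> _RunArrays:
    rng = np.random.default_rng(cfg.seed)
    t = cfg.technical
    n = cfg.n_cases
    procedures = np.zeros(n, dtype=np.int64)
    passes_total = np.zeros(n, dtype=np.int64)
    success = np.zeros(n, dtype=bool)
    n_procedures = 0
    n_successes = 0
    sum_passes = 0.0
    sumsq_passes = 0.0
    truncated_procedures = 0
    active = np.arange(n)
    for _ in range(cfg.max_procedures_per_case):
        if not active.size:
            break
        if cfg.protocol == FIXED:
            succ, passes, trunc = _bulk_procedures_fixed(t, active.size, rng)
        else:
            succ, passes, trunc = _bulk_procedures_rose(
                t, active.size, rng, cfg.max_passes_per_procedure
            )
        procedures[active] += 1
        passes_total[active] += passes
        n_procedures += active.size
        n_successes += int(succ.sum())
        sum_passes += float(passes.sum())
        sumsq_passes += float((passes.astype(float) ** 2).sum())
        truncated_procedures += trunc
        success[active[succ]] = True
        active = active[~succ]
    return _RunArrays(
        procedures=procedures,
        passes_total=passes_total,
        success=success,
        n_procedures=n_procedures,
        n_successes=n_successes,
        sum_passes=sum_passes,
        sumsq_passes=sumsq_passes,
        truncated_procedures=truncated_procedures,
        truncated_cases=int((~success).sum()),
    )


@dataclass(frozen=True)
class SamplingSummary:
    """Empirical sampling performance with Monte Carlo standard errors.

    ``adequacy`` and ``mean_passes`` are per *procedure*;
    ``mean_procedures`` is per case.
    """

    adequacy: float
    adequacy_se: float
    mean_passes: float
    mean_passes_se: float
    mean_procedures: float
    mean_procedures_se: float
    n_cases: int
    n_procedures: int
    truncated_procedures: int
    truncated_cases: int


def _summarize(run: _RunArrays, n_cases: int) -> SamplingSummary:
    n_proc = run.n_procedures
    adequacy = run.n_successes / n_proc
    adequacy_se = float(np.sqrt(adequacy * (1.0 - adequacy) / n_proc))
    mean_passes = run.sum_passes / n_proc
    var_passes = max(run.sumsq_passes / n_proc - mean_passes**2, 0.0)
    mean_passes_se = float(np.sqrt(var_passes / n_proc))
    mean_procs = float(run.procedures.mean())
    mean_procs_se = (
        float(run.procedures.std(ddof=1) / np.sqrt(n_cases)) if n_cases > 1 else 0.0
    )
    return SamplingSummary(
        adequacy=adequacy,
        adequacy_se=adequacy_se,
        mean_passes=mean_passes,
        mean_passes_se=mean_passes_se,
        mean_procedures=mean_procs,
        mean_procedures_se=mean_procs_se,
        n_cases=n_cases,
        n_procedures=n_proc,
        truncated_procedures=run.truncated_procedures,
        truncated_cases=run.truncated_cases,
    )


def simulate_sampling(cfg: SimConfig) -> SamplingSummary:
    """Simulate ``n_cases`` cases and summarize the sampling performance."""
    return _summarize(_run(cfg), cfg.n_cases)


@dataclass(frozen=True)
class EmpiricalPolicy:
    """Monte Carlo analogue of a :class:`~rosecost.economics.PolicyOutcome`."""

    protocol: str
    sampling: SamplingSummary
    t_sample: float
    t_sample_se: float
    cost_per_procedure: float
    cost_per_procedure_se: float
    cost_per_case: float
    cost_per_case_se: float


def simulate_policy_cost(
    cfg: SimConfig, o: OperationalInputs, c: CostInputs
) -> EmpiricalPolicy:
    """Simulate cases and cost each one from its event counts.

    Per-case cost = procedures x (setup-time cost + fixed cost)
    + passes x (pass-time cost + per-pass cost), with the protocol's
    effective hourly rate applied to both time terms.
    """
    run = _run(cfg)
    summary = _summarize(run, cfg.n_cases)
    rate = variable_rate(c, cfg.protocol)
    t_pass = o.t_pass_fixed if cfg.protocol == FIXED else o.t_pass_rose
    per_procedure_cost = o.t_setup / 60.0 * rate + c.cost_fixed
    per_pass_cost = t_pass / 60.0 * rate + c.cost_per_pass
    case_costs = run.procedures * per_procedure_cost + run.passes_total * per_pass_cost
    n = cfg.n_cases
    cost_se = float(case_costs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    # per-procedure quantities are linear in passes-per-procedure, so their
    # standard errors propagate by the same factor
    return EmpiricalPolicy(
        protocol=cfg.protocol,
        sampling=summary,
        t_sample=summary.mean_passes * t_pass,
        t_sample_se=summary.mean_passes_se * t_pass,
        cost_per_procedure=per_procedure_cost + summary.mean_passes * per_pass_cost,
        cost_per_procedure_se=summary.mean_passes_se * per_pass_cost,
        cost_per_case=float(case_costs.mean()),
        cost_per_case_se=cost_se,
    )
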