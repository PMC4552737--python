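"""Procedure-time and micro-costing models.

The operational model splits a procedure into two periods, setup and
sampling; sampling time is the expected number of passes times the
per-pass time.  The cost model is a bottom-up micro-costing: a
time-proportional (variable) cost at an effective hourly rate, a fixed
per-procedure cost, and an expected per-needle-pass cost that bundles
supplies with probability-weighted adverse events.  Expected cost per
*case* is cost per procedure times the expected number of procedures,
because failed procedures are repeated.

Durations are stored in minutes and hourly rates in currency per hour;
the conversion happens exactly once, at the rate product.  Currency is an
abstract unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .sampling import (
    FIXED,
    ROSE,
    PROTOCOLS,
    SamplingPerformance,
    TechnicalInputs,
    performance,
)

SOCIETAL = "societal"
PROVIDER = "provider"
PERSPECTIVES = (SOCIETAL, PROVIDER)

__all__ = [
    "SOCIETAL",
    "PROVIDER",
    "PERSPECTIVES",
    "OperationalInputs",
    "CostInputs",
    "PolicyOutcome",
    "sampling_time",
    "procedure_time",
    "variable_rate",
    "cost_per_procedure",
    "cost_per_case",
    "evaluate_policy",
    "cost_difference",
]


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class OperationalInputs:
    """Durations of the two procedure periods, in minutes.

    ``t_setup`` is shared by both protocols (setting up an image-guided
    suite does not depend on whether ROSE is used); the per-pass times
    differ because ROSE pauses for the on-site assessment, so typically
    ``t_pass_rose >= t_pass_fixed`` (violations only warn).
    """

    t_setup: float
    t_pass_fixed: float
    t_pass_rose: float

    def __post_init__(self) -> None:
        _check_nonneg("t_setup", self.t_setup)
        _check_nonneg("t_pass_fixed", self.t_pass_fixed)
        _check_nonneg("t_pass_rose", self.t_pass_rose)
        if self.t_pass_rose < self.t_pass_fixed:
            warnings.warn(
                "t_pass_rose < t_pass_fixed: ROSE passes are usually slower "
                "because each pass awaits an on-site assessment",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CostInputs:
    """Unit costs and the analytic perspective.

    ``rate_other`` carries the full hourly cost of the non-cytologist
    procedure team (proceduralist, assistants, room opportunity cost);
    ``rate_cytologist`` is the extra hourly cost ROSE adds.  Under the
    societal perspective the patient's hourly time cost ``rate_patient``
    is added to either protocol's rate; the provider perspective drops it.

    ``fixed_rate_override`` / ``rose_rate_override`` replace the composed
    pre-patient hourly total for settings where the staffing does not
    decompose that way (e.g. a simple palpation-guided FNAB where the
    cytologist *performs* the aspiration, so ROSE adds no extra rate).
    ``rate_patient`` is still added on top under the societal perspective.
    """

    rate_cytologist: float
    rate_other: float
    rate_patient: float
    cost_fixed: float
    cost_per_pass: float
    perspective: str = SOCIETAL
    fixed_rate_override: float | None = None
    rose_rate_override: float | None = None

    def __post_init__(self) -> None:
        for name in ("rate_cytologist", "rate_other", "rate_patient", "cost_fixed", "cost_per_pass"):
            _check_nonneg(name, getattr(self, name))
        for name in ("fixed_rate_override", "rose_rate_override"):
            value = getattr(self, name)
            if value is not None:
                _check_nonneg(name, value)
        if self.perspective not in PERSPECTIVES:
            raise ValueError(
                f"perspective must be one of {PERSPECTIVES}, got {self.perspective!r}"
            )


@dataclass(frozen=True)
class PolicyOutcome:
    """All model outcomes for one sampling policy.

    Times are in minutes; ``cost_variable`` is the expected time-based
    cost per procedure, ``cost_per_procedure`` adds fixed and per-pass
    costs, and ``cost_per_case`` multiplies by the expected number of
    procedures per diagnosed case.
    """

    protocol: str
    sampling: SamplingPerformance
    t_sample: float
    t_procedure: float
    cost_variable: float
    cost_per_procedure: float
    cost_per_case: float


def sampling_time(expected_passes: float, t_pass: float) -> float:
    """Expected duration of the sampling period: passes x minutes per pass."""
    return expected_passes * t_pass


def procedure_time(o: OperationalInputs, t_sample: float) -> float:
    """Total procedure duration: setup plus sampling, in minutes."""
    return o.t_setup + t_sample


def variable_rate(c: CostInputs, protocol: str) -> float:
    """Effective hourly rate for one protocol under the chosen perspective."""
    if protocol == FIXED:
        rate = c.fixed_rate_override if c.fixed_rate_override is not None else c.rate_other
    elif protocol == ROSE:
        rate = (
            c.rose_rate_override
            if c.rose_rate_override is not None
            else c.rate_other + c.rate_cytologist
        )
    else:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    if c.perspective == SOCIETAL:
        rate = rate + c.rate_patient
    return rate


def cost_per_procedure(
    perf: SamplingPerformance, o: OperationalInputs, c: CostInputs, protocol: str
) -> float:
    """Expected cost of one procedure.

    (t_setup + t_sample)/60 x hourly rate + fixed cost + passes x per-pass cost.
    """
    t_pass = o.t_pass_fixed if protocol == FIXED else o.t_pass_rose
    t_sample = sampling_time(perf.expected_passes, t_pass)
    var = procedure_time(o, t_sample) / 60.0 * variable_rate(c, protocol)
    return var + c.cost_fixed + perf.expected_passes * c.cost_per_pass


def cost_per_case(cost_procedure: float, expected_procedures: float) -> float:
    """Expected cost per diagnosed case: procedure cost x expected procedures."""
    if expected_procedures < 1.0:
        raise ValueError(
            f"expected_procedures must be >= 1, got {expected_procedures!r}"
        )
    return cost_procedure * expected_procedures


def evaluate_policy(
    t: TechnicalInputs, o: OperationalInputs, c: CostInputs, protocol: str
) -> PolicyOutcome:
    """Run the full pipeline (sampling -> time -> cost) for one policy."""
    perf = performance(t, protocol)
    t_pass = o.t_pass_fixed if protocol == FIXED else o.t_pass_rose
    t_sample = sampling_time(perf.expected_passes, t_pass)
    t_proc = procedure_time(o, t_sample)
    rate = variable_rate(c, protocol)
    cost_var = t_proc / 60.0 * rate
    cpp = cost_var + c.cost_fixed + perf.expected_passes * c.cost_per_pass
    return PolicyOutcome(
        protocol=protocol,
        sampling=perf,
        t_sample=t_sample,
        t_procedure=t_proc,
        cost_variable=cost_var,
        cost_per_procedure=cpp,
        cost_per_case=cost_per_case(cpp, perf.expected_procedures),
    )


def cost_difference(rose: PolicyOutcome, fixed: PolicyOutcome) -> float:
    """Expected cost per case with ROSE minus with fixed sampling.

    Negative values favour ROSE.  Both outcomes must come from the same
    scenario's shared parameters; the protocol tags are checked to catch
    swapped arguments.
    """
    if rose.protocol != ROSE or fixed.protocol != FIXED:
        raise ValueError(
            "cost_difference expects (rose_outcome, fixed_outcome); got "
            f"protocols ({rose.protocol!r}, {fixed.protocol!r})"
        )
    return rose.cost_per_case - fixed.cost_per_case
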