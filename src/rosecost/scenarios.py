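"""Scenario catalogue and paired fixed-vs-ROSE comparisons.

A *scenario* is one cell of the experiment grid: a procedure type
(simple = palpation guided, complex = image guided), a per-pass adequacy
level (low p = 0.3, high p = 0.6 at base), and a pair of stopping rules
(n_F fixed passes vs n_R required adequate calls).  Enumerating n_F over
2..5 and n_R over 1..2 yields the full 32-scenario catalogue.

Each scenario bundles the 11 parameters that the cost difference depends
on (c_np, c_fixed, c_pat, c_var_c, c_var_o, n_F, n_R, p, t_pass_F,
t_pass_R, t_setup), each with a base value and a plausible range for
sensitivity analysis.  The cytologist's accuracy (sn, sp) is carried as a
scenario-level constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import pandas as pd

from . import sampling
from .config import load_config
from .economics import (
    SOCIETAL,
    CostInputs,
    OperationalInputs,
    PolicyOutcome,
    cost_difference,
    evaluate_policy,
)
from .sampling import FIXED, ROSE, TechnicalInputs

#: canonical names of the 11 parameters the cost difference depends on
PARAM_NAMES = (
    "c_np",
    "c_fixed",
    "c_pat",
    "c_var_c",
    "c_var_o",
    "n_F",
    "n_R",
    "p",
    "t_pass_F",
    "t_pass_R",
    "t_setup",
)

#: the subset that varies continuously in sensitivity analysis (the two
#: stopping rules define scenario identity and stay fixed)
CONTINUOUS_PARAMS = tuple(n for n in PARAM_NAMES if n not in ("n_F", "n_R"))

PROCEDURE_TYPES = ("simple", "complex")
ADEQUACY_LEVELS = ("low", "high")

__all__ = [
    "PARAM_NAMES",
    "CONTINUOUS_PARAMS",
    "PROCEDURE_TYPES",
    "ADEQUACY_LEVELS",
    "ParameterSpec",
    "Scenario",
    "ComparisonResult",
    "build_catalogue",
    "find_scenario",
    "to_inputs",
    "compare",
    "base_case_table",
    "catalogue_frame",
]


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: base value plus the range used in sensitivity analysis."""

    name: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.name not in PARAM_NAMES:
            raise ValueError(
                f"unknown parameter {self.name!r}; valid symbols: {', '.join(PARAM_NAMES)}"
            )
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: require low <= base <= high, got "
                f"{self.low}, {self.base}, {self.high}"
            )


@dataclass(frozen=True)
class Scenario:
    """One named cell of the experiment grid.

    Identity is the 4-tuple (procedure_type, adequacy_level, n_fixed,
    n_rose).  ``parameters`` maps each of the 11 canonical symbols to its
    :class:`ParameterSpec`.  ``rose_adds_cytologist`` encodes the staffing
    rule: when False (simple procedures) the cytologist performs the FNAB,
    so both protocols cost ``c_var_o + c_var_c`` per hour; when True
    (complex procedures) the fixed protocol costs ``c_var_o`` and ROSE
    adds the cytologist.  ``rose_rate_override`` pins the pre-patient
    ROSE hourly total directly instead.
    """

    procedure_type: str
    adequacy_level: str
    n_fixed: int
    n_rose: int
    # hash=False: the mapping participates in equality but not in the hash,
    # which is computed from the hashable identity/constant fields
    parameters: Mapping[str, ParameterSpec] = field(hash=False)
    sn: float = 0.95
    sp: float = 0.975
    rose_adds_cytologist: bool = True
    rose_rate_override: float | None = None
    index: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.procedure_type not in PROCEDURE_TYPES:
            raise ValueError(f"procedure_type must be one of {PROCEDURE_TYPES}")
        if self.adequacy_level not in ADEQUACY_LEVELS:
            raise ValueError(f"adequacy_level must be one of {ADEQUACY_LEVELS}")
        if set(self.parameters) != set(PARAM_NAMES):
            missing = set(PARAM_NAMES) - set(self.parameters)
            extra = set(self.parameters) - set(PARAM_NAMES)
            raise ValueError(
                f"parameters must cover exactly the 11 model symbols; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        object.__setattr__(self, "parameters", MappingProxyType(dict(self.parameters)))

    @property
    def label(self) -> str:
        return (
            f"{self.procedure_type}-{self.adequacy_level}"
            f"-nF{self.n_fixed}-nR{self.n_rose}"
        )

    def base_values(self) -> dict[str, float]:
        return {name: spec.base for name, spec in self.parameters.items()}


@dataclass(frozen=True)
class ComparisonResult:
    """Paired evaluation of one scenario: ROSE vs fixed, with rose-minus-fixed deltas."""

    scenario: Scenario
    rose: PolicyOutcome
    fixed: PolicyOutcome
    delta_cost: float
    deltas: Mapping[str, float]


def _spec(name: str, node: Mapping) -> ParameterSpec:
    return ParameterSpec(name, float(node["base"]), float(node["low"]), float(node["high"]))


def build_catalogue(config: str | Mapping | None = None) -> list[Scenario]:
    """Build the deterministic scenario catalogue from a configuration.

    ``config`` may be a packaged name ('paper-base' by default), a file
    path, or an already-loaded configuration mapping.  Ordering follows
    the experiment grid: procedure type, then adequacy level, then n_R,
    then n_F; scenarios are numbered 1..N in that order.
    """
    if config is None:
        config = "paper-base"
    if isinstance(config, str):
        config = load_config(config)

    shared = config["shared"]
    rules = config["stopping_rules"]
    levels = config["adequacy_levels"]
    sn = float(config["cytologist"]["sn"]["base"])
    sp = float(config["cytologist"]["sp"]["base"])
    nf_lo, nf_hi = int(rules["n_F"]["low"]), int(rules["n_F"]["high"])
    nr_lo, nr_hi = int(rules["n_R"]["low"]), int(rules["n_R"]["high"])

    catalogue: list[Scenario] = []
    index = 1
    for ptype, block in config["procedure_types"].items():
        for level in ADEQUACY_LEVELS:
            for n_rose in range(nr_lo, nr_hi + 1):
                for n_fixed in range(nf_lo, nf_hi + 1):
                    params = {
                        "p": _spec("p", levels[level]),
                        "n_F": ParameterSpec("n_F", n_fixed, nf_lo, nf_hi),
                        "n_R": ParameterSpec("n_R", n_rose, nr_lo, nr_hi),
                        "t_pass_F": _spec("t_pass_F", shared["t_pass_F_min"]),
                        "t_pass_R": _spec("t_pass_R", shared["t_pass_R_min"]),
                        "c_var_c": _spec("c_var_c", shared["c_var_c_per_hr"]),
                        "c_pat": _spec("c_pat", shared["c_pat_per_hr"]),
                        "t_setup": _spec("t_setup", block["t_setup_min"]),
                        "c_var_o": _spec("c_var_o", block["c_var_o_per_hr"]),
                        "c_np": _spec("c_np", block["c_np_per_pass"]),
                        "c_fixed": _spec("c_fixed", block["c_fixed"]),
                    }
                    override = block.get("c_var_R_total_per_hr")
                    catalogue.append(
                        Scenario(
                            procedure_type=ptype,
                            adequacy_level=level,
                            n_fixed=n_fixed,
                            n_rose=n_rose,
                            parameters=params,
                            sn=sn,
                            sp=sp,
                            rose_adds_cytologist=block.get("rose_adds_cytologist", True),
                            rose_rate_override=float(override) if override is not None else None,
                            index=index,
                        )
                    )
                    index += 1
    return catalogue


def find_scenario(
    catalogue: list[Scenario],
    procedure_type: str,
    adequacy_level: str,
    n_fixed: int,
    n_rose: int,
) -> Scenario:
    """Look up the unique scenario with the given identity 4-tuple."""
    matches = [
        s
        for s in catalogue
        if (s.procedure_type, s.adequacy_level, s.n_fixed, s.n_rose)
        == (procedure_type, adequacy_level, n_fixed, n_rose)
    ]
    if len(matches) != 1:
        raise KeyError(
            f"expected exactly one scenario ({procedure_type}, {adequacy_level}, "
            f"nF={n_fixed}, nR={n_rose}); found {len(matches)}"
        )
    return matches[0]


def to_inputs(
    scenario: Scenario,
    values: Mapping[str, float] | None = None,
    perspective: str = SOCIETAL,
) -> tuple[TechnicalInputs, OperationalInputs, CostInputs]:
    """Assemble model inputs for one scenario, optionally overriding parameter values.

    ``values`` maps canonical symbols to replacement values (used by the
    sensitivity module); unspecified parameters stay at base.
    """
    v = scenario.base_values()
    if values:
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(
                f"unknown parameter names {sorted(unknown)}; "
                f"valid symbols: {', '.join(PARAM_NAMES)}"
            )
        v.update(values)
    tech = TechnicalInputs(
        p=v["p"], sn=scenario.sn, sp=scenario.sp,
        n_fixed=int(v["n_F"]), n_rose=int(v["n_R"]),
    )
    oper = OperationalInputs(
        t_setup=v["t_setup"], t_pass_fixed=v["t_pass_F"], t_pass_rose=v["t_pass_R"]
    )
    fixed_override = None if scenario.rose_adds_cytologist else v["c_var_o"] + v["c_var_c"]
    cost = CostInputs(
        rate_cytologist=v["c_var_c"],
        rate_other=v["c_var_o"],
        rate_patient=v["c_pat"],
        cost_fixed=v["c_fixed"],
        cost_per_pass=v["c_np"],
        perspective=perspective,
        fixed_rate_override=fixed_override,
        rose_rate_override=scenario.rose_rate_override,
    )
    return tech, oper, cost


def compare(scenario: Scenario, perspective: str = SOCIETAL) -> ComparisonResult:
    """Evaluate both policies at base values and report rose-minus-fixed deltas."""
    tech, oper, cost = to_inputs(scenario, perspective=perspective)
    rose = evaluate_policy(tech, oper, cost, ROSE)
    fixed = evaluate_policy(tech, oper, cost, FIXED)
    delta = cost_difference(rose, fixed)
    deltas = {
        "cost_per_case": delta,
        "expected_passes": rose.sampling.expected_passes - fixed.sampling.expected_passes,
        "adequacy": rose.sampling.adequacy - fixed.sampling.adequacy,
        "expected_procedures": (
            rose.sampling.expected_procedures - fixed.sampling.expected_procedures
        ),
        "cost_per_procedure": rose.cost_per_procedure - fixed.cost_per_procedure,
        "t_sample": rose.t_sample - fixed.t_sample,
    }
    return ComparisonResult(
        scenario=scenario, rose=rose, fixed=fixed, delta_cost=delta, deltas=deltas
    )


# (outcome label, PolicyOutcome accessor, decimals for display)
_TABLE_ROWS = (
    ("expected total cost per case ($)", lambda o: o.cost_per_case, 0),
    ("needle passes per procedure", lambda o: o.sampling.expected_passes, 1),
    ("adequacy rate", lambda o: o.sampling.adequacy, 2),
    ("procedures per diagnosis", lambda o: o.sampling.expected_procedures, 2),
    ("cost per procedure ($)", lambda o: o.cost_per_procedure, 0),
    ("duration of sample period (min)", lambda o: o.t_sample, 1),
)


def base_case_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Render paired comparisons as a report table, one column per scenario.

    Rows come in blocks of three (rose / fixed / difference) per outcome.
    All arithmetic happens at full precision; rounding is applied exactly
    once here, at render time.
    """
    columns: dict[str, list[float]] = {}
    rows: list[tuple[str, str]] = []
    first = True
    for result in results:
        cells: list[float] = []
        for name, accessor, nd in _TABLE_ROWS:
            r, f = accessor(result.rose), accessor(result.fixed)
            for tag, value in (("rose", r), ("fixed", f), ("difference", r - f)):
                if first:
                    rows.append((name, tag))
                cells.append(round(value, nd) if nd else round(value))
        columns[result.scenario.label] = cells
        first = False
    frame = pd.DataFrame(
        columns, index=pd.MultiIndex.from_tuples(rows, names=["outcome", "policy"])
    )
    return frame


def catalogue_frame(catalogue: list[Scenario]) -> pd.DataFrame:
    """Flatten a catalogue to one row per scenario with all base values."""
    records = []
    for s in catalogue:
        rec = {
            "index": s.index,
            "label": s.label,
            "procedure_type": s.procedure_type,
            "adequacy_level": s.adequacy_level,
            "n_F": s.n_fixed,
            "n_R": s.n_rose,
            "sn": s.sn,
            "sp": s.sp,
        }
        for name in PARAM_NAMES:
            if name in ("n_F", "n_R"):
                continue
            rec[name] = s.parameters[name].base
        records.append(rec)
    return pd.DataFrame.from_records(records)


def adequacy_dominance(scenario: Scenario) -> bool:
    """True when ROSE's per-case adequacy exceeds the fixed protocol's at base."""
    tech, _, _ = to_inputs(scenario)
    return sampling.adequacy_rose(tech.p, tech.sp, tech.n_rose) > sampling.adequacy_fixed(
        tech.p, tech.n_fixed
    )
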