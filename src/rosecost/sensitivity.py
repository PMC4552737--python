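"""One-way (tornado) and probabilistic (Monte Carlo) sensitivity analysis.

Both analyses perturb the cost difference per case, ΔTC = TC^R − TC^F,
around a scenario's base values.  One-way analysis moves a single
parameter to each end of its plausible range with everything else at
base; the resulting spans, sorted descending, are the bars of a tornado
diagram.  Probabilistic sensitivity analysis draws all continuous
parameters jointly — independent uniforms over [low, high] by default,
the minimal-information choice when only ranges are stated — and pushes
every draw through the full closed-form pipeline.  The stopping rules
n_F and n_R define scenario identity and are never drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from . import sampling
from .economics import SOCIETAL
from .scenarios import CONTINUOUS_PARAMS, PARAM_NAMES, Scenario

logger = logging.getLogger(__name__)

#: signature of a pluggable per-parameter sampler: (rng, low, high, size) -> draws
Sampler = Callable[[np.random.Generator, float, float, int], np.ndarray]

__all__ = ["OneWayResult", "MonteCarloResult", "delta_total_cost", "one_way", "probabilistic"]


@dataclass(frozen=True)
class OneWayResult:
    """ΔTC at the two ends of one parameter's range; span = |high − low|."""

    parameter: str
    delta_at_low: float
    delta_at_high: float
    span: float


@dataclass(frozen=True)
class MonteCarloResult:
    """Per-draw ΔTC values and their summary for one scenario."""

    scenario_label: str
    n_draws: int
    seed: int
    deltas: np.ndarray
    summary: Mapping[str, float]


def delta_total_cost(
    scenario: Scenario,
    values: Mapping[str, float | np.ndarray] | None = None,
    perspective: str = SOCIETAL,
):
    """ΔTC per case for one scenario, vectorized over parameter arrays.

    ``values`` maps canonical parameter symbols to scalars or equal-length
    arrays; unspecified parameters stay at base.  The computation mirrors
    :func:`rosecost.economics.evaluate_policy` exactly (a unit test holds
    the two routes together) but broadcasts elementwise, which makes the
    100,000-draw Monte Carlo analysis effectively instantaneous.
    """
    v: dict[str, float | np.ndarray] = scenario.base_values()
    if values:
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(
                f"unknown parameter names {sorted(unknown)}; "
                f"valid symbols: {', '.join(PARAM_NAMES)}"
            )
        v.update(values)
    n_fixed, n_rose = int(v["n_F"]), int(v["n_R"])
    p = v["p"]
    sn, sp = scenario.sn, scenario.sp

    adequacy_f = sampling.adequacy_fixed(p, n_fixed)
    passes_f = float(n_fixed)
    adequacy_r = sampling.adequacy_rose(p, sp, n_rose)
    passes_r = sampling._expected_passes_rose(p, sn, sp, n_rose)

    if scenario.rose_adds_cytologist:
        rate_f = v["c_var_o"]
        rate_r = v["c_var_o"] + v["c_var_c"]
    else:
        rate_f = rate_r = v["c_var_o"] + v["c_var_c"]
    if scenario.rose_rate_override is not None:
        rate_r = scenario.rose_rate_override
    if perspective == SOCIETAL:
        rate_f = rate_f + v["c_pat"]
        rate_r = rate_r + v["c_pat"]

    cost_f = (
        (v["t_setup"] + passes_f * v["t_pass_F"]) / 60.0 * rate_f
        + v["c_fixed"]
        + passes_f * v["c_np"]
    ) / adequacy_f
    cost_r = (
        (v["t_setup"] + passes_r * v["t_pass_R"]) / 60.0 * rate_r
        + v["c_fixed"]
        + passes_r * v["c_np"]
    ) / adequacy_r
    return cost_r - cost_f


def one_way(scenario: Scenario, perspective: str = SOCIETAL) -> list[OneWayResult]:
    """Tornado analysis: ΔTC at each continuous parameter's range ends.

    Returns one result per parameter, ordered by descending span (ties
    broken by name).  The integer stopping rules are skipped — varying
    them changes which scenario is being compared, not how uncertain the
    comparison is.
    """
    results = []
    for name in PARAM_NAMES:
        if name in ("n_F", "n_R"):
            logger.info("one_way: skipping %s (defines scenario identity)", name)
            continue
        spec = scenario.parameters[name]
        at_low = float(delta_total_cost(scenario, {name: spec.low}, perspective))
        at_high = float(delta_total_cost(scenario, {name: spec.high}, perspective))
        results.append(OneWayResult(name, at_low, at_high, abs(at_high - at_low)))
    results.sort(key=lambda r: (-r.span, r.parameter))
    return results


def _uniform(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    if low == high:
        return np.full(size, float(low))
    return rng.uniform(low, high, size)


def probabilistic(
    scenario: Scenario,
    n_draws: int = 100_000,
    seed: int | np.random.Generator = 0,
    perspective: str = SOCIETAL,
    distributions: Mapping[str, Sampler] | None = None,
    quantiles: Sequence[float] = (2.5, 25.0, 50.0, 75.0, 97.5),
) -> MonteCarloResult:
    """Monte Carlo sensitivity analysis of ΔTC for one scenario.

    All nine continuous parameters are drawn independently — uniform over
    [low, high] unless ``distributions`` supplies another sampler for a
    parameter — and ΔTC is computed for every draw.  Reproducible for a
    given integer seed.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    distributions = dict(distributions or {})
    unknown = set(distributions) - set(CONTINUOUS_PARAMS)
    if unknown:
        raise ValueError(
            f"distributions given for unknown/non-continuous parameters {sorted(unknown)}"
        )
    draws: dict[str, np.ndarray] = {}
    for name in CONTINUOUS_PARAMS:  # fixed order => reproducible stream use
        spec = scenario.parameters[name]
        sampler = distributions.get(name, _uniform)
        draws[name] = np.asarray(sampler(rng, spec.low, spec.high, n_draws), dtype=float)
    deltas = np.atleast_1d(np.asarray(delta_total_cost(scenario, draws, perspective), float))
    qs = np.percentile(deltas, quantiles)
    summary = {
        "mean": float(deltas.mean()),
        "sd": float(deltas.std(ddof=1)) if n_draws > 1 else 0.0,
        **{f"q{q:g}": float(val) for q, val in zip(quantiles, qs)},
        "fraction_favoring_rose": float(np.mean(deltas < 0.0)),
    }
    return MonteCarloResult(
        scenario_label=scenario.label,
        n_draws=n_draws,
        seed=seed if isinstance(seed, int) else -1,
        deltas=deltas,
        summary=summary,
    )
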