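"""Closed-form sampling performance of FNAB protocols with and without ROSE.

The sampling model treats every needle pass as an independent Bernoulli
trial with a constant per-pass probability ``p`` of yielding a sample that
is adequate for cytologic diagnosis.  Two stopping rules are modelled:

* **fixed** -- the aspirator always takes exactly ``n_fixed`` passes;
* **rose** -- a cytologist assesses each pass on site (rapid on-site
  evaluation) and sampling stops once ``n_rose`` passes have been *called*
  adequate.  The on-site call is imperfect, with sensitivity ``sn`` and
  specificity ``sp`` relative to the final laboratory assessment.  A false
  positive call can terminate sampling on inadequate material; a false
  negative call costs an unnecessary extra pass.

A *procedure* (one sitting) succeeds when at least one truly adequate
sample was collected; failed procedures are repeated, so the expected
number of procedures per diagnosed case is the reciprocal of the per-case
adequacy rate.

All closed forms accept NumPy arrays in place of the scalar probability
arguments and broadcast elementwise, which is what the sensitivity-analysis
module relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

FIXED = "fixed"
ROSE = "rose"
PROTOCOLS = (FIXED, ROSE)

__all__ = [
    "FIXED",
    "ROSE",
    "PROTOCOLS",
    "TechnicalInputs",
    "SamplingPerformance",
    "binomial_pmf",
    "adequacy_fixed",
    "adequacy_rose",
    "expected_passes_fixed",
    "expected_passes_rose",
    "expected_procedures",
    "performance",
]


def _check_protocol(protocol: str) -> None:
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")


def _check_prob(name: str, value: float, *, allow_zero: bool = False) -> None:
    lo_ok = value >= 0.0 if allow_zero else value > 0.0
    if not (lo_ok and value <= 1.0):
        bound = "[0, 1]" if allow_zero else "(0, 1]"
        raise ValueError(f"{name} must lie in {bound}, got {value!r}")


def _check_count(name: str, value: int) -> None:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    if value < 1:
        raise ValueError(f"{name} must be >= 1, got {value!r}")


@dataclass(frozen=True)
class TechnicalInputs:
    """Technical inputs of the sampling model.

    Parameters
    ----------
    p
        Per-pass adequacy probability (0 < p <= 1).
    sn, sp
        Sensitivity and specificity of the on-site cytologic adequacy call
        relative to the final laboratory assessment (each in (0, 1]).
    n_fixed
        Number of needle passes taken by the fixed protocol.
    n_rose
        Number of positive adequacy calls after which ROSE sampling stops.
        Treated as preset before the procedure; adaptive stopping is out of
        scope.
    """

    p: float
    sn: float = 0.95
    sp: float = 0.975
    n_fixed: int = 3
    n_rose: int = 1

    def __post_init__(self) -> None:
        _check_prob("p", self.p)
        _check_prob("sn", self.sn)
        _check_prob("sp", self.sp)
        _check_count("n_fixed", self.n_fixed)
        _check_count("n_rose", self.n_rose)


@dataclass(frozen=True)
class SamplingPerformance:
    """Per-case sampling performance of one protocol.

    ``adequacy`` is the probability that a single procedure yields at least
    one truly adequate sample; ``expected_passes`` is the expected number
    of needle passes per procedure; ``expected_procedures`` (= 1/adequacy)
    is the expected number of procedures needed per diagnosed case when
    failed procedures are repeated.
    """

    adequacy: float
    expected_passes: float
    expected_procedures: float


def binomial_pmf(k: int, n: int, p: float) -> float:
    """P(X = k) for X ~ Binomial(n, p): C(n, k) p^k (1-p)^(n-k)."""
    _check_count("n", n)
    if isinstance(k, bool) or not isinstance(k, (int, np.integer)):
        raise TypeError(f"k must be an integer, got {k!r}")
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    _check_prob("p", p, allow_zero=True)
    return float(stats.binom.pmf(k, n, p))


def adequacy_fixed(p, n_fixed):
    """Per-case adequacy of a fixed protocol: 1 - (1-p)^n_fixed.

    The procedure fails only if all ``n_fixed`` independent passes fail.
    """
    return 1.0 - (1.0 - p) ** n_fixed


def adequacy_rose(p, sp, n_rose):
    """Per-case adequacy under ROSE with an imperfect cytologist.

    Sampling stops at the ``n_rose``-th positive call.  The case fails only
    if every collected sample is truly inadequate, i.e. each positive call
    was a false positive and every sample in between was inadequate and
    (correctly) called negative.  The per-stopping-stage failure odds are
    (1-sp)(1-p) / (1 - sp(1-p)), whence

        adequacy = 1 - [(1-sp)(1-p) / (1 - sp(1-p))]^n_rose.

    Independent of ``sn``: adequate samples miscalled negative merely
    prolong sampling, they still rescue the case.
    """
    fail = ((1.0 - sp) * (1.0 - p)) / (1.0 - sp * (1.0 - p))
    return 1.0 - fail**n_rose


def expected_passes_fixed(n_fixed):
    """Expected passes of the fixed protocol: exactly ``n_fixed`` (no variation)."""
    return float(n_fixed)


def expected_passes_rose(t: TechnicalInputs) -> float:
    """Expected passes until ROSE stops: n_rose / ((1-sp)(1-p) + p sn).

    The denominator is the per-pass probability of a positive call (true or
    false), so the pass count is negative binomial with ``n_rose`` required
    successes.
    """
    return float(_expected_passes_rose(t.p, t.sn, t.sp, t.n_rose))


def _expected_passes_rose(p, sn, sp, n_rose):
    denom = (1.0 - sp) * (1.0 - p) + p * sn
    if np.any(np.asarray(denom) <= 0.0):
        raise ValueError(
            "positive-call probability (1-sp)(1-p) + p*sn must be > 0; "
            "ROSE sampling would never stop"
        )
    return n_rose / denom


def expected_procedures(adequacy):
    """Expected procedures per case: 1/adequacy (failed procedures repeat)."""
    if np.any(np.asarray(adequacy) <= 0.0):
        raise ValueError("adequacy must be > 0")
    return 1.0 / adequacy


def performance(t: TechnicalInputs, protocol: str) -> SamplingPerformance:
    """Bundle adequacy, expected passes and expected procedures for one protocol."""
    _check_protocol(protocol)
    if protocol == FIXED:
        adequacy = float(adequacy_fixed(t.p, t.n_fixed))
        passes = expected_passes_fixed(t.n_fixed)
    else:
        adequacy = float(adequacy_rose(t.p, t.sp, t.n_rose))
        passes = expected_passes_rose(t)
    return SamplingPerformance(
        adequacy=adequacy,
        expected_passes=passes,
        expected_procedures=float(expected_procedures(adequacy)),
    )
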