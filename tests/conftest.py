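import pytest

import rosecost as rc


@pytest.fixture(scope="session")
def catalogue():
    return rc.build_catalogue("paper-base")


@pytest.fixture(scope="session")
def base_cases(catalogue):
    """The four headline scenarios: n_F=3, n_R=1 for each (type, level)."""
    return {
        (t, lvl): rc.find_scenario(catalogue, t, lvl, 3, 1)
        for t in ("simple", "complex")
        for lvl in ("low", "high")
    }


@pytest.fixture
def complex_base_inputs():
    """Complex-procedure base inputs: the ones behind the $558 fixed-protocol cell."""
    tech = rc.TechnicalInputs(p=0.6, sn=0.95, sp=0.975, n_fixed=3, n_rose=1)
    oper = rc.OperationalInputs(t_setup=30.0, t_pass_fixed=2.0, t_pass_rose=9.0)
    cost = rc.CostInputs(
        rate_cytologist=100.0,
        rate_other=260.0,
        rate_patient=20.0,
        cost_fixed=300.0,
        cost_per_pass=30.0,
    )
    return tech, oper, cost
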