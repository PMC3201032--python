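import pytest

import scgma


@pytest.fixture(scope="session")
def net_a():
    return scgma.model_a()


@pytest.fixture(scope="session")
def net_b():
    return scgma.model_b()


@pytest.fixture(scope="session")
def net_mm():
    return scgma.mm_chain()


@pytest.fixture(scope="session")
def gma_a(net_a):
    return scgma.recast_sc(net_a)


@pytest.fixture(scope="session")
def gma_b(net_b):
    return scgma.recast_sc(net_b)


@pytest.fixture(scope="session")
def gma_mm(net_mm):
    return scgma.recast_rational(net_mm)


@pytest.fixture(scope="session")
def basal_a(net_a):
    return scgma.basal_state(net_a)


class SolutionCache:
    """Solve each reference scenario once per test session and share it."""

    def __init__(self, gma, basal):
        self.gma = gma
        self.basal = basal
        self._cache = {}

    def get(self, scen_name: str, objective: str) -> scgma.GlobalSolution:
        key = (scen_name, objective)
        if key not in self._cache:
            scen = scgma.scenario(scen_name, objective)
            problem = scgma.build_problem(self.gma, scen, basal=self.basal)
            if scen.cardinality is not None:
                sol = scgma.solve_with_cardinality(problem, time_limit=240.0)
            else:
                sol = scgma.solve_global(problem, time_limit=120.0)
            self._cache[key] = sol
        return self._cache[key]


@pytest.fixture(scope="session")
def solutions(gma_a, basal_a):
    return SolutionCache(gma_a, basal_a)
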