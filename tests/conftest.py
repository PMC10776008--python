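import numpy as np
import pytest

from scwforge.assembly import ScenarioSpec, assemble_scenario, compress_to_density
from scwforge.builders import (
    FibrilSpec,
    LigninSpec,
    XylanSpec,
    build_cellulose_fibril,
    build_lignin,
    build_xylan,
)
from scwforge.core import Structure


@pytest.fixture(scope="session")
def default_fibril():
    return build_cellulose_fibril(FibrilSpec())


@pytest.fixture(scope="session")
def small_fibril():
    return build_cellulose_fibril(FibrilSpec(dp=8))


@pytest.fixture(scope="session")
def xylan_twofold():
    return build_xylan(XylanSpec())


@pytest.fixture(scope="session")
def xylan_threefold():
    return build_xylan(XylanSpec(conformation="threefold"))


@pytest.fixture(scope="session")
def lignin_default():
    structure, linkages = build_lignin(LigninSpec(), seed=11)
    return structure, linkages


def _toy_spec(scenario, seed=1, **kw):
    kw.setdefault("n_xylan", 8)
    kw.setdefault("n_lignin", 12)
    return ScenarioSpec(
        scenario=scenario, n_fibrils=2, fibril_dp=10, xylan_dp=10, seed=seed, **kw
    )


@pytest.fixture(scope="session")
def toy_models():
    """Small 2-fibril builds for the a / d / e scenario comparisons."""
    out = {}
    for sc in ("a", "d", "e"):
        structure, report = assemble_scenario(_toy_spec(sc))
        out[sc] = (structure, report)
    return out


@pytest.fixture(scope="session")
def toy_models_compressed(toy_models):
    return {
        sc: compress_to_density(structure, 1.5, seed=1)
        for sc, (structure, _rep) in toy_models.items()
    }


@pytest.fixture(scope="session")
def scenario_counts():
    """Full-count assemblies (shortened chains, dp=10) for the composition
    checks; chain counts are independent of the degree of polymerization."""
    out = {}
    for sc in ("a", "b", "b.8", "b.10"):
        structure, report = assemble_scenario(
            ScenarioSpec(scenario=sc, fibril_dp=10, xylan_dp=10, seed=0)
        )
        out[sc] = (structure, report)
    return out


@pytest.fixture(scope="session")
def toy_trapped():
    """b.8-style toy with trapped xylan between two fibrils."""
    structure, report = assemble_scenario(_toy_spec("b.8", n_xylan=10))
    return structure, report


def random_periodic_structure(rng, n, box):
    """Helper used by proximity tests: n carbon atoms in a periodic box."""
    pos = rng.uniform(-2 * max(box), 3 * max(box), (n, 3))
    return Structure(
        pos,
        ["C"] * n,
        ["C1"] * n,
        np.arange(n) % 9 + 1,
        ["GLC"] * n,
        np.zeros(n, dtype=int),
        ["cellulose"] * n,
        box=np.asarray(box, dtype=float),
        periodic=True,
    )
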