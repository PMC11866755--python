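import numpy as np
import pytest

from cphlab.dynamics import IntegratorConfig
from cphlab.model import ThermoContext
from cphlab.scenarios import ScenarioSpec, make_scenario, run_titration


@pytest.fixture(scope="session")
def thermo():
    return ThermoContext()


@pytest.fixture(scope="session")
def single_scenario():
    """Calibrated Glu-like single-site system (reference pKa 4.40)."""
    return make_scenario(ScenarioSpec(tag="single", seed=1))


@pytest.fixture(scope="session")
def tautomer_scenario():
    """Calibrated dual-lambda His-like site (micro pKa 6.53 / 6.92)."""
    return make_scenario(ScenarioSpec(tag="tautomer", seed=1))


@pytest.fixture(scope="session")
def pair_scenario_uncoupled():
    return make_scenario(ScenarioSpec(tag="coupled_pair", coupling_w=0.0, seed=2))


@pytest.fixture(scope="session")
def pair_scenario_anticooperative():
    return make_scenario(ScenarioSpec(tag="coupled_pair", coupling_w=10.0, seed=2))


@pytest.fixture(scope="session")
def mini_titration(single_scenario):
    """Short titration of the single-site system (5 pH x 4 replicas x 1 ns)."""
    return run_titration(single_scenario, n_replicas=4, duration=1000.0,
                         config=IntegratorConfig(), keep_trajectories=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def conf_fma_data():
    """FMA model + binned-titration items for a conformation-coupled site.

    The generator injects a 2.0 pKa-unit shift between the two basins of a
    slow conformational coordinate; configurations are the coordinate plus
    three pure-noise dimensions.  Items are (projection, deprotonated, pH,
    replica, configurations) per trajectory.
    """
    import numpy as np

    from cphlab.fma import fit_fma, project

    rng = np.random.default_rng(99)
    scen = make_scenario(ScenarioSpec(tag="conformation_coupled", seed=3,
                                      delta_pka=2.0))
    ds = run_titration(scen, ph_values=[3.9, 4.4, 4.9, 5.4, 5.9, 6.4],
                       n_replicas=6, duration=1200.0)

    def features(t):
        keep = ~t.censored
        c = t.conf[keep]
        noise = rng.standard_normal((c.shape[0], 3)) * 0.3
        return np.hstack([c, noise]), t.column("SITE1:p")[keep]

    train = [t for t in ds.trajectories if t.metadata["pH"] == 4.4]
    xs, ys, reps = [], [], []
    for t in train:
        x, y = features(t)
        xs.append(x)
        ys.append(y)
        reps.append(np.full(len(y), t.metadata["replica"]))
    model = fit_fma(np.vstack(xs), np.concatenate(ys), np.concatenate(reps),
                    rng=np.random.default_rng(11))
    items = []
    for t in ds.trajectories:
        x, y = features(t)
        items.append((project(x, model), y >= 0.5, t.metadata["pH"],
                      t.metadata["replica"], x))
    return model, items
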