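import numpy as np
import pytest

from apneadbn.clg import DBNStructure, build_lagged_table, fit_mle
from apneadbn.simulate import GeneratorParams, generate_protocol


@pytest.fixture(scope="session")
def protocol():
    return generate_protocol(n_rats=5, seed=11)


@pytest.fixture(scope="session")
def hmm_like_model():
    """A small fitted CLG DBN with a hidden binary chain driving RR and DS."""
    rng = np.random.default_rng(7)
    n = 1500
    ap = np.zeros(n, dtype=int)
    for t in range(1, n):
        ap[t] = int(rng.random() < (0.9 if ap[t - 1] else 0.06))
    rr = np.zeros(n)
    ds = np.zeros(n)
    for t in range(1, n):
        rr[t] = 0.6 * rr[t - 1] + 1.4 * ap[t] + rng.normal(0, 0.5)
        ds[t] = 0.5 * ds[t - 1] - 1.1 * ap[t] + rng.normal(0, 0.5)
    kinds = {"Ap": "discrete", "RR": "continuous", "DS": "continuous"}
    struct = DBNStructure(kinds, 3, {
        (("Ap", 1), ("Ap", 0)),
        (("RR", 1), ("RR", 0)),
        (("DS", 1), ("DS", 0)),
        (("Ap", 0), ("RR", 0)),
        (("Ap", 0), ("DS", 0)),
    })
    data = build_lagged_table({"Ap": ap, "RR": rr, "DS": ds}, 3)
    model = fit_mle(struct, data, pseudocount=0.5)
    series = {"Ap": ap, "RR": rr, "DS": ds}
    return model, series


def random_clg_model(seed: int, order: int = 2):
    """A randomized small CLG DBN for oracle batteries."""
    rng = np.random.default_rng(seed)
    kinds = {"Ap": "discrete", "RR": "continuous"}
    arcs = {(("Ap", 1), ("Ap", 0)), (("Ap", 0), ("RR", 0))}
    if order >= 2 and rng.random() < 0.5:
        arcs.add((("Ap", 2), ("Ap", 0)))
    if rng.random() < 0.7:
        arcs.add((("RR", 1), ("RR", 0)))
    if rng.random() < 0.4:
        arcs.add((("Ap", min(order, 1)), ("RR", 0)))
    struct = DBNStructure(kinds, order, arcs)

    from apneadbn.clg import (CLGModel, ContinuousNodeParams,
                              DiscreteNodeParams)
    import itertools

    params = {}
    dp = struct.parents("Ap")
    cpt = {}
    for cfg in itertools.product([0, 1], repeat=len(dp)):
        p1 = rng.uniform(0.05, 0.95)
        cpt[cfg] = np.array([1 - p1, p1])
    params["Ap"] = DiscreteNodeParams(dp, [0, 1], cpt)
    cp = struct.continuous_parents("RR")
    dpr = struct.discrete_parents("RR")
    table = {}
    for cfg in itertools.product([0, 1], repeat=len(dpr)):
        table[cfg] = (rng.normal(0, 1), rng.normal(0, 0.5, size=len(cp)),
                      rng.uniform(0.3, 1.2))
    params["RR"] = ContinuousNodeParams(cp, dpr, table)
    prior = {"Ap": np.array([0.7, 0.3])}
    return CLGModel(structure=struct, params=params, prior=prior,
                    states={"Ap": [0, 1]})
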