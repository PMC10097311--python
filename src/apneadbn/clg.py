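"""Conditional linear Gaussian dynamic Bayesian networks.

The joint distribution over all nodes factorizes into per-node conditionals,
``P(X) = prod_i P(X_i | pa(X_i))``. Discrete nodes carry multinomial
conditional probability tables and may have only discrete parents; a
continuous node Z with discrete parents z_D and continuous parents z_C is
Gaussian with a mean linear in its continuous parents and parameters switched
by the discrete configuration:

    f(z | z_D, z_C) = N(z; alpha(z_D) + beta(z_D)' z_C, sigma^2(z_D)).

For any fixed discrete configuration the continuous nodes are therefore
jointly multivariate normal.

Time is unrolled into slices, one per heartbeat. The structure is
time-homogeneous: arcs and parameters are tied across slices, arcs never run
from the present into the past, and learned parents attach only to lag-0
nodes. The Markov order L bounds the deepest parent lag. The likelihood is
the transition likelihood conditional on the first L slices; no separate
initial-slice model is learned.

Parameter fitting is by maximum likelihood: per discrete-parent
configuration, ordinary least squares for continuous nodes with the residual
SD taken with divisor n (the ML estimator), and empirical frequencies with a
configurable pseudocount for discrete nodes. The BIC used for model
selection is ``loglik - k/2 * log(n)`` (larger is better) and decomposes
node-wise.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "DBNStructure",
    "ContinuousNodeParams",
    "DiscreteNodeParams",
    "CLGModel",
    "StructureError",
    "ModelError",
    "col_name",
    "build_lagged_table",
    "clg_logdensity",
    "fit_mle",
    "joint_loglik",
    "bic_score",
    "node_bic",
    "sample_model",
    "save_model",
    "load_model",
]

Node = tuple[str, int]  # (variable name, lag); lag 0 is the present slice

_LOG2PI = math.log(2.0 * math.pi)


class StructureError(ValueError):
    """Invalid DBN structure (cycle, forbidden arc, unknown node)."""


class ModelError(ValueError):
    """Invalid parameters or query (unknown configuration, sigma <= 0)."""


def col_name(node: Node) -> str:
    return f"{node[0]}@{node[1]}"


def parse_col(col: str) -> Node:
    name, lag = col.rsplit("@", 1)
    return name, int(lag)


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DBNStructure:
    """Time-homogeneous DAG over lagged variables.

    ``arcs`` are (parent, child) pairs of (name, lag) nodes; children are
    always at lag 0 (homogeneity makes deeper children redundant), parents at
    lags 0..order. Constraints enforced at construction: acyclicity of the
    intra-slice subgraph, no continuous parent of a discrete node, no arc
    from the present into the past.
    """

    variables: Mapping[str, str]          # name -> "continuous" | "discrete"
    order: int
    arcs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", dict(self.variables))
        object.__setattr__(self, "arcs", frozenset(self.arcs))
        if self.order < 0:
            raise StructureError("order must be >= 0")
        for kind in self.variables.values():
            if kind not in ("continuous", "discrete"):
                raise StructureError(f"unknown variable kind {kind!r}")
        for parent, child in self.arcs:
            pname, plag = parent
            cname, clag = child
            for name in (pname, cname):
                if name not in self.variables:
                    raise StructureError(f"arc references unknown variable {name!r}")
            if clag != 0:
                raise StructureError("learned parents attach only to lag-0 nodes")
            if not 0 <= plag <= self.order:
                raise StructureError(
                    f"parent lag {plag} outside 0..{self.order}")
            if (self.variables[cname] == "discrete"
                    and self.variables[pname] == "continuous"):
                raise StructureError(
                    f"continuous parent {pname!r} of discrete node {cname!r}")
        # intra-slice acyclicity (lag-0 subgraph)
        intra = {(p[0], c[0]) for p, c in self.arcs if p[1] == 0}
        if _has_cycle(set(self.variables), intra):
            raise StructureError("intra-slice arcs form a cycle")

    def parents(self, name: str) -> list[Node]:
        """Sorted parent nodes of the lag-0 variable ``name``."""
        return sorted(p for p, c in self.arcs if c == (name, 0))

    def discrete_parents(self, name: str) -> list[Node]:
        return [p for p in self.parents(name)
                if self.variables[p[0]] == "discrete"]

    def continuous_parents(self, name: str) -> list[Node]:
        return [p for p in self.parents(name)
                if self.variables[p[0]] == "continuous"]

    def with_arcs(self, arcs: Iterable) -> "DBNStructure":
        return DBNStructure(self.variables, self.order, frozenset(arcs))

    def intra_topological_order(self) -> list[str]:
        """Topological order of variables under intra-slice arcs."""
        intra = {(p[0], c[0]) for p, c in self.arcs if p[1] == 0}
        remaining = sorted(self.variables)
        order = []
        while remaining:
            for v in remaining:
                if all(p not in remaining for p, c in intra if c == v):
                    order.append(v)
                    remaining.remove(v)
                    break
            else:  # pragma: no cover - guarded by __post_init__
                raise StructureError("cycle detected")
        return order

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)


def _has_cycle(nodes: set[str], edges: set[tuple[str, str]]) -> bool:
    adj: dict[str, list[str]] = {v: [] for v in nodes}
    for p, c in edges:
        adj[p].append(c)
    state = dict.fromkeys(nodes, 0)  # 0 unseen, 1 on stack, 2 done

    def visit(v: str) -> bool:
        state[v] = 1
        for w in adj[v]:
            if state[w] == 1 or (state[w] == 0 and visit(w)):
                return True
        state[v] = 2
        return False

    return any(state[v] == 0 and visit(v) for v in nodes)


# ---------------------------------------------------------------------------
# Lagged design table
# ---------------------------------------------------------------------------

def build_lagged_table(series: Mapping[str, np.ndarray], order: int,
                       ) -> pd.DataFrame:
    """Unroll equal-length series into a lagged design table.

    Row t (for t = order .. n-1) holds every variable at lags 0..order:
    column ``X@k`` of row t equals ``X[t-k]``. The result has n - order rows
    and (#variables)*(order+1) columns.
    """
    lengths = {k: len(v) for k, v in series.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"series lengths differ: {lengths}")
    n = next(iter(lengths.values()))
    if n <= order:
        raise ValueError(f"need more than order={order} observations, got {n}")
    cols = {}
    for name, x in series.items():
        x = np.asarray(x)
        for k in range(order + 1):
            cols[col_name((name, k))] = x[order - k: n - k]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ContinuousNodeParams:
    """Per-configuration linear-Gaussian parameters of one continuous node."""

    cont_parents: list[Node]
    disc_parents: list[Node]
    # config (tuple of discrete parent states) -> (alpha, beta, sigma)
    table: dict[tuple[int, ...], tuple[float, np.ndarray, float]]

    def coef(self, config: tuple[int, ...]):
        if config not in self.table:
            raise ModelError(f"unknown discrete configuration {config}")
        return self.table[config]


@dataclass
class DiscreteNodeParams:
    """Conditional probability table of one discrete node."""

    parents: list[Node]
    states: list[int]
    # config -> probability vector over states
    cpt: dict[tuple[int, ...], np.ndarray]

    def prob(self, config: tuple[int, ...], value: int) -> float:
        if config not in self.cpt:
            raise ModelError(f"unknown discrete configuration {config}")
        return float(self.cpt[config][self.states.index(value)])


@dataclass
class CLGModel:
    """A fitted conditional linear Gaussian DBN: structure + parameters.

    ``prior`` maps each discrete variable to its empirical marginal
    distribution in the training data, used to initialize filtering over the
    first L slices.
    """

    structure: DBNStructure
    params: dict[str, ContinuousNodeParams | DiscreteNodeParams]
    prior: dict[str, np.ndarray] = field(default_factory=dict)
    states: dict[str, list[int]] = field(default_factory=dict)

    @property
    def order(self) -> int:
        return self.structure.order

    def loglik(self, data: pd.DataFrame) -> float:
        return joint_loglik(self, data)

    def n_free_parameters(self) -> int:
        k = 0
        for name, p in self.params.items():
            if isinstance(p, ContinuousNodeParams):
                k += len(p.table) * (len(p.cont_parents) + 2)
            else:
                k += len(p.cpt) * (len(p.states) - 1)
        return k

    def bic(self, data: pd.DataFrame) -> float:
        n = len(data)
        return self.loglik(data) - 0.5 * self.n_free_parameters() * math.log(n)


def clg_logdensity(alpha: float, beta: np.ndarray, sigma: float,
                   z_c: np.ndarray, z: float) -> float:
    """Log-density of a CLG node: log N(z; alpha + beta' z_C, sigma^2)."""
    if sigma <= 0:
        raise ModelError(f"sigma must be positive, got {sigma}")
    mu = alpha + (float(np.dot(beta, z_c)) if len(beta) else 0.0)
    r = (z - mu) / sigma
    return -0.5 * (r * r + _LOG2PI) - math.log(sigma)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-9


def _state_space(data_col: np.ndarray, declared: Sequence[int] | None) -> list[int]:
    if declared is not None:
        return list(declared)
    return sorted(int(v) for v in np.unique(data_col))


def _fit_continuous_node(data: pd.DataFrame, name: str,
                         cont_parents: list[Node], disc_parents: list[Node],
                         disc_states: dict[str, list[int]],
                         ) -> ContinuousNodeParams:
    y = data[col_name((name, 0))].to_numpy(dtype=float)
    X = (data[[col_name(p) for p in cont_parents]].to_numpy(dtype=float)
         if cont_parents else np.empty((len(y), 0)))
    n, p = X.shape

    def ols(yy: np.ndarray, XX: np.ndarray):
        design = np.column_stack([np.ones(len(yy)), XX])
        coef, *_ = np.linalg.lstsq(design, yy, rcond=None)
        resid = yy - design @ coef
        sigma = float(np.sqrt(np.mean(resid ** 2)))
        return float(coef[0]), coef[1:].copy(), max(sigma, _SIGMA_FLOOR)

    if not disc_parents:
        return ContinuousNodeParams(cont_parents, [], {(): ols(y, X)})

    cfg_cols = [data[col_name(q)].to_numpy() for q in disc_parents]
    spaces = [disc_states[q[0]] for q in disc_parents]
    pooled = None
    table = {}
    for config in itertools.product(*spaces):
        mask = np.ones(n, dtype=bool)
        for colv, s in zip(cfg_cols, config):
            mask &= colv == s
        if mask.sum() < p + 2:
            # configuration too sparse for its own regression: fall back to
            # the pooled fit that ignores the discrete split
            if pooled is None:
                pooled = ols(y, X)
                logger.warning(
                    "node %s: sparse configuration(s); using pooled fallback",
                    name)
            table[tuple(config)] = pooled
        else:
            table[tuple(config)] = ols(y[mask], X[mask])
    return ContinuousNodeParams(cont_parents, list(disc_parents), table)


def _fit_discrete_node(data: pd.DataFrame, name: str, parents: list[Node],
                       disc_states: dict[str, list[int]],
                       pseudocount: float) -> DiscreteNodeParams:
    y = data[col_name((name, 0))].to_numpy()
    states = disc_states[name]
    idx = {s: i for i, s in enumerate(states)}
    spaces = [disc_states[q[0]] for q in parents]
    cfg_cols = [data[col_name(q)].to_numpy() for q in parents]
    cpt = {}
    for config in itertools.product(*spaces) if parents else [()]:
        mask = np.ones(len(y), dtype=bool)
        for colv, s in zip(cfg_cols, config):
            mask &= colv == s
        counts = np.full(len(states), pseudocount, dtype=float)
        for v in y[mask]:
            counts[idx[int(v)]] += 1.0
        total = counts.sum()
        if total == 0:
            probs = np.full(len(states), 1.0 / len(states))
        else:
            probs = counts / total
        cpt[tuple(config)] = probs
    return DiscreteNodeParams(list(parents), states, cpt)


def fit_mle(structure: DBNStructure, data: pd.DataFrame,
            pseudocount: float = 0.5,
            states: Mapping[str, Sequence[int]] | None = None) -> CLGModel:
    """Fit maximum-likelihood parameters for every lag-0 node.

    Continuous nodes get one OLS regression per discrete-parent
    configuration with ML residual SD (divisor n); configurations with fewer
    than (#continuous parents + 2) rows fall back to the pooled regression.
    Discrete nodes get CPTs from empirical frequencies with the given
    pseudocount (0 reproduces raw frequencies).
    """
    states = dict(states or {})
    disc_states = {}
    for name, kind in structure.variables.items():
        if kind == "discrete":
            disc_states[name] = _state_space(
                data[col_name((name, 0))].to_numpy(), states.get(name))
    params: dict[str, ContinuousNodeParams | DiscreteNodeParams] = {}
    prior: dict[str, np.ndarray] = {}
    for name, kind in structure.variables.items():
        if kind == "continuous":
            params[name] = _fit_continuous_node(
                data, name, structure.continuous_parents(name),
                structure.discrete_parents(name), disc_states)
        else:
            params[name] = _fit_discrete_node(
                data, name, structure.parents(name), disc_states, pseudocount)
            vals = data[col_name((name, 0))].to_numpy()
            marg = np.array([(vals == s).mean() for s in disc_states[name]])
            # pseudocount keeps the filtering prior off the boundary
            marg = (marg * len(vals) + pseudocount) / (
                len(vals) + pseudocount * len(disc_states[name]))
            prior[name] = marg
    return CLGModel(structure=structure, params=params, prior=prior,
                    states=disc_states)


# ---------------------------------------------------------------------------
# Likelihood and BIC
# ---------------------------------------------------------------------------

def _node_loglik(model: CLGModel, name: str, data: pd.DataFrame) -> float:
    p = model.params[name]
    y = data[col_name((name, 0))].to_numpy()
    n = len(y)
    if isinstance(p, ContinuousNodeParams):
        X = (data[[col_name(q) for q in p.cont_parents]].to_numpy(dtype=float)
             if p.cont_parents else np.empty((n, 0)))
        total = 0.0
        if not p.disc_parents:
            alpha, beta, sigma = p.table[()]
            mu = alpha + (X @ beta if len(beta) else 0.0)
            r = (y - mu) / sigma
            return float(np.sum(-0.5 * (r * r + _LOG2PI) - math.log(sigma)))
        cfg_cols = np.column_stack(
            [data[col_name(q)].to_numpy() for q in p.disc_parents])
        for config, (alpha, beta, sigma) in p.table.items():
            mask = np.all(cfg_cols == np.asarray(config), axis=1)
            if not mask.any():
                continue
            mu = alpha + (X[mask] @ beta if len(beta) else 0.0)
            r = (y[mask] - mu) / sigma
            total += float(np.sum(-0.5 * (r * r + _LOG2PI) - math.log(sigma)))
        return total
    # discrete node
    total = 0.0
    if p.parents:
        cfg_cols = np.column_stack(
            [data[col_name(q)].to_numpy() for q in p.parents])
    for i in range(n):
        config = tuple(int(v) for v in cfg_cols[i]) if p.parents else ()
        prob = p.prob(config, int(y[i]))
        if prob <= 0.0:
            logger.warning("zero-probability event for node %s at row %d",
                           name, i)
            return -math.inf
        total += math.log(prob)
    return total


def joint_loglik(model: CLGModel, data: pd.DataFrame) -> float:
    """Total transition log-likelihood: sum over rows and lag-0 nodes.

    Returns -inf (not an exception) when a zero-probability discrete event
    occurs under a zero-pseudocount CPT.
    """
    return sum(_node_loglik(model, name, data)
               for name in model.structure.variables)


def node_bic(structure: DBNStructure, name: str, data: pd.DataFrame,
             pseudocount: float = 0.5,
             states: Mapping[str, Sequence[int]] | None = None) -> float:
    """BIC contribution of a single node under the given structure."""
    sub = structure.with_arcs({(p, c) for p, c in structure.arcs
                               if c == (name, 0)})
    model = fit_mle(sub, data, pseudocount=pseudocount, states=states)
    p = model.params[name]
    if isinstance(p, ContinuousNodeParams):
        k = len(p.table) * (len(p.cont_parents) + 2)
    else:
        k = len(p.cpt) * (len(p.states) - 1)
    return _node_loglik(model, name, data) - 0.5 * k * math.log(len(data))


def bic_score(structure: DBNStructure, data: pd.DataFrame,
              pseudocount: float = 0.5,
              states: Mapping[str, Sequence[int]] | None = None) -> float:
    """BIC of the whole structure: loglik - k/2 log n; larger is better.

    Decomposes node-wise, which is what makes greedy arc search cheap.
    """
    model = fit_mle(structure, data, pseudocount=pseudocount, states=states)
    return model.bic(data)


# ---------------------------------------------------------------------------
# Ancestral sampling
# ---------------------------------------------------------------------------

def sample_model(model: CLGModel, n: int, seed: int = 0, burn: int = 200,
                 ) -> dict[str, np.ndarray]:
    """Draw ``n`` time slices from the model by ancestral sampling.

    The chain is initialized from the stored discrete priors (continuous
    histories start at their no-information intercepts) and a burn-in of
    ``burn`` slices is discarded, so the returned sample is approximately
    stationary.
    """
    rng = np.random.default_rng(seed)
    struct = model.structure
    L = struct.order
    total = n + L + burn
    topo = struct.intra_topological_order()
    out: dict[str, np.ndarray] = {}
    for name, kind in struct.variables.items():
        out[name] = np.zeros(total, dtype=float if kind == "continuous"
                             else int)
    # history initialization
    for name, kind in struct.variables.items():
        if kind == "discrete":
            pr = model.prior.get(name)
            sts = model.states[name]
            if pr is None:
                pr = np.full(len(sts), 1.0 / len(sts))
            out[name][:L] = rng.choice(sts, size=L, p=pr)
        else:
            p = model.params[name]
            cfg = next(iter(p.table))
            out[name][:L] = p.table[cfg][0]
    for t in range(L, total):
        for name in topo:
            p = model.params[name]
            if isinstance(p, DiscreteNodeParams):
                config = tuple(int(out[q][t - lag]) for q, lag in p.parents)
                probs = p.cpt.get(config)
                if probs is None:
                    raise ModelError(f"unseen configuration {config} for {name}")
                out[name][t] = rng.choice(p.states, p=probs)
            else:
                config = tuple(int(out[q][t - lag]) for q, lag in p.disc_parents)
                alpha, beta, sigma = p.coef(config)
                zc = np.array([out[q][t - lag] for q, lag in p.cont_parents])
                mu = alpha + (float(zc @ beta) if len(beta) else 0.0)
                out[name][t] = rng.normal(mu, sigma)
    return {k: v[L + burn:] for k, v in out.items()}


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _cfg_key(config: tuple[int, ...]) -> str:
    return ",".join(str(int(v)) for v in config)


def _cfg_unkey(key: str) -> tuple[int, ...]:
    return tuple(int(v) for v in key.split(",")) if key else ()


def model_to_dict(model: CLGModel) -> dict:
    struct = model.structure
    d = {
        "format": "apneadbn-clg-model",
        "version": 1,
        "order": struct.order,
        "variables": {k: v for k, v in sorted(struct.variables.items())},
        "arcs": sorted([[p[0], p[1], c[0], c[1]] for p, c in struct.arcs]),
        "states": {k: list(map(int, v)) for k, v in model.states.items()},
        "prior": {k: list(map(float, v)) for k, v in model.prior.items()},
        "nodes": {},
    }
    for name, p in model.params.items():
        if isinstance(p, ContinuousNodeParams):
            d["nodes"][name] = {
                "kind": "continuous",
                "cont_parents": [[q, lag] for q, lag in p.cont_parents],
                "disc_parents": [[q, lag] for q, lag in p.disc_parents],
                "table": {_cfg_key(cfg): {
                    "alpha": float(a), "beta": [float(b) for b in bb],
                    "sigma": float(s)} for cfg, (a, bb, s) in p.table.items()},
            }
        else:
            d["nodes"][name] = {
                "kind": "discrete",
                "parents": [[q, lag] for q, lag in p.parents],
                "states": list(map(int, p.states)),
                "cpt": {_cfg_key(cfg): [float(v) for v in probs]
                        for cfg, probs in p.cpt.items()},
            }
    return d


def model_from_dict(d: dict) -> CLGModel:
    if d.get("format") != "apneadbn-clg-model":
        raise ValueError("not a CLG model file")
    variables = d["variables"]
    arcs = set()
    for pn, pl, cn, cl in d["arcs"]:
        for nm in (pn, cn):
            if nm not in variables:
                raise ValueError(f"arc references undeclared node {nm!r}")
        arcs.add(((pn, int(pl)), (cn, int(cl))))
    struct = DBNStructure(variables=variables, order=int(d["order"]),
                          arcs=frozenset(arcs))
    params: dict[str, ContinuousNodeParams | DiscreteNodeParams] = {}
    for name, nd in d["nodes"].items():
        if name not in variables:
            raise ValueError(f"parameter block for undeclared node {name!r}")
        kind = nd.get("kind")
        if kind == "continuous":
            table = {}
            for key, blk in nd["table"].items():
                table[_cfg_unkey(key)] = (float(blk["alpha"]),
                                          np.array(blk["beta"], dtype=float),
                                          float(blk["sigma"]))
            cp = [(q, int(l)) for q, l in nd["cont_parents"]]
            dp = [(q, int(l)) for q, l in nd["disc_parents"]]
            if set(cp) != set(struct.continuous_parents(name)) or \
                    set(dp) != set(struct.discrete_parents(name)):
                raise ValueError(
                    f"parameters of {name!r} inconsistent with structure")
            params[name] = ContinuousNodeParams(cp, dp, table)
        elif kind == "discrete":
            cpt = {_cfg_unkey(k): np.array(v, dtype=float)
                   for k, v in nd["cpt"].items()}
            pp = [(q, int(l)) for q, l in nd["parents"]]
            if set(pp) != set(struct.parents(name)):
                raise ValueError(
                    f"parameters of {name!r} inconsistent with structure")
            params[name] = DiscreteNodeParams(pp, list(map(int, nd["states"])),
                                              cpt)
        else:
            raise ValueError(f"unknown node kind {kind!r}")
    prior = {k: np.array(v, dtype=float) for k, v in d.get("prior", {}).items()}
    states = {k: list(map(int, v)) for k, v in d.get("states", {}).items()}
    return CLGModel(structure=struct, params=params, prior=prior, states=states)


def save_model(model: CLGModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)


def load_model(path: str | Path) -> CLGModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
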