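"""DBN structure learning by dynamic max-min hill-climbing.

Two phases, mirroring the static/transition split of the dynamic variant of
max-min hill-climbing:

1. *Static structure*: intra-slice arcs among lag-0 nodes. A max-min
   parents-children screen restricts the candidate skeleton, then greedy
   hill-climbing with add/delete/reverse moves scored by BIC directs the
   arcs.
2. *Transition structure*: inter-slice parents at lags 1..L for each lag-0
   node, screened and hill-climbed with the intra-slice arcs held fixed.
   Inter-slice arcs have a forced direction (past to present), so no
   reversal moves apply.

Conditional-independence tests by variable-kind pair: Fisher-z on partial
correlation for continuous-continuous, a likelihood-ratio test comparing
regressions with and without the discrete dummy for mixed pairs, and a
(stratified) chi-square test for discrete-discrete. Conditioning sets are
capped at size 3. Structural constraints are enforced throughout: no
continuous parent of a discrete node, no future-to-past arc, acyclicity.

Everything is deterministic given the data: ties are broken by lexicographic
(target, parent, lag) order and the stopping rule is a fixed BIC-improvement
threshold.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clg import (CLGModel, ContinuousNodeParams, DBNStructure,
                  DiscreteNodeParams, Node, build_lagged_table, col_name,
                  fit_mle)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSet",
    "mmpc_screen",
    "hill_climb",
    "learn_dbn",
    "structure_to_dot",
]

_BIC_EPS = 1e-6
_MAX_COND = 3


@dataclass
class CandidateSet:
    """Allowed parent (node, lag) pairs per lag-0 target."""

    target: str
    candidates: set[Node] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Conditional-independence tests (p-values; small p = dependent)
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    if Z.shape[1] == 0:
        return y - y.mean()
    design = np.column_stack([np.ones(len(y)), Z])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def _fisher_z(x: np.ndarray, y: np.ndarray, Z: np.ndarray) -> float:
    """Partial-correlation test via Fisher's z transform."""
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return 1.0
    r = float(rx @ ry) / denom
    r = min(max(r, -0.999999999), 0.999999999)
    n = len(x)
    df = n - Z.shape[1] - 3
    if df <= 0:
        return 1.0
    z = 0.5 * math.log((1 + r) / (1 - r)) * math.sqrt(df)
    return 2.0 * stats.norm.sf(abs(z))


def _lrt_mixed(y: np.ndarray, d: np.ndarray, Z: np.ndarray) -> float:
    """LRT: does the discrete variable's dummy improve the regression of y?"""
    levels = np.unique(d)
    if len(levels) < 2:
        return 1.0
    dummies = np.column_stack([(d == lv).astype(float) for lv in levels[1:]])
    r0 = _residualize(y, Z)
    r1 = _residualize(y, np.column_stack([Z, dummies]) if Z.size
                      else dummies)
    rss0 = float(r0 @ r0)
    rss1 = float(r1 @ r1)
    if rss1 <= 0 or rss0 <= 0:
        return 0.0 if rss0 > rss1 else 1.0
    n = len(y)
    stat = n * math.log(rss0 / rss1)
    return float(stats.chi2.sf(stat, df=len(levels) - 1))


def _chi2_discrete(x: np.ndarray, y: np.ndarray, strata: np.ndarray) -> float:
    """Chi-square independence test of x vs y, summed over discrete strata."""
    stat = 0.0
    dof = 0
    if strata.size == 0:
        groups = [np.ones(len(x), dtype=bool)]
    else:
        keys = [tuple(row) for row in strata]
        uniq = sorted(set(keys))
        keys = np.array([uniq.index(k) for k in keys])
        groups = [keys == i for i in range(len(uniq))]
    for mask in groups:
        if mask.sum() < 5:
            continue
        tab = pd.crosstab(x[mask], y[mask]).to_numpy()
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        s, _, d, _ = stats.chi2_contingency(tab, correction=False)
        stat += s
        dof += d
    if dof == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df=dof))


def _ci_pvalue(data: pd.DataFrame, kinds: dict[str, str], a: Node, b: Node,
               cond: tuple[Node, ...]) -> float:
    xa = data[col_name(a)].to_numpy(dtype=float)
    xb = data[col_name(b)].to_numpy(dtype=float)
    ka, kb = kinds[a[0]], kinds[b[0]]
    cont_cond = [c for c in cond if kinds[c[0]] == "continuous"]
    disc_cond = [c for c in cond if kinds[c[0]] == "discrete"]
    Zc = (data[[col_name(c) for c in cont_cond]].to_numpy(dtype=float)
          if cont_cond else np.empty((len(xa), 0)))
    Zd = (data[[col_name(c) for c in disc_cond]].to_numpy()
          if disc_cond else np.empty((len(xa), 0)))
    if ka == "continuous" and kb == "continuous":
        # discrete conditioners enter the partial correlation as dummies
        if Zd.size:
            dummies = [(Zd[:, j] == lv).astype(float)
                       for j in range(Zd.shape[1])
                       for lv in np.unique(Zd[:, j])[1:]]
            Z = np.column_stack([Zc] + [np.column_stack(dummies)]) \
                if dummies else Zc
        else:
            Z = Zc
        return _fisher_z(xa, xb, Z)
    if ka == "discrete" and kb == "discrete":
        return _chi2_discrete(xa.astype(int), xb.astype(int), Zd)
    # mixed: regress the continuous one on conditioners, test the dummy
    y, d = (xa, xb.astype(int)) if ka == "continuous" else (xb, xa.astype(int))
    if Zd.size:
        dummies = [(Zd[:, j] == lv).astype(float)
                   for j in range(Zd.shape[1]) for lv in np.unique(Zd[:, j])[1:]]
        Z = np.column_stack([Zc] + [np.column_stack(dummies)]) \
            if dummies else Zc
    else:
        Z = Zc
    return _lrt_mixed(y, d, Z)


# ---------------------------------------------------------------------------
# Max-min parents-children screening
# ---------------------------------------------------------------------------

def mmpc_screen(data: pd.DataFrame, target: Node, kinds: dict[str, str],
                candidates: list[Node], alpha: float = 0.05,
                max_cond: int = _MAX_COND) -> CandidateSet:
    """Screen candidate parents of ``target`` with the max-min heuristic.

    Grow phase: repeatedly admit the candidate whose *minimum* association
    with the target over conditioning subsets of the current set (size <=
    ``max_cond``) is largest, stopping when even the best candidate is
    independent (max p-value > alpha). Shrink phase: drop any member that is
    independent of the target given some subset of the others. Constant
    columns are excluded with a notice. Deterministic given the data.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    tkind = kinds[target[0]]
    usable = []
    for c in sorted(candidates):
        if tkind == "discrete" and kinds[c[0]] == "continuous":
            continue  # a discrete node may not have continuous parents
        colv = data[col_name(c)].to_numpy()
        if np.all(colv == colv[0]):
            logger.info("mmpc: excluding constant column %s", col_name(c))
            continue
        usable.append(c)
    tcol = data[col_name(target)].to_numpy()
    if np.all(tcol == tcol[0]):
        return CandidateSet(target=target[0], candidates=set())

    cpc: list[Node] = []

    def max_p_over_subsets(c: Node, members: list[Node]) -> float:
        worst = 0.0
        others = [m for m in members if m != c]
        for size in range(0, min(max_cond, len(others)) + 1):
            for sub in itertools.combinations(others, size):
                p = _ci_pvalue(data, kinds, target, c, sub)
                worst = max(worst, p)
                if worst > alpha:
                    return worst
        return worst

    remaining = list(usable)
    while remaining:
        scored = [(max_p_over_subsets(c, cpc), c) for c in remaining]
        scored.sort(key=lambda t: (t[0], t[1]))
        best_p, best = scored[0]
        if best_p > alpha:
            break
        cpc.append(best)
        remaining.remove(best)
    # shrink
    for c in sorted(cpc):
        if max_p_over_subsets(c, [m for m in cpc if m != c]) > alpha:
            cpc.remove(c)
    return CandidateSet(target=target[0], candidates=set(cpc))


# ---------------------------------------------------------------------------
# BIC hill-climbing
# ---------------------------------------------------------------------------

class _NodeScorer:
    """Caches per-node BIC contributions keyed by the parent set."""

    def __init__(self, data: pd.DataFrame, kinds: dict[str, str],
                 order: int, pseudocount: float,
                 states: dict[str, list[int]]):
        self.data = data
        self.kinds = kinds
        self.order = order
        self.pseudocount = pseudocount
        self.states = states
        self.logn = math.log(len(data))
        self._cache: dict[tuple[str, tuple[Node, ...]], float] = {}

    def score(self, name: str, parents: frozenset) -> float:
        key = (name, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        struct = DBNStructure(
            variables=self.kinds, order=self.order,
            arcs=frozenset((p, (name, 0)) for p in parents))
        model = fit_mle(struct, self.data, pseudocount=self.pseudocount,
                        states=self.states)
        p = model.params[name]
        if isinstance(p, ContinuousNodeParams):
            k = len(p.table) * (len(p.cont_parents) + 2)
        else:
            k = len(p.cpt) * (len(p.states) - 1)
        from .clg import _node_loglik
        val = _node_loglik(model, name, self.data) - 0.5 * k * self.logn
        self._cache[key] = val
        return val


def _arc_allowed(kinds: dict[str, str], parent: Node, child: Node) -> bool:
    if kinds[child[0]] == "discrete" and kinds[parent[0]] == "continuous":
        return False
    if parent == child:
        return False
    return True


def _creates_cycle(arcs: set, parent: Node, child: Node) -> bool:
    if parent[1] != 0:
        return False
    intra = {(p[0], c[0]) for p, c in arcs if p[1] == 0}
    intra.add((parent[0], child[0]))
    # DFS from child name to parent name
    adj: dict[str, set[str]] = {}
    for p, c in intra:
        adj.setdefault(p, set()).add(c)
    stack, seen = [child[0]], set()
    while stack:
        v = stack.pop()
        if v == parent[0]:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(adj.get(v, ()))
    return False


def hill_climb(data: pd.DataFrame, kinds: dict[str, str], order: int,
               candidates: dict[str, set[Node]],
               initial_arcs: frozenset = frozenset(),
               frozen_arcs: frozenset = frozenset(),
               allow_reverse: bool = True,
               pseudocount: float = 0.5,
               states: dict[str, list[int]] | None = None) -> DBNStructure:
    """Greedy BIC search over arcs restricted to the candidate sets.

    Moves: add an arc (parent in the target's candidate set), delete a
    non-frozen arc, or reverse an intra-slice arc (when the reversed arc is
    itself a candidate). The single best move is accepted per iteration if it
    improves total BIC by more than 1e-6; ties are broken by lexicographic
    (target, parent) order, so the result is deterministic given the data.
    """
    if states is None:
        states = {}
        for name, kind in kinds.items():
            if kind == "discrete":
                states[name] = sorted(
                    int(v) for v in np.unique(data[col_name((name, 0))]))
    scorer = _NodeScorer(data, kinds, order, pseudocount, states)
    arcs: set = set(initial_arcs)

    def parents_of(name: str, arcset: set) -> frozenset:
        return frozenset(p for p, c in arcset if c == (name, 0))

    current = {name: scorer.score(name, parents_of(name, arcs))
               for name in kinds}

    while True:
        moves = []  # (gain, sort_key, new_arcs, affected updates)
        # additions
        for child_name in sorted(kinds):
            child = (child_name, 0)
            pset = parents_of(child_name, arcs)
            for parent in sorted(candidates.get(child_name, ())):
                if (parent, child) in arcs or not _arc_allowed(kinds, parent,
                                                               child):
                    continue
                if _creates_cycle(arcs, parent, child):
                    continue
                new = scorer.score(child_name, pset | {parent})
                gain = new - current[child_name]
                moves.append((gain, ("add", child_name, parent),
                              {child_name: new},
                              [("add", parent, child)]))
        # deletions
        for parent, child in sorted(arcs - set(frozen_arcs)):
            pset = parents_of(child[0], arcs)
            new = scorer.score(child[0], pset - {parent})
            gain = new - current[child[0]]
            moves.append((gain, ("del", child[0], parent),
                          {child[0]: new},
                          [("del", parent, child)]))
        # reversals (intra-slice only)
        if allow_reverse:
            for parent, child in sorted(arcs - set(frozen_arcs)):
                if parent[1] != 0:
                    continue
                rev_parent, rev_child = (child[0], 0), (parent[0], 0)
                if rev_parent not in candidates.get(parent[0], set()):
                    continue
                if not _arc_allowed(kinds, rev_parent, rev_child):
                    continue
                tmp = set(arcs)
                tmp.discard((parent, child))
                if _creates_cycle(tmp, rev_parent, rev_child):
                    continue
                new_c = scorer.score(child[0],
                                     parents_of(child[0], arcs) - {parent})
                new_p = scorer.score(parent[0],
                                     parents_of(parent[0], arcs)
                                     | {rev_parent})
                gain = (new_c - current[child[0]]) + (new_p - current[parent[0]])
                moves.append((gain, ("rev", child[0], parent),
                              {child[0]: new_c, parent[0]: new_p},
                              [("del", parent, child),
                               ("add", rev_parent, rev_child)]))
        if not moves:
            break
        moves.sort(key=lambda m: (-m[0], m[1]))
        gain, _, updates, edits = moves[0]
        if gain <= _BIC_EPS:
            break
        for op, p, c in edits:
            if op == "add":
                arcs.add((p, c))
            else:
                arcs.discard((p, c))
        current.update(updates)
    return DBNStructure(variables=kinds, order=order, arcs=frozenset(arcs))


# ---------------------------------------------------------------------------
# Full dynamic learning
# ---------------------------------------------------------------------------

def learn_dbn(series: dict[str, np.ndarray], kinds: dict[str, str],
              order: int, alpha: float = 0.05, pseudocount: float = 0.5,
              force_self_chain: bool = False,
              max_cond: int = _MAX_COND) -> DBNStructure:
    """Learn a time-homogeneous DBN structure of Markov order ``order``.

    Step 1 learns the static (intra-slice) structure among lag-0 nodes with
    screening plus hill-climbing; step 2 learns the transition structure —
    parents at lags 1..order for every lag-0 node — with the intra-slice
    arcs frozen. Self-lags (X at lag k as a parent of X) are always admitted
    to the candidate set, since autoregression is the central temporal
    mechanism. With ``force_self_chain`` the discrete variables' first-lag
    self-arcs are forced into the structure.
    """
    data = build_lagged_table(series, order)
    names = sorted(series)
    states = {name: sorted(int(v) for v in np.unique(series[name]))
              for name in names if kinds[name] == "discrete"}

    # step 1: static structure among lag-0 nodes
    static_cands: dict[str, set[Node]] = {}
    for name in names:
        cands = [(other, 0) for other in names if other != name]
        cs = mmpc_screen(data, (name, 0), kinds, cands, alpha=alpha,
                         max_cond=max_cond)
        static_cands[name] = cs.candidates
    # symmetrize: keep a candidate pair only if either side proposed it
    for name in names:
        static_cands[name] = {c for c in static_cands[name]}
    static = hill_climb(data, kinds, order, static_cands,
                        allow_reverse=True, pseudocount=pseudocount,
                        states=states)

    # step 2: transition structure, intra-slice arcs frozen
    trans_cands: dict[str, set[Node]] = {}
    forced: set = set()
    for name in names:
        cands = []
        for other in names:
            if kinds[name] == "discrete" and kinds[other] == "continuous":
                continue
            for lag in range(1, order + 1):
                cands.append((other, lag))
        cs = mmpc_screen(data, (name, 0), kinds, cands, alpha=alpha,
                         max_cond=max_cond)
        cset = set(cs.candidates)
        cset.update({(name, lag) for lag in range(1, order + 1)})  # self-lags
        trans_cands[name] = {c for c in cset if c not in
                             static.parents(name)}
        if force_self_chain and kinds[name] == "discrete":
            forced.add(((name, 1), (name, 0)))
    # merge static candidates so deletions of static arcs stay possible:
    # static arcs are frozen instead (two-phase procedure)
    initial = set(static.arcs) | forced
    full = hill_climb(data, kinds, order, trans_cands,
                      initial_arcs=frozenset(initial),
                      frozen_arcs=frozenset(initial),
                      allow_reverse=False, pseudocount=pseudocount,
                      states=states)
    return full


def structure_to_dot(structure: DBNStructure) -> str:
    """DOT rendering of the unrolled graph (for figures)."""
    lines = ["digraph dbn {", "  rankdir=LR;"]
    L = structure.order
    for name, kind in sorted(structure.variables.items()):
        for lag in range(L, -1, -1):
            shape = "box" if kind == "discrete" else "ellipse"
            lines.append(f'  "{name}@{lag}" [shape={shape}];')
    for (pn, pl), (cn, cl) in sorted(structure.arcs):
        lines.append(f'  "{pn}@{pl}" -> "{cn}@{cl}";')
    lines.append("}")
    return "\n".join(lines)
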