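"""Exact filtering, prediction and fixed-lag smoothing for the apnea DBN.

The apnea indicator is hidden at inference time; the beat-to-beat marker
series are observed. Because every continuous lagged parent is itself a
measured marker, the emission terms factor per beat and exact inference
reduces to a forward recursion over the 2^L discrete *history states* — the
tuples of hidden apnea values over the most recent L slices. The filtering
density p(Ap_t | y_{1:t}) is the marginal of the newest bit of that state.

States are encoded as L-bit integers, bit i holding the apnea value i beats
back. A step appends the new bit: the full (L+1)-bit configuration seen by
the slice-t conditionals is ``c = (state << 1) | bit`` and the successor
state is ``c & (2^L - 1)``. The recursion is normalized at every step, so it
is numerically stable over arbitrarily long recordings; emission products
are accumulated in log space.

Exact inference is feasible up to L = 15 (32,768 states); larger orders
raise a capability error rather than silently approximating.

The first L beats of a recording precede any complete slice, so they carry
the training prior and are flagged as such in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clg import (CLGModel, ContinuousNodeParams, DiscreteNodeParams,
                  ModelError, col_name)

__all__ = [
    "ProbabilitySignal",
    "EvidenceError",
    "CapabilityError",
    "filter_posterior",
    "brute_force_posterior",
    "predict_ahead",
    "fixed_lag_smooth",
    "training_rmse",
]

_LOG2PI = float(np.log(2.0 * np.pi))
MAX_EXACT_ORDER = 15


class EvidenceError(ValueError):
    """A continuous parent required by the model is not observed."""


class CapabilityError(ValueError):
    """Problem size beyond the exact-inference cap."""


@dataclass
class ProbabilitySignal:
    """Per-beat posterior apnea probability.

    ``prior_flag`` marks beats whose value is the training prior (the first
    L beats, which precede any complete slice of evidence).
    """

    p: np.ndarray
    t_s: np.ndarray | None = None
    prior_flag: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.prior_flag is None:
            self.prior_flag = np.zeros(len(self.p), dtype=bool)
        if np.any((self.p < -1e-12) | (self.p > 1 + 1e-12)):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        self.p = np.clip(self.p, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.p)

    def to_frame(self) -> pd.DataFrame:
        d = {"p": self.p, "flag_prior": self.prior_flag.astype(int)}
        if self.t_s is not None:
            d = {"t_s": self.t_s, **d}
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Model unpacking helpers
# ---------------------------------------------------------------------------

def _hidden_name(model: CLGModel) -> str:
    disc = [n for n, k in model.structure.variables.items() if k == "discrete"]
    if len(disc) != 1:
        raise ModelError("inference requires exactly one discrete variable")
    name = disc[0]
    if model.states.get(name, [0, 1]) != [0, 1]:
        raise ModelError("the hidden apnea variable must be binary {0,1}")
    return name


def _observation_table(model: CLGModel, observations) -> pd.DataFrame:
    """Lagged design table of the continuous series (hidden column absent)."""
    from .clg import build_lagged_table

    struct = model.structure
    cont = [n for n, k in struct.variables.items() if k == "continuous"]
    if isinstance(observations, pd.DataFrame) and any(
            "@" in c for c in observations.columns):
        missing = [col_name((n, k)) for n in cont
                   for k in range(struct.order + 1)
                   if col_name((n, k)) not in observations.columns]
        if missing:
            raise EvidenceError(f"missing observed columns: {missing}")
        return observations
    if isinstance(observations, pd.DataFrame):
        series = {c: observations[c].to_numpy(dtype=float)
                  for c in observations.columns}
    else:
        series = {k: np.asarray(v, dtype=float)
                  for k, v in dict(observations).items()}
    missing = [n for n in cont if n not in series]
    if missing:
        raise EvidenceError(f"unobserved continuous variables: {missing}")
    return build_lagged_table({n: series[n] for n in cont}, struct.order)


def _transition_table(model: CLGModel, name: str) -> np.ndarray:
    """trans_flat[c] = P(Ap_t = c&1 | history bits of c>>1), c over L+1 bits."""
    L = model.order
    p = model.params[name]
    assert isinstance(p, DiscreteNodeParams)
    n_cfg = 1 << (L + 1)
    out = np.empty(n_cfg)
    for c in range(n_cfg):
        b = c & 1
        s = c >> 1
        config = tuple((s >> (lag - 1)) & 1 for _, lag in p.parents)
        out[c] = p.prob(config, b)
    return out


def _emission_matrix(model: CLGModel, data: pd.DataFrame,
                     name_hidden: str) -> np.ndarray:
    """E[t, c] = sum of continuous-node log-densities under config c.

    Config c is the (L+1)-bit apnea history (bit j = value at lag j).
    Continuous parents are observed, so each node contributes
    log N(y_t; alpha_c + beta_c' z_t, sigma_c^2) and terms add across nodes.
    """
    L = model.order
    n_cfg = 1 << (L + 1)
    T = len(data)
    E = np.zeros((T, n_cfg))
    for name, params in model.params.items():
        if not isinstance(params, ContinuousNodeParams):
            continue
        y = data[col_name((name, 0))].to_numpy(dtype=float)
        X = (data[[col_name(q) for q in params.cont_parents]]
             .to_numpy(dtype=float)
             if params.cont_parents else np.empty((T, 0)))
        lags = [lag for q, lag in params.disc_parents]
        alpha = np.empty(n_cfg)
        sigma = np.empty(n_cfg)
        beta = np.empty((n_cfg, X.shape[1]))
        for c in range(n_cfg):
            key = tuple((c >> lag) & 1 for lag in lags)
            a, b, s = params.coef(key)
            alpha[c], beta[c], sigma[c] = a, b, s
        mu = alpha[None, :] + X @ beta.T          # (T, n_cfg)
        r = (y[:, None] - mu) / sigma[None, :]
        E += -0.5 * (r * r + _LOG2PI) - np.log(sigma)[None, :]
    return E


def _initial_state_dist(model: CLGModel, name: str) -> np.ndarray:
    """Product prior over the 2^L history states, independent per slot."""
    L = model.order
    p1 = float(model.prior.get(name, np.array([0.5, 0.5]))[1])
    states = np.arange(1 << L)
    bits = ((states[:, None] >> np.arange(L)[None, :]) & 1)
    w = np.prod(np.where(bits == 1, p1, 1.0 - p1), axis=1)
    return w / w.sum()


def _forward(model: CLGModel, data: pd.DataFrame, name: str,
             store: bool = False):
    """Normalized forward recursion; returns per-row filtered bit-0 marginal
    and, optionally, the per-row state distributions (plus the initial one).
    """
    L = model.order
    mask = (1 << L) - 1
    trans = _transition_table(model, name)
    E = _emission_matrix(model, data, name)
    alpha = _initial_state_dist(model, name)
    T = len(data)
    configs = np.arange(1 << (L + 1))
    prev_idx = configs >> 1
    succ = configs & mask
    newbit = (configs & 1).astype(bool)
    p_out = np.empty(T)
    alphas = [alpha.copy()] if store else None
    for t in range(T):
        logw = np.log(np.maximum(alpha[prev_idx] * trans, 1e-300)) + E[t]
        logw[alpha[prev_idx] * trans == 0.0] = -np.inf
        m = logw.max()
        if not np.isfinite(m):
            raise ModelError(
                "all transition paths have zero probability (inconsistent "
                "deterministic CPT vs evidence)")
        w = np.exp(logw - m)
        alpha = np.bincount(succ, weights=w, minlength=1 << L)
        alpha /= alpha.sum()
        p_out[t] = alpha[(np.arange(1 << L) & 1) == 1].sum()
        if store:
            alphas.append(alpha.copy())
    return (p_out, alphas, trans, E) if store else (p_out, None, trans, E)


def _check_order(model: CLGModel) -> None:
    if model.order > MAX_EXACT_ORDER:
        raise CapabilityError(
            f"exact inference supports order <= {MAX_EXACT_ORDER} "
            f"(2^{model.order} history states requested); reduce the order")
    if model.order < 1:
        raise CapabilityError("inference requires order >= 1")


def _assemble(model: CLGModel, name: str, p_rows: np.ndarray,
              observations, t_s) -> ProbabilitySignal:
    L = model.order
    p1 = float(model.prior.get(name, np.array([0.5, 0.5]))[1])
    p = np.concatenate([np.full(L, p1), p_rows])
    flag = np.zeros(len(p), dtype=bool)
    flag[:L] = True
    return ProbabilitySignal(p=p, t_s=None if t_s is None
                             else np.asarray(t_s, dtype=float),
                             prior_flag=flag)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def filter_posterior(model: CLGModel, observations,
                     t_s=None) -> ProbabilitySignal:
    """Exact filtering: p_t = P(Ap_t = 1 | markers up to beat t).

    ``observations`` may be a mapping/DataFrame of per-beat marker series
    (lagging is done internally) or an already-lagged design table. The
    first L beats carry the training prior, flagged in the output.
    """
    _check_order(model)
    name = _hidden_name(model)
    data = _observation_table(model, observations)
    p_rows, *_ = _forward(model, data, name)
    return _assemble(model, name, p_rows, observations, t_s)


def predict_ahead(model: CLGModel, observations, delta_steps: int,
                  t_s=None) -> ProbabilitySignal:
    """h-step-ahead prediction: P(Ap_{t+delta} | markers up to beat t).

    The filtered state distribution is pushed ``delta_steps`` times through
    the transition CPT with no new evidence; continuous parents at future
    lags never enter (the apnea chain is autonomous given its history).
    """
    if delta_steps < 0:
        raise ValueError("delta_steps must be >= 0")
    _check_order(model)
    name = _hidden_name(model)
    data = _observation_table(model, observations)
    _, alphas, trans, _ = _forward(model, data, name, store=True)
    L = model.order
    mask = (1 << L) - 1
    configs = np.arange(1 << (L + 1))
    prev_idx = configs >> 1
    succ = configs & mask
    odd = (np.arange(1 << L) & 1) == 1
    p_rows = np.empty(len(data))
    for t in range(len(data)):
        a = alphas[t + 1]
        for _ in range(delta_steps):
            w = a[prev_idx] * trans
            a = np.bincount(succ, weights=w, minlength=1 << L)
            a /= a.sum()
        p_rows[t] = a[odd].sum()
    return _assemble(model, name, p_rows, observations, t_s)


def fixed_lag_smooth(model: CLGModel, observations, tau: int,
                     t_s=None) -> ProbabilitySignal:
    """Fixed-lag smoothing: P(Ap_{t - tau} | markers up to beat t).

    Reported per beat m as its posterior given evidence through beat
    m + tau (capped at the end of the recording). For tau < L the smoothed
    marginal is read directly off the forward state distribution, which
    still contains the bit; deeper lags run a backward recursion over the
    intervening slices. tau = 0 reproduces filtering exactly.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    _check_order(model)
    name = _hidden_name(model)
    data = _observation_table(model, observations)
    _, alphas, trans, E = _forward(model, data, name, store=True)
    L = model.order
    R = len(data)
    n = R + L
    mask = (1 << L) - 1
    configs = np.arange(1 << (L + 1))
    prev_idx = configs >> 1
    succ = configs & mask
    p1 = float(model.prior.get(name, np.array([0.5, 0.5]))[1])
    states = np.arange(1 << L)
    p = np.empty(n)
    flag = np.zeros(n, dtype=bool)
    exp_E = np.exp(E - E.max(axis=1, keepdims=True))
    for m in range(n):
        h = min(m + tau, n - 1)
        r_h = h - L
        if r_h < 0:
            p[m] = p1
            flag[m] = True
            continue
        r0 = min(r_h, m - 1)
        bit = L + r0 - m  # position of beat m in the state after row r0
        gamma = alphas[r0 + 1]
        if r0 < r_h:
            beta = np.ones(1 << L)
            for r in range(r_h, r0, -1):
                contrib = trans * exp_E[r] * beta[succ]
                beta = np.bincount(prev_idx, weights=contrib,
                                   minlength=1 << L)
                beta /= beta.max()
            gamma = gamma * beta
            gamma = gamma / gamma.sum()
        p[m] = gamma[((states >> bit) & 1) == 1].sum()
    return ProbabilitySignal(p=p, t_s=None if t_s is None
                             else np.asarray(t_s, dtype=float),
                             prior_flag=flag)


def brute_force_posterior(model: CLGModel, observations, mode: str = "filter",
                          t_s=None) -> ProbabilitySignal:
    """Enumeration oracle: marginalize over every apnea sequence.

    Enumerates all 2^n hidden sequences (n = number of beats, capped at 16),
    weighting each by its prior, transition and emission factors. In
    ``filter`` mode beat t uses factors from evidence up to beat t only —
    exactly the quantity the forward recursion computes; ``smooth`` mode
    conditions every beat on the full recording.
    """
    if mode not in ("filter", "smooth"):
        raise ValueError("mode must be 'filter' or 'smooth'")
    _check_order(model)
    name = _hidden_name(model)
    data = _observation_table(model, observations)
    L = model.order
    R = len(data)
    n = R + L
    if n > 16:
        raise CapabilityError(f"enumeration over 2^{n} sequences refused (n > 16)")
    trans = _transition_table(model, name)
    E = _emission_matrix(model, data, name)
    p1 = float(model.prior.get(name, np.array([0.5, 0.5]))[1])

    seqs = np.arange(1 << n)
    bits = ((seqs[:, None] >> np.arange(n)[None, :]) & 1)  # bit j = beat j
    # prior over the first L beats
    logw0 = np.where(bits[:, :L] == 1, np.log(max(p1, 1e-300)),
                     np.log(max(1.0 - p1, 1e-300))).sum(axis=1)
    # per-row factors: config bit j = beat (L + r - j)
    row_terms = np.empty((R, len(seqs)))
    for r in range(R):
        c = np.zeros(len(seqs), dtype=int)
        for j in range(L + 1):
            c |= bits[:, L + r - j] << j
        with np.errstate(divide="ignore"):
            row_terms[r] = np.log(trans[c]) + E[r, c]
    cum = np.cumsum(row_terms, axis=0)

    p = np.empty(n)
    flag = np.zeros(n, dtype=bool)
    for m in range(n):
        if mode == "filter":
            r_last = m - L
            logw = logw0 if r_last < 0 else logw0 + cum[r_last]
            if r_last < 0:
                flag[m] = True
        else:
            logw = logw0 + cum[R - 1]
        mx = logw.max()
        w = np.exp(logw - mx)
        p[m] = w[bits[:, m] == 1].sum() / w.sum()
    return ProbabilitySignal(p=p, t_s=None if t_s is None
                             else np.asarray(t_s, dtype=float),
                             prior_flag=flag)


def training_rmse(p: ProbabilitySignal, labels: np.ndarray) -> float:
    """RMSE between the posterior and the binary labels, over beats with
    evidence (prior-flagged beats excluded)."""
    labels = np.asarray(labels, dtype=float)
    if len(labels) != len(p):
        raise ValueError(
            f"length mismatch: {len(p)} probabilities vs {len(labels)} labels")
    keep = ~p.prior_flag
    if not keep.any():
        raise ValueError("no evidence-bearing beats")
    d = p.p[keep] - labels[keep]
    return float(np.sqrt(np.mean(d * d)))
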