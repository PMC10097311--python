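"""Model/Results interface tying the pipeline together.

:class:`ApneaDBN` is built from per-beat data (marker columns plus a binary
apnea label); ``fit()`` learns the network structure (unless one is given),
estimates the CLG parameters by maximum likelihood and returns an
:class:`ApneaDBNResults` carrying the fitted model, its training-fit
diagnostics (log-likelihood, BIC, RMSE of the filtered posterior against the
labels) and a ``summary()`` table. Filtering new recordings, epoch
detection, simulation and plotting hang off the results object.

Marker series are detrended (order-20 polynomial) and z-scored per recording
before entering the network; the same preparation is applied to any new
recording passed to the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clg, detection, inference, preprocess, structure
from .records import BeatSeries, RunConfig

__all__ = ["ApneaDBN", "ApneaDBNResults", "default_fit_fn", "default_infer_fn"]

HIDDEN = "Ap"


def _prepared_series(bs: BeatSeries | pd.DataFrame, markers, poly_order: int,
                     normalize: bool) -> dict[str, np.ndarray]:
    if isinstance(bs, pd.DataFrame):
        bs = BeatSeries(table=bs)
    prep = preprocess.prepare_markers(bs, markers, poly_order=poly_order,
                                      normalize=normalize)
    return {m: prep[m].to_numpy() for m in markers}


class ApneaDBN:
    """Conditional linear Gaussian DBN for apnea detection.

    Parameters
    ----------
    data : BeatSeries or DataFrame
        Per-beat table with the marker columns and a binary ``apnea`` column
        (the training label).
    markers : sequence of str
        Marker series to include as continuous nodes (default RR + DS, the
        pairing with the best generalization in the motivating experiments).
    order : int
        Markov order L in beats (default 5; orders beyond ~5 mostly add
        complexity without better generalization).
    poly_order, normalize
        Detrending order and whether to z-score after detrending.
    """

    def __init__(self, data: BeatSeries | pd.DataFrame,
                 markers=("RR", "DS"), order: int = 5,
                 poly_order: int = 20, normalize: bool = True):
        if isinstance(data, pd.DataFrame):
            data = BeatSeries(table=data)
        if data.apnea is None:
            raise ValueError("training data needs an 'apnea' label column")
        if order < 1:
            raise ValueError("order must be >= 1")
        self.data = data
        self.markers = tuple(markers)
        self.order = int(order)
        self.poly_order = int(poly_order)
        self.normalize = bool(normalize)
        self.kinds = {HIDDEN: "discrete",
                      **{m: "continuous" for m in self.markers}}

    @classmethod
    def from_beat_series(cls, bs: BeatSeries, intervals=None, **kw) -> "ApneaDBN":
        """Build from a beat series, deriving labels from apnea intervals."""
        table = bs.table.copy()
        if intervals is not None:
            table["apnea"] = preprocess.label_beats(bs.t_s, intervals)
        return cls(BeatSeries(table=table, subject_id=bs.subject_id,
                              recording_id=bs.recording_id), **kw)

    @classmethod
    def from_config(cls, data, config: RunConfig) -> "ApneaDBN":
        return cls(data, markers=config.markers, order=config.order,
                   poly_order=config.poly_order)

    # -- fitting -----------------------------------------------------------

    def _series(self) -> dict[str, np.ndarray]:
        s = _prepared_series(self.data, self.markers, self.poly_order,
                             self.normalize)
        s[HIDDEN] = self.data.apnea.astype(int)
        return s

    def fit(self, structure_: clg.DBNStructure | None = None,
            alpha: float = 0.05, pseudocount: float = 0.5,
            force_self_chain: bool = False) -> "ApneaDBNResults":
        """Learn structure (unless given), fit MLE parameters, diagnose fit."""
        series = self._series()
        if structure_ is None:
            structure_ = structure.learn_dbn(
                series, self.kinds, self.order, alpha=alpha,
                pseudocount=pseudocount, force_self_chain=force_self_chain)
        data = clg.build_lagged_table(series, self.order)
        model = clg.fit_mle(structure_, data, pseudocount=pseudocount,
                            states={HIDDEN: [0, 1]})
        loglik = clg.joint_loglik(model, data)
        bic = model.bic(data)
        obs = {m: series[m] for m in self.markers}
        psig = inference.filter_posterior(model, obs, t_s=self.data.t_s)
        rmse = inference.training_rmse(psig, series[HIDDEN])
        return ApneaDBNResults(model=self, clg_model=model, loglik=loglik,
                               bic=bic, rmse=rmse,
                               train_posterior=psig)


@dataclass
class ApneaDBNResults:
    """Fitted apnea DBN with training diagnostics."""

    model: ApneaDBN
    clg_model: clg.CLGModel
    loglik: float
    bic: float
    rmse: float
    train_posterior: inference.ProbabilitySignal = field(repr=False, default=None)

    @property
    def structure(self) -> clg.DBNStructure:
        return self.clg_model.structure

    @property
    def n_arcs(self) -> int:
        return self.structure.n_arcs

    # -- inference on new data --------------------------------------------

    def _observations(self, data: BeatSeries | pd.DataFrame):
        m = self.model
        return _prepared_series(data, m.markers, m.poly_order, m.normalize)

    def filter(self, data: BeatSeries | pd.DataFrame,
               ) -> inference.ProbabilitySignal:
        """Per-beat filtered apnea posterior on a (new) recording."""
        bs = data if isinstance(data, BeatSeries) else BeatSeries(table=data)
        return inference.filter_posterior(self.clg_model,
                                          self._observations(bs),
                                          t_s=bs.t_s)

    def predict(self, data, delta_steps: int = 0) -> inference.ProbabilitySignal:
        bs = data if isinstance(data, BeatSeries) else BeatSeries(table=data)
        return inference.predict_ahead(self.clg_model,
                                       self._observations(bs), delta_steps,
                                       t_s=bs.t_s)

    def smooth(self, data, tau: int) -> inference.ProbabilitySignal:
        bs = data if isinstance(data, BeatSeries) else BeatSeries(table=data)
        return inference.fixed_lag_smooth(self.clg_model,
                                         self._observations(bs), tau,
                                         t_s=bs.t_s)

    def detect(self, data: BeatSeries | pd.DataFrame, intervals=(),
               delta: float = 0.2, smooth_window: int = 40,
               epoch_len_s: float = 15.0,
               duration_s: float | None = None) -> detection.EpochTable:
        """Filter, smooth, epoch and classify a recording."""
        psig = self.filter(data)
        sm = detection.smooth_posterior(psig, window_beats=smooth_window)
        epochs = detection.make_epochs(sm, epoch_len_s=epoch_len_s,
                                       apnea_intervals=intervals,
                                       duration_s=duration_s)
        return detection.classify_epochs(epochs, delta=delta)

    def simulate(self, n: int, seed: int = 0) -> pd.DataFrame:
        """Ancestral sample of n slices from the fitted network."""
        out = clg.sample_model(self.clg_model, n, seed=seed)
        return pd.DataFrame(out)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "Apnea CLG-DBN results",
            "=" * 52,
            f"markers:        {', '.join(m.markers)}",
            f"Markov order:   {m.order}",
            f"beats (train):  {len(m.data)}",
            f"arcs:           {self.n_arcs}",
            f"log-likelihood: {self.loglik:.3f}",
            f"BIC:            {self.bic:.3f}",
            f"training RMSE:  {self.rmse:.4f}",
            "-" * 52,
            "arcs (parent -> child):",
        ]
        for (pn, pl), (cn, cl) in sorted(self.structure.arcs):
            lines.append(f"  {pn}@{pl} -> {cn}@{cl}")
        lines.append("-" * 52)
        for name in sorted(self.clg_model.params):
            p = self.clg_model.params[name]
            if isinstance(p, clg.DiscreteNodeParams):
                for cfg, probs in sorted(p.cpt.items()):
                    pv = ", ".join(f"{q:.3f}" for q in probs)
                    lines.append(f"  P({name} | {cfg}) = [{pv}]")
            else:
                for cfg, (a, b, s) in sorted(p.table.items()):
                    bv = ", ".join(f"{q:+.3f}" for q in b)
                    lines.append(
                        f"  {name} | z_D={cfg}: alpha={a:+.3f} "
                        f"beta=[{bv}] sigma={s:.3f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        clg.save_model(self.clg_model, path)

    def plot_posterior(self, psig: inference.ProbabilitySignal,
                       labels=None, ax=None):
        """Plot a posterior trace (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = psig.t_s if psig.t_s is not None else np.arange(len(psig))
        ax.plot(t, psig.p, color="0.2", lw=0.8, label="P(apnea)")
        if labels is not None:
            ax.fill_between(t, 0, np.asarray(labels, dtype=float),
                            color="tab:red", alpha=0.2, label="apnea")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("probability")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(loc="upper right")
        return ax


# ---------------------------------------------------------------------------
# Default protocol hooks
# ---------------------------------------------------------------------------

def _as_intervals(sched_or_intervals):
    eps = getattr(sched_or_intervals, "episodes", sched_or_intervals)
    return list(eps)


def default_fit_fn(config: RunConfig):
    """Train an ApneaDBN on one (beat_series, schedule) recording tuple."""

    def fit(recording) -> ApneaDBNResults:
        bs, sched = recording
        intervals = None if bs.apnea is not None else _as_intervals(sched)
        m = ApneaDBN.from_beat_series(bs, intervals=intervals,
                                      markers=config.markers,
                                      order=config.order,
                                      poly_order=config.poly_order)
        return m.fit(alpha=config.alpha, pseudocount=config.pseudocount)

    return fit


def default_infer_fn(config: RunConfig):
    """Filter + smooth + epoch + classify one recording tuple."""

    def infer(results: ApneaDBNResults, recording) -> detection.EpochTable:
        bs, sched = recording
        duration = getattr(sched, "duration_s", None)
        return results.detect(bs, intervals=_as_intervals(sched),
                              delta=config.delta,
                              smooth_window=config.smooth_window,
                              epoch_len_s=config.epoch_len_s,
                              duration_s=duration)

    return infer
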