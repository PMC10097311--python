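"""Epoch-level apnea detection and performance scoring.

The per-beat posterior is smoothed with a centered moving average (default
40 beats, widened to 41 for symmetry), split into 15-s epochs anchored at
the recording start, and each epoch is called apneic when the RMS of the
smoothed posterior over its beats reaches the decision threshold delta. A
ground-truth epoch is apneic when at least half of it overlaps an annotated
episode (episodes and epochs are both 15 s, so grid alignment is a real
ambiguity; the overlap fraction is a parameter).

Two evaluation protocols:

* *ideal record-specific* — train and test on the same recording, one report
  per recording;
* *record-specific* — train on each rat's first recording, test on the
  remaining two.

Metrics are averaged per rat and then across rats (unweighted); per-
recording metrics that are undefined (no positive or no negative epochs)
are dropped from that rat's mean rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import ProbabilitySignal

logger = logging.getLogger(__name__)

__all__ = [
    "EpochTable",
    "PerformanceReport",
    "smooth_posterior",
    "make_epochs",
    "classify_epochs",
    "score",
    "rank_auc",
    "threshold_sweep",
    "run_protocol",
]


@dataclass
class EpochTable:
    """Per-epoch RMS, predicted and true labels.

    ``table`` columns: epoch, start_s, end_s, n_beats, rms, truth and (after
    classification) pred; epochs with no beats are marked invalid and are
    excluded from metrics.
    """

    table: pd.DataFrame
    epoch_len_s: float

    def valid(self) -> pd.DataFrame:
        return self.table[self.table["n_beats"] > 0]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PerformanceReport:
    """Confusion counts plus Se/Sp/Acc (percent) and rank-based AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None
    level: str = "recording"
    label: str = ""

    @property
    def se(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def sp(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    @property
    def acc(self) -> float | None:
        d = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / d if d else None

    def to_dict(self) -> dict:
        return {"label": self.label, "level": self.level,
                "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
                "Se": self.se, "Sp": self.sp, "Acc": self.acc, "AUC": self.auc}


def smooth_posterior(p: ProbabilitySignal | np.ndarray,
                     window_beats: int = 40) -> ProbabilitySignal:
    """Centered moving average of the posterior.

    Even windows are widened to the next odd length so the filter has
    symmetric phase; at the edges the window is truncated symmetrically
    (equal reach on both sides), which keeps the output inside [0, 1].
    """
    if isinstance(p, ProbabilitySignal):
        x, t_s, flag = p.p, p.t_s, p.prior_flag
    else:
        x = np.asarray(p, dtype=float)
        t_s, flag = None, None
    if window_beats < 1:
        raise ValueError("window must be >= 1")
    w = int(window_beats)
    if w % 2 == 0:
        w += 1
    n = len(x)
    if w > n:
        logger.warning("smoothing window %d exceeds series length %d; "
                       "returning the series mean", w, n)
        out = np.full(n, x.mean())
        return ProbabilitySignal(p=out, t_s=t_s, prior_flag=flag)
    half = w // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return ProbabilitySignal(p=out, t_s=t_s, prior_flag=flag)


def make_epochs(p_smoothed: ProbabilitySignal | np.ndarray,
                beat_times: np.ndarray | None = None,
                epoch_len_s: float = 15.0,
                apnea_intervals=(),
                duration_s: float | None = None,
                truth_overlap: float = 0.5) -> EpochTable:
    """Split the smoothed posterior into fixed epochs and compute RMS.

    Epochs tile [0, duration) on a grid anchored at the recording start.
    ``rms`` is the root mean square of the posterior over the beats whose
    R-peak time falls in the epoch; ``truth`` marks epochs whose overlap
    with annotated episodes is at least ``truth_overlap`` of the epoch
    length.
    """
    if isinstance(p_smoothed, ProbabilitySignal):
        p = p_smoothed.p
        if beat_times is None:
            beat_times = p_smoothed.t_s
    else:
        p = np.asarray(p_smoothed, dtype=float)
    if beat_times is None:
        raise ValueError("beat times are required")
    t = np.asarray(beat_times, dtype=float)
    if len(t) != len(p):
        raise ValueError("beat_times and posterior lengths differ")
    if len(t) == 0:
        raise ValueError("no beats: cannot build an epoch table")
    if duration_s is None:
        duration_s = float(t[-1]) + 1e-9
    n_epochs = int(np.ceil(duration_s / epoch_len_s))
    rows = []
    for k in range(n_epochs):
        start, end = k * epoch_len_s, (k + 1) * epoch_len_s
        mask = (t >= start) & (t < end)
        nb = int(mask.sum())
        rms = float(np.sqrt(np.mean(p[mask] ** 2))) if nb else np.nan
        overlap = sum(max(0.0, min(end, b) - max(start, a))
                      for a, b in apnea_intervals)
        truth = overlap >= truth_overlap * epoch_len_s
        rows.append({"epoch": k, "start_s": start, "end_s": end,
                     "n_beats": nb, "rms": rms, "truth": int(truth)})
    return EpochTable(table=pd.DataFrame(rows), epoch_len_s=epoch_len_s)


def classify_epochs(epochs: EpochTable, delta: float = 0.2) -> EpochTable:
    """Call an epoch apneic when its RMS reaches the threshold (rms >= delta)."""
    df = epochs.table.copy()
    df["pred"] = (df["rms"] >= delta).astype(int)
    df.loc[df["n_beats"] == 0, "pred"] = 0
    return EpochTable(table=df, epoch_len_s=epochs.epoch_len_s)


def rank_auc(scores: np.ndarray, truth: np.ndarray) -> float | None:
    """Rank-based AUC: P(random apneic epoch scores above a random normal
    one), ties counted one half. None when either class is absent."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    if n0 == 0 or n1 == 0:
        return None
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[truth == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def score(epochs: EpochTable, label: str = "",
          level: str = "recording") -> PerformanceReport:
    """Confusion counts, Se/Sp/Acc and rank AUC over the valid epochs."""
    df = epochs.valid()
    if len(df) == 0:
        raise ValueError("no valid epochs to score")
    if "pred" not in df.columns:
        raise ValueError("epochs are not classified; call classify_epochs")
    truth = df["truth"].to_numpy(dtype=int)
    pred = df["pred"].to_numpy(dtype=int)
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    auc = rank_auc(df["rms"].to_numpy(), truth)
    return PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc,
                             label=label, level=level)


def threshold_sweep(epochs: EpochTable,
                    deltas=np.round(np.arange(0.1, 1.0, 0.1), 10),
                    ) -> pd.DataFrame:
    """Se/Sp/Acc over a grid of decision thresholds."""
    rows = []
    for d in deltas:
        rep = score(classify_epochs(epochs, delta=float(d)))
        rows.append({"delta": float(d), "Se": rep.se, "Sp": rep.sp,
                     "Acc": rep.acc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

def _mean_ignoring_none(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


@dataclass
class ProtocolResult:
    """Per-recording, per-rat and population performance."""

    per_recording: list[PerformanceReport]
    per_rat: dict[str, dict[str, float | None]]
    population: dict[str, float | None]
    mode: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"mode": self.mode,
                "population": self.population,
                "per_rat": self.per_rat,
                "per_recording": [r.to_dict() for r in self.per_recording]}


def aggregate_reports(reports: list[PerformanceReport],
                      rat_of: list[str], mode: str = "") -> ProtocolResult:
    """Average metrics per rat, then across rats (unweighted means);
    undefined per-recording metrics are dropped from that rat's mean."""
    per_rat: dict[str, dict[str, float | None]] = {}
    rats = sorted(set(rat_of))
    for rat in rats:
        own = [r for r, rid in zip(reports, rat_of) if rid == rat]
        per_rat[rat] = {
            "Se": _mean_ignoring_none(r.se for r in own),
            "Sp": _mean_ignoring_none(r.sp for r in own),
            "Acc": _mean_ignoring_none(r.acc for r in own),
            "AUC": _mean_ignoring_none(r.auc for r in own),
        }
    population = {m: _mean_ignoring_none(per_rat[r][m] for r in rats)
                  for m in ("Se", "Sp", "Acc", "AUC")}
    return ProtocolResult(per_recording=reports, per_rat=per_rat,
                          population=population, mode=mode)


def run_protocol(dataset, mode: str, config=None,
                 fit_fn=None, infer_fn=None) -> ProtocolResult:
    """Run an evaluation protocol over a multi-rat dataset.

    ``dataset`` maps rat id to an ordered list of recordings; each recording
    is a tuple ``(beat_series, schedule_or_intervals)``. ``fit_fn`` trains a
    model on one recording; ``infer_fn(model, recording)`` returns the
    classified epoch table for a recording. Defaults build the standard
    pipeline from ``config`` (a RunConfig).
    """
    from .model import default_fit_fn, default_infer_fn
    from .records import RunConfig

    config = config or RunConfig()
    fit_fn = fit_fn or default_fit_fn(config)
    infer_fn = infer_fn or default_infer_fn(config)

    if mode not in ("ideal_record_specific", "record_specific"):
        raise ValueError(f"unknown protocol mode {mode!r}")
    reports: list[PerformanceReport] = []
    rat_of: list[str] = []
    for rat, recordings in sorted(dataset.items()):
        need = 1 if mode == "ideal_record_specific" else 2
        if len(recordings) < need:
            raise ValueError(
                f"rat {rat!r} has {len(recordings)} recordings; mode "
                f"{mode!r} needs at least {need}")
        if mode == "ideal_record_specific":
            pairs = [(rec, rec) for rec in recordings]
        else:
            train = recordings[0]
            pairs = [(train, rec) for rec in recordings[1:]]
        for i, (train, test) in enumerate(pairs):
            model = fit_fn(train)
            epochs = infer_fn(model, test)
            rep = score(epochs, label=f"{rat}/test{i + 1}")
            reports.append(rep)
            rat_of.append(rat)
    return aggregate_reports(reports, rat_of, mode=mode)
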