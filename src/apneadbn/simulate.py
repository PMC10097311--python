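"""Synthetic data emulating the obstructive-apnea rat protocol.

The experimental design being emulated: five anesthetized rats, each
undergoing three 15-minute recordings of recurrent obstructive apnea at event
frequencies F of 20, 40 and 60 events/hour (order randomized per rat,
balanced across the population), with every episode lasting exactly 15 s —
150 episodes in total, 30 per rat, over 15 recordings.

Three layers are generated, all fully seeded:

* :func:`generate_protocol` — the apnea schedules;
* :func:`generate_marker_series` — beat-to-beat RR and QRS-morphology marker
  series with apnea-coupled transients, slow drift, correlated morphology
  fluctuations and measurement noise;
* :func:`generate_raw_ecg` — a sampled ECG rendered from QRS templates at
  the generated beat times, for end-to-end exercise of the feature extractor.

The apnea response is modelled as an additive shift shared across markers
through a latent respiratory-effort factor, with exponential onset/offset
kinetics: during an episode the gating function g(t) rises toward 1 with time
constant ``tau_on`` and decays with ``tau_off`` after the obstruction is
released. This is the simplest structure that reproduces the wide, slow
posterior peaks seen around real episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .records import BeatSeries, ECGRecord, write_beat_series, write_intervals

__all__ = [
    "RecordingSchedule",
    "ProtocolSchedule",
    "GeneratorParams",
    "generate_protocol",
    "generate_marker_series",
    "generate_raw_ecg",
    "generate_dataset",
]

EPISODE_LEN_S = 15.0
RECORDING_LEN_S = 900.0
FREQUENCIES = (20, 40, 60)  # events/hour


@dataclass(frozen=True)
class RecordingSchedule:
    """One 15-min recording: its event frequency and episode intervals."""

    rat_id: str
    recording_id: str
    frequency: int                       # events/hour
    episodes: tuple[tuple[float, float], ...]
    duration_s: float = RECORDING_LEN_S

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)


@dataclass(frozen=True)
class ProtocolSchedule:
    """Full protocol: per rat, three recordings at F = 20, 40, 60 ev/h."""

    recordings: tuple[RecordingSchedule, ...]

    @property
    def rats(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            seen.setdefault(r.rat_id, None)
        return list(seen)

    def by_rat(self, rat_id: str) -> list[RecordingSchedule]:
        return [r for r in self.recordings if r.rat_id == rat_id]

    @property
    def total_episodes(self) -> int:
        return sum(r.n_episodes for r in self.recordings)


@dataclass(frozen=True)
class GeneratorParams:
    """Beat-level generator parameters.

    Effect sizes are expressed in units of each marker's baseline
    fluctuation SD, so "effect 2.5" means the apnea plateau shifts the marker
    by 2.5 baseline SDs. ``noise_sd`` (measurement noise) and
    ``drift_amplitude`` (slow trend over the recording) use the same units.
    Baseline marker means/SDs are rat-scale: RR ~0.13-0.17 s (350-450 bpm),
    R amplitude ~1 mV, QRS slopes of order 100 mV/s.
    """

    rr_mean_s: float = 0.15
    rr_rel_sd: float = 0.012             # relative AR(1) fluctuation of RR
    effects: dict = field(default_factory=lambda: {
        # apnea-plateau shift per marker, in baseline-SD units: pronounced
        # bradycardia (RR up) plus depolarization-morphology shifts
        "RR": 4.0, "Ra": 2.5, "Sa": -2.2, "US": 1.9, "DS": -3.2,
    })
    tau_on_s: float = 0.3                # obstruction onset response (s)
    tau_off_s: float = 0.3               # post-release recovery (s)
    ar_coef: float = 0.7                 # beat-to-beat AR(1) memory
    latent_load: float = 0.3             # shared effort-factor loading
    drift_amplitude: float = 1.5
    drift_order: int = 5
    noise_sd: float = 0.6
    # baseline morphology means (mV, mV/s)
    ra_mean: float = 1.0
    sa_mean: float = -0.35
    us_mean: float = 120.0
    ds_mean: float = -160.0
    morph_rel_sd: float = 0.03           # baseline SD as fraction of |mean|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rr_mean_s <= 0:
            raise ValueError("rr_mean_s must be positive")
        if self.tau_on_s < 0 or self.tau_off_s < 0:
            raise ValueError("time constants must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Default onset jitter (s). The protocol being emulated triggers episodes
#: under software control at a fixed frequency, so onsets are near-periodic;
#: the jitter default models sub-second trigger variability and can be
#: widened (up to MAX_JITTER_S) to emulate less regular event timing.
DEFAULT_JITTER_S = 0.5
MAX_JITTER_S = 10.0


def generate_protocol(n_rats: int = 5, seed: int = 0,
                      jitter_s: float = DEFAULT_JITTER_S) -> ProtocolSchedule:
    """Generate the apnea schedules for ``n_rats`` rats.

    Each rat gets three recordings, one per frequency in {20, 40, 60} ev/h in
    seeded-random order. Episodes are placed periodically with period
    3600/F s; each onset is jittered by a seeded uniform offset of at most
    ``jitter_s`` seconds (bounded by 10 s) and clipped so the full 15-s
    episode stays inside the recording. Defaults reproduce the protocol
    totals: 150 episodes, 30 per rat, 15 recordings.
    """
    if not 0 <= jitter_s <= MAX_JITTER_S:
        raise ValueError(f"jitter_s must lie in [0, {MAX_JITTER_S}]")
    if n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    rng = np.random.default_rng(seed)
    recordings = []
    for i in range(n_rats):
        order = rng.permutation(FREQUENCIES)
        for j, freq in enumerate(order):
            period = 3600.0 / freq
            n_ep = round(freq * RECORDING_LEN_S / 3600.0)
            eps = []
            for k in range(n_ep):
                onset = k * period + rng.uniform(0.0, jitter_s)
                onset = min(onset, RECORDING_LEN_S - EPISODE_LEN_S)
                eps.append((onset, onset + EPISODE_LEN_S))
            recordings.append(RecordingSchedule(
                rat_id=f"rat{i + 1}", recording_id=f"rat{i + 1}_rec{j + 1}",
                frequency=int(freq), episodes=tuple(eps)))
    return ProtocolSchedule(recordings=tuple(recordings))


def _gate(t: np.ndarray, episodes, tau_on: float, tau_off: float) -> np.ndarray:
    """Obstruction gating g(t): exponential rise inside episodes, decay after."""
    g = np.zeros_like(t)
    for onset, offset in episodes:
        inside = (t >= onset) & (t < offset)
        if tau_on > 0:
            g[inside] = np.maximum(g[inside],
                                   1.0 - np.exp(-(t[inside] - onset) / tau_on))
        else:
            g[inside] = 1.0
        after = t >= offset
        g_end = 1.0 - np.exp(-(offset - onset) / tau_on) if tau_on > 0 else 1.0
        if tau_off > 0:
            g[after] = np.maximum(g[after],
                                  g_end * np.exp(-(t[after] - offset) / tau_off))
    return g


def _smooth_drift(n: int, order: int, amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Seeded smooth random polynomial trend of degree <= order, SD ~ amplitude."""
    if amplitude == 0 or order == 0:
        return np.zeros(n)
    x = np.linspace(-1.0, 1.0, n)
    coefs = rng.standard_normal(order + 1)
    coefs[0] = 0.0
    trend = np.polynomial.legendre.legval(x, coefs)
    sd = trend.std()
    return trend * (amplitude / sd) if sd > 0 else trend


def generate_marker_series(schedule: RecordingSchedule,
                           params: GeneratorParams | None = None,
                           seed: int | None = None,
                           return_truth: bool = False):
    """Generate one recording's beat-to-beat marker series and apnea labels.

    Beats are placed sequentially: ``RR_t`` is the mean RR times
    ``(1 + AR(1) fluctuation)`` plus the apnea effect ``effect_RR * g(t)``
    (in baseline-SD units) and white measurement noise. Morphology markers
    are a baseline mean plus AR(1) fluctuation, a shared latent effort factor
    (inducing cross-marker correlation), the apnea shift ``effect * g(t)``,
    a slow seeded polynomial drift and measurement noise. ``RSd`` is derived
    exactly as ``Ra - Sa``. Labels mark beats whose R-peak time falls inside
    an episode interval.

    Returns a :class:`~apneadbn.records.BeatSeries` whose table carries the
    ``apnea`` column; with ``return_truth=True`` also returns a dict of
    noise-free per-beat modulation arrays (the gating signal and per-marker
    clean values) for generator-verification tests.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if params.rr_mean_s <= 0:
        raise ValueError("rr_mean_s must be positive")

    rr_sd = params.rr_mean_s * params.rr_rel_sd
    eff = dict(params.effects)

    # upper bound on beat count; trimmed after placement
    n_max = int(np.ceil(schedule.duration_s / (params.rr_mean_s * 0.7))) + 10

    a = params.ar_coef
    innov_sd = np.sqrt(1.0 - a * a)

    def ar1(n: int) -> np.ndarray:
        e = rng.standard_normal(n) * innov_sd
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = a * x[i - 1] + e[i]
        return x

    frac = ar1(n_max)                    # RR AR(1) fluctuation, unit SD
    latent = ar1(n_max)                  # shared respiratory-effort factor
    own = {m: ar1(n_max) for m in ("Ra", "Sa", "US", "DS")}
    noise = {m: rng.standard_normal(n_max)
             for m in ("RR", "Ra", "Sa", "US", "DS")}
    drift = {m: _smooth_drift(n_max, params.drift_order, params.drift_amplitude,
                              rng) for m in ("Ra", "Sa", "US", "DS")}
    drift["RR"] = _smooth_drift(n_max, params.drift_order,
                                params.drift_amplitude, rng)

    # sequential beat placement: RR of beat i spans (t_{i-1}, t_i]
    t = np.empty(n_max)
    rr = np.empty(n_max)
    gate = np.empty(n_max)
    t_prev = 0.0
    i = 0
    ep = schedule.episodes
    while True:
        g = _gate(np.array([t_prev]), ep, params.tau_on_s, params.tau_off_s)[0]
        rr_i = (params.rr_mean_s
                + rr_sd * frac[i]
                + rr_sd * eff.get("RR", 0.0) * g
                + rr_sd * drift["RR"][i]
                + rr_sd * params.noise_sd * noise["RR"][i])
        rr_i = max(rr_i, 0.3 * params.rr_mean_s)
        t_i = t_prev + rr_i
        if t_i >= schedule.duration_s or i >= n_max:
            break
        t[i], rr[i], gate[i] = t_i, rr_i, g
        t_prev = t_i
        i += 1
    n = i
    t, rr, gate = t[:n], rr[:n], gate[:n]

    base = {"Ra": params.ra_mean, "Sa": params.sa_mean,
            "US": params.us_mean, "DS": params.ds_mean}
    cols: dict[str, np.ndarray] = {"t_s": t, "RR": rr}
    clean: dict[str, np.ndarray] = {"gate": gate, "RR": rr - (
        rr_sd * params.noise_sd * noise["RR"][:n])}
    lam = params.latent_load
    for m in ("Ra", "Sa", "US", "DS"):
        sd = abs(base[m]) * params.morph_rel_sd
        fluct = np.sqrt(1 - lam * lam) * own[m][:n] + lam * latent[:n]
        signal = (base[m]
                  + sd * fluct
                  + sd * eff.get(m, 0.0) * gate
                  + sd * drift[m][:n])
        clean[m] = signal
        cols[m] = signal + sd * params.noise_sd * noise[m][:n]
    cols["RSd"] = cols["Ra"] - cols["Sa"]
    clean["RSd"] = clean["Ra"] - clean["Sa"]

    labels = np.zeros(n, dtype=int)
    for onset, offset in ep:
        labels |= ((t >= onset) & (t < offset)).astype(int)
    cols["apnea"] = labels

    order = ["t_s", "RR", "Ra", "Sa", "RSd", "US", "DS", "apnea"]
    bs = BeatSeries(table=pd.DataFrame({c: cols[c] for c in order}),
                    subject_id=schedule.rat_id,
                    recording_id=schedule.recording_id)
    if return_truth:
        return bs, clean
    return bs


# ---------------------------------------------------------------------------
# Raw-ECG rendering
# ---------------------------------------------------------------------------

def _qrs_template_lobes():
    """Gaussian lobe layout of a rat-scale QRS complex (centers s, widths s)."""
    return {
        "Q": (-0.008, 0.0015),
        "R": (0.0, 0.0022),
        "S": (0.007, 0.0020),
    }


def generate_raw_ecg(schedule: RecordingSchedule,
                     params: GeneratorParams | None = None,
                     fs: float = 1250.0,
                     wander_amp_mv: float = 0.0,
                     noise_mv: float = 0.0,
                     seed: int | None = None) -> tuple[ECGRecord, BeatSeries]:
    """Render a sampled ECG from QRS templates at generated beat times.

    Each beat places a piecewise-Gaussian Q/R/S complex whose R and S lobe
    amplitudes follow the per-beat ground-truth ``Ra``/``Sa`` markers from
    :func:`generate_marker_series`. Low-frequency sinusoidal baseline wander
    and white noise are optional. Returns the record and the ground-truth
    beat series.
    """
    if fs < 250:
        raise ValueError("fs too low to render the QRS template (< 250 Hz)")
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    truth = generate_marker_series(schedule, params, seed=seed)

    n = int(round(schedule.duration_s * fs))
    x = np.zeros(n)
    tt = np.arange(n) / fs
    lobes = _qrs_template_lobes()
    qc, qw = lobes["Q"]
    rc, rw = lobes["R"]
    sc, sw = lobes["S"]
    half = int(round(0.02 * fs)) + 1
    for t_beat, ra, sa in zip(truth.t_s, truth.marker("Ra"), truth.marker("Sa")):
        c = int(round(t_beat * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        ts = tt[lo:hi] - t_beat
        x[lo:hi] += (-0.12 * ra * np.exp(-0.5 * ((ts - qc) / qw) ** 2)
                     + ra * np.exp(-0.5 * ((ts - rc) / rw) ** 2)
                     + sa * np.exp(-0.5 * ((ts - sc) / sw) ** 2))
    if wander_amp_mv > 0:
        for f, amp in ((0.31, 1.0), (0.77, 0.55), (1.13, 0.3)):
            phase = rng.uniform(0, 2 * np.pi)
            x += wander_amp_mv * amp * np.sin(2 * np.pi * f * tt + phase)
    if noise_mv > 0:
        x += noise_mv * rng.standard_normal(n)
    rec = ECGRecord(signal=x, fs=fs,
                    annotations=list(schedule.episodes),
                    subject_id=schedule.rat_id,
                    recording_id=schedule.recording_id)
    return rec, truth


def generate_dataset(out_dir: str | Path | None = None, n_rats: int = 5,
                     seed: int = 0,
                     params: GeneratorParams | None = None,
                     jitter_s: float = DEFAULT_JITTER_S,
                     ) -> dict[str, list[tuple[BeatSeries, RecordingSchedule]]]:
    """Generate (and optionally write) the full multi-rat beat-series dataset.

    Per-recording seeds are derived from the root seed through a seeded
    SeedSequence spawn, so the dataset is reproducible as a whole. Each rat
    draws its own mean RR from the 350-450 bpm range. When ``out_dir`` is
    given, beat-series and interval CSVs are written there.
    """
    base = params or GeneratorParams()
    protocol = generate_protocol(n_rats=n_rats, seed=seed, jitter_s=jitter_s)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(n_rats * 3 + n_rats)]
    rat_rr_rng = np.random.default_rng(child_seeds[-n_rats:][0])
    rr_means = {rat: 60.0 / rat_rr_rng.uniform(350.0, 450.0)
                for rat in protocol.rats}
    dataset: dict[str, list[tuple[BeatSeries, RecordingSchedule]]] = {}
    for idx, sched in enumerate(protocol.recordings):
        p = replace(base, rr_mean_s=rr_means[sched.rat_id])
        bs = generate_marker_series(sched, p, seed=child_seeds[idx])
        dataset.setdefault(sched.rat_id, []).append((bs, sched))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rat, recs in dataset.items():
            for bs, sched in recs:
                write_beat_series(bs, out / f"{sched.recording_id}.beats.csv")
                write_intervals(sched.episodes,
                                out / f"{sched.recording_id}.intervals.csv")
    return dataset
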