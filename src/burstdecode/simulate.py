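"""Synthetic intracranial EEG sessions for the delayed verbal free-recall task.

The generator emulates the structure of a single free-recall experiment:
lists of 12 words shown for 1,600 ms each, separated by a 750-1,000 ms blank
inter-stimulus interval, followed by a 20 s arithmetic distractor and a 30 s
free-recall period.  Channels carry 1/f-shaped background noise plus optional
60 Hz line contamination, and discrete oscillatory bursts (Hann-windowed
sinusoids) in the high-gamma (80-200 Hz) and beta (15-40 Hz) bands whose
rate and amplitude depend on the trial class.  Every injected burst is
recorded in a ground-truth table so downstream detection, tensorization and
decoding stages can be validated without any external recordings.

Channels are generated as an already bipolar-referenced montage (independent
channels); a referential layout for exercising the bipolar re-referencing
step can be built from the same primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WordEvent",
    "TaskSchedule",
    "BurstSpec",
    "SyntheticSession",
    "generate_schedule",
    "simulate_background",
    "plant_bursts",
    "inject_bursts",
    "simulate_session",
    "write_session",
    "read_session",
    "HG_SPEC",
    "BETA_SPEC",
    "RECALL_HG_SPEC",
    "RECALL_BETA_SPEC",
    "SUPPORTED_FS",
]

#: sampling rates used across the study's recording sites
SUPPORTED_FS = (500, 512, 1000, 1024, 2000)

WORD_DURATION_S = 1.6
ISI_RANGE_S = (0.75, 1.0)
DISTRACTOR_S = 20.0
RECALL_S = 30.0
WORDS_PER_LIST = 12


@dataclass(frozen=True)
class WordEvent:
    list_index: int
    word_index: int
    onset_s: float
    duration_s: float = WORD_DURATION_S


@dataclass(frozen=True)
class TaskSchedule:
    """Event times of one delayed free-recall experiment."""

    word_events: tuple[WordEvent, ...]
    distractor_windows: tuple[tuple[float, float], ...]
    recall_windows: tuple[tuple[float, float], ...]

    @property
    def n_lists(self) -> int:
        return len(self.recall_windows)

    @property
    def n_words(self) -> int:
        return len(self.word_events)

    @property
    def end_s(self) -> float:
        onset, dur = self.recall_windows[-1]
        return onset + dur

    def validate(self) -> None:
        if self.n_words != WORDS_PER_LIST * self.n_lists:
            raise ValueError("schedule must contain 12 words per list")
        for li in range(self.n_lists):
            words = [w for w in self.word_events if w.list_index == li]
            onsets = [w.onset_s for w in words]
            if len(words) != WORDS_PER_LIST:
                raise ValueError(f"list {li} does not have 12 word events")
            if not all(b - a > WORD_DURATION_S for a, b in zip(onsets, onsets[1:])):
                raise ValueError(f"list {li} word events overlap or are unordered")
            d_on, d_dur = self.distractor_windows[li]
            r_on, _ = self.recall_windows[li]
            if not np.isclose(d_on, onsets[-1] + WORD_DURATION_S):
                raise ValueError("distractor must immediately follow word 12")
            if not np.isclose(r_on, d_on + d_dur):
                raise ValueError("recall must immediately follow the distractor")


def generate_schedule(
    n_lists: int,
    seed: int,
    *,
    isi_range: tuple[float, float] = ISI_RANGE_S,
    start_s: float = 2.0,
    inter_list_gap_s: float = 2.0,
) -> TaskSchedule:
    """Draw the event schedule for ``n_lists`` lists of 12 words.

    Inter-stimulus intervals are drawn uniformly from ``isi_range``
    (default 0.75-1.0 s).  Each list ends with a 20 s distractor followed
    immediately by a 30 s free-recall window.
    """
    if n_lists < 1:
        raise ValueError("n_lists must be >= 1")
    rng = np.random.default_rng(seed)
    words: list[WordEvent] = []
    distractors: list[tuple[float, float]] = []
    recalls: list[tuple[float, float]] = []
    t = float(start_s)
    for li in range(n_lists):
        for wi in range(WORDS_PER_LIST):
            words.append(WordEvent(li, wi, round(t, 6)))
            t += WORD_DURATION_S
            if wi < WORDS_PER_LIST - 1:
                t += float(rng.uniform(*isi_range))
        distractors.append((round(t, 6), DISTRACTOR_S))
        t += DISTRACTOR_S
        recalls.append((round(t, 6), RECALL_S))
        t += RECALL_S + inter_list_gap_s
    sched = TaskSchedule(tuple(words), tuple(distractors), tuple(recalls))
    sched.validate()
    return sched


@dataclass(frozen=True)
class BurstSpec:
    """Rate/shape/amplitude distribution of one band's oscillatory bursts.

    ``rate_hz`` is the mean number of bursts per second per channel inside a
    trial window; burst timing is a Poisson process, with bursts that would
    cross the window edge re-drawn inside it.  Amplitudes are the peak of the
    Hann-windowed sinusoid in microvolts.  ``class_multipliers`` maps a trial
    label to ``(rate_multiplier, amplitude_multiplier)``.
    """

    band: str  # "hg" or "beta"
    rate_hz: float
    center_freq_hz: float
    freq_jitter_hz: float
    duration_mean_s: float
    duration_sd_s: float
    amp_mean_uv: float
    amp_sd_uv: float
    class_multipliers: dict = field(default_factory=dict)

    BAND_LIMITS = {"hg": (80.0, 200.0), "beta": (15.0, 40.0)}

    def __post_init__(self):
        if self.band not in self.BAND_LIMITS:
            raise ValueError(f"unknown band {self.band!r}")
        lo, hi = self.BAND_LIMITS[self.band]
        if not (lo <= self.center_freq_hz <= hi):
            raise ValueError(f"{self.band} center frequency must lie in [{lo}, {hi}]")
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be >= 0")
        if self.duration_mean_s <= 0:
            raise ValueError("duration_mean_s must be > 0")

    def with_multipliers(self, multipliers: dict) -> "BurstSpec":
        return replace(self, class_multipliers=dict(multipliers))


# Default study conditions.  Background RMS is 20 uV; burst amplitudes of
# 8x the background standard deviation keep planted events comfortably above
# the wavelet detection threshold, mirroring recordings that pass the
# low-voltage quality screen.
BACKGROUND_RMS_UV = 20.0

HG_SPEC = BurstSpec("hg", rate_hz=1.0, center_freq_hz=120.0, freq_jitter_hz=30.0,
                    duration_mean_s=0.15, duration_sd_s=0.04,
                    amp_mean_uv=8.0 * BACKGROUND_RMS_UV, amp_sd_uv=2.0 * BACKGROUND_RMS_UV)
BETA_SPEC = BurstSpec("beta", rate_hz=0.8, center_freq_hz=25.0, freq_jitter_hz=8.0,
                      duration_mean_s=0.20, duration_sd_s=0.05,
                      amp_mean_uv=8.0 * BACKGROUND_RMS_UV, amp_sd_uv=2.0 * BACKGROUND_RMS_UV)
# The recall period is not characterized by the task literature beyond its
# timing; a distinct burst regime (more high-gamma, less beta) is a modeling
# choice that makes the memory-state contrast learnable.
RECALL_HG_SPEC = replace(HG_SPEC, rate_hz=2.0)
RECALL_BETA_SPEC = replace(BETA_SPEC, rate_hz=0.3)

MIN_BURST_DURATION_S = 0.05


def simulate_background(
    n_channels: int,
    duration_s: float,
    fs_hz: int,
    *,
    line_amp_uv: float = 2.0,
    slope: float = -2.0,
    rms_uv: float = BACKGROUND_RMS_UV,
    seed: int = 0,
) -> np.ndarray:
    """1/f-shaped Gaussian noise plus a 60 Hz line component, in microvolts.

    Each channel is generated from an independent child seed, so channels are
    mutually uncorrelated.  The power spectral density follows ``f**slope``
    (default -2) and the trace is rescaled to ``rms_uv`` RMS before the line
    sinusoid is added.
    """
    if fs_hz not in SUPPORTED_FS:
        raise ValueError(f"fs_hz must be one of {SUPPORTED_FS}, got {fs_hz}")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = int(round(duration_s * fs_hz))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (slope / 2.0)
    t = np.arange(n) / fs_hz
    out = np.empty((n_channels, n), dtype=np.float64)
    streams = np.random.SeedSequence(seed).spawn(n_channels)
    for ch, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        white = rng.standard_normal(n)
        x = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
        x *= rms_uv / np.std(x)
        if line_amp_uv > 0:
            x = x + line_amp_uv * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        out[ch] = x
    return out


TRUTH_COLUMNS = ["channel", "band", "onset_s", "offset_s", "freq_hz", "amp_uv",
                 "trial_kind", "trial_id", "label"]


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=TRUTH_COLUMNS)


def plant_bursts(signal: np.ndarray, fs_hz: float, bursts: pd.DataFrame) -> np.ndarray:
    """Add Hann-windowed sinusoids described by ``bursts`` to ``signal`` in place.

    ``bursts`` needs columns channel, onset_s, offset_s, freq_hz, amp_uv.
    """
    n = signal.shape[1]
    for row in bursts.itertuples(index=False):
        i0 = int(round(row.onset_s * fs_hz))
        i1 = int(round(row.offset_s * fs_hz))
        m = i1 - i0
        if m < 4:
            continue
        t = np.arange(m) / fs_hz
        wave = row.amp_uv * np.hanning(m) * np.sin(2 * np.pi * row.freq_hz * t)
        lo, hi = max(i0, 0), min(i1, n)
        if hi <= lo:
            continue
        signal[int(row.channel), lo:hi] += wave[lo - i0:hi - i0]
    return signal


def _draw_bursts_for_window(rng, spec: BurstSpec, channel: int,
                            onset: float, duration: float,
                            trial_kind: str, trial_id, label) -> list[dict]:
    rate_mult, amp_mult = spec.class_multipliers.get(label, (1.0, 1.0))
    rate = spec.rate_hz * rate_mult
    n = rng.poisson(rate * duration) if rate > 0 else 0
    lo, hi = BurstSpec.BAND_LIMITS[spec.band]
    events = []
    for _ in range(n):
        d = float(np.clip(rng.normal(spec.duration_mean_s, spec.duration_sd_s),
                          MIN_BURST_DURATION_S, None))
        # the burst center falls inside the window; tails may spill over, so
        # burst statistics stay stationary across window boundaries when
        # neighboring windows share a regime
        center = float(rng.uniform(onset, onset + duration))
        start = center - d / 2.0
        f = float(np.clip(spec.center_freq_hz + rng.uniform(-1, 1) * spec.freq_jitter_hz, lo, hi))
        a = float(max(rng.normal(spec.amp_mean_uv * amp_mult, spec.amp_sd_uv), 0.0))
        events.append(dict(channel=channel, band=spec.band, onset_s=start,
                           offset_s=start + d, freq_hz=f, amp_uv=a,
                           trial_kind=trial_kind, trial_id=trial_id, label=label))
    return events


def inject_bursts(
    signal: np.ndarray,
    fs_hz: float,
    windows: list[tuple[float, float, str, object, object]],
    spec: BurstSpec,
    seed: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Inject Poisson-timed bursts of one band into trial windows.

    ``windows`` is a list of ``(onset_s, duration_s, trial_kind, trial_id,
    label)``; the label selects the class multiplier from ``spec``.  Bursts
    never cross a window edge.  Returns the modified signal and the exact
    ground-truth table of every injected burst.
    """
    rng = np.random.default_rng(seed)
    all_events: list[dict] = []
    for ch in range(signal.shape[0]):
        for onset, duration, kind, tid, label in windows:
            all_events.extend(
                _draw_bursts_for_window(rng, spec, ch, onset, duration, kind, tid, label))
    truth = pd.DataFrame(all_events, columns=TRUTH_COLUMNS)
    if len(truth):
        # keep ground truth inside the recording (spill past the edges is
        # possible only when a window abuts the recording boundary)
        end_s = signal.shape[1] / fs_hz
        truth = truth[(truth.onset_s >= 0) & (truth.offset_s <= end_s)]
        truth = truth.reset_index(drop=True)
        plant_bursts(signal, fs_hz, truth)
    return signal, truth


@dataclass
class SyntheticSession:
    """One simulated experiment: signal, schedule, behavior and ground truth."""

    signal: np.ndarray  # channels x samples, microvolts (bipolar montage)
    fs_hz: int
    schedule: TaskSchedule
    recalled: np.ndarray  # bool per word event
    recall_counts: np.ndarray  # words recalled per list
    truth_bursts: pd.DataFrame
    seed: int
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs_hz


def simulate_session(
    n_lists: int = 20,
    n_channels: int = 2,
    fs_hz: int = 500,
    *,
    recall_p: float = 0.25,
    hg_spec: BurstSpec = HG_SPEC,
    beta_spec: BurstSpec = BETA_SPEC,
    recall_hg_spec: BurstSpec = RECALL_HG_SPEC,
    recall_beta_spec: BurstSpec = RECALL_BETA_SPEC,
    hg_effect: tuple[float, float] = (1.5, 1.0),
    beta_effect: tuple[float, float] = (1.0, 1.0),
    line_amp_uv: float = 2.0,
    channel_gain: np.ndarray | None = None,
    seed: int = 0,
) -> SyntheticSession:
    """Simulate a full delayed free-recall session.

    Each word is independently recalled with probability ``recall_p``;
    recalled-word encoding windows receive the ``hg_effect``/``beta_effect``
    ``(rate, amplitude)`` multipliers.  Recall windows receive their own burst
    regime.  ``channel_gain`` optionally scales individual channels (e.g. to
    produce low-voltage channels for the quality screen).
    """
    if not 0.0 <= recall_p <= 1.0:
        raise ValueError("recall_p must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    s_sched, s_bg, s_beh, s_hg, s_beta, s_rhg, s_rbeta = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(7)]

    schedule = generate_schedule(n_lists, s_sched)
    duration = schedule.end_s + 2.0
    signal = simulate_background(n_channels, duration, fs_hz,
                                 line_amp_uv=line_amp_uv, seed=s_bg)
    if channel_gain is not None:
        signal *= np.asarray(channel_gain, dtype=float)[:, None]

    rng_beh = np.random.default_rng(s_beh)
    recalled = rng_beh.random(schedule.n_words) < recall_p
    recall_counts = np.array([
        int(recalled[[w.list_index == li for w in schedule.word_events]].sum())
        for li in range(n_lists)])

    # Complete, non-overlapping partition of the session into burst windows:
    # word windows span word onset to the next word (word + ISI) and carry
    # the class multiplier; distractor periods and gaps carry the baseline
    # regime, so with all multipliers at 1 burst statistics are stationary
    # across the whole recording.
    enc_windows: list[tuple[float, float, str, object, object]] = []
    bg_windows: list[tuple[float, float, str, object, object]] = []
    cursor = 0.0
    for li in range(n_lists):
        words = [w for w in schedule.word_events if w.list_index == li]
        first_on = words[0].onset_s
        if first_on > cursor:
            bg_windows.append((cursor, first_on - cursor, "BG", -1, "bg"))
        for j, w in enumerate(words):
            wi = li * WORDS_PER_LIST + j
            end = words[j + 1].onset_s if j + 1 < len(words) \
                else w.onset_s + w.duration_s
            enc_windows.append((w.onset_s, end - w.onset_s, "WORD", wi,
                                int(recalled[wi])))
        d_on, d_dur = schedule.distractor_windows[li]
        bg_windows.append((d_on, d_dur, "BG", -1, "bg"))
        r_on, r_dur = schedule.recall_windows[li]
        cursor = r_on + r_dur
    rec_windows = [
        (onset, dur, "RECALL", li, "recall")
        for li, (onset, dur) in enumerate(schedule.recall_windows)]

    _, t1 = inject_bursts(signal, fs_hz, enc_windows + bg_windows,
                          hg_spec.with_multipliers({1: hg_effect}), s_hg)
    _, t2 = inject_bursts(signal, fs_hz, enc_windows + bg_windows,
                          beta_spec.with_multipliers({1: beta_effect}), s_beta)
    _, t3 = inject_bursts(signal, fs_hz, rec_windows, recall_hg_spec, s_rhg)
    _, t4 = inject_bursts(signal, fs_hz, rec_windows, recall_beta_spec, s_rbeta)
    truth = pd.concat([t1, t2, t3, t4], ignore_index=True)

    names = [f"LSMG{i + 1}-LSMG{i + 2}" for i in range(n_channels)]
    return SyntheticSession(signal=signal, fs_hz=fs_hz, schedule=schedule,
                            recalled=recalled, recall_counts=recall_counts,
                            truth_bursts=truth, seed=seed, channel_names=names)


# ---------------------------------------------------------------------------
# BIDS-iEEG-style on-disk layout: raw float32 + JSON sidecar, events/channels
# TSV, ground-truth burst TSV.

def write_session(session: SyntheticSession, out_dir, prefix: str = "sub-synth") -> None:
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig = session.signal.astype("<f4")
    (out / f"{prefix}_ieeg.bin").write_bytes(sig.tobytes())
    sidecar = {
        "dtype": "float32", "byte_order": "little", "order": "C",
        "shape": list(sig.shape), "units": "uV",
        "sampling_frequency_hz": session.fs_hz, "seed": session.seed,
    }
    (out / f"{prefix}_ieeg.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    rows = []
    for i, w in enumerate(session.schedule.word_events):
        rows.append(dict(onset=w.onset_s, duration=w.duration_s, trial_type="WORD",
                         item=i, recalled=int(session.recalled[i])))
    for onset, dur in session.schedule.distractor_windows:
        rows.append(dict(onset=onset, duration=dur, trial_type="DISTRACTOR",
                         item=-1, recalled=-1))
    for onset, dur in session.schedule.recall_windows:
        rows.append(dict(onset=onset, duration=dur, trial_type="REC_START",
                         item=-1, recalled=-1))
    events = pd.DataFrame(rows).sort_values("onset", kind="stable")
    events.to_csv(out / f"{prefix}_events.tsv", sep="\t", index=False)

    chans = pd.DataFrame({
        "name": session.channel_names or [f"ch{i}" for i in range(session.n_channels)],
        "type": "ECOG", "units": "uV", "sampling_frequency": session.fs_hz})
    chans.to_csv(out / f"{prefix}_channels.tsv", sep="\t", index=False)
    session.truth_bursts.to_csv(out / "truth_bursts.tsv", sep="\t", index=False)


def read_session(in_dir, prefix: str = "sub-synth") -> SyntheticSession:
    """Load a session written by :func:`write_session`."""
    import json
    from pathlib import Path

    src = Path(in_dir)
    sidecar = json.loads((src / f"{prefix}_ieeg.json").read_text())
    sig = np.frombuffer((src / f"{prefix}_ieeg.bin").read_bytes(), dtype="<f4")
    sig = sig.reshape(sidecar["shape"]).astype(np.float64)
    fs = sidecar["sampling_frequency_hz"]
    events = pd.read_csv(src / f"{prefix}_events.tsv", sep="\t")
    words = events[events.trial_type == "WORD"].sort_values("item")
    dists = events[events.trial_type == "DISTRACTOR"].sort_values("onset")
    recs = events[events.trial_type == "REC_START"].sort_values("onset")
    n_lists = len(recs)
    word_events = tuple(
        WordEvent(i // WORDS_PER_LIST, i % WORDS_PER_LIST, float(r.onset), float(r.duration))
        for i, r in enumerate(words.itertuples(index=False)))
    schedule = TaskSchedule(
        word_events,
        tuple((float(r.onset), float(r.duration)) for r in dists.itertuples(index=False)),
        tuple((float(r.onset), float(r.duration)) for r in recs.itertuples(index=False)))
    recalled = words.recalled.to_numpy().astype(bool)
    recall_counts = np.array([
        int(recalled[li * WORDS_PER_LIST:(li + 1) * WORDS_PER_LIST].sum())
        for li in range(n_lists)])
    truth_path = src / "truth_bursts.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else _empty_truth()
    chans = pd.read_csv(src / f"{prefix}_channels.tsv", sep="\t")
    return SyntheticSession(signal=sig, fs_hz=int(fs), schedule=schedule,
                            recalled=recalled, recall_counts=recall_counts,
                            truth_bursts=truth, seed=int(sidecar.get("seed", -1)),
                            channel_names=list(chans.name))
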