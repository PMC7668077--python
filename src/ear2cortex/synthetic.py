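"""Synthetic stimuli and simulated A1-like units with known ground truth.

Real cortical recordings are scarce and noisy; this module builds
benchmark datasets whose generating parameters are known exactly, so
every pipeline stage — front end, STRF/LN fitting, CC_norm scoring, and
the noise-ratio inclusion filter — can be validated quantitatively.

A simulated unit is an LN neuron: a ground-truth STRF (Gaussian
excitatory blob with a lagging inhibitory blob) applied to the
cochleagram of a chosen front end, a 4-parameter sigmoid output
nonlinearity, a rate gain, and independent Poisson spike counts per
repeat.  The rate gain doubles as a *noise dial*: under Poisson
statistics the expected noise ratio of a unit is mean(r)/Var(r) over
its rate trace r, so a requested noise ratio is hit by an analytic
gain calibration (see `gain_for_noise_ratio`).

The default benchmark emulates the structure of a natural-sound
recording session: 20 stimulus snippets of 5 s each, responses binned
at the cochleagram resolution with multiple repeats, and a 16/4
train/test split of the stimuli.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.signal import butter, filtfilt

from .frontend import (
    AudioSignal,
    Cochleagram,
    ConfigurationError,
    InputError,
    write_wav,
    read_wav,
)
from .encoding import STRF, SigmoidParams, predict_design, lag_design_matrix
from .evaluation import NeuralRecording

logger = logging.getLogger("ear2cortex")

DEFAULT_SAMPLE_RATE = 48000.0
#: natural-sound-session analog: 20 snippets x 5 s, 16 train / 4 test
DEFAULT_N_SNIPPETS = 20
DEFAULT_SNIPPET_S = 5.0
DEFAULT_SPLIT = (16, 4)
DEFAULT_N_REPEATS = 10
#: dynamic-random-chord analog: random tone levels over 40 dB, 25-ms hops
DEFAULT_CHORD_HOP_MS = 25.0
DEFAULT_CHORD_RANGE_DB = 40.0


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Recipe for one synthetic sound snippet.

    ``kind`` is one of ``click | pure_tone | white_noise | am_noise |
    chord_sequence``.  ``am_noise`` is white noise multiplied by a slow
    (< ``am_cutoff_hz``) positive envelope — a stand-in for the slow
    spectrotemporal modulation of natural sounds.  ``chord_sequence``
    draws a random level per tone per hop, uniformly over a
    ``chord_range_db`` range.
    """

    kind: str
    duration_s: float = DEFAULT_SNIPPET_S
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0
    tone_freq: float = 1000.0
    chord_hop_ms: float = DEFAULT_CHORD_HOP_MS
    chord_range_db: float = DEFAULT_CHORD_RANGE_DB
    n_chord_tones: int = 24
    chord_f_min: float = 500.0
    chord_f_max: float = 22627.0
    am_cutoff_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.kind == "chord_sequence" and self.chord_hop_ms <= 0:
            raise ConfigurationError("chord_hop_ms must be positive")


def gen_stimulus(spec: StimulusSpec) -> AudioSignal:
    """Deterministically synthesize a peak-normalized snippet."""
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "click":
        x = np.zeros(n)
        x[n // 2] = 1.0
    elif spec.kind == "pure_tone":
        if spec.tone_freq >= fs / 2:
            raise ConfigurationError(
                f"tone at {spec.tone_freq} Hz is at/above Nyquist ({fs / 2} Hz)"
            )
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * spec.tone_freq * t)
    elif spec.kind == "white_noise":
        x = rng.standard_normal(n)
    elif spec.kind == "am_noise":
        carrier = rng.standard_normal(n)
        slow = rng.standard_normal(n)
        b, a = butter(4, spec.am_cutoff_hz / (fs / 2), btype="low")
        env = filtfilt(b, a, slow)
        env = env - env.min()  # positive envelope
        peak = env.max()
        if peak > 0:
            env /= peak
        x = carrier * env
    elif spec.kind == "chord_sequence":
        if spec.chord_f_max >= fs / 2:
            raise ConfigurationError("chord tones must stay below Nyquist")
        hop = int(round(spec.chord_hop_ms * fs / 1000.0))
        n_hops = int(np.ceil(n / hop))
        freqs = np.geomspace(spec.chord_f_min, spec.chord_f_max, spec.n_chord_tones)
        # per-tone per-hop level, uniform over chord_range_db below full scale
        levels_db = -spec.chord_range_db * rng.random((spec.n_chord_tones, n_hops))
        amps = 10.0 ** (levels_db / 20.0)
        env = np.repeat(amps, hop, axis=1)[:, :n]
        # short linear cross-fade between hops to avoid broadband clicks
        ramp = max(int(0.002 * fs), 1)
        kernel = np.ones(ramp) / ramp
        env = np.apply_along_axis(
            lambda e: np.convolve(e, kernel, mode="same"), 1, env
        )
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, spec.n_chord_tones)
        x = np.zeros(n)
        for f, ph, e in zip(freqs, phases, env):
            x += e * np.sin(2 * np.pi * f * t + ph)
    else:
        raise ConfigurationError(f"unknown stimulus kind {spec.kind!r}")
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return AudioSignal(x, fs)


def default_stimulus_suite(
    n_snippets: int = DEFAULT_N_SNIPPETS,
    snippet_s: float = DEFAULT_SNIPPET_S,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    kinds: Sequence[str] = ("am_noise", "chord_sequence"),
) -> list[StimulusSpec]:
    """A session-like suite alternating amplitude-modulated noise and chords."""
    return [
        StimulusSpec(
            kind=kinds[i % len(kinds)],
            duration_s=snippet_s,
            sample_rate=sample_rate,
            seed=seed * 100003 + i,
        )
        for i in range(n_snippets)
    ]


# ---------------------------------------------------------------------------
# Ground-truth receptive fields
# ---------------------------------------------------------------------------

def gen_ground_truth_strf(
    bf: float,
    latency_ms: float,
    bandwidth_oct: float,
    inhibition_delay_ms: float,
    ie_target: float,
    center_freqs: np.ndarray,
    n_lags: int,
    bin_ms: float,
    temporal_width_ms: float = 10.0,
) -> STRF:
    """Gabor-style ground-truth STRF: excitatory blob + lagging inhibition.

    The excitatory field is a Gaussian at (``bf``, ``latency_ms``) with
    ``bandwidth_oct`` spectral s.d. (octaves) and ``temporal_width_ms``
    temporal s.d.; the inhibitory field is the same blob delayed by
    ``inhibition_delay_ms`` and scaled (by scalar root finding on the
    final matrix) so the inhibitory/excitatory mass ratio matches
    ``ie_target`` within 5%.  The peak positive weight is normalized to 1.
    """
    center_freqs = np.asarray(center_freqs, float)
    if not (center_freqs[0] <= bf <= center_freqs[-1]):
        raise InputError(f"bf {bf} Hz outside the channel range")
    lags_ms = np.arange(n_lags) * bin_ms
    if latency_ms > lags_ms[-1] or latency_ms + inhibition_delay_ms > lags_ms[-1]:
        raise InputError("latency (+ inhibition delay) exceeds the lag window")
    logf = np.log2(center_freqs)
    df = (logf - np.log2(bf)) / bandwidth_oct
    exc_t = (lags_ms - latency_ms) / temporal_width_ms
    inh_t = (lags_ms - latency_ms - inhibition_delay_ms) / temporal_width_ms
    exc = np.exp(-0.5 * df[:, None] ** 2) * np.exp(-0.5 * exc_t[None, :] ** 2)
    inh = np.exp(-0.5 * df[:, None] ** 2) * np.exp(-0.5 * inh_t[None, :] ** 2)

    def ie_of(scale: float) -> float:
        w = exc - scale * inh
        pos = w[w > 0].sum()
        neg = -w[w < 0].sum()
        return neg / pos if pos > 0 else np.inf

    if ie_target < 0:
        raise ConfigurationError("ie_target must be >= 0")
    if ie_target == 0:
        scale = 0.0
    else:
        hi = 1.0
        while ie_of(hi) < ie_target and hi < 1e6:
            hi *= 2.0
        scale = brentq(lambda s: ie_of(s) - ie_target, 0.0, hi, xtol=1e-10)
    w = exc - scale * inh
    w /= w.max()
    return STRF(weights=w, bias=0.0, bin_ms=bin_ms, center_freqs=center_freqs)


# ---------------------------------------------------------------------------
# Response simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNeuronSpec:
    """Generating parameters of one simulated unit."""

    true_strf: STRF
    true_sigmoid: SigmoidParams
    rate_gain: float = 1.0      # spikes/bin scale applied after the sigmoid
    n_repeats: int = DEFAULT_N_REPEATS
    seed: int = 0
    unit_id: str = ""

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ConfigurationError("n_repeats must be >= 2")
        if self.rate_gain < 0:
            raise ConfigurationError("rate_gain must be >= 0")


def expected_rate(cochleagram: Cochleagram, neuron: SyntheticNeuronSpec) -> np.ndarray:
    """Deterministic per-bin rate (spikes/bin) of a simulated unit."""
    if cochleagram.n_channels != neuron.true_strf.n_channels:
        raise InputError(
            "cochleagram channel count does not match the ground-truth STRF"
        )
    design = lag_design_matrix(
        cochleagram, neuron.true_strf.n_lags, onset_exclude_ms=0.0
    )
    drive = predict_design(neuron.true_strf, design)
    rate = neuron.rate_gain * neuron.true_sigmoid(drive)
    assert np.min(rate) >= 0, "nonnegative by construction (a >= 0, gain >= 0)"
    return rate


def simulate_responses(
    cochleagram: Cochleagram,
    neuron: SyntheticNeuronSpec,
    noiseless: bool = False,
) -> NeuralRecording:
    """Draw per-repeat Poisson spike counts for one stimulus.

    With ``noiseless=True`` every repeat equals the expected rate (no
    sampling), giving a zero noise ratio — useful for endpoint tests.
    """
    rate = expected_rate(cochleagram, neuron)
    if noiseless:
        counts = np.tile(rate, (neuron.n_repeats, 1))
    else:
        rng = np.random.default_rng(neuron.seed)
        counts = rng.poisson(rate, size=(neuron.n_repeats, rate.size)).astype(float)
    return NeuralRecording(
        counts=counts,
        bin_ms=cochleagram.bin_ms,
        stimulus_id=str(cochleagram.provenance.get("stimulus_id", "")),
        unit_id=neuron.unit_id,
    )


def gain_for_noise_ratio(unit_rate: np.ndarray, target_nr: float) -> float:
    """Rate gain that targets a requested noise ratio under Poisson spiking.

    For counts ~ Poisson(g * r(t)) the per-repeat noise power is the mean
    rate and the signal power the rate variance, so NR = mean(g r) /
    Var(g r) = m / (g v): solving for g gives the calibration in closed
    form.  ``unit_rate`` is the unit's sigmoid output at gain 1.
    """
    if target_nr <= 0:
        raise ConfigurationError("target noise ratio must be positive")
    m = float(np.mean(unit_rate))
    v = float(np.var(unit_rate, ddof=1))
    if v <= 0 or m <= 0:
        raise InputError("unit rate trace must vary and be positive on average")
    return m / (v * target_nr)


# ---------------------------------------------------------------------------
# Benchmark datasets
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Stimuli, per-unit recordings, split, and generating ground truth."""

    stimuli: dict                      # stimulus_id -> AudioSignal
    recordings: dict                   # unit_id -> {stimulus_id: NeuralRecording}
    train_ids: list
    test_ids: list
    neurons: dict = field(default_factory=dict)   # unit_id -> SyntheticNeuronSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise InputError("train/test split must be a partition")
        for unit, recs in self.recordings.items():
            for sid in recs:
                if sid not in self.stimuli:
                    raise InputError(
                        f"unit {unit} references unknown stimulus {sid!r}"
                    )

    @property
    def unit_ids(self) -> list:
        return list(self.recordings)

    def unit_counts(self, unit_id, stimulus_ids=None) -> np.ndarray:
        """Concatenated repeats x bins counts over the given stimuli."""
        if stimulus_ids is None:
            stimulus_ids = self.train_ids + self.test_ids
        return np.hstack(
            [self.recordings[unit_id][sid].counts for sid in stimulus_ids]
        )

    def digest(self) -> str:
        """Content hash of stimuli and counts (reproducibility check)."""
        import hashlib

        h = hashlib.sha256()
        for sid in sorted(self.stimuli):
            h.update(np.ascontiguousarray(self.stimuli[sid].samples).tobytes())
        for uid in sorted(self.recordings):
            for sid in sorted(self.recordings[uid]):
                h.update(
                    np.ascontiguousarray(self.recordings[uid][sid].counts).tobytes()
                )
        return h.hexdigest()


def draw_neuron_population(
    rng: np.random.Generator,
    n_units: int,
    center_freqs: np.ndarray,
    n_lags: int,
    bin_ms: float,
) -> list[dict]:
    """Sample ground-truth tuning parameters for a unit population.

    Best frequencies are log-uniform over the central channel range,
    latencies 10-40 ms, bandwidths 0.3-0.8 octaves, IE scores 0.3-0.7 —
    spanning the qualitative range of A1 receptive fields.
    """
    lo, hi = center_freqs[1], center_freqs[-2]
    out = []
    for _ in range(n_units):
        out.append(
            dict(
                bf=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                latency_ms=float(rng.uniform(10.0, 40.0)),
                bandwidth_oct=float(rng.uniform(0.3, 0.8)),
                inhibition_delay_ms=float(rng.uniform(20.0, 40.0)),
                ie_target=float(rng.uniform(0.3, 0.7)),
            )
        )
    return out


def build_benchmark_dataset(
    n_units: int = 20,
    stimulus_suite: Sequence[StimulusSpec] | None = None,
    front_end: Callable[[AudioSignal], Cochleagram] | None = None,
    split: tuple[int, int] = DEFAULT_SPLIT,
    seed: int = 0,
    n_repeats: int = DEFAULT_N_REPEATS,
    noise_ratio_targets: Sequence[float] | None = None,
    n_lags: int = 20,
    sigmoid_quantile: float = 0.75,
    sigmoid_width_frac: float = 0.15,
) -> Dataset:
    """Generate a full benchmark: stimuli, units, recordings, split.

    Every unit is an LN neuron driven by the cochleagram of ``front_end``
    (default: a 16-channel spec-log model).  The per-unit sigmoid midpoint
    sits at the ``sigmoid_quantile`` of that unit's drive distribution and
    its width at ``sigmoid_width_frac`` of the drive s.d., giving sparse,
    peaky responses.  ``noise_ratio_targets`` sets each unit's noise dial;
    the default population spans noise ratios log-uniform in [2, 120],
    straddling the conventional inclusion threshold of 40.
    """
    from .frontend import build_front_end  # local to avoid import cycle noise

    rng = np.random.default_rng(seed)
    if stimulus_suite is None:
        stimulus_suite = default_stimulus_suite(seed=seed)
    if front_end is None:
        front_end = build_front_end("spec-log", n_channels=16)
    if sum(split) != len(stimulus_suite):
        raise ConfigurationError(
            f"split {split} does not sum to the suite size {len(stimulus_suite)}"
        )
    stim_ids = [f"stim{i:03d}" for i in range(len(stimulus_suite))]
    if len(set(stim_ids)) != len(stim_ids):
        raise InputError("duplicate stimulus ids")
    stimuli = {sid: gen_stimulus(s) for sid, s in zip(stim_ids, stimulus_suite)}
    cochleagrams = {}
    for sid in stim_ids:
        cg = front_end(stimuli[sid])
        cg.provenance["stimulus_id"] = sid
        cochleagrams[sid] = cg
    cg0 = cochleagrams[stim_ids[0]]
    if noise_ratio_targets is None:
        noise_ratio_targets = np.exp(
            rng.uniform(np.log(2.0), np.log(120.0), size=n_units)
        )
    tunings = draw_neuron_population(
        rng, n_units, cg0.center_freqs, n_lags, cg0.bin_ms
    )
    neurons: dict = {}
    recordings: dict = {}
    for u, (tuning, nr_target) in enumerate(zip(tunings, noise_ratio_targets)):
        uid = f"unit{u:03d}"
        strf = gen_ground_truth_strf(
            center_freqs=cg0.center_freqs,
            n_lags=n_lags,
            bin_ms=cg0.bin_ms,
            **tuning,
        )
        # drive distribution over the whole corpus fixes the sigmoid scale
        drives = np.concatenate(
            [
                predict_design(
                    strf, lag_design_matrix(cochleagrams[sid], n_lags, 0.0)
                )
                for sid in stim_ids
            ]
        )
        c = float(np.quantile(drives, sigmoid_quantile))
        d = max(sigmoid_width_frac * float(drives.std()), 1e-9)
        sigmoid = SigmoidParams(a=0.0, b=1.0, c=c, d=d)
        unit_rate = sigmoid(drives)
        gain = gain_for_noise_ratio(unit_rate, float(nr_target))
        neuron = SyntheticNeuronSpec(
            true_strf=strf,
            true_sigmoid=sigmoid,
            rate_gain=gain,
            n_repeats=n_repeats,
            seed=int(rng.integers(0, 2**31 - 1)),
            unit_id=uid,
        )
        neurons[uid] = neuron
        recordings[uid] = {
            sid: simulate_responses(cochleagrams[sid], neuron) for sid in stim_ids
        }
    return Dataset(
        stimuli=stimuli,
        recordings=recordings,
        train_ids=stim_ids[: split[0]],
        test_ids=stim_ids[split[0] :],
        neurons=neurons,
        provenance={
            "seed": seed,
            "front_end": cg0.provenance.get("front_end"),
            "n_channels": cg0.n_channels,
            "n_lags": n_lags,
            "n_repeats": n_repeats,
            "noise_ratio_targets": [float(v) for v in noise_ratio_targets],
        },
    )


# ---------------------------------------------------------------------------
# Dataset serialization: WAVs + manifest + per-unit count tables
# ---------------------------------------------------------------------------

def save_dataset(path, dataset: Dataset) -> None:
    """Write a dataset directory: WAV stimuli, JSON manifest, CSV counts."""
    root = Path(path)
    (root / "stimuli").mkdir(parents=True, exist_ok=True)
    (root / "units").mkdir(exist_ok=True)
    manifest = {
        "train_ids": list(dataset.train_ids),
        "test_ids": list(dataset.test_ids),
        "provenance": dataset.provenance,
        "stimuli": {},
        "units": {},
    }
    for sid, audio in dataset.stimuli.items():
        write_wav(root / "stimuli" / f"{sid}.wav", audio)
        manifest["stimuli"][sid] = {"sample_rate": audio.sample_rate}
    for uid, recs in dataset.recordings.items():
        udir = root / "units" / uid
        udir.mkdir(exist_ok=True)
        stim_meta = {}
        for sid, rec in recs.items():
            np.savetxt(udir / f"{sid}.csv", rec.counts, fmt="%.10g", delimiter=",")
            stim_meta[sid] = {"bin_ms": rec.bin_ms, "n_repeats": rec.n_repeats}
        manifest["units"][uid] = stim_meta
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(path) -> Dataset:
    """Load a dataset directory written by `save_dataset`.

    Ground-truth neuron specs are not round-tripped; the loaded dataset
    carries stimuli, counts, split, and provenance (all the pipeline
    needs).
    """
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    stimuli = {
        sid: read_wav(root / "stimuli" / f"{sid}.wav")
        for sid in manifest["stimuli"]
    }
    recordings: dict = {}
    for uid, stim_meta in manifest["units"].items():
        recordings[uid] = {}
        for sid, meta in stim_meta.items():
            counts = np.loadtxt(root / "units" / uid / f"{sid}.csv", delimiter=",")
            counts = np.atleast_2d(counts)
            recordings[uid][sid] = NeuralRecording(
                counts=counts,
                bin_ms=float(meta["bin_ms"]),
                stimulus_id=sid,
                unit_id=uid,
            )
    return Dataset(
        stimuli=stimuli,
        recordings=recordings,
        train_ids=manifest["train_ids"],
        test_ids=manifest["test_ids"],
        provenance=manifest.get("provenance", {}),
    )
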