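"""Spectrogram-based cochlear front ends.

Converts a sound waveform into a *cochleagram* — a channels x time-bins
matrix approximating the output of the auditory periphery — in three
stages: an STFT frequency decomposition, a weighted summation through
overlapping triangular filters spaced on a logarithmic frequency axis,
and a pointwise compressive nonlinearity.

Five single-threshold variants are provided, named after their
compression stage:

========================  ==========  ==========================================
name                      spectrogram compression
========================  ==========  ==========================================
``spec-lin``              amplitude   none (identity)
``spec-log``              amplitude   log of max(x, theta)
``spec-log1plus``         amplitude   log(1 + x / scale)
``spec-power``            power       log of max(x, theta)
``spec-hill``             power       thresholded log followed by a Hill function
========================  ==========  ==========================================

plus a multithreshold variant (``spec-hill-mt``) in which every frequency
channel is passed through three Hill functions with increasing thresholds
and narrowing dynamic ranges, mimicking the low/medium/high
spontaneous-rate classes of auditory nerve fibers.  Its output has
3 x n_channels rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import scipy.io.wavfile
from scipy.signal import get_window

logger = logging.getLogger("ear2cortex")

#: default analysis band (Hz); spans the tuning range of ferret A1 and is
#: an exact 5.5-octave span (22627 ~= 500 * 2**5.5)
DEFAULT_F_MIN = 500.0
DEFAULT_F_MAX = 22627.0

#: default STFT framing: 20-ms Hann window advanced in 10-ms hops, giving
#: 10-ms cochleagram bins — fine enough to resolve 25-ms chord stimuli
DEFAULT_FRAME_MS = 20.0
DEFAULT_HOP_MS = 10.0

#: compression floor defaults, in dB below the corpus peak
DEFAULT_THETA_DB_AMPLITUDE = 60.0
DEFAULT_THETA_DB_POWER = 120.0


class ConfigurationError(ValueError):
    """A front-end or model configuration is internally inconsistent."""


class InputError(ValueError):
    """The supplied data violates an operation's preconditions."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AudioSignal:
    """A mono sound-pressure waveform.

    Parameters
    ----------
    samples : ndarray
        Real-valued pressure sequence in arbitrary units.
    sample_rate : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise InputError(
                f"AudioSignal requires a mono (1-D) sample array, got shape "
                f"{samples.shape}"
            )
        if samples.size and not np.all(np.isfinite(samples)):
            raise InputError("AudioSignal samples must all be finite")
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def peak_normalized(self) -> "AudioSignal":
        peak = np.max(np.abs(self.samples)) if self.samples.size else 0.0
        if peak == 0:
            return self
        return AudioSignal(self.samples / peak, self.sample_rate)


@dataclass(frozen=True)
class FilterbankSpec:
    """STFT framing plus triangular log-spaced filterbank geometry."""

    n_channels: int
    f_min: float = DEFAULT_F_MIN
    f_max: float = DEFAULT_F_MAX
    frame_ms: float = DEFAULT_FRAME_MS
    hop_ms: float = DEFAULT_HOP_MS
    spectrogram_mode: str = "amplitude"  # "amplitude" | "power"

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2")
        if not (0 < self.f_min < self.f_max):
            raise ConfigurationError("need 0 < f_min < f_max")
        if self.hop_ms > self.frame_ms:
            raise ConfigurationError("hop_ms must not exceed frame_ms")
        if self.spectrogram_mode not in ("amplitude", "power"):
            raise ConfigurationError(
                f"spectrogram_mode must be 'amplitude' or 'power', got "
                f"{self.spectrogram_mode!r}"
            )


@dataclass(frozen=True)
class CompressionSpec:
    """Pointwise compressive nonlinearity applied to the filterbank output.

    ``theta`` is the floor of the thresholded-log kinds, in the same units
    as the spectrogram values.  When ``theta`` is None it is resolved per
    corpus so the floor sits ``theta_db_down`` dB below the corpus peak
    (60 dB in amplitude mode, 120 dB in power mode by default).

    For ``kind="hill"`` the thresholded-log output is min-max rescaled to
    [0, 1] over the corpus before the Hill stage x^h / (x^h + k^h), so
    ``hill_halfmax`` is unit-scaled; the resolved rescaling constants are
    recorded in the cochleagram provenance.
    """

    kind: str  # "lin" | "log_thresholded" | "log1plus" | "power_log" | "hill"
    theta: float | None = None
    theta_db_down: float | None = None
    log1plus_scale: float = 1.0
    hill_halfmax: float = 0.5
    hill_exponent: float = 2.0
    hill_rescale: tuple[float, float] | None = None  # (lo, hi) of log output

    _KINDS = ("lin", "log_thresholded", "log1plus", "power_log", "hill")
    _LOG_KINDS = ("log_thresholded", "power_log", "hill")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigurationError(f"unknown compression kind {self.kind!r}")
        if self.kind in self._LOG_KINDS and self.theta is not None and self.theta <= 0:
            raise ConfigurationError("theta must be positive for log compression")
        if self.log1plus_scale <= 0:
            raise ConfigurationError("log1plus_scale must be positive")
        if self.hill_halfmax <= 0 or self.hill_exponent <= 0:
            raise ConfigurationError("Hill parameters must be positive")


@dataclass(frozen=True)
class MultithresholdSpec:
    """Three (theta, hill_halfmax, hill_exponent) triples, ordered from the
    low-threshold (narrow dynamic range) to the high-threshold (wide dynamic
    range) class, mirroring the HSR/MSR/LSR auditory nerve fiber types.

    ``thetas_db_down`` may be given instead of absolute ``thetas``; they are
    resolved against the corpus peak like ``CompressionSpec.theta_db_down``.
    Thresholds must be non-decreasing across the triples (equal thresholds
    are allowed — three identical triples degenerate to a triplicated
    single-threshold model).
    """

    thetas: tuple[float, float, float] | None = None
    thetas_db_down: tuple[float, float, float] | None = (60.0, 40.0, 20.0)
    # each class saturates within its own level range: the low-threshold
    # class (HSR-like) sits just above its threshold with a steep, narrow
    # dynamic range; the high-threshold class (LSR-like) is shallow and wide
    hill_halfmaxes: tuple[float, float, float] = (0.2, 0.4, 0.6)
    hill_exponents: tuple[float, float, float] = (4.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        if self.thetas is not None:
            t = np.asarray(self.thetas, float)
            if np.any(np.diff(t) < 0):
                raise ConfigurationError(
                    "multithreshold thetas must be non-decreasing (low to high)"
                )
            if np.any(t <= 0):
                raise ConfigurationError("multithreshold thetas must be positive")
        elif self.thetas_db_down is not None:
            d = np.asarray(self.thetas_db_down, float)
            # more dB below peak = lower threshold, so db values must be
            # non-increasing for thresholds to be non-decreasing
            if np.any(np.diff(d) > 0):
                raise ConfigurationError(
                    "thetas_db_down must be non-increasing so that thresholds "
                    "run low to high"
                )
        else:
            raise ConfigurationError("either thetas or thetas_db_down is required")

    def triples(self, corpus_peak: float, mode: str) -> list[CompressionSpec]:
        """Resolve to three Hill `CompressionSpec`s with absolute thresholds."""
        if self.thetas is not None:
            thetas = list(self.thetas)
        else:
            factor = 10.0 if mode == "power" else 20.0
            thetas = [corpus_peak * 10 ** (-db / factor) for db in self.thetas_db_down]
        return [
            CompressionSpec(
                kind="hill", theta=th, hill_halfmax=k, hill_exponent=h,
            )
            for th, k, h in zip(thetas, self.hill_halfmaxes, self.hill_exponents)
        ]


THRESHOLD_CLASSES = ("LTH", "MTH", "HTH")  # low / medium / high threshold


@dataclass
class Cochleagram:
    """Channels x time-bins output of a cochlear front end.

    ``provenance`` records the front-end identity and every resolved
    compression constant so a cochleagram is reproducible from metadata.
    """

    values: np.ndarray           # (n_channels, n_bins)
    center_freqs: np.ndarray     # Hz, ascending (per threshold block if MT)
    bin_ms: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if self.values.ndim != 2:
            raise InputError("cochleagram values must be 2-D (channels x bins)")
        if self.values.shape[0] != self.center_freqs.size:
            raise InputError("one center frequency per channel required")
        if not np.all(np.isfinite(self.values)):
            raise InputError("cochleagram values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# STFT stage
# ---------------------------------------------------------------------------

def _frame_params(audio: AudioSignal, spec: FilterbankSpec) -> tuple[int, int]:
    win = int(round(spec.frame_ms * audio.sample_rate / 1000.0))
    hop = int(round(spec.hop_ms * audio.sample_rate / 1000.0))
    if win < 2 or hop < 1:
        raise ConfigurationError("frame/hop too short for this sample rate")
    return win, hop


def stft_power_spectrogram(
    audio: AudioSignal, spec: FilterbankSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time Fourier spectrogram of a waveform.

    Frames of ``frame_ms`` are taken every ``hop_ms`` (one output row per
    hop, final frames zero-padded), Hann-windowed, and Fourier transformed.

    Returns
    -------
    S : ndarray, shape (n_frames, n_fft_bins)
        Magnitude spectrogram in amplitude mode, squared magnitude in
        power mode.
    freqs : ndarray
        Frequency of each FFT bin in Hz.
    """
    if audio.samples.size == 0:
        raise InputError("cannot compute a spectrogram of empty audio")
    if audio.sample_rate < 2 * spec.f_max:
        raise ConfigurationError(
            f"sample rate {audio.sample_rate} Hz is below twice the upper "
            f"filterbank edge ({spec.f_max} Hz)"
        )
    win, hop = _frame_params(audio, spec)
    x = audio.samples
    n_frames = int(np.ceil(x.size / hop))
    padded = np.zeros((n_frames - 1) * hop + win)
    padded[: x.size] = x
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = padded[idx] * get_window("hann", win, fftbins=True)[None, :]
    S = np.abs(np.fft.rfft(frames, axis=1))
    if spec.spectrogram_mode == "power":
        S = S ** 2
    freqs = np.fft.rfftfreq(win, d=1.0 / audio.sample_rate)
    return S, freqs


# ---------------------------------------------------------------------------
# Triangular log-spaced filterbank
# ---------------------------------------------------------------------------

def center_frequencies(n_channels: int, f_min: float, f_max: float) -> np.ndarray:
    """Geometrically spaced channel centers spanning [f_min, f_max]."""
    return np.geomspace(f_min, f_max, n_channels)


def triangular_filterbank(
    spec: FilterbankSpec, fft_bin_freqs: np.ndarray
) -> np.ndarray:
    """Weight matrix of overlapping triangular filters on a log axis.

    Channel i's triangle peaks at its center frequency with feet at the
    neighboring centers; virtual edge centers sit one geometric step
    beyond f_min and f_max so every triangle has full support.
    """
    fft_bin_freqs = np.asarray(fft_bin_freqs, float)
    if spec.f_min < fft_bin_freqs[0] or spec.f_max > fft_bin_freqs[-1]:
        raise ConfigurationError(
            "filterbank range [f_min, f_max] must lie within the FFT bin range"
        )
    centers = center_frequencies(spec.n_channels, spec.f_min, spec.f_max)
    step = (spec.f_max / spec.f_min) ** (1.0 / (spec.n_channels - 1))
    edges = np.concatenate([[spec.f_min / step], centers, [spec.f_max * step]])
    W = np.zeros((spec.n_channels, fft_bin_freqs.size))
    f = fft_bin_freqs
    for i in range(spec.n_channels):
        lo, c, hi = edges[i], edges[i + 1], edges[i + 2]
        rising = (f - lo) / (c - lo)
        falling = (hi - f) / (hi - c)
        W[i] = np.clip(np.minimum(rising, falling), 0.0, None)
        if not np.any(W[i] > 0):
            raise ConfigurationError(
                f"channel {i} (center {c:.1f} Hz) has no FFT bin support; "
                f"reduce n_channels or increase the frame length"
            )
    return W


# ---------------------------------------------------------------------------
# Compression stage
# ---------------------------------------------------------------------------

def resolve_compression(
    x: np.ndarray, comp: CompressionSpec, mode: str
) -> CompressionSpec:
    """Fill corpus-dependent constants (theta, Hill rescale) of a spec.

    The floor ``theta`` defaults to 60 dB (amplitude) / 120 dB (power)
    below the corpus peak; for the Hill kind the min-max range of the
    thresholded-log output is frozen so the spec becomes corpus-independent.
    """
    if comp.kind in ("lin", "log1plus"):
        return comp
    theta = comp.theta
    if theta is None:
        db = comp.theta_db_down
        if db is None:
            db = DEFAULT_THETA_DB_POWER if mode == "power" else DEFAULT_THETA_DB_AMPLITUDE
        peak = float(np.max(x)) if x.size else 0.0
        if peak <= 0:
            theta = np.finfo(float).tiny  # silent corpus: floor is arbitrary
        else:
            factor = 10.0 if mode == "power" else 20.0
            theta = peak * 10 ** (-db / factor)
    resolved = dataclasses.replace(comp, theta=theta, theta_db_down=None)
    if comp.kind == "hill" and comp.hill_rescale is None:
        u = np.log(np.maximum(x, theta))
        resolved = dataclasses.replace(
            resolved, hill_rescale=(float(u.min()), float(u.max()))
        )
    return resolved


def apply_compression(x: np.ndarray, comp: CompressionSpec) -> np.ndarray:
    """Apply a compressive nonlinearity elementwise.

    Every kind is monotone nondecreasing in the input.  For the log kinds
    ``comp.theta`` must already be resolved (see `resolve_compression`).
    """
    x = np.asarray(x, float)
    if x.size and np.min(x) < 0:
        raise InputError("compression input must be nonnegative")
    if comp.kind == "lin":
        return x.copy()
    if comp.kind == "log1plus":
        return np.log1p(x / comp.log1plus_scale)
    if comp.theta is None:
        raise ConfigurationError(
            f"theta unresolved for compression kind {comp.kind!r}; call "
            f"resolve_compression first or set theta explicitly"
        )
    u = np.log(np.maximum(x, comp.theta))
    if comp.kind in ("log_thresholded", "power_log"):
        return u
    # hill: min-max rescale the log output to [0, 1], then x^h/(x^h + k^h)
    lo, hi = comp.hill_rescale if comp.hill_rescale is not None else (u.min(), u.max())
    if hi <= lo:
        r = np.zeros_like(u)
    else:
        r = np.clip((u - lo) / (hi - lo), 0.0, 1.0)
    h, k = comp.hill_exponent, comp.hill_halfmax
    rh = r ** h
    return rh / (rh + k ** h)


# ---------------------------------------------------------------------------
# Cochleagram assembly
# ---------------------------------------------------------------------------

def _filterbank_output(
    audio: AudioSignal, fspec: FilterbankSpec
) -> tuple[np.ndarray, np.ndarray]:
    S, freqs = stft_power_spectrogram(audio, fspec)
    W = triangular_filterbank(fspec, freqs)
    return W @ S.T, center_frequencies(fspec.n_channels, fspec.f_min, fspec.f_max)


def make_cochleagram(
    audio: AudioSignal,
    fspec: FilterbankSpec,
    comp: CompressionSpec,
    name: str | None = None,
) -> Cochleagram:
    """Full front end: STFT -> triangular filterbank -> compression."""
    fb, centers = _filterbank_output(audio, fspec)
    resolved = resolve_compression(fb, comp, fspec.spectrogram_mode)
    values = apply_compression(fb, resolved)
    prov = {
        "front_end": name or f"spec-{comp.kind}",
        "filterbank": dataclasses.asdict(fspec),
        "compression": dataclasses.asdict(resolved),
    }
    return Cochleagram(values, centers, fspec.hop_ms, prov)


def make_multithreshold_cochleagram(
    audio: AudioSignal,
    fspec: FilterbankSpec,
    mt: MultithresholdSpec,
) -> Cochleagram:
    """Three-fiber-type front end.

    Each frequency channel is passed through three Hill functions with
    increasing thresholds and decreasing dynamic ranges, assigning the
    changing sound level in one channel to three separate output channels.
    Output blocks are stacked low -> medium -> high threshold, frequencies
    ascending within each block (3 x n_channels rows total).
    """
    fb, centers = _filterbank_output(audio, fspec)
    peak = float(np.max(fb)) if fb.size else 0.0
    blocks = []
    resolved_triples = []
    for comp in mt.triples(peak, fspec.spectrogram_mode):
        resolved = resolve_compression(fb, comp, fspec.spectrogram_mode)
        resolved_triples.append(dataclasses.asdict(resolved))
        blocks.append(apply_compression(fb, resolved))
    values = np.vstack(blocks)
    prov = {
        "front_end": "spec-hill-mt",
        "filterbank": dataclasses.asdict(fspec),
        "threshold_classes": list(THRESHOLD_CLASSES),
        "compression": resolved_triples,
    }
    return Cochleagram(values, np.tile(centers, 3), fspec.hop_ms, prov)


# ---------------------------------------------------------------------------
# Named front ends
# ---------------------------------------------------------------------------

_SINGLE_THRESHOLD = {
    "spec-lin": ("amplitude", "lin"),
    "spec-log": ("amplitude", "log_thresholded"),
    "spec-log1plus": ("amplitude", "log1plus"),
    "spec-power": ("power", "power_log"),
    "spec-hill": ("power", "hill"),
}

FRONT_END_NAMES = tuple(_SINGLE_THRESHOLD) + ("spec-hill-mt",)


def build_front_end(
    name: str,
    n_channels: int,
    *,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    frame_ms: float = DEFAULT_FRAME_MS,
    hop_ms: float = DEFAULT_HOP_MS,
    compression: CompressionSpec | None = None,
    multithreshold: MultithresholdSpec | None = None,
) -> Callable[[AudioSignal], Cochleagram]:
    """Return ``audio -> Cochleagram`` for a named spectrogram front end."""
    if name == "spec-hill-mt":
        fspec = FilterbankSpec(n_channels, f_min, f_max, frame_ms, hop_ms, "power")
        mt = multithreshold or MultithresholdSpec()

        def run_mt(audio: AudioSignal) -> Cochleagram:
            return make_multithreshold_cochleagram(audio, fspec, mt)

        return run_mt
    if name not in _SINGLE_THRESHOLD:
        raise ConfigurationError(
            f"unknown front end {name!r}; choose from {FRONT_END_NAMES}"
        )
    mode, kind = _SINGLE_THRESHOLD[name]
    fspec = FilterbankSpec(n_channels, f_min, f_max, frame_ms, hop_ms, mode)
    comp = compression or CompressionSpec(kind=kind)
    if comp.kind != kind:
        raise ConfigurationError(
            f"front end {name!r} requires compression kind {kind!r}"
        )

    def run(audio: AudioSignal) -> Cochleagram:
        return make_cochleagram(audio, fspec, comp, name=name)

    return run


# ---------------------------------------------------------------------------
# Plugin contract for external cochlear models
# ---------------------------------------------------------------------------

class CochlearModelProvider(Protocol):
    """Callable contract for plugging in external cochlear models.

    The provider maps ``(samples, sample_rate, n_channels)`` to
    ``(values, center_freqs, bin_ms)``.  Stochastic providers (e.g. models
    with simulated synaptic noise) declare a repeat count; the adapter
    averages the declared number of independent runs.
    """

    def __call__(
        self, samples: np.ndarray, sample_rate: float, n_channels: int
    ) -> tuple[np.ndarray, np.ndarray, float]: ...


@dataclass
class PluginFrontEnd:
    """Adapter turning an external provider into ``audio -> Cochleagram``."""

    provider: CochlearModelProvider
    name: str
    n_repeats: int = 1  # >1 for stochastic providers: outputs are averaged

    def __call__(self, audio: AudioSignal, n_channels: int) -> Cochleagram:
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        acc = None
        centers = bin_ms = None
        for _ in range(self.n_repeats):
            values, centers, bin_ms = self.provider(
                audio.samples, audio.sample_rate, n_channels
            )
            values = np.asarray(values, float)
            acc = values if acc is None else acc + values
        values = acc / self.n_repeats
        prov = {"front_end": self.name, "plugin": True, "n_repeats": self.n_repeats}
        return Cochleagram(values, np.asarray(centers, float), float(bin_ms), prov)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_wav(path) -> AudioSignal:
    """Read a mono WAV file (PCM 16/32-bit, 8-bit unsigned, or float)."""
    rate, data = scipy.io.wavfile.read(path)
    if data.ndim != 1:
        raise InputError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise InputError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioSignal(samples, float(rate))


def write_wav(path, audio: AudioSignal) -> None:
    """Write an `AudioSignal` as a 32-bit float WAV file."""
    scipy.io.wavfile.write(
        path, int(round(audio.sample_rate)), audio.samples.astype(np.float32)
    )


def save_cochleagram(path, cg: Cochleagram) -> None:
    """Persist a cochleagram (bit-exact round trip) as an .npz archive."""
    np.savez(
        path,
        values=cg.values,
        center_freqs=cg.center_freqs,
        bin_ms=np.asarray(cg.bin_ms),
        provenance=np.asarray(json.dumps(cg.provenance)),
    )


def load_cochleagram(path) -> Cochleagram:
    with np.load(path, allow_pickle=False) as z:
        return Cochleagram(
            values=z["values"],
            center_freqs=z["center_freqs"],
            bin_ms=float(z["bin_ms"]),
            provenance=json.loads(str(z["provenance"])),
        )
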