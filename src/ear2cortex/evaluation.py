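"""Prediction scoring and receptive-field characterization.

The central metric is the normalized correlation coefficient CC_norm:
the correlation between a model prediction and the repeat-averaged
response, normalized by the response's *signal power* so that 1 means
the model predicts all of the stimulus-dependent variance in the firing
rate and 0 means no correlation.  The normalization rests on a
decomposition of across-repeat response variance into a stimulus-locked
(signal) and a repeat-varying (noise) component:

    TP = mean_n Var(r_n)                          (total power)
    SP = (Var(sum_n r_n) - sum_n Var(r_n)) / (N (N - 1))
    NP = TP - SP

    CC_norm = Cov(ybar, yhat) / sqrt(SP * Var(yhat))

with r_n the n-th repeat and ybar the repeat average.  The *noise ratio*
NR = NP / SP quantifies how little a unit's response depends on the
stimulus; units with NR >= 40 are conventionally excluded from encoding
analyses.  All variances/covariances here use ddof=1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frontend import InputError
from .encoding import STRF

__all__ = [
    "NeuralRecording",
    "EvalResult",
    "StrfFeatures",
    "signal_noise_power",
    "noise_ratio",
    "cc_raw",
    "cc_norm",
    "evaluate_prediction",
    "strf_features",
    "strf_similarity",
    "mse_by_spike_probability",
]


@dataclass
class NeuralRecording:
    """Per-repeat binned spike counts of one unit for one stimulus.

    ``counts`` is a repeats x time-bins matrix; entries are nonnegative
    spike counts (floats are tolerated so that noiseless simulated rates
    can flow through the same container).  At least 2 repeats are needed
    for CC_norm and the noise ratio.
    """

    counts: np.ndarray
    bin_ms: float
    stimulus_id: str = ""
    unit_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InputError("counts must be a repeats x bins matrix")
        if self.counts.size and np.min(self.counts) < 0:
            raise InputError("spike counts must be nonnegative")

    @property
    def n_repeats(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def mean_rate(self) -> np.ndarray:
        """Repeat-averaged response (spike probability per bin)."""
        return self.counts.mean(axis=0)


@dataclass
class EvalResult:
    """Scores of one prediction against one recorded unit."""

    cc_raw: float
    cc_norm: float
    signal_power: float
    noise_power: float
    noise_ratio: float
    n_bins_used: int
    flags: list = field(default_factory=list)


def signal_noise_power(counts: np.ndarray) -> tuple[float, float, float]:
    """Decompose across-repeat response variance into signal and noise.

    Returns ``(SP, NP, TP)`` with SP + NP = TP by construction.  SP is an
    unbiased estimate of the variance of the stimulus-locked rate; it can
    come out <= 0 for units whose response carries no stimulus information.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise InputError(
            "signal_noise_power needs a repeats x bins matrix with >= 2 "
            "repeats; with a single repeat only cc_raw is defined"
        )
    n = counts.shape[0]
    tp = float(np.mean(np.var(counts, axis=1, ddof=1)))
    var_sum = float(np.var(counts.sum(axis=0), ddof=1))
    sp = (var_sum - n * tp) / (n * (n - 1))
    return sp, tp - sp, tp


def noise_ratio(counts: np.ndarray) -> float:
    """NP / SP; infinite (the unit is uninformative) when SP <= 0."""
    sp, np_, _ = signal_noise_power(counts)
    if sp <= 0:
        warnings.warn(
            "signal power <= 0: noise ratio undefined, reporting inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return np_ / sp


def cc_raw(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation between observed mean rate and prediction.

    A constant input leaves the correlation undefined; it is scored 0
    with a warning, so downstream averages stay finite.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise InputError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        warnings.warn(
            "correlation undefined for constant input; scoring 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1])


def cc_norm(counts: np.ndarray, yhat: np.ndarray) -> float:
    """Normalized correlation coefficient of a prediction.

    Equals `cc_raw` exactly when the repeats are identical (no noise) and
    is invariant to positive affine transformations of the prediction.
    NaN (with a warning) when the signal power is nonpositive.
    """
    counts = np.asarray(counts, float)
    yhat = np.asarray(yhat, float)
    sp, _, _ = signal_noise_power(counts)
    ybar = counts.mean(axis=0)
    if ybar.shape != yhat.shape:
        raise InputError(f"length mismatch: {ybar.shape} vs {yhat.shape}")
    if sp <= 0:
        warnings.warn(
            "signal power <= 0: CC_norm undefined for this unit",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    var_hat = np.var(yhat, ddof=1)
    if var_hat == 0:
        warnings.warn(
            "constant prediction: CC_norm undefined; scoring 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    cov = float(np.cov(ybar, yhat, ddof=1)[0, 1])
    return cov / np.sqrt(sp * var_hat)


def evaluate_prediction(counts: np.ndarray, yhat: np.ndarray) -> EvalResult:
    """Score one prediction: CC, CC_norm, and the power decomposition."""
    counts = np.asarray(counts, float)
    sp, np_, _ = signal_noise_power(counts)
    flags = []
    if sp <= 0:
        flags.append("signal_power_nonpositive")
        nr = float("inf")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ccn = cc_norm(counts, yhat)
    else:
        nr = np_ / sp
        ccn = cc_norm(counts, yhat)
    return EvalResult(
        cc_raw=cc_raw(counts.mean(axis=0), yhat),
        cc_norm=ccn,
        signal_power=sp,
        noise_power=np_,
        noise_ratio=nr,
        n_bins_used=counts.shape[1],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# STRF characterization
# ---------------------------------------------------------------------------

@dataclass
class StrfFeatures:
    best_frequency: float  # Hz; NaN when no positive weight exists
    latency_ms: float      # lag of the largest positive weight
    ie_score: float        # sum |negative weights| / sum positive weights
    flags: list = field(default_factory=list)


def strf_features(strf: STRF) -> StrfFeatures:
    """Best frequency, latency, and inhibitory/excitatory score of an STRF.

    The best frequency is the center frequency of the largest positive
    weight and the latency its time lag; the IE score is the ratio of
    total inhibitory (negative) to excitatory (positive) weight mass.
    """
    w = strf.weights
    if not np.any(w):
        raise InputError("strf_features requires a nonzero weight matrix")
    pos = w[w > 0].sum()
    neg = -w[w < 0].sum()
    flags = []
    if pos <= 0:
        flags.append("no_positive_weights")
        bf = float("nan")
        latency = float("nan")
        ie = float("inf")
    else:
        ch, lag = np.unravel_index(np.argmax(w), w.shape)
        bf = float(strf.center_freqs[ch])
        latency = lag * strf.bin_ms
        ie = neg / pos
    return StrfFeatures(bf, latency, ie, flags)


def _as_weights(x) -> np.ndarray:
    return x.weights if isinstance(x, STRF) else np.asarray(x, float)


def strf_similarity(
    a, b, blur_sigma: tuple[float, float] = (0.0, 0.0), allow_resample: bool = False
) -> float:
    """Pearson correlation of two (optionally Gaussian-blurred) STRFs.

    ``blur_sigma`` is the (channels, bins) standard deviation of the blur;
    blurring absorbs small frequency or temporal shifts between the two
    receptive fields.  ``(0, 0)`` gives the plain correlation.  Unequal
    shapes raise unless ``allow_resample`` is set, in which case ``b`` is
    resampled onto ``a``'s grid (spline interpolation) with a warning.
    """
    wa, wb = _as_weights(a), _as_weights(b)
    if wa.shape != wb.shape:
        if not allow_resample:
            raise InputError(
                f"STRF shape mismatch {wa.shape} vs {wb.shape}; pass "
                f"allow_resample=True to compare across grids"
            )
        warnings.warn("resampling second STRF to match shapes", RuntimeWarning)
        zoom = (wa.shape[0] / wb.shape[0], wa.shape[1] / wb.shape[1])
        wb = ndimage.zoom(wb, zoom, order=1)
        wb = wb[: wa.shape[0], : wa.shape[1]]
    if any(s > 0 for s in blur_sigma):
        wa = ndimage.gaussian_filter(wa, sigma=blur_sigma)
        wb = ndimage.gaussian_filter(wb, sigma=blur_sigma)
    return cc_raw(wa.ravel(), wb.ravel())


def mse_by_spike_probability(
    y: np.ndarray, yhat: np.ndarray, n_quantiles: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean squared error of a prediction, resolved by response level.

    Bins are partitioned into ``n_quantiles`` groups of (near-)equal
    occupancy by the observed spike probability; the squared error is
    averaged within each group.  Reveals whether a model fails mainly at
    response peaks.

    Returns
    -------
    mse : ndarray (n_quantiles,)
        Mean squared error per quantile, lowest spike probability first.
    mean_rate : ndarray (n_quantiles,)
        Mean observed rate per quantile.
    occupancy : ndarray (n_quantiles,)
        Number of bins per quantile (differ by at most 1).
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise InputError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < n_quantiles:
        warnings.warn(
            f"only {y.size} bins for {n_quantiles} quantiles; reducing",
            RuntimeWarning,
        )
        n_quantiles = max(1, y.size)
    order = np.argsort(y, kind="stable")
    groups = np.array_split(order, n_quantiles)
    sq = (y - yhat) ** 2
    mse = np.array([sq[g].mean() for g in groups])
    mean_rate = np.array([y[g].mean() for g in groups])
    occupancy = np.array([g.size for g in groups])
    return mse, mean_rate, occupancy
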