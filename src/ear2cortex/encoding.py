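"""Encoding models: linear (STRF), linear-nonlinear, and network receptive field.

All three models map a window of preceding cochleagram content to the
firing rate of a cortical unit:

* **linear** — the spectrotemporal receptive field (STRF): a weight
  matrix over frequency channels x time lags plus a bias, fitted by
  L1-penalized least squares with the penalty chosen by k-fold
  cross-validation over contiguous stimulus blocks;
* **LN** — the STRF followed by a static 4-parameter sigmoid output
  nonlinearity ``y = a + b / (1 + exp(-(x - c)/d))`` fitted to the
  frozen linear drive (two-stage fit, no joint refinement);
* **NRF** — a network receptive field: a single-hidden-layer network
  with sigmoid units at the hidden and output layer, L1 penalty on the
  input-layer weights, trained by L-BFGS with early stopping on a
  held-out fraction of the training data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize
from scipy.special import expit, logit
from sklearn.linear_model import Lasso

from .frontend import Cochleagram, ConfigurationError, InputError

logger = logging.getLogger("ear2cortex")

#: default STRF history window: 20 lags of 10-ms bins = 200 ms, long enough
#: to cover an excitatory field plus its lagging inhibitory field
DEFAULT_N_LAGS = 20
#: onset transient excluded from fitting and scoring, per stimulus
DEFAULT_ONSET_EXCLUDE_MS = 800.0
DEFAULT_K_FOLDS = 8

_LASSO_TOL = 1e-4
_LASSO_MAX_ITER = 5000


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Lagged-cochleagram regressors aligned to response bins.

    Row ``t`` holds the cochleagram at lags ``0..n_lags-1`` before and
    including bin ``t`` (zero-padded where the history runs off the start
    of a stimulus).  Column ``c * n_lags + l`` is channel ``c`` at lag
    ``l`` — channel-major, lag-minor.  ``excluded`` flags onset rows that
    fitting and scoring drop by default; ``stimulus_ids`` records which
    stimulus each row came from, which drives contiguous-block fold
    assignment in cross-validation.
    """

    X: np.ndarray                # (n_bins, n_channels * n_lags)
    excluded: np.ndarray         # bool, (n_bins,)
    stimulus_ids: np.ndarray     # (n_bins,) str/int labels
    n_channels: int
    n_lags: int
    bin_ms: float
    center_freqs: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def usable_rows(self) -> np.ndarray:
        return ~self.excluded


def lag_design_matrix(
    cochleagram: Cochleagram,
    n_lags: int = DEFAULT_N_LAGS,
    onset_exclude_ms: float = DEFAULT_ONSET_EXCLUDE_MS,
    stimulus_id: str = "0",
) -> DesignMatrix:
    """Unroll a cochleagram into lagged regressors for one stimulus."""
    if n_lags < 1:
        raise ConfigurationError("n_lags must be >= 1")
    n_ch, n_bins = cochleagram.values.shape
    n_excluded = int(round(onset_exclude_ms / cochleagram.bin_ms))
    if n_bins <= n_lags + n_excluded:
        raise InputError(
            f"stimulus has {n_bins} bins but the history window ({n_lags}) "
            f"plus onset exclusion ({n_excluded}) needs more"
        )
    X = np.zeros((n_bins, n_ch * n_lags))
    cg = cochleagram.values
    for lag in range(n_lags):
        X[lag:, lag::n_lags] = cg[:, : n_bins - lag].T
    excluded = np.zeros(n_bins, dtype=bool)
    excluded[:n_excluded] = True
    return DesignMatrix(
        X=X,
        excluded=excluded,
        stimulus_ids=np.full(n_bins, stimulus_id, dtype=object),
        n_channels=n_ch,
        n_lags=n_lags,
        bin_ms=cochleagram.bin_ms,
        center_freqs=cochleagram.center_freqs,
    )


def concat_designs(designs: Sequence[DesignMatrix]) -> DesignMatrix:
    """Stack per-stimulus design matrices along the time axis."""
    first = designs[0]
    for d in designs[1:]:
        if (d.n_channels, d.n_lags) != (first.n_channels, first.n_lags):
            raise InputError("all designs must share channel and lag counts")
    return DesignMatrix(
        X=np.vstack([d.X for d in designs]),
        excluded=np.concatenate([d.excluded for d in designs]),
        stimulus_ids=np.concatenate([d.stimulus_ids for d in designs]),
        n_channels=first.n_channels,
        n_lags=first.n_lags,
        bin_ms=first.bin_ms,
        center_freqs=first.center_freqs,
    )


def build_design(
    cochleagrams: Sequence[Cochleagram],
    stimulus_ids: Sequence[str] | None = None,
    n_lags: int = DEFAULT_N_LAGS,
    onset_exclude_ms: float = DEFAULT_ONSET_EXCLUDE_MS,
) -> DesignMatrix:
    """Lag-unroll and concatenate a sequence of stimulus cochleagrams."""
    if stimulus_ids is None:
        stimulus_ids = [str(i) for i in range(len(cochleagrams))]
    return concat_designs(
        [
            lag_design_matrix(cg, n_lags, onset_exclude_ms, stimulus_id=sid)
            for cg, sid in zip(cochleagrams, stimulus_ids)
        ]
    )


# ---------------------------------------------------------------------------
# Model parameterizations
# ---------------------------------------------------------------------------

@dataclass
class STRF:
    """Spectrotemporal receptive field: weights over channels x lags + bias."""

    weights: np.ndarray          # (n_channels, n_lags)
    bias: float
    bin_ms: float
    center_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if self.weights.ndim != 2:
            raise InputError("STRF weights must be channels x lags")
        if not np.all(np.isfinite(self.weights)):
            raise InputError("STRF weights must be finite")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_lags(self) -> int:
        return self.weights.shape[1]

    def flat(self) -> np.ndarray:
        """Weights in design-matrix column order (channel-major)."""
        return self.weights.reshape(-1)


@dataclass
class SigmoidParams:
    """Static output nonlinearity ``y = a + b / (1 + exp(-(x - c)/d))``.

    ``a >= 0`` keeps predicted rates nonnegative; ``b >= 0`` and ``d > 0``
    resolve the (b, d) sign symmetry of the logistic.
    """

    a: float
    b: float
    c: float
    d: float
    degenerate: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        if self.b < 0 or self.d <= 0:
            raise ConfigurationError("sigmoid requires b >= 0 and d > 0")
        if self.a < 0:
            raise ConfigurationError("sigmoid floor a must be >= 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.a + self.b * expit((np.asarray(x, float) - self.c) / self.d)


@dataclass
class LNModel:
    """Linear-nonlinear model: STRF followed by a sigmoid output stage."""

    strf: STRF
    sigmoid: SigmoidParams


@dataclass
class NRFParams:
    """Network receptive field: one hidden layer, sigmoid at both layers.

    Inputs are standardized with the stored feature mean/scale before the
    hidden layer, so the parameters are portable across cochleagrams from
    the same front end.
    """

    w_hidden: np.ndarray     # (n_hidden, n_features)
    b_hidden: np.ndarray     # (n_hidden,)
    w_out: np.ndarray        # (n_hidden,)
    b_out: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    n_channels: int
    n_lags: int
    bin_ms: float

    @property
    def n_hidden(self) -> int:
        return self.w_hidden.shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feature_mean) / self.feature_scale
        H = expit(Z @ self.w_hidden.T + self.b_hidden)
        return expit(H @ self.w_out + self.b_out)


@dataclass
class FitResult:
    """Metadata of one model fit."""

    selected_lambda: float | None = None
    lambda_grid: np.ndarray | None = None
    cv_fold_scores: np.ndarray | None = None  # (k, len(grid)) held-out r
    seed: int | None = None
    iterations: int = 0
    converged: bool = True


@dataclass
class CVResult:
    selected_lambda: float
    lambda_grid: np.ndarray
    fold_scores: np.ndarray   # (k, len(grid)) held-out correlation
    mean_scores: np.ndarray   # (len(grid),)


# ---------------------------------------------------------------------------
# L1-penalized STRF fitting
# ---------------------------------------------------------------------------

def _fit_l1_centered(
    Xc: np.ndarray,
    yc: np.ndarray,
    l1_penalty: float,
    gram: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize mean((yc - Xc w)^2) + l1_penalty * sum|w| on centered data.

    scikit-learn's Lasso minimizes ||y - Xw||^2 / (2n) + alpha ||w||_1,
    so alpha = l1_penalty / 2.  The unpenalized limit falls back to
    ordinary least squares.
    """
    if l1_penalty < 0:
        raise ConfigurationError("l1_penalty must be nonnegative")
    if l1_penalty == 0:
        col_ptp = np.ptp(Xc, axis=0)
        if np.any(col_ptp == 0):
            logger.warning(
                "design has %d constant column(s); unpenalized fit uses the "
                "minimum-norm least-squares solution",
                int(np.sum(col_ptp == 0)),
            )
        w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        return w
    model = Lasso(
        alpha=l1_penalty / 2.0,
        fit_intercept=False,
        precompute=gram if gram is not None else True,
        max_iter=_LASSO_MAX_ITER,
        tol=_LASSO_TOL,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny penalties
        model.fit(Xc, yc)
    return model.coef_.copy()


def fit_strf_l1(
    design: DesignMatrix,
    rates: np.ndarray,
    l1_penalty: float,
    rows: np.ndarray | None = None,
    gram: np.ndarray | None = None,
) -> STRF:
    """Fit an STRF by L1-penalized least squares (bias unpenalized).

    ``rows`` restricts the fit to an index subset (already net of onset
    exclusion when provided); by default all non-excluded rows are used.
    ``gram`` may pass a precomputed Gram matrix of the centered regressors
    for those rows — sharable across units and penalties.
    """
    rates = np.asarray(rates, float)
    if rates.shape[0] != design.n_rows:
        raise InputError("rates must align with design rows")
    if not np.all(np.isfinite(rates)):
        raise InputError("rates must be finite")
    if rows is None:
        rows = np.flatnonzero(design.usable_rows())
    Xr = design.X[rows]
    yr = rates[rows]
    xmean = Xr.mean(axis=0)
    ymean = yr.mean()
    w = _fit_l1_centered(Xr - xmean, yr - ymean, l1_penalty, gram=gram)
    bias = ymean - float(xmean @ w)
    return STRF(
        weights=w.reshape(design.n_channels, design.n_lags),
        bias=bias,
        bin_ms=design.bin_ms,
        center_freqs=design.center_freqs,
    )


def _fold_rows(design: DesignMatrix, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous stimulus-block folds over the usable rows.

    Stimuli (in first-appearance order) are split into k contiguous
    groups; each fold holds out one group.  With a single stimulus the
    usable rows themselves are split into k contiguous blocks.
    """
    usable = np.flatnonzero(design.usable_rows())
    if usable.size < k:
        raise InputError(f"only {usable.size} usable bins for {k} folds")
    ids = design.stimulus_ids
    unique_ids = list(dict.fromkeys(ids))
    if len(unique_ids) >= k:
        groups = np.array_split(np.arange(len(unique_ids)), k)
        folds = []
        for g in groups:
            held = {unique_ids[i] for i in g}
            mask = np.isin(ids[usable], list(held))
            folds.append((usable[~mask], usable[mask]))
        return folds
    blocks = np.array_split(usable, k)
    return [
        (np.concatenate([b for j, b in enumerate(blocks) if j != i]), blocks[i])
        for i, b_i in enumerate(blocks)
    ]


def make_fold_cache(design: DesignMatrix, k: int = DEFAULT_K_FOLDS) -> dict:
    """Precompute per-fold row sets and centered Gram matrices.

    The cache depends only on the design (not the unit), so one cache
    serves every unit recorded with the same stimuli and front end.
    """
    cache: dict = {"k": k, "folds": []}
    for train, test in _fold_rows(design, k):
        Xr = design.X[train]
        mu = Xr.mean(axis=0)
        Xc = Xr - mu
        cache["folds"].append(
            {"train": train, "test": test, "gram": Xc.T @ Xc}
        )
    all_rows = np.flatnonzero(design.usable_rows())
    Xc = design.X[all_rows] - design.X[all_rows].mean(axis=0)
    cache["full"] = {"rows": all_rows, "gram": Xc.T @ Xc}
    return cache


def default_lambda_grid(
    design: DesignMatrix, rates: np.ndarray, n: int = 6
) -> np.ndarray:
    """Geometric penalty grid anchored at the data's critical penalty.

    The largest grid value is half the smallest penalty that zeroes every
    weight (lambda_max = 2 max|Xc' yc| / n for the MSE + lambda*sum|w|
    objective); the grid descends three decades from there — receptive
    fields selected below 1e-3 lambda_max are indistinguishable from the
    unpenalized fit on data of this size.
    """
    rows = np.flatnonzero(design.usable_rows())
    Xr = design.X[rows]
    yr = np.asarray(rates, float)[rows]
    xty = (Xr - Xr.mean(0)).T @ (yr - yr.mean())
    lam_max = 2.0 * np.max(np.abs(xty)) / rows.size
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max * 1e-3, lam_max * 0.5, n)


def select_lambda_cv(
    design: DesignMatrix,
    rates: np.ndarray,
    k: int = DEFAULT_K_FOLDS,
    lambda_grid: np.ndarray | None = None,
    fold_cache: dict | None = None,
) -> CVResult:
    """Choose the L1 penalty by k-fold cross-validation.

    Folds are contiguous stimulus blocks (no shuffling of autocorrelated
    bins).  The selected penalty maximizes the mean held-out prediction
    correlation; exact ties break toward the larger (sparser) penalty.
    """
    if k < 2:
        raise InputError("cross-validation needs k >= 2")
    rates = np.asarray(rates, float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(design, rates)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))
    if fold_cache is None or fold_cache.get("k") != k:
        fold_cache = make_fold_cache(design, k)
    scores = np.zeros((k, lambda_grid.size))
    for i, fold in enumerate(fold_cache["folds"]):
        tr, te = fold["train"], fold["test"]
        Xr, yr = design.X[tr], rates[tr]
        mu, ym = Xr.mean(axis=0), yr.mean()
        Xc, yc = Xr - mu, yr - ym
        Xte = design.X[te] - mu
        yte = rates[te]
        for j, lam in enumerate(lambda_grid):
            w = _fit_l1_centered(Xc, yc, lam, gram=fold["gram"])
            pred = Xte @ w + ym
            if np.ptp(pred) == 0 or np.ptp(yte) == 0:
                scores[i, j] = 0.0
            else:
                scores[i, j] = np.corrcoef(yte, pred)[0, 1]
    mean_scores = scores.mean(axis=0)
    best = np.flatnonzero(mean_scores == mean_scores.max())[-1]  # tie -> larger lambda
    return CVResult(
        selected_lambda=float(lambda_grid[best]),
        lambda_grid=lambda_grid,
        fold_scores=scores,
        mean_scores=mean_scores,
    )


# ---------------------------------------------------------------------------
# Output nonlinearity
# ---------------------------------------------------------------------------

def _sigmoid_fn(x, a, b, c, d):
    return a + b * expit((x - c) / d)


def fit_output_nonlinearity(
    linear_drive: np.ndarray, rates: np.ndarray
) -> SigmoidParams:
    """Least-squares fit of the 4-parameter sigmoid to (drive, rate) pairs.

    Uses multi-start nonlinear least squares (starts spread over drive
    quantiles and slopes).  A constant drive or constant rate yields a
    flat sigmoid flagged as degenerate; non-convergence falls back to an
    identity-like affine sigmoid (locally linear regime) with
    ``converged=False``.
    """
    x = np.asarray(linear_drive, float)
    y = np.asarray(rates, float)
    if x.shape != y.shape:
        raise InputError("drive and rates must have equal length")
    ymean = max(float(y.mean()), 0.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SigmoidParams(
            a=ymean, b=0.0, c=float(x.mean()), d=1.0,
            degenerate=True, converged=True,
        )
    x_std = float(x.std())
    y_lo = max(float(np.quantile(y, 0.02)), 0.0)
    y_range = max(float(np.quantile(y, 0.98)) - y_lo, 1e-12)
    slope = float(np.polyfit(x, y, 1)[0])
    starts = []
    for cq in (0.25, 0.5, 0.75, 0.9):
        for dfrac in (0.1, 0.3, 1.0):
            starts.append(
                (y_lo, y_range, float(np.quantile(x, cq)), max(dfrac * x_std, 1e-9))
            )
    # near-affine start covering the "sigmoid as identity" regime
    d_big = max(2.0 * np.ptp(x), 1e-9)
    starts.append(
        (max(float(y.mean()) - 2 * abs(slope) * d_big, 0.0),
         max(4.0 * d_big * slope, 1e-12), float(x.mean()), d_big)
    )
    bounds = ([0.0, 0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf, np.inf])
    best = None
    best_sse = np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _sigmoid_fn, x, y, p0=p0, bounds=bounds, maxfev=2000
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((_sigmoid_fn(x, *popt) - y) ** 2))
        if sse < best_sse:
            best_sse, best = sse, popt
    if best is not None:
        a, b, c, d = best
        return SigmoidParams(a=float(a), b=float(b), c=float(c), d=float(d))
    logger.warning("sigmoid fit did not converge; using affine fallback")
    slope_pos = max(slope, 0.0)
    b = 4.0 * d_big * slope_pos
    a = max(float(y.mean()) - b / 2.0, 0.0)
    return SigmoidParams(
        a=a, b=b, c=float(x.mean()), d=d_big, converged=False
    )


def fit_ln(
    design: DesignMatrix,
    rates: np.ndarray,
    k: int = DEFAULT_K_FOLDS,
    lambda_grid: np.ndarray | None = None,
    fold_cache: dict | None = None,
) -> tuple[LNModel, FitResult]:
    """Two-stage LN fit: CV-selected L1 STRF, then the output sigmoid.

    The sigmoid is fitted to the frozen linear drive on the training rows;
    there is no joint refinement.
    """
    cv = select_lambda_cv(design, rates, k, lambda_grid, fold_cache)
    gram = None
    rows = None
    if fold_cache is not None and "full" in fold_cache:
        rows, gram = fold_cache["full"]["rows"], fold_cache["full"]["gram"]
    strf = fit_strf_l1(design, rates, cv.selected_lambda, rows=rows, gram=gram)
    use = np.flatnonzero(design.usable_rows())
    drive = design.X[use] @ strf.flat() + strf.bias
    sigmoid = fit_output_nonlinearity(drive, np.asarray(rates, float)[use])
    result = FitResult(
        selected_lambda=cv.selected_lambda,
        lambda_grid=cv.lambda_grid,
        cv_fold_scores=cv.fold_scores,
        converged=sigmoid.converged,
    )
    return LNModel(strf, sigmoid), result


# ---------------------------------------------------------------------------
# Network receptive field
# ---------------------------------------------------------------------------

DEFAULT_N_HIDDEN = 20
DEFAULT_NRF_L1 = 1e-4
_L1_SMOOTH_EPS = 1e-8


def _nrf_pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _nrf_unpack(theta, n_hidden, n_feat):
    i = n_hidden * n_feat
    w1 = theta[:i].reshape(n_hidden, n_feat)
    b1 = theta[i : i + n_hidden]
    w2 = theta[i + n_hidden : i + 2 * n_hidden]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _nrf_loss_grad(theta, Z, y, n_hidden, l1_penalty):
    n, p = Z.shape
    w1, b1, w2, b2 = _nrf_unpack(theta, n_hidden, p)
    H = expit(Z @ w1.T + b1)
    yhat = expit(H @ w2 + b2)
    resid = yhat - y
    loss = float(resid @ resid) / n
    # smoothed |w| = sqrt(w^2 + eps): differentiable everywhere
    smooth = np.sqrt(w1 ** 2 + _L1_SMOOTH_EPS)
    loss += l1_penalty * float(smooth.sum())
    r = (2.0 / n) * resid * yhat * (1.0 - yhat)
    g_b2 = float(r.sum())
    g_w2 = H.T @ r
    G = np.outer(r, w2) * H * (1.0 - H)
    g_b1 = G.sum(axis=0)
    g_w1 = G.T @ Z + l1_penalty * (w1 / smooth)
    return loss, _nrf_pack(g_w1, g_b1, g_w2, g_b2)


def fit_nrf(
    design: DesignMatrix,
    rates: np.ndarray,
    n_hidden: int = DEFAULT_N_HIDDEN,
    l1_penalty: float = DEFAULT_NRF_L1,
    seed: int = 0,
    max_iter: int = 300,
    val_fraction: float = 0.2,
    patience: int = 5,
    chunk_iter: int = 10,
) -> tuple[NRFParams, FitResult]:
    """Fit a network receptive field by L-BFGS with early stopping.

    The penalized MSE (L1 on the input-layer weights only, smoothed for
    differentiability) is minimized in chunks of ``chunk_iter`` L-BFGS
    iterations; after each chunk the MSE on the held-out tail
    (``val_fraction`` of the training rows) is checked and the
    best-so-far parameters kept.  Training stops after ``patience``
    chunks without improvement.  Fully reproducible given ``seed``.
    """
    if n_hidden < 1:
        raise ConfigurationError("n_hidden must be >= 1")
    rates = np.asarray(rates, float)
    rows = np.flatnonzero(design.usable_rows())
    X = design.X[rows]
    y = rates[rows]
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    n_val = max(1, int(round(val_fraction * Z.shape[0])))
    Z_tr, y_tr = Z[:-n_val], y[:-n_val]
    Z_va, y_va = Z[-n_val:], y[-n_val:]
    p = Z.shape[1]
    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(p), size=(n_hidden, p))
    b1 = np.zeros(n_hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=n_hidden)
    b2 = float(logit(np.clip(y.mean(), 1e-4, 1 - 1e-4)))
    theta = _nrf_pack(w1, b1, w2, b2)

    def val_mse(th):
        w1_, b1_, w2_, b2_ = _nrf_unpack(th, n_hidden, p)
        pred = expit(expit(Z_va @ w1_.T + b1_) @ w2_ + b2_)
        return float(np.mean((pred - y_va) ** 2))

    best_theta = theta.copy()
    best_val = val_mse(theta)
    stale = 0
    total_iter = 0
    converged = False
    while total_iter < max_iter:
        res = minimize(
            _nrf_loss_grad,
            theta,
            args=(Z_tr, y_tr, n_hidden, l1_penalty),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": chunk_iter},
        )
        theta = res.x
        total_iter += max(res.nit, 1)
        v = val_mse(theta)
        if v < best_val - 1e-12:
            best_val = v
            best_theta = theta.copy()
            stale = 0
        else:
            stale += 1
        if res.success and res.nit < chunk_iter:
            converged = True  # optimizer hit its own tolerance
            break
        if stale >= patience:
            converged = True  # early stop on validation plateau
            break
    w1, b1, w2, b2 = _nrf_unpack(best_theta, n_hidden, p)
    params = NRFParams(
        w_hidden=w1,
        b_hidden=b1,
        w_out=w2,
        b_out=float(b2),
        feature_mean=mean,
        feature_scale=scale,
        n_channels=design.n_channels,
        n_lags=design.n_lags,
        bin_ms=design.bin_ms,
    )
    result = FitResult(
        selected_lambda=l1_penalty,
        seed=seed,
        iterations=total_iter,
        converged=converged,
    )
    if not converged:
        logger.warning("NRF fit hit max_iter=%d; returning best-so-far", max_iter)
    return params, result


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _model_channels(model) -> tuple[int, int]:
    if isinstance(model, STRF):
        return model.n_channels, model.n_lags
    if isinstance(model, LNModel):
        return model.strf.n_channels, model.strf.n_lags
    if isinstance(model, NRFParams):
        return model.n_channels, model.n_lags
    raise InputError(f"unknown model type {type(model).__name__}")


def predict(model, cochleagram: Cochleagram) -> np.ndarray:
    """Predicted rate per cochleagram bin for any encoding model.

    The lagged design is built internally (zero-padded history at the
    stimulus start); one value is returned per bin.  Onset exclusion is a
    scoring concern and is not applied here.
    """
    n_ch, n_lags = _model_channels(model)
    if cochleagram.n_channels != n_ch:
        raise InputError(
            f"channel mismatch: model expects {n_ch} channels, cochleagram "
            f"from front end {cochleagram.provenance.get('front_end', '?')!r} "
            f"has {cochleagram.n_channels}"
        )
    design = lag_design_matrix(cochleagram, n_lags, onset_exclude_ms=0.0)
    return predict_design(model, design)


def predict_design(model, design: DesignMatrix) -> np.ndarray:
    """Predicted rate for every row of a prebuilt design matrix."""
    n_ch, n_lags = _model_channels(model)
    if (design.n_channels, design.n_lags) != (n_ch, n_lags):
        raise InputError(
            f"design shape ({design.n_channels} ch x {design.n_lags} lags) "
            f"does not match model ({n_ch} ch x {n_lags} lags)"
        )
    if isinstance(model, STRF):
        return design.X @ model.flat() + model.bias
    if isinstance(model, LNModel):
        return model.sigmoid(design.X @ model.strf.flat() + model.strf.bias)
    return model.forward(design.X)


# ---------------------------------------------------------------------------
# Serialization (exact round trip)
# ---------------------------------------------------------------------------

def save_model(path, model, meta: dict | None = None) -> None:
    """Persist any encoding model plus provenance as an .npz archive."""
    meta = dict(meta or {})
    if isinstance(model, STRF):
        arrays = {
            "kind": np.asarray("strf"),
            "weights": model.weights,
            "bias": np.asarray(model.bias),
            "bin_ms": np.asarray(model.bin_ms),
            "center_freqs": model.center_freqs,
        }
    elif isinstance(model, LNModel):
        arrays = {
            "kind": np.asarray("ln"),
            "weights": model.strf.weights,
            "bias": np.asarray(model.strf.bias),
            "bin_ms": np.asarray(model.strf.bin_ms),
            "center_freqs": model.strf.center_freqs,
            "sigmoid": np.asarray(
                [model.sigmoid.a, model.sigmoid.b, model.sigmoid.c, model.sigmoid.d]
            ),
            "sigmoid_flags": np.asarray(
                [model.sigmoid.degenerate, model.sigmoid.converged]
            ),
        }
    elif isinstance(model, NRFParams):
        arrays = {
            "kind": np.asarray("nrf"),
            "w_hidden": model.w_hidden,
            "b_hidden": model.b_hidden,
            "w_out": model.w_out,
            "b_out": np.asarray(model.b_out),
            "feature_mean": model.feature_mean,
            "feature_scale": model.feature_scale,
            "shape": np.asarray([model.n_channels, model.n_lags]),
            "bin_ms": np.asarray(model.bin_ms),
        }
    else:
        raise InputError(f"cannot serialize {type(model).__name__}")
    arrays["meta"] = np.asarray(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path):
    """Load a model saved by `save_model`; returns (model, meta)."""
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["kind"])
        meta = json.loads(str(z["meta"]))
        if kind in ("strf", "ln"):
            strf = STRF(
                weights=z["weights"],
                bias=float(z["bias"]),
                bin_ms=float(z["bin_ms"]),
                center_freqs=z["center_freqs"],
            )
            if kind == "strf":
                return strf, meta
            a, b, c, d = z["sigmoid"]
            degen, conv = z["sigmoid_flags"]
            sig = SigmoidParams(
                a=float(a), b=float(b), c=float(c), d=float(d),
                degenerate=bool(degen), converged=bool(conv),
            )
            return LNModel(strf, sig), meta
        if kind == "nrf":
            n_ch, n_lags = (int(v) for v in z["shape"])
            return (
                NRFParams(
                    w_hidden=z["w_hidden"],
                    b_hidden=z["b_hidden"],
                    w_out=z["w_out"],
                    b_out=float(z["b_out"]),
                    feature_mean=z["feature_mean"],
                    feature_scale=z["feature_scale"],
                    n_channels=n_ch,
                    n_lags=n_lags,
                    bin_ms=float(z["bin_ms"]),
                ),
                meta,
            )
    raise InputError(f"unrecognized model kind {kind!r}")
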