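"""Model-comparison grid: front end x channel count x encoding model.

Runs the full study design on a dataset: for every grid cell the stimuli
are passed through the cochlear front end, an encoding model is fitted
per unit on the training stimuli, scored (CC and CC_norm) on the
held-out stimuli, and the scores aggregated to mean +/- SEM per cell.
Units whose noise ratio is at or above the inclusion threshold
(NR < 40 by default, strict inequality) are excluded up front.

Per-unit scores are persisted before aggregation, so alternative
summaries (median, best-model-per-neuron tallies) are post-hoc table
operations.  Cells are cached by a content digest of their inputs and
the grid is resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import encoding, evaluation
from .frontend import AudioSignal, Cochleagram, ConfigurationError, build_front_end
from .synthetic import Dataset

logger = logging.getLogger("ear2cortex")

ENCODING_MODELS = ("linear", "LN", "NRF")
DEFAULT_CHANNEL_COUNTS = (2, 4, 8, 16, 32, 64, 128)
DEFAULT_NOISE_RATIO_THRESHOLD = 40.0


@dataclass
class GridConfig:
    """Configuration of one comparison run."""

    front_ends: Sequence[str] = ("spec-log",)
    channel_counts: Sequence[int] = DEFAULT_CHANNEL_COUNTS
    encoding_models: Sequence[str] = ("LN",)
    noise_ratio_threshold: float = DEFAULT_NOISE_RATIO_THRESHOLD
    onset_exclude_ms: float = encoding.DEFAULT_ONSET_EXCLUDE_MS
    n_lags: int = encoding.DEFAULT_N_LAGS
    k_folds: int = encoding.DEFAULT_K_FOLDS
    lambda_grid: np.ndarray | None = None
    n_hidden: int = encoding.DEFAULT_N_HIDDEN
    nrf_l1: float = encoding.DEFAULT_NRF_L1
    nrf_max_iter: int = 300
    seed: int = 0
    cache_dir: str | None = None
    front_end_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.front_ends or not self.channel_counts or not self.encoding_models:
            raise ConfigurationError("front_ends/channel_counts/encoding_models empty")
        for m in self.encoding_models:
            if m not in ENCODING_MODELS:
                raise ConfigurationError(
                    f"unknown encoding model {m!r}; choose from {ENCODING_MODELS}"
                )
        if self.noise_ratio_threshold <= 0:
            raise ConfigurationError("noise_ratio_threshold must be positive")


# ---------------------------------------------------------------------------
# Unit inclusion
# ---------------------------------------------------------------------------

def filter_units_by_noise_ratio(
    dataset: Dataset, threshold: float = DEFAULT_NOISE_RATIO_THRESHOLD
) -> tuple[list, pd.DataFrame]:
    """Units with noise ratio strictly below the threshold.

    Returns the included unit ids and a per-unit log (unit, noise_ratio,
    included).  Units with nonpositive signal power get an infinite noise
    ratio and are excluded.
    """
    rows = []
    included = []
    for uid in dataset.unit_ids:
        counts = dataset.unit_counts(uid)
        if counts.shape[0] < 2:
            raise evaluation.InputError(
                f"unit {uid} has <2 repeats; noise ratio undefined"
            )
        sp, np_, _ = evaluation.signal_noise_power(counts)
        nr = np_ / sp if sp > 0 else float("inf")
        ok = nr < threshold
        rows.append({"unit": uid, "noise_ratio": nr, "included": ok})
        if ok:
            included.append(uid)
    log = pd.DataFrame(rows)
    if not included:
        logger.warning("noise-ratio filter excluded every unit")
    else:
        logger.info(
            "noise-ratio filter: %d/%d units included (NR < %g)",
            len(included), len(rows), threshold,
        )
    return included, log


# ---------------------------------------------------------------------------
# Grid execution
# ---------------------------------------------------------------------------

def _cochleagrams_for(
    dataset: Dataset, front_end_name: str, n_channels: int, fe_kwargs: dict
) -> dict[str, Cochleagram]:
    fe = build_front_end(front_end_name, n_channels, **fe_kwargs)
    out = {}
    for sid in list(dataset.train_ids) + list(dataset.test_ids):
        cg = fe(dataset.stimuli[sid])
        cg.provenance["stimulus_id"] = sid
        out[sid] = cg
    return out


def _cell_digest(dataset: Dataset, config: GridConfig, fe: str, nc: int, model: str) -> str:
    h = hashlib.sha256()
    h.update(dataset.digest().encode())
    payload = {
        "front_end": fe,
        "n_channels": nc,
        "model": model,
        "n_lags": config.n_lags,
        "onset_exclude_ms": config.onset_exclude_ms,
        "k_folds": config.k_folds,
        "n_hidden": config.n_hidden,
        "nrf_l1": config.nrf_l1,
        "seed": config.seed,
        "threshold": config.noise_ratio_threshold,
    }
    h.update(json.dumps(payload, sort_keys=True).encode())
    return h.hexdigest()[:16]


def _score_unit(
    model,
    test_design: encoding.DesignMatrix,
    test_counts: np.ndarray,
) -> evaluation.EvalResult:
    yhat = encoding.predict_design(model, test_design)
    use = test_design.usable_rows()
    return evaluation.evaluate_prediction(test_counts[:, use], yhat[use])


def fit_unit(
    train_design: encoding.DesignMatrix,
    rates: np.ndarray,
    model_kind: str,
    config: GridConfig,
    fold_cache: dict | None = None,
    seed: int = 0,
):
    """Fit one unit with one encoding model; returns the fitted model."""
    if model_kind == "linear":
        cv = encoding.select_lambda_cv(
            train_design, rates, config.k_folds, config.lambda_grid, fold_cache
        )
        rows = gram = None
        if fold_cache and "full" in fold_cache:
            rows, gram = fold_cache["full"]["rows"], fold_cache["full"]["gram"]
        return encoding.fit_strf_l1(
            train_design, rates, cv.selected_lambda, rows=rows, gram=gram
        )
    if model_kind == "LN":
        model, _ = encoding.fit_ln(
            train_design, rates, config.k_folds, config.lambda_grid, fold_cache
        )
        return model
    if model_kind == "NRF":
        params, _ = encoding.fit_nrf(
            train_design,
            rates,
            n_hidden=config.n_hidden,
            l1_penalty=config.nrf_l1,
            seed=seed,
            max_iter=config.nrf_max_iter,
        )
        return params
    raise ConfigurationError(f"unknown encoding model {model_kind!r}")


def run_model_grid(
    dataset: Dataset, config: GridConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the full comparison grid.

    Returns
    -------
    summary : DataFrame
        One row per (front_end, n_channels, encoding_model): mean CC_norm,
        SEM, mean raw CC, and the number of units.
    per_unit : DataFrame
        One row per (front_end, n_channels, encoding_model, unit) with
        cc_raw, cc_norm, noise_ratio, and STRF features where available.
    """
    included, _ = filter_units_by_noise_ratio(dataset, config.noise_ratio_threshold)
    cache_dir = Path(config.cache_dir) if config.cache_dir else None
    if cache_dir:
        cache_dir.mkdir(parents=True, exist_ok=True)
    ds_digest = dataset.digest() if cache_dir else None
    all_rows = []
    for fe_name in config.front_ends:
        for nc in config.channel_counts:
            try:
                cgs = _cochleagrams_for(
                    dataset, fe_name, nc, config.front_end_kwargs
                )
            except Exception:
                logger.exception(
                    "front end %s @ %d channels failed; cell skipped", fe_name, nc
                )
                continue
            train_design = encoding.build_design(
                [cgs[s] for s in dataset.train_ids],
                stimulus_ids=dataset.train_ids,
                n_lags=config.n_lags,
                onset_exclude_ms=config.onset_exclude_ms,
            )
            test_design = encoding.build_design(
                [cgs[s] for s in dataset.test_ids],
                stimulus_ids=dataset.test_ids,
                n_lags=config.n_lags,
                onset_exclude_ms=config.onset_exclude_ms,
            )
            fold_cache = encoding.make_fold_cache(train_design, config.k_folds)
            for model_kind in config.encoding_models:
                cell_file = None
                if cache_dir:
                    digest = _cell_digest(dataset, config, fe_name, nc, model_kind)
                    cell_file = cache_dir / f"cell_{digest}.csv"
                    if cell_file.exists():
                        logger.info("cell %s/%d/%s loaded from cache",
                                    fe_name, nc, model_kind)
                        all_rows.append(pd.read_csv(cell_file))
                        continue
                rows = _run_cell(
                    dataset, config, included, fe_name, nc, model_kind,
                    train_design, test_design, fold_cache,
                )
                cell_df = pd.DataFrame(rows)
                if cell_file is not None:
                    cell_df.to_csv(cell_file, index=False)
                all_rows.append(cell_df)
    per_unit = (
        pd.concat(all_rows, ignore_index=True)
        if all_rows
        else pd.DataFrame(
            columns=["front_end", "n_channels", "encoding_model", "unit",
                     "cc_raw", "cc_norm", "noise_ratio"]
        )
    )
    summary = summarize(per_unit)
    return summary, per_unit


def _run_cell(
    dataset, config, included, fe_name, nc, model_kind,
    train_design, test_design, fold_cache,
):
    logger.info("fitting cell %s / %d channels / %s", fe_name, nc, model_kind)
    rows = []
    for u_idx, uid in enumerate(included):
        rates = (
            dataset.unit_counts(uid, dataset.train_ids).mean(axis=0)
        )
        model = fit_unit(
            train_design, rates, model_kind, config, fold_cache,
            seed=config.seed * 100003 + u_idx,
        )
        test_counts = dataset.unit_counts(uid, dataset.test_ids)
        res = _score_unit(model, test_design, test_counts)
        row = {
            "front_end": fe_name,
            "n_channels": nc,
            "encoding_model": model_kind,
            "unit": uid,
            "cc_raw": res.cc_raw,
            "cc_norm": res.cc_norm,
            "noise_ratio": res.noise_ratio,
            "best_frequency": np.nan,
            "latency_ms": np.nan,
            "ie_score": np.nan,
        }
        strf = model if isinstance(model, encoding.STRF) else (
            model.strf if isinstance(model, encoding.LNModel) else None
        )
        if strf is not None and np.any(strf.weights):
            feats = evaluation.strf_features(strf)
            row.update(
                best_frequency=feats.best_frequency,
                latency_ms=feats.latency_ms,
                ie_score=feats.ie_score,
            )
        rows.append(row)
    return rows


def summarize(per_unit: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-unit scores to mean +/- SEM per grid cell."""
    if per_unit.empty:
        return pd.DataFrame(
            columns=["front_end", "n_channels", "encoding_model",
                     "mean_cc_norm", "sem_cc_norm", "mean_cc_raw", "n_units"]
        )
    def _sem(x):
        x = np.asarray(x, float)
        return x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0
    g = per_unit.groupby(["front_end", "n_channels", "encoding_model"])
    out = g.agg(
        mean_cc_norm=("cc_norm", "mean"),
        sem_cc_norm=("cc_norm", _sem),
        mean_cc_raw=("cc_raw", "mean"),
        n_units=("unit", "count"),
    ).reset_index()
    return out


def peak_ccnorm(summary: pd.DataFrame) -> pd.DataFrame:
    """Peak mean CC_norm across channel counts per (front end, model).

    The peak is the exact maximum; ties break toward fewer channels.
    """
    rows = []
    for (fe, model), grp in summary.groupby(["front_end", "encoding_model"]):
        grp = grp.sort_values("n_channels")
        best = grp.loc[grp["mean_cc_norm"].idxmax()]  # first occurrence on ties
        rows.append(
            {
                "front_end": fe,
                "encoding_model": model,
                "peak_cc_norm": float(best["mean_cc_norm"]),
                "argmax_channels": int(best["n_channels"]),
                "n_channel_counts": len(grp),
            }
        )
    return pd.DataFrame(rows)


def best_model_per_neuron(per_unit: pd.DataFrame) -> pd.DataFrame:
    """Tally which grid cell wins for each unit (post-hoc report option)."""
    idx = per_unit.groupby("unit")["cc_norm"].idxmax()
    winners = per_unit.loc[idx]
    return (
        winners.groupby(["front_end", "n_channels", "encoding_model"])
        .size()
        .reset_index(name="n_best_units")
        .sort_values("n_best_units", ascending=False)
        .reset_index(drop=True)
    )
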