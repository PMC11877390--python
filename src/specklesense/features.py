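"""Time-series featurization of chunks and hypothesis-test feature filtering.

A fixed, documented registry of 18 per-channel descriptors is computed for
each chunk: basic statistics (mean, median, standard deviation), shape
descriptors (skewness, kurtosis, quantiles), signal measures (RMS, mean
absolute change, lag-1 autocorrelation, energy) and two spectral summaries
motivated by the physiology — the dominant frequency and the fraction of
power in the 0.5-3 Hz cardiac band.  With 4 channels this yields 72 feature
columns per chunk.

Feature filtering follows the classical univariate recipe: one rank-based
hypothesis test per feature against the target labels (Mann-Whitney U for a
binary target, Kruskal-Wallis otherwise), discarding features whose p-value
exceeds the significance level.  Benjamini-Hochberg FDR control over the
per-feature p-values is available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .preprocess import CHANNEL_NAMES, ElementChunk
from .simulate import CARDIAC_BAND_HZ

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("subject_id", "recording_id", "chunk_index", "time_label")


def _autocorr_lag1(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    denom = (xc**2).sum(axis=1)
    num = (xc[:, :-1] * xc[:, 1:]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def _periodogram(x: np.ndarray, fps: float) -> tuple[np.ndarray, np.ndarray]:
    freqs, power = sp_signal.periodogram(x, fs=fps, axis=1, detrend=False)
    return freqs[1:], power[:, 1:]  # drop the DC bin


def _dominant_freq(x: np.ndarray, fps: float) -> np.ndarray:
    freqs, power = _periodogram(x, fps)
    return freqs[np.argmax(power, axis=1)]


def _band_fraction(x: np.ndarray, fps: float) -> np.ndarray:
    freqs, power = _periodogram(x, fps)
    lo, hi = CARDIAC_BAND_HZ
    in_band = (freqs >= lo) & (freqs <= hi)
    total = power.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, power[:, in_band].sum(axis=1) / total, np.nan)


# Every entry maps an (n_chunks, L) array (+ fps) to an (n_chunks,) vector.
# Quantiles use linear interpolation between order statistics so values are
# bit-reproducible across platforms.
FEATURE_REGISTRY: dict = {
    "mean": lambda x, fps: x.mean(axis=1),
    "median": lambda x, fps: np.median(x, axis=1),
    "std": lambda x, fps: x.std(axis=1),
    "skewness": lambda x, fps: sp_stats.skew(x, axis=1),
    "kurtosis": lambda x, fps: sp_stats.kurtosis(x, axis=1),
    "minimum": lambda x, fps: x.min(axis=1),
    "maximum": lambda x, fps: x.max(axis=1),
    "range": lambda x, fps: np.ptp(x, axis=1),
    "quantile_10": lambda x, fps: np.quantile(x, 0.10, axis=1),
    "quantile_25": lambda x, fps: np.quantile(x, 0.25, axis=1),
    "quantile_75": lambda x, fps: np.quantile(x, 0.75, axis=1),
    "quantile_90": lambda x, fps: np.quantile(x, 0.90, axis=1),
    "rms": lambda x, fps: np.sqrt((x**2).mean(axis=1)),
    "mean_abs_change": lambda x, fps: np.abs(np.diff(x, axis=1)).mean(axis=1),
    "autocorr_lag1": lambda x, fps: _autocorr_lag1(x),
    "energy": lambda x, fps: (x**2).sum(axis=1),
    "dominant_freq": _dominant_freq,
    "band_fraction": _band_fraction,
}

DEFAULT_REGISTRY = tuple(FEATURE_REGISTRY)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything except chunk metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def extract_features(
    chunks: list[ElementChunk],
    registry: tuple[str, ...] | list[str] = DEFAULT_REGISTRY,
    fps: float = 500.0,
) -> pd.DataFrame:
    """Compute the feature table: one row per chunk, ``channel__feature`` columns.

    Degenerate values (NaN from constant channels, e.g. skewness of a flat
    signal) are imputed to 0 with a logged warning, so downstream models
    never see missing values.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    unknown = [name for name in registry if name not in FEATURE_REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown feature names {unknown}; valid names: {sorted(FEATURE_REGISTRY)}"
        )
    if not chunks:
        raise ValueError("no chunks given")
    stack = np.stack([c.channels for c in chunks])  # (n, 4, L)
    data: dict[str, np.ndarray] = {}
    for ci, channel in enumerate(CHANNEL_NAMES):
        x = stack[:, ci, :]
        for name in registry:
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                # constant channels trip scipy's moment precision warning;
                # the resulting NaNs are imputed below
                warnings.simplefilter("ignore", RuntimeWarning)
                values = np.asarray(FEATURE_REGISTRY[name](x, fps), dtype=float)
            bad = ~np.isfinite(values)
            if bad.any():
                logger.warning(
                    "feature %s__%s degenerate for %d/%d chunks; imputing 0",
                    channel, name, int(bad.sum()), len(values),
                )
                values = np.where(bad, 0.0, values)
            data[f"{channel}__{name}"] = values
    table = pd.DataFrame(data)
    table.insert(0, "subject_id", [c.subject_id for c in chunks])
    table.insert(1, "recording_id", [c.recording_id for c in chunks])
    table.insert(2, "chunk_index", [c.chunk_index for c in chunks])
    table.insert(3, "time_label", [c.time_label for c in chunks])
    return table


@dataclass
class SelectionResult:
    """Outcome of univariate feature filtering on a training table.

    ``kept`` holds the significant feature names; ``pvalues`` the full
    per-feature ledger (NaN for zero-variance features, which are always
    dropped); ``test_name`` records which test produced each p-value.
    Applying the result to another table only subsets columns — p-values are
    never recomputed on validation data.
    """

    pvalues: dict[str, float]
    kept: list[str]
    alpha: float
    correction: str
    test_name: dict[str, str] = field(default_factory=dict)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = [c for c in METADATA_COLUMNS if c in table.columns] + self.kept
        missing = [c for c in self.kept if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing selected feature columns: {missing}")
        return table[cols]


def select_features(
    table: pd.DataFrame,
    target: str = "time_label",
    alpha: float = 0.05,
    correction: str = "none",
) -> SelectionResult:
    """Filter features by per-feature rank tests against the target labels.

    Binary targets use the two-sided Mann-Whitney U test; targets with three
    or more classes use Kruskal-Wallis.  Features with p <= ``alpha`` are
    kept.  ``correction="fdr"`` applies Benjamini-Hochberg adjustment to the
    p-values before thresholding; ``"none"`` thresholds raw p-values.
    """
    if correction not in ("none", "fdr"):
        raise ValueError("correction must be 'none' or 'fdr'")
    if target not in table.columns:
        raise ValueError(f"target column {target!r} not in table")
    labels = table[target].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("target must have at least 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 rows: {small}")

    cols = feature_columns(table)
    groups_idx = [labels == c for c in classes]
    pvalues: dict[str, float] = {}
    tests: dict[str, str] = {}
    for col in cols:
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("feature %s has zero variance; dropped", col)
            pvalues[col] = float("nan")
            tests[col] = "degenerate"
            continue
        groups = [x[idx] for idx in groups_idx]
        if len(classes) == 2:
            res = sp_stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            tests[col] = "mannwhitneyu"
        else:
            res = sp_stats.kruskal(*groups)
            tests[col] = "kruskal"
        pvalues[col] = float(res.pvalue)

    names = [c for c in cols if np.isfinite(pvalues[c])]
    raw = np.array([pvalues[c] for c in names])
    if correction == "fdr" and len(raw):
        adjusted = sp_stats.false_discovery_control(raw, method="bh")
    else:
        adjusted = raw
    kept = [name for name, p in zip(names, adjusted) if p <= alpha]
    return SelectionResult(
        pvalues=pvalues, kept=kept, alpha=alpha, correction=correction, test_name=tests
    )
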