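"""Multimodal OCM / dMRI comparison: per-ROI image features, quantile
grouping by a diffusion metric, and Bonferroni-corrected two-group tests.

Per ROI, four features are computed from its en-face AIP and attenuation
fit: mean normalized reflectivity <rN>, reflectivity standard deviation
sigma_r, mean attenuation <mu> (mm^-1), attenuation standard deviation
sigma_mu.  ROIs are split into quartile groups Q1..Q4 at the 25/50/75%
sample quantiles of each dMRI metric, and every (feature, metric) pair is
tested Q1 (low) vs Q4 (high) with a two-sample t-test at a significance
threshold of alpha divided by the number of comparisons (0.05/20 = 0.0025
for the default 4 features x 5 metrics design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateInputError

__all__ = [
    "ROIFeatures",
    "QuantileGroups",
    "FEATURE_NAMES",
    "METRIC_NAMES",
    "ocm_features",
    "features_table",
    "quantile_groups",
    "low_high_ttests",
]

FEATURE_NAMES = ("mean_reflectivity", "sd_reflectivity", "mean_attenuation", "sd_attenuation")
METRIC_NAMES = ("FA", "AFD_max", "NuFO", "OD", "IC_VF")


@dataclass
class ROIFeatures:
    """OCM image features of one ROI.  Reflectivity is normalized to [0, 1]
    by an external reference before the statistics are taken."""

    mean_reflectivity: float
    sd_reflectivity: float
    mean_attenuation_mm: float
    sd_attenuation_mm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_reflectivity": self.mean_reflectivity,
            "sd_reflectivity": self.sd_reflectivity,
            "mean_attenuation": self.mean_attenuation_mm,
            "sd_attenuation": self.sd_attenuation_mm,
        }


@dataclass
class QuantileGroups:
    """Quartile labels (1..4) per ROI and the three cut values."""

    labels: np.ndarray
    cuts: tuple[float, float, float]


def norm_reference_from_aips(aips: list[np.ndarray], quantile: float = 0.999) -> float:
    """Reflectivity normalization reference: a high quantile (default
    99.9%) of all ROI AIP intensities in the brain, robust to isolated
    specular pixels."""
    pooled = np.concatenate([np.asarray(a, dtype=float).ravel() for a in aips])
    ref = float(np.quantile(pooled, quantile))
    if ref <= 0:
        raise ValueError("reference quantile is not positive")
    return ref


def ocm_features(
    roi_aip: np.ndarray,
    roi_attenuation_mm: np.ndarray,
    norm_reference: float,
) -> ROIFeatures:
    """Features from one ROI's AIP and per-A-line attenuation values.

    Reflectivity is divided by ``norm_reference`` and clipped to [0, 1];
    NaN attenuation entries (invalid fits) are ignored.
    """
    aip = np.asarray(roi_aip, dtype=float)
    mu = np.asarray(roi_attenuation_mm, dtype=float)
    if aip.size == 0 or mu.size == 0:
        raise ValueError("empty ROI inputs")
    if norm_reference <= 0:
        raise ValueError("norm_reference must be > 0")
    rn = np.clip(aip / norm_reference, 0.0, 1.0)
    mu = mu[np.isfinite(mu)]
    if mu.size == 0:
        mu = np.array([np.nan])
    return ROIFeatures(
        mean_reflectivity=float(rn.mean()),
        sd_reflectivity=float(rn.std()),
        mean_attenuation_mm=float(np.nanmean(mu)),
        sd_attenuation_mm=float(np.nanstd(mu)),
    )


def features_table(features: list[ROIFeatures], labels: list[int] | None = None) -> pd.DataFrame:
    """Stack per-ROI features into a table indexed by ROI label."""
    df = pd.DataFrame([f.as_dict() for f in features])
    if labels is not None:
        df.index = pd.Index(labels, name="roi_label")
    return df


def quantile_groups(
    values: np.ndarray, probs: tuple[float, float, float] = (0.25, 0.5, 0.75)
) -> QuantileGroups:
    """Quartile grouping at the stated sample quantiles.

    Quantiles use the linear-interpolation definition; assignment is by
    half-open intervals: v <= q25 -> Q1, q25 < v <= q50 -> Q2, etc.  Rank
    invariance: any strictly increasing transform of the values preserves
    the grouping.  Raises when all values are identical.
    """
    v = np.asarray(values, dtype=float)
    v = np.where(np.isfinite(v), v, np.nan)
    finite = v[np.isfinite(v)]
    if finite.size < 4:
        raise ValueError("need >= 4 finite values")
    if np.ptp(finite) == 0:
        raise DegenerateInputError("all metric values identical: no grouping")
    cuts = tuple(float(np.quantile(finite, p, method="linear")) for p in probs)
    labels = np.full(v.shape, 0, dtype=int)
    labels[v <= cuts[0]] = 1
    labels[(v > cuts[0]) & (v <= cuts[1])] = 2
    labels[(v > cuts[1]) & (v <= cuts[2])] = 3
    labels[v > cuts[2]] = 4
    labels[~np.isfinite(v)] = 0
    return QuantileGroups(labels=labels, cuts=cuts)


def low_high_ttests(
    features: pd.DataFrame,
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Q1-vs-Q4 two-sample t-tests for every (feature, metric) pair.

    ``features``: one row per ROI, one column per image feature.
    ``metrics``: one row per ROI (same index), one column per dMRI metric.
    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled variant).  Significance threshold = alpha / n_comparisons.
    Pairs whose low or high group has < 2 members are skipped with a
    warning (NaN statistics).
    """
    if not features.index.equals(metrics.index):
        raise ValueError("features and metrics must be indexed by the same ROIs")
    n_comparisons = features.shape[1] * metrics.shape[1]
    threshold = alpha / n_comparisons
    rows = []
    for metric in metrics.columns:
        groups = quantile_groups(metrics[metric].to_numpy())
        low = groups.labels == 1
        high = groups.labels == 4
        for feature in features.columns:
            x = features.loc[low, feature].to_numpy()
            y = features.loc[high, feature].to_numpy()
            x = x[np.isfinite(x)]
            y = y[np.isfinite(y)]
            if len(x) < 2 or len(y) < 2:
                warnings.warn(
                    "skipping %s vs %s: group with < 2 ROIs" % (feature, metric)
                )
                t_stat, p_val = float("nan"), float("nan")
            else:
                t_stat, p_val = stats.ttest_ind(y, x, equal_var=equal_var)
            rows.append(
                {
                    "feature": feature,
                    "metric": metric,
                    "t": float(t_stat),
                    "p": float(p_val),
                    "low_mean": float(x.mean()) if len(x) else float("nan"),
                    "high_mean": float(y.mean()) if len(y) else float("nan"),
                    "low_sd": float(x.std(ddof=1)) if len(x) > 1 else float("nan"),
                    "high_sd": float(y.std(ddof=1)) if len(y) > 1 else float("nan"),
                    "n_low": int(len(x)),
                    "n_high": int(len(y)),
                    "alpha": alpha,
                    "corrected_threshold": threshold,
                    "significant": bool(np.isfinite(p_val) and p_val < threshold),
                }
            )
    return pd.DataFrame(rows)
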