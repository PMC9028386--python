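"""Contour-robustness screening with the intraclass correlation coefficient.

Each feature is measured on every lesion under four contour variants
(-1 mm, original, +1 mm, +2 mm). Robustness is scored with the two-way,
absolute-agreement, single-measurement ICC — ICC(2,1) in the
Shrout-Fleiss taxonomy — treating contour variants as a fixed, crossed
factor:

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))

with MS_R the between-lesion, MS_C the between-variant and MS_E the
residual mean square of the two-way layout (n lesions x k variants).
Absolute agreement penalizes systematic offsets between variants, which is
exactly what contour inflation produces for contour-dependent features.
Features are retained iff ICC strictly exceeds the threshold (default 0.6).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .volumes import VARIANTS

DEFAULT_THRESHOLD = 0.6
#: drop a feature outright if more than this fraction of lesions is lost
#: to missing variants (degenerate contractions, undefined features)
MAX_MISSING_FRACTION = 0.2


def icc(table: np.ndarray) -> float | None:
    """Two-way absolute-agreement single-measurement ICC of an
    n-lesions x k-variants table.

    Rows containing any non-finite value are dropped listwise. Returns
    ``None`` with fewer than 3 usable lesions or fewer than 2 variants.
    A table with zero total variance (all measurements identical) has ICC 1
    by convention: the measurements agree perfectly.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D lesion x variant table, got shape {x.shape}")
    x = x[np.isfinite(x).all(axis=1)]
    n, k = x.shape
    if n < 3 or k < 2:
        return None
    grand = x.mean()
    if np.allclose(x, grand, rtol=0.0, atol=1e-12 * max(1.0, abs(grand))):
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_r = k * np.sum((row_means - grand) ** 2)
    ss_c = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_e = np.sum(resid**2)
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        return 1.0
    return float((ms_r - ms_e) / denom)


def feature_variant_table(features: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Pivot a long-format feature table to lesion x variant for one feature."""
    sub = features[features["feature"] == feature]
    table = sub.pivot_table(index="lesion_id", columns="variant", values="value", aggfunc="first")
    cols = [v for v in VARIANTS if v in table.columns]
    return table[cols]


def stability_filter(
    features: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[str], pd.DataFrame]:
    """Score every feature's contour robustness and filter at the threshold.

    Parameters
    ----------
    features : DataFrame
        Long format with columns ``lesion_id, variant, feature, value``
        (missing values as NaN or absent rows).
    threshold : float
        Strict lower bound: a feature passes iff ICC > threshold.

    Returns
    -------
    (stable, report) : list of str, DataFrame
        Stable feature names (original battery order) and the full report
        with columns ``feature, icc, n_lesions, n_variants, passed``.
    """
    required = {"lesion_id", "variant", "feature", "value"}
    if not required.issubset(features.columns):
        raise ValueError(f"feature table must have columns {sorted(required)}")
    n_total = features["lesion_id"].nunique()
    rows = []
    for feat in features["feature"].unique():
        table = feature_variant_table(features, feat)
        usable = table.dropna()
        n_used, k = usable.shape
        lost_frac = 1.0 - n_used / n_total if n_total else 1.0
        if lost_frac > MAX_MISSING_FRACTION:
            value = None
        else:
            value = icc(usable.to_numpy())
        rows.append(
            dict(
                feature=feat,
                icc=np.nan if value is None else value,
                n_lesions=n_used,
                n_variants=k,
                passed=bool(value is not None and value > threshold),
            )
        )
    report = pd.DataFrame(rows, columns=["feature", "icc", "n_lesions", "n_variants", "passed"])
    stable = report.loc[report["passed"], "feature"].tolist()
    return stable, report
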