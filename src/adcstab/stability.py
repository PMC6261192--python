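"""Stability and discrimination statistics.

For each feature and translation entity the protocol yields one percentage
variation per (subject, translation) pair and one intra-class correlation
per translation (the original feature column against the translated one
over subjects).  Feature robustness is summarized by the means of those
distributions, Diff%_mean and ICC_mean.

The ICC is the two-way mixed-effects, single-measurement, consistency form
(McGraw-Wong C,1): the translation effect is fixed, subject variability is
random.  With n subjects and k = 2 measurement columns,

    ICC = (MS_subjects - MS_error) / (MS_subjects + (k - 1) * MS_error)

from the two-way ANOVA decomposition.  ICC never exceeds 1 and may be
negative; negative values are kept unclamped.  The absolute-agreement form
(A,1) is available as an option.

Data-driven selection thresholds come from pooling the ICC values of the
minimal (10%) and maximal (100%) entities across datasets, discretizations
and features, fitting an equal-weight Gaussian kernel mixture (default
bandwidth 0.05) to each pool, and taking its 0.1 / 0.9 quantiles:
ICC_min = Q_0.1 of the ICC_10 pool, ICC_max = Q_0.9 of the ICC_100 pool.
A feature is then *stable* if ICC_10 >= ICC_min and *discriminative* if
ICC_100 <= ICC_max; only features that are both are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

logger = logging.getLogger(__name__)

ORIGINAL_ID = "original"


def diff_percent(f_original: float, f_transf: float) -> float:
    """Absolute percentage variation of a feature, 100*|Ft - Fo|/|Fo|.

    Undefined (NaN) when the reference is zero or either value is NaN.
    """
    if not np.isfinite(f_original) or not np.isfinite(f_transf) or f_original == 0:
        return float("nan")
    return 100.0 * abs(f_transf - f_original) / abs(f_original)


def icc_two_way_mixed(original, transformed, form: str = "consistency") -> float:
    """Two-way mixed-effects single-measurement ICC of two paired columns.

    Pairs with an undefined (NaN) value are removed; fewer than 2 remaining
    subjects gives NaN.  When both columns are constant (zero variance
    everywhere) the ICC is defined as 1 by convention: agreement is
    degenerate but perfect, which is what lets constant features score as
    non-discriminative at maximal translations.
    """
    if form not in ("consistency", "agreement"):
        raise ValueError(f"form must be 'consistency' or 'agreement', got {form!r}")
    a = np.asarray(original, dtype=float)
    b = np.asarray(transformed, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("original and transformed must be 1-D arrays of equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        return float("nan")
    k = 2
    x = np.stack([a, b], axis=1)
    grand = x.mean()
    # degenerate case: zero variance everywhere (a constant feature) is
    # perfect, if vacuous, agreement; the check is tolerance-based so that
    # float rounding in an analytically constant feature cannot turn the
    # 0/0 mean-square ratio into an arbitrary value
    scale = max(1.0, abs(grand))
    if np.all(np.abs(x - grand) <= 1e-12 * scale):
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    if ms_rows == 0 and ms_err == 0:
        return 1.0  # degenerate: zero variance everywhere, perfect agreement
    if form == "consistency":
        return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))
    denom = ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
    if denom == 0:
        return float("nan")
    return float((ms_rows - ms_err) / denom)


def _t_ci95(values: np.ndarray) -> tuple[float, float]:
    v = values[np.isfinite(values)]
    if v.size < 2:
        return (float("nan"), float("nan"))
    m = v.mean()
    half = stats.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return (float(m - half), float(m + half))


@dataclass(frozen=True)
class StabilityRecord:
    """Per (feature, binning, entity) stability summary."""

    feature_name: str
    binning: int
    entity: float
    icc_by_translation: dict[str, float]
    icc_mean: float
    icc_ci95: tuple[float, float]
    diffpct_mean: float
    diffpct_ci95: tuple[float, float]
    n_diffpct: int
    n_excluded: int  # undefined Diff% or ICC contributions dropped


def _entity_pct(transform_id: str) -> int:
    return int(transform_id[1:4])


def summarize(
    features_by_transform: pd.DataFrame,
    entity: float,
    binning: int,
    icc_form: str = "consistency",
) -> list[StabilityRecord]:
    """Summarize feature robustness at one translation entity.

    Parameters
    ----------
    features_by_transform : tidy DataFrame
        Columns ``subject_id, binning, feature_name, value, transform_id``;
        must contain the original (transform_id = "original") plus the four
        signed in-plane translations at this entity for every subject.
    entity : translation entity (bounding-box fraction).
    binning : the discretization (n_bins) to summarize.

    Returns one :class:`StabilityRecord` per feature: four ICCs (one per
    translation), one Diff% per (subject, translation), and their means
    with t-based 95% confidence intervals.
    """
    df = features_by_transform
    df = df[df["binning"] == binning]
    pct = int(round(entity * 100))
    variant_ids = sorted(
        t for t in df["transform_id"].unique() if t != ORIGINAL_ID and _entity_pct(t) == pct
    )
    if len(variant_ids) != 4:
        expected = {f"t{pct:03d}{s}{ax}" for s in "+-" for ax in "xy"}
        missing = sorted(expected - set(variant_ids))
        raise ValueError(
            f"entity {entity} requires 4 translated variants, found {variant_ids} "
            f"(missing {missing})"
        )
    if ORIGINAL_ID not in set(df["transform_id"]):
        raise ValueError("table lacks the original (untransformed) features")

    wide = df.pivot_table(
        index=["feature_name", "subject_id"],
        columns="transform_id",
        values="value",
        aggfunc="first",
        dropna=False,
    )
    records = []
    for feat, sub in wide.groupby(level="feature_name", sort=True):
        orig = sub[ORIGINAL_ID].to_numpy(dtype=float)
        iccs = {}
        diffs = []
        n_excluded = 0
        for tid in variant_ids:
            trans = sub[tid].to_numpy(dtype=float)
            iccs[tid] = icc_two_way_mixed(orig, trans, form=icc_form)
            d = np.array([diff_percent(o, t) for o, t in zip(orig, trans)])
            n_excluded += int(np.isnan(d).sum())
            diffs.append(d)
        diffs = np.concatenate(diffs)
        icc_vals = np.array(list(iccs.values()), dtype=float)
        defined_icc = icc_vals[np.isfinite(icc_vals)]
        defined_diff = diffs[np.isfinite(diffs)]
        records.append(
            StabilityRecord(
                feature_name=str(feat),
                binning=int(binning),
                entity=float(entity),
                icc_by_translation=iccs,
                icc_mean=float(defined_icc.mean()) if defined_icc.size else float("nan"),
                icc_ci95=_t_ci95(icc_vals),
                diffpct_mean=float(defined_diff.mean()) if defined_diff.size else float("nan"),
                diffpct_ci95=_t_ci95(diffs),
                n_diffpct=int(defined_diff.size),
                n_excluded=n_excluded,
            )
        )
    if any(r.n_excluded for r in records):
        logger.info(
            "entity %.2f bins %d: excluded %d undefined Diff%% contributions",
            entity, binning, sum(r.n_excluded for r in records),
        )
    return records


def kde_cdf(t, values, bandwidth: float) -> np.ndarray:
    """CDF of the equal-weight Gaussian kernel mixture centred on *values*."""
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    return ndtr((t[..., None] - values) / bandwidth).mean(axis=-1)


def fit_kde_quantile(values, q: float, bandwidth: float = 0.05) -> float:
    """Quantile q of a Gaussian-kernel density fitted to *values*.

    Each kernel has mean equal to an observed value and SD equal to the
    bandwidth; the quantile is the point where the mixture CDF equals q,
    solved numerically to better than 1e-6.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("cannot fit a kernel distribution to an empty pool")
    if not 0 < q < 1:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lo = float(values.min() - 10 * bandwidth)
    hi = float(values.max() + 10 * bandwidth)
    return float(
        optimize.brentq(lambda t: kde_cdf(t, values, bandwidth) - q, lo, hi, xtol=1e-9)
    )


@dataclass(frozen=True)
class ThresholdPair:
    """Data-driven ICC thresholds for the selection rule."""

    icc_min: float
    icc_max: float
    kde_bandwidth: float = 0.05
    quantile_low: float = 0.1
    quantile_high: float = 0.9
    n_pool_low: int = 0
    n_pool_high: int = 0


def derive_thresholds(
    pooled_icc10,
    pooled_icc100,
    bandwidth: float = 0.05,
    quantile_low: float = 0.1,
    quantile_high: float = 0.9,
) -> ThresholdPair:
    """Derive (ICC_min, ICC_max) from the pooled minimal/maximal-entity ICCs.

    The pools gather ICC_mean values across datasets, discretizations and
    features; ICC_min is the ``quantile_low`` of the ICC_10 pool and ICC_max
    the ``quantile_high`` of the ICC_100 pool.
    """
    p10 = np.asarray(pooled_icc10, dtype=float)
    p100 = np.asarray(pooled_icc100, dtype=float)
    p10 = p10[np.isfinite(p10)]
    p100 = p100[np.isfinite(p100)]
    if p10.size < 2 or p100.size < 2:
        raise ValueError("threshold pools need at least 2 finite ICC values each")
    return ThresholdPair(
        icc_min=fit_kde_quantile(p10, quantile_low, bandwidth),
        icc_max=fit_kde_quantile(p100, quantile_high, bandwidth),
        kde_bandwidth=bandwidth,
        quantile_low=quantile_low,
        quantile_high=quantile_high,
        n_pool_low=int(p10.size),
        n_pool_high=int(p100.size),
    )


def kde_chi2_diagnostic(values, bandwidth: float = 0.05, n_bins: int = 10) -> dict:
    """Optional chi-square goodness-of-fit report of the kernel density.

    Bins the pooled values, compares observed counts against the expected
    counts under the fitted mixture, and reports the statistic and p value.
    Purely diagnostic; never gates the analysis.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    edges = np.linspace(v.min() - bandwidth, v.max() + bandwidth, n_bins + 1)
    obs, _ = np.histogram(v, bins=edges)
    cdf_edges = kde_cdf(edges, v, bandwidth)
    exp = np.diff(cdf_edges) * v.size
    keep = exp > 0
    chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
    dof = max(1, int(keep.sum()) - 1)
    return {"chi2": chi2, "dof": dof, "p_value": float(stats.chi2.sf(chi2, dof))}


LABEL_SELECTED = "selected"
LABEL_UNSTABLE = "unstable"
LABEL_NON_DISCRIMINATIVE = "non_discriminative"
LABEL_UNDEFINED = "undefined"


def classify_feature(icc_10: float, icc_100: float, thresholds: ThresholdPair) -> str:
    """Apply the selection rule to one feature.

    Unstable if ICC_10 < ICC_min; otherwise non-discriminative if
    ICC_100 > ICC_max; otherwise selected.  Undefined ICCs flag the feature
    instead of silently dropping it.
    """
    if not np.isfinite(icc_10) or not np.isfinite(icc_100):
        return LABEL_UNDEFINED
    if icc_10 < thresholds.icc_min:
        return LABEL_UNSTABLE
    if icc_100 > thresholds.icc_max:
        return LABEL_NON_DISCRIMINATIVE
    return LABEL_SELECTED


def classify_features(
    records_minimal: list[StabilityRecord],
    records_maximal: list[StabilityRecord],
    thresholds: ThresholdPair,
) -> pd.DataFrame:
    """Classify every feature from its minimal- and maximal-entity records.

    Returns a DataFrame with columns ``feature_name, binning, icc_10,
    icc_100, label``.
    """
    by_key_min = {(r.feature_name, r.binning): r for r in records_minimal}
    by_key_max = {(r.feature_name, r.binning): r for r in records_maximal}
    missing = set(by_key_min) ^ set(by_key_max)
    if missing:
        raise ValueError(f"features lack one of the two entities: {sorted(missing)[:5]}")
    rows = []
    for key in sorted(by_key_min):
        rmin, rmax = by_key_min[key], by_key_max[key]
        rows.append(
            {
                "feature_name": key[0],
                "binning": key[1],
                "icc_10": rmin.icc_mean,
                "icc_100": rmax.icc_mean,
                "label": classify_feature(rmin.icc_mean, rmax.icc_mean, thresholds),
            }
        )
    return pd.DataFrame(rows)


def jaccard(set_a, set_b) -> float:
    """Jaccard similarity |A & B| / |A | B| of two feature-name sets (1 if both empty)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
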