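"""Poisson log-linear differential-abundance testing for reporter counts.

The model treats each sample's reporter intensities as count data with a
sample-specific sequencing-depth-like size factor d_i (sum 1 over the
contrast's samples).  Depths are estimated iteratively on the least
differentiated features (goodness-of-fit between the 25th and 75th
percentiles), after which each feature gets a two-class Poisson score
statistic

    T = sum_k (n_k - D_k N)^2 / (D_k N)

with class count sums n_k, class depth sums D_k, and N = n_1 + n_2.
Under the null T is asymptotically chi-square with 1 df; p-values come
from that reference distribution (default) or from a pooled permutation
null.  Multiple testing is controlled with Benjamini-Hochberg q-values;
features are called differential at q below a configurable cutoff
(default 0.05).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Contrast, ReporterMatrix, SampleDesign

log = logging.getLogger(__name__)


@dataclass
class DepthEstimate:
    """Relative depths d (sum 1), per-feature GOF and the kept set S."""

    d: pd.Series
    gof: pd.Series
    kept_features: set[str]
    n_iterations: int


@dataclass
class DiffConfig:
    q_cutoff: float = 0.05
    p_method: str = "chisq"  # or "permutation"
    n_permutations: int = 500
    permutation_seed: int = 0
    min_total_count: int = 10
    #: normalized intensities are rescaled so their median is near this
    #: count before integer rounding; None disables rescaling
    target_median_count: float | None = 500.0
    gof_window: tuple[float, float] = (25.0, 75.0)
    depth_tol: float = 1e-10
    depth_max_iter: int = 20


# ----------------------------------------------------------------------

def estimate_depths(
    counts: pd.DataFrame,
    gof_window: tuple[float, float] = (25.0, 75.0),
    tol: float = 1e-10,
    max_iter: int = 20,
) -> DepthEstimate:
    """Iteratively estimate per-sample depths on least-differential features.

    ``counts`` is features x samples, non-negative with no missing values.
    All-zero feature rows are dropped.  With fewer than 20 features the
    estimate falls back to plain column-sum proportions.
    """
    counts = counts.loc[counts.sum(axis=1) > 0]
    if counts.empty:
        raise ValueError("no nonzero features to estimate depths from")
    grand = counts.to_numpy().sum()
    d = counts.sum(axis=0) / grand
    if len(counts) < 20:
        warnings.warn("fewer than 20 features: falling back to column-sum depths", stacklevel=2)
        gof = _gof(counts, d)
        return DepthEstimate(d=d, gof=gof, kept_features=set(counts.index), n_iterations=0)

    n_iter = 0
    kept = pd.Series(True, index=counts.index)
    gof = _gof(counts, d)
    for n_iter in range(1, max_iter + 1):
        gof = _gof(counts, d)
        lo, hi = np.percentile(gof, gof_window)
        kept = (gof >= lo) & (gof <= hi)
        sums = counts.loc[kept].sum(axis=0)
        total = sums.sum()
        if total <= 0:  # pathological window; keep previous estimate
            break
        d_new = sums / total
        delta = float((d_new - d).abs().max())
        d = d_new
        if delta < tol:
            break
    return DepthEstimate(
        d=d, gof=gof, kept_features=set(counts.index[kept]), n_iterations=n_iter
    )


def _gof(counts: pd.DataFrame, d: pd.Series) -> pd.Series:
    """Per-feature Poisson goodness-of-fit against expected d_i * N_j."""
    n_j = counts.sum(axis=1).to_numpy()
    expected = np.outer(n_j, d.to_numpy())
    obs = counts.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (obs - expected) ** 2 / expected
    return pd.Series(np.nansum(cells, axis=1), index=counts.index)


def score_statistics(
    counts: pd.DataFrame, depths: DepthEstimate, contrast: Contrast
) -> tuple[pd.Series, pd.Series]:
    """Vectorized two-class Poisson score statistic T and log2 fold change.

    log2fc is the depth-adjusted class-mean ratio log2((n_a/D_a)/(n_b/D_b));
    features with N = 0 get T = 0 and log2fc = 0 by convention.
    """
    d = depths.d
    a = [s for s in contrast.group_a if s in counts.columns]
    b = [s for s in contrast.group_b if s in counts.columns]
    if set(a) != set(contrast.group_a) or set(b) != set(contrast.group_b):
        raise ValueError("depth/count columns do not cover the contrast samples")
    n_a = counts[a].sum(axis=1).to_numpy(dtype=float)
    n_b = counts[b].sum(axis=1).to_numpy(dtype=float)
    d_a = float(d[a].sum())
    d_b = float(d[b].sum())
    n = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (n_a - d_a * n) ** 2 / (d_a * n) + (n_b - d_b * n) ** 2 / (d_b * n)
        lfc = np.log2((n_a / d_a) / (n_b / d_b))
    t = np.where(n == 0, 0.0, t)
    lfc = np.where(n == 0, 0.0, lfc)
    return pd.Series(t, index=counts.index), pd.Series(lfc, index=counts.index)


def p_values(
    statistics: pd.Series,
    method: str = "chisq",
    counts: pd.DataFrame | None = None,
    depths: DepthEstimate | None = None,
    contrast: Contrast | None = None,
    n_permutations: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Null calibration of the score statistic.

    ``chisq`` uses the upper tail of chi-square(1).  ``permutation``
    permutes class labels ``n_permutations`` times, pools the permuted
    statistics across features, and uses p = (1 + #{T* >= T}) / (1 + B).
    """
    if method == "chisq":
        return pd.Series(stats.chi2.sf(statistics.to_numpy(), df=1), index=statistics.index).clip(lower=np.finfo(float).tiny)
    if method != "permutation":
        raise ValueError(f"unknown p-value method {method!r}")
    if counts is None or depths is None or contrast is None:
        raise ValueError("permutation p-values need counts, depths and contrast")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    samples = list(contrast.group_a) + list(contrast.group_b)
    k = len(contrast.group_a)
    null: list[np.ndarray] = []
    for _ in range(n_permutations):
        perm = rng.permutation(samples)
        c = Contrast(contrast.name, list(perm[:k]), list(perm[k:]))
        t_star, _ = score_statistics(counts, depths, c)
        null.append(t_star.to_numpy())
    pooled = np.sort(np.concatenate(null))
    b_total = pooled.size
    t_obs = statistics.to_numpy()
    n_ge = b_total - np.searchsorted(pooled, t_obs, side="left")
    return pd.Series((1.0 + n_ge) / (1.0 + b_total), index=statistics.index)


def q_values(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    if len(p) == 0:
        return p.copy()
    _, q, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
    return pd.Series(q, index=p.index)


# ----------------------------------------------------------------------

def paired_contrasts(design: SampleDesign) -> list[Contrast]:
    """The study's four flg22-vs-matched-mock contrasts (genotype x time)."""
    out = []
    for g in ("WT", "quad"):
        for tm in (3, 15):
            a = design.sample_ids(genotype=g, treatment="flg22", time_min=tm)
            b = design.sample_ids(genotype=g, treatment="mock", time_min=tm)
            if len(a) >= 2 and len(b) >= 2:
                out.append(Contrast(f"{g}_{tm}min_flg22_vs_mock", a, b))
    return out


def to_counts(
    values: pd.DataFrame, target_median_count: float | None = 500.0
) -> pd.DataFrame:
    """Round (optionally rescaled) intensities to count-like integers.

    When ``target_median_count`` is set, values are divided by
    (median positive intensity / target) first, so arbitrary intensity
    units land on a count scale the Poisson model can digest.
    """
    arr = values.to_numpy(dtype=float)
    if target_median_count is not None:
        pos = arr[np.isfinite(arr) & (arr > 0)]
        if pos.size:
            scale = np.median(pos) / float(target_median_count)
            if scale > 0:
                arr = arr / scale
    return pd.DataFrame(
        np.maximum(np.rint(arr), 0.0), index=values.index, columns=values.columns
    )


def run_contrast(
    matrix: ReporterMatrix,
    design: SampleDesign,
    contrast: Contrast,
    config: DiffConfig | None = None,
    excluded_features: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full differential test for one contrast on a normalized matrix.

    Returns (results, excluded): one row per tested feature with statistic,
    p, q, log2fc, significance call and direction; and a table of features
    excluded before testing with the reason (not cross-plex comparable,
    incomplete, low count).
    """
    cfg = config or DiffConfig()
    cols = [design.column_of(s) for s in contrast.group_a + contrast.group_b]
    sub = matrix.values[cols].copy()
    sub.columns = contrast.group_a + contrast.group_b

    excluded: list[tuple[str, str]] = []
    if excluded_features:
        drop = [f for f in sub.index if f in excluded_features]
        excluded += [(f, "not_cross_plex") for f in drop]
        sub = sub.drop(index=drop)
    incomplete = sub.index[sub.isna().any(axis=1)]
    excluded += [(f, "incomplete") for f in incomplete]
    sub = sub.dropna(axis=0, how="any")

    counts = to_counts(sub, cfg.target_median_count)
    low = counts.index[counts.sum(axis=1) < cfg.min_total_count]
    excluded += [(f, "low_count") for f in low]
    counts = counts.drop(index=low)

    excluded_df = pd.DataFrame(excluded, columns=["feature_id", "reason"])
    if counts.empty:
        empty = pd.DataFrame(
            columns=["feature_id", "statistic", "p_value", "q_value", "log2fc",
                     "significant", "direction", "contrast"]
        )
        return empty, excluded_df

    depths = estimate_depths(counts, cfg.gof_window, cfg.depth_tol, cfg.depth_max_iter)
    t, lfc = score_statistics(counts, depths, contrast)
    p = p_values(
        t, method=cfg.p_method, counts=counts, depths=depths, contrast=contrast,
        n_permutations=cfg.n_permutations, seed=cfg.permutation_seed,
    )
    q = q_values(p)
    sig = q < cfg.q_cutoff
    direction = np.where(lfc > 0, "up", "down")
    anomaly = sig & (lfc == 0)
    if anomaly.any():
        log.warning("%d significant feature(s) with zero fold change", int(anomaly.sum()))
    results = pd.DataFrame(
        {
            "feature_id": counts.index,
            "statistic": t.to_numpy(),
            "p_value": p.to_numpy(),
            "q_value": q.to_numpy(),
            "log2fc": lfc.to_numpy(),
            "significant": sig.to_numpy(),
            "direction": direction,
            "contrast": contrast.name,
        }
    ).reset_index(drop=True)
    return results, excluded_df
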