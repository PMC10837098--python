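"""Two-stage normalization of multi-plex reporter intensities.

Stage 1, sample loading (SL): within each plex, channels are scaled so
that the summed intensity of complete features is equal across channels,
removing pipetting/labeling differences in total protein load.

Stage 2, internal reference scaling (IRS): per feature, each plex is
scaled so that the pooled-reference profile agrees across plexes (to the
geometric mean of the per-plex reference values), removing plex-specific
batch effects.  Features absent from any plex's reference cannot be
placed on the common scale; they are flagged not-cross-plex-comparable
and left untouched.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import NormalizationFactors, ReporterMatrix, SampleDesign

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


def sample_loading_normalize(
    matrix: ReporterMatrix, design: SampleDesign
) -> tuple[ReporterMatrix, NormalizationFactors]:
    """Equalize within-plex channel totals (loading normalization).

    Factors are computed on features with no missing value within the
    plex: factor(channel) = mean(channel totals) / channel total.
    """
    vals = matrix.values.copy()
    factors: dict[tuple[str, str], float] = {}
    for plex in design.plexes:
        cols = [c for c in vals.columns if c[0] == plex]
        sub = vals[cols]
        complete = sub.dropna(axis=0, how="any")
        if complete.empty:
            raise NormalizationError(f"plex {plex!r} has no complete features for loading factors")
        totals = complete.sum(axis=0)
        zero = totals[totals <= 0]
        if len(zero):
            raise NormalizationError(f"zero total intensity in channel {zero.index[0]}")
        f = totals.mean() / totals
        vals[cols] = sub * f
        factors.update({c: float(x) for c, x in f.items()})
    return ReporterMatrix(vals, matrix.feature_kind), NormalizationFactors(loading_factor=factors)


def internal_reference_scale(
    matrix: ReporterMatrix, design: SampleDesign
) -> tuple[ReporterMatrix, NormalizationFactors]:
    """Scale each plex per feature to the common reference profile (IRS).

    For feature j: r_pj = geometric mean of the reference intensities in
    plex p; target t_j = geometric mean over plexes of r_pj; every channel
    of plex p is scaled by t_j / r_pj at feature j.
    """
    vals = matrix.values.copy()
    plexes = design.plexes
    # per-plex log geometric mean of reference channels, per feature
    logref = pd.DataFrame(index=vals.index, columns=plexes, dtype=float)
    for plex in plexes:
        ref_cols = design.reference_columns(plex)
        missing = [c for c in ref_cols if c not in vals.columns]
        if missing:
            raise NormalizationError(f"reference channel(s) {missing} absent from matrix")
        ref = vals[ref_cols]
        with np.errstate(divide="ignore"):
            lr = np.log(ref.where(ref > 0))
        logref[plex] = lr.mean(axis=1, skipna=False)
    usable = logref.notna().all(axis=1)
    if not usable.any():
        raise NormalizationError("no feature observed in the reference channel of every plex")
    target = logref[usable].mean(axis=1)
    logfac = target.to_numpy()[:, None] - logref[usable].to_numpy()  # features x plexes
    fac = pd.DataFrame(np.exp(logfac), index=logref.index[usable], columns=plexes)

    plex_of_col = np.array([plexes.index(p) for p, _ in vals.columns])
    scale = np.ones(vals.shape)
    scale[usable.to_numpy()] = fac.to_numpy()[:, plex_of_col]
    out = vals * scale

    irs = pd.DataFrame(np.nan, index=vals.index, columns=plexes)
    irs.loc[fac.index] = fac
    flagged = list(vals.index[~usable])
    if flagged:
        log.info("%d feature(s) not cross-plex comparable (missing/zero in a reference)", len(flagged))
    return (
        ReporterMatrix(out, matrix.feature_kind),
        NormalizationFactors(irs_factor=irs, not_cross_plex=flagged),
    )


@dataclass
class NormalizationReport:
    """Factors plus before/after per-plex coefficient-of-variation QC."""

    factors: NormalizationFactors
    cv_before: pd.Series | None = None
    cv_after: pd.Series | None = None
    flagged: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"plex_id": p, "channel_id": c, "loading_factor": f,
             "cv_before": None if self.cv_before is None else self.cv_before.get(p),
             "cv_after": None if self.cv_after is None else self.cv_after.get(p)}
            for (p, c), f in sorted(self.factors.loading_factor.items())
        ]
        return pd.DataFrame(rows)


def _plex_cv(values: pd.DataFrame, plexes: list[str]) -> pd.Series:
    """Median per-feature CV of complete features, per plex."""
    out = {}
    for plex in plexes:
        cols = [c for c in values.columns if c[0] == plex]
        sub = values[cols].dropna()
        if sub.empty:
            out[plex] = np.nan
            continue
        cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
        out[plex] = float(cv.median())
    return pd.Series(out)


def normalize_pipeline(
    matrix: ReporterMatrix,
    design: SampleDesign,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> tuple[ReporterMatrix, NormalizationFactors, NormalizationReport]:
    """Sample-loading then internal-reference normalization, with QC.

    The two stages are alternated until their factors converge to 1
    (each stage perturbs the other's invariant slightly), so the output
    is a joint fixed point: within-plex totals are equalized and
    cross-plex reference profiles identical, and re-running the pipeline
    leaves the matrix unchanged.  Accumulated factors are reported.
    """
    plexes = design.plexes
    cv_before = _plex_cv(matrix.values, plexes)
    current = matrix
    loading_acc: dict[tuple[str, str], float] = {c: 1.0 for c in matrix.columns}
    irs_acc: pd.DataFrame | None = None
    f_irs = NormalizationFactors()
    for _ in range(max_iter):
        sl, f_sl = sample_loading_normalize(current, design)
        irs, f_irs = internal_reference_scale(sl, design)
        current = irs
        for c, f in f_sl.loading_factor.items():
            loading_acc[c] *= f
        step = f_irs.irs_factor.fillna(1.0)
        irs_acc = step if irs_acc is None else irs_acc * step
        drift = max(
            max(abs(f - 1.0) for f in f_sl.loading_factor.values()),
            float(np.nanmax(np.abs(f_irs.irs_factor.to_numpy() - 1.0), initial=0.0)),
        )
        if drift < tol:
            break
    assert irs_acc is not None
    irs_acc[f_irs.irs_factor.isna()] = np.nan
    cv_after = _plex_cv(current.values, plexes)
    factors = NormalizationFactors(
        loading_factor=loading_acc,
        irs_factor=irs_acc,
        not_cross_plex=f_irs.not_cross_plex,
    )
    report = NormalizationReport(
        factors=factors, cv_before=cv_before, cv_after=cv_after, flagged=f_irs.not_cross_plex
    )
    return current, factors, report
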