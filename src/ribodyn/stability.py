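"""mRNA half-life estimation from transcription-shutoff time courses.

After actinomycin D blocks transcription, an mRNA's level decays as
level(t) = level(0) * exp(-lambda * t).  Regressing ln(level_t/level_0)
on time gives the decay constant lambda = -slope and the half-life
t1/2 = ln(2)/lambda.  Fits are kept only when the slope p-value is below
0.05, R^2 exceeds 0.5, and lambda is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 1.0, 3.0)


@dataclass
class DecayFit:
    """An exponential-decay fit for one gene (one condition)."""

    gene_id: str
    decay_rate: float  # lambda, per hour
    t_half: float  # hours; inf when lambda <= 0
    r_squared: float
    slope_p_value: float
    n_points: int
    passes: bool

    @classmethod
    def failed(cls, gene_id: str, n_points: int = 0) -> "DecayFit":
        return cls(gene_id, np.nan, np.nan, np.nan, np.nan, n_points, False)


def fit_decay(
    times: Sequence[float],
    levels: np.ndarray,
    gene_id: str = "",
    through_origin: bool = False,
    p_threshold: float = 0.05,
    r2_threshold: float = 0.5,
) -> DecayFit:
    """Fit ln(level_t / level_0) = -lambda * t by least squares.

    ``levels`` is either a vector (one value per timepoint) or a
    (timepoints x replicates) array; replicates are averaged per
    timepoint before the fit.  Nonpositive levels are dropped; fewer
    than three surviving points fails the fit.  The default fit includes
    an intercept, which absorbs normalization error at t0;
    ``through_origin`` forces the strict zero-intercept form.
    """
    t = np.asarray(times, dtype=float)
    lv = np.asarray(levels, dtype=float)
    if lv.ndim == 2:
        lv = np.nanmean(lv, axis=1)
    if t.shape != lv.shape:
        raise ValueError("times and levels must align")
    if 0.0 not in t:
        raise ValueError("a t = 0 baseline timepoint is required")
    base = lv[t == 0.0][0]
    if not np.isfinite(base) or base <= 0:
        return DecayFit.failed(gene_id)
    keep = np.isfinite(lv) & (lv > 0)
    t, lv = t[keep], lv[keep]
    if t.size < 3:
        return DecayFit.failed(gene_id, n_points=int(t.size))
    y = np.log(lv / base)

    if through_origin:
        slope = float(np.dot(t, y) / np.dot(t, t))
        resid = y - slope * t
        ss_res = float(np.dot(resid, resid))
        ss_tot = float(np.dot(y, y))
        df = t.size - 1
        se = np.sqrt(ss_res / df / np.dot(t, t)) if df > 0 else np.nan
        tstat = slope / se if se and se > 0 else np.inf * np.sign(slope)
        p = float(2 * stats.t.sf(abs(tstat), df)) if df > 0 else np.nan
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
    else:
        res = stats.linregress(t, y)
        slope, p, r2 = float(res.slope), float(res.pvalue), float(res.rvalue**2)
        if np.isnan(p) and r2 > 0.999999:
            # exact linear data: linregress reports nan p at zero residual
            p = 0.0

    lam = -slope
    t_half = np.log(2) / lam if lam > 0 else np.inf
    passes = bool(np.isfinite(p) and p < p_threshold and r2 > r2_threshold and lam > 0)
    return DecayFit(
        gene_id=gene_id,
        decay_rate=lam,
        t_half=float(t_half),
        r_squared=float(r2),
        slope_p_value=float(p),
        n_points=int(t.size),
        passes=passes,
    )


def batch_decay(
    levels_by_condition: Mapping[str, pd.DataFrame],
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    through_origin: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit decay for every gene in every condition and compare conditions.

    Each condition maps to a DataFrame of genes x samples with a
    ``(timepoint, replicate)`` column MultiIndex.  Replicates are
    averaged per timepoint for the primary fit; per-replicate fits feed
    a two-sample t-test on half-lives between each pair of conditions
    (genes passing in both).

    Returns (fits, comparisons): ``fits`` has one row per gene x
    condition; ``comparisons`` one row per gene x condition pair.
    """
    fit_rows = []
    rep_halves: dict[tuple[str, str], list[float]] = {}
    for cond, mat in levels_by_condition.items():
        if not isinstance(mat.columns, pd.MultiIndex):
            raise ValueError("levels need (timepoint, replicate) MultiIndex columns")
        tps = [tp for tp in pd.unique(mat.columns.get_level_values(0))]
        if sorted(float(tp) for tp in tps) != sorted(float(t) for t in timepoints):
            raise ValueError(f"condition {cond}: timepoints {tps} != {list(timepoints)}")
        reps = pd.unique(mat.columns.get_level_values(1))
        for gene in mat.index:
            arr = np.column_stack(
                [mat.loc[gene, tp].to_numpy(dtype=float) for tp in tps]
            ).T  # timepoints x replicates
            fit = fit_decay(
                [float(tp) for tp in tps], arr, gene_id=gene, through_origin=through_origin
            )
            fit_rows.append(
                {
                    "gene_id": gene,
                    "condition": cond,
                    "decay_rate": fit.decay_rate,
                    "t_half": fit.t_half,
                    "r_squared": fit.r_squared,
                    "slope_p_value": fit.slope_p_value,
                    "n_points": fit.n_points,
                    "passes": fit.passes,
                }
            )
            halves = []
            for rep in reps:
                series = np.array(
                    [float(mat.loc[gene, (tp, rep)]) for tp in tps], dtype=float
                )
                rfit = fit_decay(
                    [float(tp) for tp in tps], series, gene_id=gene,
                    through_origin=through_origin,
                )
                halves.append(rfit.t_half if np.isfinite(rfit.t_half) else np.nan)
            rep_halves[(gene, cond)] = halves
    fits = pd.DataFrame(fit_rows)

    comp_rows = []
    conds = list(levels_by_condition)
    passing = {
        (r["gene_id"], r["condition"]) for r in fit_rows if r["passes"]
    }
    for i, ca in enumerate(conds):
        for cb in conds[i + 1 :]:
            genes = sorted(
                {g for g, c in passing if c == ca} & {g for g, c in passing if c == cb}
            )
            for gene in genes:
                ha = [h for h in rep_halves[(gene, ca)] if np.isfinite(h)]
                hb = [h for h in rep_halves[(gene, cb)] if np.isfinite(h)]
                if len(ha) >= 2 and len(hb) >= 2:
                    tt = stats.ttest_ind(ha, hb)
                    pval = float(tt.pvalue)
                else:
                    pval = np.nan
                comp_rows.append(
                    {
                        "gene_id": gene,
                        "condition_a": ca,
                        "condition_b": cb,
                        "t_half_a": float(np.mean(ha)) if ha else np.nan,
                        "t_half_b": float(np.mean(hb)) if hb else np.nan,
                        "delta_t_half": (float(np.mean(hb)) - float(np.mean(ha)))
                        if ha and hb
                        else np.nan,
                        "t_test_p": pval,
                    }
                )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=[
            "gene_id", "condition_a", "condition_b",
            "t_half_a", "t_half_b", "delta_t_half", "t_test_p",
        ],
    )
    return fits, comparisons
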