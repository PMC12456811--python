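"""Codon-level analytics: RSCU, A-site occupancy, pause calling, and CSC.

RSCU (relative synonymous codon usage) is a codon's count scaled so that
the mean over its synonymous family is 1.  A-site occupancy is the
footprint density at a codon identity relative to the transcript's mean
CDS density, averaged across transcripts.  Pause sites are codons whose
footprint count is improbably large under a zero-truncated negative
binomial (ZTNB) fitted to the transcript's nonzero codon counts.  The
codon stabilization coefficient (CSC) is the per-codon Pearson
correlation between codon frequency and mRNA stability across mRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ribo_io import CodonCountVector
from .transcriptome import (
    AU3_CODONS,
    CODON_TO_AA,
    FAMILY_SIZES,
    GC3_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    CodonProfile,
    Transcript,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RSCU

def rscu(profiles: Iterable[CodonProfile] | CodonProfile) -> pd.Series:
    """Relative synonymous codon usage over a pooled gene set.

    For codon j of amino acid i with pooled count x_ij and family size
    n_i:  RSCU_ij = x_ij * n_i / sum_j x_ij.  Amino acids with zero total
    usage are reported as NaN.  Single-codon families (Met, Trp) are 1 by
    construction whenever used.
    """
    if isinstance(profiles, CodonProfile):
        profiles = [profiles]
    pooled = {c: 0 for c in SENSE_CODONS}
    for prof in profiles:
        for codon, n in prof.counts.items():
            pooled[codon] += n
    values = pd.Series(np.nan, index=list(SENSE_CODONS), name="rscu")
    for aa, n_i in FAMILY_SIZES.items():
        family = [c for c in SENSE_CODONS if CODON_TO_AA[c] == aa]
        total = sum(pooled[c] for c in family)
        if total == 0:
            continue
        for c in family:
            values[c] = pooled[c] * n_i / total
    return values


def rscu_per_gene_mean(profiles: Sequence[CodonProfile]) -> pd.Series:
    """Mean of per-gene RSCU vectors (alternative to pooled counting)."""
    mat = pd.DataFrame([rscu(p) for p in profiles])
    return mat.mean(axis=0, skipna=True).rename("rscu")


# ---------------------------------------------------------------------------
# A-site occupancy

@dataclass
class OccupancyTable:
    """Per-codon mean normalized A-site occupancy."""

    occupancy: pd.Series  # index: 61 sense codons, NaN where absent
    n_transcripts: pd.Series  # transcripts contributing per codon
    n_used: int  # transcripts passing filters


def a_site_occupancy(
    vectors: Mapping[str, CodonCountVector] | Iterable[CodonCountVector],
    transcripts: Sequence[Transcript],
    min_footprints: int = 32,
    trim_codons: int = 30,
) -> OccupancyTable:
    """Mean normalized footprint occupancy per codon identity at the A-site.

    Per transcript, counts at each interior codon (the first and last
    ``trim_codons`` codons are excluded) are divided by the mean count
    over interior codons; occupancies of the same codon identity are
    averaged within the transcript, then averaged across transcripts.
    Transcripts with fewer than ``min_footprints`` total CDS footprints,
    or too short to have an interior region, are excluded.
    """
    if isinstance(vectors, Mapping):
        vec_by_id = dict(vectors)
    else:
        vec_by_id = {v.transcript_id: v for v in vectors}
    sums = pd.Series(0.0, index=list(SENSE_CODONS))
    n_contrib = pd.Series(0, index=list(SENSE_CODONS))
    n_used = 0
    for tx in transcripts:
        vec = vec_by_id.get(tx.transcript_id)
        if vec is None:
            continue
        if vec.total < min_footprints:
            continue
        L = tx.cds_codons
        if L <= 2 * trim_codons + 1:
            logger.warning("%s: too short for interior occupancy window", tx.transcript_id)
            continue
        interior = slice(trim_codons, L - trim_codons)
        counts = vec.counts[interior].astype(float)
        mean_density = counts.mean()
        if mean_density == 0:
            continue
        norm = counts / mean_density
        cds = tx.cds
        codons = [cds[3 * i : 3 * i + 3] for i in range(trim_codons, L - trim_codons)]
        per_codon: dict[str, list[float]] = {}
        for codon, occ in zip(codons, norm):
            if codon in STOP_CODONS:
                continue
            per_codon.setdefault(codon, []).append(occ)
        for codon, occs in per_codon.items():
            sums[codon] += float(np.mean(occs))
            n_contrib[codon] += 1
        n_used += 1
    occupancy = sums / n_contrib.replace(0, np.nan)
    return OccupancyTable(
        occupancy=occupancy.rename("occupancy"),
        n_transcripts=n_contrib.rename("n_transcripts"),
        n_used=n_used,
    )


def compare_codon_groups(
    table_a: OccupancyTable | pd.Series, table_b: OccupancyTable | pd.Series
) -> tuple[pd.DataFrame, float]:
    """Per-codon fold changes between two conditions and an AU3-vs-GC3 test.

    Fold change is condition B over condition A; codons missing in either
    table are dropped pairwise.  Returns the fold-change table (with the
    codon's wobble group) and the two-sided Wilcoxon rank-sum p-value
    comparing AU3 against GC3 fold changes.
    """
    occ_a = table_a.occupancy if isinstance(table_a, OccupancyTable) else table_a
    occ_b = table_b.occupancy if isinstance(table_b, OccupancyTable) else table_b
    df = pd.DataFrame({"a": occ_a, "b": occ_b}).dropna()
    df = df[(df["a"] > 0)]
    df["fold_change"] = df["b"] / df["a"]
    df["group"] = ["AU3" if c in AU3_CODONS else "GC3" for c in df.index]
    au3 = df.loc[df["group"] == "AU3", "fold_change"]
    gc3 = df.loc[df["group"] == "GC3", "fold_change"]
    if len(au3) and len(gc3):
        p = float(stats.mannwhitneyu(au3, gc3, alternative="two-sided").pvalue)
    else:
        p = float("nan")
    return df[["fold_change", "group"]], p


# ---------------------------------------------------------------------------
# Zero-truncated negative binomial pause calling

@dataclass
class ZTNBFit:
    """A zero-truncated negative binomial (or Poisson fallback) null."""

    r: float  # NB size (dispersion); inf marks the Poisson fallback
    mu: float  # NB mean before truncation
    converged: bool
    poisson_fallback: bool = False

    def _p0(self) -> float:
        if self.poisson_fallback:
            return float(np.exp(-self.mu))
        return float(stats.nbinom.pmf(0, self.r, self.r / (self.r + self.mu)))

    def sf_truncated(self, x: np.ndarray | int) -> np.ndarray | float:
        """P(X >= x | X >= 1) for x >= 1 under the fitted null."""
        x = np.asarray(x)
        if self.poisson_fallback:
            upper = stats.poisson.sf(x - 1, self.mu)
        else:
            upper = stats.nbinom.sf(x - 1, self.r, self.r / (self.r + self.mu))
        return upper / (1.0 - self._p0())


def fit_ztnb(counts: np.ndarray) -> ZTNBFit:
    """Fit a zero-truncated negative binomial to positive counts by MLE.

    The likelihood is the NB pmf conditioned on X >= 1, maximized over
    (log r, log mu) with Nelder-Mead from a method-of-moments start.
    Underdispersed samples (variance <= mean) fall back to a
    zero-truncated Poisson; non-convergence falls back to the
    method-of-moments estimate.
    """
    x = np.asarray(counts, dtype=float)
    x = x[x >= 1]
    if x.size < 2:
        raise ValueError("need at least two positive counts to fit")
    m, v = x.mean(), x.var(ddof=1)
    if v <= m:
        # zero-truncated Poisson: mean of truncated = mu / (1 - e^-mu)
        mu = _ztp_mle(x)
        return ZTNBFit(r=np.inf, mu=mu, converged=True, poisson_fallback=True)
    # method-of-moments on the untruncated approximation
    mu0 = m
    r0 = max(m * m / (v - m), 1e-2)

    def nll(theta: np.ndarray) -> float:
        r, mu = np.exp(theta)
        p = r / (r + mu)
        logpmf = stats.nbinom.logpmf(x, r, p)
        log_trunc = np.log1p(-stats.nbinom.pmf(0, r, p))
        val = -(logpmf.sum() - x.size * log_trunc)
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        nll, np.log([r0, mu0]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    if res.success:
        r, mu = np.exp(res.x)
        return ZTNBFit(r=float(r), mu=float(mu), converged=True)
    logger.warning("ZTNB MLE did not converge; using method-of-moments estimate")
    return ZTNBFit(r=float(r0), mu=float(mu0), converged=False)


def _ztp_mle(x: np.ndarray) -> float:
    """MLE of the zero-truncated Poisson rate (solves m = mu/(1-e^-mu))."""
    m = x.mean()
    if m <= 1:
        return max(m - 1e-9, 1e-9)
    sol = optimize.brentq(lambda mu: mu / (1 - np.exp(-mu)) - m, 1e-9, 10 * m)
    return float(sol)


@dataclass(frozen=True)
class PauseSite:
    transcript_id: str
    codon_index: int  # 0-based CDS codon index
    codon: str
    count: int
    p_value: float


def pause_sites(
    vector: CodonCountVector,
    transcript: Transcript,
    alpha: float = 0.05,
    min_total: int = 10,
    min_nonzero: int = 20,
    adjust: bool = False,
) -> list[PauseSite]:
    """Codons with significantly elevated footprint counts on one transcript.

    A ZTNB null is fitted to the transcript's nonzero codon counts; each
    nonzero codon gets the upper-tail probability P(X >= count | X >= 1).
    Sites with p < ``alpha`` are returned (raw p-values by default; set
    ``adjust`` for BH within the transcript).  Transcripts with fewer
    than ``min_total`` reads or ``min_nonzero`` occupied codons are
    skipped.
    """
    counts = vector.counts
    if counts.sum() < min_total:
        return []
    nz_idx = np.nonzero(counts)[0]
    if nz_idx.size < min_nonzero:
        return []
    fit = fit_ztnb(counts[nz_idx])
    p = np.asarray(fit.sf_truncated(counts[nz_idx]), dtype=float)
    if adjust:
        from .quant import bh_fdr

        p = bh_fdr(np.clip(p, 0, 1))
    cds = transcript.cds
    out = []
    for idx, pv in zip(nz_idx, p):
        if pv < alpha:
            out.append(
                PauseSite(
                    transcript_id=vector.transcript_id,
                    codon_index=int(idx),
                    codon=cds[3 * idx : 3 * idx + 3],
                    count=int(counts[idx]),
                    p_value=float(min(pv, 1.0)),
                )
            )
    return out


def pause_sites_to_frame(sites: Iterable[PauseSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": s.transcript_id,
                "codon_index": s.codon_index,
                "codon": s.codon,
                "count": s.count,
                "p_value": s.p_value,
            }
            for s in sites
        ],
        columns=["transcript_id", "codon_index", "codon", "count", "p_value"],
    )


# ---------------------------------------------------------------------------
# Codon stabilization coefficient

def csc(
    profiles: Mapping[str, CodonProfile],
    half_lives: Mapping[str, float] | pd.Series,
    min_mrnas: int = 10,
) -> pd.DataFrame:
    """Codon stabilization coefficient: Pearson r(codon frequency, stability).

    ``profiles`` maps mRNA id -> codon profile; ``half_lives`` maps mRNA
    id -> stability (half-life in hours by convention; any monotone
    stability measure works since only the correlation is used).  The
    frequency of codon j in mRNA m is its count over the mRNA's total
    sense-codon count.  Codons with zero variance across mRNAs are NaN.
    """
    hl = pd.Series(dict(half_lives)) if not isinstance(half_lives, pd.Series) else half_lives
    shared = [m for m in profiles if m in hl.index and np.isfinite(hl[m])]
    if len(shared) < min_mrnas:
        raise ValueError(f"need at least {min_mrnas} mRNAs with profile and stability")
    freq = np.zeros((len(shared), len(SENSE_CODONS)))
    for i, m in enumerate(shared):
        prof = profiles[m]
        total = prof.total
        if total == 0:
            continue
        for j, codon in enumerate(SENSE_CODONS):
            freq[i, j] = prof.counts.get(codon, 0) / total
    y = hl.loc[shared].to_numpy(dtype=float)
    out = pd.DataFrame(
        index=list(SENSE_CODONS), columns=["csc", "n_mrnas"], dtype=float
    )
    for j, codon in enumerate(SENSE_CODONS):
        x = freq[:, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.loc[codon] = [np.nan, len(shared)]
            continue
        r, _ = stats.pearsonr(x, y)
        out.loc[codon] = [r, len(shared)]
    out["n_mrnas"] = out["n_mrnas"].astype(int)
    return out
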