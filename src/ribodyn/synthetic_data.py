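"""Ground-truthed synthetic Ribo-seq / RNA-seq / decay data.

The generator emulates the statistical structure the analysis assumes:
~29-nt footprints with 3-nt periodicity at a configurable in-frame
fidelity and known per-length P-site offsets, planted 5'UTR uORFs with
near-cognate starts, codon-specific dwell times with an AU3-wide
multiplier in selected conditions, six archetypal LPS time-course
expression profiles, and per-transcript exponential decay over an
actinomycin-D 0/1/3 h chase.  Every stochastic choice derives from the
config seed, so identical configs give byte-identical outputs, and the
returned truth object is sufficient to score every downstream call.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ribo_io import FootprintRead, write_bed6
from .transcriptome import (
    AU3_CODONS,
    GC3_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    UORF_START_CODONS,
    Transcript,
)

#: Timepoint-dependent expression multipliers for the six planted
#: time-course archetypes (early spike, late plateau, dip-recover,
#: monotone up, monotone down, oscillating).
CLUSTER_ARCHETYPES: dict[int, tuple[float, float, float, float]] = {
    1: (1.0, 8.0, 4.0, 1.0),
    2: (1.0, 1.0, 4.0, 4.0),
    3: (4.0, 1.0, 1.0, 4.0),
    4: (1.0, 2.0, 4.0, 8.0),
    5: (8.0, 4.0, 2.0, 1.0),
    6: (1.0, 4.0, 1.0, 4.0),
}

DEFAULT_PSITE_OFFSETS: dict[int, int] = {
    26: 11, 27: 12, 28: 12, 29: 12, 30: 13, 31: 13, 32: 14,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: two replicates at LPS
    0/6/12/24 h, footprints with mode 29 nt and ~74% in-frame fidelity,
    ~30% of genes carrying a translated uORF, codon dwell times with an
    AU3-wide reduction late in the time course, and mRNA decay over an
    ActD 0/1/3 h chase whose rate is coupled to AU3 codon content.
    """

    seed: int = 0
    n_genes: int = 500
    # sequence geometry
    utr5_len_median: float = 150.0
    utr5_len_sigma: float = 0.3
    utr5_len_min: int = 60
    cds_len_median_codons: float = 400.0
    cds_len_sigma: float = 0.3
    cds_len_min_codons: int = 80
    utr3_len_median: float = 120.0
    utr3_len_sigma: float = 0.3
    # codon composition: per-gene AU3 propensity drawn uniformly
    au3_fraction_low: float = 0.3
    au3_fraction_high: float = 0.7
    # footprints
    frame_fidelity: float = 0.74
    read_lengths: tuple[int, ...] = (26, 27, 28, 29, 30, 31, 32)
    read_length_probs: tuple[float, ...] = (0.04, 0.08, 0.18, 0.40, 0.18, 0.08, 0.04)
    psite_offsets: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_PSITE_OFFSETS)
    )
    depth: int = 300_000  # footprint reads per sample
    # codon dwell times: lognormal codon-to-codon variation, plus an
    # AU3-wide multiplier in the listed conditions
    dwell_sigma: float = 0.15
    au3_dwell_multiplier: float = 0.8
    dwell_shift_conditions: tuple[str, ...] = ("24h",)
    # initiating ribosomes (P-site on the start codon) accumulate in real
    # libraries; the peak is the absolute anchor that pins offsets mod 3
    initiation_peak: float = 5.0
    # planted ribosome pauses
    pause_fraction: float = 0.0  # fraction of genes with one planted pause
    pause_multiplier: float = 20.0
    # uORFs
    uorf_fraction: float = 0.3
    uorf_loading: float = 0.5  # uORF reads relative to the gene's CDS reads
    uorf_cds_attenuation: float = 0.6
    uorf_len_codons: tuple[int, int] = (5, 15)
    utr_background: float = 0.02  # frame-uniform UTR reads relative to CDS reads
    # expression / design
    lps_timepoints: tuple[str, ...] = ("0h", "6h", "12h", "24h")
    n_replicates: int = 2
    expression_sigma: float = 1.0
    cluster_null_fraction: float = 0.2  # genes with a flat profile
    te_sigma: float = 0.3
    rna_depth: int = 300_000
    rna_dispersion: float = 0.05
    # decay
    actd_timepoints: tuple[float, ...] = (0.0, 1.0, 3.0)
    decay_replicates: int = 3
    decay_lambda_median: float = 0.35  # per hour; t1/2 ~ 2 h
    decay_lambda_sigma: float = 0.3
    decay_au3_beta: Mapping[str, float] = field(
        default_factory=lambda: {"0h": 0.0, "6h": 2.0}
    )
    decay_noise_sd: float = 0.1  # lognormal SD on measured levels


@dataclass
class SyntheticTruth:
    """Everything needed to score downstream calls exactly."""

    gene_ids: list[str]
    cluster_labels: pd.Series  # 0 = flat/null gene
    expression_base: pd.Series
    te: pd.Series
    au3_frequency: pd.Series  # realized AU3 fraction of CDS codons
    uorfs: pd.DataFrame  # transcript_id, start, end, start_codon
    dwell_by_condition: dict[str, pd.Series]  # codon -> relative dwell
    lambda_by_condition: dict[str, pd.Series]
    pause_sites: pd.DataFrame  # transcript_id, codon_index
    psite_offsets: dict[int, int]

    def t_half(self, condition: str) -> pd.Series:
        return np.log(2) / self.lambda_by_condition[condition]


def _rng(config: SimulationConfig, *salts: str) -> np.random.Generator:
    parts = [config.seed % (2**31)] + [
        zlib.crc32(s.encode()) % (2**31) for s in salts
    ]
    return np.random.default_rng(parts)


def _lognormal_int(
    rng: np.random.Generator, median: float, sigma: float, minimum: int, n: int
) -> np.ndarray:
    vals = rng.lognormal(np.log(median), sigma, size=n)
    return np.maximum(np.round(vals).astype(int), minimum)


_AU3_LIST = sorted(AU3_CODONS)
_GC3_LIST = sorted(GC3_CODONS)
_SENSE_LIST = list(SENSE_CODONS)
_NTS = np.array(list("ACGT"))


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[Transcript], SyntheticTruth]:
    """Generate transcripts with planted composition, uORFs, and decay truth."""
    rng = _rng(config, "transcriptome")
    n = config.n_genes
    utr5_lens = _lognormal_int(rng, config.utr5_len_median, config.utr5_len_sigma,
                               config.utr5_len_min, n)
    cds_codons = _lognormal_int(rng, config.cds_len_median_codons,
                                config.cds_len_sigma, config.cds_len_min_codons, n)
    utr3_lens = _lognormal_int(rng, config.utr3_len_median, config.utr3_len_sigma, 20, n)
    au3_props = rng.uniform(config.au3_fraction_low, config.au3_fraction_high, size=n)
    uorf_mask = rng.random(n) < config.uorf_fraction
    stops = sorted(STOP_CODONS)

    transcripts: list[Transcript] = []
    uorf_rows = []
    au3_freq = np.zeros(n)
    for i in range(n):
        gid = f"g{i:05d}"
        tid = f"t{i:05d}"
        # CDS: ATG + sense codons drawn by wobble-base propensity + stop
        p = au3_props[i]
        n_internal = cds_codons[i] - 2
        pick_au3 = rng.random(n_internal) < p
        internal = np.where(
            pick_au3,
            rng.choice(_AU3_LIST, size=n_internal),
            rng.choice(_GC3_LIST, size=n_internal),
        )
        cds = "ATG" + "".join(internal) + rng.choice(stops)
        au3_freq[i] = (np.sum([c in AU3_CODONS for c in ["ATG", *internal]])) / (
            cds_codons[i] - 1
        )
        utr5 = "".join(rng.choice(_NTS, size=utr5_lens[i]))
        if uorf_mask[i]:
            utr5, row = _plant_uorf(rng, utr5, tid, config)
            if row is not None:
                uorf_rows.append(row)
        utr3 = "".join(rng.choice(_NTS, size=utr3_lens[i]))
        seq = utr5 + cds + utr3
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=gid,
                sequence=seq,
                cds_start=len(utr5),
                cds_end=len(utr5) + len(cds),
            )
        )

    gene_ids = [t.gene_id for t in transcripts]
    # cluster labels: a null fraction stays flat, the rest split evenly
    labels = np.zeros(n, dtype=int)
    non_null = rng.random(n) >= config.cluster_null_fraction
    labels[non_null] = rng.integers(1, 7, size=int(non_null.sum()))
    expression = rng.lognormal(np.log(10.0), config.expression_sigma, size=n)
    te = rng.lognormal(0.0, config.te_sigma, size=n)

    # decay truth: lambda coupled to AU3 content (beta > 0 means AU3-rich
    # mRNAs are MORE stable, i.e., lambda decreases with AU3 frequency)
    lam_base = rng.lognormal(np.log(config.decay_lambda_median),
                             config.decay_lambda_sigma, size=n)
    lambda_by_condition = {}
    centered = au3_freq - au3_freq.mean()
    for cond, beta in config.decay_au3_beta.items():
        lambda_by_condition[cond] = pd.Series(
            lam_base * np.exp(-beta * centered), index=gene_ids
        )

    # dwell maps: codon-specific lognormal variation shared across
    # conditions; AU3 codons slowed/sped by the multiplier where listed
    base_dwell = pd.Series(
        rng.lognormal(0.0, config.dwell_sigma, size=len(SENSE_CODONS)),
        index=_SENSE_LIST,
    )
    dwell_by_condition = {}
    for cond in config.lps_timepoints:
        d = base_dwell.copy()
        if cond in config.dwell_shift_conditions:
            d.loc[_AU3_LIST] = d.loc[_AU3_LIST] * config.au3_dwell_multiplier
        dwell_by_condition[cond] = d

    # planted pause sites: one random interior codon per selected gene
    pause_rows = []
    pause_mask = rng.random(n) < config.pause_fraction
    for i in np.nonzero(pause_mask)[0]:
        idx = int(rng.integers(31, cds_codons[i] - 32))
        pause_rows.append({"transcript_id": transcripts[i].transcript_id,
                           "codon_index": idx})

    truth = SyntheticTruth(
        gene_ids=gene_ids,
        cluster_labels=pd.Series(labels, index=gene_ids),
        expression_base=pd.Series(expression, index=gene_ids),
        te=pd.Series(te, index=gene_ids),
        au3_frequency=pd.Series(au3_freq, index=gene_ids),
        uorfs=pd.DataFrame(
            uorf_rows, columns=["transcript_id", "start", "end", "start_codon"]
        ),
        dwell_by_condition=dwell_by_condition,
        lambda_by_condition=lambda_by_condition,
        pause_sites=pd.DataFrame(pause_rows, columns=["transcript_id", "codon_index"]),
        psite_offsets=dict(config.psite_offsets),
    )
    return transcripts, truth


def _plant_uorf(rng, utr5, tid, config):
    """Insert a uORF (near-cognate start .. first in-frame stop) into a UTR."""
    lo, hi = config.uorf_len_codons
    n_codons = int(rng.integers(lo, hi + 1))
    length = 3 * n_codons
    if length + 6 > len(utr5):
        return utr5, None
    start_codon = str(rng.choice(UORF_START_CODONS, p=[0.55, 0.15, 0.15, 0.15]))
    internal = "".join(rng.choice(_SENSE_LIST, size=n_codons - 2))
    stop = str(rng.choice(sorted(STOP_CODONS)))
    orf = start_codon + internal + stop
    pos = int(rng.integers(0, len(utr5) - length + 1))
    new_utr = utr5[:pos] + orf + utr5[pos + length:]
    return new_utr, {
        "transcript_id": tid, "start": pos, "end": pos + length,
        "start_codon": start_codon,
    }


@dataclass
class FootprintSample:
    """Simulated footprints for one sample, with per-codon truth counts."""

    reads: list[FootprintRead]
    true_asite_counts: dict[str, np.ndarray]  # per CDS codon index
    condition: str
    replicate: int


def expression_at(
    truth: SyntheticTruth, config: SimulationConfig, condition: str
) -> pd.Series:
    """Per-gene RNA expression level in a condition (archetype-modulated)."""
    tp_index = list(config.lps_timepoints).index(condition)
    mult = np.array(
        [
            CLUSTER_ARCHETYPES[c][tp_index] if c else 1.0
            for c in truth.cluster_labels
        ]
    )
    return truth.expression_base * mult


def simulate_footprints(
    transcripts: Sequence[Transcript],
    truth: SyntheticTruth,
    config: SimulationConfig,
    condition: str,
    replicate: int = 1,
) -> FootprintSample:
    """Place footprints codon-by-codon with dwell-weighted A-site sampling.

    Reads are distributed over genes proportionally to ribosome density
    (RNA expression x TE x CDS length), over CDS codons proportionally
    to the condition's dwell map evaluated at the A-site, and phased so
    the 5' end sits at P-site minus the true per-length offset with
    probability ``frame_fidelity`` (else +-1 nt).  uORF-bearing genes
    receive in-frame uORF reads and a CDS attenuation; all UTRs receive
    a frame-uniform background.
    """
    rng = _rng(config, "footprints", condition, str(replicate))
    dwell = truth.dwell_by_condition[condition]
    dwell_arr = dwell.reindex(_SENSE_LIST).to_numpy()
    codon_index = {c: k for k, c in enumerate(_SENSE_LIST)}
    expr = expression_at(truth, config, condition)
    uorf_by_tx = {
        r.transcript_id: r for r in truth.uorfs.itertuples(index=False)
    }
    pause_by_tx: dict[str, int] = {
        r.transcript_id: r.codon_index
        for r in truth.pause_sites.itertuples(index=False)
    }

    # expected CDS reads per gene ~ density share; uORF genes attenuated
    weights = np.array(
        [
            expr[t.gene_id]
            * truth.te[t.gene_id]
            * t.cds_codons
            * (config.uorf_cds_attenuation if t.transcript_id in uorf_by_tx else 1.0)
            for t in transcripts
        ]
    )
    n_per_tx = rng.multinomial(config.depth, weights / weights.sum())

    lengths = np.array(config.read_lengths)
    len_probs = np.array(config.read_length_probs)
    len_probs = len_probs / len_probs.sum()
    offsets = np.array([config.psite_offsets[ln] for ln in lengths])

    reads: list[FootprintRead] = []
    true_counts: dict[str, np.ndarray] = {}
    for t, n_reads in zip(transcripts, n_per_tx):
        L = t.cds_codons
        true_counts[t.transcript_id] = np.zeros(L, dtype=np.int64)
        if n_reads == 0 and t.transcript_id not in uorf_by_tx:
            continue
        # A-site candidates: codons 1..L-2 (P-site stays inside the CDS)
        cds = t.cds
        asite_codons = np.array(
            [codon_index.get(cds[3 * a : 3 * a + 3], -1) for a in range(1, L - 1)]
        )
        w = np.where(asite_codons >= 0, dwell_arr[asite_codons], 0.0)
        w[0] *= config.initiation_peak  # P-site on the start codon
        if t.transcript_id in pause_by_tx:
            w[pause_by_tx[t.transcript_id] - 1] *= config.pause_multiplier
        if w.sum() > 0 and n_reads > 0:
            counts = rng.multinomial(n_reads, w / w.sum())
            asites = np.repeat(np.arange(1, L - 1), counts)
            true_counts[t.transcript_id][np.arange(1, L - 1)] += counts
            psite_nt = t.cds_start + 3 * (asites - 1)
            reads.extend(
                _emit_reads(rng, t, psite_nt, config, lengths, len_probs, offsets)
            )
        # planted uORF reads, phased to the uORF's own frame
        u = uorf_by_tx.get(t.transcript_id)
        if u is not None:
            n_uorf = int(round(config.uorf_loading * max(n_reads, 1)))
            if n_uorf:
                u_codons = (u.end - u.start) // 3
                starts = rng.integers(0, max(u_codons - 1, 1), size=n_uorf)
                psite_nt = u.start + 3 * starts
                reads.extend(
                    _emit_reads(rng, t, psite_nt, config, lengths, len_probs, offsets)
                )
        # frame-uniform UTR background
        n_bg = rng.poisson(config.utr_background * max(n_reads, 1))
        if n_bg:
            utr_positions = np.concatenate(
                [np.arange(0, t.cds_start), np.arange(t.cds_end, len(t))]
            )
            psite_nt = rng.choice(utr_positions, size=n_bg)
            reads.extend(
                _emit_reads(rng, t, psite_nt, config, lengths, len_probs, offsets)
            )
    return FootprintSample(
        reads=reads, true_asite_counts=true_counts,
        condition=condition, replicate=replicate,
    )


def _emit_reads(rng, t, psite_nt, config, lengths, len_probs, offsets):
    """Turn true P-site positions into reads with fuzzy 5' ends."""
    n = len(psite_nt)
    li = rng.choice(len(lengths), size=n, p=len_probs)
    starts = psite_nt - offsets[li]
    fuzzy = rng.random(n) >= config.frame_fidelity
    shift = np.where(rng.random(n) < 0.5, -1, 1)
    starts = starts + fuzzy * shift
    read_len = lengths[li]
    ok = (starts >= 0) & (starts + read_len <= len(t))
    return [
        FootprintRead(
            transcript_id=t.transcript_id,
            start=int(s),
            length=int(ln),
        )
        for s, ln in zip(starts[ok], read_len[ok])
    ]


def simulate_rnaseq(
    transcripts: Sequence[Transcript],
    truth: SyntheticTruth,
    config: SimulationConfig,
    condition: str,
    replicate: int = 1,
) -> pd.Series:
    """Per-gene RNA-seq CDS counts, negative-binomial around expression."""
    rng = _rng(config, "rnaseq", condition, str(replicate))
    expr = expression_at(truth, config, condition)
    weights = np.array(
        [expr[t.gene_id] * t.cds_codons for t in transcripts], dtype=float
    )
    mean = config.rna_depth * weights / weights.sum()
    disp = config.rna_dispersion
    if disp <= 1e-9:
        counts = rng.poisson(mean)
    else:
        # NB with var = mu + disp * mu^2, via gamma-Poisson mixture
        shape = 1.0 / disp
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam)
    return pd.Series(counts, index=[t.gene_id for t in transcripts], name=condition)


def simulate_timecourse_matrix(
    truth: SyntheticTruth,
    config: SimulationConfig,
    noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Gene x (timepoint, replicate) expression matrix with archetype profiles.

    Levels are archetype multiplier x base expression x lognormal
    replicate noise (``noise_sd`` on the log scale); null genes are flat.
    """
    rng = _rng(config, "timecourse")
    cols = pd.MultiIndex.from_product(
        [list(config.lps_timepoints), range(1, config.n_replicates + 1)],
        names=["timepoint", "replicate"],
    )
    data = np.zeros((len(truth.gene_ids), len(cols)))
    for j, (tp, _rep) in enumerate(cols):
        base = expression_at(truth, config, tp).to_numpy()
        data[:, j] = base * rng.lognormal(0.0, noise_sd, size=len(base))
    return pd.DataFrame(data, index=truth.gene_ids, columns=cols)


def simulate_decay(
    transcripts: Sequence[Transcript],
    truth: SyntheticTruth,
    config: SimulationConfig,
    condition: str,
) -> pd.DataFrame:
    """Relative mRNA levels over the ActD chase, with lognormal noise.

    Returns genes x (timepoint, replicate) with level(0) = 1 expectation;
    measured levels are exp(-lambda t) times multiplicative noise.
    """
    rng = _rng(config, "decay", condition)
    lam = truth.lambda_by_condition[condition].to_numpy()
    cols = pd.MultiIndex.from_product(
        [list(config.actd_timepoints), range(1, config.decay_replicates + 1)],
        names=["timepoint", "replicate"],
    )
    data = np.zeros((len(lam), len(cols)))
    for j, (tp, _rep) in enumerate(cols):
        noise = rng.lognormal(0.0, config.decay_noise_sd, size=len(lam))
        data[:, j] = np.exp(-lam * float(tp)) * noise
    return pd.DataFrame(data, index=truth.gene_ids, columns=cols)


def score_uorf_calls(calls, truth: SyntheticTruth) -> dict[str, float]:
    """Recall and empirical FDR of translated uORF calls against the truth.

    A call counts as correct when it shares its stop codon (transcript
    and end coordinate, hence frame) with a planted uORF; nested starts
    over the same stop carry the same in-frame signal and are not
    separable.  Candidates overlapping the main CDS in its own frame
    read genuine main-ORF translation and are excluded from scoring
    (they carry the ``overlaps_cds`` flag in the output).
    """
    planted = set(zip(truth.uorfs["transcript_id"], truth.uorfs["end"]))
    called = [
        c for c in calls if c.translated and not c.candidate.overlaps_cds
    ]
    keys = [(c.candidate.transcript_id, c.candidate.end) for c in called]
    n_tp = sum(1 for k in keys if k in planted)
    recall = (
        sum(1 for p in planted if p in set(keys)) / len(planted)
        if planted
        else float("nan")
    )
    fdr = 1 - n_tp / len(called) if called else 0.0
    return {
        "recall": recall,
        "fdr": fdr,
        "n_called": len(called),
        "n_planted": len(planted),
    }


# ---------------------------------------------------------------------------
# File output

def write_fasta(transcripts: Sequence[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.sequence), 80):
                fh.write(t.sequence[i : i + 80] + "\n")


def write_annotation(transcripts: Sequence[Transcript], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "gene_id": [t.gene_id for t in transcripts],
            "cds_start": [t.cds_start for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
        }
    ).to_csv(path, sep="\t", index=False)


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Simulate a full dataset and write it as plain-text files.

    Writes the transcriptome FASTA and annotation TSV, one BED6 footprint
    file per (timepoint, replicate), RNA-seq count TSVs, decay level
    TSVs per decay condition, and the truth tables.  Returns a manifest
    of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = simulate_transcriptome(config)
    manifest: dict[str, str] = {}

    fasta = outdir / "transcriptome.fa"
    annot = outdir / "annotation.tsv"
    write_fasta(transcripts, fasta)
    write_annotation(transcripts, annot)
    manifest["fasta"] = str(fasta)
    manifest["annotation"] = str(annot)

    rna_tables = {}
    for cond in config.lps_timepoints:
        for rep in range(1, config.n_replicates + 1):
            sample = simulate_footprints(transcripts, truth, config, cond, rep)
            bed = outdir / f"ribo_{cond}_rep{rep}.bed"
            write_bed6(sample.reads, bed)
            manifest[f"ribo_{cond}_rep{rep}"] = str(bed)
            rna_tables[(cond, rep)] = simulate_rnaseq(
                transcripts, truth, config, cond, rep
            )
    rna = pd.DataFrame(
        {f"{cond}_rep{rep}": s for (cond, rep), s in rna_tables.items()}
    )
    rna_path = outdir / "rnaseq_counts.tsv"
    rna.to_csv(rna_path, sep="\t")
    manifest["rnaseq"] = str(rna_path)

    for cond in config.decay_au3_beta:
        levels = simulate_decay(transcripts, truth, config, cond)
        levels.columns = [f"t{tp}_rep{rep}" for tp, rep in levels.columns]
        p = outdir / f"decay_lps{cond}.tsv"
        levels.to_csv(p, sep="\t")
        manifest[f"decay_lps{cond}"] = str(p)

    truth_path = outdir / "truth_genes.tsv"
    pd.DataFrame(
        {
            "gene_id": truth.gene_ids,
            "cluster": truth.cluster_labels.values,
            "expression_base": truth.expression_base.values,
            "te": truth.te.values,
            "au3_frequency": truth.au3_frequency.values,
        }
    ).to_csv(truth_path, sep="\t", index=False)
    manifest["truth_genes"] = str(truth_path)
    uorf_path = outdir / "truth_uorfs.tsv"
    truth.uorfs.to_csv(uorf_path, sep="\t", index=False)
    manifest["truth_uorfs"] = str(uorf_path)
    return manifest
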