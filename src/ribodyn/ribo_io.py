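"""Footprint alignment reading, P-site offset calibration, and frame QC.

Ribosome footprints protect ~26-32 nt of mRNA; the P-site codon sits at a
fixed, length-dependent offset downstream of the footprint 5' end.  Library
protocols with template-switch reverse transcription blur the 5' end, so the
offset is calibrated per read length from the 3-nt periodicity of footprints
over annotated start codons: for each length, the offset (candidates
11-14 nt) maximizing the fraction of reads landing in frame 0 of the CDS is
chosen.  The fraction at the chosen offset is the in-frame fidelity reported
by QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .transcriptome import Transcript

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATE_OFFSETS: tuple[int, ...] = (11, 12, 13, 14)


@dataclass(frozen=True)
class FootprintRead:
    """A single footprint (or RNA-seq read) alignment in transcript space."""

    transcript_id: str
    start: int  # 0-based transcript offset of the 5' end
    length: int
    mismatches: int = 0
    n_hits: int = 1


@dataclass
class ReadFilterStats:
    """Bookkeeping of how many reads each filter removed."""

    n_input: int = 0
    n_kept: int = 0
    n_multimapped: int = 0
    n_mismatch: int = 0
    n_short: int = 0
    n_unknown_transcript: int = 0
    n_out_of_bounds: int = 0


@dataclass
class PsiteOffsetModel:
    """Per-length P-site offsets with in-frame (frame-0) fractions."""

    offset_by_length: dict[int, int]
    in_frame_fraction_by_length: dict[int, float]
    global_in_frame_fraction: float
    n_reads_by_length: dict[int, int] = field(default_factory=dict)
    low_confidence: bool = False

    def offset(self, length: int) -> int:
        if length in self.offset_by_length:
            return self.offset_by_length[length]
        # lengths never calibrated fall back to the global modal offset
        return self.modal_offset

    @property
    def modal_offset(self) -> int:
        weights: dict[int, int] = {}
        for length, off in self.offset_by_length.items():
            weights[off] = weights.get(off, 0) + self.n_reads_by_length.get(length, 1)
        return max(weights, key=lambda o: (weights[o], -o))


@dataclass
class CodonCountVector:
    """Integer counts per CDS codon index for one transcript."""

    transcript_id: str
    counts: np.ndarray  # length = CDS codon count

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def read_alignments(
    path: str | Path,
    format: Literal["bed6", "sam"],
    transcripts: Sequence[Transcript],
    max_mismatches: int = 2,
    min_length: int = 15,
    stats: ReadFilterStats | None = None,
) -> Iterator[FootprintRead]:
    """Stream alignment records, applying uniqueness/mismatch/length filters.

    Reads aligned to multiple positions (``n_hits > 1``), with more than
    ``max_mismatches`` mismatches, or shorter than ``min_length`` nt are
    dropped, as are reads on transcripts absent from ``transcripts``.
    Pass a :class:`ReadFilterStats` to collect filter tallies.
    """
    lengths = {t.transcript_id: len(t) for t in transcripts}
    if stats is None:
        stats = ReadFilterStats()
    if str(format).lower() in ("bed", "bed6"):
        raw = _iter_bed6(path)
    elif str(format).lower() in ("sam", "bam"):
        raw = _iter_sam(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    for read in raw:
        stats.n_input += 1
        if read.transcript_id not in lengths:
            stats.n_unknown_transcript += 1
            continue
        if read.n_hits > 1:
            stats.n_multimapped += 1
            continue
        if read.mismatches > max_mismatches:
            stats.n_mismatch += 1
            continue
        if read.length < min_length:
            stats.n_short += 1
            continue
        if read.start < 0 or read.start + read.length > lengths[read.transcript_id]:
            stats.n_out_of_bounds += 1
            continue
        stats.n_kept += 1
        yield read


def _iter_bed6(path: str | Path) -> Iterator[FootprintRead]:
    # BED6 convention here: chrom = transcript id, score = alignment
    # multiplicity, strand always '+' (transcript space).
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
            chrom, start, end, _name, score, _strand = fields[:6]
            start_i, end_i = int(start), int(end)
            yield FootprintRead(
                transcript_id=chrom,
                start=start_i,
                length=end_i - start_i,
                mismatches=0,
                n_hits=int(float(score)) if score not in (".", "") else 1,
            )


def _iter_sam(path: str | Path) -> Iterator[FootprintRead]:
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        missing_tags = False
        for aln in fh:
            if aln.is_unmapped:
                continue
            try:
                nm = aln.get_tag("NM")
            except KeyError:
                nm, missing_tags = 0, True
            try:
                nh = aln.get_tag("NH")
            except KeyError:
                nh, missing_tags = 1, True
            yield FootprintRead(
                transcript_id=aln.reference_name,
                start=aln.reference_start,
                length=aln.query_length or aln.infer_read_length() or 0,
                mismatches=int(nm),
                n_hits=int(nh),
            )
        if missing_tags:
            logger.warning("%s: NM/NH tags absent on some records; treated as unique/0-mismatch", path)


def calibrate_offsets(
    reads: Iterable[FootprintRead],
    transcripts: Sequence[Transcript],
    candidate_offsets: Sequence[int] = DEFAULT_CANDIDATE_OFFSETS,
    min_reads_per_length: int = 200,
) -> PsiteOffsetModel:
    """Calibrate per-length P-site offsets from CDS 3-nt periodicity.

    For each read length, the candidate offset maximizing the fraction of
    reads whose inferred P-site lands in frame 0 of the CDS is selected.
    Periodicity pins the offset only modulo 3, so candidates whose
    in-frame fractions are statistically tied (within two binomial SE of
    the best) are resolved by the start-codon anchor: initiating
    ribosomes pile up with the P-site on the AUG, and the candidate that
    places the most reads exactly on annotated start codons wins.
    Length classes with fewer than ``min_reads_per_length`` reads inherit
    the read-weighted modal offset of the calibrated classes.  The model
    is flagged ``low_confidence`` when the global in-frame fraction does
    not exceed the uniform-frame baseline of 1/3 by a clear margin.
    """
    cds_start = {t.transcript_id: t.cds_start for t in transcripts}
    cds_end = {t.transcript_id: t.cds_end for t in transcripts}
    offsets = list(candidate_offsets)
    # frame_hits[length][k] = reads in frame 0 under candidate offset k;
    # start_hits[length][k] = reads landing exactly on the start codon
    frame_hits: dict[int, np.ndarray] = {}
    start_hits: dict[int, np.ndarray] = {}
    totals: dict[int, int] = {}
    for read in reads:
        cs = cds_start.get(read.transcript_id)
        if cs is None:
            continue
        ce = cds_end[read.transcript_id]
        hits = frame_hits.setdefault(read.length, np.zeros(len(offsets), dtype=np.int64))
        anchors = start_hits.setdefault(read.length, np.zeros(len(offsets), dtype=np.int64))
        counted = False
        for k, off in enumerate(offsets):
            pos = read.start + off
            if cs <= pos < ce:
                counted = True
                if (pos - cs) % 3 == 0:
                    hits[k] += 1
                if pos == cs:
                    anchors[k] += 1
        if counted:
            totals[read.length] = totals.get(read.length, 0) + 1
    calibrated = {
        length: n for length, n in totals.items() if n >= min_reads_per_length
    }
    if not calibrated:
        raise ValueError("insufficient reads for calibration in every length class")

    offset_by_length: dict[int, int] = {}
    frac_by_length: dict[int, float] = {}
    for length, n in sorted(calibrated.items()):
        fracs = frame_hits[length] / n
        best_frac = float(fracs.max())
        se = np.sqrt(max(best_frac * (1 - best_frac), 1e-12) / n)
        tied = [k for k in range(len(offsets)) if fracs[k] >= best_frac - 2 * se]
        best = min(tied, key=lambda k: (-start_hits[length][k], offsets[k]))
        offset_by_length[length] = offsets[best]
        frac_by_length[length] = float(fracs[best])

    model = PsiteOffsetModel(
        offset_by_length=offset_by_length,
        in_frame_fraction_by_length=frac_by_length,
        global_in_frame_fraction=0.0,
        n_reads_by_length=dict(calibrated),
    )
    modal = model.modal_offset
    # uncalibrated length classes inherit the modal offset
    for length, n in totals.items():
        if length not in offset_by_length:
            offset_by_length[length] = modal
            frac_by_length[length] = float(
                frame_hits[length][offsets.index(modal)] / n
            ) if n else float("nan")
    total_n = sum(calibrated.values())
    model.global_in_frame_fraction = float(
        sum(frac_by_length[ln] * n for ln, n in calibrated.items()) / total_n
    )
    # a fraction near 1/3 means no periodicity signal was found
    se = np.sqrt((1 / 3) * (2 / 3) / total_n)
    model.low_confidence = model.global_in_frame_fraction < 1 / 3 + 3 * se + 0.02
    return model


@dataclass
class PsiteAssignment:
    """Result of P/A-site assignment: codon vectors plus region tallies."""

    vectors: dict[str, CodonCountVector]
    utr5_counts: dict[str, int]
    utr3_counts: dict[str, int]
    n_assigned_cds: int = 0
    n_utr5: int = 0
    n_utr3: int = 0
    n_out_of_bounds: int = 0

    @property
    def n_total(self) -> int:
        return self.n_assigned_cds + self.n_utr5 + self.n_utr3 + self.n_out_of_bounds


def assign_psites(
    reads: Iterable[FootprintRead],
    model: PsiteOffsetModel,
    transcripts: Sequence[Transcript],
    site: Literal["P", "A"] = "P",
) -> PsiteAssignment:
    """Resolve each read to a CDS codon index (P- or A-site).

    The P-site nucleotide is ``start + offset(length)``; the A-site codon
    is one codon downstream of the P-site codon.  Reads whose site falls
    in a UTR are tallied per region instead of entering the codon vector.
    """
    tx_by_id = {t.transcript_id: t for t in transcripts}
    vectors = {
        t.transcript_id: CodonCountVector(
            t.transcript_id, np.zeros(t.cds_codons, dtype=np.int64)
        )
        for t in transcripts
    }
    out = PsiteAssignment(vectors=vectors, utr5_counts={}, utr3_counts={})
    shift = 1 if site == "A" else 0
    for read in reads:
        tx = tx_by_id.get(read.transcript_id)
        if tx is None:
            out.n_out_of_bounds += 1
            continue
        pos = read.start + model.offset(read.length)
        if pos < 0 or pos >= len(tx):
            out.n_out_of_bounds += 1
            continue
        if pos < tx.cds_start:
            out.utr5_counts[tx.transcript_id] = out.utr5_counts.get(tx.transcript_id, 0) + 1
            out.n_utr5 += 1
            continue
        codon_idx = (pos - tx.cds_start) // 3 + shift
        if pos >= tx.cds_end or codon_idx >= tx.cds_codons:
            out.utr3_counts[tx.transcript_id] = out.utr3_counts.get(tx.transcript_id, 0) + 1
            out.n_utr3 += 1
            continue
        vectors[tx.transcript_id].counts[codon_idx] += 1
        out.n_assigned_cds += 1
    return out


def psite_nt_profile(
    reads: Iterable[FootprintRead],
    model: PsiteOffsetModel,
    transcripts: Sequence[Transcript],
) -> dict[str, np.ndarray]:
    """Per-nucleotide P-site counts along each transcript.

    Used by uORF calling, which needs sub-codon frame resolution in
    5'UTRs rather than CDS codon indices.
    """
    lengths = {t.transcript_id: len(t) for t in transcripts}
    profiles = {
        t.transcript_id: np.zeros(len(t), dtype=np.int64) for t in transcripts
    }
    for read in reads:
        n = lengths.get(read.transcript_id)
        if n is None:
            continue
        pos = read.start + model.offset(read.length)
        if 0 <= pos < n:
            profiles[read.transcript_id][pos] += 1
    return profiles


@dataclass
class FrameReport:
    """Frame composition and metagene QC summary."""

    frame_fractions: np.ndarray  # shape (3,), sums to 1
    frame_fractions_by_length: pd.DataFrame  # index length, columns 0/1/2
    metagene_start: np.ndarray  # mean count per nt, window around CDS start
    metagene_stop: np.ndarray
    window: int


def frame_stats(
    reads: Iterable[FootprintRead],
    model: PsiteOffsetModel,
    transcripts: Sequence[Transcript],
    window: int = 30,
) -> FrameReport:
    """Fraction of P-sites in CDS frames 0/1/2 plus start/stop metagene profiles."""
    tx_by_id = {t.transcript_id: t for t in transcripts}
    frame_counts: dict[int, np.ndarray] = {}
    meta_start = np.zeros(2 * window + 1)
    meta_stop = np.zeros(2 * window + 1)
    n_tx = max(len(transcripts), 1)
    for read in reads:
        tx = tx_by_id.get(read.transcript_id)
        if tx is None:
            continue
        pos = read.start + model.offset(read.length)
        if not (0 <= pos < len(tx)):
            continue
        rel_start = pos - tx.cds_start
        if -window <= rel_start <= window:
            meta_start[rel_start + window] += 1
        rel_stop = pos - (tx.cds_end - 3)
        if -window <= rel_stop <= window:
            meta_stop[rel_stop + window] += 1
        if tx.cds_start <= pos < tx.cds_end:
            row = frame_counts.setdefault(read.length, np.zeros(3, dtype=np.int64))
            row[rel_start % 3] += 1
    if frame_counts:
        total = np.sum(list(frame_counts.values()), axis=0).astype(float)
        fractions = total / total.sum() if total.sum() else np.full(3, np.nan)
        by_len = pd.DataFrame(
            {ln: row / row.sum() for ln, row in sorted(frame_counts.items()) if row.sum()}
        ).T
        by_len.columns = [0, 1, 2]
    else:
        fractions = np.full(3, np.nan)
        by_len = pd.DataFrame(columns=[0, 1, 2])
    return FrameReport(
        frame_fractions=fractions,
        frame_fractions_by_length=by_len,
        metagene_start=meta_start / n_tx,
        metagene_stop=meta_stop / n_tx,
        window=window,
    )


def write_bed6(reads: Iterable[FootprintRead], path: str | Path) -> int:
    """Write reads as BED6 (chrom = transcript id, score = multiplicity)."""
    n = 0
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(
                f"{read.transcript_id}\t{read.start}\t{read.start + read.length}"
                f"\tread{i}\t{read.n_hits}\t+\n"
            )
            n += 1
    return n
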