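"""Transcript models, representative-isoform selection, and codon-level views.

All coordinates are 0-based, half-open, in transcript space.  The CDS of a
transcript is ``sequence[cds_start:cds_end]``; the 5'UTR is everything before
``cds_start`` and the 3'UTR everything from ``cds_end`` on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons of the standard genetic code.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)

#: Codon -> one-letter amino acid for the 61 sense codons.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

#: The 61 sense codons in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: Amino acid -> number of synonymous codons (family size n_i).
FAMILY_SIZES: dict[str, int] = {
    aa: sum(1 for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in set(CODON_TO_AA.values())
}

#: Sense codons with A or T (U) at the wobble (third) position.
AU3_CODONS: frozenset[str] = frozenset(c for c in SENSE_CODONS if c[2] in "AT")

#: Sense codons with G or C at the wobble position.
GC3_CODONS: frozenset[str] = frozenset(c for c in SENSE_CODONS if c[2] in "GC")

UORF_START_CODONS: tuple[str, ...] = ("ATG", "CTG", "TTG", "GTG")


def codon_group(codon: str) -> str:
    """Classify a codon as ``"AU3"`` or ``"GC3"`` by its third base."""
    return "AU3" if codon[2] in "AT" else "GC3"


@dataclass(frozen=True)
class Transcript:
    """A protein-coding transcript with CDS coordinates.

    Parameters
    ----------
    transcript_id, gene_id : str
        Identifiers; one representative transcript is kept per gene.
    sequence : str
        Nucleotide sequence over {A, C, G, T}; RNA input is normalized
        with U -> T.
    cds_start, cds_end : int
        0-based half-open CDS bounds on the transcript.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not (0 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(
                f"{self.transcript_id}: CDS bounds [{self.cds_start}, "
                f"{self.cds_end}) invalid for length {len(seq)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length not divisible by 3"
            )

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    @property
    def cds_codons(self) -> int:
        """Number of codons in the CDS, stop included."""
        return (self.cds_end - self.cds_start) // 3

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CodonProfile:
    """Sense-codon counts of one CDS (or a pool of CDSs).

    ``counts`` maps each of the 61 sense codons to a non-negative integer;
    stop codons are excluded.  ``internal_stop`` marks profiles whose CDS
    contained an in-frame stop before the final codon: counting halts at
    the first in-frame stop.
    """

    counts: dict[str, int]
    family_sizes: dict[str, int] = field(default_factory=lambda: dict(FAMILY_SIZES))
    internal_stop: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def load_transcriptome(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[Transcript]:
    """Load transcripts from a FASTA file and a CDS annotation table.

    The annotation is a TSV with columns ``transcript_id``, ``gene_id``,
    ``cds_start``, ``cds_end`` (0-based half-open).  Records whose CDS
    length is not divisible by 3 or whose bounds are out of range are
    skipped with a warning; an annotated transcript missing from the
    FASTA is a hard error.
    """
    seqs = {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    annot = pd.read_csv(annotation_path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    required = {"transcript_id", "gene_id", "cds_start", "cds_end"}
    if not required.issubset(annot.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")

    transcripts: list[Transcript] = []
    n_skipped = 0
    for row in annot.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise KeyError(f"no sequence for annotated transcript {row.transcript_id}")
        try:
            tx = Transcript(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                sequence=seqs[row.transcript_id],
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        except ValueError as exc:
            n_skipped += 1
            logger.warning("skipping %s: %s", row.transcript_id, exc)
            continue
        transcripts.append(tx)
    if n_skipped:
        logger.warning("skipped %d/%d annotated transcripts", n_skipped, len(annot))
    return transcripts


def select_representative(transcripts: Iterable[Transcript]) -> list[Transcript]:
    """Keep one transcript per gene: the isoform with the longest CDS.

    Ties on CDS length go to the longer transcript, then to the
    lexicographically smallest transcript id, so the choice is
    deterministic.
    """
    best: dict[str, Transcript] = {}
    for tx in transcripts:
        cur = best.get(tx.gene_id)
        if cur is None:
            best[tx.gene_id] = tx
            continue
        key_new = (tx.cds_end - tx.cds_start, len(tx), _neg_id(tx.transcript_id))
        key_cur = (cur.cds_end - cur.cds_start, len(cur), _neg_id(cur.transcript_id))
        if key_new > key_cur:
            best[tx.gene_id] = tx
    return sorted(best.values(), key=lambda t: t.transcript_id)


class _neg_id(str):
    """String wrapper with reversed ordering (smallest id wins a max)."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def codon_profile(transcript: Transcript) -> CodonProfile:
    """Count sense codons in the CDS reading frame.

    The terminal stop codon is excluded.  If an in-frame stop occurs
    before the end of the CDS, counting stops there and the profile is
    flagged ``internal_stop``.
    """
    cds = transcript.cds
    counts = {c: 0 for c in SENSE_CODONS}
    internal_stop = False
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            internal_stop = i < n_codons - 1
            break
        if codon in counts:
            counts[codon] += 1
    return CodonProfile(counts=counts, internal_stop=internal_stop)
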