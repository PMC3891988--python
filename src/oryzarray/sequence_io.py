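"""Sequence input/output and the transcript/genome record model.

Probe design operates on mRNA transcript sequences (5'->3' sense); the
specificity screen operates on whole-genome contig sets from the two
cultivated rice subspecies (japonica and indica).  All coordinates in this
package are 1-based inclusive on the mRNA sense strand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class Subspecies(str, enum.Enum):
    JAPONICA = "japonica"
    INDICA = "indica"
    OTHER = "other"


@dataclass(frozen=True)
class TranscriptRecord:
    """One gene's mRNA sequence, the substrate of probe design.

    ``sequence`` is uppercase DNA over {A,C,G,T,N}, 5'->3' mRNA sense.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    subspecies: Subspecies = Subspecies.JAPONICA

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"{self.transcript_id}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeRecord:
    """A genome as an ordered list of (contig_id, sequence) pairs."""

    genome_id: str
    contigs: tuple[tuple[str, str], ...]
    subspecies: Subspecies = Subspecies.OTHER

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.genome_id}: duplicate contig ids")
        if sum(len(s) for _, s in self.contigs) < 1:
            raise ValueError(f"{self.genome_id}: total length must be >= 1")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


def _clean(seq: str, rec_id: str) -> str:
    """Uppercase, map RNA U->T, and validate the alphabet."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"record {rec_id!r}: invalid characters {sorted(bad)!r}")
    return s


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file into (id, sequence) pairs.

    Sequences are uppercased and U is mapped to T.  Raises on an empty file,
    on a duplicate record id, and on any character outside {A,C,G,T,N}.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, _clean(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_transcripts(
    path: str | Path, subspecies: Subspecies = Subspecies.JAPONICA
) -> list[TranscriptRecord]:
    """Read transcripts from FASTA; the record id doubles as the gene id."""
    return [
        TranscriptRecord(
            transcript_id=rid, gene_id=rid, sequence=seq, subspecies=subspecies
        )
        for rid, seq in read_fasta(path)
    ]


def read_genome(
    path: str | Path,
    genome_id: str | None = None,
    subspecies: Subspecies = Subspecies.OTHER,
) -> GenomeRecord:
    path = Path(path)
    contigs = tuple(read_fasta(path))
    return GenomeRecord(
        genome_id=genome_id or path.stem, contigs=contigs, subspecies=subspecies
    )


def three_prime_window(t: TranscriptRecord, window: int) -> tuple[int, int]:
    """1-based inclusive coordinates of the 3'-terminal design window.

    Labeled aRNA is 3'-biased, so probes are restricted to the last
    ``window`` nucleotides of the transcript.  A transcript shorter than one
    probe length cannot host any probe.
    """
    if window < 60:
        raise ValueError("window must be >= 60 nt")
    n = len(t)
    if n < 60:
        raise ValueError(f"{t.transcript_id}: too short for any probe ({n} nt)")
    return (max(1, n - window + 1), n)
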