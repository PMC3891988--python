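"""Cross-subspecies probe specificity: genome search and group assignment.

Each 60-mer probe is searched against the japonica-like and indica-like
genomes with an internal seed-and-extend matcher (exact seed words followed
by ungapped end-to-end comparison of the 60-nt window).  The per-genome hit
count collapses to a status (none / unique / multiple) and the status pair
maps to one of seven cross-hybridization groups:

    A (unique, unique)    B (unique, none)      C (none, unique)
    D (unique, multiple)  E (multiple, unique)  F (multiple, none)
    G (multiple, multiple)

Probes hitting neither genome, or only multiply in the second genome, have
no group and are reported UNASSIGNED.  The japonica-represented set is
{A,B,D,E,F,G}; the indica-represented set is {A,C,D,E,G}.

Seeding is a heuristic: a window passing the identity threshold need not
contain any exact seed word, so rare hits can be missed at long seed
lengths.  ``seed_len=1`` degenerates to an exact all-offsets scan.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from .probe_design import reverse_complement
from .sequence_io import GenomeRecord

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class HitStatus(str, enum.Enum):
    NONE = "none"
    UNIQUE = "unique"
    MULTIPLE = "multiple"


class Group(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    G = "G"
    UNASSIGNED = "UNASSIGNED"


#: status pair (first genome, second genome) -> group
_GROUP_TABLE: dict[tuple[HitStatus, HitStatus], Group] = {
    (HitStatus.UNIQUE, HitStatus.UNIQUE): Group.A,
    (HitStatus.UNIQUE, HitStatus.NONE): Group.B,
    (HitStatus.NONE, HitStatus.UNIQUE): Group.C,
    (HitStatus.UNIQUE, HitStatus.MULTIPLE): Group.D,
    (HitStatus.MULTIPLE, HitStatus.UNIQUE): Group.E,
    (HitStatus.MULTIPLE, HitStatus.NONE): Group.F,
    (HitStatus.MULTIPLE, HitStatus.MULTIPLE): Group.G,
    (HitStatus.NONE, HitStatus.NONE): Group.UNASSIGNED,
    (HitStatus.NONE, HitStatus.MULTIPLE): Group.UNASSIGNED,
}

#: groups counted as represented on each genome
JAPONICA_GROUPS = frozenset({Group.A, Group.B, Group.D, Group.E, Group.F, Group.G})
INDICA_GROUPS = frozenset({Group.A, Group.C, Group.D, Group.E, Group.G})


@dataclass(frozen=True)
class MatchParams:
    """Matcher thresholds.

    ``min_matches`` of 47/60 (~78% identity) is a conventional
    cross-hybridization cutoff; ``seed_len=1`` gives the exact exhaustive
    scan.
    """

    seed_len: int = 16
    min_matches: int = 47
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        if not (0 < self.min_matches <= 60):
            raise ValueError("min_matches must be in (0, 60]")


@dataclass(frozen=True)
class GenomeHit:
    contig_id: str
    position: int  # 1-based start of the aligned 60-nt window, forward coords
    strand: str  # '+' or '-'
    matches: int


@dataclass(frozen=True)
class ProbeClassification:
    probe_id: str
    status_japonica: HitStatus
    status_indica: HitStatus
    group: Group


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class GenomeIndex:
    """Per-genome seed-word index reused across probes."""

    def __init__(self, genome: GenomeRecord, seed_len: int):
        self.genome = genome
        self.seed_len = seed_len
        self.arrays = {cid: _encode(s) for cid, s in genome.contigs}
        self.kmer_positions: dict[str, dict[str, list[int]]] = {}
        if seed_len > 1:
            for cid, seq in genome.contigs:
                d: dict[str, list[int]] = defaultdict(list)
                for i in range(len(seq) - seed_len + 1):
                    d[seq[i : i + seed_len]].append(i)
                self.kmer_positions[cid] = d

    def candidate_starts(self, contig_id: str, probe: str) -> np.ndarray:
        """0-based candidate window starts sharing >=1 exact seed word."""
        arr = self.arrays[contig_id]
        n = len(arr)
        plen = len(probe)
        if n < plen:
            return np.empty(0, dtype=np.int64)
        if self.seed_len == 1:
            return np.arange(0, n - plen + 1, dtype=np.int64)
        index = self.kmer_positions[contig_id]
        starts: set[int] = set()
        for q in range(plen - self.seed_len + 1):
            word = probe[q : q + self.seed_len]
            for g in index.get(word, ()):
                s = g - q
                if 0 <= s <= n - plen:
                    starts.add(s)
        return np.fromiter(sorted(starts), dtype=np.int64, count=len(starts))


def _window_matches(arr: np.ndarray, starts: np.ndarray, probe_arr: np.ndarray) -> np.ndarray:
    """Identical-base counts of ungapped windows at the given starts."""
    if starts.size == 0:
        return np.empty(0, dtype=np.int64)
    plen = probe_arr.size
    windows = arr[starts[:, None] + np.arange(plen)[None, :]]
    return (windows == probe_arr[None, :]).sum(axis=1).astype(np.int64)


def _merge_nearby(hits: list[GenomeHit], span: int = 59) -> list[GenomeHit]:
    """Merge accepted windows within ``span`` nt on the same contig+strand.

    Overlapping windows describe one genomic locus; the best-matching
    position represents the cluster (leftmost on ties).
    """
    out: list[GenomeHit] = []
    bykey: dict[tuple[str, str], list[GenomeHit]] = defaultdict(list)
    for h in hits:
        bykey[(h.contig_id, h.strand)].append(h)
    for key in sorted(bykey):
        group = sorted(bykey[key], key=lambda h: h.position)
        cluster: list[GenomeHit] = []
        for h in group:
            if cluster and h.position - cluster[-1].position <= span:
                cluster.append(h)
            else:
                if cluster:
                    out.append(max(cluster, key=lambda c: (c.matches, -c.position)))
                cluster = [h]
        if cluster:
            out.append(max(cluster, key=lambda c: (c.matches, -c.position)))
    return sorted(out, key=lambda h: (h.contig_id, h.strand, h.position))


def find_hits(
    probe: str,
    genome: GenomeRecord | GenomeIndex,
    p: MatchParams = MatchParams(),
) -> list[GenomeHit]:
    """All genome loci matching the probe at >= ``p.min_matches`` of 60.

    Every window sharing an exact seed word with the probe (on either
    strand when ``both_strands``) is scored by ungapped end-to-end
    comparison; accepted windows are deduplicated and nearby windows merged
    into single loci.  Pass a prebuilt :class:`GenomeIndex` to amortize
    indexing across many probes.
    """
    if "N" in probe:
        raise ValueError("probe contains N")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, p.seed_len)
    if index.seed_len != p.seed_len:
        raise ValueError("GenomeIndex seed_len differs from MatchParams.seed_len")

    queries = [(probe, "+")]
    if p.both_strands:
        queries.append((reverse_complement(probe), "-"))

    hits: list[GenomeHit] = []
    seen: set[tuple[str, int, str]] = set()
    for query, strand in queries:
        q_arr = _encode(query)
        for cid, _ in index.genome.contigs:
            arr = index.arrays[cid]
            starts = index.candidate_starts(cid, query)
            matches = _window_matches(arr, starts, q_arr)
            for s, m in zip(starts.tolist(), matches.tolist()):
                if m >= p.min_matches:
                    key = (cid, s + 1, strand)
                    if key not in seen:
                        seen.add(key)
                        hits.append(GenomeHit(cid, s + 1, strand, m))
    return _merge_nearby(hits)


def hit_status(hits: list[GenomeHit]) -> HitStatus:
    """Collapse a hit list to none / unique / multiple."""
    n = len(hits)
    if n == 0:
        return HitStatus.NONE
    if n == 1:
        return HitStatus.UNIQUE
    return HitStatus.MULTIPLE


def classify(status_j: HitStatus, status_i: HitStatus) -> Group:
    """Map a (japonica, indica) hit-status pair to its group A-G.

    Total over all nine status pairs; pairs with no japonica hit and zero or
    multiple indica hits have no defined group and map to UNASSIGNED.
    """
    return _GROUP_TABLE[(status_j, status_i)]


def classify_probes(
    probes: dict[str, str] | list[tuple[str, str]],
    genome_japonica: GenomeRecord,
    genome_indica: GenomeRecord,
    p: MatchParams = MatchParams(),
) -> pd.DataFrame:
    """Classify many probes against both genomes; one row per probe."""
    items = list(probes.items()) if isinstance(probes, dict) else list(probes)
    idx_j = GenomeIndex(genome_japonica, p.seed_len)
    idx_i = GenomeIndex(genome_indica, p.seed_len)
    rows = []
    for pid, seq in items:
        hits_j = find_hits(seq, idx_j, p)
        hits_i = find_hits(seq, idx_i, p)
        sj, si = hit_status(hits_j), hit_status(hits_i)
        rows.append(
            {
                "probe_id": pid,
                "hits_japonica": len(hits_j),
                "hits_indica": len(hits_i),
                "status_japonica": sj.value,
                "status_indica": si.value,
                "group": classify(sj, si).value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "hits_japonica",
            "hits_indica",
            "status_japonica",
            "status_indica",
            "group",
        ],
    )


def coverage_summary(classifications: pd.DataFrame | list[ProbeClassification]) -> dict:
    """Probe counts per group and per genome-represented set."""
    if isinstance(classifications, pd.DataFrame):
        groups = [Group(g) for g in classifications["group"]]
    else:
        groups = [c.group for c in classifications]
    per_group = {g.value: 0 for g in Group}
    for g in groups:
        per_group[g.value] += 1
    return {
        "per_group": per_group,
        "japonica_represented": sum(1 for g in groups if g in JAPONICA_GROUPS),
        "indica_represented": sum(1 for g in groups if g in INDICA_GROUPS),
        "total": len(groups),
    }
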