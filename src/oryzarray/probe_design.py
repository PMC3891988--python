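"""60-mer probe candidate enumeration and intrinsic filtering.

Candidates are enumerated inside the transcript's 3' design window and
scored on composition: GC fraction (40-60% inclusive by default), longest
simple-repeat run (mono- or dinucleotide tandem runs of 6 nt or more fail),
and a self-complementarity stem-length proxy for hairpin-prone sequences.
One probe per gene is then selected deterministically, favouring the most
3'-proximal passing candidate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .sequence_io import TranscriptRecord, three_prime_window

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Verdict(str, enum.Enum):
    PASS = "pass"
    FAIL_N = "fail_N"
    FAIL_WINDOW = "fail_window"
    FAIL_GC = "fail_gc"
    FAIL_REPEAT = "fail_repeat"
    FAIL_SELFCOMP = "fail_selfcomp"


@dataclass(frozen=True)
class DesignParams:
    """Tunable probe-design thresholds.

    ``max_repeat`` is the longest tolerated simple-repeat run in nt: runs of
    ``max_repeat + 1`` or more fail.  ``selfcomp_max`` is the longest
    tolerated self-complementary stem.  ``step`` strides the candidate
    enumeration (1 = exhaustive).
    """

    probe_len: int = 60
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_repeat: int = 5
    window: int = 1200
    selfcomp_max: int = 15
    step: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.probe_len < 1:
            raise ValueError("probe_len must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class ProbeCandidate:
    probe_id: str
    gene_id: str
    start: int  # 1-based inclusive on the transcript
    end: int
    sequence: str
    gc_fraction: float
    max_repeat_run: int
    dist_3prime: int  # nt from probe 3' end to transcript 3' end
    self_comp_score: int
    verdict: Verdict

    @property
    def passed(self) -> bool:
        return self.verdict is Verdict.PASS


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases; rejects N so the fraction is well defined."""
    if not seq:
        raise ValueError("empty sequence")
    if "N" in seq:
        raise ValueError("sequence contains N")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_repeat_run(seq: str) -> int:
    """Longest simple-repeat run in nt.

    Considers homopolymer runs (period 1) and tandem dinucleotide repeats
    (period 2 with two distinct letters); returns the longer, measured in
    nucleotides.  "ATATATATAT" scores 10; "AAAAAA" scores 6.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    best = 1
    # homopolymer runs
    run = 1
    for i in range(1, n):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    # period-2 runs with non-identical letters; a run covering positions
    # [i-run+1, i] satisfies seq[j] == seq[j-2] throughout
    if n >= 2 and seq[0] != seq[1]:
        best = max(best, 2)
    run = 2 if n >= 2 else 1
    for i in range(2, n):
        run = run + 1 if seq[i] == seq[i - 2] else 2
        if seq[i] != seq[i - 1]:
            best = max(best, run)
    return best


def self_complementarity(seq: str) -> int:
    """Length of the longest segment whose reverse complement also occurs.

    This is the longest common substring of the sequence and its reverse
    complement — a proxy for the longest perfect hairpin stem the probe can
    form with itself.  Computed exactly by dynamic programming.
    """
    if not seq:
        raise ValueError("empty sequence")
    rc = reverse_complement(seq)
    n = len(seq)
    best = 0
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        ci = seq[i - 1]
        for j in range(1, n + 1):
            if ci == rc[j - 1]:
                v = prev[j - 1] + 1
                cur[j] = v
                if v > best:
                    best = v
        prev = cur
    return best


def score_candidate(
    t: TranscriptRecord, start: int, p: DesignParams = DesignParams()
) -> ProbeCandidate:
    """Score one candidate window and assign its verdict.

    The verdict reports the first failing filter in the fixed order
    fail_N, fail_window, fail_gc, fail_repeat, fail_selfcomp; the pass/fail
    outcome is nevertheless order-independent because a candidate passes iff
    it passes every individual filter.
    """
    L = len(t)
    end = start + p.probe_len - 1
    if start < 1 or end > L:
        raise ValueError(f"window [{start},{end}] outside transcript of {L} nt")
    seq = t.sequence[start - 1 : end]
    dist3p = L - end
    win_start, _ = three_prime_window(t, p.window)

    if "N" in seq:
        return ProbeCandidate(
            probe_id=f"{t.gene_id}_p{start}",
            gene_id=t.gene_id,
            start=start,
            end=end,
            sequence=seq,
            gc_fraction=float("nan"),
            max_repeat_run=max_repeat_run(seq),
            dist_3prime=dist3p,
            self_comp_score=0,
            verdict=Verdict.FAIL_N,
        )

    gc = gc_fraction(seq)
    rep = max_repeat_run(seq)
    sc = self_complementarity(seq)
    if end < win_start:
        # probe's 3' end falls upstream of the design window
        verdict = Verdict.FAIL_WINDOW
    elif not (p.gc_min <= gc <= p.gc_max):
        verdict = Verdict.FAIL_GC
    elif rep > p.max_repeat:
        verdict = Verdict.FAIL_REPEAT
    elif sc > p.selfcomp_max:
        verdict = Verdict.FAIL_SELFCOMP
    else:
        verdict = Verdict.PASS
    return ProbeCandidate(
        probe_id=f"{t.gene_id}_p{start}",
        gene_id=t.gene_id,
        start=start,
        end=end,
        sequence=seq,
        gc_fraction=gc,
        max_repeat_run=rep,
        dist_3prime=dist3p,
        self_comp_score=sc,
        verdict=verdict,
    )


def enumerate_candidates(
    t: TranscriptRecord, p: DesignParams = DesignParams()
) -> list[ProbeCandidate]:
    """All candidate windows whose 3' end lies inside the design window.

    Returns one scored candidate per start position at stride ``p.step``;
    an empty list if the transcript is shorter than one probe.
    """
    L = len(t)
    if L < p.probe_len:
        return []
    # window constraint binds the probe's LAST base: end >= L - window + 1
    first = max(1, L - p.window + 2 - p.probe_len)
    last = L - p.probe_len + 1
    return [score_candidate(t, s, p) for s in range(first, last + 1, p.step)]


def select_probe(cands: list[ProbeCandidate]) -> ProbeCandidate | None:
    """Pick one probe among passing candidates of a single gene.

    Deterministic: smallest distance to the 3' end wins; ties broken by GC
    closest to 0.50, then by smallest start coordinate.
    """
    passing = [c for c in cands if c.passed]
    if not passing:
        return None
    return min(
        passing, key=lambda c: (c.dist_3prime, abs(c.gc_fraction - 0.5), c.start)
    )


def design_probes(
    transcripts: list[TranscriptRecord], p: DesignParams = DesignParams()
) -> pd.DataFrame:
    """Design one probe per gene; returns the full candidate table.

    The returned frame has one row per candidate plus a ``selected`` column
    marking the chosen probe of each gene.  Genes without any candidate
    (transcript shorter than one probe) are absent from the table.
    """
    rows = []
    for t in transcripts:
        cands = enumerate_candidates(t, p)
        chosen = select_probe(cands)
        for c in cands:
            rows.append(
                {
                    "probe_id": c.probe_id,
                    "gene_id": c.gene_id,
                    "start": c.start,
                    "end": c.end,
                    "sequence": c.sequence,
                    "gc": c.gc_fraction,
                    "max_run": c.max_repeat_run,
                    "selfcomp": c.self_comp_score,
                    "dist3p": c.dist_3prime,
                    "verdict": c.verdict.value,
                    "selected": chosen is not None and c.probe_id == chosen.probe_id,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "gene_id",
            "start",
            "end",
            "sequence",
            "gc",
            "max_run",
            "selfcomp",
            "dist3p",
            "verdict",
            "selected",
        ],
    )
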