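"""Synthetic genomes, transcripts, and replicate array data with known truth.

The generator emulates the study design the toolkit targets: two divergent
rice-like subspecies genomes sharing a common ancestor (with per-genome
gene duplications and deletions to create every cross-hybridization group),
and a one-channel two-tissue experiment with several technical replicate
arrays per tissue, planted log2 effects, and log-scale replicate noise.

Everything is driven by a single integer seed through one numpy Generator;
the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .array_analysis import ArraySample, SpotMeasurement
from .sequence_io import GenomeRecord, Subspecies, TranscriptRecord, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulation.

    Defaults mirror the validation setting: five technical replicate arrays
    per tissue, planted 2.0 log2-unit effects on 10% of probes, 0.3 log2
    units of replicate noise, and mildly divergent (2% per base) subspecies
    genomes with 10% duplicated and 10% singly-deleted genes.
    """

    seed: int = 0
    n_genes: int = 200
    gene_len: int = 600
    spacer_len: int = 200
    divergence: float = 0.02
    dup_fraction: float = 0.1
    absent_fraction: float = 0.1
    n_arrays_per_tissue: int = 5
    de_fraction: float = 0.1
    effect_log2: float = 2.0
    noise_sd: float = 0.3
    absent_genome: str = "either"  # which genome loses deleted genes
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    background_mean: float = 100.0
    background_sd: float = 10.0
    floor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("divergence", "dup_fraction", "absent_fraction", "de_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 1 or self.n_arrays_per_tissue < 1:
            raise ValueError("counts must be >= 1")
        if self.absent_genome not in ("japonica", "indica", "either"):
            raise ValueError("absent_genome must be japonica, indica or either")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with the given probability."""
    out = seq.copy()
    mask = rng.random(seq.size) < divergence
    idx = np.flatnonzero(mask)
    if idx.size:
        codes = np.searchsorted(_BASES, out[idx])  # ACGT are sorted bytes
        new_codes = (codes + rng.integers(1, 4, size=idx.size)) % 4
        out[idx] = _BASES[new_codes]
    return out


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def simulate_genomes(
    c: SimConfig,
) -> tuple[GenomeRecord, GenomeRecord, list[TranscriptRecord], pd.DataFrame]:
    """Two subspecies genomes, the transcript set, and the hit-status truth.

    Ancestor genes are mutated independently into a japonica-like and an
    indica-like version (divergence per base).  Per gene each genome then
    independently duplicates it (``dup_fraction``, verbatim second copy),
    and with probability ``absent_fraction`` the gene is deleted from one
    genome (chosen 50/50, or always the ``absent_genome`` side when
    configured).  Transcripts carry the japonica-version sequence
    whether or not the gene survives in the japonica genome, mirroring
    probes designed from a curated transcript set.

    The truth table records, per gene, the planted copy number and the hit
    status / group expected of a perfectly specific matcher.
    """
    from .specificity import HitStatus, classify  # local import to avoid cycle

    rng = np.random.default_rng(c.seed)
    gene_ids = [f"SYNG{i:05d}" for i in range(c.n_genes)]
    ancestors = [_random_seq(rng, c.gene_len) for _ in gene_ids]
    ver_j = [_mutate(s, c.divergence, rng) for s in ancestors]
    ver_i = [_mutate(s, c.divergence, rng) for s in ancestors]

    copies_j = np.ones(c.n_genes, dtype=int)
    copies_i = np.ones(c.n_genes, dtype=int)
    copies_j[rng.random(c.n_genes) < c.dup_fraction] = 2
    copies_i[rng.random(c.n_genes) < c.dup_fraction] = 2
    deleted = rng.random(c.n_genes) < c.absent_fraction
    side = rng.random(c.n_genes) < 0.5  # drawn regardless, for determinism
    if c.absent_genome == "japonica":
        delete_from_j = np.ones(c.n_genes, dtype=bool)
    elif c.absent_genome == "indica":
        delete_from_j = np.zeros(c.n_genes, dtype=bool)
    else:
        delete_from_j = side
    copies_j[deleted & delete_from_j] = 0
    copies_i[deleted & ~delete_from_j] = 0

    def build_contig(versions: list[np.ndarray], copies: np.ndarray) -> str:
        parts = []
        for seq, k in zip(versions, copies):
            for _ in range(int(k)):
                parts.append(_random_seq(rng, c.spacer_len))
                parts.append(seq)
        parts.append(_random_seq(rng, c.spacer_len))
        return _to_str(np.concatenate(parts)) if parts else ""

    genome_j = GenomeRecord(
        genome_id="synthetic_japonica",
        contigs=(("chrJ", build_contig(ver_j, copies_j)),),
        subspecies=Subspecies.JAPONICA,
    )
    genome_i = GenomeRecord(
        genome_id="synthetic_indica",
        contigs=(("chrI", build_contig(ver_i, copies_i)),),
        subspecies=Subspecies.INDICA,
    )
    transcripts = [
        TranscriptRecord(
            transcript_id=g, gene_id=g, sequence=_to_str(s),
            subspecies=Subspecies.JAPONICA,
        )
        for g, s in zip(gene_ids, ver_j)
    ]

    def status(k: int) -> HitStatus:
        return (HitStatus.NONE, HitStatus.UNIQUE, HitStatus.MULTIPLE)[min(k, 2)]

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "copies_japonica": copies_j,
            "copies_indica": copies_i,
            "status_japonica": [status(k).value for k in copies_j],
            "status_indica": [status(k).value for k in copies_i],
            "group": [
                classify(status(kj), status(ki)).value
                for kj, ki in zip(copies_j, copies_i)
            ],
        }
    )
    return genome_j, genome_i, transcripts, truth


def simulate_arrays(
    c: SimConfig, probe_ids: list[str]
) -> tuple[list[ArraySample], pd.DataFrame]:
    """Replicate intensity data for two tissues with planted DE truth.

    Per probe the baseline log2 intensity is Normal(baseline_mean,
    baseline_sd); a ``de_fraction`` subset is shifted by +-``effect_log2``
    in tissue A (half up, half down).  Replicates add Normal(0, noise_sd)
    on the log2 scale; the foreground is the exponentiated signal plus an
    additive background drawn Normal(background_mean, background_sd)
    truncated at 0.  All flags are good.
    """
    rng = np.random.default_rng(c.seed + 1)
    n = len(probe_ids)
    baseline = rng.normal(c.baseline_mean, c.baseline_sd, size=n)
    n_de = int(round(c.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    effect = np.zeros(n)
    half = n_de // 2
    effect[de_idx[:half]] = c.effect_log2
    effect[de_idx[half:]] = -c.effect_log2

    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_de": effect != 0,
            "effect_log2": effect,
        }
    )

    arrays: list[ArraySample] = []
    for tissue, shift in (("shoot", effect), ("root", np.zeros(n))):
        for rep in range(c.n_arrays_per_tissue):
            log2_signal = baseline + shift + rng.normal(0, c.noise_sd, size=n)
            signal = np.exp2(log2_signal)
            bg = np.clip(
                rng.normal(c.background_mean, c.background_sd, size=n), 0, None
            )
            spots = tuple(
                SpotMeasurement(
                    probe_id=pid,
                    foreground=float(sig + b),
                    background=float(b),
                    flag="good",
                )
                for pid, sig, b in zip(probe_ids, signal, bg)
            )
            arrays.append(
                ArraySample(array_id=f"{tissue}_{rep + 1}", tissue=tissue, spots=spots)
            )
    return arrays, truth


def write_simulation(c: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize a full simulated study on disk (FASTA + TSV files)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_j, genome_i, transcripts, truth_genomes = simulate_genomes(c)

    paths = {
        "genome_japonica": outdir / "genome_japonica.fasta",
        "genome_indica": outdir / "genome_indica.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "truth_genomes": outdir / "truth_genomes.tsv",
        "truth_de": outdir / "truth_de.tsv",
        "sample_sheet": outdir / "samples.tsv",
    }
    write_fasta(genome_j.contigs, paths["genome_japonica"])
    write_fasta(genome_i.contigs, paths["genome_indica"])
    write_fasta([(t.transcript_id, t.sequence) for t in transcripts], paths["transcripts"])
    truth_genomes.to_csv(paths["truth_genomes"], sep="\t", index=False)

    probe_ids = [t.gene_id for t in transcripts]
    arrays, truth_de = simulate_arrays(c, probe_ids)
    truth_de.to_csv(paths["truth_de"], sep="\t", index=False)

    sheet_rows = []
    for a in arrays:
        p = outdir / f"array_{a.array_id}.tsv"
        df = pd.DataFrame(
            {
                "probe_id": [s.probe_id for s in a.spots],
                "F_median": [s.foreground for s in a.spots],
                "B_median": [s.background for s in a.spots],
                "flag": [s.flag for s in a.spots],
            }
        )
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        # path relative to the sheet so a run directory is relocatable
        sheet_rows.append({"array_id": a.array_id, "tissue": a.tissue, "path": p.name})
        paths[f"array_{a.array_id}"] = p
    pd.DataFrame(sheet_rows).to_csv(paths["sample_sheet"], sep="\t", index=False)
    return paths
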