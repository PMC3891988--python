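"""Term-enrichment reporting over gene clusters.

Given a gene cluster (e.g. the up-regulated genes of a contrast) and a
gene -> term annotation map over a background universe, reports per term
the member count, the percentage of the cluster annotated with the term
(rounded half-up to two decimals, matching the conventional report format),
and a one-sided Fisher exact p-value (hypergeometric upper tail).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnnotationMap:
    """gene_id -> set of term labels over an explicit background universe."""

    annotations: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        stray = set(self.annotations) - set(self.background)
        if stray:
            raise ValueError(
                f"{len(stray)} annotated genes missing from background, "
                f"e.g. {sorted(stray)[:3]}"
            )

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]], background: set[str] | None = None
    ) -> "AnnotationMap":
        ann: dict[str, set[str]] = {}
        for gene, term in pairs:
            ann.setdefault(gene, set()).add(term)
        bg = frozenset(background) if background is not None else frozenset(ann)
        return cls({g: frozenset(t) for g, t in ann.items()}, bg)

    def genes_with(self, term: str) -> frozenset[str]:
        return frozenset(g for g, ts in self.annotations.items() if term in ts)

    @property
    def terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return frozenset(out)


def read_annotation_tsv(path: str | Path, background: set[str] | None = None) -> AnnotationMap:
    """Two-column TSV (gene_id, term), '#' comments allowed."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns")
    return AnnotationMap.from_pairs(
        list(zip(df.iloc[:, 0], df.iloc[:, 1])), background
    )


def percentage(count: int, cluster_size: int) -> float:
    """100*count/cluster_size rounded half-up to 2 decimals."""
    if cluster_size <= 0:
        raise ValueError("cluster_size must be positive")
    frac = Decimal(100 * count) / Decimal(cluster_size)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p for the 2x2 table [[a, b], [c, d]].

    P(X >= a) for X hypergeometric with the table's margins: drawing
    a+b cluster genes from a population of a+b+c+d containing a+c
    term-annotated genes.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be nonnegative")
    total = a + b + c + d
    if total == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, total, a + c, a + b))


def enrich(cluster: set[str], ann: AnnotationMap) -> pd.DataFrame:
    """Per-term enrichment rows for one cluster, sorted by p ascending.

    The 2x2 table per term is (in-cluster & annotated, in-cluster & not,
    out-of-cluster & annotated, out-of-cluster & not) over the background.
    Only terms with at least one cluster member are reported.
    """
    if not cluster:
        raise ValueError("empty cluster")
    stray = cluster - set(ann.background)
    if stray:
        raise ValueError(
            f"{len(stray)} cluster genes not in background, e.g. {sorted(stray)[:3]}"
        )
    n_cluster = len(cluster)
    n_bg = len(ann.background)
    rows = []
    for term in sorted(ann.terms):
        members = ann.genes_with(term)
        a = len(members & cluster)
        if a == 0:
            continue
        b = n_cluster - a
        c = len(members) - a
        d = n_bg - n_cluster - c
        rows.append(
            {
                "term": term,
                "count": a,
                "cluster_size": n_cluster,
                "percentage": percentage(a, n_cluster),
                "p_value": fisher_one_sided(a, b, c, d),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "count", "cluster_size", "percentage", "p_value"]
    )
    return out.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
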