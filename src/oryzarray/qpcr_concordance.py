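"""qRT-PCR relative quantification and microarray concordance.

Relative expression between two tissues is computed by the 2^-ddCt method
with an internal reference gene (Actin): per tissue dCt = mean Ct(target)
- mean Ct(reference); ddCt = dCt_A - dCt_B; the log2 fold change is -ddCt
so that fold = 2^-ddCt.  Concordance between paired microarray and qPCR
log2 ratios is the Pearson correlation with its two-sided t-based p-value.

A published validation panel of 66 rice transcription-factor genes with
both microarray and qRT-PCR log2(shoot/root) ratios is bundled as a
package fixture for a no-download end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: target and reference Ct for a gene/tissue/replicate."""

    gene_id: str
    tissue: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not (0 < ct < 45):
                raise ValueError(f"{self.gene_id}: {name}={ct} outside (0, 45)")


def delta_delta_ct(
    recs: list[CtRecord] | pd.DataFrame, tissue_a: str, tissue_b: str
) -> float:
    """log2 fold change of one gene between two tissues by 2^-ddCt.

    dCt per tissue is mean(ct_target) - mean(ct_reference) over replicates;
    ddCt = dCt_A - dCt_B; returns -ddCt, the log2 fold of A over B.
    """
    if isinstance(recs, pd.DataFrame):
        df = recs
    else:
        df = pd.DataFrame([r.__dict__ for r in recs])
    genes = df["gene_id"].unique()
    if len(genes) != 1:
        raise ValueError(f"expected records for one gene, got {len(genes)}")
    dct = {}
    for tissue in (tissue_a, tissue_b):
        sub = df[df["tissue"] == tissue]
        if sub.empty:
            raise ValueError(f"{genes[0]}: no Ct records for tissue {tissue!r}")
        dct[tissue] = float(sub["ct_target"].mean() - sub["ct_reference"].mean())
    return -(dct[tissue_a] - dct[tissue_b])


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Ct TSV with columns gene_id, tissue, replicate, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"gene_id", "tissue", "replicate", "ct_target", "ct_reference"}
    if not expected.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(expected)}")
    # route rows through CtRecord so range checks apply
    for row in df.itertuples(index=False):
        CtRecord(
            str(row.gene_id), str(row.tissue), int(row.replicate),
            float(row.ct_target), float(row.ct_reference),
        )
    return df


def qpcr_log2_table(df: pd.DataFrame, tissue_a: str, tissue_b: str) -> pd.Series:
    """Per-gene 2^-ddCt log2 fold changes from a Ct table."""
    return pd.Series(
        {
            gene: delta_delta_ct(sub, tissue_a, tissue_b)
            for gene, sub in df.groupby("gene_id", sort=True)
        },
        name="qpcr_log2",
    )


def concordance(pairs: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson concordance of paired (array_log2, qpcr_log2) ratios.

    Returns (r, two-sided p from the t transform with n-2 df, n).  Requires
    n >= 3 finite pairs and nonzero variance in both columns.
    """
    x = np.asarray(pairs["array_log2"], dtype=float)
    y = np.asarray(pairs["qpcr_log2"], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite log2 ratios in pairs")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one column")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def load_validation_pairs() -> pd.DataFrame:
    """The bundled 66-gene rice shoot/root validation panel.

    Columns: gene_id (MSU locus), description, array_log2, qpcr_log2.
    """
    ref = resources.files("oryzarray.data").joinpath("qpcr_validation_pairs.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
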