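"""One-channel microarray intensity pipeline.

Stages, in the order they run on a shoot-vs-root experiment:

1. spot filtering and detection calls (flag must be good, signal-to-noise
   ratio above a threshold),
2. background subtraction (floored at 1) and median-scaling normalization
   (every array's detected-spot median is scaled to the global reference
   median),
3. technical-replicate quality control via pairwise Pearson correlation of
   log2 intensities over commonly detected spots,
4. per-tissue replicate averaging on the log2 scale,
5. error-weighted log2 ratios with a Welch two-sample t-test per probe,
6. differential-expression calling at |log2 ratio| >= 1 and p < 0.05
   (defaults), and detection-based tissue-specific calling.

The original platform's proprietary error model is replaced here by
inverse-variance weighting over pairwise log differences — which, with the
uniform weights of equal-variance technical replicates, reduces to the
difference of tissue means — plus a Welch t-test for the per-probe p-value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

FLAGS = ("good", "bad", "not_found", "empty")


@dataclass(frozen=True)
class SpotMeasurement:
    probe_id: str
    foreground: float
    background: float
    flag: str = "good"
    snr: float | None = None  # foreground/background when not supplied

    def __post_init__(self) -> None:
        if self.foreground < 0 or self.background < 0:
            raise ValueError(f"{self.probe_id}: negative intensity")
        if self.flag not in FLAGS:
            raise ValueError(f"{self.probe_id}: unknown flag {self.flag!r}")

    @property
    def snr_value(self) -> float:
        if self.snr is not None:
            return self.snr
        if self.background == 0:
            return math.inf
        return self.foreground / self.background


@dataclass(frozen=True)
class ArraySample:
    array_id: str
    tissue: str
    spots: tuple[SpotMeasurement, ...]

    def __post_init__(self) -> None:
        ids = [s.probe_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.array_id}: duplicate probe ids")


@dataclass
class ExpressionMatrix:
    """Probes x arrays normalized intensities with a detection mask."""

    values: pd.DataFrame  # normalized, background-subtracted intensities
    detected: pd.DataFrame  # boolean, same shape
    tissues: pd.Series  # array_id -> tissue label
    floor: float = 1.0

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def arrays_for(self, tissue: str) -> list[str]:
        return [a for a in self.values.columns if self.tissues[a] == tissue]


class Specificity(str, enum.Enum):
    SHOOT_SPECIFIC = "shoot_specific"
    ROOT_SPECIFIC = "root_specific"
    SHARED = "shared"
    UNDETECTED = "undetected"


@dataclass(frozen=True)
class AnalysisParams:
    snr_min: float = 2.0
    floor: float = 1.0
    lfc_min: float = 1.0
    alpha: float = 0.05
    bh_correct: bool = False  # Benjamini-Hochberg over probe p-values


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_gpr(path: str | Path, array_id: str | None = None, tissue: str = "") -> ArraySample:
    """Read a GenePix-results-like TSV: probe_id, F_median, B_median, flag[, snr].

    Lines starting with '#' are ignored; a header row is detected by a
    non-numeric second column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    cols = list(df.columns)
    if len(cols) < 4:
        raise ValueError(f"{path}: expected >=4 columns, got {len(cols)}")
    has_snr = len(cols) >= 5
    spots = []
    for row in df.itertuples(index=False):
        spots.append(
            SpotMeasurement(
                probe_id=str(row[0]),
                foreground=float(row[1]),
                background=float(row[2]),
                flag=str(row[3]),
                snr=float(row[4]) if has_snr and not pd.isna(row[4]) else None,
            )
        )
    return ArraySample(array_id=array_id or path.stem, tissue=tissue, spots=tuple(spots))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with columns array_id, tissue, path."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = {"array_id", "tissue", "path"}
    if not expected.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(expected)}")
    return df


# ---------------------------------------------------------------------------
# detection and normalization
# ---------------------------------------------------------------------------

def detection_call(s: SpotMeasurement, snr_min: float = 2.0) -> bool:
    """A spot is detected iff its flag is good and SNR >= snr_min.

    SNR is foreground/background; zero background with a good flag counts
    as detected.
    """
    if s.flag != "good":
        return False
    return s.snr_value >= snr_min


def median_scale(
    arrays: list[ArraySample], params: AnalysisParams = AnalysisParams()
) -> ExpressionMatrix:
    """Background-subtract, floor, and median-scale a set of arrays.

    Per array the spot value is max(foreground - background, floor).  Each
    array is then multiplied by (reference median / its detected-spot
    median) where the reference is the median of per-array detected-spot
    medians, so all detected medians coincide afterwards.
    """
    if not arrays:
        raise ValueError("need at least one array")
    values: dict[str, pd.Series] = {}
    detected: dict[str, pd.Series] = {}
    tissues: dict[str, str] = {}
    for a in arrays:
        ids = [s.probe_id for s in a.spots]
        raw = pd.Series(
            [max(s.foreground - s.background, params.floor) for s in a.spots],
            index=ids,
            dtype=float,
        )
        det = pd.Series(
            [detection_call(s, params.snr_min) for s in a.spots], index=ids
        )
        if int(det.sum()) == 0:
            raise ValueError(f"array {a.array_id!r} has no detected spots")
        values[a.array_id] = raw
        detected[a.array_id] = det
        tissues[a.array_id] = a.tissue

    vals = pd.DataFrame(values)
    det = pd.DataFrame(detected).fillna(False).astype(bool)
    medians = pd.Series(
        {aid: vals.loc[det[aid], aid].median() for aid in vals.columns}
    )
    reference = float(medians.median())
    scaled = vals * (reference / medians)
    scaled = scaled.clip(lower=params.floor)
    return ExpressionMatrix(
        values=scaled,
        detected=det,
        tissues=pd.Series(tissues),
        floor=params.floor,
    )


# ---------------------------------------------------------------------------
# replicate QC and averaging
# ---------------------------------------------------------------------------

def replicate_correlation(m: ExpressionMatrix, min_common: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2 intensities, commonly detected spots.

    Symmetric with unit diagonal; entries with fewer than ``min_common``
    commonly detected spots are NaN.
    """
    cols = list(m.values.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 arrays")
    log2 = m.log2
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            common = m.detected[a] & m.detected[b]
            if int(common.sum()) < min_common:
                r = np.nan
            else:
                r = float(np.corrcoef(log2.loc[common, a], log2.loc[common, b])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def average_replicates(m: ExpressionMatrix, tissue: str) -> pd.DataFrame:
    """Per-probe mean/SE of log2 intensity over detected replicate arrays.

    Columns: mean (NaN when never detected), se (0 for a single detection),
    n_detected, n_arrays.
    """
    cols = m.arrays_for(tissue)
    if not cols:
        raise ValueError(f"no arrays labeled {tissue!r}")
    log2 = m.log2[cols]
    det = m.detected[cols]
    masked = log2.where(det)
    n = det.sum(axis=1)
    mean = masked.mean(axis=1)
    sd = masked.std(axis=1, ddof=1)
    se = sd / np.sqrt(n.where(n > 0))
    se = se.where(n > 1, other=np.where(n == 1, 0.0, np.nan))
    return pd.DataFrame(
        {"mean": mean, "se": pd.Series(se, index=mean.index), "n_detected": n,
         "n_arrays": len(cols)}
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def log2_ratio_ew(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Error-weighted log2 ratio and Welch p for one probe.

    The ratio is the inverse-variance-weighted mean of all pairwise
    differences log2(a_i) - log2(b_j); with the uniform weights appropriate
    for equal-variance technical replicates this equals mean(a) - mean(b),
    which is what is computed.  The p-value is a two-sided Welch two-sample
    t-test and requires >= 2 values per side (NaN otherwise).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sides need >= 1 detected value")
    ratio = float(a.mean() - b.mean())
    if a.size < 2 or b.size < 2:
        return ratio, float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ratio, float(p)


def differential_expression(
    m: ExpressionMatrix,
    tissue_a: str,
    tissue_b: str,
    params: AnalysisParams = AnalysisParams(),
) -> pd.DataFrame:
    """Per-probe log2(A/B) ratio, p-value and detection bookkeeping.

    Probes detected in only one tissue are compared against the intensity
    floor: the ratio uses log2(floor) for the missing side and, when the
    detected side covers at least half of its arrays, the p-value is a
    two-sided one-sample t-test of the detected log2 values against the
    floor.  Such calls carry ``one_sided_detection=True``.  Probes detected
    in neither tissue get NaN ratio and p.
    """
    summary_a = average_replicates(m, tissue_a)
    summary_b = average_replicates(m, tissue_b)
    n_a = int(summary_a["n_arrays"].iloc[0])
    n_b = int(summary_b["n_arrays"].iloc[0])
    log2_floor = math.log2(params.floor) if params.floor > 0 else 0.0
    log2v = m.log2
    cols_a = m.arrays_for(tissue_a)
    cols_b = m.arrays_for(tissue_b)

    rows = []
    for probe in m.values.index:
        det_a = int(summary_a.loc[probe, "n_detected"])
        det_b = int(summary_b.loc[probe, "n_detected"])
        va = log2v.loc[probe, cols_a][m.detected.loc[probe, cols_a]].to_numpy(float)
        vb = log2v.loc[probe, cols_b][m.detected.loc[probe, cols_b]].to_numpy(float)
        one_sided = False
        if det_a == 0 and det_b == 0:
            ratio, p = float("nan"), float("nan")
        elif det_a > 0 and det_b > 0:
            ratio, p = log2_ratio_ew(va, vb)
        else:
            one_sided = True
            present, n_present = (va, n_a) if det_a > 0 else (vb, n_b)
            diff = float(present.mean() - log2_floor)
            ratio = diff if det_a > 0 else -diff
            if len(present) >= math.ceil(n_present / 2) and len(present) >= 2:
                _, p = stats.ttest_1samp(present, log2_floor)
                p = float(p)
            else:
                p = float("nan")
        rows.append(
            {
                "probe_id": probe,
                "log2_ratio": ratio,
                "p_value": p,
                "det_a": det_a,
                "det_b": det_b,
                "n_a": n_a,
                "n_b": n_b,
                "one_sided_detection": one_sided,
            }
        )
    out = pd.DataFrame(rows).set_index("probe_id")
    if params.bh_correct:
        mask = out["p_value"].notna()
        adj = stats.false_discovery_control(out.loc[mask, "p_value"], method="bh")
        out.loc[mask, "p_value"] = adj
    return out


def select_de(
    results: pd.DataFrame, lfc_min: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Partition probes into up / down / not-DE.

    Up iff log2_ratio >= lfc_min and p < alpha (fold threshold inclusive,
    p threshold strict); down symmetric.  Adds ``significant`` and
    ``direction`` columns; the three classes are exhaustive and disjoint.
    """
    out = results.copy()
    p_ok = out["p_value"] < alpha  # NaN compares False
    up = (out["log2_ratio"] >= lfc_min) & p_ok
    down = (out["log2_ratio"] <= -lfc_min) & p_ok
    out["significant"] = up | down
    out["direction"] = np.where(up, "up", np.where(down, "down", "not_de"))
    return out


def call_specific(row: pd.Series) -> str:
    """Detection-based tissue-specific label for one DE row.

    Shoot-specific: significantly up, detected in at least half the shoot
    arrays and in zero root arrays; root-specific symmetric (significantly
    down, detected only in root).  Detected anywhere else -> shared;
    detected nowhere -> undetected.
    """
    det_a, det_b = int(row["det_a"]), int(row["det_b"])
    n_a, n_b = int(row["n_a"]), int(row["n_b"])
    if det_a == 0 and det_b == 0:
        return Specificity.UNDETECTED.value
    sig = bool(row["significant"])
    direction = row["direction"]
    if sig and direction == "up" and det_a >= math.ceil(n_a / 2) and det_b == 0:
        return Specificity.SHOOT_SPECIFIC.value
    if sig and direction == "down" and det_b >= math.ceil(n_b / 2) and det_a == 0:
        return Specificity.ROOT_SPECIFIC.value
    return Specificity.SHARED.value


def analyze(
    arrays: list[ArraySample],
    tissue_a: str,
    tissue_b: str,
    params: AnalysisParams = AnalysisParams(),
) -> dict:
    """Run the full pipeline; returns matrix, QC, and the DE table."""
    m = median_scale(arrays, params)
    qc = replicate_correlation(m)
    de = differential_expression(m, tissue_a, tissue_b, params)
    de = select_de(de, lfc_min=params.lfc_min, alpha=params.alpha)
    de["specificity"] = de.apply(call_specific, axis=1)
    return {"matrix": m, "correlation": qc, "de": de}
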