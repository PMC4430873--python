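"""RNA-seq count processing and the qPCR ddCt utility.

The workflow mirrors a knockdown-vs-control experiment with three
biologically independent replicates per condition: raw counts are scaled to
one million reads per sample, detection requires at least 10 raw reads
combined over all samples plus a transcript length of at least 125 nt, and
per-gene differential expression is tested with a two-sided pooled-variance
Student t on log2(normalized + 1) replicate values (unadjusted p < 0.05 by
default; Benjamini-Hochberg available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation

CONDITION_KD = "myc_kd"
CONDITION_CTRL = "ctrl_kd"

NORMALIZATION_TARGET = 1_000_000
MIN_READS = 10
MIN_LENGTH = 125
ALPHA = 0.05
FOLD_FRACTION = 1.0 / 3.0

REGULATION_CLASSES = ("down_significant", "up_significant", "unchanged", "undetected")
FOLD_CLASSES = ("down_by_third", "up_by_third", "unchanged")


@dataclass
class CountMatrix:
    """Gene x sample raw counts with per-sample condition labels."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    conditions: pd.Series  # sample -> {myc_kd, ctrl_kd}
    normalized: pd.DataFrame | None = None

    def __post_init__(self):
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = list(self.conditions[self.conditions.isna()].index)
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.conditions) - {CONDITION_KD, CONDITION_CTRL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        n_kd = int((self.conditions == CONDITION_KD).sum())
        n_ctrl = int((self.conditions == CONDITION_CTRL).sum())
        if (n_kd, n_ctrl) != (3, 3):
            warnings.warn(
                f"non-standard design: {n_kd} knockdown vs {n_ctrl} control replicates",
                stacklevel=2,
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions[self.conditions == condition].index)


def normalize_counts(cm: CountMatrix, target: int = NORMALIZATION_TARGET) -> CountMatrix:
    """Scale every sample to ``target`` total reads (library-size normalization)."""
    colsums = cm.counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    normalized = cm.counts * (target / colsums)
    return CountMatrix(cm.counts, cm.conditions, normalized)


def filter_detected(
    cm: CountMatrix,
    ann: GenomeAnnotation,
    min_reads: int = MIN_READS,
    min_length: int = MIN_LENGTH,
) -> list[str]:
    """Genes passing both detection filters, in count-matrix order.

    A gene is retained iff its raw counts summed over all samples reach
    ``min_reads`` and its annotated transcript length reaches ``min_length``.
    """
    missing = [g for g in cm.genes if g not in ann]
    if missing:
        raise ValueError(f"genes missing from annotation: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    totals = cm.counts.sum(axis=1)
    return [
        g
        for g in cm.genes
        if totals[g] >= min_reads and ann[g].transcript_length >= min_length
    ]


def differential_test(
    cm: CountMatrix,
    detected: list[str],
    alpha: float = ALPHA,
    pseudocount: float = 1.0,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene knockdown-vs-control differential test.

    Returns a frame indexed by gene_id with columns ``mean_ctrl``,
    ``mean_kd`` (means of normalized counts), ``log2_ratio``
    (log2((mean_kd + c) / (mean_ctrl + c)), c = ``pseudocount``),
    ``p_value`` (two-sided pooled-variance Student t on log2(normalized + 1)
    replicate values) and ``regulation``. The pooled test is used rather
    than Welch's: at three replicates per group the pooled statistic holds
    its nominal size under (log-)normality, whereas Welch-Satterthwaite
    degree-of-freedom estimation is noticeably conservative. Undetected genes appear with NaN statistics
    and regulation ``undetected``. When both groups have zero variance and
    equal means the p-value is 1. ``adjust=True`` applies Benjamini-Hochberg
    and bases significance on the adjusted values (column ``q_value``).
    """
    if cm.normalized is None:
        cm = normalize_counts(cm)
    kd_samples = cm.samples_of(CONDITION_KD)
    ctrl_samples = cm.samples_of(CONDITION_CTRL)

    det = [g for g in cm.genes if g in set(detected)]
    norm = cm.normalized.loc[det]
    kd = norm[kd_samples].to_numpy(dtype=float)
    ctrl = norm[ctrl_samples].to_numpy(dtype=float)
    mean_kd = kd.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    log2_ratio = np.log2((mean_kd + pseudocount) / (mean_ctrl + pseudocount))

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # identical replicate values are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(np.log2(kd + 1), np.log2(ctrl + 1), axis=1, equal_var=True)
        pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p = 1 when means agree, ~0 when they differ
    degenerate = np.isnan(pvals)
    if degenerate.any():
        same = np.isclose(np.log2(kd + 1).mean(axis=1), np.log2(ctrl + 1).mean(axis=1))
        pvals[degenerate & same] = 1.0
        pvals[degenerate & ~same] = 0.0

    out = pd.DataFrame(
        {
            "mean_ctrl": mean_ctrl,
            "mean_kd": mean_kd,
            "log2_ratio": log2_ratio,
            "p_value": pvals,
        },
        index=pd.Index(det, name="gene_id"),
    )
    crit = out["p_value"]
    if adjust:
        out["q_value"] = multipletests(pvals, method="fdr_bh")[1]
        crit = out["q_value"]
    regulation = np.where(
        (crit < alpha) & (mean_kd < mean_ctrl),
        "down_significant",
        np.where((crit < alpha) & (mean_kd > mean_ctrl), "up_significant", "unchanged"),
    )
    out["regulation"] = regulation

    undet = [g for g in cm.genes if g not in set(det)]
    if undet:
        pad = pd.DataFrame(
            {
                "mean_ctrl": np.nan,
                "mean_kd": np.nan,
                "log2_ratio": np.nan,
                "p_value": np.nan,
                "regulation": "undetected",
            },
            index=pd.Index(undet, name="gene_id"),
        )
        if adjust:
            pad["q_value"] = np.nan
        out = pd.concat([out, pad]).loc[cm.genes]
    return out


def classify_regulation(
    dr: pd.DataFrame | pd.Series,
    fold_fraction: float = FOLD_FRACTION,
) -> pd.Series | str:
    """Fold-change class on normalized condition means (inclusive boundary).

    ``down_by_third``: mean_kd <= (1 - f) * mean_ctrl; ``up_by_third`` is the
    reciprocal on the ratio scale: mean_ctrl <= (1 - f) * mean_kd. Both means
    zero -> ``unchanged``. Accepts a DiffResult frame (returns a Series) or a
    single row/Series with ``mean_ctrl``/``mean_kd`` (returns a string).
    """
    single = isinstance(dr, pd.Series) or (
        isinstance(dr, dict)
    )
    if single:
        dr = pd.DataFrame([dr])
    kd = dr["mean_kd"].to_numpy(dtype=float)
    ctrl = dr["mean_ctrl"].to_numpy(dtype=float)
    keep = 1.0 - fold_fraction
    down = kd <= keep * ctrl
    up = ctrl <= keep * kd
    both_zero = (kd == 0) & (ctrl == 0)
    cls = np.where(both_zero, "unchanged", np.where(down, "down_by_third",
                                                    np.where(up, "up_by_third", "unchanged")))
    cls = np.where(np.isnan(kd) | np.isnan(ctrl), "undetected", cls)
    result = pd.Series(cls, index=dr.index, name="fold_class")
    return result.iloc[0] if single else result


def ddct_relative_expression(
    ct: pd.DataFrame,
    reference_genes: list[str],
    conditions: pd.Series,
    calibrator: str,
) -> pd.DataFrame:
    """Relative expression by the ddCt method, in percent of the calibrator.

    ``ct`` is a gene x sample table of Ct values; ``reference_genes`` are
    averaged per sample to give the reference Ct. For each target gene:
    dCt = Ct(target) - mean Ct(references) per sample; ddCt subtracts the
    mean dCt over the calibrator condition; relative expression is
    2**(-ddCt) * 100, averaged per condition, so the calibrator reads 100%.
    """
    if ct.isna().any().any():
        bad = [(g, s) for g in ct.index for s in ct.columns if pd.isna(ct.at[g, s])]
        raise ValueError(f"missing Ct values: {bad[:5]}")
    missing_refs = [g for g in reference_genes if g not in ct.index]
    if missing_refs:
        raise ValueError(f"reference genes missing from Ct table: {missing_refs}")
    conditions = conditions.reindex(ct.columns)
    if calibrator not in set(conditions):
        raise ValueError(f"no samples with calibrator condition {calibrator!r}")
    ref_ct = ct.loc[reference_genes].mean(axis=0)
    targets = [g for g in ct.index if g not in set(reference_genes)]
    dct = ct.loc[targets].sub(ref_ct, axis=1)
    calib_samples = conditions[conditions == calibrator].index
    ddct = dct.sub(dct[calib_samples].mean(axis=1), axis=0)
    rel = (2.0 ** (-ddct)) * 100.0
    return rel.T.groupby(conditions).mean().T


# ---------------------------------------------------------------------------
# I/O


def read_counts(path: str) -> CountMatrix:
    """Count matrix TSV: gene_id column plus one column per sample.

    Sample headers carry the condition label as a prefix, e.g.
    ``myc_kd_1`` or ``ctrl_kd_2``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    conds = {}
    for s in df.columns:
        for cond in (CONDITION_KD, CONDITION_CTRL):
            if s.startswith(cond):
                conds[s] = cond
                break
        else:
            raise ValueError(f"sample {s!r}: cannot infer condition from header")
    return CountMatrix(df, pd.Series(conds))


def write_counts(cm: CountMatrix, path: str) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def write_diff_result(dr: pd.DataFrame, path: str) -> None:
    dr.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


def read_diff_result(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
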