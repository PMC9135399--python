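"""Omics preprocessing and differential expression/abundance calling.

Transcript matrices are brought to TPM scale (columns sum to 1e6), protein
matrices are quantile-normalized and log2 transformed, samples are split
into aneuploid vs diploid groups per aneuploidy case, and features are
tested with two-sided Wilcoxon rank-sum tests.  Transcript calls use
Benjamini-Hochberg adjusted p < 0.1 with a fallback to raw p < 0.05 when
fewer than 250 protein-coding genes pass; protein calls use raw p < 0.1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aneuploidy import AneuploidyCase

TRANSCRIPT_ADJ_P = 0.1
TRANSCRIPT_FALLBACK_RAW_P = 0.05
TRANSCRIPT_FALLBACK_MIN_GENES = 250
PROTEIN_RAW_P = 0.1
TPM_TOTAL = 1e6


def fpkm_to_tpm(matrix: pd.DataFrame, mito_genes: set[str] = frozenset()) -> pd.DataFrame:
    """Convert an FPKM matrix (genes x samples) to TPM.

    TPM_gs = FPKM_gs / sum_g FPKM_gs * 1e6.  Genes in ``mito_genes`` and
    genes that are zero in every sample are removed first.
    """
    if (matrix < 0).any().any():
        raise ValueError("FPKM values must be nonnegative")
    mat = matrix.drop(index=[g for g in mito_genes if g in matrix.index])
    mat = mat.loc[(mat != 0).any(axis=1)]
    colsum = mat.sum(axis=0)
    zero_cols = colsum[colsum == 0]
    if not zero_cols.empty:
        raise ValueError(f"all-zero sample column(s): {list(zero_cols.index)}")
    return mat / colsum * TPM_TOTAL


def quantile_normalize_log2(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Quantile normalization to the mean order-statistic profile, then log2.

    After normalization every column shares the same sorted-value profile
    (the mean across columns of each order statistic); tied values within a
    column receive the mean of the reference values at the tied ranks.
    Finally log2(x + pseudocount) is applied.
    """
    if (matrix < 0).any().any():
        raise ValueError("quantile normalization expects nonnegative values")
    values = matrix.to_numpy(dtype=float)
    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, len(reference) + 1), reference)
    return pd.DataFrame(np.log2(out + pseudocount), index=matrix.index, columns=matrix.columns)


def average_replicates(matrix: pd.DataFrame, replicate_map: dict[str, str]) -> pd.DataFrame:
    """Average replicate columns; ``replicate_map`` maps column -> sample id."""
    groups = matrix.columns.to_series().map(lambda c: replicate_map.get(c, c))
    return matrix.T.groupby(groups).mean().T


def split_by_case(
    matrix: pd.DataFrame,
    chrom_scores: pd.DataFrame,
    case: AneuploidyCase,
    min_group: int = 5,
) -> tuple[list[str], list[str]] | None:
    """Split samples into aneuploid and diploid groups for a case.

    Aneuploid samples carry the case direction on the case chromosome;
    diploid samples score 0.  Samples with the opposite alteration or an
    undetermined (NaN) state are excluded.  Returns None (with a warning)
    when either group is smaller than ``min_group``.
    """
    scores = chrom_scores[case.chromosome].reindex(matrix.columns)
    aneuploid = list(scores.index[scores == case.direction])
    diploid = list(scores.index[scores == 0])
    if len(aneuploid) < min_group or len(diploid) < min_group:
        warnings.warn(
            f"case {case.label}: group sizes {len(aneuploid)}/{len(diploid)} "
            f"below minimum {min_group}; skipped"
        )
        return None
    return aneuploid, diploid


def differential_test(
    matrix: pd.DataFrame,
    groups: tuple[list[str], list[str]],
    mode: str,
    protein_coding: pd.Series | None = None,
    min_nonmissing: int = 3,
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test, aneuploid vs diploid.

    Transcript mode drops features that are zero in all retained samples,
    BH-adjusts p-values and calls significance at adjusted p < 0.1; when
    fewer than 250 protein-coding features pass, calls fall back to raw
    p < 0.05.  Protein mode uses raw p < 0.1 without adjustment and skips
    features with fewer than ``min_nonmissing`` observed values per group.

    Returns a DataFrame indexed by feature with columns raw_p, adj_p,
    direction (+1 up / -1 down in aneuploid, 0 for non-significant),
    median_diff, log2_fc (transcript mode), significant, threshold_rule_used.
    """
    if mode not in ("transcript", "protein"):
        raise ValueError(f"mode must be 'transcript' or 'protein', got {mode!r}")
    aneuploid, diploid = groups
    if not aneuploid or not diploid:
        raise ValueError("both groups must be non-empty")
    sub = matrix[list(aneuploid) + list(diploid)]
    if mode == "transcript":
        sub = sub.loc[(sub != 0).any(axis=1)]
    x = sub[aneuploid].to_numpy(dtype=float)
    y = sub[diploid].to_numpy(dtype=float)

    if mode == "protein":
        enough = (~np.isnan(x)).sum(axis=1) >= min_nonmissing
        enough &= (~np.isnan(y)).sum(axis=1) >= min_nonmissing
        if not enough.all():
            warnings.warn(f"{int((~enough).sum())} proteins with insufficient coverage skipped")
        sub, x, y = sub.loc[enough], x[enough], y[enough]

    raw_p = _ranksum_p(x, y)
    med_diff = np.nanmedian(x, axis=1) - np.nanmedian(y, axis=1)
    constant = np.array(
        [np.nanmax(row) == np.nanmin(row) for row in np.concatenate([x, y], axis=1)]
    )
    raw_p[constant] = 1.0  # constant feature: no evidence by convention

    res = pd.DataFrame(index=sub.index)
    res["raw_p"] = raw_p
    res["median_diff"] = med_diff
    res["constant"] = constant
    if mode == "transcript":
        res["adj_p"] = multipletests(raw_p, method="fdr_bh")[1]
        res["log2_fc"] = np.log2(
            (np.nanmean(x, axis=1) + 1.0) / (np.nanmean(y, axis=1) + 1.0)
        )
        significant = res["adj_p"] < TRANSCRIPT_ADJ_P
        coding = (
            protein_coding.reindex(res.index).fillna(True).astype(bool)
            if protein_coding is not None
            else pd.Series(True, index=res.index)
        )
        rule = "adj_p_0.1"
        if int((significant & coding).sum()) < TRANSCRIPT_FALLBACK_MIN_GENES:
            significant = res["raw_p"] < TRANSCRIPT_FALLBACK_RAW_P
            rule = "raw_p_0.05"
    else:
        res["adj_p"] = multipletests(raw_p, method="fdr_bh")[1]
        significant = res["raw_p"] < PROTEIN_RAW_P
        rule = "raw_p_0.1"
    res["significant"] = significant
    res["direction"] = np.where(significant, np.sign(res["median_diff"]), 0).astype(int)
    res["threshold_rule_used"] = rule
    return res


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per row, pairwise-complete over NaN."""
    complete = ~np.isnan(x).any() and ~np.isnan(y).any()
    if complete:
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        return np.asarray(res.pvalue, dtype=float)
    out = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        xi = x[i][~np.isnan(x[i])]
        yi = y[i][~np.isnan(y[i])]
        out[i] = stats.mannwhitneyu(xi, yi, alternative="two-sided").pvalue
    return out


def locate_features(
    result: pd.DataFrame, gene_annotation: pd.Series, case: AneuploidyCase
) -> pd.DataFrame:
    """Annotate results with aneuploid- vs other-chromosome location.

    Features without a chromosome annotation are excluded with a warning.
    """
    chrom = gene_annotation.reindex(result.index)
    missing = chrom.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} features lack chromosome annotation; excluded")
    out = result.loc[~missing].copy()
    out["location"] = np.where(
        chrom[~missing].astype(int) == case.chromosome,
        "aneuploid_chromosome",
        "other_chromosome",
    )
    return out


def location_fractions(located: pd.DataFrame) -> dict[str, float]:
    """Fraction of detected features that are significant, per location."""
    out = {}
    for loc in ("aneuploid_chromosome", "other_chromosome"):
        sub = located[located["location"] == loc]
        out[loc] = float(sub["significant"].mean()) if len(sub) else float("nan")
    return out
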