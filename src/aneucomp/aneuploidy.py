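"""Whole-chromosome aneuploidy calling and recurrence testing.

Arm-level aneuploidy calls (gain +1, loss -1, neutral 0, or missing) are
collapsed to whole-chromosome states, recurrent cancer-type-specific
aneuploidies are detected with one-vs-rest chi-square tests (Holm-corrected,
standard residual >= 2), co-amplified chromosome pairs are identified, and
per-chromosome contributions to transcriptional dysregulation are compared
between co-amplified and other chromosomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Autosomes whose centromere-proximal p arm is too short to be scored;
#: the q arm represents the whole chromosome.
ACROCENTRIC = frozenset({13, 14, 15, 21, 22})

_VALID_SCORES = {-1, 0, 1}


@dataclass(frozen=True)
class AneuploidyCase:
    """A recurrent cancer-type-specific whole-chromosome alteration."""

    cancer_type: str
    chromosome: int
    direction: int  # +1 amplification, -1 deletion
    chi2_p: float
    adj_p: float
    std_residual: float
    n_altered: int
    n_type: int

    @property
    def label(self) -> str:
        sign = "amp" if self.direction > 0 else "del"
        return f"{self.cancer_type}:chr{self.chromosome}:{sign}"


def whole_chromosome_score(p_score, q_score, chromosome: int):
    """Collapse arm scores to a whole-chromosome score.

    For metacentric/submetacentric autosomes (1-12, 16-20) both arms must
    agree and be non-missing; any conflict or missing arm yields NaN. For
    acrocentric chromosomes (13-15, 21-22) the q arm is representative.

    Parameters
    ----------
    p_score, q_score
        Arm scores in {-1, 0, +1} or NaN/None for missing.
    chromosome
        Autosome number 1-22.

    Returns
    -------
    float
        -1.0, 0.0, +1.0, or NaN.
    """
    if not 1 <= int(chromosome) <= 22:
        raise ValueError(f"chromosome must be in 1..22, got {chromosome}")
    p_missing = p_score is None or (isinstance(p_score, float) and math.isnan(p_score))
    q_missing = q_score is None or (isinstance(q_score, float) and math.isnan(q_score))
    for val, missing in ((p_score, p_missing), (q_score, q_missing)):
        if not missing and int(val) not in _VALID_SCORES:
            raise ValueError(f"arm score must be in {{-1,0,+1}} or missing, got {val!r}")
    if int(chromosome) in ACROCENTRIC:
        return float("nan") if q_missing else float(int(q_score))
    if p_missing or q_missing or int(p_score) != int(q_score):
        return float("nan")
    return float(int(p_score))


def chromosome_scores(arm_scores: pd.DataFrame) -> pd.DataFrame:
    """Vectorised whole-chromosome calls for a samples x arms matrix.

    Columns are named ``"<chrom><arm>"`` (e.g. ``"5p"``, ``"13q"``); a missing
    p column for an acrocentric chromosome is allowed.  Returns a samples x
    chromosomes DataFrame with integer chromosome columns and NaN where arms
    conflict or data are missing.
    """
    chroms = sorted({int(c[:-1]) for c in arm_scores.columns})
    out = {}
    for chrom in chroms:
        q = arm_scores.get(f"{chrom}q")
        if q is None:
            raise ValueError(f"q-arm column missing for chromosome {chrom}")
        q = q.astype(float)
        if chrom in ACROCENTRIC:
            out[chrom] = q
            continue
        p = arm_scores.get(f"{chrom}p")
        if p is None:
            raise ValueError(f"p-arm column missing for chromosome {chrom}")
        p = p.astype(float)
        agree = (p == q) & p.notna() & q.notna()
        out[chrom] = p.where(agree)
    return pd.DataFrame(out, index=arm_scores.index)


def standard_residual(observed: float, expected: float) -> float:
    """Pearson standard residual (observed - expected) / sqrt(expected)."""
    if expected <= 0:
        raise ValueError(f"expected count must be positive, got {expected}")
    return (observed - expected) / math.sqrt(expected)


def chi2_2x2(table: np.ndarray, cell: tuple[int, int] = (0, 0)) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns ``(std_residual, p)`` where the residual is taken at ``cell``.
    Raises ``ValueError`` on a degenerate table (zero row or column margin).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    resid = standard_residual(table[cell], expected[cell])
    return resid, p


def detect_recurrent(
    chrom_scores: pd.DataFrame,
    cancer_types: pd.Series,
    alpha: float = 0.05,
    min_residual: float = 2.0,
    min_samples_per_type: int = 10,
    alpha_method: str = "holm",
) -> list[AneuploidyCase]:
    """Detect recurrent cancer-type-specific whole-chromosome aneuploidies.

    For every (cancer type, chromosome, direction) the occurrence of the
    alteration inside the type is tested against all other types with a 2x2
    chi-square (one-vs-rest); p-values are Holm-corrected across all tests
    and cases are kept when ``adj_p <= alpha`` and the standard residual of
    the (this type, altered) cell is ``>= min_residual``.  Samples with an
    undetermined (NaN) state for a chromosome are excluded from that
    chromosome's tables.
    """
    cancer_types = cancer_types.reindex(chrom_scores.index)
    types = cancer_types.dropna().unique()
    if len(types) < 2:
        raise ValueError("need at least two cancer types")
    counts = cancer_types.value_counts()
    small = [t for t in types if counts[t] < min_samples_per_type]
    if small:
        warnings.warn(f"cancer types below {min_samples_per_type} samples excluded: {small}")
        types = [t for t in types if t not in small]

    records = []
    for chrom in chrom_scores.columns:
        col = chrom_scores[chrom]
        valid = col.notna() & cancer_types.isin(types)
        col_v, type_v = col[valid], cancer_types[valid]
        for direction in (+1, -1):
            altered = col_v == direction
            for ctype in types:
                in_type = type_v == ctype
                table = np.array(
                    [
                        [(altered & in_type).sum(), (~altered & in_type).sum()],
                        [(altered & ~in_type).sum(), (~altered & ~in_type).sum()],
                    ],
                    dtype=float,
                )
                if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                    continue
                expected = stats.contingency.expected_freq(table)
                if (expected < 1).any():
                    warnings.warn(
                        f"expected cell < 1 for {ctype} chr{chrom} dir {direction:+d}; skipped"
                    )
                    continue
                resid, p = chi2_2x2(table)
                records.append(
                    (ctype, int(chrom), direction, p, resid, int(table[0, 0]), int(in_type.sum()))
                )
    if not records:
        return []
    pvals = np.array([r[3] for r in records])
    adj = multipletests(pvals, method=alpha_method)[1]
    cases = [
        AneuploidyCase(ct, ch, d, p, ap, resid, n_alt, n_ty)
        for (ct, ch, d, p, resid, n_alt, n_ty), ap in zip(records, adj)
        if ap <= alpha and resid >= min_residual
    ]
    cases.sort(key=lambda c: (c.cancer_type, c.chromosome, -c.direction))
    return cases


def detect_coamplifications(
    chrom_scores: pd.DataFrame,
    cases: list[AneuploidyCase],
    cancer_types: pd.Series,
    alpha: float = 0.01,
) -> list[tuple[AneuploidyCase, int, float]]:
    """Find chromosomes co-amplified with recurrent amplification cases.

    Within each amplification case's cancer type, the co-occurrence of the
    case-chromosome amplification with amplification of every other
    chromosome is chi-square tested; Holm correction is applied across all
    (case, partner) pairs and pairs with adjusted p strictly below ``alpha``
    are returned.
    """
    cancer_types = cancer_types.reindex(chrom_scores.index)
    records = []
    for case in cases:
        if case.direction != +1:
            continue
        sub = chrom_scores[cancer_types == case.cancer_type]
        a = sub[case.chromosome]
        for other in chrom_scores.columns:
            if other == case.chromosome:
                continue
            b = sub[other]
            valid = a.notna() & b.notna()
            amp_a = (a[valid] == 1).to_numpy()
            amp_b = (b[valid] == 1).to_numpy()
            table = np.array(
                [
                    [(amp_a & amp_b).sum(), (amp_a & ~amp_b).sum()],
                    [(~amp_a & amp_b).sum(), (~amp_a & ~amp_b).sum()],
                ],
                dtype=float,
            )
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            resid, p = chi2_2x2(table)
            if resid <= 0:
                # only positive dependence counts as co-amplification
                records.append((case, int(other), p, False))
            else:
                records.append((case, int(other), p, True))
    if not records:
        return []
    adj = multipletests([r[2] for r in records], method="holm")[1]
    return [
        (case, other, ap)
        for (case, other, _, positive), ap in zip(records, adj)
        if positive and ap < alpha
    ]


def chromosome_contribution(
    de_genes: set[str], gene_annotation: pd.Series
) -> pd.Series:
    """Per-chromosome fraction of genes that are differentially expressed.

    ``gene_annotation`` maps gene -> chromosome over the full gene universe.
    Chromosomes with zero annotated genes are excluded with a warning.
    """
    missing = de_genes - set(gene_annotation.index)
    if missing:
        raise ValueError(f"DE genes missing from annotation: {sorted(missing)[:5]}")
    totals = gene_annotation.value_counts()
    de_by_chrom = gene_annotation[gene_annotation.index.isin(de_genes)].value_counts()
    frac = (de_by_chrom.reindex(totals.index).fillna(0) / totals).sort_index()
    return frac


def compare_contributions(
    fractions: pd.DataFrame, coamplified: list[set[int]], other: list[set[int]]
) -> tuple[float, pd.Series]:
    """Paired Wilcoxon test of mean chromosome contributions across cases.

    ``fractions`` is cases x chromosomes; per case the mean contribution of
    its co-amplified chromosomes is paired with the mean over its remaining
    chromosomes.  Returns (p, per-case differences).
    """
    diffs = []
    for (_, row), co, oth in zip(fractions.iterrows(), coamplified, other):
        co, oth = list(co), list(oth)
        if not co or not oth:
            continue
        diffs.append(row[co].mean() - row[oth].mean())
    diffs = pd.Series(diffs, dtype=float)
    if diffs.empty or (diffs == 0).all():
        return 1.0, diffs
    _, p = stats.wilcoxon(diffs)
    return float(p), diffs
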