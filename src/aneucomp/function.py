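"""Functional-term enrichment among complexes of top-correlated partners.

Per aneuploidy case, the 20 strongest positive and 20 strongest negative
co-abundance correlations define the top pair set; pairs with rho in
[-0.2, 0.2] form the background.  For each functional term annotating the
complexes of the partner proteins, a 2x2 chi-square (top vs background x
annotated vs not) is computed along with the enrichment score
(observed - expected) / sqrt(expected); terms with p < 0.05 are called
significant.  Sensitivity variants re-run the analysis after removing
ribosomal proteins or complexes with more than 10 subunits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aneuploidy import chi2_2x2, standard_residual
from .complexes import ComplexDatabase

N_TOP_EACH_SIDE = 20
BACKGROUND_BAND = 0.2
TERM_P = 0.05
LARGE_COMPLEX_SIZE = 10  # more than this many subunits -> "large"


@dataclass(frozen=True)
class TermEnrichment:
    term: str
    observed: int
    expected: float
    enrichment_score: float
    p: float
    significant: bool


def select_top_and_background(
    table: pd.DataFrame, n_each: int = N_TOP_EACH_SIDE, band: float = BACKGROUND_BAND
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split a correlation table into top-correlated and background pairs.

    Top = the ``n_each`` largest and ``n_each`` smallest rho values (fewer if
    not available, flagged); background = rows with rho in [-band, band].
    Ties at the selection boundary are broken by (aneuploid_protein,
    partner) lexicographic order so the split is deterministic.
    """
    if table.empty:
        raise ValueError("empty correlation table")
    ordered = table.sort_values(
        ["rho", "aneuploid_protein", "partner"], ascending=[False, True, True]
    )
    top_pos = ordered[ordered["rho"] > 0].head(n_each)
    top_neg = ordered[ordered["rho"] < 0].tail(n_each)
    top = pd.concat([top_pos, top_neg]).drop_duplicates(
        subset=["aneuploid_protein", "partner"]
    )
    background = table[(table["rho"] >= -band) & (table["rho"] <= band)]
    if background.empty:
        raise ValueError("background band is empty: no null reference")
    flags = {
        "short_positive_side": len(top_pos) < n_each,
        "short_negative_side": len(top_neg) < n_each,
        "n_top": len(top),
    }
    if flags["short_positive_side"] or flags["short_negative_side"]:
        warnings.warn("fewer than requested strong correlations on one side; top set truncated")
    return top.reset_index(drop=True), background.reset_index(drop=True), flags


def complexes_of(pairs: pd.DataFrame, db: ComplexDatabase) -> set[str]:
    """Complexes containing the partner protein of each pair."""
    out: set[str] = set()
    for partner in pairs["partner"]:
        out |= db.membership(partner)
    return out


def term_enrichment(
    top_complexes: set[str],
    background_complexes: set[str],
    db: ComplexDatabase,
    alpha: float = TERM_P,
    bh_correct: bool = False,
) -> list[TermEnrichment]:
    """Per-term chi-square enrichment of top vs background complexes.

    For each term annotating at least one complex in either set, the 2x2
    table {top, background} x {annotated, not} is tested; the enrichment
    score is the standard residual (O - E)/sqrt(E) of the top-annotated
    cell.  Terms are returned sorted by p; significance is raw p < alpha
    (optionally BH-corrected).
    """
    if not top_complexes or not background_complexes:
        raise ValueError("both complex sets must be non-empty")
    terms: set[str] = set()
    for cid in top_complexes | background_complexes:
        terms |= db.annotations.get(cid, frozenset())
    results = []
    for term in sorted(terms):
        annotated = {c for c in db.annotations if term in db.annotations[c]}
        a = len(top_complexes & annotated)
        b = len(top_complexes - annotated)
        c = len(background_complexes & annotated)
        d = len(background_complexes - annotated)
        if a + c == 0:
            continue
        table = np.array([[a, b], [c, d]], dtype=float)
        try:
            _, p = chi2_2x2(table)
        except ValueError:
            continue
        expected = (a + b) * (a + c) / (a + b + c + d)
        score = standard_residual(a, expected) if expected > 0 else float("nan")
        results.append([term, a, expected, score, p])
    if not results:
        return []
    pvals = np.array([r[4] for r in results])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    out = [
        TermEnrichment(term, obs, exp, score, float(p), bool(p < alpha))
        for (term, obs, exp, score, _), p in zip(results, pvals)
    ]
    out.sort(key=lambda t: (t.p, t.term))
    return out


def run_case_enrichment(
    table: pd.DataFrame,
    db: ComplexDatabase,
    variant: str = "none",
    ribosomal_proteins: set[str] = frozenset(),
) -> list[TermEnrichment]:
    """Full per-case enrichment analysis, with sensitivity variants.

    ``variant``: 'none', 'drop_ribosomal' (remove ribosomal proteins from
    the database), or 'drop_large_complexes' (remove complexes with more
    than 10 subunits).
    """
    if variant == "drop_ribosomal":
        db = db.filtered(drop_proteins=set(ribosomal_proteins))
    elif variant == "drop_large_complexes":
        db = db.filtered(max_size=LARGE_COMPLEX_SIZE)
    elif variant != "none":
        raise ValueError(f"unknown variant {variant!r}")
    top, background, _ = select_top_and_background(table)
    top_cx = complexes_of(top, db)
    bg_cx = complexes_of(background, db)
    if not top_cx:
        raise ValueError("filtering emptied the top complex set")
    if not bg_cx:
        raise ValueError("filtering emptied the background complex set")
    return term_enrichment(top_cx, bg_cx, db)


def concordance(
    base: list[TermEnrichment], variant: list[TermEnrichment]
) -> float:
    """Jaccard overlap of significant term sets between two runs."""
    s_base = {t.term for t in base if t.significant}
    s_var = {t.term for t in variant if t.significant}
    if not s_base and not s_var:
        return 1.0
    return len(s_base & s_var) / len(s_base | s_var)
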