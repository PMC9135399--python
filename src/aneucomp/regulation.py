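"""Regulatory-layer attribution of other-chromosome dysregulation.

Three tests ask whether expression/abundance changes on non-aneuploid
chromosomes can be explained by upstream regulation: promoter methylation
shifts between aneuploid and diploid samples, enrichment of targets of
differentially expressed transcription factors (empirical randomization
null, 100 iterations, two-tailed), and ubiquitination-site loads of
top-correlated co-complex partners.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .aneuploidy import chi2_2x2
from .complexes import ComplexDatabase

TOP_CORRELATION_THRESHOLD = 0.4  # |rho| >= 0.4 defines top partners


def methylation_shift_test(
    methylation: pd.DataFrame,
    promoter_map: dict[str, str],
    genes: set[str],
    aneuploid_samples: list[str],
    diploid_samples: list[str],
    paired: bool = True,
) -> tuple[float, float]:
    """Compare promoter methylation of a gene set between sample groups.

    Per gene, mean promoter methylation is computed across aneuploid and
    diploid samples separately; the two per-gene mean vectors are compared
    with a Wilcoxon test — signed-rank on per-gene differences by default,
    or a pooled rank-sum test with ``paired=False``.

    Returns (p, median per-gene shift aneuploid - diploid).
    """
    if not genes:
        raise ValueError("empty gene set")
    if not aneuploid_samples or not diploid_samples:
        raise ValueError("both sample groups must be non-empty")
    promoters, kept = [], []
    for g in sorted(genes):
        prom = promoter_map.get(g)
        if prom is None or prom not in methylation.index:
            warnings.warn(f"gene {g} has no promoter measurement; dropped")
            continue
        promoters.append(prom)
        kept.append(g)
    if not promoters:
        raise ValueError("no gene in the set has promoter methylation data")
    sub = methylation.loc[promoters]
    mean_aneu = sub[aneuploid_samples].mean(axis=1).to_numpy()
    mean_dip = sub[diploid_samples].mean(axis=1).to_numpy()
    diffs = mean_aneu - mean_dip
    shift = float(np.median(diffs))
    if np.allclose(diffs, 0):
        return 1.0, shift
    if paired:
        p = float(stats.wilcoxon(diffs).pvalue)
    else:
        p = float(stats.mannwhitneyu(mean_aneu, mean_dip, alternative="two-sided").pvalue)
    return p, shift


def tf_target_randomization(
    tf_map: dict[str, set[str]],
    de_tfs_aneuploid: set[str],
    de_genes_other: set[str],
    all_tfs: set[str] | None = None,
    n_iter: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Randomization test for excess TF-target hits among DE genes.

    Observed = number of differentially expressed other-chromosome genes
    that are targets of the differentially expressed aneuploid-chromosome
    TFs.  The null recounts targets for ``n_iter`` random TF sets of equal
    size drawn from ``all_tfs`` minus the observed set; the two-tailed
    empirical p-value is 2*min(P(null > obs), P(null < obs)) with
    pseudocounts and mid-p tie handling, capped at 1.

    Returns dict with observed, expected (null mean), p, null, status.
    """
    if not de_tfs_aneuploid:
        return {"status": "skipped_empty_tf_set", "observed": None, "expected": None,
                "p": None, "null": None}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # the DE TF set is replaced by other TFs, so it is excluded from the pool
    pool = sorted(set(all_tfs if all_tfs is not None else tf_map) - de_tfs_aneuploid)
    k = len(de_tfs_aneuploid)
    if len(pool) < k:
        raise ValueError(f"TF pool ({len(pool)}) smaller than DE TF set ({k})")

    def n_targets(tfs) -> int:
        targets: set[str] = set()
        for tf in tfs:
            targets |= tf_map.get(tf, set())
        return len(targets & de_genes_other)

    observed = n_targets(de_tfs_aneuploid)
    null = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        null[it] = n_targets(rng.choice(pool, size=k, replace=False))
    # mid-p tie handling: target counts are discrete and tie mass would
    # otherwise make the two-tailed p badly conservative
    n_eq = int((null == observed).sum())
    upper = (1 + int((null > observed).sum()) + 0.5 * n_eq) / (n_iter + 1)
    lower = (1 + int((null < observed).sum()) + 0.5 * n_eq) / (n_iter + 1)
    p = min(1.0, 2 * min(upper, lower))
    return {
        "status": "ok",
        "observed": observed,
        "expected": float(null.mean()),
        "excess": observed - float(null.mean()),
        "p": float(p),
        "null": null,
    }


def target_enrichment_chisq(
    tf: str, tf_map: dict[str, set[str]], de_genes: set[str], universe: set[str]
) -> tuple[float, float] | None:
    """2x2 chi-square {target of tf} x {differentially expressed}."""
    if tf not in tf_map:
        raise KeyError(f"unknown TF {tf!r}")
    targets = tf_map[tf] & universe
    if not targets:
        warnings.warn(f"TF {tf} has no targets in universe; skipped")
        return None
    de = de_genes & universe
    a = len(de & targets)
    b = len(de - targets)
    c = len(targets - de)
    d = len(universe) - a - b - c
    try:
        return chi2_2x2(np.array([[a, b], [c, d]], dtype=float))
    except ValueError:
        warnings.warn(f"degenerate table for TF {tf}; skipped")
        return None


def correlation_groups_for_ubiquitination(
    table: pd.DataFrame,
    db: ComplexDatabase,
    all_proteins: set[str],
    threshold: float = TOP_CORRELATION_THRESHOLD,
) -> dict[str, set[str]]:
    """Partner protein groups for the ubiquitination comparison.

    Groups: all quantified proteins; complex subunits among them; partner
    proteins from top positive (rho >= threshold) and top negative
    (rho <= -threshold) correlation rows.
    """
    top_pos = set(table.loc[table["rho"] >= threshold, "partner"])
    top_neg = set(table.loc[table["rho"] <= -threshold, "partner"])
    return {
        "all": set(all_proteins),
        "complex_subunits": db.all_subunits & set(all_proteins),
        "top_positive": top_pos,
        "top_negative": top_neg,
    }


def ubiquitination_comparison(
    groups: dict[str, set[str]],
    counts: pd.Series,
    min_group: int = 3,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Compare ubiquitination-site totals between protein groups.

    Proteins absent from ``counts`` are removed (not zero-filled).  Every
    group pair with at least ``min_group`` covered proteins per side is
    compared with a two-sided rank-sum test.

    Returns (per-group count arrays, long-format p-value table).
    """
    dists = {}
    for name, prots in groups.items():
        covered = sorted(p for p in prots if p in counts.index)
        dists[name] = counts.loc[covered].to_numpy(dtype=float)
    rows = []
    names = list(dists)
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            if len(dists[gi]) < min_group or len(dists[gj]) < min_group:
                warnings.warn(f"ubiquitination contrast {gi} vs {gj} under-populated; skipped")
                continue
            pooled = np.concatenate([dists[gi], dists[gj]])
            if np.ptp(pooled) == 0:
                p = 1.0
            else:
                p = float(
                    stats.mannwhitneyu(dists[gi], dists[gj], alternative="two-sided").pvalue
                )
            rows.append((gi, gj, p, float(np.median(dists[gi])), float(np.median(dists[gj]))))
    pmat = pd.DataFrame(rows, columns=["group_a", "group_b", "p", "median_a", "median_b"])
    return dists, pmat
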