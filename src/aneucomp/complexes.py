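"""Protein-complex membership analyses.

Houses the complex database container (GMT-backed) and the co-complex
association machinery: partner lookup, enrichment of partners among
differentially abundant proteins on non-aneuploid chromosomes, pooled
Spearman co-abundance correlations with the per-pair maximum rule, and
the promiscuity / co-occurrence / aggregation-propensity contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aneuploidy import chi2_2x2

PROMISCUITY_THRESHOLD = 5  # in more than this many complexes -> promiscuous


@dataclass
class ComplexDatabase:
    """Named protein complexes with functional-term annotations.

    ``complexes`` maps complex id -> subunit set (every complex has >= 2
    subunits); ``annotations`` maps complex id -> set of functional terms.
    A reverse membership index (protein -> complex ids) is kept in sync.
    """

    complexes: dict[str, frozenset[str]]
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for cid, subunits in self.complexes.items():
            subunits = frozenset(subunits)
            if len(subunits) < 2:
                raise ValueError(f"complex {cid} has fewer than 2 subunits")
            clean[cid] = subunits
        self.complexes = clean
        self.annotations = {cid: frozenset(self.annotations.get(cid, ())) for cid in clean}
        self._membership: dict[str, set[str]] = {}
        for cid, subunits in self.complexes.items():
            for prot in subunits:
                self._membership.setdefault(prot, set()).add(cid)

    def __len__(self) -> int:
        return len(self.complexes)

    def membership(self, protein: str) -> frozenset[str]:
        """Complex ids containing ``protein`` (empty if unknown)."""
        return frozenset(self._membership.get(protein, ()))

    @property
    def all_subunits(self) -> frozenset[str]:
        return frozenset(self._membership)

    def filtered(
        self, drop_proteins: set[str] = frozenset(), max_size: int | None = None
    ) -> "ComplexDatabase":
        """Copy with proteins removed and/or large complexes dropped.

        Complexes falling below 2 subunits after protein removal are dropped;
        ``max_size`` drops complexes whose *original* subunit count exceeds it.
        """
        out, ann = {}, {}
        for cid, subunits in self.complexes.items():
            if max_size is not None and len(subunits) > max_size:
                continue
            kept = subunits - drop_proteins
            if len(kept) >= 2:
                out[cid] = kept
                ann[cid] = self.annotations[cid]
        return ComplexDatabase(out, ann)

    # -- GMT I/O ----------------------------------------------------------
    @classmethod
    def from_gmt(cls, path) -> "ComplexDatabase":
        """Read a GMT file: complex id, semicolon-joined terms, subunits."""
        complexes, annotations = {}, {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: GMT line needs id, terms, >=2 subunits")
                cid, terms, subunits = parts[0], parts[1], parts[2:]
                if len(set(subunits)) < len(subunits):
                    warnings.warn(f"{path}:{lineno}: duplicate subunits in {cid} deduplicated")
                complexes[cid] = frozenset(subunits)
                annotations[cid] = frozenset(t for t in terms.split(";") if t)
        return cls(complexes, annotations)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for cid in sorted(self.complexes):
                terms = ";".join(sorted(self.annotations[cid]))
                subunits = "\t".join(sorted(self.complexes[cid]))
                fh.write(f"{cid}\t{terms}\t{subunits}\n")


def co_complex_partners(proteins: set[str], db: ComplexDatabase) -> set[str]:
    """All co-subunits of the input proteins, excluding the inputs themselves."""
    partners: set[str] = set()
    for prot in proteins:
        for cid in db.membership(prot):
            partners |= db.complexes[cid]
    return partners - set(proteins)


def promiscuity(protein: str, db: ComplexDatabase) -> str:
    """'promiscuous' if the protein is in more than five complexes."""
    return (
        "promiscuous"
        if len(db.membership(protein)) > PROMISCUITY_THRESHOLD
        else "non_promiscuous"
    )


def co_occurrence_frequency(a: str, b: str, db: ComplexDatabase) -> float:
    """Complexes containing both proteins over complexes containing either."""
    in_a, in_b = db.membership(a), db.membership(b)
    union = in_a | in_b
    if not union:
        raise ValueError(f"neither {a} nor {b} is in any complex")
    return len(in_a & in_b) / len(union)


def partner_enrichment_test(
    da_other: set[str],
    da_aneuploid: set[str],
    universe: set[str],
    db: ComplexDatabase,
) -> tuple[float, float] | None:
    """Association between partner status and differential abundance.

    2x2 chi-square over the universe of proteins quantified on non-aneuploid
    chromosomes: {differentially abundant} x {co-complex partner of the
    aneuploid differentially abundant set}.  Returns (standard residual of
    the DA-and-partner cell, p), or None when the test is undefined.
    """
    if not da_aneuploid:
        warnings.warn("empty aneuploid DA set; partner enrichment skipped")
        return None
    partners = co_complex_partners(da_aneuploid, db) & universe
    if not partners:
        warnings.warn("no co-complex partners in universe; partner enrichment skipped")
        return None
    return _set_association(da_other & universe, partners, universe)


def subunit_association_test(
    da_other: set[str], universe: set[str], db: ComplexDatabase
) -> tuple[float, float] | None:
    """Association between complex membership (any complex) and DA status."""
    subunits = db.all_subunits & universe
    if not subunits:
        warnings.warn("no complex subunits in universe; association skipped")
        return None
    return _set_association(da_other & universe, subunits, universe)


def _set_association(
    hits: set[str], feature: set[str], universe: set[str]
) -> tuple[float, float] | None:
    n = len(universe)
    a = len(hits & feature)
    b = len(hits - feature)
    c = len(feature - hits)
    d = n - a - b - c
    try:
        return chi2_2x2(np.array([[a, b], [c, d]], dtype=float))
    except ValueError:
        warnings.warn("degenerate association table; test skipped")
        return None


def abundance_correlations(
    pairs: list[tuple[str, str]],
    protein_by_cohort: dict[str, pd.DataFrame],
    min_samples: int = 3,
) -> pd.DataFrame:
    """Spearman co-abundance correlations per pair per cohort.

    ``protein_by_cohort`` maps cohort label -> proteins x samples matrix
    (NaN allowed).  Correlations use pairwise-complete samples with
    average-rank ties; pair-cohort rows with fewer than ``min_samples``
    complete observations or a constant vector are dropped.

    Returns a CorrelationTable: columns (aneuploid_protein, partner, cohort,
    rho, n_samples).
    """
    rows = []
    for cohort, mat in protein_by_cohort.items():
        for a, b in pairs:
            if a not in mat.index or b not in mat.index:
                continue
            x = mat.loc[a].to_numpy(dtype=float)
            y = mat.loc[b].to_numpy(dtype=float)
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < min_samples:
                continue
            xv, yv = x[ok], y[ok]
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                continue  # constant vector: correlation undefined
            rho = stats.spearmanr(xv, yv).statistic
            rows.append((a, b, cohort, float(rho), int(ok.sum())))
    return pd.DataFrame(
        rows, columns=["aneuploid_protein", "partner", "cohort", "rho", "n_samples"]
    )


def pool_correlations(table: pd.DataFrame, absolute_max: bool = False) -> pd.DataFrame:
    """Pool cohorts: keep one row per unordered pair, with the maximum rho.

    The default keeps the maximum *signed* rho across cohorts; with
    ``absolute_max`` the rho of largest magnitude is kept instead.
    """
    if table.empty:
        return table.copy()
    t = table.copy()
    t["_pair"] = [
        tuple(sorted((a, b)))
        for a, b in zip(t["aneuploid_protein"], t["partner"])
    ]
    key = t["rho"].abs() if absolute_max else t["rho"]
    idx = key.groupby(t["_pair"]).idxmax()
    return t.loc[idx.to_numpy()].drop(columns="_pair").reset_index(drop=True)


def compare_correlation_groups(
    table: pd.DataFrame, in_group_a, in_group_b
) -> tuple[float, float, float]:
    """Rank-sum comparison of rho between two row subsets.

    ``in_group_a``/``in_group_b`` are row predicates (callables on a row or
    boolean masks).  Returns (p, median_a, median_b); raises if either group
    has fewer than 3 rows.
    """
    mask_a = _as_mask(table, in_group_a)
    mask_b = _as_mask(table, in_group_b)
    rho_a = table.loc[mask_a, "rho"]
    rho_b = table.loc[mask_b, "rho"]
    if len(rho_a) < 3 or len(rho_b) < 3:
        raise ValueError(f"correlation groups too small ({len(rho_a)}, {len(rho_b)})")
    p = stats.mannwhitneyu(rho_a, rho_b, alternative="two-sided").pvalue
    return float(p), float(rho_a.median()), float(rho_b.median())


def _as_mask(table: pd.DataFrame, pred) -> pd.Series:
    if callable(pred):
        return table.apply(pred, axis=1).astype(bool)
    return pd.Series(np.asarray(pred, dtype=bool), index=table.index)


def co_occurrence_by_correlation_class(
    table: pd.DataFrame,
    db: ComplexDatabase,
    positive_threshold: float = 0.2,
    negative_threshold: float = -0.2,
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], float]]:
    """Co-occurrence frequency distributions per correlation class.

    Pairs are classed as positive (rho > ``positive_threshold``), negative
    (rho < ``negative_threshold``) or non_correlated (in between, inclusive).
    Returns per-class co-occurrence frequency arrays and rank-sum p-values
    for every class contrast with both sides non-empty.
    """
    freqs: dict[str, list[float]] = {"positive": [], "negative": [], "non_correlated": []}
    for _, row in table.iterrows():
        try:
            f = co_occurrence_frequency(row["aneuploid_protein"], row["partner"], db)
        except ValueError:
            continue
        if row["rho"] > positive_threshold:
            freqs["positive"].append(f)
        elif row["rho"] < negative_threshold:
            freqs["negative"].append(f)
        else:
            freqs["non_correlated"].append(f)
    dists = {k: np.asarray(v) for k, v in freqs.items()}
    pvals: dict[tuple[str, str], float] = {}
    names = list(dists)
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            if len(dists[gi]) == 0 or len(dists[gj]) == 0:
                continue
            if np.ptp(np.concatenate([dists[gi], dists[gj]])) == 0:
                pvals[(gi, gj)] = 1.0
                continue
            pvals[(gi, gj)] = float(
                stats.mannwhitneyu(dists[gi], dists[gj], alternative="two-sided").pvalue
            )
    return dists, pvals
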