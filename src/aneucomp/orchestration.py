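"""End-to-end pipeline over a cohort: aneuploidy calls to survival.

Stages run in method order: whole-chromosome calling and recurrence
detection, per-case differential expression/abundance, co-complex
association and correlation analyses, PPI randomization, regulatory-layer
attribution, functional-term enrichment, and the stoichiometry deviation
score with survival stratification.  Stage failures are recorded as skip
reasons, not fatal errors; all randomness derives from one seed via
per-stage child streams so stage order cannot silently change results.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aneuploidy as an
from . import complexes as cx
from . import expression as ex
from . import function as fn
from . import ppi as pp
from . import regulation as rg
from . import stoichiometry as st
from .synthetic_cohort import Cohort


@dataclass
class PipelineConfig:
    """Thresholds and sizes for a pipeline run (defaults follow the method)."""

    seed: int = 0
    case_alpha: float = 0.05  # Holm-adjusted p for recurrent aneuploidies
    min_residual: float = 2.0
    coamp_alpha: float = 0.01
    min_samples_per_type: int = 10
    min_group: int = 5  # smallest aneuploid/diploid group per case
    ppi_iterations: int = 1000
    tf_iterations: int = 100
    n_top_pairs: int = 30
    survival_permutations: int = 0  # naive log-rank p by default
    correlation_band: float = 0.2
    top_correlation: float = 0.4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj)
        if isinstance(obj, (set, frozenset)):
            items = sorted(items, key=str)
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> dict:
    """Run every analysis stage on a cohort and return the report dict."""
    config = config or PipelineConfig()
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("ppi", "tf", "survival"),
            np.random.SeedSequence(config.seed).spawn(3),
        )
    }
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config": asdict(config),
            "n_samples": int(cohort.samples.shape[0]),
            "n_genes": int(cohort.transcript.shape[0]),
            "n_proteins": int(cohort.protein.shape[0]),
        },
        "cases": {},
    }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _run_stages(cohort, config, streams, report)
    return _jsonable(report)


def _run_stages(cohort, config, streams, report):
    gene_chrom = cohort.annotation["chromosome"]
    cancer_type = cohort.samples["cancer_type"]

    # -- aneuploidy stage ---------------------------------------------------
    chrom_scores = an.chromosome_scores(cohort.arm_scores)
    cases = an.detect_recurrent(
        chrom_scores, cancer_type,
        alpha=config.case_alpha, min_residual=config.min_residual,
        min_samples_per_type=config.min_samples_per_type,
    )
    report["aneuploidy"] = {
        "n_cases": len(cases),
        "n_amplifications": sum(c.direction == 1 for c in cases),
        "n_deletions": sum(c.direction == -1 for c in cases),
        "cases": [
            {"cancer_type": c.cancer_type, "chromosome": c.chromosome,
             "direction": c.direction, "adj_p": c.adj_p,
             "std_residual": c.std_residual, "n_altered": c.n_altered}
            for c in cases
        ],
    }
    coamps = an.detect_coamplifications(chrom_scores, cases, cancer_type,
                                        alpha=config.coamp_alpha)
    report["aneuploidy"]["coamplifications"] = [
        {"case": case.label, "partner_chromosome": other, "adj_p": p}
        for case, other, p in coamps
    ]
    if not cases:
        report["skip_reason"] = "no recurrent aneuploidy detected"
        for stage in ("expression", "complexes", "ppi", "regulation",
                      "function", "stoichiometry"):
            report[stage] = {"status": "skipped", "reason": "no cases"}
        return

    # -- per-case differential expression / abundance -----------------------
    coamp_by_case = {}
    for case, other, _ in coamps:
        coamp_by_case.setdefault(case.label, set()).add(other)
    de_store: dict[str, dict] = {}
    contribution_rows, contribution_sets = [], []
    for case in cases:
        case_samples = cancer_type.index[cancer_type == case.cancer_type]
        entry: dict = {"case": case.label, "direction": case.direction}
        tmat = cohort.transcript[case_samples]
        split = ex.split_by_case(tmat, chrom_scores, case, min_group=config.min_group)
        if split is None:
            entry["status"] = "skipped"
            entry["reason"] = "group below minimum size"
            report["cases"][case.label] = entry
            continue
        de_t = ex.differential_test(
            tmat, split, "transcript",
            protein_coding=cohort.annotation["protein_coding"],
        )
        de_t = ex.locate_features(de_t, gene_chrom, case)
        entry["transcript"] = {
            "n_significant": int(de_t["significant"].sum()),
            "threshold_rule_used": de_t["threshold_rule_used"].iloc[0],
            "fraction_significant_by_location": ex.location_fractions(de_t),
            "group_sizes": [len(split[0]), len(split[1])],
        }
        pmat = cohort.protein[case_samples]
        psplit = ex.split_by_case(pmat, chrom_scores, case, min_group=config.min_group)
        de_p = None
        if psplit is not None:
            de_p = ex.differential_test(pmat, psplit, "protein")
            de_p = ex.locate_features(de_p, gene_chrom, case)
            entry["protein"] = {
                "n_significant": int(de_p["significant"].sum()),
                "fraction_significant_by_location": ex.location_fractions(de_p),
            }
        de_store[case.label] = {"case": case, "transcript": de_t, "protein": de_p,
                                "samples": list(case_samples)}
        report["cases"][case.label] = entry

        de_genes = set(de_t.index[de_t["significant"]])
        frac = an.chromosome_contribution(de_genes, gene_chrom)
        if case.label in coamp_by_case:
            co = coamp_by_case[case.label]
            others = set(frac.index) - co - {case.chromosome}
            contribution_rows.append(frac)
            contribution_sets.append((co, others))
    if contribution_rows:
        frac_df = pd.DataFrame(contribution_rows).fillna(0.0)
        p, diffs = an.compare_contributions(
            frac_df, [c for c, _ in contribution_sets], [o for _, o in contribution_sets]
        )
        report["aneuploidy"]["contribution_comparison"] = {
            "p": p, "n_cases": len(diffs), "median_diff": float(diffs.median())
            if len(diffs) else None,
        }

    # -- complexes stage -----------------------------------------------------
    db = cohort.complexes
    protein_by_type = cohort.protein_by_type()
    all_pairs: dict[int, set[tuple[str, str]]] = {1: set(), -1: set()}
    complexes_report = {"associations": []}
    for label, store in de_store.items():
        case, de_p = store["case"], store["protein"]
        if de_p is None:
            continue
        quantified = set(de_p.index)
        on_aneu = {g for g in quantified
                   if gene_chrom.get(g) == case.chromosome}
        universe = quantified - on_aneu
        da = de_p[de_p["significant"]]
        # direction-consistent aneuploid DA set: up for amplifications,
        # down for deletions
        da_aneuploid = {
            g for g in da.index
            if g in on_aneu and da.loc[g, "direction"] == case.direction
        }
        da_other = set(da.index) & universe
        assoc = {"case": label}
        res = cx.partner_enrichment_test(da_other, da_aneuploid, universe, db)
        assoc["partner_enrichment"] = (
            {"std_residual": res[0], "p": res[1]} if res else {"status": "skipped"}
        )
        res2 = cx.subunit_association_test(da_other, universe, db)
        assoc["subunit_association"] = (
            {"std_residual": res2[0], "p": res2[1]} if res2 else {"status": "skipped"}
        )
        if da_other:
            partners = cx.co_complex_partners(da_aneuploid, db) & universe
            assoc["partner_fraction_of_da_other"] = (
                len(da_other & partners) / len(da_other)
            )
        complexes_report["associations"].append(assoc)
        for a in sorted(da_aneuploid):
            for b in sorted(cx.co_complex_partners({a}, db) & universe):
                all_pairs[case.direction].add((a, b))

    corr_tables = []
    for direction, pair_set in all_pairs.items():
        if not pair_set:
            continue
        table = cx.abundance_correlations(sorted(pair_set), protein_by_type)
        if table.empty:
            continue
        pooled = cx.pool_correlations(table)
        pooled["direction"] = direction
        table["direction"] = direction
        corr_tables.append((direction, table, pooled))
    pooled_all = (
        pd.concat([p for _, _, p in corr_tables], ignore_index=True)
        if corr_tables else pd.DataFrame(
            columns=["aneuploid_protein", "partner", "cohort", "rho",
                     "n_samples", "direction"])
    )
    complexes_report["n_correlation_pairs"] = int(len(pooled_all))
    if not pooled_all.empty:
        agg = cohort.ground_truth.aggregation_prone
        for direction, name in ((1, "amplification"), (-1, "deletion")):
            sub = pooled_all[pooled_all["direction"] == direction]
            if sub.empty:
                continue
            block = {}
            try:
                p, m_in, m_out = cx.compare_correlation_groups(
                    sub,
                    sub["aneuploid_protein"].isin(agg),
                    ~sub["aneuploid_protein"].isin(agg),
                )
                block["aggregation_contrast"] = {
                    "p": p, "median_prone": m_in, "median_not_prone": m_out}
            except ValueError as exc:
                block["aggregation_contrast"] = {"status": f"skipped: {exc}"}
            promiscuous = sub["aneuploid_protein"].map(
                lambda g: cx.promiscuity(g, db) == "promiscuous")
            try:
                p, m_in, m_out = cx.compare_correlation_groups(
                    sub, promiscuous, ~promiscuous)
                block["promiscuity_contrast"] = {
                    "p": p, "median_promiscuous": m_in, "median_not": m_out}
            except ValueError as exc:
                block["promiscuity_contrast"] = {"status": f"skipped: {exc}"}
            _, co_p = cx.co_occurrence_by_correlation_class(
                sub, db, positive_threshold=config.correlation_band,
                negative_threshold=-config.correlation_band)
            block["co_occurrence_contrasts"] = {
                f"{a}_vs_{b}": p for (a, b), p in co_p.items()}
            complexes_report[name] = block
    report["complexes"] = complexes_report

    # -- PPI stage ------------------------------------------------------------
    ppi_report = []
    for label, store in de_store.items():
        case, de_p = store["case"], store["protein"]
        if de_p is None:
            continue
        da = de_p[de_p["significant"]]
        set_a = {g for g in da.index if gene_chrom.get(g) == case.chromosome}
        set_b = {g for g in da.index if gene_chrom.get(g) != case.chromosome}
        if not set_a or not set_b:
            ppi_report.append({"case": label, "status": "skipped",
                               "reason": "empty DA set"})
            continue
        try:
            obs, null, p = pp.degree_preserving_test(
                set_a, set_b, cohort.network,
                n_iter=config.ppi_iterations, seed=streams["ppi"],
            )
        except (ValueError, RuntimeError) as exc:
            ppi_report.append({"case": label, "status": f"skipped: {exc}"})
            continue
        interacting = {
            b for b in set_b if b in cohort.network
            and any(a in cohort.network.graph.adj[b] for a in set_a)
        }
        ppi_report.append({
            "case": label, "observed": obs, "null_mean": float(null.mean()),
            "p": p,
            "fraction_da_other_interacting": len(interacting) / len(set_b),
        })
    report["ppi"] = ppi_report

    # -- regulation stage ------------------------------------------------------
    reg_report = {"methylation": [], "tf_randomization": []}
    is_tf = cohort.annotation["is_tf"]
    for label, store in de_store.items():
        case, de_t = store["case"], store["transcript"]
        case_samples = store["samples"]
        split = ex.split_by_case(cohort.transcript[case_samples], chrom_scores, case,
                                 min_group=config.min_group)
        if split is None:
            continue
        aneuploid_samples, diploid_samples = split
        other = de_t["location"] == "other_chromosome"
        for reg_dir, dname in ((1, "upregulated"), (-1, "downregulated")):
            genes = set(de_t.index[other & (de_t["direction"] == reg_dir)])
            if not genes:
                continue
            try:
                p, shift = rg.methylation_shift_test(
                    cohort.methylation, cohort.promoter_map, genes,
                    aneuploid_samples, diploid_samples,
                )
            except ValueError as exc:
                reg_report["methylation"].append(
                    {"case": label, "genes": dname, "status": f"skipped: {exc}"})
                continue
            consistent = (reg_dir == -1 and shift > 0) or (reg_dir == 1 and shift < 0)
            reg_report["methylation"].append({
                "case": label, "genes": dname, "p": p, "median_shift": shift,
                "consistent": bool(consistent and p < 0.05),
            })
        de_tfs = {
            g for g in de_t.index[de_t["significant"]]
            if is_tf.get(g, False) and gene_chrom.get(g) == case.chromosome
        }
        de_other_genes = set(de_t.index[other & de_t["significant"]])
        res = rg.tf_target_randomization(
            cohort.tf_targets, de_tfs, de_other_genes,
            n_iter=config.tf_iterations, seed=streams["tf"],
        )
        res.pop("null", None)
        res["case"] = label
        reg_report["tf_randomization"].append(res)
    if not pooled_all.empty:
        groups = rg.correlation_groups_for_ubiquitination(
            pooled_all, db, set(cohort.protein.index),
            threshold=config.top_correlation,
        )
        dists, pmat = rg.ubiquitination_comparison(groups, cohort.ubiquitination)
        reg_report["ubiquitination"] = {
            "group_sizes": {k: len(v) for k, v in dists.items()},
            "group_medians": {k: float(np.median(v)) if len(v) else None
                              for k, v in dists.items()},
            "contrasts": pmat.to_dict(orient="records"),
        }
    report["regulation"] = reg_report

    # -- function stage ---------------------------------------------------------
    fn_report = []
    ribosomal = cohort.ground_truth.ribosomal_genes
    for direction, table, pooled in corr_tables:
        name = "amplification" if direction == 1 else "deletion"
        entry = {"cases": name}
        for variant in ("none", "drop_ribosomal", "drop_large_complexes"):
            try:
                terms = fn.run_case_enrichment(
                    pooled, db, variant=variant, ribosomal_proteins=ribosomal)
            except ValueError as exc:
                entry[variant] = {"status": f"skipped: {exc}"}
                continue
            entry[variant] = {
                "n_terms_tested": len(terms),
                "significant_terms": [
                    {"term": t.term, "enrichment_score": t.enrichment_score,
                     "p": t.p}
                    for t in terms if t.significant
                ],
            }
        base = fn.run_case_enrichment(pooled, db, variant="none",
                                      ribosomal_proteins=ribosomal)
        for variant in ("drop_ribosomal", "drop_large_complexes"):
            try:
                var_terms = fn.run_case_enrichment(
                    pooled, db, variant=variant, ribosomal_proteins=ribosomal)
                entry[f"concordance_{variant}"] = fn.concordance(base, var_terms)
            except ValueError:
                pass
        fn_report.append(entry)
    report["function"] = fn_report

    # -- stoichiometry stage ------------------------------------------------------
    sto_report = {}
    amp_pool = pooled_all[pooled_all["direction"] == 1] if not pooled_all.empty \
        else pd.DataFrame()
    states = cohort.ground_truth.chromosome_states
    for ctype, pmat in protein_by_type.items():
        entry: dict = {}
        try:
            # per-cohort strongest pairs, from per-cohort correlation rows
            cohort_rows = pd.concat(
                [t[t["cohort"] == ctype] for _, t, _ in corr_tables
                 if not t[t["cohort"] == ctype].empty],
                ignore_index=True,
            ) if corr_tables else pd.DataFrame()
            top = st.select_top30_pairs(cohort_rows, cohort=ctype,
                                        n_pairs=config.n_top_pairs)
            models = st.fit_pair_models(top, pmat)
            scores = st.deviation_scores(models, pmat)
        except ValueError as exc:
            sto_report[ctype] = {"status": f"skipped: {exc}"}
            continue
        entry["n_models"] = len(models)
        entry["n_scored_samples"] = int(len(scores))
        entry["score_summary"] = {
            "mean": float(scores["score"].mean()),
            "median": float(scores["score"].median()),
        }
        for endpoint in ("overall", "disease_free"):
            try:
                strat = st.survival_stratify(
                    scores, cohort.survival, endpoint=endpoint,
                    n_permutations=config.survival_permutations,
                    seed=streams["survival"],
                )
            except ValueError as exc:
                entry[endpoint] = {"status": f"skipped: {exc}"}
                continue
            median_t = float(cohort.survival.loc[
                cohort.survival["endpoint"] == endpoint, "time"].median())
            entry[endpoint] = {
                "cutpoint": strat.cutpoint,
                "n_low": len(strat.low_samples),
                "n_high": len(strat.high_samples),
                "logrank_p": strat.logrank_p,
                "adjusted_p": strat.adjusted_p,
                "low_minus_high_survival_at_median_followup": (
                    st.km_survival_at(strat.curves, "low", median_t)
                    - st.km_survival_at(strat.curves, "high", median_t)
                ),
            }
        try:
            deg = cohort.ground_truth.degradation_genes
            rho, p = st.degradation_correlation(scores, pmat, deg)
            entry["degradation_correlation"] = {
                "p": p,
                "median_rho_degradation": float(
                    rho[rho.index.isin(deg)].median()),
                "median_rho_all": float(rho.median()),
            }
        except ValueError as exc:
            entry["degradation_correlation"] = {"status": f"skipped: {exc}"}
        sto_report[ctype] = entry
    report["stoichiometry"] = sto_report


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


REQUIRED_STAGES = ("provenance", "aneuploidy", "cases")


def validate_report(report: dict) -> None:
    """Minimal structural validation of a pipeline report."""
    for key in REQUIRED_STAGES:
        if key not in report:
            raise ValueError(f"report missing required section {key!r}")
    if "skip_reason" not in report:
        for stage in ("expression", "complexes", "ppi", "regulation",
                      "function", "stoichiometry"):
            if stage not in report and not report["cases"]:
                raise ValueError(f"report missing stage {stage!r} without skip reason")
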