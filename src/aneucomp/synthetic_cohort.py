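"""Synthetic multi-omics cohort generator with recorded ground truth.

Emulates the data landscape of an aneuploid pan-cancer proteogenomic study:
per-sample arm-level aneuploidy calls with planted recurrent alterations,
a TPM transcript matrix with dosage effects on altered chromosomes, an
attenuated log-scale protein matrix with planted partner co-abundance,
a GMT complex database, an undirected PPI network, promoter methylation,
TF-target edges, ubiquitination-site counts, and survival times whose
hazard depends on a planted per-sample stoichiometry-deviation magnitude.

Every planted signal is recorded in a :class:`GroundTruth` object so each
downstream analysis stage has a recovery test.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aneuploidy import ACROCENTRIC, chromosome_scores
from .complexes import ComplexDatabase
from .ppi import InteractionNetwork

TERM_POOL = (
    "translation", "rna_splicing", "rna_processing", "complex_assembly",
    "metabolism", "transport", "signaling", "dna_repair", "cell_cycle",
    "chromatin", "proteolysis", "adhesion",
)
#: Functional term planted preferentially on complexes that contain a
#: compensated pair, so term-enrichment recovery is testable.
PLANTED_TERM = "proteostasis_core"


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults define the study conditions."""

    n_samples_per_type: int = 100
    n_cancer_types: int = 4
    n_genes: int = 1000
    n_chromosomes: int = 10
    planted_aneuploidies: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [("CT1", 1, +1, 0.6), ("CT2", 2, -1, 0.6)]
    )
    background_alteration_rate: float = 0.05
    dosage_effect: float = 1.0  # log2 fold change on transcripts
    attenuation: float = 0.5  # protein-level multiplier on the dosage effect
    compensation_rho: float = 0.6  # target partner Spearman correlation
    noise_sd_transcript: float = 0.5
    noise_sd_protein: float = 0.5
    n_complexes: int = 120
    complex_size_range: tuple[int, int] = (3, 8)
    n_ppi_edges: int = 2500
    n_tfs: int = 30
    targets_per_tf: int = 40
    frac_aggregation_prone: float = 0.10
    ubiq_rate_compensated: float = 6.0
    ubiq_rate_background: float = 2.0
    survival_hazard_ratio: float = 3.0
    seed: int = 0
    # secondary knobs
    n_pairs_per_case: int = 15  # compensated (aggregation-prone) pairs per case
    n_null_pairs_per_case: int = 15  # co-complex but uncorrelated pairs per case
    n_negative_pairs_per_case: int = 5  # co-complex anti-correlated pairs per case
    protein_detection_rate: float = 0.75
    protein_missing_rate: float = 0.10
    arm_conflict_rate: float = 0.02
    arm_missing_rate: float = 0.02
    frac_protein_coding: float = 0.90
    frac_ribosomal: float = 0.04
    n_degradation_genes: int = 25
    degradation_coupling: float = 1.0
    deviation_noise_scale: float = 1.5
    ubiq_dropout: float = 0.08

    def validate(self) -> None:
        if not 1 <= self.n_chromosomes <= 22:
            raise ConfigurationError("n_chromosomes must be in [1, 22]")
        for dim in ("n_samples_per_type", "n_cancer_types", "n_genes"):
            if getattr(self, dim) <= 0:
                raise ConfigurationError(f"{dim} must be positive")
        if self.n_genes < 4 * self.n_chromosomes:
            raise ConfigurationError("need at least 4 genes per chromosome")
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("complex_size_range must satisfy 2 <= lo <= hi")
        types = self.cancer_types()
        for ctype, chrom, direction, frac in self.planted_aneuploidies:
            if ctype not in types:
                raise ConfigurationError(f"planted aneuploidy in unknown type {ctype}")
            if not 1 <= chrom <= self.n_chromosomes:
                raise ConfigurationError(f"planted chromosome {chrom} out of range")
            if direction not in (-1, 1):
                raise ConfigurationError("planted direction must be -1 or +1")
            if not 0 < frac <= 1:
                raise ConfigurationError("carrier_fraction must be in (0, 1]")
            if frac <= self.background_alteration_rate:
                raise ConfigurationError(
                    "carrier_fraction must exceed background_alteration_rate"
                )

    def cancer_types(self) -> list[str]:
        return [f"CT{i + 1}" for i in range(self.n_cancer_types)]


@dataclass
class GroundTruth:
    """Planted signals recorded at generation time."""

    planted: list[tuple[str, int, int, float]]
    gene_chromosome: pd.Series
    compensated_pairs: pd.DataFrame  # cancer_type, chromosome, direction, aneuploid_protein, partner, target_rho, compensated
    aggregation_prone: set[str]
    deviation: pd.Series  # per-sample planted deviation magnitude in [0, 1]
    cancer_type: pd.Series
    degradation_genes: set[str]
    ribosomal_genes: set[str]
    chromosome_states: pd.DataFrame  # noise-free per-sample whole-chromosome states


@dataclass
class Cohort:
    """The full generated (or loaded) synthetic cohort."""

    arm_scores: pd.DataFrame  # samples x arms, NaN = missing
    transcript: pd.DataFrame  # genes x samples, TPM
    protein: pd.DataFrame  # proteins x samples, log scale, NaN allowed
    complexes: ComplexDatabase
    network: InteractionNetwork
    methylation: pd.DataFrame  # promoters x samples in [0, 1]
    promoter_map: dict[str, str]
    tf_targets: dict[str, set[str]]
    ubiquitination: pd.Series  # protein -> site count
    survival: pd.DataFrame  # sample, time, event, endpoint
    annotation: pd.DataFrame  # gene -> chromosome + flags
    samples: pd.DataFrame  # sample -> cancer_type, deviation
    ground_truth: GroundTruth
    config: CohortConfig | None = None

    def protein_by_type(self) -> dict[str, pd.DataFrame]:
        """Protein matrix split by cancer type (the per-cohort view)."""
        out = {}
        for ctype, sub in self.samples.groupby("cancer_type"):
            out[str(ctype)] = self.protein[sub.index]
        return out


def _spearman_to_pearson(rho: float) -> float:
    """Pearson r giving Spearman rho under a bivariate normal model."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a deterministic synthetic cohort from a configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = config.cancer_types()
    n_total = config.n_samples_per_type * config.n_cancer_types

    samples = [
        f"{ctype}-S{i + 1:03d}" for ctype in types for i in range(config.n_samples_per_type)
    ]
    cancer_type = pd.Series(
        [s.split("-")[0] for s in samples], index=samples, name="cancer_type"
    )
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    gene_chrom = pd.Series(
        [1 + i % config.n_chromosomes for i in range(config.n_genes)],
        index=genes, name="chromosome",
    )

    # --- chromosome states (noise-free truth) -----------------------------
    states = np.zeros((n_total, config.n_chromosomes), dtype=int)
    bg = rng.random(states.shape) < config.background_alteration_rate
    signs = rng.choice([-1, 1], size=states.shape)
    states[bg] = signs[bg]
    planted_mask = np.zeros(states.shape, dtype=bool)
    type_arr = cancer_type.to_numpy()
    for ctype, chrom, direction, frac in config.planted_aneuploidies:
        in_type = type_arr == ctype
        carriers = in_type & (rng.random(n_total) < frac)
        states[carriers, chrom - 1] = direction
        planted_mask[carriers, chrom - 1] = True
    chrom_states = pd.DataFrame(
        states, index=pd.Index(samples, name="sample"),
        columns=range(1, config.n_chromosomes + 1),
    )

    # --- arm scores with conflict/missing noise off the planted entries ---
    arm_cols: dict[str, np.ndarray] = {}
    for c in range(1, config.n_chromosomes + 1):
        q = states[:, c - 1].astype(float)
        if c in ACROCENTRIC:
            p = None
        else:
            p = q.copy()
            conflict = (rng.random(n_total) < config.arm_conflict_rate) & ~planted_mask[:, c - 1]
            if conflict.any():
                shift = rng.choice([-1, 1], size=n_total)
                p[conflict] = np.clip(q[conflict] + shift[conflict], -1, 1)
                same = conflict & (p == q)
                p[same] = np.clip(q[same] - 2 * np.sign(q[same] + 0.5), -1, 1)
        miss = (rng.random(n_total) < config.arm_missing_rate) & ~planted_mask[:, c - 1]
        if p is not None:
            pick_p = rng.random(n_total) < 0.5
            p = p.copy()
            p[miss & pick_p] = np.nan
            qq = q.copy()
            qq[miss & ~pick_p] = np.nan
            arm_cols[f"{c}p"] = p
            arm_cols[f"{c}q"] = qq
        else:
            qq = q.copy()
            qq[miss] = np.nan
            arm_cols[f"{c}q"] = qq
    arm_scores = pd.DataFrame(arm_cols, index=pd.Index(samples, name="sample"))

    # --- gene annotation flags --------------------------------------------
    coding = rng.random(config.n_genes) < config.frac_protein_coding
    ribosomal = rng.random(config.n_genes) < config.frac_ribosomal
    aggregation = rng.random(config.n_genes) < config.frac_aggregation_prone

    # --- planted compensated / null pairs ---------------------------------
    planted_chroms = {chrom for _, chrom, _, _ in config.planted_aneuploidies}
    pair_rows = []
    used: set[str] = set()
    gene_idx = {g: i for i, g in enumerate(genes)}
    for ctype, chrom, direction, _ in config.planted_aneuploidies:
        on_chrom = [g for g in genes if gene_chrom[g] == chrom and g not in used]
        off_chrom = [
            g for g in genes
            if gene_chrom[g] not in planted_chroms and g not in used
        ]
        n_comp = config.n_pairs_per_case
        n_null = config.n_null_pairs_per_case
        n_neg = config.n_negative_pairs_per_case
        need = n_comp + n_null + n_neg
        if len(on_chrom) < need or len(off_chrom) < need:
            raise ConfigurationError("not enough genes to plant pair sets")
        a_genes = list(rng.choice(on_chrom, size=need, replace=False))
        b_genes = list(rng.choice(off_chrom, size=need, replace=False))
        used.update(a_genes)
        used.update(b_genes)
        for k in range(need):
            if k < n_comp:
                pair_class, rho = "compensated", config.compensation_rho
            elif k < n_comp + n_null:
                pair_class, rho = "null", 0.0
            else:
                pair_class, rho = "negative", -config.compensation_rho
            pair_rows.append(
                (ctype, chrom, direction, a_genes[k], b_genes[k], rho, pair_class)
            )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["cancer_type", "chromosome", "direction", "aneuploid_protein",
                 "partner", "target_rho", "pair_class"],
    )
    pairs["compensated"] = pairs["pair_class"] == "compensated"
    # compensated aneuploid members are aggregation-prone; null ones are not
    for _, row in pairs.iterrows():
        aggregation[gene_idx[row["aneuploid_protein"]]] = bool(row["compensated"])

    # --- degradation machinery genes --------------------------------------
    pair_genes = set(pairs["aneuploid_protein"]) | set(pairs["partner"])
    deg_candidates = [
        g for g in genes
        if gene_chrom[g] not in planted_chroms and g not in pair_genes
    ]
    degradation = set(rng.choice(deg_candidates, size=config.n_degradation_genes,
                                 replace=False))

    # --- TFs ---------------------------------------------------------------
    tf_genes = list(rng.choice(
        [g for g in genes if g not in pair_genes], size=config.n_tfs, replace=False
    ))
    tf_targets = {
        tf: set(rng.choice([g for g in genes if g != tf],
                           size=config.targets_per_tf, replace=False))
        for tf in tf_genes
    }

    annotation = pd.DataFrame(
        {
            "chromosome": gene_chrom,
            "protein_coding": coding,
            "is_tf": [g in tf_genes for g in genes],
            "aggregation_prone": aggregation,
            "ribosomal": ribosomal,
            "degradation": [g in degradation for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )

    # --- per-sample planted deviation magnitude ----------------------------
    deviation = pd.Series(rng.uniform(0.0, 1.0, n_total), index=samples, name="deviation")
    noise_multiplier = 1.0 + config.deviation_noise_scale * deviation.to_numpy()
    m2 = float(np.mean(noise_multiplier**2))

    # --- transcript matrix (log2 latent -> TPM) ----------------------------
    base_t = rng.normal(5.0, 1.5, config.n_genes)
    state_per_gene = states[:, gene_chrom.to_numpy() - 1].T  # genes x samples
    log2_expr = (
        base_t[:, None]
        + config.dosage_effect * state_per_gene
        + rng.normal(0.0, config.noise_sd_transcript, (config.n_genes, n_total))
    )
    linear = np.power(2.0, log2_expr)
    transcript = pd.DataFrame(linear, index=pd.Index(genes, name="gene"),
                              columns=samples)
    transcript = transcript / transcript.sum(axis=0) * 1e6

    # --- protein matrix -----------------------------------------------------
    detected = rng.random(config.n_genes) < config.protein_detection_rate
    must_have = pair_genes | degradation
    detected |= np.array([g in must_have for g in genes])
    prot_genes = [g for g, d in zip(genes, detected) if d]
    prot_idx = {g: i for i, g in enumerate(prot_genes)}
    base_p = rng.normal(0.0, 1.0, len(prot_genes))
    state_pg = states[:, gene_chrom[prot_genes].to_numpy() - 1].T
    protein_vals = (
        base_p[:, None]
        + config.attenuation * config.dosage_effect * state_pg
        + rng.normal(0.0, config.noise_sd_protein, (len(prot_genes), n_total))
    )

    # planted partner co-abundance: heteroscedastic noise redistributes
    # residual variance toward high-deviation samples while keeping the
    # pooled correlation at its target
    for _, row in pairs.iterrows():
        a, b = row["aneuploid_protein"], row["partner"]
        av = protein_vals[prot_idx[a]]
        z_a = (av - av.mean()) / av.std()
        eps = rng.normal(0.0, 1.0, n_total) * noise_multiplier / math.sqrt(m2)
        r = _spearman_to_pearson(row["target_rho"])
        protein_vals[prot_idx[b]] = (
            base_p[prot_idx[b]]
            + config.noise_sd_protein * (r * z_a + math.sqrt(1.0 - r**2) * eps)
        )

    # degradation machinery tracks the planted deviation magnitude
    # (sorted: set iteration order must not steer the random stream)
    dev_centered = deviation.to_numpy() - 0.5
    for g in sorted(degradation):
        protein_vals[prot_idx[g]] = (
            base_p[prot_idx[g]]
            + config.degradation_coupling * dev_centered
            + rng.normal(0.0, 0.5 * config.noise_sd_protein, n_total)
        )

    missing = rng.random(protein_vals.shape) < config.protein_missing_rate
    protein_vals = np.where(missing, np.nan, protein_vals)
    protein = pd.DataFrame(protein_vals,
                           index=pd.Index(prot_genes, name="protein"),
                           columns=samples)

    # --- complex database ---------------------------------------------------
    lo, hi = config.complex_size_range
    complexes: dict[str, frozenset[str]] = {}
    annotations: dict[str, frozenset[str]] = {}
    cid = 0
    # planted pair complexes are dimers so each contributes exactly one
    # correlation pair downstream
    for _, row in pairs.iterrows():
        cid += 1
        members = frozenset([row["aneuploid_protein"], row["partner"]])
        complexes[f"CPX{cid:04d}"] = members
        terms = {PLANTED_TERM} if (row["compensated"] and rng.random() < 0.8) else set()
        terms |= set(rng.choice(TERM_POOL, size=int(rng.integers(1, 3)), replace=False))
        annotations[f"CPX{cid:04d}"] = frozenset(terms)
    while cid < config.n_complexes:
        cid += 1
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(prot_genes, size=size, replace=False))
        complexes[f"CPX{cid:04d}"] = members
        annotations[f"CPX{cid:04d}"] = frozenset(
            rng.choice(TERM_POOL, size=int(rng.integers(1, 4)), replace=False)
        )
    # promiscuity hubs: a few proteins inserted into many complexes; half
    # sit on planted chromosomes so promiscuous aneuploid proteins exist
    on_planted = [g for g in prot_genes if gene_chrom[g] in planted_chroms]
    hub_proteins = np.concatenate([
        rng.choice(on_planted, size=min(4, len(on_planted)), replace=False),
        rng.choice(prot_genes, size=4, replace=False),
    ])
    all_cids = sorted(complexes)
    for hub in hub_proteins:
        for target in rng.choice(all_cids, size=8, replace=False):
            complexes[target] = complexes[target] | {hub}
    db = ComplexDatabase(complexes, annotations)

    # --- PPI network ---------------------------------------------------------
    edges: set[tuple[str, str]] = set()
    n_prot = len(prot_genes)
    while len(edges) < config.n_ppi_edges:
        need = config.n_ppi_edges - len(edges)
        ii = rng.integers(0, n_prot, size=need * 2)
        jj = rng.integers(0, n_prot, size=need * 2)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            u, v = prot_genes[i], prot_genes[j]
            edges.add((u, v) if u < v else (v, u))
            if len(edges) >= config.n_ppi_edges:
                break
    # planted cross edges: every pair, plus extra aneuploid-to-partner edges
    case_groups = pairs.groupby(["cancer_type", "chromosome"])
    for _, grp in case_groups:
        a_list = list(grp["aneuploid_protein"])
        b_list = list(grp["partner"])
        for a, b in zip(a_list, b_list):
            edges.add((a, b) if a < b else (b, a))
        for _ in range(4 * len(a_list)):
            a = a_list[int(rng.integers(len(a_list)))]
            b = b_list[int(rng.integers(len(b_list)))]
            if a != b:
                edges.add((a, b) if a < b else (b, a))
    network = InteractionNetwork(sorted(edges))

    # --- methylation ---------------------------------------------------------
    promoter_map = {g: f"P|{g}" for g in genes}
    gene_meth_mean = rng.beta(2.0, 5.0, config.n_genes)
    meth_vals = np.clip(
        gene_meth_mean[:, None] + rng.normal(0.0, 0.05, (config.n_genes, n_total)),
        0.0, 1.0,
    )
    methylation = pd.DataFrame(
        meth_vals,
        index=pd.Index([promoter_map[g] for g in genes], name="promoter"),
        columns=samples,
    )

    # --- ubiquitination ------------------------------------------------------
    covered = rng.random(len(prot_genes)) >= config.ubiq_dropout
    rates = np.full(len(prot_genes), config.ubiq_rate_background)
    comp_partners = set(pairs.loc[pairs["compensated"], "partner"])
    for g in comp_partners:
        rates[prot_idx[g]] = config.ubiq_rate_compensated
        covered[prot_idx[g]] = True  # planted partners stay observable
    counts = rng.poisson(rates)
    ubiquitination = pd.Series(
        counts[covered],
        index=pd.Index([g for g, c in zip(prot_genes, covered) if c],
                       name="protein"),
        name="n_sites", dtype=int,
    )

    # --- survival ------------------------------------------------------------
    log_hr = math.log(config.survival_hazard_ratio)
    surv_frames = []
    for endpoint, base_median in (("overall", 36.0), ("disease_free", 24.0)):
        lam = math.log(2.0) / base_median * np.exp(log_hr * deviation.to_numpy())
        event_time = rng.exponential(1.0 / lam)
        censor_time = rng.uniform(24.0, 96.0, n_total)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
        surv_frames.append(pd.DataFrame({
            "sample": samples, "time": time, "event": event, "endpoint": endpoint,
        }))
    survival = pd.concat(surv_frames, ignore_index=True)

    sample_table = pd.DataFrame(
        {"cancer_type": cancer_type, "deviation": deviation},
        index=pd.Index(samples, name="sample"),
    )
    truth = GroundTruth(
        planted=list(config.planted_aneuploidies),
        gene_chromosome=gene_chrom,
        compensated_pairs=pairs,
        aggregation_prone=set(annotation.index[annotation["aggregation_prone"]]),
        deviation=deviation,
        cancer_type=cancer_type,
        degradation_genes=degradation,
        ribosomal_genes=set(annotation.index[annotation["ribosomal"]]),
        chromosome_states=chrom_states,
    )
    return Cohort(
        arm_scores=arm_scores,
        transcript=transcript,
        protein=protein,
        complexes=db,
        network=network,
        methylation=methylation,
        promoter_map=promoter_map,
        tf_targets=tf_targets,
        ubiquitination=ubiquitination,
        survival=survival,
        annotation=annotation,
        samples=sample_table,
        ground_truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Cohort directory I/O (TSV / GMT, round-trip safe)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory) -> None:
    """Write a cohort to a directory of TSV/GMT/YAML files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.arm_scores.rename_axis("sample").to_csv(d / "arm_scores.tsv", sep="\t",
                                                   na_rep="NA")
    cohort.transcript.rename_axis("gene").to_csv(d / "transcript_tpm.tsv", sep="\t")
    cohort.protein.rename_axis("protein").to_csv(d / "protein.tsv", sep="\t",
                                                 na_rep="NA")
    cohort.complexes.to_gmt(d / "complexes.gmt")
    cohort.network.to_edge_list(d / "ppi_edges.tsv")
    cohort.methylation.rename_axis("promoter").to_csv(d / "methylation.tsv", sep="\t")
    pd.Series(cohort.promoter_map, name="promoter").rename_axis("gene").to_csv(
        d / "promoter_map.tsv", sep="\t"
    )
    with open(d / "tf_targets.tsv", "w") as fh:
        fh.write("tf\ttarget\n")
        for tf in sorted(cohort.tf_targets):
            for target in sorted(cohort.tf_targets[tf]):
                fh.write(f"{tf}\t{target}\n")
    cohort.ubiquitination.rename_axis("protein").to_csv(d / "ubiquitination.tsv",
                                                        sep="\t")
    cohort.survival.to_csv(d / "survival.tsv", sep="\t", index=False)
    cohort.annotation.to_csv(d / "gene_annotation.tsv", sep="\t")
    cohort.samples.to_csv(d / "samples.tsv", sep="\t")
    truth = cohort.ground_truth
    pd.DataFrame(
        truth.planted,
        columns=["cancer_type", "chromosome", "direction", "carrier_fraction"],
    ).to_csv(d / "planted_aneuploidies.tsv", sep="\t", index=False)
    truth.compensated_pairs.to_csv(d / "compensated_pairs.tsv", sep="\t", index=False)
    truth.chromosome_states.rename_axis("sample").to_csv(
        d / "chromosome_states.tsv", sep="\t"
    )
    if cohort.config is not None:
        cfg = dataclasses.asdict(cohort.config)
        cfg["planted_aneuploidies"] = [list(p) for p in cfg["planted_aneuploidies"]]
        cfg["complex_size_range"] = list(cfg["complex_size_range"])
        with open(d / "cohort_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def read_cohort(directory) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    d = Path(directory)

    def matrix(name: str, index_name: str) -> pd.DataFrame:
        try:
            df = pd.read_csv(d / name, sep="\t", index_col=0, na_values=["NA"],
                             keep_default_na=False)
        except Exception as exc:  # noqa: BLE001 - reraise with file context
            raise ValueError(f"malformed file {d / name}: {exc}") from exc
        df.index.name = index_name
        return df

    arm_scores = matrix("arm_scores.tsv", "sample")
    transcript = matrix("transcript_tpm.tsv", "gene")
    protein = matrix("protein.tsv", "protein")
    methylation = matrix("methylation.tsv", "promoter")
    promoter_map = pd.read_csv(d / "promoter_map.tsv", sep="\t", index_col=0)[
        "promoter"
    ].to_dict()
    tf_df = pd.read_csv(d / "tf_targets.tsv", sep="\t", dtype=str)
    tf_targets: dict[str, set[str]] = {}
    for tf, target in tf_df.itertuples(index=False):
        tf_targets.setdefault(tf, set()).add(target)
    ubiq = pd.read_csv(d / "ubiquitination.tsv", sep="\t", index_col=0)["n_sites"]
    survival = pd.read_csv(d / "survival.tsv", sep="\t")
    annotation = pd.read_csv(d / "gene_annotation.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0)
    planted_df = pd.read_csv(d / "planted_aneuploidies.tsv", sep="\t")
    pairs = pd.read_csv(d / "compensated_pairs.tsv", sep="\t")
    db = ComplexDatabase.from_gmt(d / "complexes.gmt")
    network = InteractionNetwork.from_edge_list(d / "ppi_edges.tsv")

    config = None
    cfg_path = d / "cohort_config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = yaml.safe_load(fh)
        raw["planted_aneuploidies"] = [tuple(p) for p in raw["planted_aneuploidies"]]
        raw["complex_size_range"] = tuple(raw["complex_size_range"])
        config = CohortConfig(**raw)

    states_path = d / "chromosome_states.tsv"
    if states_path.exists():
        chrom_states = pd.read_csv(states_path, sep="\t", index_col=0)
        chrom_states.columns = chrom_states.columns.astype(int)
    else:
        chrom_states = chromosome_scores(arm_scores).fillna(0).astype(int)
    truth = GroundTruth(
        planted=[tuple(r) for r in planted_df.itertuples(index=False)],
        gene_chromosome=annotation["chromosome"],
        compensated_pairs=pairs,
        aggregation_prone=set(annotation.index[annotation["aggregation_prone"]]),
        deviation=samples["deviation"],
        cancer_type=samples["cancer_type"],
        degradation_genes=set(annotation.index[annotation["degradation"]]),
        ribosomal_genes=set(annotation.index[annotation["ribosomal"]]),
        chromosome_states=chrom_states,
    )
    return Cohort(
        arm_scores=arm_scores,
        transcript=transcript,
        protein=protein,
        complexes=db,
        network=network,
        methylation=methylation,
        promoter_map=promoter_map,
        tf_targets=tf_targets,
        ubiquitination=ubiq,
        survival=survival,
        annotation=annotation,
        samples=samples,
        ground_truth=truth,
        config=config,
    )
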