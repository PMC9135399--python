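"""Per-sample stoichiometry deviation score and its phenotypic correlates.

The top 30 strongest amplification-case correlation pairs define per-pair
ordinary-least-squares models (partner abundance regressed on aneuploid
protein abundance); a sample's stoichiometry deviation score is the mean
absolute residual over those models.  Samples are split at the maximally
selected log-rank cutpoint (exhaustive scan over the 10-90% score quantile
window) for Kaplan-Meier survival comparison, and the coupling between
deviation scores and degradation-machinery protein abundance is tested
against the all-protein background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

N_TOP_PAIRS = 30
QUANTILE_WINDOW = (0.10, 0.90)


@dataclass(frozen=True)
class PairModel:
    aneuploid_protein: str
    partner: str
    slope: float
    intercept: float
    n_fit: int


@dataclass
class StratifyResult:
    cutpoint: float
    low_samples: list[str]
    high_samples: list[str]
    statistic: float  # standardized log-rank statistic at the cutpoint
    logrank_p: float  # naive log-rank p at the selected cutpoint
    adjusted_p: float | None
    curves: pd.DataFrame = field(repr=False)


def select_top30_pairs(
    table: pd.DataFrame,
    cohort: str | None = None,
    n_pairs: int = N_TOP_PAIRS,
    absolute: bool = True,
) -> pd.DataFrame:
    """Top strongest amplification-case correlation pairs for a cohort.

    ``table`` must carry a ``direction`` column (+1 amplification rows are
    kept) and, when ``cohort`` is given, a ``cohort`` column.  Strength is
    |rho| by default (signed rho with ``absolute=False``); ties break on
    (aneuploid_protein, partner).  Returns all available pairs with a
    warning when fewer than ``n_pairs`` exist.
    """
    t = table
    if cohort is not None:
        t = t[t["cohort"] == cohort]
    if "direction" in t.columns:
        t = t[t["direction"] == 1]
    if t.empty:
        raise ValueError("no amplification-case correlation pairs available")
    strength = t["rho"].abs() if absolute else t["rho"]
    t = t.assign(_strength=strength).sort_values(
        ["_strength", "aneuploid_protein", "partner"], ascending=[False, True, True]
    )
    if len(t) < n_pairs:
        warnings.warn(f"only {len(t)} pairs available (requested {n_pairs})")
    return t.head(n_pairs).drop(columns="_strength").reset_index(drop=True)


def fit_pair_models(pairs: pd.DataFrame, protein: pd.DataFrame, min_samples: int = 3
                    ) -> list[PairModel]:
    """OLS fit per pair: partner abundance ~ aneuploid protein abundance.

    Fitting uses all cohort samples where both proteins are observed;
    pairs with a constant predictor or fewer than ``min_samples`` complete
    observations are skipped with a warning.
    """
    models = []
    for _, row in pairs.iterrows():
        a, b = row["aneuploid_protein"], row["partner"]
        if a not in protein.index or b not in protein.index:
            warnings.warn(f"pair ({a}, {b}) not in protein matrix; skipped")
            continue
        x = protein.loc[a].to_numpy(dtype=float)
        y = protein.loc[b].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < min_samples:
            warnings.warn(f"pair ({a}, {b}) has <{min_samples} complete samples; skipped")
            continue
        xv, yv = x[ok], y[ok]
        if np.ptp(xv) == 0:
            warnings.warn(f"pair ({a}, {b}) has constant predictor; skipped")
            continue
        slope, intercept = np.polyfit(xv, yv, 1)
        models.append(PairModel(a, b, float(slope), float(intercept), int(ok.sum())))
    return models


def deviation_scores(
    models: list[PairModel], protein: pd.DataFrame, min_model_fraction: float = 0.5
) -> pd.DataFrame:
    """Mean absolute regression residual per sample over the pair models.

    A sample's score averages |partner - (slope*aneuploid + intercept)|
    over the models for which both protein values are observed; samples
    covered by fewer than ``min_model_fraction`` of the models are excluded
    with a warning.
    """
    if not models:
        raise ValueError("no pair models provided")
    resid = np.full((len(models), protein.shape[1]), np.nan)
    for k, m in enumerate(models):
        x = protein.loc[m.aneuploid_protein].to_numpy(dtype=float)
        y = protein.loc[m.partner].to_numpy(dtype=float)
        resid[k] = np.abs(y - (m.slope * x + m.intercept))
    n_obs = (~np.isnan(resid)).sum(axis=0)
    enough = n_obs >= max(1, int(np.ceil(min_model_fraction * len(models))))
    if not enough.all():
        warnings.warn(f"{int((~enough).sum())} samples covered by too few models; excluded")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = np.nanmean(resid, axis=0)
    out = pd.DataFrame(
        {"score": score, "n_models": n_obs}, index=protein.columns
    ).loc[enough]
    return out


def _logrank_z(time: np.ndarray, event: np.ndarray, in_high: np.ndarray) -> float:
    """Standardized log-rank statistic for a two-group split (numpy)."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], in_high[order].astype(float)
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    # counts at risk just before each distinct time
    at_risk_total = n - start
    cum_g = np.concatenate([[0.0], np.cumsum(g)])
    at_risk_high = g.sum() - cum_g[start]
    # events at each distinct time, per group
    d_tot = np.add.reduceat(e.astype(float), start)
    d_high = np.add.reduceat(e * g, start)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = at_risk_high / at_risk_total
        expected = d_tot * frac
        var = d_tot * frac * (1 - frac) * (at_risk_total - d_tot) / (at_risk_total - 1)
    var = np.where(at_risk_total > 1, var, 0.0)
    v = np.nansum(var)
    if v <= 0:
        return 0.0
    return float((np.nansum(d_high) - np.nansum(expected)) / np.sqrt(v))


def maximally_selected_cutpoint(
    scores: pd.Series,
    time: pd.Series,
    event: pd.Series,
    quantile_window: tuple[float, float] = QUANTILE_WINDOW,
) -> tuple[float, float]:
    """Cutpoint maximizing the absolute standardized log-rank statistic.

    Candidate cutpoints are the observed score values within the quantile
    window; samples with score <= cutpoint form the low group.  Returns
    (cutpoint, standardized statistic at the cutpoint).
    """
    s = scores.to_numpy(dtype=float)
    t = time.to_numpy(dtype=float)
    e = event.to_numpy(dtype=float)
    lo, hi = np.quantile(s, quantile_window)
    candidates = np.unique(s[(s >= lo) & (s <= hi)])
    candidates = candidates[candidates < s.max()]  # both groups must be non-empty
    if len(candidates) == 0:
        raise ValueError("no valid cutpoint candidates (scores degenerate)")
    best_cut, best_z = None, 0.0
    for cut in candidates:
        z = _logrank_z(t, e, s > cut)
        if abs(z) > abs(best_z) or best_cut is None:
            best_cut, best_z = float(cut), z
    return best_cut, best_z


def survival_stratify(
    scores: pd.DataFrame,
    survival: pd.DataFrame,
    endpoint: str = "overall",
    min_samples: int = 20,
    min_event_fraction: float = 0.10,
    n_permutations: int = 0,
    seed: int | np.random.Generator = 0,
) -> StratifyResult:
    """Stratify samples at the maximally selected deviation-score cutpoint.

    Samples with score <= cutpoint form the low group.  Kaplan-Meier curves
    and the naive log-rank p are computed at the selected cutpoint; with
    ``n_permutations`` > 0 a selection-adjusted p is estimated by re-running
    the cutpoint scan on score-permuted data.
    """
    surv = survival[survival["endpoint"] == endpoint].set_index("sample")
    common = scores.index.intersection(surv.index)
    if len(common) < min_samples:
        raise ValueError(f"only {len(common)} samples with both score and survival")
    s = scores.loc[common, "score"]
    t = surv.loc[common, "time"]
    e = surv.loc[common, "event"]
    if s.nunique() == 1:
        raise ValueError("all deviation scores identical: no cutpoint")
    if e.mean() < min_event_fraction:
        raise ValueError(f"event fraction {e.mean():.2f} below {min_event_fraction}")

    cut, z = maximally_selected_cutpoint(s, t, e)
    low = s.index[s <= cut]
    high = s.index[s > cut]
    lr = logrank_test(t[low], t[high], event_observed_A=e[low], event_observed_B=e[high])
    curves = _km_curves({"low": (t[low], e[low]), "high": (t[high], e[high])})

    adjusted = None
    if n_permutations > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sv, tv, ev = s.to_numpy(), t.to_numpy(float), e.to_numpy(float)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(sv)
            try:
                _, z_perm = maximally_selected_cutpoint(pd.Series(perm), pd.Series(tv),
                                                        pd.Series(ev))
            except ValueError:
                continue
            if abs(z_perm) >= abs(z):
                hits += 1
        adjusted = (1 + hits) / (n_permutations + 1)

    return StratifyResult(
        cutpoint=cut,
        low_samples=list(low),
        high_samples=list(high),
        statistic=z,
        logrank_p=float(lr.p_value),
        adjusted_p=adjusted,
        curves=curves,
    )


def _km_curves(groups: dict[str, tuple[pd.Series, pd.Series]]) -> pd.DataFrame:
    frames = []
    for name, (t, e) in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e, label=name)
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        df["group"] = name
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def km_survival_at(curves: pd.DataFrame, group: str, time: float) -> float:
    """Step-function Kaplan-Meier survival of a group at a given time."""
    sub = curves[curves["group"] == group].sort_values("time")
    before = sub[sub["time"] <= time]
    return float(before["survival"].iloc[-1]) if len(before) else 1.0


def degradation_correlation(
    scores: pd.DataFrame,
    protein: pd.DataFrame,
    degradation_set: set[str],
    sample_subset: list[str] | None = None,
    min_samples: int = 5,
) -> tuple[pd.Series, float]:
    """Spearman coupling of protein abundance with deviation scores.

    Per protein, Spearman rho between its abundance and the deviation score
    across samples (optionally a carrier subset); the rho distribution of
    the degradation-machinery set is compared to that of all proteins with
    a two-sided rank-sum test.  Returns (per-protein rho, p).
    """
    if not degradation_set:
        raise ValueError("empty degradation protein set")
    samples = scores.index if sample_subset is None else pd.Index(sample_subset)
    samples = samples.intersection(protein.columns)
    sc = scores.loc[samples.intersection(scores.index), "score"]
    mat = protein[sc.index]
    rhos = {}
    sv = sc.to_numpy(dtype=float)
    for prot, row in mat.iterrows():
        x = row.to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < min_samples or np.ptp(x[ok]) == 0:
            continue
        rhos[prot] = float(stats.spearmanr(x[ok], sv[ok]).statistic)
    rho = pd.Series(rhos, dtype=float)
    deg = rho[rho.index.isin(degradation_set)]
    if deg.empty:
        raise ValueError("no degradation-set protein with computable correlation")
    p = float(stats.mannwhitneyu(deg, rho, alternative="two-sided").pvalue)
    return rho, p
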