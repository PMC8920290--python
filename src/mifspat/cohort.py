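"""Abundance × clustering grouping and survival association.

Per-sample abundance (% positive cells) and degree of spatial clustering
are categorised into five groups — ``None`` (no positive cells), then
``{L,H} × {L,H}`` for abundance and clustering levels — or, for
co-occurrence of two cell types, into ``AAN/APN/PAN/PPL/PPH``
(absent/present per type, then none/low/high clustering).  Cut-points are
chosen by a constrained optimal cut-point search: a 10-fold
cross-validated grid search maximising the multi-group log-rank statistic,
with every candidate required to leave at least ``min_group`` samples in
each nonzero-abundance group; the final cuts are the per-dimension medians
of the fold optima.  Survival association uses Cox proportional-hazards
models with age and stage covariates and a cluster-robust (sandwich)
variance over subjects, since subjects contribute up to three samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .cells_io import CellTable, phenotype_name
from .errors import InfeasibleCutpointError, MifspatError, NonNestedGroupingError
from .synthetic import UNIVARIATE_GROUPS

__all__ = [
    "abundance",
    "build_cohort",
    "assign_group_univariate",
    "assign_groups_univariate",
    "assign_group_bivariate",
    "assign_groups_bivariate",
    "coarsen_univariate",
    "coarsen_bivariate",
    "multigroup_logrank",
    "candidate_cutpoints",
    "feasible_candidates",
    "optimal_cutpoints_cv",
    "CutpointResult",
    "CoxFit",
    "fit_cox_groups",
    "LRTResult",
    "lrt_spatial_vs_abundance",
    "predicted_survival_curves",
]

BIVARIATE_GROUPS = ("AAN", "APN", "PAN", "PPL", "PPH")

_COARSE_UNI = {"None": "None", "LL": "Low", "LH": "Low", "HL": "High", "HH": "High"}
_COARSE_BI = {"AAN": "AAN", "APN": "APN", "PAN": "PAN", "PPL": "PP", "PPH": "PP"}


def abundance(table: CellTable, phenotype) -> float:
    """Percent of the sample's cells positive for the phenotype."""
    if table.n_cells < 1:
        raise ValueError("abundance undefined for an empty sample")
    return 100.0 * float(table.positive_mask(phenotype).sum()) / table.n_cells


def build_cohort(degree_df: pd.DataFrame, clinical_df: pd.DataFrame) -> pd.DataFrame:
    """Join per-sample degree rows to per-subject survival covariates."""
    missing = set(degree_df["subject_id"].astype(str)) - set(clinical_df["subject_id"].astype(str))
    if missing:
        raise MifspatError(f"samples reference subjects absent from the clinical table: {sorted(missing)[:5]}")
    out = degree_df.copy()
    out["subject_id"] = out["subject_id"].astype(str)
    clin = clinical_df.copy()
    clin["subject_id"] = clin["subject_id"].astype(str)
    return out.merge(clin, on="subject_id", validate="many_to_one")


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------


def assign_group_univariate(abundance_pct: float, degree: float, cuts) -> str:
    """Five-group label from abundance % and clustering degree.

    Zero abundance → ``None``; otherwise the first letter is the abundance
    level (≥ cut → H) and the second the clustering level (≥ cut → H).  An
    undefined degree (single positive cell) counts as Low clustering: one
    cell cannot exhibit clustering.
    """
    a_cut, d_cut = cuts
    if not (np.isfinite(a_cut) and np.isfinite(d_cut)):
        raise ValueError("cut-points must be finite")
    if abundance_pct == 0:
        return "None"
    a = "H" if abundance_pct >= a_cut else "L"
    c = "H" if (np.isfinite(degree) and degree >= d_cut) else "L"
    return a + c


def assign_groups_univariate(abundance_pct, degree, a_cut: float, d_cut: float) -> np.ndarray:
    """Vectorised :func:`assign_group_univariate`."""
    ab = np.asarray(abundance_pct, dtype=float)
    de = np.asarray(degree, dtype=float)
    a_high = ab >= a_cut
    d_high = np.isfinite(de) & (de >= d_cut)
    out = np.where(a_high, "H", "L").astype(object) + np.where(d_high, "H", "L")
    out[ab == 0] = "None"
    return out.astype(str)


def assign_group_bivariate(n1: int, n2: int, degree: float, d_cut: float) -> str:
    """Co-occurrence label: (A)bsent/(P)resent per type × (N)one/(L)ow/(H)igh.

    A type is present with at least one positive cell; the clustering level
    only exists when both types are present (bivariate K is estimable with
    one cell of each).
    """
    if n1 == 0 and n2 == 0:
        return "AAN"
    if n1 == 0:
        return "APN"
    if n2 == 0:
        return "PAN"
    return "PPH" if (np.isfinite(degree) and degree >= d_cut) else "PPL"


def assign_groups_bivariate(n1, n2, degree, d_cut: float) -> np.ndarray:
    """Vectorised :func:`assign_group_bivariate`."""
    return np.array(
        [assign_group_bivariate(a, b, d, d_cut) for a, b, d in zip(np.asarray(n1), np.asarray(n2), np.asarray(degree, dtype=float))]
    )


def coarsen_univariate(labels) -> np.ndarray:
    """Merge clustering levels: {None, LL+LH→Low, HL+HH→High}."""
    return np.array([_COARSE_UNI[g] for g in labels])


def coarsen_bivariate(labels) -> np.ndarray:
    """Merge clustering levels: PPL+PPH→PP; absence categories unchanged."""
    return np.array([_COARSE_BI[g] for g in labels])


# ---------------------------------------------------------------------------
# multi-group log-rank statistic (cut-point search objective)
# ---------------------------------------------------------------------------


def multigroup_logrank(time, event, labels) -> tuple[float, int, float]:
    """G-sample log-rank chi-square statistic.

    Returns ``(chi2, df, p)`` with df = G−1.  Used as the survival-curve
    separation objective in the cut-point grid search; an independent
    implementation (lifelines) cross-checks it in the test suite.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("log-rank needs at least two groups")
    uts = np.unique(time[event == 1])
    if uts.size == 0:
        raise ValueError("log-rank needs at least one event")
    at_risk = np.empty((len(uts), n_groups))
    events = np.empty((len(uts), n_groups))
    for g in range(n_groups):
        tg = np.sort(time[codes == g])
        at_risk[:, g] = len(tg) - np.searchsorted(tg, uts, side="left")
        te = np.sort(time[(codes == g) & (event == 1)])
        events[:, g] = np.searchsorted(te, uts, side="right") - np.searchsorted(te, uts, side="left")
    n_k = at_risk.sum(axis=1)
    d_k = events.sum(axis=1)
    p_gk = at_risk / n_k[:, None]
    expected = d_k[:, None] * p_gk
    u = (events - expected).sum(axis=0)
    c_k = d_k * (n_k - d_k) / np.maximum(n_k - 1.0, 1.0)
    cov = np.einsum("k,kg,kh->gh", c_k, p_gk, p_gk)
    cov = np.diag(np.einsum("k,kg->g", c_k, p_gk)) - cov
    df = n_groups - 1
    u_r = u[:-1]
    cov_r = cov[:-1, :-1]
    try:
        chi2 = float(u_r @ np.linalg.solve(cov_r, u_r))
    except np.linalg.LinAlgError:
        chi2 = float(u_r @ np.linalg.pinv(cov_r) @ u_r)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# constrained optimal cut-points by cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CutpointResult:
    """Cross-validated cut-points: per-dimension medians of fold optima."""

    abundance_cut: float
    degree_cut: float
    per_fold_optima: list
    trace: pd.DataFrame
    k_folds: int
    min_group: int


def candidate_cutpoints(values, max_candidates: int = 50) -> np.ndarray:
    """Candidate cuts: midpoints between consecutive unique observed values.

    Thinned to at most ``max_candidates`` by quantile subsampling so grid
    search stays tractable on large cohorts.
    """
    v = np.unique(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size < 2:
        return np.array([])
    mids = 0.5 * (v[:-1] + v[1:])
    if len(mids) > max_candidates:
        mids = np.unique(np.quantile(mids, np.linspace(0, 1, max_candidates), method="nearest"))
    return mids


def feasible_candidates(
    abundance_pct, degree, a_cands, d_cands, min_group: int
) -> np.ndarray:
    """Boolean (len(a_cands), len(d_cands)) feasibility matrix.

    A candidate pair is feasible when each of LL/LH/HL/HH holds at least
    ``min_group`` samples among nonzero-abundance samples (zero-abundance
    samples form the None group and do not constrain the grid).
    """
    ab = np.asarray(abundance_pct, dtype=float)
    de = np.asarray(degree, dtype=float)
    nz = ab > 0
    ab, de = ab[nz], de[nz]
    a_high = ab[None, :] >= np.asarray(a_cands)[:, None]  # (A, n)
    d_high = np.isfinite(de)[None, :] & (de[None, :] >= np.asarray(d_cands)[:, None])  # (D, n)
    a_high_f = a_high.astype(float)
    d_high_f = d_high.astype(float)
    hh = a_high_f @ d_high_f.T
    hl = a_high_f @ (1.0 - d_high_f).T
    lh = (1.0 - a_high_f) @ d_high_f.T
    ll = (1.0 - a_high_f) @ (1.0 - d_high_f).T
    return (hh >= min_group) & (hl >= min_group) & (lh >= min_group) & (ll >= min_group)


def optimal_cutpoints_cv(
    cohort: pd.DataFrame,
    k_folds: int = 10,
    min_group: int = 10,
    seed: int = 0,
    max_candidates: int = 50,
) -> CutpointResult:
    """Constrained optimal cut-points for abundance and clustering degree.

    Folds partition *subjects* (all samples of a subject share a fold, so a
    subject never informs the cuts applied to itself).  Within each fold's
    training set, every feasible candidate pair — both cuts drawn from the
    observed training values, constrained so each of LL/LH/HL/HH keeps at
    least ``min_group`` training samples — is scored by the 5-group
    log-rank chi-square, and the best pair wins the fold.  The returned
    cuts are the per-dimension medians of the fold optima.

    Raises
    ------
    InfeasibleCutpointError
        When a fold admits no candidate pair under the group-size
        constraint, naming the binding constraint.
    """
    required = {"subject_id", "abundance_pct", "degree", "time_months", "event"}
    if not required <= set(cohort.columns):
        raise ValueError(f"cohort is missing columns {sorted(required - set(cohort.columns))}")
    nonzero = cohort[cohort["abundance_pct"] > 0]
    if len(nonzero) < 4 * min_group:
        raise InfeasibleCutpointError(
            f"{len(nonzero)} nonzero-abundance samples cannot fill 4 groups of >= {min_group}"
        )
    rng = np.random.default_rng(seed)
    subjects = np.array(sorted(cohort["subject_id"].astype(str).unique()))
    folds = np.array_split(rng.permutation(subjects), k_folds)
    optima = []
    trace_rows = []
    for f, held_out in enumerate(folds):
        train = cohort[~cohort["subject_id"].astype(str).isin(held_out)]
        tr_nz = train[train["abundance_pct"] > 0]
        a_cands = candidate_cutpoints(tr_nz["abundance_pct"], max_candidates)
        d_cands = candidate_cutpoints(tr_nz["degree"], max_candidates)
        if a_cands.size == 0 or d_cands.size == 0:
            raise InfeasibleCutpointError(f"fold {f}: too few distinct training values to form candidates")
        ok = feasible_candidates(train["abundance_pct"], train["degree"], a_cands, d_cands, min_group)
        if not ok.any():
            raise InfeasibleCutpointError(
                f"fold {f}: no candidate pair keeps >= {min_group} training samples in each of LL/LH/HL/HH"
            )
        time = train["time_months"].to_numpy(dtype=float)
        event = train["event"].to_numpy(dtype=int)
        ab = train["abundance_pct"].to_numpy(dtype=float)
        de = train["degree"].to_numpy(dtype=float)
        best = None
        for ia, a_cut in enumerate(a_cands):
            for id_, d_cut in enumerate(d_cands):
                if not ok[ia, id_]:
                    continue
                labels = assign_groups_univariate(ab, de, a_cut, d_cut)
                chi2, _, _ = multigroup_logrank(time, event, labels)
                trace_rows.append({"fold": f, "abundance_cut": a_cut, "degree_cut": d_cut, "chi2": chi2})
                if best is None or chi2 > best[0]:
                    best = (chi2, float(a_cut), float(d_cut))
        optima.append((best[1], best[2]))
    return CutpointResult(
        abundance_cut=float(np.median([a for a, _ in optima])),
        degree_cut=float(np.median([d for _, d in optima])),
        per_fold_optima=optima,
        trace=pd.DataFrame(trace_rows),
        k_folds=k_folds,
        min_group=min_group,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards with clustered samples
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Cox PH fit of group labels with age/stage covariates.

    ``summary`` has one row per group (reference HR fixed at 1); the
    overall p-value is a robust Wald test of all group coefficients
    jointly.  The variance is the sandwich estimate clustered by subject.
    """

    summary: pd.DataFrame
    covariates: pd.DataFrame
    overall_p: float
    overall_df: int
    log_likelihood: float
    reference: str
    model: CoxPHFitter


def _design_matrix(cohort: pd.DataFrame, group_col: str, reference: str, group_order) -> tuple[pd.DataFrame, list, list]:
    df = pd.DataFrame(
        {
            "time_months": cohort["time_months"].to_numpy(dtype=float),
            "event": cohort["event"].to_numpy(dtype=int),
            "age_dx": cohort["age_dx"].to_numpy(dtype=float),
        }
    )
    stage_cols = []
    for s in ("II", "III", "IV"):
        col = f"stage_{s}"
        vals = (cohort["stage"].astype(str) == s).astype(float).to_numpy()
        if vals.any():
            df[col] = vals
            stage_cols.append(col)
    groups = cohort[group_col].astype(str).to_numpy()
    present = [g for g in group_order if g in set(groups)]
    for g in set(groups) - set(present):  # groups outside the canonical order
        present.append(g)
    if reference not in present:
        raise MifspatError(f"reference group {reference!r} has no samples")
    group_cols = []
    for g in present:
        if g == reference:
            continue
        col = f"group_{g}"
        df[col] = (groups == g).astype(float)
        group_cols.append(col)
    df["subject_id"] = cohort["subject_id"].astype(str).to_numpy()
    return df, group_cols, stage_cols


def _robust_covariance(fitter: CoxPHFitter, df: pd.DataFrame) -> pd.DataFrame:
    """Full cluster-robust (sandwich) covariance of a lifelines Cox fit.

    lifelines only exposes the sandwich variance through per-coefficient
    standard errors; the joint Wald test needs the full matrix, so this
    rebuilds it from the model's delta-beta residuals exactly as lifelines
    does for its own standard errors.
    """
    from lifelines.utils import normalize

    sp = fitter._model
    X, T, E, weights, *_ = sp._preprocess_dataframe(df)
    x_norm = pd.DataFrame(
        normalize(X.values, sp._norm_mean.values, sp._norm_std.values), index=X.index, columns=X.columns
    )
    vmat = sp._compute_sandwich_estimator(x_norm, T, E, weights)
    return pd.DataFrame(vmat, index=X.columns, columns=X.columns)


def fit_cox_groups(
    cohort: pd.DataFrame,
    group_col: str = "group",
    reference: str = "None",
    group_order=UNIVARIATE_GROUPS,
    robust: bool = True,
) -> CoxFit:
    """Cox PH model of overall survival on group labels.

    Per-sample rows with age (linear, years) and stage (I reference,
    dummies for II–IV); repeated samples per subject are handled with a
    cluster-robust sandwich variance.  The overall p-value is the Wald
    chi-square of all group coefficients (4 df with five populated groups).
    """
    if cohort[group_col].nunique() < 2:
        raise MifspatError("need at least two populated groups to fit a Cox model")
    if int(cohort["event"].sum()) == 0:
        raise MifspatError("no events in the cohort; Cox model is not identifiable")
    df, group_cols, _ = _design_matrix(cohort, group_col, reference, group_order)
    if not robust:
        df = df.drop(columns="subject_id")
    fitter = CoxPHFitter()
    fitter.fit(
        df,
        duration_col="time_months",
        event_col="event",
        cluster_col="subject_id" if robust else None,
    )
    counts = cohort[group_col].astype(str).value_counts()
    rows = [
        {
            "group": reference,
            "n_samples": int(counts.get(reference, 0)),
            "hr": 1.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
        }
    ]
    ci = fitter.confidence_intervals_
    for col in group_cols:
        g = col.removeprefix("group_")
        rows.append(
            {
                "group": g,
                "n_samples": int(counts.get(g, 0)),
                "hr": float(np.exp(fitter.params_[col])),
                "ci_low": float(np.exp(ci.loc[col].iloc[0])),
                "ci_high": float(np.exp(ci.loc[col].iloc[1])),
                "p": float(fitter.summary.loc[col, "p"]),
            }
        )
    beta = fitter.params_[group_cols].to_numpy()
    full_v = _robust_covariance(fitter, df) if robust else fitter.variance_matrix_
    vmat = full_v.loc[group_cols, group_cols].to_numpy()
    chi2 = float(beta @ np.linalg.solve(vmat, beta))
    overall_df = len(group_cols)
    covar_rows = []
    for col in fitter.params_.index:
        if col in group_cols:
            continue
        covar_rows.append(
            {
                "term": col,
                "hr": float(np.exp(fitter.params_[col])),
                "ci_low": float(np.exp(ci.loc[col].iloc[0])),
                "ci_high": float(np.exp(ci.loc[col].iloc[1])),
                "p": float(fitter.summary.loc[col, "p"]),
            }
        )
    return CoxFit(
        summary=pd.DataFrame(rows),
        covariates=pd.DataFrame(covar_rows),
        overall_p=float(stats.chi2.sf(chi2, overall_df)),
        overall_df=overall_df,
        log_likelihood=float(fitter.log_likelihood_),
        reference=reference,
        model=fitter,
    )


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of spatial vs abundance-only groupings."""

    statistic: float
    df: int
    p_value: float
    log_likelihood_full: float
    log_likelihood_reduced: float


def lrt_spatial_vs_abundance(
    cohort: pd.DataFrame,
    full_col: str = "group",
    coarse_col: str = "group_abundance",
    reference_full: str | None = None,
    reference_coarse: str | None = None,
    group_order_full=UNIVARIATE_GROUPS,
) -> LRTResult:
    """Does the clustering level add survival information beyond abundance?

    Compares unweighted Cox partial likelihoods of the full grouping (5
    levels) against the abundance-only coarsening (a likelihood ratio is
    undefined for sandwich-variance fits, so the robust clustering is set
    aside here); the statistic is referred to a chi-square with df equal to
    the difference in group indicator counts (2 for the univariate scheme).

    Raises
    ------
    NonNestedGroupingError
        If the coarse labels are not a deterministic function of the full
        labels.
    """
    full = cohort[full_col].astype(str)
    coarse = cohort[coarse_col].astype(str)
    mapping = cohort.groupby(full_col)[coarse_col].nunique()
    if (mapping > 1).any():
        raise NonNestedGroupingError("abundance-only labels are not a coarsening of the full labels")
    ref_full = reference_full if reference_full is not None else _pick_reference(full, group_order_full)
    coarse_order = list(dict.fromkeys(coarsen_univariate(group_order_full))) if set(coarse) <= set(
        _COARSE_UNI.values()
    ) else sorted(set(coarse))
    ref_coarse = reference_coarse if reference_coarse is not None else _pick_reference(coarse, coarse_order)
    fit_full = fit_cox_groups(cohort, full_col, reference=ref_full, group_order=group_order_full, robust=False)
    fit_red = fit_cox_groups(cohort, coarse_col, reference=ref_coarse, group_order=coarse_order, robust=False)
    df = fit_full.overall_df - fit_red.overall_df
    stat = max(0.0, 2.0 * (fit_full.log_likelihood - fit_red.log_likelihood))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(
        statistic=stat,
        df=df,
        p_value=p,
        log_likelihood_full=fit_full.log_likelihood,
        log_likelihood_reduced=fit_red.log_likelihood,
    )


def _pick_reference(labels: pd.Series, order) -> str:
    present = set(labels)
    for g in order:
        if g in present:
            return g
    return sorted(present)[0]


def predicted_survival_curves(fit: CoxFit, cohort: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Model-predicted survival curve per group at average covariate values.

    Returns a long table (group, time, survival) suitable for plotting.
    """
    model = fit.model
    design_cols = [c for c in model.params_.index]
    base = {c: 0.0 for c in design_cols}
    for c in design_cols:
        if not c.startswith("group_"):
            base[c] = float(np.mean(model._norm_mean.get(c, 0.0))) if hasattr(model, "_norm_mean") else 0.0
    # covariate averages from the cohort itself
    base["age_dx"] = float(cohort["age_dx"].mean())
    for s in ("II", "III", "IV"):
        col = f"stage_{s}"
        if col in base:
            base[col] = float((cohort["stage"].astype(str) == s).mean())
    groups = [fit.reference] + [c.removeprefix("group_") for c in design_cols if c.startswith("group_")]
    rows = []
    for g in groups:
        x = dict(base)
        for c in design_cols:
            if c.startswith("group_"):
                x[c] = 1.0 if c == f"group_{g}" else 0.0
        surv = model.predict_survival_function(pd.DataFrame([x]))
        rows.append(pd.DataFrame({"group": g, "time": surv.index.to_numpy(), "survival": surv.iloc[:, 0].to_numpy()}))
    return pd.concat(rows, ignore_index=True)
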