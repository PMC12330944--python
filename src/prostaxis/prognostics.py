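"""Survival screening and adverse-feature scoring.

Centerpiece is a stratified Cox proportional-hazards fit (separate baseline
hazard per study cohort, biopsy site as a covariate) used three ways: a
univariate screen of every pathway score with Benjamini-Hochberg control, a
joint multivariable model of the four composite axes, and screening of
per-gene hazard ratios. Group survival differences are summarized with
Kaplan-Meier curves and the log-rank test; matched pre-/on-treatment shifts
with the Wilcoxon signed-rank test (exact for small n); response-versus-
adverse-count association with the Cochran-Armitage trend test.

The cumulative adverse-feature score counts, per patient, how many of the
four composite axes fall in their unfavorable tertile: the bottom tertile of
the protective Luminal_AR axis, or the top tertile of the adverse
Proliferation, mTOR_glycolysis and NEPC axes. Counts are grouped 0 / 1-2 /
3-4 for survival stratification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "ConvergenceError",
    "CollinearityError",
    "cox_fit",
    "encode_site",
    "select_analysis_samples",
    "univariate_screen",
    "multivariable_fit",
    "km_logrank",
    "KMResult",
    "wilcoxon_signed_rank",
    "cochran_armitage_trend",
    "TrendResult",
    "adverse_feature_score",
    "AdverseFeatureProfile",
    "bh_adjust",
]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (e.g. monotone likelihood)."""


class CollinearityError(ValueError):
    """Design matrix is numerically rank-deficient."""


@dataclass
class CoxResult:
    """Per-term estimates from a stratified proportional-hazards fit."""

    summary: pd.DataFrame  # index=term: beta, hr, se, z, p (+ q after BH)
    loglik: float
    n: int
    n_events: int
    ties: str
    strata_col: str | None
    n_iter: int
    converged: bool

    def __getitem__(self, term: str) -> pd.Series:
        return self.summary.loc[term]


def _cox_loglik_derivs(beta, x, time, event, strata_codes, ties):
    """Log partial likelihood, gradient and negative Hessian (information).

    Efron tie handling adjusts the risk-set denominator for each of the d
    tied deaths by removing an l/d fraction of the tied deaths' weight;
    Breslow leaves the denominator whole. On tie-free data they coincide.
    """
    p = x.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    eta = x @ beta
    for s in np.unique(strata_codes):
        mask = strata_codes == s
        t, d, xs, es = time[mask], event[mask], x[mask], eta[mask]
        order = np.argsort(-t, kind="stable")
        t, d, xs, es = t[order], d[order], xs[order], es[order]
        w = np.exp(es)
        cw = np.cumsum(w)
        cxw = np.cumsum(xs * w[:, None], axis=0)
        cxxw = np.cumsum(xs[:, :, None] * xs[:, None, :] * w[:, None, None], axis=0)
        # risk set at an event time = all rows up to the last row sharing it
        end = np.searchsorted(-t, -t, side="right") - 1
        epos = np.flatnonzero(d)
        if epos.size == 0:
            continue
        gend = end[epos]
        uniq, counts = np.unique(gend, return_counts=True)
        ll += es[epos].sum()
        grad += xs[epos].sum(axis=0)
        # untied deaths: fully vectorized (Efron and Breslow coincide)
        single_groups = set(uniq[counts == 1])
        singles = np.array(
            [e for e, g in zip(epos, gend) if g in single_groups], dtype=int
        )
        if singles.size:
            g = end[singles]
            s0 = cw[g]
            mu = cxw[g] / s0[:, None]
            ll -= np.log(s0).sum()
            grad -= mu.sum(axis=0)
            info += (
                cxxw[g] / s0[:, None, None] - mu[:, :, None] * mu[:, None, :]
            ).sum(axis=0)
        # tied deaths: per-group Efron/Breslow denominators
        for g in uniq[counts > 1]:
            dead = epos[gend == g]
            nd = dead.size
            s0, s1, s2 = cw[g], cxw[g], cxxw[g]
            wd = w[dead]
            sd0 = wd.sum()
            sd1 = (xs[dead] * wd[:, None]).sum(axis=0)
            sd2 = (
                xs[dead][:, :, None] * xs[dead][:, None, :] * wd[:, None, None]
            ).sum(axis=0)
            fracs = (np.arange(nd) / nd) if ties == "efron" else np.zeros(nd)
            for f in fracs:
                z0 = s0 - f * sd0
                z1 = s1 - f * sd1
                mu = z1 / z0
                ll -= np.log(z0)
                grad -= mu
                info += (s2 - f * sd2) / z0 - np.outer(mu, mu)
    return ll, grad, info


def _check_collinearity(x: np.ndarray, terms: list[str]) -> None:
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    if (sd == 0).any():
        bad = [t for t, s in zip(terms, sd) if s == 0]
        raise CollinearityError(f"constant covariates: {bad}")
    xs = xc / sd
    cond = np.linalg.cond(xs.T @ xs)
    if cond > 1e8:
        corr = np.corrcoef(xs.T)
        pairs = [
            (terms[i], terms[j])
            for i in range(len(terms))
            for j in range(i + 1, len(terms))
            if abs(corr[i, j]) > 0.9999
        ]
        raise CollinearityError(
            f"design matrix ill-conditioned (cond={cond:.3g}); "
            f"near-duplicate terms: {pairs or 'none isolated'}"
        )


def cox_fit(
    d: pd.DataFrame,
    covariates: list[str],
    *,
    time_col: str = "time",
    event_col: str = "event",
    strata_col: str | None = "cohort",
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Fit a (possibly stratified) Cox model by Newton-Raphson.

    Strata get separate baseline hazards and contribute additively to the
    partial likelihood; strata without events are dropped with a warning.
    Wald standard errors come from the inverse observed information.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    cols = [time_col, event_col, *covariates] + ([strata_col] if strata_col else [])
    work = d[cols].dropna()
    x = work[covariates].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariates must be finite")
    time = work[time_col].to_numpy(dtype=float)
    event = work[event_col].to_numpy(dtype=int)
    if strata_col:
        codes, _ = pd.factorize(work[strata_col], sort=True)
    else:
        codes = np.zeros(len(work), dtype=int)
    # drop event-free strata: they contribute nothing to the likelihood
    keep = np.ones(len(work), dtype=bool)
    for s in np.unique(codes):
        if event[codes == s].sum() == 0:
            warnings.warn(f"stratum {s} has no events; dropped", stacklevel=2)
            keep &= codes != s
    x, time, event, codes = x[keep], time[keep], event[keep], codes[keep]
    if event.sum() == 0:
        raise ValueError("no events in the data; Cox model undefined")
    _check_collinearity(x, covariates)

    beta = np.zeros(len(covariates))
    ll, grad, info = _cox_loglik_derivs(beta, x, time, event, codes, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving to guarantee likelihood ascent
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, info_new = _cox_loglik_derivs(
                cand, x, time, event, codes, ties
            )
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise ConvergenceError("step-halving failed to increase likelihood")
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "coefficients diverging (monotone likelihood / perfect separation)"
            )
        if delta < tol or np.max(np.abs(grad)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    # a level with no events in its stratum can legitimately have a huge SE;
    # its upper confidence limit is then infinite
    with np.errstate(over="ignore"):
        ci_low = np.exp(beta - 1.959963984540054 * se)
        ci_high = np.exp(beta + 1.959963984540054 * se)
    summary = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": se,
            "z": z,
            "p": pvals,
            "ci_low": ci_low,
            "ci_high": ci_high,
        },
        index=pd.Index(covariates, name="term"),
    )
    return CoxResult(
        summary=summary,
        loglik=float(ll),
        n=int(len(time)),
        n_events=int(event.sum()),
        ties=ties,
        strata_col=strata_col,
        n_iter=it,
        converged=converged,
    )


def encode_site(site: pd.Series, prefix: str = "site") -> pd.DataFrame:
    """Dummy-code biopsy site with the most frequent site as reference."""
    counts = site.value_counts()
    ref = counts.index[0]
    levels = [l for l in sorted(site.unique()) if l != ref]
    out = pd.DataFrame(
        {f"{prefix}[{l}]": (site == l).astype(float) for l in levels},
        index=site.index,
    )
    return out


def select_analysis_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """One analysis sample per patient: earliest pre-treatment biopsy.

    Post-ASI timepoints (on-treatment, progression) are excluded first; the
    earliest remaining biopsy (smallest ``biopsy_order``) is retained.
    Patients left with no eligible sample are excluded with a logged reason.
    """
    eligible = meta[meta["timepoint"] == "pre"]
    dropped = set(meta["patient_id"]) - set(eligible["patient_id"])
    for pat in sorted(dropped):
        logger.info("patient %s excluded: no pre-treatment sample", pat)
    eligible = eligible.sort_values(["patient_id", "biopsy_order"], kind="stable")
    return eligible.groupby("patient_id", sort=True).head(1).reset_index(drop=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def univariate_screen(
    scores: pd.DataFrame,
    d: pd.DataFrame,
    *,
    alpha: float = 0.05,
    ties: str = "efron",
) -> pd.DataFrame:
    """Screen every pathway score for association with overall survival.

    One Cox fit per pathway: continuous score plus biopsy-site indicators,
    stratified by cohort. P-values are BH-adjusted across the full pathway
    family; ``significant`` flags adjusted p < alpha and ``direction``
    labels the hazard-ratio sign (favorable if HR < 1). Per-pathway fit
    failures are recorded in the ``error`` column, not raised.

    Parameters
    ----------
    scores
        Pathway-by-patient matrix (columns are patient ids).
    d
        Survival table indexed by patient id with columns
        ``time, event, site, cohort``.
    """
    patients = [p for p in scores.columns if p in d.index]
    if not patients:
        raise ValueError("no overlap between score columns and survival index")
    surv = d.loc[patients]
    site_dm = encode_site(surv["site"])
    rows = []
    for pathway in scores.index:
        frame = pd.concat(
            [
                surv[["time", "event", "cohort"]],
                site_dm,
                scores.loc[pathway, patients].rename("score").astype(float),
            ],
            axis=1,
        )
        try:
            res = cox_fit(
                frame,
                ["score", *site_dm.columns],
                strata_col="cohort",
                ties=ties,
            )
            term = res["score"]
            rows.append(
                dict(
                    pathway=pathway,
                    beta=term["beta"],
                    hr=term["hr"],
                    se=term["se"],
                    z=term["z"],
                    p=term["p"],
                    error="",
                )
            )
        except (ConvergenceError, CollinearityError, ValueError) as exc:
            logger.warning("screen failed for %s: %s", pathway, exc)
            rows.append(
                dict(
                    pathway=pathway,
                    beta=np.nan,
                    hr=np.nan,
                    se=np.nan,
                    z=np.nan,
                    p=np.nan,
                    error=str(exc),
                )
            )
    table = pd.DataFrame(rows).set_index("pathway")
    ok = table["p"].notna()
    table["q"] = np.nan
    table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"])
    table["significant"] = (table["q"] < alpha).fillna(False)
    table["direction"] = np.where(table["hr"] < 1, "favorable", "adverse")
    table.loc[~ok, "direction"] = ""
    return table


def multivariable_fit(
    composites: pd.DataFrame, d: pd.DataFrame, *, ties: str = "efron"
) -> CoxResult:
    """Joint Cox model of the composite axes plus biopsy site, cohort strata."""
    patients = [p for p in composites.columns if p in d.index]
    if not patients:
        raise ValueError("no overlap between composite columns and survival index")
    surv = d.loc[patients]
    site_dm = encode_site(surv["site"])
    frame = pd.concat(
        [surv[["time", "event", "cohort"]], site_dm, composites[patients].T], axis=1
    )
    return cox_fit(
        frame,
        [*composites.index, *site_dm.columns],
        strata_col="cohort",
        ties=ties,
    )


@dataclass
class KMResult:
    """Kaplan-Meier curves per group with the log-rank comparison."""

    curves: dict  # group label -> DataFrame(timeline, survival)
    medians: dict  # group label -> median survival (nan if not reached)
    chi2: float
    p: float
    df: int


def km_logrank(d: pd.DataFrame, groups: pd.Series) -> KMResult:
    """Product-limit curves per group and the k-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = groups.loc[d.index]
    labels = sorted(groups.dropna().unique().tolist())
    if len(labels) < 2:
        raise ValueError("log-rank comparison needs at least 2 groups")
    curves, medians = {}, {}
    for lab in labels:
        sub = d[groups == lab]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(lab))
        curves[lab] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(lab): "survival"}
        )
        medians[lab] = float(kmf.median_survival_time_)
    res = multivariate_logrank_test(d["time"], groups, d["event"])
    return KMResult(
        curves=curves,
        medians=medians,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        df=len(labels) - 1,
    )


def wilcoxon_signed_rank(
    paired_before, paired_after, *, exact_max_n: int = 12
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-sided p).

    Zero differences are dropped before ranking. For n <= ``exact_max_n``
    the exact two-sided p-value is computed by enumerating all 2^n sign
    assignments of the tie-averaged ranks; larger n uses the normal
    approximation with continuity correction.
    """
    before = np.asarray(paired_before, dtype=float)
    after = np.asarray(paired_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired vectors must have equal length")
    diff = after - before
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(diff))
    w_pos = float(ranks[diff > 0].sum())
    if n <= exact_max_n:
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        sums = bits @ ranks
        tol = 1e-9
        p_ge = np.mean(sums >= w_pos - tol)
        p_le = np.mean(sums <= w_pos + tol)
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        _, p = stats.wilcoxon(
            diff, correction=True, method="approx", alternative="two-sided"
        )
    return w_pos, float(p)


@dataclass
class TrendResult:
    z: float
    p: float
    p_perm: float | None = None
    table: pd.DataFrame | None = None


def cochran_armitage_trend(
    response,
    score,
    *,
    weights=None,
    n_perm: int = 0,
    seed: int | None = None,
) -> TrendResult:
    """Cochran-Armitage test for trend in response across ordinal scores.

    Ordinal weights default to the score levels themselves (the adverse
    counts 0-4). The statistic is the weighted difference between observed
    and expected responders, standardized under the hypergeometric null;
    the two-sided p comes from the standard normal. ``n_perm > 0`` adds a
    permutation p-value by reshuffling responses.
    """
    y = np.asarray(response, dtype=float)
    s = np.asarray(score, dtype=float)
    if y.shape != s.shape:
        raise ValueError("response and score must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("all responses identical; trend test undefined")
    levels = np.unique(s)
    if levels.size < 2:
        raise ValueError("need at least 2 distinct score levels")
    w_map = (
        dict(zip(levels, levels))
        if weights is None
        else dict(zip(levels, np.asarray(weights, dtype=float)))
    )
    w = np.array([w_map[v] for v in s])
    n_tot = y.size
    pbar = y.mean()
    num = float(np.sum(w * (y - pbar)))
    var = pbar * (1 - pbar) * (np.sum(w ** 2) - np.sum(w) ** 2 / n_tot)
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    p_perm = None
    if n_perm:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            count += abs(np.sum(w * (yp - pbar))) >= abs(num) - 1e-12
        p_perm = (1 + count) / (1 + n_perm)
    table = (
        pd.DataFrame({"score": s, "response": y})
        .groupby("score")["response"]
        .agg(n="size", responders="sum")
    )
    return TrendResult(z=float(z), p=float(p), p_perm=p_perm, table=table)


@dataclass
class AdverseFeatureProfile:
    """Per-patient adverse-feature flags, counts and groups.

    ``table`` holds, per patient, the four axis values, four boolean flags,
    the integer count 0-4 and the group label ("0", "1-2", "3-4");
    ``thresholds`` holds the q33/q67 tertile cutpoints per axis computed on
    the declared reference population.
    """

    table: pd.DataFrame
    thresholds: pd.DataFrame
    reference: list = field(default_factory=list)


def adverse_feature_score(
    composites: pd.DataFrame,
    reference_population=None,
    *,
    favorable_axis: str = "Luminal_AR",
    adverse_axes: tuple = ("Proliferation", "mTOR_glycolysis", "NEPC"),
) -> AdverseFeatureProfile:
    """Count unfavorable-tertile axes per patient.

    Tertile thresholds (empirical 1/3 and 2/3 quantiles, linear
    interpolation) are computed per axis over the reference population
    (default: all patients in ``composites``). A patient is flagged on the
    favorable axis when its value is <= q33, and on an adverse axis when
    >= q67 (boundaries inclusive toward the flagged side). The count of
    flags (0-4) maps to the groups "0", "1-2", "3-4".
    """
    axes = [favorable_axis, *adverse_axes]
    missing = [a for a in axes if a not in composites.index]
    if missing:
        raise ValueError(f"composite axes missing: {missing}")
    ref = (
        list(composites.columns)
        if reference_population is None
        else list(reference_population)
    )
    if len(ref) < 3:
        raise ValueError("reference population must contain at least 3 patients")
    q = composites.loc[axes, ref].quantile([1 / 3, 2 / 3], axis=1).T
    q.columns = ["q33", "q67"]
    table = composites.loc[axes].T.copy()
    flags = pd.DataFrame(index=table.index)
    flags[f"{favorable_axis}_low"] = table[favorable_axis] <= q.loc[favorable_axis, "q33"]
    for ax in adverse_axes:
        flags[f"{ax}_high"] = table[ax] >= q.loc[ax, "q67"]
    table = pd.concat([table, flags], axis=1)
    table["count"] = flags.sum(axis=1).astype(int)
    table["group"] = pd.Categorical(
        np.select(
            [table["count"] == 0, table["count"] <= 2],
            ["0", "1-2"],
            default="3-4",
        ),
        categories=["0", "1-2", "3-4"],
        ordered=True,
    )
    return AdverseFeatureProfile(table=table, thresholds=q, reference=ref)
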