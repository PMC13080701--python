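"""Subject-level inference for compound-HEP comparisons.

All inference operates on subject summaries (one value per subject per
comparison).  The toolbox mirrors a clinical-neurophysiology workflow on
unbalanced cohorts:

* single-pass 3-SD outlier exclusion;
* OLS/ANCOVA with seizure type and semiology as fixed factors and
  heart-rate change as a covariate (type-II sums of squares, robust to
  unbalanced cells);
* non-parametric subject-level bootstrap (2000 resamples, with replacement,
  stratified where applicable) giving empirical two-tailed p-values with
  the +1-smoothed estimator p = (1 + k) / (B + 1);
* classical paired t-tests for the tilt-table arm, judged at a
  Bonferroni-divided alpha (0.05/4 = 0.0125 for the four planned seizure
  contrasts; 0.05/6 ~ 0.0083 for the six symptom categories).

One-sample and two-sample bootstrap nulls are built by re-centering the
data to the null hypothesis before resampling, so the empirical p-value is
calibrated under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ModelSpec",
    "OLSFit",
    "exclude_outliers",
    "fit_ols",
    "bootstrap_test",
    "paired_symptom_test",
    "bonferroni_gate",
]

DEFAULT_RESAMPLES = 2000


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p_classical: float
    p_empirical: float | None
    n_resamples: int
    alpha: float
    significant: bool
    seed: int | None = None
    group_ns: tuple[int, ...] = ()
    boot_mean_stat: float | None = None
    degenerate: bool = False
    #: which p-value the significance flag is judged on
    criterion: str = "empirical"
    extra: dict = field(default_factory=dict)

    @property
    def p_decision(self) -> float:
        if self.criterion == "empirical" and self.p_empirical is not None:
            return self.p_empirical
        return self.p_classical

    def decide(self, alpha: float) -> "TestResult":
        """Re-judge significance at a (possibly Bonferroni-adjusted) alpha."""
        self.alpha = alpha
        self.significant = bool(np.isfinite(self.p_decision) and self.p_decision < alpha) or self.degenerate
        return self

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        d["group_ns"] = list(self.group_ns)
        d.update(self.extra)
        return d


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "hep_change_uv"
    fixed_factors: tuple[str, ...] = ("event_type", "semiology")
    covariates: tuple[str, ...] = ("hr_change_bpm",)
    strata: tuple[str, ...] = ("event_type", "semiology")

    def __post_init__(self) -> None:
        if not set(self.strata) <= set(self.fixed_factors):
            raise ValueError("strata must be a subset of fixed_factors")

    @property
    def formula(self) -> str:
        terms = [f"C({f})" for f in self.fixed_factors] + list(self.covariates)
        return f"{self.outcome} ~ " + " + ".join(terms)


@dataclass
class OLSFit:
    formula: str
    params: pd.Series
    anova: pd.DataFrame  # type-II F table
    residuals: np.ndarray
    fitted: np.ndarray
    n: int

    def term_f(self, term: str) -> tuple[float, float]:
        row = self.anova.loc[f"C({term})"] if f"C({term})" in self.anova.index else self.anova.loc[term]
        return float(row["F"]), float(row["PR(>F)"])


# ---------------------------------------------------------------------------
# Outlier gating
# ---------------------------------------------------------------------------

def exclude_outliers(values: np.ndarray, ids: list | None = None, z_max: float = 3.0):
    """Single-pass removal of values more than ``z_max`` SDs from the mean.

    Mean and SD are computed once from the full sample (sample SD, ddof=1);
    a zero-SD (all-equal) sample excludes nothing.  Returns the kept values
    and the excluded identifiers (indices when ``ids`` is None).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 3:
        raise ValueError("need at least 3 values for outlier exclusion")
    sd = v.std(ddof=1)
    if sd == 0:
        keep = np.ones(v.size, dtype=bool)
    else:
        keep = np.abs(v - v.mean()) <= z_max * sd
    ids = list(range(v.size)) if ids is None else list(ids)
    excluded = [i for i, k in zip(ids, keep) if not k]
    return v[keep], excluded


# ---------------------------------------------------------------------------
# OLS / ANCOVA
# ---------------------------------------------------------------------------

def fit_ols(summaries: pd.DataFrame, spec: ModelSpec) -> OLSFit:
    """OLS with fixed factors + covariates; type-II F per term.

    Raises on factors with < 2 observed levels and on rank-deficient
    designs, naming the aliased terms.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = summaries.dropna(subset=[spec.outcome, *spec.covariates]).copy()
    for f in spec.fixed_factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels in the data")
    model = smf.ols(spec.formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        aliased = [model.exog_names[i] for i in range(r.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    if res.ssr < 1e-12 and np.allclose(data[spec.outcome], 0):
        # Degenerate all-zero outcome: F is 0/0; report zeros explicitly.
        anova = pd.DataFrame(
            {"F": 0.0, "PR(>F)": 1.0},
            index=[f"C({f})" for f in spec.fixed_factors] + list(spec.covariates),
        )
    else:
        anova = anova_lm(res, typ=2)
    return OLSFit(
        formula=spec.formula,
        params=res.params,
        anova=anova,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        n=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# Bootstrap machinery
# ---------------------------------------------------------------------------

def _t_one_sample(v: np.ndarray) -> float:
    sd = v.std(ddof=1)
    if sd == 0:
        return 0.0 if v.mean() == 0 else np.inf * np.sign(v.mean())
    return float(v.mean() / (sd / np.sqrt(v.size)))


def _t_welch(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / denom)


def _empirical_p(null_stats: np.ndarray, observed: float) -> float:
    k = int(np.sum(np.abs(null_stats) >= abs(observed)))
    return (1 + k) / (null_stats.size + 1)


def bootstrap_test(
    values=None,
    *,
    kind: str = "one_sample",
    group: np.ndarray | None = None,
    summaries: pd.DataFrame | None = None,
    model: ModelSpec | None = None,
    term: str | None = None,
    n_resamples: int = DEFAULT_RESAMPLES,
    alpha: float = 0.05,
    seed: int = 0,
    name: str | None = None,
) -> TestResult:
    """Subject-level bootstrap test with an empirical two-tailed p-value.

    kinds:

    ``one_sample``
        mean of ``values`` vs 0.  Null resamples draw from the re-centered
        values (v - mean).
    ``two_sample``
        unpaired Welch t between the two levels of ``group``.  Each group is
        its own resampling stratum and is re-centered to its own mean for
        the null distribution.
    ``ols_F``
        type-II F of ``term`` in ``model`` fit to ``summaries``.  Cases are
        resampled with replacement within ``strata``; the reported
        ``boot_mean_stat`` is the mean resampled F, and the empirical
        p-value comes from resampling an outcome with the term's fitted
        effect removed (the null-transformed outcome).
    """
    rng = np.random.default_rng(seed)

    if kind == "one_sample":
        v = np.asarray(values, dtype=np.float64)
        if v.size < 2:
            raise ValueError("one_sample test needs n >= 2")
        t_obs = _t_one_sample(v)
        _, p_classical = sps.ttest_1samp(v, 0.0)
        centered = v - v.mean()
        idx = rng.integers(0, v.size, size=(n_resamples, v.size))
        draws = centered[idx]
        means = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(sds > 0, means / (sds / np.sqrt(v.size)), 0.0)
        p_emp = _empirical_p(t_null, t_obs)
        return TestResult(
            name=name or "one_sample_bootstrap_t",
            statistic=t_obs,
            df=v.size - 1,
            p_classical=float(p_classical),
            p_empirical=p_emp,
            n_resamples=n_resamples,
            alpha=alpha,
            significant=p_emp < alpha,
            seed=seed,
            group_ns=(v.size,),
        )

    if kind == "two_sample":
        v = np.asarray(values, dtype=np.float64)
        g = np.asarray(group)
        levels = pd.unique(g)
        if len(levels) != 2:
            raise ValueError("two_sample test needs exactly 2 groups")
        a, b = v[g == levels[0]], v[g == levels[1]]
        if min(a.size, b.size) < 2:
            raise ValueError("each stratum needs n >= 2")
        t_obs = _t_welch(a, b)
        _, p_classical = sps.ttest_ind(a, b, equal_var=False)
        ca, cb = a - a.mean(), b - b.mean()
        ia = rng.integers(0, a.size, size=(n_resamples, a.size))
        ib = rng.integers(0, b.size, size=(n_resamples, b.size))
        da, db = ca[ia], cb[ib]
        va = da.var(axis=1, ddof=1) / a.size
        vb = db.var(axis=1, ddof=1) / b.size
        denom = np.sqrt(va + vb)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(denom > 0, (da.mean(axis=1) - db.mean(axis=1)) / denom, 0.0)
        p_emp = _empirical_p(t_null, t_obs)
        return TestResult(
            name=name or "two_sample_bootstrap_t",
            statistic=t_obs,
            df=a.size + b.size - 2,
            p_classical=float(p_classical),
            p_empirical=p_emp,
            n_resamples=n_resamples,
            alpha=alpha,
            significant=p_emp < alpha,
            seed=seed,
            group_ns=(a.size, b.size),
        )

    if kind == "ols_F":
        if summaries is None or model is None or term is None:
            raise ValueError("ols_F requires summaries, model and term")
        data = summaries.dropna(subset=[model.outcome, *model.covariates]).reset_index(drop=True)
        fit = fit_ols(data, model)
        f_obs, p_classical = fit.term_f(term)

        strat = (
            data[list(model.strata)].astype(str).agg("|".join, axis=1).to_numpy()
            if model.strata
            else np.zeros(len(data), dtype=int)
        )
        if pd.Series(strat).value_counts().min() < 2:
            raise ValueError("each stratum needs n >= 2")
        groups = {s: np.nonzero(strat == s)[0] for s in pd.unique(strat)}

        # Null-transformed outcome: subtract the term's fitted contribution.
        reduced = ModelSpec(
            outcome=model.outcome,
            fixed_factors=tuple(f for f in model.fixed_factors if f != term),
            covariates=model.covariates,
            strata=(),
        )
        if reduced.fixed_factors:
            fit_red = fit_ols(data, reduced)
            null_outcome = data[model.outcome].to_numpy() - (fit.fitted - fit_red.fitted)
        else:
            # term is the only factor: null = covariate-only fit + residuals
            import statsmodels.formula.api as smf

            rhs = " + ".join(model.covariates) if model.covariates else "1"
            res_red = smf.ols(f"{model.outcome} ~ {rhs}", data=data).fit()
            null_outcome = data[model.outcome].to_numpy() - (fit.fitted - np.asarray(res_red.fittedvalues))

        f_boot = np.empty(n_resamples)
        f_null = np.empty(n_resamples)
        data_null = data.copy()
        data_null[model.outcome] = null_outcome
        for b in range(n_resamples):
            take = np.concatenate([idx[rng.integers(0, idx.size, size=idx.size)] for idx in groups.values()])
            try:
                f_boot[b] = fit_ols(data.iloc[take], model).term_f(term)[0]
            except ValueError:
                f_boot[b] = np.nan
            try:
                f_null[b] = fit_ols(data_null.iloc[take], model).term_f(term)[0]
            except ValueError:
                f_null[b] = np.nan
        f_null_ok = f_null[np.isfinite(f_null)]
        p_emp = (1 + int(np.sum(f_null_ok >= f_obs))) / (f_null_ok.size + 1)
        return TestResult(
            name=name or f"ols_F_{term}",
            statistic=f_obs,
            df=np.nan,
            p_classical=float(p_classical),
            p_empirical=p_emp,
            n_resamples=n_resamples,
            alpha=alpha,
            significant=p_emp < alpha,
            seed=seed,
            group_ns=tuple(len(v) for v in groups.values()),
            boot_mean_stat=float(np.nanmean(f_boot)),
        )

    raise ValueError(f"unknown test kind {kind!r}")


def paired_symptom_test(
    pre: np.ndarray,
    base: np.ndarray,
    alpha: float = 0.05 / 6,
    name: str = "paired_symptom_t",
) -> TestResult:
    """Classical paired t-test of pre-symptom vs baseline subject values.

    A zero-variance nonzero difference (every subject shifted identically)
    is degenerate for the t statistic; it is flagged and treated as
    significant (p below any alpha), matching the intuition that an exact
    constant shift is maximal evidence.
    """
    pre = np.asarray(pre, dtype=np.float64)
    base = np.asarray(base, dtype=np.float64)
    if pre.shape != base.shape:
        raise ValueError("pre and base must be matched per subject")
    if pre.size < 2:
        raise ValueError("paired test needs n >= 2")
    d = pre - base
    if d.std(ddof=1) <= 1e-9 * max(abs(float(d.mean())), 1.0):
        if d.mean() == 0:
            return TestResult(name, 0.0, pre.size - 1, 1.0, None, 0, alpha, False,
                              group_ns=(pre.size,), criterion="classical")
        return TestResult(
            name, np.inf * np.sign(d.mean()), pre.size - 1, 0.0, None, 0, alpha, True,
            group_ns=(pre.size,), degenerate=True, criterion="classical",
        )
    t, p = sps.ttest_rel(pre, base)
    return TestResult(
        name=name,
        statistic=float(t),
        df=pre.size - 1,
        p_classical=float(p),
        p_empirical=None,
        n_resamples=0,
        alpha=alpha,
        significant=float(p) < alpha,
        group_ns=(pre.size,),
        criterion="classical",
    )


def bonferroni_gate(results: list[TestResult], family_size: int, base_alpha: float = 0.05) -> list[TestResult]:
    """Recompute significance at alpha = base_alpha / family_size."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    adj = base_alpha / family_size
    return [r.decide(adj) for r in results]
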