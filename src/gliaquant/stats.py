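"""Statistical layer: dose–response regressions, group comparisons, mixed
models and exact set-overlap tests.

Regressions and group tests wrap statsmodels/scipy. The multi-set
intersection test is the exact law of the common intersection of m
independent uniformly drawn fixed-size subsets of an N-element background:
conditioning on the running intersection, the overlap with each further
independent subset is hypergeometric, so the pmf is obtained by iterated
hypergeometric convolution — identical to the inclusion–exclusion closed
form but numerically stable at N in the tens of thousands. At m = 2 it
reduces exactly to the hypergeometric distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class RegressionResult:
    params: dict
    se: dict
    pvalues: dict
    r_squared: float
    n: int

    @property
    def slope(self) -> float:
        keys = [k for k in self.params if k not in ("const", "Intercept")]
        return self.params[keys[0]]

    @property
    def intercept(self) -> float:
        for k in ("const", "Intercept"):
            if k in self.params:
                return self.params[k]
        raise KeyError("no intercept term")


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    flags: list = field(default_factory=list)


@dataclass
class MixedModelSpec:
    response: str
    fixed_effects: list
    group: str                      # random-intercept grouping factor
    family: str = "gaussian"        # or "binomial"
    log_response: bool = False

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")


@dataclass
class MixedModelResult:
    params: dict
    se: dict
    pvalues: dict
    random_intercept_var: float
    residual_quantiles: np.ndarray | None = None
    converged: bool = True


@dataclass
class MultiSetTestResult:
    background_size: int
    set_sizes: tuple
    observed_intersection: int
    pmf: np.ndarray        # over intersection sizes 0..min(set_sizes)
    tail_p: float          # P(X >= k)
    p_adjusted: float


def _wrap_ols(res) -> RegressionResult:
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)
    if not np.isfinite(r2):  # constant response: no variance to explain
        r2 = 0.0
    return RegressionResult(params=dict(res.params), se=dict(res.bse),
                            pvalues=dict(res.pvalues),
                            r_squared=r2,
                            n=int(res.nobs))


def ols_fit(x, y) -> RegressionResult:
    """Simple linear regression y ~ x with a two-sided t-test on the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    X = sm.add_constant(pd.Series(x, name="x"))
    return _wrap_ols(sm.OLS(y, X).fit())


def multiple_regression(y, treatment, covariate) -> RegressionResult:
    """y ~ treatment + covariate; the treatment coefficient is the adjusted
    group contrast (confounder-adjusted comparison)."""
    y = np.asarray(y, float)
    X = pd.DataFrame({"treatment": np.asarray(treatment, float),
                      "covariate": np.asarray(covariate, float)})
    if X["treatment"].nunique() < 2 or X["covariate"].nunique() < 2:
        raise ValueError("both predictors must vary")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("collinear design matrix")
    return _wrap_ols(sm.OLS(y, Xc).fit())


def anova_tukey(groups: list, labels=None) -> GroupComparisonResult:
    """One-way ANOVA with Tukey's studentized-range pairwise comparisons."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    flags = [f"group {i} has zero variance and n = 2"
             for i, g in enumerate(groups)
             if len(g) == 2 and np.ptp(g) == 0]
    f, p = sps.f_oneway(*groups)
    labels = labels or [f"g{i}" for i in range(len(groups))]
    vals = np.concatenate([np.asarray(g, float) for g in groups])
    labs = np.concatenate([[labels[i]] * len(g) for i, g in enumerate(groups)])
    tk = pairwise_tukeyhsd(vals, labs)
    pair = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return GroupComparisonResult(test="anova_tukey", statistic=float(f),
                                 p_value=float(p), pairwise=pair, flags=flags)


def unpaired_t(a, b, welch: bool = False) -> GroupComparisonResult:
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                         equal_var=not welch)
    return GroupComparisonResult(test="welch_t" if welch else "t",
                                 statistic=float(t), p_value=float(p))


def fit_mixed_model(spec: MixedModelSpec, table: pd.DataFrame
                    ) -> MixedModelResult:
    """Random-intercept mixed model.

    gaussian: linear mixed model by REML (Wald z for fixed-effect p);
    binomial: random-intercept logistic fit (variational Bayes posterior,
    p from the posterior z-score). Residual quantiles are returned for Q-Q
    normality checks of the gaussian fit.
    """
    df = table.copy()
    if df[spec.group].nunique() < 2:
        raise ValueError("grouping factor needs >= 2 levels")
    resp = spec.response
    if spec.log_response:
        df["_resp"] = np.log(df[resp])
        resp = "_resp"
    fixed = " + ".join(spec.fixed_effects) if spec.fixed_effects else "1"
    if spec.family == "gaussian":
        model = smf.mixedlm(f"{resp} ~ {fixed}", df, groups=df[spec.group])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        re_var = float(res.cov_re.iloc[0, 0])
        resid = np.sort(np.asarray(res.resid))
        fe = res.fe_params.index
        return MixedModelResult(
            params={k: float(res.params[k]) for k in fe},
            se={k: float(res.bse[k]) for k in fe},
            pvalues={k: float(res.pvalues[k]) for k in fe},
            random_intercept_var=re_var,
            residual_quantiles=resid,
            converged=bool(res.converged))
    # binomial random-intercept logistic
    vc = {"re": f"0 + C({spec.group})"}
    model = BinomialBayesMixedGLM.from_formula(f"{resp} ~ {fixed}", vc, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_vb()
    k = model.k_fep
    names = list(res.model.exog_names[:k])
    means = res.fe_mean[:k]
    sds = res.fe_sd[:k]
    pz = 2.0 * sps.norm.sf(np.abs(means / sds))
    re_sd = float(np.exp(res.vcp_mean[0]))
    return MixedModelResult(
        params=dict(zip(names, map(float, means))),
        se=dict(zip(names, map(float, sds))),
        pvalues=dict(zip(names, map(float, pz))),
        random_intercept_var=re_sd**2,
        residual_quantiles=None,
        converged=True)


def multiset_intersection_pmf(N: int, set_sizes) -> np.ndarray:
    """Exact pmf of the common-intersection size of m independent uniform
    fixed-size subsets of {1..N}; support 0..min(set_sizes)."""
    ns = [int(n) for n in set_sizes]
    if any(n > N for n in ns):
        raise ValueError("every set size must be <= N")
    if len(ns) < 2:
        raise ValueError("need at least two sets")
    # after the first two sets the overlap is hypergeometric; keep the full
    # running support (intermediate intersections can exceed min(ns))
    cur_max = min(ns[0], ns[1])
    support = np.arange(cur_max + 1)
    pmf = sps.hypergeom.pmf(support, N, ns[0], ns[1])
    for nj in ns[2:]:
        # transition: overlap of a size-s running intersection with an
        # independent uniform nj-subset ~ Hypergeom(N, s, nj)
        new_max = min(cur_max, nj)
        new_support = np.arange(new_max + 1)
        trans = sps.hypergeom.pmf(new_support[:, None], N,
                                  support[None, :], nj)
        pmf = trans @ pmf
        cur_max, support = new_max, new_support
    return pmf


def multiset_exact_test(N: int, set_sizes, k_observed: int,
                        n_tests: int = 1) -> MultiSetTestResult:
    """Exact upper-tail test of an observed m-set intersection size."""
    ns = tuple(int(n) for n in set_sizes)
    if k_observed > min(ns):
        raise ValueError("observed intersection exceeds the smallest set")
    if k_observed < 0:
        raise ValueError("intersection size must be >= 0")
    pmf = multiset_intersection_pmf(N, ns)
    tail = float(pmf[k_observed:].sum())
    tail = min(tail, 1.0)
    return MultiSetTestResult(background_size=int(N), set_sizes=ns,
                              observed_intersection=int(k_observed),
                              pmf=pmf, tail_p=tail,
                              p_adjusted=min(1.0, tail * n_tests))


def enrichment_tests(hit_set_size: int, category_size: int, overlap: int,
                     background: int, n_tests: int = 1) -> tuple[float, float]:
    """Hypergeometric upper-tail enrichment p with Bonferroni adjustment."""
    if overlap > min(hit_set_size, category_size) or \
            max(hit_set_size, category_size) > background:
        raise ValueError("inconsistent counts")
    p = float(sps.hypergeom.sf(overlap - 1, background, category_size,
                               hit_set_size))
    return p, min(1.0, p * n_tests)


def fisher_exact_2x2(table, n_tests: int = 1,
                     alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table, Bonferroni-adjusted."""
    tab = np.asarray(table, int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    _, p = sps.fisher_exact(tab, alternative=alternative)
    return float(p), min(1.0, float(p) * n_tests)
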