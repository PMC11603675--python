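"""Statistical layer: descriptives, random-intercept LMM, rank tests, trends.

Two interval conventions coexist in clinical summary tables and both are
implemented explicitly: ``ci_mean`` = mean ± 1.96·SD/√n (a confidence
interval for the mean) and ``range_1_96sd`` = mean ± 1.96·SD (a normal-range
band for individuals).  1.96 — the normal 97.5% quantile — is used
throughout rather than a t quantile, matching printed-table recomputation.

The mixed model is a single-random-intercept LMM

    y = Xβ + Z b + ε,   b_i ~ N(0, σ_b²),  ε ~ N(0, σ_e²)

fitted by REML with the variance ratio λ = σ_b²/σ_e² profiled out by 1-D
bounded optimization on log λ; β follows by generalized least squares at
the optimum, with Wald z confidence intervals and p-values.  Presented
statsmodels-style: ``RandomInterceptLMM.from_dataframe(...).fit()`` returns
an :class:`LMMResults` with ``params``, ``conf_int()``, ``pvalues`` and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.interpolate import make_smoothing_spline
from scipy.special import ndtr

from .errors import DesignError, InsufficientDataError

__all__ = [
    "DescriptiveSummary",
    "describe",
    "interval_from_summary",
    "assign_age_group",
    "RandomInterceptLMM",
    "LMMResults",
    "fit_lmm",
    "RankTestResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "average_dependent",
    "smooth_age_trend",
    "AGE_GROUP_BOUNDS",
]

Z975 = 1.96

# ---------------------------------------------------------------------------
# descriptive summaries


@dataclass
class DescriptiveSummary:
    n: int
    mean: float
    sd: float  # n−1 denominator
    min: float
    max: float
    skewness: float  # moment-based g1 (or bias-adjusted G1)
    excess_kurtosis: float  # g2 (or adjusted G2)
    ci_mean: tuple  # mean ± 1.96·sd/√n
    range_1_96sd: tuple  # mean ± 1.96·sd


def describe(values, bias: bool = True) -> DescriptiveSummary:
    """Moments, extremes and both 1.96-interval conventions.

    ``bias=True`` gives the plain moment estimators g1 = m3/m2^1.5 and
    g2 = m4/m2² − 3; ``bias=False`` the sample-adjusted G1/G2.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise InsufficientDataError("describe needs at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return DescriptiveSummary(
        n=n,
        mean=mean,
        sd=sd,
        min=float(v.min()),
        max=float(v.max()),
        skewness=float(sps.skew(v, bias=bias)),
        excess_kurtosis=float(sps.kurtosis(v, fisher=True, bias=bias)),
        ci_mean=interval_from_summary(mean, sd, n, kind="ci_mean"),
        range_1_96sd=interval_from_summary(mean, sd, kind="range"),
    )


def interval_from_summary(mean: float, sd: float, n: int | None = None,
                          kind: str = "ci_mean") -> tuple:
    """Recompute a printed interval from summary statistics.

    ``ci_mean``: mean ± 1.96·sd/√n.  ``range``: mean ± 1.96·sd.  Rounding
    is the caller's concern (presentation only).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if kind == "ci_mean":
        if n is None or n < 1:
            raise ValueError("ci_mean needs n ≥ 1")
        half = Z975 * sd / np.sqrt(n)
    elif kind == "range":
        half = Z975 * sd
    else:
        raise ValueError(f"unknown interval kind {kind!r}")
    return (mean - half, mean + half)


AGE_GROUP_BOUNDS = {"4-12": (4, 12), "13-16": (13, 16), "17-20": (17, 20)}


def assign_age_group(age_years) -> str:
    """Integer-year binning into the 4–12 / 13–16 / 17–20 groups."""
    age = int(age_years)
    for name, (lo, hi) in AGE_GROUP_BOUNDS.items():
        if lo <= age <= hi:
            return name
    raise ValueError(f"age {age_years} outside the study range [4, 20]")


# ---------------------------------------------------------------------------
# random-intercept linear mixed model

#: reference levels for treatment coding (anterior/male/no-teeth/left/0°)
DEFAULT_REFERENCES = {
    "age_group": "4-12",
    "sex": "male",
    "teeth": False,
    "side": "l",
    "roi": 1,
    "angle_deg": 0,
    "point": 2,
}

#: display order for categorical levels, where alphanumeric sort is wrong
_LEVEL_ORDER = {"age_group": ["4-12", "13-16", "17-20"]}


def _encode_design(df: pd.DataFrame, fixed_terms, references) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(df))}
    for term in fixed_terms:
        col = df[term]
        ref = references.get(term, None)
        levels = _LEVEL_ORDER.get(term) or sorted(col.unique(), key=str)
        if ref is None:
            ref = levels[0]
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{term}[{lev}]"] = (col == lev).astype(float).to_numpy()
    return pd.DataFrame(cols, index=df.index)


class RandomInterceptLMM:
    """Linear mixed model with one random intercept per group.

    Build with :meth:`from_dataframe`, then :meth:`fit`.
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame, groups: np.ndarray):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.groups = np.asarray(groups)
        codes, uniques = pd.factorize(self.groups)
        self._codes = codes
        self.n_groups = len(uniques)
        if self.n_groups < 2:
            raise DesignError("need at least 2 groups for a random intercept")
        X = exog.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise DesignError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
                f"columns: {list(exog.columns)})"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str = "response",
        fixed_terms=("age_group", "sex", "teeth", "side", "roi"),
        group: str = "patient_id",
        references: dict | None = None,
    ) -> "RandomInterceptLMM":
        refs = dict(DEFAULT_REFERENCES)
        refs.update(references or {})
        exog = _encode_design(df, fixed_terms, refs)
        return cls(df[response].to_numpy(dtype=float), exog, df[group].to_numpy())

    # ---------------------------------------------------------------- REML
    def _group_sums(self, arr: np.ndarray) -> np.ndarray:
        if arr.ndim == 1:
            out = np.zeros(self.n_groups)
            np.add.at(out, self._codes, arr)
        else:
            out = np.zeros((self.n_groups, arr.shape[1]))
            np.add.at(out, self._codes, arr)
        return out

    def _profile(self, lam: float):
        """GLS at fixed λ; returns (criterion, beta, A, sigma_e2)."""
        X = self.exog.to_numpy(dtype=float)
        y = self.endog
        n_i = np.bincount(self._codes, minlength=self.n_groups).astype(float)
        gamma = lam / (1.0 + lam * n_i)  # per-group shrinkage
        Sx = self._group_sums(X)
        Sy = self._group_sums(y)
        A = X.T @ X - (Sx * gamma[:, None]).T @ Sx
        c = X.T @ y - (Sx * gamma[:, None]).T @ Sy
        beta = np.linalg.solve(A, c)
        r = y - X @ beta
        Sr = self._group_sums(r)
        rss_w = float(r @ r - gamma @ Sr**2)
        n, p = len(y), X.shape[1]
        sigma_e2 = rss_w / (n - p)
        sign, logdet_a = np.linalg.slogdet(A)
        crit = (
            (n - p) * np.log(sigma_e2)
            + float(np.log1p(lam * n_i).sum())
            + logdet_a
        )
        return crit, beta, A, sigma_e2

    def fit(self) -> "LMMResults":
        res = optimize.minimize_scalar(
            lambda loglam: self._profile(np.exp(loglam))[0],
            bounds=(-15.0, 15.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam_opt = float(np.exp(res.x))
        crit_opt, beta, A, sigma_e2 = self._profile(lam_opt)
        crit_zero, beta0, A0, sig0 = self._profile(0.0)
        converged = bool(res.success)
        if crit_zero <= crit_opt:  # boundary σ_b = 0
            lam_opt, beta, A, sigma_e2 = 0.0, beta0, A0, sig0
        cov = sigma_e2 * np.linalg.inv(A)
        bse = np.sqrt(np.diag(cov))
        names = list(self.exog.columns)
        return LMMResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            sigma_e=float(np.sqrt(sigma_e2)),
            sigma_b=float(np.sqrt(lam_opt * sigma_e2)),
            n_obs=len(self.endog),
            n_groups=self.n_groups,
            converged=converged,
            model=self,
        )


@dataclass
class LMMResults:
    """REML estimates with Wald z inference."""

    params: pd.Series
    bse: pd.Series
    sigma_e: float
    sigma_b: float
    n_obs: int
    n_groups: int
    converged: bool
    model: RandomInterceptLMM = field(repr=False, default=None)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        p = 2.0 * ndtr(-np.abs(self.zvalues))  # accurate in the far tail
        return pd.Series(np.clip(p, np.finfo(float).tiny, 1.0),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        half = Z975 * self.bse if np.isclose(alpha, 0.05) else (
            sps.norm.ppf(1 - alpha / 2) * self.bse
        )
        return pd.DataFrame(
            {"lower": self.params - half, "upper": self.params + half}
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Random-intercept linear mixed model (REML, Wald z)",
            f"observations: {self.n_obs}   groups: {self.n_groups}   "
            f"sigma_b: {self.sigma_b:.4f}   sigma_e: {self.sigma_e:.4f}",
            f"{'term':<22}{'coef':>10}{'ci_low':>10}{'ci_high':>10}{'p':>10}",
        ]
        for name in self.params.index:
            p = self.pvalues[name]
            p_str = "<0.001" if p < 0.001 else f"{p:.3f}"
            lines.append(
                f"{name:<22}{self.params[name]:>10.3f}{ci.loc[name, 'lower']:>10.3f}"
                f"{ci.loc[name, 'upper']:>10.3f}{p_str:>10}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "terms": {
                name: {
                    "coefficient": float(self.params[name]),
                    "ci_lower": float(ci.loc[name, "lower"]),
                    "ci_upper": float(ci.loc[name, "upper"]),
                    "p_value": float(self.pvalues[name]),
                }
                for name in self.params.index
            },
            "sigma_b": self.sigma_b,
            "sigma_e": self.sigma_e,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }


def fit_lmm(
    table: pd.DataFrame,
    response: str = "response",
    fixed_terms=("age_group", "sex", "teeth", "side", "roi"),
    group: str = "patient_id",
    references: dict | None = None,
) -> LMMResults:
    """Convenience wrapper: build and fit a :class:`RandomInterceptLMM`."""
    return RandomInterceptLMM.from_dataframe(
        table, response=response, fixed_terms=fixed_terms, group=group,
        references=references,
    ).fit()


# ---------------------------------------------------------------------------
# nonparametric tests

EXACT_N_MAX = 12


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    method: str  # "exact" | "asymptotic"

    def __iter__(self):  # allow (stat, p) unpacking
        return iter((self.statistic, self.pvalue))


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney(x, y) -> RankTestResult:
    """Two-sample Mann–Whitney U with an exact small-sample branch.

    For combined n ≤ 12 the null distribution is enumerated over all
    C(n, n_x) group assignments of the pooled (mid)ranks — valid under
    ties.  Larger samples use the tie- and continuity-corrected normal
    approximation.  Two-sided p by symmetric tails around n_x·n_y/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if nx + ny <= EXACT_N_MAX:
        mu = nx * ny / 2.0
        dev = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(nx + ny), nx):
            u = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return RankTestResult(u_obs, count / total, "exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return RankTestResult(float(res.statistic), float(res.pvalue), "asymptotic")


def wilcoxon_signed_rank(diffs) -> RankTestResult:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; all-zero input is undefined.  For n ≤ 12 non-zero
    differences the 2ⁿ sign patterns are enumerated (midranks make this
    valid under tied magnitudes); otherwise the corrected normal
    approximation is used.  The statistic is W⁺, the positive-rank sum.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: test undefined")
    n = d.size
    ranks = _midranks(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total_rank = float(ranks.sum())
    if n <= EXACT_N_MAX:
        mu = total_rank / 2.0
        dev = abs(w_obs - mu)
        count = 0
        for signs in product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        return RankTestResult(w_obs, count / 2**n, "exact")
    res = sps.wilcoxon(d, correction=True, method="approx")
    return RankTestResult(w_obs, float(res.pvalue), "asymptotic")


def average_dependent(
    table: pd.DataFrame,
    by: str = "patient_id",
    condition_keys: tuple = (),
    response: str = "response",
) -> pd.DataFrame:
    """Collapse statistically dependent rows to one mean per patient×condition.

    Guards the nonparametric tests against pseudoreplication: repeated
    measurements of the same palate (ROIs, sides, angles…) are averaged
    before testing.  Patient-level covariates are carried through.
    """
    keys = [by] + list(condition_keys)
    meta_cols = [
        c for c in table.columns
        if c not in keys + [response] and table.groupby(keys)[c].nunique().max() == 1
    ]
    agg = {response: "mean", **{c: "first" for c in meta_cols}}
    out = table.groupby(keys, as_index=False, sort=True).agg(agg)
    return out


def smooth_age_trend(
    ages,
    values,
    smoothing: float | None = None,
    grid: np.ndarray | None = None,
) -> tuple:
    """Cubic smoothing-spline fit of a thickness–age trend.

    Duplicate ages are averaged (with multiplicity weights); the smoothing
    parameter defaults to generalized cross-validation.  Returns
    ``(age_grid, fitted_values)``.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame({"age": ages, "val": values}).groupby("age", sort=True).agg(
        val=("val", "mean"), w=("val", "size")
    )
    x = df.index.to_numpy()
    if x.size < 4:
        raise InsufficientDataError("need at least 4 distinct ages for a spline")
    spline = make_smoothing_spline(x, df["val"].to_numpy(),
                                   w=df["w"].to_numpy(dtype=float), lam=smoothing)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    return grid, spline(grid)
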