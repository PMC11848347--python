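"""Association, mediation, and moderation statistics for cohort tables.

The models here mirror the standard biostatistics battery for linking sleep
microarchitecture to CSF biomarkers and cognition:

* :class:`RobustGLM` — GLMs with Huber/White sandwich (heteroskedasticity-
  robust) standard errors, HC1 small-sample scaling by default, with VIF
  collinearity and Shapiro-Wilk residual-normality diagnostics;
* :func:`tukey_ladder_select` — Tukey ladder-of-powers choice of an
  outcome transformation by residual/marginal normality;
* :func:`bh_fdr` — Benjamini-Hochberg step-up false-discovery-rate control;
* :func:`mmse_decline_odds` — covariate-adjusted odds of MMSE decline per
  unit of a sleep metric;
* :class:`Mediation` — Sobel-Goodman normal-theory tests of the indirect
  (a·b) effect, with proportion mediated and suppression flagging;
* :class:`Moderation` — interaction GLMs with simple slopes at moderator
  quantiles;
* :func:`run_full_battery` — the composed outcome-by-metric grid with
  per-outcome-family FDR.

Every model follows the construct-then-``fit()`` convention and returns a
results object carrying estimates, robust uncertainties, diagnostics, and a
``summary()`` table. Missing data are handled complete-case per model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "sex", "ahi")
Z975 = float(sst.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# design-matrix helpers


def _complete_cases(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns missing from table: {missing}")
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    return sub.dropna()

def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank == mat.shape[1]:
        return
    redundant = []
    for j, name in enumerate(X.columns):
        sub = np.delete(mat, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            redundant.append(name)
    raise ValueError(
        f"design matrix is rank deficient; collinear terms: {redundant}"
    )


def _vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors of the non-intercept design columns."""
    cols = [c for c in X.columns if c != "const"]
    if len(cols) < 2:
        return {c: 1.0 for c in cols}
    corr = np.corrcoef(X[cols].to_numpy(dtype=float), rowvar=False)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        return {c: float("inf") for c in cols}
    return {c: float(inv[i, i]) for i, c in enumerate(cols)}


def _shapiro_p(resid: np.ndarray, cap: int = 5000) -> float:
    resid = np.asarray(resid, dtype=float)
    if resid.size < 3 or np.ptp(resid) == 0:
        return float("nan")
    if resid.size > cap:
        step = int(np.ceil(resid.size / cap))
        resid = resid[::step]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sst.shapiro(resid).pvalue)


# ---------------------------------------------------------------------------
# robust GLM


@dataclass
class TermResult:
    name: str
    coef: float
    robust_se: float
    ci_low: float
    ci_high: float
    p: float
    p_fdr: float | None = None


@dataclass
class RobustGLMResults:
    """Fitted robust GLM: coefficients, sandwich SEs, and diagnostics."""

    outcome: str
    family: str
    terms: list[TermResult]
    n: int
    vif: dict[str, float]
    residual_normality_p: float
    cov_type: str
    params: pd.Series = field(repr=False, default=None)
    cov_params: pd.DataFrame = field(repr=False, default=None)
    resid: np.ndarray = field(repr=False, default=None)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.terms])

    def summary(self) -> str:
        lines = [
            f"Robust GLM ({self.family}, {self.cov_type} SEs)  "
            f"outcome: {self.outcome}   n = {self.n}",
            f"{'term':<22}{'coef':>12}{'robust SE':>12}{'p':>10}"
            f"{'95% CI low':>12}{'95% CI high':>12}{'VIF':>8}",
        ]
        for t in self.terms:
            v = self.vif.get(t.name)
            lines.append(
                f"{t.name:<22}{t.coef:>12.4g}{t.robust_se:>12.4g}{t.p:>10.3g}"
                f"{t.ci_low:>12.4g}{t.ci_high:>12.4g}"
                + (f"{v:>8.2f}" if v is not None else f"{'':>8}")
            )
        lines.append(
            f"residual Shapiro-Wilk p = {self.residual_normality_p:.3g}"
        )
        return "\n".join(lines)


class RobustGLM:
    """GLM with Huber/White sandwich standard errors.

    Parameters
    ----------
    data : DataFrame
    outcome : str
    predictors : list of str
        Terms of interest (reported first).
    covariates : sequence of str
        Adjustment terms; defaults to age, sex, AHI.
    family : {"gaussian", "binomial"}
    cov_type : {"HC0", "HC1", "HC3"}
        Sandwich flavor; HC1 applies the n/(n-k) small-sample factor.
    min_obs_per_param : int
        The 10-observations-per-parameter rule; violation warns, never errors.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, predictors,
                 covariates=DEFAULT_COVARIATES, family: str = "gaussian",
                 cov_type: str = "HC1", min_obs_per_param: int = 10):
        if family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        self.data = data
        self.outcome = outcome
        self.predictors = list(predictors)
        self.covariates = [c for c in covariates if c not in self.predictors]
        self.family = family
        self.cov_type = cov_type
        self.min_obs_per_param = min_obs_per_param

    def fit(self) -> RobustGLMResults:
        cols = [self.outcome] + self.predictors + self.covariates
        sub = _complete_cases(self.data, cols)
        y = sub[self.outcome].to_numpy(dtype=float)
        X = sm.add_constant(sub[self.predictors + self.covariates], has_constant="add")
        n, k = X.shape
        if n <= k:
            raise ValueError(
                f"only {n} complete cases for {k} parameters in model for "
                f"{self.outcome}"
            )
        _check_rank(X)
        n_terms = len(self.predictors) + len(self.covariates)
        if n < self.min_obs_per_param * n_terms:
            warnings.warn(
                f"{n} observations for {n_terms} modelled variables violates "
                f"the {self.min_obs_per_param}-per-parameter rule; estimates "
                "may be overfitted"
            )
        if self.family == "gaussian":
            res = sm.OLS(y, X).fit(cov_type=self.cov_type, use_t=False)
            resid = res.resid
        else:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(cov_type=self.cov_type)
            resid = res.resid_response
        ci = res.conf_int()
        terms = [
            TermResult(
                name=name,
                coef=float(res.params[name]),
                robust_se=float(res.bse[name]),
                ci_low=float(ci.loc[name, 0]),
                ci_high=float(ci.loc[name, 1]),
                p=float(res.pvalues[name]),
            )
            for name in X.columns
        ]
        return RobustGLMResults(
            outcome=self.outcome,
            family=self.family,
            terms=terms,
            n=n,
            vif=_vif(X),
            residual_normality_p=(
                _shapiro_p(resid) if self.family == "gaussian" else float("nan")
            ),
            cov_type=self.cov_type,
            params=res.params,
            cov_params=pd.DataFrame(res.cov_params(), index=X.columns,
                                    columns=X.columns),
            resid=np.asarray(resid, dtype=float),
        )


def fit_glm_robust(table: pd.DataFrame, outcome: str, predictors,
                   covariates=DEFAULT_COVARIATES, family: str = "gaussian",
                   cov_type: str = "HC1") -> RobustGLMResults:
    """Functional entry point to :class:`RobustGLM`."""
    return RobustGLM(table, outcome, predictors, covariates, family,
                     cov_type).fit()


# ---------------------------------------------------------------------------
# Tukey ladder of powers

TUKEY_LADDER = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


def apply_power(y: np.ndarray, lam: float) -> np.ndarray:
    """Tukey ladder transform, order-preserving for every rung.

    lam = 0 is log; negative rungs are sign-flipped (``-y**lam``) so the
    transform stays monotone increasing.
    """
    y = np.asarray(y, dtype=float)
    if lam <= 0 and np.any(y <= 0):
        raise ValueError(
            f"ladder rung lambda={lam:g} requires strictly positive values"
        )
    if lam == 0:
        return np.log(y)
    if lam < 0:
        return -np.power(y, lam)
    if lam != round(lam) and np.any(y < 0):
        raise ValueError(
            f"ladder rung lambda={lam:g} requires non-negative values"
        )
    return np.power(y, lam)


@dataclass
class TukeyResult:
    lam: float
    shapiro_w: float
    table: pd.DataFrame

    @property
    def name(self) -> str:
        return {0.0: "log", 0.5: "sqrt", 1.0: "identity", 2.0: "square",
                -0.5: "reciprocal sqrt", -1.0: "reciprocal",
                -2.0: "reciprocal square"}.get(self.lam, f"power {self.lam:g}")

    def transform(self, y) -> np.ndarray:
        return apply_power(y, self.lam)


def tukey_ladder_select(y, ladder=TUKEY_LADDER) -> TukeyResult:
    """Pick the ladder rung whose transform is closest to normal.

    The criterion is the Shapiro-Wilk W statistic of the transformed
    sample; rungs whose domain excludes the data (log/negative powers with
    non-positive values) are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 3:
        raise ValueError("need at least 3 finite observations")
    rows = []
    for lam in ladder:
        try:
            t = apply_power(y, lam)
        except ValueError:
            warnings.warn(
                f"skipping ladder rung lambda={lam:g}: out of domain for the data"
            )
            continue
        if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
            continue
        sub = t if t.size <= 5000 else t[:: int(np.ceil(t.size / 5000))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = sst.shapiro(sub)
        rows.append((lam, float(w), float(p)))
    if not rows:
        raise ValueError("no admissible ladder rung for the data")
    table = pd.DataFrame(rows, columns=["lambda", "shapiro_w", "shapiro_p"])
    best = table.loc[table["shapiro_w"].idxmax()]
    return TukeyResult(lam=float(best["lambda"]), shapiro_w=float(best["shapiro_w"]),
                       table=table)


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected flags, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# odds of MMSE decline


@dataclass
class OddsResult:
    metric: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    beta: float
    robust_se: float
    p: float
    n: int
    n_declined: int

    def summary(self) -> str:
        return (
            f"Odds of MMSE decline per unit {self.metric}: "
            f"OR {self.odds_ratio:.3g} (95% CI {self.ci_low:.3g}, "
            f"{self.ci_high:.3g}), p = {self.p:.3g}, n = {self.n} "
            f"({self.n_declined} declined)"
        )


def mmse_decline_odds(table: pd.DataFrame, metric: str,
                      covariates=DEFAULT_COVARIATES,
                      baseline_col: str = "mmse_0",
                      follow_col: str = "mmse_36") -> OddsResult:
    """Covariate-adjusted logistic odds of MMSE decline per unit of metric.

    Decline is ``follow < baseline`` on complete cases. A constant or
    perfectly separating decline indicator raises ``ValueError``.
    """
    cols = [metric, baseline_col, follow_col, *covariates]
    sub = _complete_cases(table, cols)
    decline = (sub[follow_col] < sub[baseline_col]).astype(int)
    if decline.nunique() < 2:
        raise ValueError(
            "decline indicator is constant; odds of decline are not estimable"
        )
    X = sm.add_constant(sub[[metric, *covariates]], has_constant="add")
    _check_rank(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(decline.to_numpy(), X).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises/warns on separation
        raise ValueError(f"logistic fit failed (possible separation): {exc}")
    beta = float(res.params[metric])
    if not res.mle_retvals.get("converged", True) or abs(beta) > 50:
        raise ValueError("perfect separation: the metric separates decliners")
    se = float(res.bse[metric])
    return OddsResult(
        metric=metric,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        beta=beta,
        robust_se=se,
        p=float(res.pvalues[metric]),
        n=len(sub),
        n_declined=int(decline.sum()),
    )


# ---------------------------------------------------------------------------
# mediation (Sobel-Goodman)


@dataclass
class MediationResults:
    exposure: str
    mediator: str
    outcome: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    c_prime: float
    indirect: float
    sobel_z: float
    sobel_p: float
    goodman1_z: float
    goodman1_p: float
    goodman2_z: float
    goodman2_p: float
    prop_mediated: float
    ratio_indirect_direct: float
    suppression: bool
    n: int

    def summary(self) -> str:
        lines = [
            f"Sobel-Goodman mediation: {self.exposure} -> {self.mediator} -> "
            f"{self.outcome}  (n = {self.n})",
            f"  a = {self.a:.4g} (SE {self.se_a:.4g})   "
            f"b = {self.b:.4g} (SE {self.se_b:.4g})",
            f"  total c = {self.c:.4g}   direct c' = {self.c_prime:.4g}   "
            f"indirect a*b = {self.indirect:.4g}",
            f"  Sobel z = {self.sobel_z:.3f} (p = {self.sobel_p:.3g}); "
            f"Goodman-1 p = {self.goodman1_p:.3g}, "
            f"Goodman-2 p = {self.goodman2_p:.3g}",
            f"  proportion mediated = {self.prop_mediated:.3f}; "
            f"indirect/direct = {self.ratio_indirect_direct:.3f}",
        ]
        if self.suppression:
            lines.append("  note: indirect and direct effects have opposite "
                         "signs (suppression)")
        return "\n".join(lines)


class Mediation:
    """Three-regression mediation with Sobel-Goodman tests.

    Stage regressions (all including the covariates):
    mediator ~ exposure (a); outcome ~ exposure + mediator (b, c');
    outcome ~ exposure (c). Conventional OLS standard errors feed the
    Sobel/Goodman z statistics.
    """

    def __init__(self, data: pd.DataFrame, exposure: str, mediator: str,
                 outcome: str, covariates=()):
        self.data = data
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = list(covariates)

    def fit(self) -> MediationResults:
        cols = [self.outcome, self.exposure, self.mediator, *self.covariates]
        sub = _complete_cases(self.data, cols)
        if sub[self.mediator].std() == 0:
            raise ValueError(f"mediator {self.mediator!r} has zero variance")

        def _ols(ycol, xcols):
            X = sm.add_constant(sub[xcols], has_constant="add")
            _check_rank(X)
            return sm.OLS(sub[ycol].to_numpy(), X).fit()

        m_fit = _ols(self.mediator, [self.exposure, *self.covariates])
        y_fit = _ols(self.outcome,
                     [self.exposure, self.mediator, *self.covariates])
        c_fit = _ols(self.outcome, [self.exposure, *self.covariates])

        a, se_a = float(m_fit.params[self.exposure]), float(m_fit.bse[self.exposure])
        b, se_b = float(y_fit.params[self.mediator]), float(y_fit.bse[self.mediator])
        c_prime = float(y_fit.params[self.exposure])
        c = float(c_fit.params[self.exposure])
        indirect = a * b

        def _z_p(var: float) -> tuple[float, float]:
            if var <= 0:
                return float("nan"), float("nan")
            z = indirect / np.sqrt(var)
            return float(z), float(2 * sst.norm.sf(abs(z)))

        v_sobel = b**2 * se_a**2 + a**2 * se_b**2
        z_s, p_s = _z_p(v_sobel)
        z_g1, p_g1 = _z_p(v_sobel + se_a**2 * se_b**2)
        z_g2, p_g2 = _z_p(v_sobel - se_a**2 * se_b**2)
        prop = indirect / c if c != 0 else float("nan")
        ratio = indirect / c_prime if c_prime != 0 else float("nan")
        suppression = indirect * c_prime < 0
        return MediationResults(
            exposure=self.exposure, mediator=self.mediator, outcome=self.outcome,
            a=a, se_a=se_a, b=b, se_b=se_b, c=c, c_prime=c_prime,
            indirect=indirect, sobel_z=z_s, sobel_p=p_s,
            goodman1_z=z_g1, goodman1_p=p_g1, goodman2_z=z_g2, goodman2_p=p_g2,
            prop_mediated=prop, ratio_indirect_direct=ratio,
            suppression=suppression, n=len(sub),
        )


def sobel_goodman(table: pd.DataFrame, exposure: str, mediator: str,
                  outcome: str, covariates=()) -> MediationResults:
    """Functional entry point to :class:`Mediation`."""
    return Mediation(table, exposure, mediator, outcome, covariates).fit()


# ---------------------------------------------------------------------------
# moderation


@dataclass
class ModerationResults:
    exposure: str
    moderator: str
    outcome: str
    gamma: float
    robust_se: float
    p: float
    ci_low: float
    ci_high: float
    simple_slopes: pd.DataFrame
    n: int
    glm: RobustGLMResults = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"Moderation: {self.exposure} x {self.moderator} -> "
            f"{self.outcome}  (n = {self.n})",
            f"  interaction gamma = {self.gamma:.4g} "
            f"(robust SE {self.robust_se:.4g}, p = {self.p:.3g}, "
            f"95% CI {self.ci_low:.4g}, {self.ci_high:.4g})",
            "  simple slopes of the exposure:",
        ]
        for r in self.simple_slopes.itertuples():
            lines.append(
                f"    {self.moderator} at q{int(r.quantile * 100):02d} "
                f"({r.moderator_value:.3g}): slope {r.slope:.4g} "
                f"(SE {r.se:.4g}, p = {r.p:.3g})"
            )
        return "\n".join(lines)


class Moderation:
    """Interaction GLM with robust SEs and simple-slope decomposition."""

    def __init__(self, data: pd.DataFrame, exposure: str, moderator: str,
                 outcome: str, covariates=DEFAULT_COVARIATES,
                 cov_type: str = "HC1",
                 quantiles=(0.25, 0.5, 0.75)):
        self.data = data
        self.exposure = exposure
        self.moderator = moderator
        self.outcome = outcome
        self.covariates = list(covariates)
        self.cov_type = cov_type
        self.quantiles = quantiles

    def fit(self) -> ModerationResults:
        inter = f"{self.exposure}:{self.moderator}"
        cols = [self.outcome, self.exposure, self.moderator, *self.covariates]
        sub = _complete_cases(self.data, cols).copy()
        sub[inter] = sub[self.exposure] * sub[self.moderator]
        glm = RobustGLM(
            sub, self.outcome,
            predictors=[self.exposure, self.moderator, inter],
            covariates=self.covariates, cov_type=self.cov_type,
        ).fit()
        g = glm.term(inter)
        cov = glm.cov_params
        var_e = cov.loc[self.exposure, self.exposure]
        var_g = cov.loc[inter, inter]
        cov_eg = cov.loc[self.exposure, inter]
        rows = []
        for q in self.quantiles:
            mq = float(sub[self.moderator].quantile(q))
            slope = float(glm.params[self.exposure] + g.coef * mq)
            se = float(np.sqrt(max(var_e + mq**2 * var_g + 2 * mq * cov_eg, 0.0)))
            z = slope / se if se > 0 else float("nan")
            rows.append((q, mq, slope, se, float(2 * sst.norm.sf(abs(z)))))
        slopes = pd.DataFrame(
            rows, columns=["quantile", "moderator_value", "slope", "se", "p"]
        )
        return ModerationResults(
            exposure=self.exposure, moderator=self.moderator,
            outcome=self.outcome, gamma=g.coef, robust_se=g.robust_se,
            p=g.p, ci_low=g.ci_low, ci_high=g.ci_high,
            simple_slopes=slopes, n=glm.n, glm=glm,
        )


def moderation(table: pd.DataFrame, exposure: str, moderator: str,
               outcome: str, covariates=DEFAULT_COVARIATES,
               cov_type: str = "HC1") -> ModerationResults:
    """Functional entry point to :class:`Moderation`."""
    return Moderation(table, exposure, moderator, outcome, covariates,
                      cov_type).fit()


# ---------------------------------------------------------------------------
# full battery


@dataclass
class BatteryConfig:
    """What the composed analysis battery runs, and how."""

    metrics: tuple = ("sp_duration_s", "sp_density", "sp_power_uv2",
                      "so_duration_s", "so_density", "so_ptp_uv")
    biomarker_outcomes: tuple = ("abeta42", "ptau181", "ttau",
                                 "ratio_ptau_abeta42", "ratio_ttau_abeta42")
    cognition_cross: tuple = ("mmse_0", "adascog_0")
    cognition_long: tuple = (("mmse_12", "mmse_0"), ("mmse_24", "mmse_0"),
                             ("mmse_36", "mmse_0"), ("adascog_12", "adascog_0"))
    covariates: tuple = DEFAULT_COVARIATES
    q: float = 0.05
    cov_type: str = "HC1"
    transform_outcomes: tuple = ("ratio_ptau_abeta42",)  # Tukey-transform when
    # residual normality fails for these outcomes
    normality_alpha: float = 0.05
    mediation_exposure: str = "ratio_ptau_abeta42"
    mediation_mediators: tuple = ("sp_density", "so_duration_s")
    mediation_outcomes: tuple = ("mmse_0", "adascog_0")
    moderation_moderator: str = "ratio_ptau_abeta42"
    moderation_exposures: tuple = ("sp_density", "sp_power_uv2")
    moderation_outcomes: tuple = ("mmse_0", "adascog_0")
    min_obs_per_param: int = 10


@dataclass
class BatteryReport:
    associations: pd.DataFrame
    mediation: list[MediationResults]
    moderation: list[ModerationResults]
    warnings: list[str]

    def summary(self) -> str:
        lines = ["Association grid (FDR within each outcome family):"]
        if self.associations.empty:
            lines.append("  (no models fitted)")
        else:
            sig = self.associations[self.associations["significant"]]
            lines.append(
                f"  {len(self.associations)} outcome x metric cells, "
                f"{len(sig)} FDR-significant"
            )
            for r in sig.itertuples():
                lines.append(
                    f"    {r.outcome} ~ {r.metric}: beta {r.coef:.4g} "
                    f"(SE {r.robust_se:.4g}), p_FDR = {r.p_fdr:.3g}"
                )
        for m in self.mediation:
            lines.append(m.summary())
        for m in self.moderation:
            lines.append(m.summary())
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def run_full_battery(cohort: pd.DataFrame,
                     config: BatteryConfig | None = None) -> BatteryReport:
    """Run the outcome-by-metric association grid plus mediation/moderation.

    Each outcome family (one outcome, all metrics) receives its own
    Benjamini-Hochberg correction. Longitudinal outcomes are additionally
    adjusted for their baseline score. Outcomes listed in
    ``config.transform_outcomes`` are re-fitted under the best Tukey-ladder
    transform when their residuals fail Shapiro-Wilk normality.
    """
    cfg = config or BatteryConfig()
    required = set(cfg.metrics) | set(cfg.biomarker_outcomes) \
        | set(cfg.cognition_cross) | set(cfg.covariates) \
        | {o for o, _ in cfg.cognition_long} | {b for _, b in cfg.cognition_long}
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")

    notes: list[str] = []
    rows = []
    plans = [(o, None, "biomarker") for o in cfg.biomarker_outcomes]
    plans += [(o, None, "cognition-baseline") for o in cfg.cognition_cross]
    plans += [(o, b, "cognition-longitudinal") for o, b in cfg.cognition_long]

    for outcome, baseline, family_tag in plans:
        for metric in cfg.metrics:
            covs = list(cfg.covariates) + ([baseline] if baseline else [])
            n_params = 1 + len(covs)
            n_cc = len(_complete_cases(cohort, [outcome, metric, *covs]))
            if n_cc < cfg.min_obs_per_param * n_params or n_cc <= n_params + 1:
                notes.append(
                    f"skipped {outcome} ~ {metric}: {n_cc} complete cases for "
                    f"{n_params} modelled variables"
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res, transform = _fit_cell(cohort, outcome, metric, covs, cfg)
            t = res.term(metric)
            rows.append({
                "outcome": outcome, "metric": metric, "family": family_tag,
                "transform": transform,
                "coef": t.coef, "robust_se": t.robust_se, "p": t.p,
                "ci_low": t.ci_low, "ci_high": t.ci_high,
                "n": res.n, "vif_metric": res.vif.get(metric, float("nan")),
                "residual_normality_p": res.residual_normality_p,
            })
    assoc = pd.DataFrame(rows)
    if not assoc.empty:
        assoc["p_fdr"] = np.nan
        assoc["significant"] = False
        for outcome, grp in assoc.groupby("outcome"):
            rej, p_adj = bh_fdr(grp["p"].to_numpy(), q=cfg.q)
            assoc.loc[grp.index, "p_fdr"] = p_adj
            assoc.loc[grp.index, "significant"] = rej

    med, mod = [], []
    if not assoc.empty:
        for mediator in cfg.mediation_mediators:
            for outcome in cfg.mediation_outcomes:
                try:
                    med.append(Mediation(cohort, cfg.mediation_exposure,
                                         mediator, outcome,
                                         cfg.covariates).fit())
                except (ValueError, KeyError) as exc:
                    notes.append(f"mediation {mediator}->{outcome} failed: {exc}")
        for exposure in cfg.moderation_exposures:
            for outcome in cfg.moderation_outcomes:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        mod.append(Moderation(cohort, exposure,
                                              cfg.moderation_moderator, outcome,
                                              cfg.covariates,
                                              cfg.cov_type).fit())
                except (ValueError, KeyError) as exc:
                    notes.append(f"moderation {exposure}x{outcome} failed: {exc}")
    return BatteryReport(associations=assoc, mediation=med, moderation=mod,
                         warnings=notes)


def _fit_cell(cohort, outcome, metric, covs, cfg):
    res = RobustGLM(cohort, outcome, [metric], covs,
                    cov_type=cfg.cov_type,
                    min_obs_per_param=cfg.min_obs_per_param).fit()
    transform = "identity"
    if (outcome in cfg.transform_outcomes
            and np.isfinite(res.residual_normality_p)
            and res.residual_normality_p < cfg.normality_alpha):
        y = cohort[outcome].to_numpy(dtype=float)
        try:
            tk = tukey_ladder_select(y[np.isfinite(y)])
        except ValueError:
            return res, transform
        if tk.lam != 1.0:
            data2 = cohort.copy()
            data2[outcome] = apply_power(y, tk.lam)
            res = RobustGLM(data2, outcome, [metric], covs,
                            cov_type=cfg.cov_type,
                            min_obs_per_param=cfg.min_obs_per_param).fit()
            transform = tk.name
    return res, transform
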