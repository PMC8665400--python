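"""Trial-level analytics for the two-arm pre/post cognitive outcome design.

Covers the whole clinical chain: baseline group comparisons (pooled-variance
t and Pearson chi-square), the random-intercept mixed model for the
condition x period interaction on the standardized main outcome, Hedges g
pre/post effect sizes per arm, respondent counting against a fixed
standardized-improvement threshold, the Button-style positive predictive
value, simulation-based post hoc power, and paired t tests (with
within-family Bonferroni adjustment) for questionnaire scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTable

__all__ = [
    "two_sample_t",
    "chi_square_2x2",
    "fit_prepost_mixed_model",
    "MixedModelResult",
    "hedges_g_prepost",
    "respondent_analysis",
    "ppv",
    "simulate_power",
    "PowerPPVResult",
    "paired_t",
    "bonferroni_families",
    "baseline_table",
    "cohort_to_long",
    "TrialOutcomeModel",
    "TrialOutcomeResults",
]


# ---------------------------------------------------------------------------
# baseline comparisons


def two_sample_t(a, b, welch: bool = False) -> tuple[float, int, float]:
    """Two-sided two-sample t test; Student (pooled variance) by default.

    ``a`` and ``b`` are either raw 1-d samples or ``(mean, sd, n)`` summary
    triples.
    """

    def _moments(v):
        if isinstance(v, tuple) and len(v) == 3:
            m, s, n = v
            return float(m), float(s), int(n)
        v = np.asarray(v, float)
        return float(v.mean()), float(v.std(ddof=1)), int(v.size)

    m1, s1, n1 = _moments(a)
    m2, s2, n2 = _moments(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if welch:
        se2 = s1**2 / n1 + s2**2 / n2
        if se2 == 0:
            if m1 == m2:
                return 0.0, n1 + n2 - 2, 1.0
            raise ValueError("zero variance with unequal means")
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
        df = int(np.floor(df))
    else:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        df = n1 + n2 - 2
        if sp2 == 0:
            if m1 == m2:
                return 0.0, df, 1.0
            raise ValueError("zero pooled variance with unequal means")
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, without continuity correction.

    Uses the shortcut form N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), which is
    algebraically identical to the observed-vs-expected summation.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    a, b = t[0]
    c, d = t[1]
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("zero marginal total")
    N = t.sum()
    chi2 = N * (a * d - b * c) ** 2 / np.prod(margins)
    p = stats.chi2.sf(chi2, df=1)
    return float(chi2), 1, float(p)


def baseline_table(cohort: CohortTable) -> pd.DataFrame:
    """Between-arm baseline comparison: age (t test), categorical flags (chi2)."""
    df = cohort.data
    exp = cohort.arm_mask("experimental")
    ctl = cohort.arm_mask("control")
    rows = []

    age_e, age_c = df.loc[exp, "age"], df.loc[ctl, "age"]
    t, _, p = two_sample_t(np.asarray(age_e), np.asarray(age_c))
    rows.append(
        {
            "characteristic": "Age (years)",
            "experimental": f"{age_e.mean():.2f} ({age_e.std(ddof=1):.2f})",
            "control": f"{age_c.mean():.2f} ({age_c.std(ddof=1):.2f})",
            "statistic": abs(t),
            "test": "t",
            "p": p,
        }
    )

    cats = [
        ("Males", df["sex"] == "M"),
        ("Using medication", df["medicated"].astype(bool)),
        ("Receiving psychological treatment", df["psych_treatment"].astype(bool)),
    ]
    N = cohort.n
    for name, flag in cats:
        flag = np.asarray(flag)
        table = [
            [int(flag[exp].sum()), int((~flag[exp]).sum())],
            [int(flag[ctl].sum()), int((~flag[ctl]).sum())],
        ]
        try:
            chi2, _, p = chi_square_2x2(table)
        except ValueError:
            chi2, p = float("nan"), float("nan")
        rows.append(
            {
                "characteristic": name,
                "experimental": f"{table[0][0]} ({100 * table[0][0] / N:.1f})",
                "control": f"{table[1][0]} ({100 * table[1][0] / N:.1f})",
                "statistic": chi2,
                "test": "chi2",
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed model


@dataclass
class MixedModelResult:
    """Condition x period interaction from the random-intercept mixed model."""

    beta_interaction: float
    se: float
    t_value: float
    df: int
    p: float
    lr_chi2: float
    lr_p: float
    aic: float
    bic: float
    r2: float
    r2_adjusted: float
    age_included: bool = False
    degenerate: bool = False
    converged: bool = True


def cohort_to_long(
    cohort: CohortTable,
    pre_col: str = "cpt_commission_pre",
    post_col: str = "cpt_commission_post",
) -> pd.DataFrame:
    """Wide cohort -> long (participant, arm, age, period, score) table."""
    df = cohort.data
    frames = []
    for period, col in (("pre", pre_col), ("post", post_col)):
        part = df[["participant_id", "arm", "age"]].copy()
        part["period"] = period
        part["score"] = pd.to_numeric(df[col])
        frames.append(part)
    long = pd.concat(frames, ignore_index=True)
    return long.dropna(subset=["score"]).reset_index(drop=True)


def fit_prepost_mixed_model(
    long: pd.DataFrame,
    standardize: bool = True,
    age_covariate: str = "stepwise",
) -> MixedModelResult:
    """Random-intercept linear mixed model with condition x period interaction.

    The score is z-scored against the whole-sample baseline (pre) mean/SD, so
    the interaction coefficient reads as a standardized mean difference.
    Estimation is REML (statsmodels MixedLM); the likelihood-ratio chi-square
    for adding the interaction comes from ML refits of both models. The Wald
    p uses a t reference with participants - 2 degrees of freedom.

    ``age_covariate``: "stepwise" adds age as a fixed effect only if it
    lowers the ML AIC of the no-interaction model; "always"/"never" force it.
    """
    import statsmodels.api as sm

    required = {"participant_id", "arm", "period", "score"}
    if not required <= set(long.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    long = long.copy()
    n_subj = long["participant_id"].nunique()
    for arm in ("experimental", "control"):
        if long.loc[long["arm"] == arm, "participant_id"].nunique() < 3:
            raise ValueError(f"fewer than 3 participants in arm {arm!r}")

    if standardize:
        base = long.loc[long["period"] == "pre", "score"]
        mu, sd = base.mean(), base.std(ddof=1)
        if sd == 0:
            raise ValueError("zero baseline variance; cannot standardize")
        long["score"] = (long["score"] - mu) / sd

    # fully degenerate case: nothing changed pre -> post for anyone
    wide = long.pivot_table(index="participant_id", columns="period",
                            values="score", aggfunc="first")
    if {"pre", "post"} <= set(wide.columns):
        diffs = (wide["post"] - wide["pre"]).dropna()
        if len(diffs) and np.allclose(diffs, 0.0):
            return MixedModelResult(
                beta_interaction=0.0, se=float("nan"), t_value=0.0,
                df=n_subj - 2, p=1.0, lr_chi2=0.0, lr_p=1.0,
                aic=float("nan"), bic=float("nan"), r2=1.0, r2_adjusted=1.0,
                degenerate=True,
            )

    long["period01"] = (long["period"] == "post").astype(float)
    long["cond01"] = (long["arm"] == "experimental").astype(float)
    long["inter"] = long["period01"] * long["cond01"]

    base_cols = ["period01", "cond01"]
    y = long["score"].to_numpy()
    groups = long["participant_id"].to_numpy()

    def _exog(cols):
        X = long[cols].to_numpy()
        return np.column_stack([np.ones(len(long)), X])

    def _fit(cols, reml):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, _exog(cols), groups=groups)
            last_err = None
            for method in (None, "powell", "nm"):
                try:
                    kw = {} if method is None else {"method": method}
                    return model.fit(reml=reml, maxiter=200, **kw)
                except (np.linalg.LinAlgError, ValueError) as err:
                    last_err = err
            raise RuntimeError(f"mixed-model fit failed (singular fit?): {last_err}")

    use_age = False
    if age_covariate not in ("stepwise", "always", "never"):
        raise ValueError("age_covariate must be stepwise/always/never")
    if age_covariate != "never" and "age" in long.columns:
        if age_covariate == "always":
            use_age = True
        else:
            ml_no = _fit(base_cols, reml=False)
            ml_age = _fit(base_cols + ["age"], reml=False)
            use_age = bool(ml_age.aic < ml_no.aic)
    cols = base_cols + (["age"] if use_age else [])

    reml_full = _fit(cols + ["inter"], reml=True)
    ml_full = _fit(cols + ["inter"], reml=False)
    ml_null = _fit(cols, reml=False)

    idx = 1 + len(cols)  # intercept + covariates precede the interaction
    beta = float(reml_full.fe_params[idx])
    se = float(reml_full.bse_fe[idx])
    df = n_subj - 2
    tval = beta / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(tval), df)

    lr = max(0.0, 2.0 * (ml_full.llf - ml_null.llf))
    lr_p = stats.chi2.sf(lr, df=1)

    fitted = _exog(cols + ["inter"]) @ ml_full.fe_params
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    k = len(cols) + 1
    n_obs = len(long)
    r2_adj = 1 - (1 - r2) * (n_obs - 1) / (n_obs - k - 1)

    return MixedModelResult(
        beta_interaction=beta,
        se=se,
        t_value=float(tval),
        df=df,
        p=float(p),
        lr_chi2=float(lr),
        lr_p=float(lr_p),
        aic=float(ml_full.aic),
        bic=float(ml_full.bic),
        r2=r2,
        r2_adjusted=float(r2_adj),
        age_included=use_age,
        converged=bool(reml_full.converged),
    )


# ---------------------------------------------------------------------------
# effect sizes, respondents, PPV


def hedges_g_prepost(pre, post) -> float:
    """Hedges g for a paired pre/post contrast.

    g = J (mean(post) - mean(pre)) / s_avg with the averaged pre/post SD
    denominator s_avg = sqrt((sd_pre^2 + sd_post^2)/2) and small-sample
    correction J = 1 - 3/(4(n-1) - 1). Negative g means the score decreased.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size != post.size:
        raise ValueError("pre and post must be paired (equal length)")
    n = pre.size
    if n < 3:
        raise ValueError("need n >= 3")
    s_avg = np.sqrt((pre.std(ddof=1) ** 2 + post.std(ddof=1) ** 2) / 2)
    if s_avg == 0:
        if np.allclose(post, pre):
            return 0.0
        raise ValueError("zero averaged SD with unequal means")
    J = 1 - 3 / (4 * (n - 1) - 1)
    return float(J * (post.mean() - pre.mean()) / s_avg)


def respondent_analysis(
    pre, post, threshold_sd: float = 0.64, sd_ref: float | None = None
) -> tuple[int, float]:
    """Count participants whose improvement reaches a standardized threshold.

    A respondent satisfies (pre - post)/sd_ref >= threshold_sd (a drop in
    commission errors is improvement); the inequality is inclusive.
    ``sd_ref`` defaults to the SD of the pre scores.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size != post.size:
        raise ValueError("pre and post must be paired")
    if sd_ref is None:
        sd_ref = float(pre.std(ddof=1))
    if sd_ref <= 0:
        raise ValueError("sd_ref must be > 0")
    resp = (pre - post) / sd_ref >= threshold_sd - 1e-12
    count = int(resp.sum())
    return count, count / pre.size


def ppv(power: float, alpha: float, R: float) -> float:
    """Positive predictive value given power, alpha and prestudy odds R.

    PPV = power R / (power R + alpha): the probability a claimed positive is
    a true positive when a fraction R/(R+1) of probed effects are real.
    """
    if not 0 < power <= 1:
        raise ValueError("power must be in (0, 1]")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if R <= 0:
        raise ValueError("prestudy odds R must be > 0")
    return power * R / (power * R + alpha)


@dataclass
class PowerPPVResult:
    power: float
    n_sims: int
    alpha: float
    prestudy_odds: float
    ppv: float

    def __post_init__(self) -> None:
        expected = ppv(self.power, self.alpha, self.prestudy_odds) \
            if self.power > 0 else 0.0
        if abs(self.ppv - expected) > 1e-12:
            raise ValueError("ppv inconsistent with power/alpha/R")


def simulate_power(
    effect_sd: float,
    n_per_arm: tuple[int, int] = (15, 14),
    alpha: float = 0.05,
    n_sims: int = 200,
    seed: int | None = None,
    prestudy_odds: float = 0.5,
    icc: float = 0.5,
) -> PowerPPVResult:
    """Simulation-based power of the mixed model's interaction test.

    Each simulated cohort draws standardized scores with a participant random
    intercept of variance ``icc`` and residual variance 1 - icc (unit
    baseline variance), adds ``effect_sd`` to the experimental arm's post
    scores, and fits the same mixed model used for the real analysis. Power
    is the fraction of interaction p-values below ``alpha``; PPV follows from
    the analytic formula.
    """
    if n_sims < 50:
        raise ValueError("n_sims must be >= 50")
    if not 0 <= icc < 1:
        raise ValueError("icc must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ne, nc = n_per_arm
    n = ne + nc
    arm = np.array(["experimental"] * ne + ["control"] * nc)
    ids = np.array([f"S{i:03d}" for i in range(n)])
    rejections = 0
    for _ in range(n_sims):
        u = rng.normal(0.0, np.sqrt(icc), size=n)
        pre = u + rng.normal(0.0, np.sqrt(1 - icc), size=n)
        post = u + rng.normal(0.0, np.sqrt(1 - icc), size=n)
        post[:ne] += effect_sd
        long = pd.DataFrame(
            {
                "participant_id": np.tile(ids, 2),
                "arm": np.tile(arm, 2),
                "period": ["pre"] * n + ["post"] * n,
                "score": np.concatenate([pre, post]),
            }
        )
        res = fit_prepost_mixed_model(long, standardize=True, age_covariate="never")
        if res.p < alpha:
            rejections += 1
    power = rejections / n_sims
    return PowerPPVResult(
        power=power,
        n_sims=n_sims,
        alpha=alpha,
        prestudy_odds=prestudy_odds,
        ppv=ppv(power, alpha, prestudy_odds) if power > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# questionnaire scores


def paired_t(pre, post) -> tuple[float, int, float]:
    """Paired-samples t test on pre/post scores (two-sided)."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size != post.size:
        raise ValueError("pre and post must be paired")
    n = pre.size
    if n < 3:
        raise ValueError("need n >= 3")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences (degenerate)")
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), n - 1, float(2 * stats.t.sf(abs(t), n - 1))


def bonferroni_families(p_by_family: dict[str, dict[str, float]]
                        ) -> dict[str, dict[str, float]]:
    """Bonferroni-adjust p-values within each independent statistical family.

    The correction factor is the number of tests inside the family (not the
    grand total across families); adjusted values cap at 1.
    """
    out: dict[str, dict[str, float]] = {}
    for family, pvals in p_by_family.items():
        k = len(pvals)
        out[family] = {name: min(1.0, p * k) for name, p in pvals.items()}
    return out


def cutoff_respondents(scores, cutoff: float, direction: str = "below"
                       ) -> tuple[int, float]:
    """Count scores reaching a clinical cutoff (e.g. dropping below pathology)."""
    scores = np.asarray(scores, float)
    if direction == "below":
        hit = scores < cutoff
    elif direction == "above":
        hit = scores > cutoff
    else:
        raise ValueError("direction must be 'below' or 'above'")
    return int(hit.sum()), float(hit.mean())


# ---------------------------------------------------------------------------
# model / results facade


class TrialOutcomeModel:
    """Trial analytics bundled as a fittable model over a cohort table."""

    def __init__(self, cohort: CohortTable,
                 respondent_threshold_sd: float = 0.64):
        self.cohort = cohort
        self.respondent_threshold_sd = respondent_threshold_sd

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TrialOutcomeModel":
        return cls(CohortTable(df), **kwargs)

    def fit(self, age_covariate: str = "stepwise") -> "TrialOutcomeResults":
        cohort = self.cohort
        long = cohort_to_long(cohort)
        mixed = fit_prepost_mixed_model(long, age_covariate=age_covariate)

        df = cohort.data
        effects = {}
        respondents = {}
        sd_ref = float(df["cpt_commission_pre"].std(ddof=1))
        for arm in ("experimental", "control"):
            m = cohort.arm_mask(arm)
            pre = np.asarray(df.loc[m, "cpt_commission_pre"], float)
            post = np.asarray(df.loc[m, "cpt_commission_post"], float)
            effects[arm] = hedges_g_prepost(pre, post)
            respondents[arm] = respondent_analysis(
                pre, post, self.respondent_threshold_sd, sd_ref
            )
        return TrialOutcomeResults(
            model=self,
            baseline=baseline_table(cohort),
            mixed=mixed,
            hedges_g=effects,
            respondents=respondents,
        )


class TrialOutcomeResults:
    def __init__(self, model, baseline, mixed, hedges_g, respondents):
        self.model = model
        self.baseline = baseline
        self.mixed = mixed
        self.hedges_g = hedges_g
        self.respondents = respondents

    def power_ppv(self, effect_sd: float = 0.64, alpha: float = 0.05,
                  n_sims: int = 200, seed: int | None = None,
                  prestudy_odds: float = 0.5) -> PowerPPVResult:
        cohort = self.model.cohort
        return simulate_power(
            effect_sd,
            (cohort.n_experimental, cohort.n_control),
            alpha=alpha,
            n_sims=n_sims,
            seed=seed,
            prestudy_odds=prestudy_odds,
        )

    def summary(self) -> str:
        m = self.mixed
        lines = [
            "Two-arm pre/post trial analytics",
            "=" * 40,
            "Baseline comparisons:",
            self.baseline.to_string(index=False),
            "",
            "Mixed model (condition x period interaction, standardized):",
            f"  beta = {m.beta_interaction:.3f}  SE = {m.se:.3f}  "
            f"t({m.df}) = {m.t_value:.2f}  p = {m.p:.3f}",
            f"  LR chi2(1) = {m.lr_chi2:.3f}  p = {m.lr_p:.3f}  "
            f"AIC = {m.aic:.1f}  BIC = {m.bic:.1f}",
            "",
            "Pre/post Hedges g: "
            + ", ".join(f"{arm} = {g:.2f}" for arm, g in self.hedges_g.items()),
            "Respondents (>= {:.2f} SD improvement): ".format(
                self.model.respondent_threshold_sd
            )
            + ", ".join(
                f"{arm} = {c}/{self._arm_n(arm)} ({100 * f:.1f}%)"
                for arm, (c, f) in self.respondents.items()
            ),
        ]
        return "\n".join(lines)

    def _arm_n(self, arm: str) -> int:
        return int(self.model.cohort.arm_mask(arm).sum())
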