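"""Genotype-by-drug comparison of HRV metrics with a linear mixed model.

For each metric, the model is

    value ~ genotype + drug + genotype:drug,  random intercept per animal

fitted by REML, where ``drug`` is the pre/post indicator for a single
drug session and each animal contributes its own-day baseline as the
pre rows.  Fixed-effect tests and pairwise least-squares-mean
differences use the Satterthwaite approximation for denominator
degrees of freedom.

Fitting delegates to :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
the design construction, contrasts, Satterthwaite df and the
significance flags (genotype main effect, drug main effect, pairwise
differences under a significant interaction) are implemented here.
Each fixed-effect test has one numerator df, so F = t^2 with the same
denominator df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

#: flag glyphs: genotype main effect, drug main effect, pairwise (interaction)
FLAG_GENOTYPE = "‡"  # double dagger
FLAG_DRUG = "T"
FLAG_PAIRWISE = "*"


@dataclass
class EffectTest:
    name: str
    estimate: float
    se: float
    df: float
    f_value: float
    p_value: float


@dataclass
class ComparisonResult:
    metric: str
    effects: dict            # name -> EffectTest (genotype, drug, interaction)
    pairwise: dict           # name -> EffectTest (LS-mean differences)
    flags: str               # concatenation of significant-effect glyphs
    n_animals: int
    n_obs: int
    var_animal: float        # random-intercept variance
    var_resid: float
    fallback: bool = False   # True when a singular fit fell back to paired t

    def significant_pairs(self, alpha: float = 0.05) -> list[str]:
        if self.effects["interaction"].p_value >= alpha:
            return []
        return [k for k, v in self.pairwise.items() if v.p_value < alpha]


# ---------------------------------------------------------------------------
# REML machinery for the random-intercept model (Satterthwaite df)

def _build_v(theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    va, ve = theta
    return va * (z @ z.T) + ve * np.eye(z.shape[0])


def _reml_loglik(theta: np.ndarray, y: np.ndarray, x: np.ndarray, z: np.ndarray) -> float:
    v = _build_v(theta, z)
    sign, logdet_v = np.linalg.slogdet(v)
    if sign <= 0:
        return -np.inf
    vi = np.linalg.inv(v)
    xtvix = x.T @ vi @ x
    sign2, logdet_x = np.linalg.slogdet(xtvix)
    if sign2 <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvix, x.T @ vi @ y)
    r = y - x @ beta
    return -0.5 * (logdet_v + logdet_x + r @ vi @ r)


def _contrast_variance(theta: np.ndarray, x: np.ndarray, z: np.ndarray, c: np.ndarray) -> float:
    v = _build_v(theta, z)
    vi = np.linalg.inv(v)
    cov_beta = np.linalg.inv(x.T @ vi @ x)
    return float(c @ cov_beta @ c)


def _satterthwaite_df(
    theta: np.ndarray, y: np.ndarray, x: np.ndarray, z: np.ndarray, c: np.ndarray
) -> float:
    """Satterthwaite denominator df for the contrast c'beta.

    df = 2 f^2 / (g' A g) with f = Var(c'beta) as a function of the
    variance components, g its gradient at the REML estimate, and A the
    inverse observed REML information.  Degenerate geometry (boundary
    variance estimates, non-PD information) falls back to the residual
    df n - p.
    """
    n, p = x.shape
    resid_df = float(n - p)
    f0 = _contrast_variance(theta, x, z, c)
    steps = np.maximum(1e-4 * np.abs(theta), 1e-8)
    grad = np.empty(2)
    hess = np.empty((2, 2))
    ll = lambda t: _reml_loglik(t, y, x, z)
    f = lambda t: _contrast_variance(t, x, z, c)
    for i in range(2):
        e = np.zeros(2)
        e[i] = steps[i]
        tp, tm = theta + e, np.maximum(theta - e, 1e-12)
        grad[i] = (f(tp) - f(tm)) / (tp[i] - tm[i])
    ll0 = ll(theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = steps[i]
            ej = np.zeros(2); ej[j] = steps[j]
            if i == j:
                hess[i, i] = (ll(theta + ei) - 2 * ll0 + ll(np.maximum(theta - ei, 1e-12))) / steps[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    ll(theta + ei + ej) - ll(theta + ei - ej)
                    - ll(theta - ei + ej) + ll(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
    if not np.all(np.isfinite(hess)):
        return resid_df
    try:
        a = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return resid_df
    denom = float(grad @ a @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return resid_df
    df = 2.0 * f0**2 / denom
    return float(np.clip(df, 1.0, resid_df))


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .io import records_to_frame
    return records_to_frame(list(records))


def _prepare(
    records, metric: str, drug: str, baseline: str
) -> pd.DataFrame:
    df = _records_frame(records)
    df = df[df["metric"] == metric]
    df = df[df["condition"].isin([baseline, drug])].copy()
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r} under {baseline!r}/{drug!r}")
    have = df.groupby("animal_id")["condition"].agg(lambda s: set(s))
    unpaired = sorted(a for a, conds in have.items() if {baseline, drug} - conds)
    if unpaired:
        raise ValueError(
            f"animals missing a {baseline!r} or {drug!r} row: {unpaired}"
        )
    genotypes = sorted(df["genotype"].unique())
    if len(genotypes) != 2:
        raise ValueError(f"need exactly 2 genotypes, found {genotypes}")
    per_geno = df.groupby("genotype")["animal_id"].nunique()
    if (per_geno < 2).any():
        raise ValueError(f"need >= 2 animals per genotype, have {dict(per_geno)}")
    return df


def _paired_fallback(df: pd.DataFrame, metric: str, drug: str, baseline: str,
                     geno_ref: str, geno_alt: str, alpha: float) -> ComparisonResult:
    """Paired-difference t analysis used when the mixed model is singular."""
    wide = (
        df.groupby(["animal_id", "genotype", "condition"])["value"].mean().unstack("condition")
    )
    diff = (wide[drug] - wide[baseline]).rename("diff").reset_index()
    means = df.groupby(["animal_id", "genotype"])["value"].mean().reset_index()
    d_ref = diff.loc[diff["genotype"] == geno_ref, "diff"].to_numpy()
    d_alt = diff.loc[diff["genotype"] == geno_alt, "diff"].to_numpy()
    m_ref = means.loc[means["genotype"] == geno_ref, "value"].to_numpy()
    m_alt = means.loc[means["genotype"] == geno_alt, "value"].to_numpy()

    def _tt(t, df_, est, se) -> EffectTest:
        p = 2 * sps.t.sf(abs(t), df_)
        return EffectTest("", float(est), float(se), float(df_), float(t**2), float(p))

    tg = sps.ttest_ind(m_alt, m_ref)
    td = sps.ttest_1samp(np.concatenate([d_ref, d_alt]), 0.0)
    ti = sps.ttest_ind(d_alt, d_ref)
    effects = {
        "genotype": _tt(tg.statistic, tg.df, m_alt.mean() - m_ref.mean(), np.nan),
        "drug": _tt(td.statistic, td.df, np.concatenate([d_ref, d_alt]).mean(), np.nan),
        "interaction": _tt(ti.statistic, ti.df, d_alt.mean() - d_ref.mean(), np.nan),
    }
    for k, v in effects.items():
        v.name = k
    flags = "".join(
        g for g, k in ((FLAG_GENOTYPE, "genotype"), (FLAG_DRUG, "drug"))
        if effects[k].p_value < alpha
    )
    return ComparisonResult(
        metric=metric, effects=effects, pairwise={}, flags=flags,
        n_animals=int(df["animal_id"].nunique()), n_obs=int(len(df)),
        var_animal=float("nan"), var_resid=float("nan"), fallback=True,
    )


def fit_genotype_drug_model(
    records,
    metric: str,
    drug: str,
    baseline: str = "basal",
    genotype_ref: str = "WT",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Fit the genotype x drug mixed model for one metric.

    ``records`` is a tidy HRVRecord table (or list); rows under
    ``baseline`` are the pre-drug session, rows under ``drug`` the
    post-drug session; every animal must have both.  Main effects are
    tested at the average over the other factor (least-squares means);
    the interaction is the difference of within-animal drug responses
    between genotypes.  On a singular mixed fit, the analysis falls
    back to paired-difference t tests (``fallback=True``).
    """
    df = _prepare(records, metric, drug, baseline)
    genotypes = sorted(df["genotype"].unique())
    geno_alt = [g for g in genotypes if g != genotype_ref]
    if len(geno_alt) != 1:
        raise ValueError(f"genotype_ref {genotype_ref!r} not in data {genotypes}")
    geno_alt = geno_alt[0]

    g = (df["genotype"] == geno_alt).to_numpy(float)
    d = (df["condition"] == drug).to_numpy(float)
    x = np.column_stack([np.ones(len(df)), g, d, g * d])
    y = df["value"].to_numpy(float)
    animals = pd.Categorical(df["animal_id"])
    z = np.eye(len(animals.categories))[animals.codes]

    # exactly-identified (zero-residual) data: skip the mixed fit, which
    # cannot estimate variance components, and use OLS with a variance floor
    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    ols_resid = y - x @ beta_ols
    scale_y = max(float(np.max(np.abs(y))), 1.0)
    if float(np.max(np.abs(ols_resid))) < 1e-9 * scale_y:
        va, ve = 0.0, 0.0
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, x, groups=np.asarray(animals.codes))
                res = model.fit(reml=True)
            va = float(np.atleast_2d(res.cov_re)[0, 0])
            ve = float(res.scale)
            beta = np.asarray(res.fe_params, dtype=float)
            singular = not (np.all(np.isfinite(beta)) and np.isfinite(va) and np.isfinite(ve))
        except (np.linalg.LinAlgError, ValueError):
            singular = True
        if singular:
            return _paired_fallback(df, metric, drug, baseline, genotype_ref, geno_alt, alpha)

    # floor the residual variance: a zero-noise fit leaves V singular,
    # and GLS at a tiny floor reduces to OLS with exact estimates
    vary = float(np.var(y)) or 1.0
    theta = np.array([max(va, 0.0), max(ve, 1e-10 * vary)])
    try:
        # recompute GLS beta at the REML variance components (matches res.fe_params)
        v = _build_v(theta, z)
        vi = np.linalg.inv(v)
        beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
    except np.linalg.LinAlgError:
        return _paired_fallback(df, metric, drug, baseline, genotype_ref, geno_alt, alpha)

    contrasts = {
        "genotype": np.array([0.0, 1.0, 0.0, 0.5]),
        "drug": np.array([0.0, 0.0, 1.0, 0.5]),
        "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
    }
    pair_contrasts = {
        f"{genotype_ref}:{drug}-{baseline}": np.array([0.0, 0.0, 1.0, 0.0]),
        f"{geno_alt}:{drug}-{baseline}": np.array([0.0, 0.0, 1.0, 1.0]),
        f"{baseline}:{geno_alt}-{genotype_ref}": np.array([0.0, 1.0, 0.0, 0.0]),
        f"{drug}:{geno_alt}-{genotype_ref}": np.array([0.0, 1.0, 0.0, 1.0]),
    }

    def _test(name: str, c: np.ndarray) -> EffectTest:
        est = float(c @ beta)
        var_c = _contrast_variance(theta, x, z, c)
        se = float(np.sqrt(var_c))
        ddf = _satterthwaite_df(theta, y, x, z, c)
        t = est / se if se > 0 else np.inf
        p = float(2 * sps.t.sf(abs(t), ddf))
        return EffectTest(name, est, se, ddf, float(t**2), p)

    effects = {k: _test(k, c) for k, c in contrasts.items()}
    pairwise = {k: _test(k, c) for k, c in pair_contrasts.items()}

    flags = ""
    if effects["genotype"].p_value < alpha:
        flags += FLAG_GENOTYPE
    if effects["drug"].p_value < alpha:
        flags += FLAG_DRUG
    if effects["interaction"].p_value < alpha and any(
        v.p_value < alpha for v in pairwise.values()
    ):
        flags += FLAG_PAIRWISE

    return ComparisonResult(
        metric=metric,
        effects=effects,
        pairwise=pairwise,
        flags=flags,
        n_animals=int(df["animal_id"].nunique()),
        n_obs=int(len(df)),
        var_animal=va,
        var_resid=ve,
    )


def one_way_genotype_anova(
    records, metric: str, bin_column: str | None = None
) -> pd.DataFrame:
    """One-way genotype ANOVA, optionally per bin (e.g. hourly averages).

    Returns one row per bin with F and p; with no ``bin_column`` a
    single row is returned for the pooled data.
    """
    df = _records_frame(records)
    df = df[df["metric"] == metric]
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    genotypes = sorted(df["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError(f"need >= 2 genotypes, found {genotypes}")
    bins = [(None, df)] if bin_column is None else list(df.groupby(bin_column))
    rows = []
    for label, g in bins:
        groups = [grp["value"].to_numpy(float) for _, grp in g.groupby("genotype")]
        if np.ptp([grp.mean() for grp in groups]) == 0:
            f, p = 0.0, 1.0  # identical group means: no between-group variation
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = sps.f_oneway(*groups)
        rows.append({"bin": label, "f_value": float(f), "p_value": float(p),
                     "n": int(len(g))})
    return pd.DataFrame(rows)
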