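"""Statistical battery for cohort-level analyses.

Implements the study-style inference layer: paired t-tests with the paired
Cohen's d (d_z = mean(diff)/sd(diff)), one-sample t-tests with Bonferroni
correction, univariate repeated-measures / split-plot ANOVAs with subjects as
a random blocking factor and classical error terms (each within effect tested
against its interaction with subjects), eta-squared effect sizes
(SS_effect / SS_total), the Lilliefors normality test with a seeded
Monte Carlo p-value, and through-origin regression |y| = a|z| with the
uncentered R² and a Pearson r as effect size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


class StatError(ValueError):
    pass


# -- t tests -----------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    cohens_d: float
    p_corrected: float | None = None

    def to_dict(self) -> dict:
        d = {"t": self.t, "df": self.df, "p": self.p,
             "mean_diff": self.mean_diff, "cohens_d": self.cohens_d}
        if self.p_corrected is not None:
            d["p_corrected"] = self.p_corrected
        return d


def _one_sample(d: np.ndarray, label: str) -> TTestResult:
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n < 2:
        raise StatError(f"{label}: need n >= 2, got {n}")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise StatError(f"{label}: zero-variance differences")
    mean = float(np.mean(d))
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p, mean_diff=mean, cohens_d=mean / sd)


def paired_t(x, y) -> TTestResult:
    """Paired t-test on matched samples; d is the paired d_z on x - y."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise StatError(f"paired_t: length mismatch {x.shape} vs {y.shape}")
    return _one_sample(x - y, "paired_t")


def one_sample_t(sample, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test of mean(sample) against mu0."""
    return _one_sample(np.asarray(sample, float) - mu0, "one_sample_t")


def one_sample_t_bonferroni(samples, mu0: float = 0.0,
                            m: int | None = None) -> list[TTestResult]:
    """One-sample t per sample with Bonferroni-corrected p (min(1, m*p))."""
    samples = list(samples)
    m = len(samples) if m is None else m
    results = []
    for sample in samples:
        res = one_sample_t(sample, mu0)
        results.append(
            TTestResult(**{**res.to_dict(), "p_corrected": min(1.0, m * res.p)})
        )
    return results


# -- repeated-measures / split-plot ANOVA ------------------------------------

@dataclass
class AnovaResult:
    """Sums-of-squares decomposition with classical repeated-measures error
    terms.  ``effects`` has one row per tested effect (F, dfs, p, eta_sq,
    error term); ``strata`` lists every SS in the decomposition (they sum to
    ``ss_total``)."""

    effects: pd.DataFrame
    strata: pd.DataFrame
    ss_total: float

    def effect(self, name: str) -> pd.Series:
        hit = self.effects[self.effects["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect {name!r}; have {list(self.effects['effect'])}")
        return hit.iloc[0]


def _mean_over(df: pd.DataFrame, by: list[str], dv: str) -> pd.Series:
    if not by:
        return df[dv].mean()
    return df.groupby(by, observed=True)[dv].mean()


def _ss_effect(df: pd.DataFrame, dv: str, factors: list[str],
               all_factors: list[str]) -> float:
    """SS of one effect in a balanced full factorial via Möbius inversion:
    sum over cells of (inclusion-exclusion combination of marginal means)²,
    scaled by the number of observations per cell of the effect's margin."""
    n_total = len(df)
    grand = float(df[dv].mean())
    levels = {f: df[f].nunique() for f in all_factors}
    cells = int(np.prod([levels[f] for f in factors])) if factors else 1
    per_cell = n_total / cells
    margin = _mean_over(df, factors, dv)
    # inclusion-exclusion over sub-margins
    keys = margin.index.to_frame(index=False) if factors else pd.DataFrame([{}])
    acc = np.zeros(len(keys))
    for r in range(len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            sign = (-1) ** (len(factors) - len(sub))
            if not sub:
                acc += sign * grand
                continue
            sub_margin = _mean_over(df, list(sub), dv)
            key_cols = keys[list(sub)]
            if len(sub) == 1:
                vals = sub_margin.reindex(key_cols.iloc[:, 0]).to_numpy()
            else:
                vals = sub_margin.reindex(
                    pd.MultiIndex.from_frame(key_cols)).to_numpy()
            acc += sign * vals
    total = float(np.sum(acc ** 2) * per_cell)
    return total


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str | None = None,
) -> AnovaResult:
    """Repeated-measures (or split-plot) ANOVA with subjects as random factor.

    ``data`` is long-form with one observation per subject x within-cell.
    Every within effect (and its interactions with the between factor) is
    tested against its interaction with subjects; in the split-plot design
    the between factor is tested against the between-subject residual.
    Incomplete subjects are dropped listwise (logged); a design left
    unbalanced after deletion raises :class:`StatError`.  One pure-within
    bonus row tests the subject effect against the highest-order residual
    (the individual-differences test).  eta_sq = SS_effect / SS_total.
    """
    if not within:
        raise StatError("need at least one within factor")
    factors = list(within) + ([between] if between else [])
    df = data[[subject, dv, *factors]].copy()

    cells_per_subject = int(np.prod([df[w].nunique() for w in within]))
    counts = df.groupby(subject, observed=True).size()
    bad = counts[counts != cells_per_subject].index.tolist()
    if bad:
        logger.info("rm_anova: dropping %d incomplete subject(s): %s", len(bad), bad)
        df = df[~df[subject].isin(bad)]
    if df.empty or df[subject].nunique() < 2:
        raise StatError("fewer than 2 complete subjects")
    cell_sizes = df.groupby([subject, *within], observed=True).size()
    if (cell_sizes != 1).any():
        raise StatError(
            "design error: duplicated or missing cells "
            f"{cell_sizes[cell_sizes != 1].index.tolist()[:5]}"
        )
    if between is not None:
        per_subj_groups = df.groupby(subject, observed=True)[between].nunique()
        if (per_subj_groups != 1).any():
            raise StatError("between factor must be constant within subject")
        group_sizes = df.drop_duplicates(subject).groupby(between, observed=True).size()
        if group_sizes.nunique() != 1:
            raise StatError(f"unbalanced between-groups design: {group_sizes.to_dict()}")

    n_subj = df[subject].nunique()
    grand = float(df[dv].mean())
    ss_total = float(np.sum((df[dv] - grand) ** 2))
    all_factors = [subject, *factors]

    ss: dict[tuple[str, ...], float] = {}
    strata_rows = []

    def level_count(fs: tuple[str, ...]) -> int:
        return int(np.prod([df[f].nunique() for f in fs])) if fs else 1

    if between is None:
        # pure within: full decomposition over {subject} x within-subsets
        within_subsets = [tuple(c) for r in range(len(within) + 1)
                          for c in itertools.combinations(within, r)]
        combos = []
        for wsub in within_subsets:
            if wsub:
                combos.append(wsub)                       # fixed effect
            combos.append((subject, *wsub))               # its error stratum
        for combo in combos:
            ss[combo] = _ss_effect(df, dv, list(combo), all_factors)
        df_of = {}
        for combo in combos:
            dfree = int(np.prod([df[f].nunique() - 1 for f in combo]))
            df_of[combo] = dfree
            strata_rows.append(("*".join(combo), ss[combo], dfree))
        rows = []
        highest = (subject, *within)
        for wsub in within_subsets:
            if not wsub:
                continue
            err = (subject, *wsub)
            rows.append(_f_row("*".join(wsub), ss[wsub], df_of[wsub],
                               ss[err], df_of[err], "*".join(err), ss_total))
        # individual-differences test: subject vs highest-order residual
        rows.append(_f_row(subject, ss[(subject,)], df_of[(subject,)],
                           ss[highest], df_of[highest], "*".join(highest), ss_total))
    else:
        g = df[between].nunique()
        df_between_err = n_subj - g
        # between stratum
        ss_g = _ss_effect(df, dv, [between], all_factors)
        subj_means = df.groupby([subject, between], observed=True)[dv].mean()
        group_means = df.groupby(between, observed=True)[dv].mean()
        m_per_subj = len(df) / n_subj
        ss_subj_g = float(
            np.sum((subj_means - group_means.reindex(
                subj_means.index.get_level_values(between)).to_numpy()) ** 2)
            * m_per_subj
        )
        strata_rows += [(between, ss_g, g - 1),
                        (f"{subject}({between})", ss_subj_g, df_between_err)]
        rows = [_f_row(between, ss_g, g - 1, ss_subj_g, df_between_err,
                       f"{subject}({between})", ss_total)]
        # within strata: for each nonempty within subset W, effects W and W*G
        # are tested against W*subject(G)
        for r in range(1, len(within) + 1):
            for wsub in itertools.combinations(within, r):
                ss_w = _ss_effect(df, dv, list(wsub), all_factors)
                ss_wg = _ss_effect(df, dv, [*wsub, between], all_factors)
                # W x subject(G): inside each group, interaction of W with subject
                ss_ws = 0.0
                for _, gdf in df.groupby(between, observed=True):
                    ss_ws += _ss_effect(gdf, dv, [subject, *wsub],
                                        [subject, *within])
                dfree_w = int(np.prod([df[f].nunique() - 1 for f in wsub]))
                dfree_wg = dfree_w * (g - 1)
                dfree_ws = dfree_w * df_between_err
                strata_rows += [("*".join(wsub), ss_w, dfree_w),
                                ("*".join([*wsub, between]), ss_wg, dfree_wg),
                                ("*".join([*wsub, f"{subject}({between})"]), ss_ws, dfree_ws)]
                rows.append(_f_row("*".join(wsub), ss_w, dfree_w, ss_ws,
                                   dfree_ws, "*".join([*wsub, f"{subject}({between})"]),
                                   ss_total))
                rows.append(_f_row("*".join([*wsub, between]), ss_wg, dfree_wg,
                                   ss_ws, dfree_ws,
                                   "*".join([*wsub, f"{subject}({between})"]), ss_total))

    effects = pd.DataFrame(rows)
    strata = pd.DataFrame(strata_rows, columns=["stratum", "ss", "df"])
    if abs(strata["ss"].sum() - ss_total) > 1e-6 * max(1.0, ss_total):
        raise StatError(
            f"SS decomposition does not close: {strata['ss'].sum()} vs {ss_total}"
        )
    return AnovaResult(effects=effects, strata=strata, ss_total=ss_total)


def _f_row(name, ss_num, df_num, ss_den, df_den, error_term, ss_total) -> dict:
    ms_num = ss_num / df_num if df_num else np.nan
    ms_den = ss_den / df_den if df_den else np.nan
    f = ms_num / ms_den if ms_den and ms_den > 0 else 0.0
    p = float(sps.f.sf(f, df_num, df_den)) if df_den else np.nan
    return {
        "effect": name, "ss": ss_num, "df_num": df_num, "df_den": df_den,
        "F": float(f), "p": p, "eta_sq": ss_num / ss_total if ss_total > 0 else 0.0,
        "error_term": error_term,
    }


# -- Lilliefors normality test -----------------------------------------------

@dataclass(frozen=True)
class NormalityResult:
    D: float
    p: float
    n: int
    n_replicates: int
    seed: int


def _lilliefors_D(samples: np.ndarray) -> np.ndarray:
    """Kolmogorov-Smirnov D against a normal with estimated mean/sd.

    ``samples`` is (m, n); returns (m,) statistics.
    """
    x = np.sort(samples, axis=-1)
    n = x.shape[-1]
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=-1)
    d_minus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def lilliefors_null_distribution(n: int, n_replicates: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo null distribution of the Lilliefors D for sample size n."""
    draws = rng.standard_normal((n_replicates, n))
    return _lilliefors_D(draws)


def lilliefors(sample, n_replicates: int = 10000, seed: int = 0) -> NormalityResult:
    """Lilliefors test with a seeded Monte Carlo p-value.

    D = sup |empirical CDF - Normal(mean^, sd^) CDF|; p is the add-one
    Monte Carlo proportion of null statistics >= D from Gaussian samples of
    the same size with re-estimated parameters, so p is in (0, 1].
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise StatError(f"lilliefors: need n >= 4, got {len(x)}")
    if np.std(x, ddof=1) == 0:
        raise StatError("lilliefors: constant sample")
    d = float(_lilliefors_D(x[None, :])[0])
    rng = np.random.default_rng(seed)
    null = lilliefors_null_distribution(len(x), n_replicates, rng)
    p = (1 + int(np.sum(null >= d))) / (n_replicates + 1)
    return NormalityResult(D=d, p=float(p), n=len(x),
                           n_replicates=n_replicates, seed=seed)


# -- through-origin regression ------------------------------------------------

@dataclass
class RegressionFit:
    slope: float
    se: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    r_squared: float       # uncentered
    pearson_r: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "se": self.se, "ci95": list(self.ci95),
            "t": self.t, "df": self.df, "p": self.p,
            "r_squared": self.r_squared, "pearson_r": self.pearson_r, "n": self.n,
        }


def regress_origin(z, y, use_abs: bool = True) -> RegressionFit:
    """Through-origin fit |y| = a |z| (or y = a z with ``use_abs=False``).

    a = sum(z'y') / sum(z'^2); se = sqrt(SSE / (n - 1) / sum(z'^2)) with
    df = n - 1; R² is the uncentered 1 - SSE/sum(y'^2); the Pearson r of
    (z', y') is reported as the effect size.
    """
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    if z.shape != y.shape:
        raise StatError("regress_origin: length mismatch")
    n = len(z)
    if n < 3:
        raise StatError(f"regress_origin: need n >= 3, got {n}")
    zp, yp = (np.abs(z), np.abs(y)) if use_abs else (z, y)
    szz = float(np.sum(zp ** 2))
    if szz == 0:
        raise StatError("regress_origin: all-zero predictor")
    a = float(np.sum(zp * yp) / szz)
    resid = yp - a * zp
    df = n - 1
    sse = float(np.sum(resid ** 2))
    se = float(np.sqrt(sse / df / szz))
    tcrit = float(sps.t.ppf(0.975, df))
    t = a / se if se > 0 else np.inf
    p = 2.0 * float(sps.t.sf(abs(t), df))
    syy = float(np.sum(yp ** 2))
    r2 = 1.0 - sse / syy if syy > 0 else np.nan
    r = float(np.corrcoef(zp, yp)[0, 1]) if np.std(zp) > 0 and np.std(yp) > 0 else np.nan
    return RegressionFit(
        slope=a, se=se, ci95=(a - tcrit * se, a + tcrit * se), t=float(t),
        df=df, p=p, r_squared=r2, pearson_r=r, n=n, residuals=resid,
    )
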