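"""Cohort statistics: ROUT outliers, factorial ANOVA, Tukey, t-tests, and a
permutational three-way mixed ANOVA.

The centerpiece is :func:`perm_mixed_anova`, a split-plot (mixed-design)
ANOVA with up to two between-subject factors (genotype, age) and one
within-subject factor (brain ROI), tested by permutation. Each effect is
permuted within its exchangeability stratum:

* between-subject effects — subjects are shuffled across group labels and
  tested against the subject-within-group error stratum;
* within-subject effects — ROI labels are shuffled independently within each
  subject and tested against the ROI x subject residual stratum.

The permutation p-value is the plain proportion of permuted F-values
strictly larger than the observed F (no +1 correction by default).

Sums of squares are type II, computed as differences of residual sums of
squares between nested models. Because every permutation reuses the same
design matrices with a permuted response, each model's projection (hat)
matrix is precomputed once and all permutations reduce to vectorized
quadratic forms — 10,000 repetitions cost a handful of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaResult",
    "PosthocResult",
    "rout_outliers",
    "anova_twoway",
    "tukey_hsd",
    "t_tests",
    "perm_mixed_anova",
    "simple_main_effects",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    paired: bool
    note: str | None = None


@dataclass
class AnovaResult:
    """Per-effect F table. ``table`` has columns effect/F/df1/df2/p (and
    p_parametric when method == 'permutation')."""

    table: pd.DataFrame
    method: str  # 'parametric' | 'permutation'
    n_perm: int | None = None
    warnings: list[str] = field(default_factory=list)

    def p(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "p"])

    def F(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "F"])


@dataclass
class PosthocResult:
    table: pd.DataFrame  # group1, group2, mean_diff, q, p_adj
    method: str = "tukey_hsd"


# ---------------------------------------------------------------------------
# ROUT outlier detection


def rout_outliers(values: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Flag outliers with a ROUT-style robust FDR procedure.

    For a single sample the "robust regression" reduces to the median; scale
    is the RSDR analog — the 68.27th percentile of absolute residuals,
    inflated by n/(n-1) for the fitted parameter. Residual t-scores get
    two-sided p-values at n-1 df, and points are tested most-extreme-first
    against the Benjamini-Hochberg-style schedule p_(i) < q * i / n
    (i = 1 for the smallest p), stopping at the first failure — the
    false-discovery-rate analog of the ROUT procedure. Returns a boolean
    mask of flagged points.

    A zero-scale (all-identical) sample yields no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample with at least 3 values")
    if not 0.0 < q < 0.5:
        raise ValueError(f"Q must be in (0, 0.5), got {q}")
    n = x.size
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    flags = np.zeros(n, dtype=bool)
    if rsdr == 0.0:
        return flags
    t = np.abs(resid) / rsdr
    p = 2.0 * sps.t.sf(t, df=n - 1)
    order = np.argsort(p, kind="stable")
    for rank, idx in enumerate(order, start=1):
        if p[idx] < q * rank / n:
            flags[idx] = True
        else:
            break
    return flags


# ---------------------------------------------------------------------------
# t-tests


def t_tests(a: np.ndarray, b: np.ndarray, paired: bool = False) -> TTestResult:
    """Two-sided Student's t-test (pooled-variance when unpaired).

    Degenerate inputs (zero-variance paired differences, or two zero-variance
    samples) are flagged in ``note`` rather than raising: identical data give
    t=0, p=1; a constant nonzero shift gives an infinite t with p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("paired test requires equal-length samples")
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired:
        d = a - b
        n = d.size
        sd = d.std(ddof=1)
        df = n - 1
        if sd == 0.0:
            if np.all(d == 0):
                return TTestResult(0.0, df, 1.0, True, "all differences zero")
            t = np.inf if d[0] > 0 else -np.inf
            return TTestResult(t, df, 0.0, True, "constant nonzero differences")
        t = d.mean() / (sd / np.sqrt(n))
    else:
        na, nb = a.size, b.size
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        if sp2 == 0.0:
            if a.mean() == b.mean():
                return TTestResult(0.0, df, 1.0, False, "zero pooled variance")
            t = np.inf if a.mean() > b.mean() else -np.inf
            return TTestResult(t, df, 0.0, False, "zero pooled variance")
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df=df)
    return TTestResult(float(t), float(df), float(p), paired)


# ---------------------------------------------------------------------------
# two-way ANOVA (parametric) + Tukey


def anova_twoway(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "age",
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with type-II sums of squares.

    A factor with a single level collapses the model to a one-way ANOVA on
    the other factor (constant factors carry no sums of squares).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[value, factor_a, factor_b]].copy()
    if df[factor_a].nunique() == 1 and df[factor_b].nunique() == 1:
        raise ValueError("both factors are constant")
    for fac, other in ((factor_b, factor_a), (factor_a, factor_b)):
        if df[fac].nunique() == 1:
            d1 = df.rename(columns={value: "_y", other: "_a"})
            model = smf.ols("_y ~ C(_a)", data=d1).fit()
            aov = sm.stats.anova_lm(model, typ=2)
            row = {"effect": other, "F": float(aov.loc["C(_a)", "F"]),
                   "df1": float(aov.loc["C(_a)", "df"]),
                   "df2": float(aov.loc["Residual", "df"]),
                   "p": float(aov.loc["C(_a)", "PR(>F)"])}
            return AnovaResult(pd.DataFrame([row]), method="parametric")
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    full = pd.MultiIndex.from_product(
        [df[factor_a].unique(), df[factor_b].unique()]
    )
    missing = full.difference(counts.index)
    if len(missing) > 0:
        raise ValueError(f"empty design cell: {tuple(missing[0])}")
    if (counts < 2).any():
        cell = counts[counts < 2].index[0]
        raise ValueError(f"cell {tuple(cell)} has fewer than 2 observations")
    df = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    resid_df = float(aov.loc["Residual", "df"])
    names = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": f"{factor_a}:{factor_b}",
    }
    rows = [
        {
            "effect": names[ix],
            "F": float(aov.loc[ix, "F"]),
            "df1": float(aov.loc[ix, "df"]),
            "df2": resid_df,
            "p": float(aov.loc[ix, "PR(>F)"]),
        }
        for ix in names
    ]
    return AnovaResult(pd.DataFrame(rows), method="parametric")


def tukey_hsd(
    table: pd.DataFrame, effect: str = "group", value: str = "value"
) -> PosthocResult:
    """Tukey(-Kramer) HSD over all levels of ``effect``.

    Uses the cell-means model: MSE pooled across groups with N - k residual
    df, studentized-range statistic q = |m_i - m_j| / sqrt(MSE/2 (1/n_i +
    1/n_j)), adjusted p from the studentized-range distribution. With two
    groups this reduces to the pooled t-test via q = |t| * sqrt(2).
    """
    g = table.groupby(effect, observed=True)[value]
    means, ns, vars_ = g.mean(), g.size(), g.var(ddof=1)
    k = len(means)
    if k < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs at least 2 observations")
    n_tot = int(ns.sum())
    df_resid = n_tot - k
    mse = float(((ns - 1) * vars_).sum() / df_resid)
    levels = list(means.index)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = levels[i], levels[j]
            diff = float(means[gi] - means[gj])
            se = np.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
            q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(sps.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
            rows.append(
                {"group1": gi, "group2": gj, "mean_diff": diff, "q": float(q),
                 "p_adj": min(p, 1.0)}
            )
    return PosthocResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# permutational mixed ANOVA machinery


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(labels, return_inverse=True)
    return np.eye(len(levels))[inv]


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank (SVD-based)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    r = int((s > tol).sum())
    u = u[:, :r]
    return u @ u.T, r


def _rss(Y: np.ndarray, H: np.ndarray | None) -> np.ndarray:
    """Residual sum of squares of each row of Y under projector H."""
    tot = np.einsum("pn,pn->p", Y, Y)
    if H is None:
        return tot
    return tot - np.einsum("pn,pn->p", Y @ H, Y)


def _interaction(*blocks: np.ndarray) -> np.ndarray:
    """Columnwise products of dummy blocks (full crossing)."""
    out = blocks[0]
    for b in blocks[1:]:
        out = (out[:, :, None] * b[:, None, :]).reshape(out.shape[0], -1)
    return out


class _Stratum:
    """One error stratum: nested type-II model comparisons on a fixed design,
    evaluated on many permuted responses at once."""

    def __init__(self, effects: dict[str, tuple[np.ndarray, np.ndarray]],
                 full_cols: np.ndarray):
        # effects: name -> (reduced design, reduced+effect design)
        self.H_full, self.rank_full = _hat(full_cols)
        self.n = full_cols.shape[0]
        self.df_err = self.n - self.rank_full
        self.models = {}
        for name, (red, red_plus) in effects.items():
            H_red, r_red = _hat(red)
            H_plus, r_plus = _hat(red_plus)
            df1 = r_plus - r_red
            self.models[name] = (H_red, H_plus, df1)

    def f_stats(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """F per effect for each row of Y (rows are permuted responses)."""
        rss_full = _rss(Y, self.H_full)
        ms_err = rss_full / self.df_err
        out = {}
        for name, (H_red, H_plus, df1) in self.models.items():
            ss = _rss(Y, H_red) - _rss(Y, H_plus)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[name] = np.where(ms_err > 0, (ss / df1) / ms_err, np.inf)
        return out


def _between_stratum(a: np.ndarray, b: np.ndarray | None,
                     names: tuple[str, str | None]) -> _Stratum:
    """Type-II comparisons for subject-level (between) effects."""
    n = a.shape[0]
    one = np.ones((n, 1))
    A = _dummies(a)
    if b is None:
        eff = {names[0]: (one, np.hstack([one, A]))}
        return _Stratum(eff, np.hstack([one, A]))
    B = _dummies(b)
    AB = _interaction(A, B)
    add = np.hstack([one, A, B])
    full = np.hstack([one, A, B, AB])
    eff = {
        names[0]: (np.hstack([one, B]), add),
        names[1]: (np.hstack([one, A]), add),
        f"{names[0]}:{names[1]}": (add, full),
    }
    return _Stratum(eff, full)


def _within_stratum(subj: np.ndarray, roi: np.ndarray, a: np.ndarray,
                    b: np.ndarray | None, names: tuple[str, ...],
                    within_name: str) -> _Stratum:
    """Type-II comparisons for the ROI stratum (subject dummies in every
    model soak up the between-subject variation)."""
    S = _dummies(subj)
    R = _dummies(roi)
    blocks: dict[str, np.ndarray] = {within_name: R}
    RA = _interaction(R, _dummies(a))
    blocks[f"{names[0]}:{within_name}"] = RA
    if b is not None:
        RB = _interaction(R, _dummies(b))
        RAB = _interaction(RA, _dummies(b))
        blocks[f"{names[1]}:{within_name}"] = RB
        blocks[f"{names[0]}:{names[1]}:{within_name}"] = RAB
    full = np.hstack([S] + list(blocks.values()))
    eff = {}
    # type II: condition on every term not containing the effect
    for name in blocks:
        others = [
            v for k, v in blocks.items()
            if k != name and not _contains(k, name)
        ]
        red = np.hstack([S] + others) if others else S
        eff[name] = (red, np.hstack([red, blocks[name]]))
    return _Stratum(eff, full)


def _contains(term: str, sub: str) -> bool:
    """True if ANOVA term ``term`` contains all factors of ``sub``."""
    return set(sub.split(":")) <= set(term.split(":"))


def _validate_design(df: pd.DataFrame, subject: str, between: tuple[str, ...],
                     within: str | None) -> None:
    subj_groups = df.groupby(subject, observed=True)
    for f in between:
        if (subj_groups[f].nunique() > 1).any():
            raise ValueError(f"factor {f!r} varies within a subject")
    if between:
        cells = df.groupby(list(between), observed=True)[subject].nunique()
        lv = [df[f].unique() for f in between]
        full = pd.MultiIndex.from_product(lv) if len(lv) > 1 else pd.Index(lv[0])
        if len(full.difference(cells.index)) > 0:
            raise ValueError("unbalanced design: empty between-subject cell")
    if within is not None:
        levels = set(df[within].unique())
        for sid, sub in subj_groups:
            if set(sub[within]) != levels or len(sub) != len(levels):
                raise ValueError(
                    f"subject {sid!r} lacks a complete single set of "
                    f"{within!r} levels"
                )


def perm_mixed_anova(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    between: tuple[str, ...] = ("genotype", "age"),
    within: str | None = "roi",
    subject: str = "subject_id",
    value: str = "value",
    scheme: str = "stratified",
    plus_one: bool = False,
    alpha: float = 0.05,
) -> AnovaResult:
    """Permutational mixed-design ANOVA (between x between x within).

    Observed F-statistics come from the split-plot decomposition: between
    effects on subject means against subject-within-group error; within
    effects against the ROI x subject residual. Null distributions respect
    each effect's exchangeability stratum — subjects are shuffled across
    between-group labels, ROI labels are shuffled independently within each
    subject. ``scheme='freedman_lane'`` instead permutes reduced-model
    residuals and adds back the reduced fit before computing F.

    p = #{F_perm > F_obs} / n_perm (strict inequality); ``plus_one=True``
    switches to the (#+1)/(n_perm+1) estimator. Parametric F-test p-values
    ride along in column ``p_parametric``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if scheme not in ("stratified", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    between = tuple(between)
    if not 1 <= len(between) + (within is not None) <= 3 or len(between) > 2:
        raise ValueError("need 1-2 between factors and at most one within factor")
    _validate_design(table, subject, between, within)
    rng = np.random.default_rng(seed)
    warnings: list[str] = []
    if n_perm * alpha < 10:
        warnings.append(
            f"n_perm={n_perm} gives coarse resolution at alpha={alpha}"
        )

    df = table.sort_values([subject] + ([within] if within else [])).reset_index(drop=True)
    rows = []

    # ----- between stratum: operates on subject means
    if between:
        subj_tab = (
            df.groupby(subject, observed=True)
            .agg({value: "mean", **{f: "first" for f in between}})
            .reset_index()
        )
        m = subj_tab[value].to_numpy(float)
        a_lab = subj_tab[between[0]].to_numpy()
        b_lab = subj_tab[between[1]].to_numpy() if len(between) > 1 else None
        stratum = _between_stratum(a_lab, b_lab, (between[0], between[1] if b_lab is not None else None))
        perms = np.empty((n_perm + 1, m.size))
        perms[0] = m
        idx = np.arange(m.size)
        for k in range(n_perm):
            perms[k + 1] = m[rng.permutation(idx)]
        rows += _stratum_rows(stratum, perms, m, scheme, n_perm, plus_one)

    # ----- within stratum: ROI labels shuffled within subject
    if within is not None:
        subj_ids = df[subject].to_numpy()
        n_roi = df.groupby(subject, observed=True).size().iloc[0]
        y = df[value].to_numpy(float)
        a_lab = df[between[0]].to_numpy() if between else None
        b_lab = df[between[1]].to_numpy() if len(between) > 1 else None
        if a_lab is None:
            # pure within-subject one-way: roi vs roi x subject error
            S = _dummies(subj_ids)
            R = _dummies(df[within].to_numpy())
            stratum = _Stratum({within: (S, np.hstack([S, R]))},
                               np.hstack([S, R]))
        else:
            stratum = _within_stratum(
                subj_ids, df[within].to_numpy(), a_lab, b_lab,
                between, within,
            )
        n_subj = y.size // n_roi
        wide = y.reshape(n_subj, n_roi)
        perms = np.empty((n_perm + 1, y.size))
        perms[0] = y
        for k in range(n_perm):
            perms[k + 1] = rng.permuted(wide, axis=1).ravel()
        rows += _stratum_rows(stratum, perms, y, scheme, n_perm, plus_one)

    out = pd.DataFrame(rows)
    return AnovaResult(out, method="permutation", n_perm=n_perm, warnings=warnings)


def _stratum_rows(stratum: _Stratum, perms: np.ndarray, y_obs: np.ndarray,
                  scheme: str, n_perm: int, plus_one: bool) -> list[dict]:
    rows = []
    if scheme == "stratified":
        fstats = stratum.f_stats(perms)
        for name, (H_red, H_plus, df1) in stratum.models.items():
            f_all = fstats[name]
            rows.append(_row(name, f_all[0], f_all[1:], df1, stratum.df_err,
                             n_perm, plus_one))
    else:  # freedman_lane: permute reduced-model residuals per effect
        pis = np.stack([_recover_perm(y_obs, perms[k + 1])
                        for k in range(perms.shape[0] - 1)])
        for name, (H_red, H_plus, df1) in stratum.models.items():
            fit_red = H_red @ y_obs
            res_red = y_obs - fit_red
            # apply the same stratum-respecting permutations to the residuals
            Yp = np.empty_like(perms)
            Yp[0] = y_obs
            Yp[1:] = res_red[pis] + fit_red
            rss_full = _rss(Yp, stratum.H_full)
            ms_err = rss_full / stratum.df_err
            ss = _rss(Yp, H_red) - _rss(Yp, H_plus)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_all = np.where(ms_err > 0, (ss / df1) / ms_err, np.inf)
            rows.append(_row(name, f_all[0], f_all[1:], df1, stratum.df_err,
                             n_perm, plus_one))
    return rows


def _recover_perm(y: np.ndarray, yp: np.ndarray) -> np.ndarray:
    """Indices pi with yp == y[pi] (stable under ties)."""
    order_y = np.argsort(y, kind="stable")
    order_p = np.argsort(yp, kind="stable")
    pi = np.empty(y.size, dtype=int)
    pi[order_p] = order_y
    return pi


def _row(name: str, f_obs: float, f_perm: np.ndarray, df1: int, df2: int,
         n_perm: int, plus_one: bool) -> dict:
    exceed = int((f_perm > f_obs).sum())
    p = (exceed + 1) / (n_perm + 1) if plus_one else exceed / n_perm
    return {
        "effect": name,
        "F": float(f_obs),
        "df1": float(df1),
        "df2": float(df2),
        "p": float(p),
        "p_parametric": float(sps.f.sf(f_obs, df1, df2)),
    }


def simple_main_effects(
    table: pd.DataFrame,
    factor: str,
    by: str,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    subject: str = "subject_id",
    value: str = "value",
    **kwargs,
) -> dict[str, AnovaResult | str]:
    """Permutation test of ``factor`` within each level of ``by``.

    Typical use after a significant interaction: test the age effect within
    each ROI. Returns a mapping stratum level -> AnovaResult (or a note when
    the stratum has a single level of ``factor``). Each stratum uses the same
    strict-proportion p-value definition as :func:`perm_mixed_anova`.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, AnovaResult | str] = {}
    for level, sub in table.groupby(by, sort=True, observed=True):
        if sub[factor].nunique() < 2:
            out[str(level)] = "skipped: single factor level in stratum"
            continue
        within = None
        between: tuple[str, ...] = (factor,)
        if factor not in (subject, value) and sub.groupby(subject, observed=True)[factor].nunique().max() > 1:
            between, within = (), factor  # factor varies within subject
        # collapse replicate rows per subject (e.g. multiple ROIs) to means
        keep = [subject, factor] if within is None else [subject, factor]
        dat = (
            sub.groupby(keep, observed=True)[value].mean().reset_index()
        )
        out[str(level)] = perm_mixed_anova(
            dat, n_perm=n_perm, seed=rng, between=between, within=within,
            subject=subject, value=value, **kwargs,
        )
    return out
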