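"""The study's statistical framework.

* :class:`MixedAnova` — classical univariate mixed-design (split-plot)
  repeated-measures ANOVA: one within-subject factor (time) and one or two
  between-subject factors (sex, genotype).  Between terms are tested
  against the subjects-within-cells mean square, within terms against the
  time x subjects-within-cells mean square — the classical sums-of-squares
  partition, computed by Type-III model comparison with sum-to-zero
  coding (exactly the textbook marginal-means decomposition on balanced
  designs, and the conventional choice on near-balanced ones).  No
  sphericity correction is applied by default (Greenhouse-Geisser is
  available behind a flag).
* :func:`two_way_within_anova` — fully within-subject two-factor RM-ANOVA
  (treatment x time) for baseline-vs-recovery comparisons within a group.
* post hoc machinery: the condition gate (main effect of sex or genotype,
  or sex x time / genotype x time interaction, p < alpha), unpaired
  Student t-tests (Welch behind a flag), the sleep-pressure exception
  (per-comparison two-group RM-ANOVA to preserve the time course), and
  Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

#: ANOVA terms whose significance opens the post hoc gate
GATE_TERMS = ("sex", "genotype", "sex:time", "genotype:time")

#: the four study comparisons: within sex across genotype, and within
#: genotype across sex
POSTHOC_COMPARISONS = (
    ("sex", "M", "genotype", "WT", "MUT"),
    ("sex", "F", "genotype", "WT", "MUT"),
    ("genotype", "WT", "sex", "M", "F"),
    ("genotype", "MUT", "sex", "M", "F"),
)


# ---------------------------------------------------------------------------
# design-matrix helpers (sum-to-zero coding, Type III by model comparison)


def _codes(values) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(pd.Series(values)))
    lut = {v: i for i, v in enumerate(levels)}
    return np.array([lut[v] for v in values]), levels


def _sum_cols(idx: np.ndarray, k: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k-1 columns."""
    X = np.zeros((idx.size, k - 1))
    for j in range(k - 1):
        X[idx == j, j] = 1.0
    X[idx == k - 1, :] = -1.0
    return X


def _interact(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product (all pairwise column products)."""
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _type3_ss(blocks: dict[str, np.ndarray], y: np.ndarray) -> tuple[dict, float]:
    """Type-III SS per term block and the full-model residual SS."""
    X_full = np.hstack(list(blocks.values()))
    rss_full = _rss(X_full, y)
    ss = {}
    for name in blocks:
        X_red = np.hstack([b for t, b in blocks.items() if t != name])
        ss[name] = max(_rss(X_red, y) - rss_full, 0.0)
    return ss, rss_full


def _f_row(ss, df1, ss_err, df_err, scale):
    """F and p with guards for degenerate (zero-variance) designs."""
    if df1 <= 0 or df_err <= 0 or ss_err <= 1e-12 * max(scale, 1.0):
        return np.nan, np.nan
    F = (ss / df1) / (ss_err / df_err)
    return F, float(sps.f.sf(F, df1, df_err))


# ---------------------------------------------------------------------------
# mixed-design RM-ANOVA


class MixedAnova:
    """Mixed-design repeated-measures ANOVA model.

    Parameters
    ----------
    data : long-format DataFrame, one row per subject x time level.
    dv : name of the dependent-variable column.
    within : name of the repeated (time) factor column.
    subject : name of the subject identifier column.
    between : between-subject factor column names (1 or 2).

    Subjects missing any time level are dropped (listwise, with a
    warning).  ``fit()`` returns a :class:`MixedAnovaResults`.
    """

    def __init__(self, data: pd.DataFrame, dv: str, within: str, subject: str, between):
        if isinstance(between, str):
            between = [between]
        self.between = list(between)
        if not 1 <= len(self.between) <= 2:
            raise ValueError("between must name 1 or 2 factors")
        cols = [subject, within, dv] + self.between
        df = data[cols].dropna(subset=[dv]).copy()

        times = sorted(pd.unique(df[within]))
        counts = df.groupby(subject)[within].nunique()
        complete = counts.index[counts == len(times)]
        dropped = sorted(set(counts.index) - set(complete))
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} subject(s) with incomplete time "
                f"courses: {dropped}",
                stacklevel=2,
            )
        df = df[df[subject].isin(complete)]
        if df.empty:
            raise ValueError("no complete-case subjects")
        dup = df.groupby([subject, within]).size()
        if (dup > 1).any():
            raise ValueError("each subject must appear once per time level")

        self.dv, self.within, self.subject = dv, within, subject
        self.data = df.sort_values([subject, within]).reset_index(drop=True)
        self.time_levels = times

        cells = self.data.groupby(self.between)[subject].nunique()
        if (cells < 2).any():
            raise ValueError("every between-subject cell needs at least 2 subjects")
        self.n_cells = len(cells)

    @classmethod
    def from_dataframe(cls, data, dv, within="hour", subject="animal_id",
                       between=("sex", "genotype")):
        return cls(data, dv=dv, within=within, subject=subject, between=between)

    def fit(self, gg_correction: bool = False) -> "MixedAnovaResults":
        df = self.data
        t = len(self.time_levels)
        subj_means = df.groupby(self.subject, sort=True).agg(
            {self.dv: "mean", **{b: "first" for b in self.between}}
        )
        n_subj = len(subj_means)
        y_b = subj_means[self.dv].to_numpy(float)
        scale = float(np.var(df[self.dv].to_numpy(float))) * df.shape[0]

        # between-subjects part (on subject means; F is scale-invariant,
        # SS reported x t to match the full-data classical partition)
        fac_cols = {}
        for b in self.between:
            idx, levels = _codes(subj_means[b])
            fac_cols[b] = _sum_cols(idx, len(levels))
        blocks = {"_intercept": np.ones((n_subj, 1))}
        blocks.update(fac_cols)
        if len(self.between) == 2:
            a, b = self.between
            blocks[f"{a}:{b}"] = _interact(fac_cols[a], fac_cols[b])
        ss_b, rss_b = _type3_ss(blocks, y_b)
        df_err_b = n_subj - self.n_cells

        # within-subjects part (on deviations from subject means)
        d = (
            df[self.dv].to_numpy(float)
            - subj_means[self.dv].reindex(df[self.subject]).to_numpy(float)
        )
        t_idx, _ = _codes(df[self.within])
        T = _sum_cols(t_idx, t)
        w_blocks = {"time": T}
        for b in self.between:
            idx, levels = _codes(df[b])
            w_blocks[f"{b}:time"] = _interact(_sum_cols(idx, len(levels)), T)
        if len(self.between) == 2:
            a, b = self.between
            ia, la = _codes(df[a])
            ib, lb = _codes(df[b])
            w_blocks[f"{a}:{b}:time"] = _interact(
                _interact(_sum_cols(ia, len(la)), _sum_cols(ib, len(lb))), T
            )
        ss_w, rss_w = _type3_ss(w_blocks, d)
        df_err_w = df_err_b * (t - 1)

        eps = 1.0
        if gg_correction:
            eps = self._gg_epsilon()

        rows = []
        lvl = {b: df[b].nunique() for b in self.between}
        for term in self.between:
            df1 = lvl[term] - 1
            F, p = _f_row(ss_b[term], df1, rss_b, df_err_b, scale / t)
            rows.append((term, ss_b[term] * t, df1, df_err_b, F, p))
        if len(self.between) == 2:
            a, b = self.between
            term = f"{a}:{b}"
            df1 = (lvl[a] - 1) * (lvl[b] - 1)
            F, p = _f_row(ss_b[term], df1, rss_b, df_err_b, scale / t)
            rows.append((term, ss_b[term] * t, df1, df_err_b, F, p))
        within_terms = [("time", t - 1)]
        for b in self.between:
            within_terms.append((f"{b}:time", (lvl[b] - 1) * (t - 1)))
        if len(self.between) == 2:
            a, b = self.between
            within_terms.append(
                (f"{a}:{b}:time", (lvl[a] - 1) * (lvl[b] - 1) * (t - 1))
            )
        for term, df1 in within_terms:
            F, p = _f_row(ss_w[term], df1, rss_w, df_err_w, scale)
            if eps != 1.0 and np.isfinite(F):
                # GG correction: F unchanged, both dfs scaled by epsilon-hat
                p = float(sps.f.sf(F, df1 * eps, df_err_w * eps))
            rows.append((term, ss_w[term], df1, df_err_w, F, p))

        table = pd.DataFrame(
            rows, columns=["term", "ss", "df_num", "df_den", "F", "p"]
        ).set_index("term")
        return MixedAnovaResults(
            table=table,
            n_subjects=n_subj,
            n_dropped=0,
            time_levels=self.time_levels,
            between=self.between,
            gg_epsilon=eps if gg_correction else None,
        )

    def _gg_epsilon(self) -> float:
        """Greenhouse-Geisser epsilon-hat from the pooled covariance."""
        wide = self.data.pivot(index=self.subject, columns=self.within, values=self.dv)
        # pool within-cell covariance
        covs = []
        for _, g in self.data.groupby(self.between):
            w = g.pivot(index=self.subject, columns=self.within, values=self.dv)
            if len(w) > 1:
                covs.append(np.cov(w.to_numpy(float), rowvar=False) * (len(w) - 1))
        S = np.sum(covs, axis=0) / (len(wide) - self.n_cells)
        k = S.shape[0]
        C = np.eye(k) - np.ones((k, k)) / k
        Sc = C @ S @ C
        num = np.trace(Sc) ** 2
        den = (k - 1) * np.trace(Sc @ Sc)
        return float(num / den) if den > 0 else 1.0


@dataclass
class MixedAnovaResults:
    """Fitted mixed-design ANOVA: the term table and design bookkeeping."""

    table: pd.DataFrame
    n_subjects: int
    n_dropped: int
    time_levels: list
    between: list
    gg_epsilon: float | None = None

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def pvalue(self, name: str) -> float:
        return float(self.table.loc[name, "p"])

    def summary(self) -> str:
        lines = [
            "Mixed-design repeated-measures ANOVA",
            f"  subjects: {self.n_subjects}; time levels: {len(self.time_levels)}; "
            f"between: {' x '.join(self.between)}",
        ]
        if self.gg_epsilon is not None:
            lines.append(f"  Greenhouse-Geisser epsilon: {self.gg_epsilon:.4f}")
        lines.append("")
        lines.append(f"  {'term':<22}{'F':>10}{'df':>12}{'p':>12}")
        for term, row in self.table.iterrows():
            dfs = f"({row.df_num:g}, {row.df_den:g})"
            F = f"{row.F:.4f}" if np.isfinite(row.F) else "NA"
            p = f"{row.p:.4g}" if np.isfinite(row.p) else "NA"
            lines.append(f"  {term:<22}{F:>10}{dfs:>12}{p:>12}")
        return "\n".join(lines)


def rm_anova(data, dv, within="hour", subject="animal_id",
             between=("sex", "genotype")) -> MixedAnovaResults:
    """Convenience wrapper: build and fit a :class:`MixedAnova`."""
    return MixedAnova(data, dv=dv, within=within, subject=subject, between=between).fit()


# ---------------------------------------------------------------------------
# fully within-subject two-factor RM-ANOVA (baseline vs recovery)


def two_way_within_anova(data: pd.DataFrame, dv: str, subject: str,
                         factors: tuple[str, str]) -> pd.DataFrame:
    """Two-factor fully within-subject RM-ANOVA (e.g. treatment x time).

    Classical partition: each effect is tested against its own
    effect x subject interaction.  Requires complete balanced data
    (every subject observed at every factor-level combination); subjects
    with missing cells are dropped listwise.
    """
    fa, fb = factors
    df = data[[subject, fa, fb, dv]].dropna().copy()
    la = sorted(pd.unique(df[fa]))
    lb = sorted(pd.unique(df[fb]))
    full = len(la) * len(lb)
    counts = df.groupby(subject).size()
    keep = counts.index[counts == full]
    if len(keep) < len(counts):
        warnings.warn(
            f"dropping {len(counts) - len(keep)} subject(s) with incomplete cells",
            stacklevel=2,
        )
    df = df[df[subject].isin(keep)]
    subs = sorted(pd.unique(df[subject]))
    n, a, b = len(subs), len(la), len(lb)
    if n < 2:
        raise ValueError("need at least 2 complete subjects")

    y = np.full((n, a, b), np.nan)
    si = {s: i for i, s in enumerate(subs)}
    ai = {v: i for i, v in enumerate(la)}
    bi = {v: i for i, v in enumerate(lb)}
    for _, r in df.iterrows():
        y[si[r[subject]], ai[r[fa]], bi[r[fb]]] = r[dv]
    if np.isnan(y).any():
        raise ValueError("duplicate or missing subject x cell observations")

    G = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - G) ** 2)
    ss_b = n * a * np.sum((m_b - G) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + G) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + G) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + G) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - G
    )
    ss_abs = np.sum(resid**2)
    scale = float(np.sum((y - G) ** 2))

    rows = []
    for term, ss, df1, ss_err, df_err in (
        (fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{fa}:{fb}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        F, p = _f_row(ss, df1, ss_err, df_err, scale)
        rows.append((term, ss, df1, df_err, F, p))
    return pd.DataFrame(rows, columns=["term", "ss", "df_num", "df_den", "F", "p"]).set_index(
        "term"
    )


def baseline_vs_recovery(data: pd.DataFrame, dv: str = "pct_trt",
                         subject: str = "animal_id") -> pd.DataFrame:
    """Within-group baseline-vs-recovery RM-ANOVA over matched hours.

    ``data`` holds one group's paired hourly values with columns
    ``phase`` (baseline/recovery) and ``zt_hour``; reported terms are the
    treatment (phase) main effect and the treatment x time interaction,
    each against its own interaction-with-subject error.
    """
    return two_way_within_anova(data, dv=dv, subject=subject, factors=("phase", "zt_hour"))


# ---------------------------------------------------------------------------
# post hoc machinery


def posthoc_gate(results: MixedAnovaResults, alpha: float = ALPHA) -> list:
    """The study's post hoc trigger.

    Comparisons run iff a main effect of sex or genotype, or a
    sex x time / genotype x time interaction, is significant at ``alpha``;
    returns the four within-sex-across-genotype and
    within-genotype-across-sex comparisons, or an empty list.
    """
    for term in GATE_TERMS:
        if term in results.table.index:
            p = results.table.loc[term, "p"]
            if np.isfinite(p) and p < alpha:
                return list(POSTHOC_COMPARISONS)
    return []


def posthoc_ttests(data: pd.DataFrame, comparisons, dv: str = "value",
                   equal_var: bool = True) -> pd.DataFrame:
    """Unpaired two-sided t-tests for the gated comparisons.

    ``data`` holds one scalar value per animal (time-collapsed) with
    ``sex``/``genotype`` columns.  Student (pooled-variance) by default,
    Welch behind ``equal_var=False``.  Raw p-values are BH-adjusted as one
    family.
    """
    rows = []
    for fix_col, fix_level, var_col, lev1, lev2 in comparisons:
        sub = data[data[fix_col] == fix_level]
        g1 = sub.loc[sub[var_col] == lev1, dv].dropna().to_numpy(float)
        g2 = sub.loc[sub[var_col] == lev2, dv].dropna().to_numpy(float)
        if g1.size < 2 or g2.size < 2:
            raise ValueError(
                f"comparison {fix_col}={fix_level}: need >= 2 animals per group"
            )
        t, p = sps.ttest_ind(g1, g2, equal_var=equal_var)
        rows.append(
            {
                "comparison": f"{fix_col}={fix_level}: {lev1} vs {lev2}",
                "n1": g1.size,
                "n2": g2.size,
                "mean1": g1.mean(),
                "sem1": sps.sem(g1),
                "mean2": g2.mean(),
                "sem2": sps.sem(g2),
                "t": float(t),
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = benjamini_hochberg(out["p_raw"].to_numpy())
    return out


def posthoc_pressure(data: pd.DataFrame, comparisons, dv: str = "norm_delta",
                     within: str = "hour", subject: str = "animal_id") -> pd.DataFrame:
    """Sleep-pressure post hocs: per-comparison two-group RM-ANOVA.

    The time course is preserved (the study's stated exception to
    t-tests): each comparison fits a mixed ANOVA with the compared factor
    as the single between-subject factor; the group and group x time
    p-values are reported and BH-adjusted as one family per term.
    """
    rows = []
    for fix_col, fix_level, var_col, lev1, lev2 in comparisons:
        sub = data[(data[fix_col] == fix_level) & data[var_col].isin([lev1, lev2])]
        res = MixedAnova(sub, dv=dv, within=within, subject=subject,
                         between=[var_col]).fit()
        rows.append(
            {
                "comparison": f"{fix_col}={fix_level}: {lev1} vs {lev2}",
                "p_group": res.pvalue(var_col),
                "p_group_time": res.pvalue(f"{var_col}:time"),
                "F_group": float(res.table.loc[var_col, "F"]),
                "F_group_time": float(res.table.loc[f"{var_col}:time", "F"]),
            }
        )
    out = pd.DataFrame(rows)
    out["p_group_bh"] = benjamini_hochberg(out["p_group"].to_numpy())
    out["p_group_time_bh"] = benjamini_hochberg(out["p_group_time"].to_numpy())
    return out


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (capped at 1, monotone in rank)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class StatReport:
    """ANOVA terms plus post hoc comparisons for one dependent variable."""

    dv: str
    anova: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        a = self.anova.reset_index().assign(kind="anova", dv=self.dv)
        if self.posthoc is None or self.posthoc.empty:
            return a
        ph = self.posthoc.assign(kind="posthoc", dv=self.dv)
        return pd.concat([a, ph], ignore_index=True)


__all__ = [
    "ALPHA",
    "GATE_TERMS",
    "POSTHOC_COMPARISONS",
    "MixedAnova",
    "MixedAnovaResults",
    "rm_anova",
    "two_way_within_anova",
    "baseline_vs_recovery",
    "posthoc_gate",
    "posthoc_ttests",
    "posthoc_pressure",
    "benjamini_hochberg",
    "StatReport",
]
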