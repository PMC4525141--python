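"""Group-level inference, computable from printed summary statistics.

Behavioural tables in this literature report each treatment as mean +/- SEM
with n.  Every test here that only needs first and second moments (classic
one-way ANOVA, Welch's heteroscedastic ANOVA, Tukey HSD, Games-Howell,
one-sample t) is therefore implemented directly from (mean, SEM, n) triplets,
so published tables can be re-derived without raw data; the implied SD is
SEM * sqrt(n).  Rank-based procedures (Kruskal-Wallis, Spearman) and the
mixed pre/post ANOVA require raw per-fish values.

An ln-transform flag mirrors the convention of log-transforming hormone
concentrations before testing; it is always the caller's explicit choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class GroupSummary:
    """One treatment group's printed summary: mean +/- SEM, n."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"group {self.label}: n must be >= 2")
        if self.sem <= 0:
            raise DegenerateInputError(f"group {self.label}: SEM must be positive")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd**2

    @classmethod
    def from_raw(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValidationError("need >= 2 values")
        return cls(label=label, mean=float(v.mean()),
                   sem=float(v.std(ddof=1) / math.sqrt(v.size)), n=int(v.size))


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    df: float
    p: float


def _check_groups(groups: Sequence[GroupSummary], k_min: int = 2) -> None:
    if len(groups) < k_min:
        raise ValidationError(f"need at least {k_min} groups")


def welch_anova_summary(groups: Sequence[GroupSummary]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA from group summaries.

    With weights w_i = n_i / s_i^2 and weighted grand mean m*, the statistic is
    F = [sum w_i (m_i - m*)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) * L] with
    L = sum (1 - w_i/W)^2 / (n_i - 1), df = (k-1, (k^2-1)/(3L)).
    """
    _check_groups(groups)
    k = len(groups)
    w = np.array([g.n / g.var for g in groups])
    m = np.array([g.mean for g in groups])
    n = np.array([g.n for g in groups])
    W = w.sum()
    grand = float((w * m).sum() / W)
    num = float((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = float(((1.0 - w / W) ** 2 / (n - 1)).sum())
    denom = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    F = num / denom
    df2 = (k**2 - 1) / (3.0 * lam) if lam > 0 else math.inf
    p = float(stats.f.sf(F, k - 1, df2))
    return TestResult("welch_anova", F, (k - 1, df2), p)


def oneway_anova_summary(groups: Sequence[GroupSummary]) -> TestResult:
    """Classic one-way (fixed-effects) ANOVA reconstructed from summaries."""
    _check_groups(groups)
    k = len(groups)
    n = np.array([g.n for g in groups])
    m = np.array([g.mean for g in groups])
    v = np.array([g.var for g in groups])
    N = int(n.sum())
    grand = float((n * m).sum() / N)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * v).sum())
    df1, df2 = k - 1, N - k
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    return TestResult("oneway_anova", F, (df1, df2), p, detail={"ssb": ssb, "ssw": ssw})


def games_howell_summary(groups: Sequence[GroupSummary]) -> list[PairwiseResult]:
    """Games-Howell post-hoc pairwise comparisons from summaries.

    Per pair: q = |m_i - m_j| / sqrt((s_i^2/n_i + s_j^2/n_j)/2) with
    Welch-Satterthwaite df, p from the studentized range with k groups.
    """
    _check_groups(groups)
    k = len(groups)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se2 = a.var / a.n + b.var / b.n
            q = abs(a.mean - b.mean) / math.sqrt(se2 / 2.0)
            df = se2**2 / ((a.var / a.n) ** 2 / (a.n - 1) + (b.var / b.n) ** 2 / (b.n - 1))
            p = float(stats.studentized_range.sf(q, k, df))
            out.append(PairwiseResult(a.label, b.label, q, df, min(p, 1.0)))
    return out


def tukey_hsd_summary(groups: Sequence[GroupSummary]) -> list[PairwiseResult]:
    """Tukey HSD pairwise comparisons from summaries (pooled error variance)."""
    _check_groups(groups)
    k = len(groups)
    n = np.array([g.n for g in groups])
    v = np.array([g.var for g in groups])
    df_err = int(n.sum()) - k
    mse = float(((n - 1) * v).sum()) / df_err
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se = math.sqrt(mse / 2.0 * (1.0 / a.n + 1.0 / b.n))
            q = abs(a.mean - b.mean) / se
            p = float(stats.studentized_range.sf(q, k, df_err))
            out.append(PairwiseResult(a.label, b.label, q, float(df_err), min(p, 1.0)))
    return out


def one_sample_t_summary(mean: float, sem: float, n: int, mu0: float) -> TestResult:
    """One-sample two-sided t-test from a printed mean +/- SEM."""
    if n < 2:
        raise ValidationError("n must be >= 2")
    if sem <= 0:
        raise DegenerateInputError("SEM must be positive")
    t = (mean - mu0) / sem
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult("one_sample_t", t, (df,), p)


def ln_transform(groups_raw: Sequence[Sequence[float]]) -> list[np.ndarray]:
    """Natural-log transform raw groups (hormone-concentration convention).

    Applied only on explicit request; values must be strictly positive.
    """
    out = []
    for g in groups_raw:
        v = np.asarray(g, dtype=float)
        if (v <= 0).any():
            raise ValidationError("ln transform requires strictly positive values")
        out.append(np.log(v))
    return out


def kruskal_wallis(groups_raw: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank ANOVA on raw per-fish values (tie-corrected H)."""
    if len(groups_raw) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = [len(g) for g in groups_raw]
    if sum(sizes) < 3:
        raise ValidationError("total n must be >= 3")
    H, p = stats.kruskal(*[np.asarray(g, float) for g in groups_raw])
    detail = {}
    if min(sizes) < 3:
        detail["warning"] = "very small group sizes; chi-square p is approximate"
    return TestResult("kruskal_wallis", float(H), (len(groups_raw) - 1,), float(p), detail)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Spearman rank correlation; permutation p (seeded) for small samples.

    The statistic is the Pearson correlation of average ranks.  For n < 30 the
    p-value is a two-sided permutation p over ``n_perm`` shuffles of y (set
    n_perm=0 to force the asymptotic p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need equal-length series with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant series: correlation undefined")
    rs, p_asym = stats.spearmanr(x, y)
    rs = float(rs)
    if x.size < 30 and n_perm > 0:
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx_c = rx - rx.mean()
        count = 0
        denom_x = math.sqrt(float((rx_c**2).sum()))
        for _ in range(n_perm):
            perm = rng.permutation(ry)
            pc = perm - perm.mean()
            r_perm = float((rx_c * pc).sum()) / (denom_x * math.sqrt(float((pc**2).sum())))
            if abs(r_perm) >= abs(rs) - 1e-12:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
    else:
        p = float(p_asym)
    return TestResult("spearman", rs, (x.size - 2,), p)


@dataclass(frozen=True)
class MixedPrePostResult:
    """Two-way mixed (split-plot) ANOVA on per-fish pre/post means."""

    interaction: TestResult
    phase: TestResult
    group: TestResult
    contrasts: dict[str, TestResult]


def mixed_prepost_anova(
    pre: Sequence[float],
    post: Sequence[float],
    groups: Sequence[str],
) -> MixedPrePostResult:
    """Mixed ANOVA: between factor = treatment, within factor = phase (pre/post).

    With exactly two within levels the phase-by-group interaction reduces to a
    one-way ANOVA on the per-fish difference scores d = pre - post, giving
    F(k-1, N-k).  Contrasts:

    - ``pre_vs_post@<g>``: within-group phase change, t = d_bar_g /
      sqrt(MSW_d / n_g), df = N - k (pooled within-cell difference variance);
    - ``<g1>_vs_<g2>@pre`` / ``@post``: between-group simple effect at one
      phase, using the pooled between+within error (MS_subjects + MS_phase x
      subjects)/2 with Satterthwaite df;
    - ``<g1>_vs_<g2>@pre_t2``: plain two-sample-t variant on that phase's
      values (alternative error-term construction, reported alongside).
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    groups = np.asarray(groups)
    if pre.shape != post.shape or pre.shape != groups.shape:
        raise ValidationError("pre, post and groups must align (every fish has both phases)")
    if np.isnan(pre).any() or np.isnan(post).any():
        raise ValidationError("missing phase values are not allowed")
    labels = list(dict.fromkeys(groups.tolist()))
    k = len(labels)
    if k < 2:
        raise ValidationError("need at least 2 treatment groups")
    N = pre.size
    n_g = {g: int(np.sum(groups == g)) for g in labels}
    if min(n_g.values()) < 2:
        raise InsufficientDataError("each group needs >= 2 fish")

    d = pre - post
    subj_mean = (pre + post) / 2.0

    # interaction: one-way ANOVA on difference scores
    grand_d = float(np.average(d))
    ssb_d = sum(n_g[g] * (float(d[groups == g].mean()) - grand_d) ** 2 for g in labels)
    ssw_d = sum(float(((d[groups == g] - d[groups == g].mean()) ** 2).sum()) for g in labels)
    df_b, df_w = k - 1, N - k
    msw_d = ssw_d / df_w
    if msw_d == 0:
        F_int = 0.0 if ssb_d == 0 else math.inf
    else:
        F_int = (ssb_d / df_b) / msw_d
    interaction = TestResult(
        "phase_x_group", F_int, (df_b, df_w), float(stats.f.sf(F_int, df_b, df_w)) if np.isfinite(F_int) else 0.0
    )

    # phase main effect: grand difference against 0 on the pooled d variance
    if msw_d == 0:
        F_phase = 0.0 if grand_d == 0 else math.inf
    else:
        F_phase = N * grand_d**2 / msw_d
    phase = TestResult(
        "phase", F_phase, (1, df_w), float(stats.f.sf(F_phase, 1, df_w)) if np.isfinite(F_phase) else 0.0
    )

    # between-subject main effect on subject means (error: subjects within groups)
    grand_s = float(subj_mean.mean())
    ssb_s = 2.0 * sum(n_g[g] * (float(subj_mean[groups == g].mean()) - grand_s) ** 2 for g in labels)
    ssw_s = 2.0 * sum(
        float(((subj_mean[groups == g] - subj_mean[groups == g].mean()) ** 2).sum()) for g in labels
    )
    ms_s = ssw_s / df_w
    F_grp = (ssb_s / df_b) / ms_s if ms_s > 0 else (0.0 if ssb_s == 0 else math.inf)
    group_res = TestResult(
        "group", F_grp, (df_b, df_w), float(stats.f.sf(F_grp, df_b, df_w)) if np.isfinite(F_grp) else 0.0
    )

    ms_ps = msw_d / 2.0  # phase x subject error on the per-observation scale
    contrasts: dict[str, TestResult] = {}
    for g in labels:
        dg = d[groups == g]
        if msw_d == 0:
            t = 0.0 if dg.mean() == 0 else math.copysign(math.inf, dg.mean())
        else:
            t = float(dg.mean()) / math.sqrt(msw_d / n_g[g])
        p = 2.0 * float(stats.t.sf(abs(t), df_w)) if np.isfinite(t) else 0.0
        contrasts[f"pre_vs_post@{g}"] = TestResult("paired_contrast", t, (df_w,), p)

    ms_pool = (ms_s + ms_ps) / 2.0
    # Satterthwaite df for the pooled error
    if ms_s + ms_ps > 0:
        df_pool = (ms_s + ms_ps) ** 2 / (ms_s**2 / df_w + ms_ps**2 / df_w)
    else:
        df_pool = float(df_w)
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = labels[i], labels[j]
            for phase_name, vals in (("pre", pre), ("post", post)):
                v1, v2 = vals[groups == g1], vals[groups == g2]
                se = math.sqrt(ms_pool * (1.0 / n_g[g1] + 1.0 / n_g[g2]))
                if se > 0:
                    t = float(v1.mean() - v2.mean()) / se
                    p = 2.0 * float(stats.t.sf(abs(t), df_pool))
                else:
                    t, p = 0.0, 1.0
                contrasts[f"{g1}_vs_{g2}@{phase_name}"] = TestResult(
                    "between_contrast_pooled", t, (df_pool,), p
                )
                t2, p2 = stats.ttest_ind(v1, v2)
                contrasts[f"{g1}_vs_{g2}@{phase_name}_t2"] = TestResult(
                    "between_contrast_twosample", float(t2), (n_g[g1] + n_g[g2] - 2,), float(p2)
                )

    return MixedPrePostResult(interaction=interaction, phase=phase, group=group_res, contrasts=contrasts)
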