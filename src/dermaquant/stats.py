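"""Assumption-gated group comparisons with significance stars.

The workflow mirrors the common JASP-style decision tree for comparing
condition means:

1. Shapiro–Wilk normality per group (α = 0.05; tiny or constant groups are
   refused and routed non-parametric).
2. If every group looks normal: Levene's test for variance homogeneity
   (mean-centred by default) decides between classical one-way ANOVA with
   Tukey's HSD and Welch's ANOVA with Games–Howell.
3. Any non-normal group sends the whole comparison to Kruskal–Wallis with
   Dunn's post hoc test (Holm-adjusted by default; the adjustment is
   configurable and always recorded).

Two-group comparisons use Student/Welch t tests when both groups are normal
and Mann–Whitney otherwise.  Stars: ``***`` p < 0.001, ``**`` p < 0.01,
``*`` p < 0.05, ``ns`` otherwise (strict inequalities).

Every rule firing is recorded in an ordered decision trace so a reported
star can be audited back to the tests that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, StatsError

__all__ = [
    "GroupedSample",
    "GroupComparison",
    "NormalityResult",
    "test_normality",
    "test_variance_homogeneity",
    "compare_groups",
    "pairwise_test",
    "annotate_significance",
    "dunn_test",
]

ALPHA = 0.05
SHAPIRO_MAX_N = 5000


def annotate_significance(p: float) -> str:
    """Map a p value to the figure annotation (strict thresholds)."""
    if not np.isfinite(p) or p < 0 or p > 1:
        raise ParameterError(f"p value outside [0, 1]: {p!r}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupedSample:
    """Observations of one metric across >= 2 labelled groups."""

    metric: str
    groups: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise StatsError("need at least two groups")
        self.groups = [(str(l), np.asarray(v, dtype=float).ravel()) for l, v in self.groups]


@dataclass
class NormalityResult:
    label: str
    p: float | None
    normal: bool
    code: str = "OK"  # OK | TOO_FEW | ZERO_VARIANCE | TOO_MANY


def test_normality(groups: list[tuple[str, np.ndarray]], alpha: float = ALPHA) -> list[NormalityResult]:
    """Shapiro–Wilk per group; refusals are flagged and treated non-normal."""
    out = []
    for label, values in groups:
        values = np.asarray(values, dtype=float)
        if values.size < 3:
            out.append(NormalityResult(label, None, False, "TOO_FEW"))
        elif values.size > SHAPIRO_MAX_N:
            out.append(NormalityResult(label, None, False, "TOO_MANY"))
        elif np.ptp(values) == 0:
            out.append(NormalityResult(label, None, False, "ZERO_VARIANCE"))
        else:
            p = float(sps.shapiro(values).pvalue)
            out.append(NormalityResult(label, p, p >= alpha))
    return out


def test_variance_homogeneity(
    groups: list[tuple[str, np.ndarray]], center: str = "mean"
) -> tuple[float, float]:
    """Levene's test across groups; returns (statistic, p)."""
    arrays = [np.asarray(v, dtype=float) for _, v in groups]
    if any(a.size < 2 for a in arrays):
        raise StatsError("Levene's test needs n >= 2 per group")
    if all(np.ptp(a) == 0 for a in arrays):
        return 0.0, 1.0
    res = sps.levene(*arrays, center=center)
    return float(res.statistic), float(res.pvalue)


def dunn_test(
    groups: list[tuple[str, np.ndarray]],
    adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn's rank-based post hoc test after Kruskal–Wallis.

    z for a pair (i, j) is the difference of mean pooled ranks over
    sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie correction
    T = Σ(t³ − t) / (12(N − 1)); two-sided normal p values, multiplicity-
    adjusted with Holm by default (``none`` and ``bonferroni`` available).
    """
    labels = [l for l, _ in groups]
    arrays = [np.asarray(v, dtype=float) for _, v in groups]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"A": labels[i], "B": labels[j], "statistic": float(z), "p_unadj": float(p)})
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adj"] = table["p_unadj"]
    elif adjust in ("holm", "bonferroni"):
        table["p_adj"] = multipletests(table["p_unadj"], method=adjust)[1]
    else:
        raise ParameterError(f"unknown Dunn adjustment {adjust!r}")
    return table


def _tukey(groups: list[tuple[str, np.ndarray]]) -> pd.DataFrame:
    labels = [l for l, _ in groups]
    arrays = [np.asarray(v, dtype=float) for _, v in groups]
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "A": labels[i],
                    "B": labels[j],
                    "statistic": float(res.statistic[i, j]),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def _games_howell(groups: list[tuple[str, np.ndarray]]) -> pd.DataFrame:
    import pingouin as pg  # deferred: pingouin import is slow

    frame = pd.DataFrame(
        {
            "value": np.concatenate([v for _, v in groups]),
            "group": np.concatenate([[l] * len(v) for l, v in groups]),
        }
    )
    gh = pg.pairwise_gameshowell(data=frame, dv="value", between="group")
    return pd.DataFrame(
        {"A": gh["A"], "B": gh["B"], "statistic": gh["T"].astype(float), "p_adj": gh["pval"].astype(float)}
    )


def _welch_anova(groups: list[tuple[str, np.ndarray]]) -> tuple[float, float]:
    import pingouin as pg  # deferred: pingouin import is slow

    frame = pd.DataFrame(
        {
            "value": np.concatenate([v for _, v in groups]),
            "group": np.concatenate([[l] * len(v) for l, v in groups]),
        }
    )
    aov = pg.welch_anova(data=frame, dv="value", between="group")
    return float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])


@dataclass
class GroupComparison:
    """Omnibus + post hoc result with full decision trace."""

    metric: str
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    shapiro: list[NormalityResult]
    levene_p: float | None
    posthoc_test: str
    pairwise: pd.DataFrame
    trace: list[str] = field(default_factory=list)
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.omnibus_p < self.alpha


def compare_groups(
    sample: GroupedSample,
    alpha: float = ALPHA,
    levene_center: str = "mean",
    dunn_adjust: str = "holm",
    include_posthoc: bool = True,
) -> GroupComparison:
    """Run the full decision tree on a grouped sample.

    ``include_posthoc=False`` skips computing the pairwise table (the chosen
    post hoc pairing is still recorded); useful for large simulation sweeps
    where only the omnibus decision is consumed.
    """
    groups = sample.groups
    trace: list[str] = []

    pooled = np.concatenate([v for _, v in groups])
    if np.ptp(pooled) == 0:
        trace.append("all observations identical -> omnibus p = 1, no post hoc differences")
        pairwise = pd.DataFrame(
            [
                {"A": groups[i][0], "B": groups[j][0], "statistic": 0.0, "p_adj": 1.0, "stars": "ns"}
                for i in range(len(groups))
                for j in range(i + 1, len(groups))
            ]
        )
        return GroupComparison(sample.metric, "degenerate", 0.0, 1.0, [], None, "none", pairwise, trace, alpha)

    shapiro = test_normality(groups, alpha)
    for r in shapiro:
        msg = f"Shapiro-Wilk[{r.label}]: " + (
            f"p={r.p:.4g} -> {'normal' if r.normal else 'non-normal'}"
            if r.p is not None
            else f"refused ({r.code}) -> treated non-normal"
        )
        trace.append(msg)
    all_normal = all(r.normal for r in shapiro)

    levene_p: float | None = None
    if all_normal:
        _, levene_p = test_variance_homogeneity(groups, center=levene_center)
        homogeneous = levene_p >= alpha
        trace.append(
            f"Levene (center={levene_center}): p={levene_p:.4g} -> "
            f"{'homogeneous' if homogeneous else 'inhomogeneous'} variances"
        )
        if homogeneous:
            stat, p = sps.f_oneway(*[v for _, v in groups])
            omnibus, posthoc = "ANOVA", "Tukey"
            pairwise = _tukey(groups) if include_posthoc else None
        else:
            stat, p = _welch_anova(groups)
            omnibus, posthoc = "Welch-ANOVA", "Games-Howell"
            pairwise = _games_howell(groups) if include_posthoc else None
    else:
        trace.append("at least one group non-normal -> non-parametric branch")
        stat, p = sps.kruskal(*[v for _, v in groups])
        omnibus, posthoc = "Kruskal-Wallis", f"Dunn ({dunn_adjust})"
        pairwise = dunn_test(groups, adjust=dunn_adjust) if include_posthoc else None
    trace.append(f"omnibus {omnibus}: statistic={stat:.4g}, p={p:.4g}; post hoc: {posthoc}")

    if pairwise is None:
        pairwise = pd.DataFrame(columns=["A", "B", "statistic", "p_adj", "stars"])
    else:
        pairwise = pairwise.copy()
        pairwise["p_adj"] = pairwise["p_adj"].clip(0.0, 1.0)
        pairwise["stars"] = [annotate_significance(float(x)) for x in pairwise["p_adj"]]
    return GroupComparison(
        metric=sample.metric,
        omnibus_test=omnibus,
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        shapiro=shapiro,
        levene_p=levene_p,
        posthoc_test=posthoc,
        pairwise=pairwise,
        trace=trace,
        alpha=alpha,
    )


def pairwise_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = False,
    alpha: float = ALPHA,
) -> dict:
    """Two-group comparison: t test when both normal, Mann–Whitney otherwise.

    The t test uses the Welch variant under variance inhomogeneity.  Returns
    a dict with the test name, statistic, p and stars.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise StatsError("pairwise test needs n >= 2 per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return {"test": "degenerate", "statistic": 0.0, "p": 1.0, "stars": "ns"}

    normals = test_normality([("A", a), ("B", b)], alpha)
    both_normal = all(r.normal for r in normals)
    if paired:
        if a.size != b.size:
            raise StatsError("paired test needs equal group sizes")
        if both_normal:
            res = sps.ttest_rel(a, b)
            name = "paired t"
        else:
            res = sps.wilcoxon(a, b)
            name = "Wilcoxon"
    elif both_normal:
        _, lev_p = test_variance_homogeneity([("A", a), ("B", b)])
        equal_var = lev_p >= alpha
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        name = "t" if equal_var else "Welch t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney"
    p = float(res.pvalue)
    return {"test": name, "statistic": float(res.statistic), "p": p, "stars": annotate_significance(min(p, 1.0))}
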