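"""Group-comparison statistics for the four response parameters.

The battery mirrors a conventional three-treatment workflow: a skewness
screen decides between the parametric path (one-way ANOVA, with the
Brown–Forsythe robust F when variances are unequal, followed by Scheffé or
Tamhane T2 pairwise comparisons chosen by Levene's test) and the
nonparametric path (Kruskal–Wallis with Dunn's post hoc).

Omnibus tests with established implementations delegate to scipy
(``f_oneway``, ``levene``, ``kruskal``); Brown–Forsythe, Scheffé,
Tamhane T2 and Dunn are implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "PairwiseResult",
    "StatsReport",
    "skewness",
    "levene_test",
    "one_way_anova",
    "brown_forsythe",
    "scheffe_posthoc",
    "tamhane_t2_posthoc",
    "kruskal_wallis",
    "dunn_posthoc",
    "analyze_parameter",
]

ALPHA = 0.05
SKEWNESS_LIMIT = 2.0


@dataclass(frozen=True)
class GroupData:
    """Samples of one response parameter grouped by treatment."""

    labels: tuple
    values: tuple  # tuple of 1-D arrays, parallel to labels

    def __post_init__(self) -> None:
        if len(self.labels) < 2 or len(self.labels) != len(self.values):
            raise ValueError("need >= 2 labeled groups")
        arrays = tuple(np.asarray(v, dtype=float).ravel() for v in self.values)
        object.__setattr__(self, "values", arrays)
        if any(a.size < 2 for a in arrays):
            raise ValueError("every group needs >= 2 values")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "GroupData":
        labels = tuple(mapping.keys())
        return cls(labels=labels, values=tuple(mapping[k] for k in labels))

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n_total(self) -> int:
        return int(sum(a.size for a in self.values))


class PairwiseResult(NamedTuple):
    pair: tuple
    statistic: float
    p_adjusted: float
    method: str


def skewness(values: Sequence[float]) -> float:
    """Adjusted Fisher–Pearson skewness g1 * sqrt(n(n-1)) / (n-2)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("skewness needs n >= 3")
    return float(sps.skew(values, bias=False))


def levene_test(groups: GroupData, center: Literal["mean", "median"] = "mean") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test on deviations from the centre."""
    W, p = sps.levene(*groups.values, center=center)
    return float(W), float(p)


def one_way_anova(groups: GroupData) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df_between, df_within, p)."""
    F, p = sps.f_oneway(*groups.values)
    df1 = groups.k - 1
    df2 = groups.n_total - groups.k
    return float(F), df1, df2, float(p)


def brown_forsythe(groups: GroupData) -> tuple[float, float, float, float]:
    """Brown–Forsythe robust one-way F* (unequal variances).

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2 with Satterthwaite
    denominator df; numerator df = k - 1.  Returns (F*, df1, df2, p).
    """
    ns = np.array([a.size for a in groups.values], dtype=float)
    means = np.array([a.mean() for a in groups.values])
    variances = np.array([a.var(ddof=1) for a in groups.values])
    N = ns.sum()
    grand = float(np.sum(ns * means) / N)
    num = float(np.sum(ns * (means - grand) ** 2))
    ci = (1.0 - ns / N) * variances
    den = float(ci.sum())
    if den == 0:
        raise ValueError("zero within-group variance everywhere; test degenerate")
    F = num / den
    df1 = groups.k - 1.0
    df2 = den**2 / float(np.sum(ci**2 / (ns - 1.0)))
    p = float(sps.f.sf(F, df1, df2))
    return F, df1, df2, p


def scheffe_posthoc(groups: GroupData) -> list[PairwiseResult]:
    """Scheffé all-pairs comparisons with pooled variance.

    For each pair, p = P[F_{k-1, N-k} >= t_pair^2 / (k - 1)]; conservative
    and consistent with the ANOVA omnibus (equal to it at k = 2).
    """
    k, N = groups.k, groups.n_total
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in groups.values)
    ms_within = ss_within / (N - k)
    if ms_within == 0:
        raise ValueError("zero pooled within-group variance; Scheffé degenerate")
    out = []
    for (i, j) in itertools.combinations(range(k), 2):
        a, b = groups.values[i], groups.values[j]
        t2 = (a.mean() - b.mean()) ** 2 / (ms_within * (1.0 / a.size + 1.0 / b.size))
        Fs = t2 / (k - 1)
        p = float(sps.f.sf(Fs, k - 1, N - k))
        out.append(PairwiseResult((groups.labels[i], groups.labels[j]), float(Fs), min(1.0, p), "scheffe"))
    return out


def tamhane_t2_posthoc(groups: GroupData) -> list[PairwiseResult]:
    """Tamhane T2 all-pairs comparisons (Welch t, Sidak-adjusted).

    Appropriate when group variances are unequal: each pair uses a Welch t
    with Satterthwaite df, and the per-pair p is Sidak-corrected for the
    number of pairs.
    """
    k = groups.k
    m = k * (k - 1) // 2
    out = []
    for (i, j) in itertools.combinations(range(k), 2):
        a, b = groups.values[i], groups.values[j]
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se2 = va + vb
        if se2 == 0:
            raise ValueError("zero variance in both groups; Tamhane T2 degenerate")
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_raw = 2.0 * float(sps.t.sf(abs(t), df))
        p_adj = 1.0 - (1.0 - min(1.0, p_raw)) ** m
        out.append(PairwiseResult((groups.labels[i], groups.labels[j]), float(t), min(1.0, p_adj), "tamhane_t2"))
    return out


def kruskal_wallis(groups: GroupData) -> tuple[float, int, float]:
    """Kruskal–Wallis H with tie correction; returns (H, df, p)."""
    if all(np.all(a == groups.values[0][0]) for a in groups.values):
        raise ValueError("all values identical; Kruskal-Wallis degenerate")
    H, p = sps.kruskal(*groups.values)
    return float(H), groups.k - 1, float(p)


def dunn_posthoc(groups: GroupData, adjust: Literal["bonferroni", "none", "sidak"] = "bonferroni") -> list[PairwiseResult]:
    """Dunn's rank-based all-pairs comparisons after Kruskal–Wallis.

    z for each pair is the difference in mean mid-ranks over the
    tie-corrected standard error; adjustment defaults to Bonferroni.
    """
    pooled = np.concatenate(groups.values)
    N = pooled.size
    ranks = sps.rankdata(pooled)  # mid-ranks
    # tie correction term: sum over tie groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    if var_base <= 0:
        raise ValueError("all values identical; Dunn test degenerate")
    mean_ranks = []
    start = 0
    for a in groups.values:
        mean_ranks.append(float(ranks[start : start + a.size].mean()))
        start += a.size
    m = groups.k * (groups.k - 1) // 2
    out = []
    for (i, j) in itertools.combinations(range(groups.k), 2):
        ni, nj = groups.values[i].size, groups.values[j].size
        se = math.sqrt(var_base * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * float(sps.norm.sf(abs(z)))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif adjust == "sidak":
            p_adj = 1.0 - (1.0 - min(1.0, p_raw)) ** m
        else:
            p_adj = min(1.0, p_raw)
        out.append(PairwiseResult((groups.labels[i], groups.labels[j]), float(z), p_adj, f"dunn_{adjust}"))
    return out


@dataclass
class StatsReport:
    """Result of the full battery on one parameter."""

    parameter: str
    path: str  # "anova" | "kruskal_wallis"
    omnibus_test: str
    statistic: float
    df: tuple
    p_value: float
    skewness_by_group: dict
    levene_W: float | None
    levene_p: float | None
    pairwise: list[PairwiseResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "path": self.path,
            "omnibus_test": self.omnibus_test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "skewness_by_group": {str(k): v for k, v in self.skewness_by_group.items()},
            "levene_W": self.levene_W,
            "levene_p": self.levene_p,
            "pairwise": [
                {"pair": [str(x) for x in r.pair], "statistic": r.statistic, "p_adjusted": r.p_adjusted, "method": r.method}
                for r in self.pairwise
            ],
        }


def analyze_parameter(
    groups: GroupData,
    parameter: str = "",
    alpha: float = ALPHA,
    posthoc_assignment: Literal["conventional", "as_published"] = "conventional",
    dunn_adjust: Literal["bonferroni", "none", "sidak"] = "bonferroni",
) -> StatsReport:
    """Run the full decision battery on one parameter.

    Parametric path when every group's |skewness| < 2: Levene's test, then
    plain ANOVA (equal variances) or Brown–Forsythe (unequal), with Scheffé
    or Tamhane T2 pairwise p-values.  ``posthoc_assignment`` controls which
    post hoc goes with which Levene outcome: ``conventional`` uses Scheffé
    under homogeneity and Tamhane T2 otherwise; ``as_published`` swaps them.
    Otherwise the nonparametric Kruskal–Wallis + Dunn path is taken.
    """
    skew = {lab: skewness(vals) for lab, vals in zip(groups.labels, groups.values)}
    parametric = all(abs(s) < SKEWNESS_LIMIT for s in skew.values())
    if parametric:
        W, p_lev = levene_test(groups)
        homogeneous = p_lev >= alpha
        if homogeneous:
            F, df1, df2, p = one_way_anova(groups)
            test_name, df = "one_way_anova", (df1, df2)
        else:
            F, df1, df2, p = brown_forsythe(groups)
            test_name, df = "brown_forsythe", (df1, df2)
        use_scheffe = homogeneous if posthoc_assignment == "conventional" else not homogeneous
        pairwise = scheffe_posthoc(groups) if use_scheffe else tamhane_t2_posthoc(groups)
        return StatsReport(
            parameter=parameter, path="anova", omnibus_test=test_name, statistic=F,
            df=df, p_value=p, skewness_by_group=skew, levene_W=W, levene_p=p_lev, pairwise=pairwise,
        )
    H, df_kw, p = kruskal_wallis(groups)
    return StatsReport(
        parameter=parameter, path="kruskal_wallis", omnibus_test="kruskal_wallis", statistic=H,
        df=(df_kw,), p_value=p, skewness_by_group=skew, levene_W=None, levene_p=None,
        pairwise=dunn_posthoc(groups, adjust=dunn_adjust),
    )
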