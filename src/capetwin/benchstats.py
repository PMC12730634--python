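"""Heteroscedastic group-comparison statistics for ELISA-style plates.

The dose groups of the marker assays have unequal variances, so the
parametric pathway is Welch's one-way ANOVA followed by Games-Howell
pairwise comparisons, with the Kruskal-Wallis test and Dunn's post hoc
(Holm-corrected) as the distribution-free confirmation.  All four tests
are implemented from their standard formulas so they can be checked
against hand-computed examples and independent implementations.

Plate fixtures are generated in-package: seeded lognormal replicates
around control-normalised fold-change means (the shipped fixture table
anchors the printed marker values; interpolated entries are flagged
synthetic).
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "PlateData",
    "TestReport",
    "PairwiseResult",
    "generate_plate",
    "load_fixture_means",
    "welch_anova",
    "games_howell",
    "kruskal_wallis",
    "dunn_holm",
    "holm_adjust",
    "fold_change_table",
    "significance_tier",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """Input groups cannot support the requested test (e.g. zero variance)."""


def significance_tier(p: float) -> str:
    """The conventional significance stars: ``***``, ``**``, ``*`` or ``ns``."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class PairwiseResult:
    pair: tuple[float, float] | tuple[str, str]
    difference: float
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float

    @property
    def tier(self) -> str:
        return significance_tier(self.p_adjusted)


@dataclass
class TestReport:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "tier": self.tier,
            "pairwise": [
                {
                    "pair": list(pr.pair),
                    "difference": pr.difference,
                    "statistic": pr.statistic,
                    "df": pr.df,
                    "p_raw": pr.p_raw,
                    "p_adjusted": pr.p_adjusted,
                    "tier": pr.tier,
                }
                for pr in self.pairwise
            ],
        }


@dataclass
class PlateData:
    """Synthetic replicate fold-change measurements per dose group."""

    marker: str
    timepoint: int
    groups: dict[float, np.ndarray]
    seed: int | None = None
    cv: float = 0.0

    def group_arrays(self) -> list[np.ndarray]:
        return [np.asarray(v, dtype=float) for v in self.groups.values()]


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def load_fixture_means(marker: str, timepoint: int) -> dict[float, float]:
    """Control-normalised fold-change means for a marker/timepoint."""
    ref = importlib.resources.files("capetwin.data") / "elisa_fixtures.yaml"
    with ref.open("r") as fh:
        table = yaml.safe_load(fh)
    key = marker.lower().replace("-", "_").replace(" ", "_").replace(".", "_")
    if key in ("ca72_4", "ca_72_4"):
        key = "ca72_4"
    if key not in table:
        raise KeyError(f"unknown marker {marker!r} (have {sorted(table)})")
    if timepoint not in table[key]:
        raise KeyError(
            f"no fixture for {marker} at {timepoint} h "
            f"(have {sorted(table[key])})"
        )
    return {float(d): float(m)
            for d, m in table[key][timepoint]["means"].items()}


def generate_plate(
    marker: str,
    timepoint: int,
    dose_means: Mapping[float, float] | None = None,
    cv: float = 0.10,
    n: int = 8,
    seed: int = 0,
) -> PlateData:
    """Seeded lognormal replicates around each dose group's mean.

    The lognormal parameters are chosen so each group's arithmetic mean
    equals its target mean and its relative standard deviation equals
    *cv* (``cv = 0`` yields exact replicates).  The control group's mean
    is 1.0 by construction of the fixture table.  ``n >= 2`` is required
    (group variances are undefined otherwise).
    """
    if n < 2:
        raise ValueError("need at least n = 2 replicates per group")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    means = (dict(dose_means) if dose_means is not None
             else load_fixture_means(marker, timepoint))
    if any(m <= 0 for m in means.values()):
        raise ValueError("group means must be positive")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv ** 2)
    groups: dict[float, np.ndarray] = {}
    for dose in sorted(means):
        m = means[dose]
        mu = np.log(m) - 0.5 * sigma2
        groups[float(dose)] = rng.lognormal(
            mean=mu, sigma=np.sqrt(sigma2), size=n
        )
    return PlateData(marker=marker, timepoint=timepoint, groups=groups,
                     seed=seed, cv=cv)


def fold_change_table(plate: PlateData) -> dict[float, tuple[float, float]]:
    """Per-dose (mean ratio, sd) relative to the control group mean."""
    if 0.0 not in plate.groups:
        raise KeyError("plate has no control (0 uM) group")
    control_mean = float(np.mean(plate.groups[0.0]))
    if control_mean == 0.0:
        raise ZeroDivisionError("control group mean is zero")
    out: dict[float, tuple[float, float]] = {}
    for dose, values in plate.groups.items():
        values = np.asarray(values, dtype=float)
        out[dose] = (
            float(np.mean(values) / control_mean),
            float(np.std(values, ddof=1) / control_mean),
        )
    return out


# ---------------------------------------------------------------------------
# Welch ANOVA and Games-Howell
# ---------------------------------------------------------------------------

def _group_stats(groups: Sequence[Sequence[float]], *, require_var=True):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DegenerateDataError("need at least two groups")
    n = np.array([a.size for a in arrays], dtype=float)
    if np.any(n < 2):
        raise DegenerateDataError("every group needs at least two values")
    mean = np.array([a.mean() for a in arrays])
    var = np.array([a.var(ddof=1) for a in arrays])
    if require_var and np.any(var == 0):
        raise DegenerateDataError(
            "zero within-group variance; Welch-type tests are undefined"
        )
    return arrays, n, mean, var


def welch_anova(groups: Sequence[Sequence[float]]) -> TestReport:
    """Welch's heteroscedastic one-way ANOVA.

    Weights ``w_i = n_i / s_i^2``; the F statistic is the weighted
    between-group mean square over the Welch correction term, with
    ``k - 1`` and Welch-Satterthwaite denominator degrees of freedom.
    """
    _, n, mean, var = _group_stats(groups)
    k = len(n)
    w = n / var
    W = w.sum()
    grand = (w * mean).sum() / W
    a = ((1.0 - w / W) ** 2 / (n - 1.0)).sum()
    num = (w * (mean - grand) ** 2).sum() / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1.0) * a
    f_stat = num / den
    df1 = float(k - 1)
    df2 = (k ** 2 - 1.0) / (3.0 * a)
    p = float(stats.f.sf(f_stat, df1, df2))
    return TestReport("welch_anova", float(f_stat), (df1, float(df2)), p)


def games_howell(groups: Sequence[Sequence[float]]) -> list[PairwiseResult]:
    """Games-Howell pairwise comparisons.

    Each pair uses a Welch-type standard error and Welch-Satterthwaite
    degrees of freedom; the adjusted p value comes from the studentized
    range distribution with ``q = |t| * sqrt(2)`` and the full group
    count, which controls the family-wise error across all pairs.
    """
    _, n, mean, var = _group_stats(groups)
    k = len(n)
    labels = list(range(k))
    results: list[PairwiseResult] = []
    for i, j in itertools.combinations(labels, 2):
        se2 = var[i] / n[i] + var[j] / n[j]
        se = np.sqrt(se2)
        diff = mean[i] - mean[j]
        t = diff / se
        df = se2 ** 2 / (
            (var[i] / n[i]) ** 2 / (n[i] - 1)
            + (var[j] / n[j]) ** 2 / (n[j] - 1)
        )
        q = abs(t) * np.sqrt(2.0)
        p = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
        results.append(
            PairwiseResult(pair=(i, j), difference=float(diff),
                           statistic=float(t), df=float(df),
                           p_raw=p, p_adjusted=p)
        )
    return results


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn / Holm
# ---------------------------------------------------------------------------

def _pooled_ranks(groups: Sequence[Sequence[float]]):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)  # midranks for ties
    out = []
    start = 0
    for a in arrays:
        out.append(ranks[start:start + a.size])
        start += a.size
    return arrays, out, pooled


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts ** 3 - counts).sum())


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestReport:
    """Kruskal-Wallis H with the midrank ties correction.

    ``H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)``, divided by
    ``1 - sum(t^3 - t)/(N^3 - N)``; p from chi-square with ``k - 1`` df.
    All-identical data gives ``H = 0`` (not an error).
    """
    arrays, rank_groups, pooled = _pooled_ranks(groups)
    if len(arrays) < 2:
        raise DegenerateDataError("need at least two groups")
    N = pooled.size
    h = (
        12.0 / (N * (N + 1.0))
        * sum(rg.sum() ** 2 / rg.size for rg in rank_groups)
        - 3.0 * (N + 1.0)
    )
    correction = 1.0 - _tie_term(pooled) / (N ** 3 - N)
    h = 0.0 if correction == 0.0 else h / correction
    h = max(h, 0.0)
    df = float(len(arrays) - 1)
    p = float(stats.chi2.sf(h, df))
    return TestReport("kruskal_wallis", float(h), (df,), p)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, monotone in the raw-p ordering."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return adjusted.tolist()


def dunn_holm(groups: Sequence[Sequence[float]]) -> list[PairwiseResult]:
    """Dunn's rank-based pairwise z tests with Holm correction.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt(s2 (1/n_i + 1/n_j))`` with the
    ties-corrected variance ``s2 = N(N+1)/12 - sum(t^3 - t)/(12(N-1))``.
    """
    arrays, rank_groups, pooled = _pooled_ranks(groups)
    N = pooled.size
    s2 = N * (N + 1.0) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1.0))
    labels = list(range(len(arrays)))
    raw = []
    meta = []
    for i, j in itertools.combinations(labels, 2):
        ri = rank_groups[i].mean()
        rj = rank_groups[j].mean()
        ni, nj = arrays[i].size, arrays[j].size
        denom = np.sqrt(s2 * (1.0 / ni + 1.0 / nj))
        z = 0.0 if denom == 0.0 else (ri - rj) / denom
        p = float(2.0 * stats.norm.sf(abs(z)))
        raw.append(min(p, 1.0))
        meta.append(((i, j), float(ri - rj), float(z)))
    adjusted = holm_adjust(raw)
    return [
        PairwiseResult(pair=pair, difference=diff, statistic=z,
                       df=float("inf"), p_raw=p, p_adjusted=pa)
        for (pair, diff, z), p, pa in zip(meta, raw, adjusted)
    ]


# ---------------------------------------------------------------------------
# the full plate pathway
# ---------------------------------------------------------------------------

def analyse_plate(plate: PlateData) -> dict:
    """Run the complete statistics pathway on one plate.

    Returns the Welch ANOVA report with Games-Howell pairs and the
    Kruskal-Wallis report with Dunn-Holm pairs, both with dose-labelled
    pairs and significance tiers.
    """
    doses = sorted(plate.groups)
    groups = [plate.groups[d] for d in doses]
    welch = welch_anova(groups)
    welch.pairwise = games_howell(groups)
    kw = kruskal_wallis(groups)
    kw.pairwise = dunn_holm(groups)
    for report in (welch, kw):
        for pr in report.pairwise:
            i, j = pr.pair
            pr.pair = (doses[i], doses[j])
    return {
        "marker": plate.marker,
        "timepoint_h": plate.timepoint,
        "n_per_group": int(len(next(iter(plate.groups.values())))),
        "fold_changes": {
            str(d): {"mean_ratio": m, "sd": s}
            for d, (m, s) in fold_change_table(plate).items()
        },
        "welch_games_howell": welch.to_dict(),
        "kruskal_dunn_holm": kw.to_dict(),
    }
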