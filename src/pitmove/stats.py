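"""Inferential and descriptive statistics for diel movement classes.

Per-fish movement proportions over the four direction-by-diel classes
(downstream-night, upstream-night, downstream-day, upstream-day) are compared
with a tie-corrected Kruskal-Wallis rank-sum test, followed by Nemenyi's
all-pairs post-hoc comparison referenced to the studentized-range (Tukey)
distribution with infinite degrees of freedom.  Detection probability from a
mark-recapture design is an exact binomial proportion with a Clopper-Pearson
confidence interval.

The Kruskal-Wallis statistic (tie-corrected) is

    H = [ 12 / (N(N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2 ] / C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N),

with p from chi-square on k-1 df.  The Nemenyi pairwise statistic over the
pooled midranks is

    q_ij = sqrt(2) |Rbar_i - Rbar_j| / sqrt( N(N+1)/12 * (1/n_i + 1/n_j) ),

with the p-value from the upper tail of the studentized range with k groups
and infinite df.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Diel, Direction, MovementEvent, SiteGeometry

__all__ = [
    "DIEL_CLASSES",
    "BinomCI",
    "KWResult",
    "NemenyiResult",
    "class_proportions",
    "kruskal_wallis",
    "nemenyi_tukey",
    "clopper_pearson",
    "detection_probability",
    "descriptives",
]

# column order: dominant class first, as conventionally reported
DIEL_CLASSES = (
    "downstream_night",
    "upstream_night",
    "downstream_day",
    "upstream_day",
)


@dataclass(frozen=True)
class BinomCI:
    """Exact binomial point estimate with a Clopper-Pearson interval."""

    k: int
    n: int
    conf_level: float
    lower: float
    upper: float

    @property
    def p_hat(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float
    n_per_group: tuple[int, ...]


@dataclass(frozen=True)
class NemenyiResult:
    """Symmetric matrix of pairwise p-values (diagonal fixed at 1)."""

    p_values: pd.DataFrame
    q_statistics: pd.DataFrame
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        out = []
        groups = list(self.p_values.index)
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                if self.p_values.loc[a, b] < self.alpha:
                    out.append((a, b))
        return out


def _class_label(mv: MovementEvent) -> str | None:
    if mv.direction is Direction.UNKNOWN or mv.diel is None:
        return None
    return f"{mv.direction.value}_{mv.diel.value}"


def class_proportions(movements: Iterable[MovementEvent]) -> pd.DataFrame:
    """Per-tag proportions over the four direction-by-diel classes.

    Only movements with known direction and an assigned diel period count;
    tags with zero classified movements are excluded (not zero-filled).
    Returns a DataFrame indexed by tag with the four class-proportion
    columns plus ``n_movements``; per-tag proportions sum to 1.
    """
    counts: dict[str, dict[str, int]] = {}
    for mv in movements:
        label = _class_label(mv)
        if label is None:
            continue
        row = counts.setdefault(mv.tag_id, {c: 0 for c in DIEL_CLASSES})
        row[label] += 1
    if not counts:
        return pd.DataFrame(columns=[*DIEL_CLASSES, "n_movements"])
    df = pd.DataFrame.from_dict(counts, orient="index")[list(DIEL_CLASSES)]
    df = df.sort_index()
    n = df.sum(axis=1)
    props = df.div(n, axis=0)
    props["n_movements"] = n.astype(int)
    props.index.name = "tag_id"
    return props


def class_summary(proportions: pd.DataFrame) -> pd.DataFrame:
    """Median and range of each class proportion across tags."""
    cols = list(DIEL_CLASSES)
    return pd.DataFrame(
        {
            "median": proportions[cols].median(),
            "min": proportions[cols].min(),
            "max": proportions[cols].max(),
        }
    )


def kruskal_wallis(samples_by_group: Mapping[str, Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis rank-sum test across groups.

    With every observation identical the statistic is 0 and p is 1 (scipy
    raises on zero tie-corrected variance, so that degenerate case is
    handled directly).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in samples_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, arr in groups.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        return KWResult(
            H=0.0,
            df=len(groups) - 1,
            p_value=1.0,
            n_per_group=tuple(len(v) for v in groups.values()),
        )
    stat, p = sps.kruskal(*groups.values())
    return KWResult(
        H=float(stat),
        df=len(groups) - 1,
        p_value=float(p),
        n_per_group=tuple(len(v) for v in groups.values()),
    )


def nemenyi_tukey(samples_by_group: Mapping[str, Sequence[float]]) -> NemenyiResult:
    """Nemenyi all-pairs comparison via the studentized-range distribution.

    Pooled midranks; the pairwise statistic is scaled so its null reference
    is the studentized range with k groups and infinite df.  No additional
    tie correction is applied in this (Tukey) variant.
    """
    names = list(samples_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(samples_by_group[g], dtype=float) for g in names]
    sizes = np.array([a.size for a in arrays])
    if np.any(sizes == 0):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)  # midranks
    n_total = pooled.size
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    mean_ranks = np.array(mean_ranks)
    k = len(names)
    q = np.full((k, k), 0.0)
    p = np.eye(k) * 0.0 + np.where(np.eye(k, dtype=bool), 1.0, np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(
                n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            qij = np.sqrt(2.0) * abs(mean_ranks[i] - mean_ranks[j]) / se
            q[i, j] = q[j, i] = qij
            pij = float(sps.studentized_range.sf(qij, k, np.inf))
            p[i, j] = p[j, i] = min(1.0, pij)
    return NemenyiResult(
        p_values=pd.DataFrame(p, index=names, columns=names),
        q_statistics=pd.DataFrame(q, index=names, columns=names),
    )


def clopper_pearson(k: int, n: int, conf_level: float = 0.95) -> BinomCI:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion.

    Computed from Beta quantiles: lower = B(alpha/2; k, n-k+1), upper =
    B(1-alpha/2; k+1, n-k), with the conventional closures lower = 0 at
    k = 0 and upper = 1 at k = n.  Equivalent to inverting the exact
    binomial tail probabilities.
    """
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    alpha = 1.0 - conf_level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return BinomCI(k=k, n=n, conf_level=conf_level, lower=lower, upper=upper)


def detection_probability(
    recaptured_tags: Iterable[str],
    detected_tags: Iterable[str],
    conf_level: float = 0.95,
    all_tagged: Iterable[str] | None = None,
) -> dict:
    """Detection probability from a mark-recapture design.

    The estimate is the proportion of animals recaptured downstream that were
    detected at one or more upstream antennas: k = |recaptured & detected|,
    n = |recaptured|, with a Clopper-Pearson interval.  When the full tagged
    universe is given, the overall detected fraction among all tagged animals
    is reported alongside.
    """
    recaptured = set(recaptured_tags)
    detected = set(detected_tags)
    if not recaptured:
        raise ValueError("detection probability undefined without recaptures")
    k = len(recaptured & detected)
    n = len(recaptured)
    ci = clopper_pearson(k, n, conf_level)
    out = {"ci": ci, "k": k, "n": n, "p_hat": ci.p_hat}
    if all_tagged is not None:
        universe = set(all_tagged)
        out["n_tagged"] = len(universe)
        out["overall_detected_frac"] = len(detected & universe) / len(universe)
    return out


def descriptives(
    movements: Sequence[MovementEvent],
    geometry: SiteGeometry,
    n_tagged: int | None = None,
) -> dict:
    """Cohort summaries of final-filtered movements.

    Includes per-tag downstream speed medians (cm/s) with the
    median-of-medians, mover counts (and fraction of ``n_tagged`` when
    given), per-tag movement counts, and total first-order distance per tag
    in meters and raceway laps.
    """
    speeds: dict[str, list[float]] = {}
    counts: dict[str, int] = {}
    dist: dict[str, float] = {}
    for mv in movements:
        counts[mv.tag_id] = counts.get(mv.tag_id, 0) + 1
        if mv.first_order and mv.direction is Direction.DOWNSTREAM and mv.rate_m_s:
            speeds.setdefault(mv.tag_id, []).append(mv.rate_m_s * 100.0)
        if mv.first_order and mv.distance_m:
            dist[mv.tag_id] = dist.get(mv.tag_id, 0.0) + mv.distance_m
    per_tag_speed = {t: float(np.median(v)) for t, v in speeds.items()}
    movers = sorted(counts)
    count_values = np.array(list(counts.values()), dtype=float)
    out = {
        "n_movers": len(movers),
        "movers": movers,
        "per_tag_median_speed_cm_s": per_tag_speed,
        "cohort_median_speed_cm_s": (
            float(np.median(list(per_tag_speed.values()))) if per_tag_speed else float("nan")
        ),
        "movements_per_tag": counts,
        "median_movements_per_tag": (
            float(np.median(count_values)) if count_values.size else 0.0
        ),
        "total_distance_m": dist,
    }
    if geometry.circumference_m:
        out["total_laps"] = {
            t: d / geometry.circumference_m for t, d in dist.items()
        }
    if n_tagged:
        out["n_tagged"] = n_tagged
        out["mover_fraction"] = len(movers) / n_tagged
    return out
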