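"""Gene-set overlap and feature co-occurrence statistics.

Binding-expression integration asks whether differentially expressed genes
are over-represented among bound genes: with a universe of N genes, K bound,
n differential and k in both, the upper hypergeometric tail P(X >= k) is the
enrichment p-value. Feature co-occurrence on 2x2 region tables uses Fisher's
exact test. Report fractions are printed as whole percents, rounded half-up
(e.g. 888/1718 -> 52%).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio


@dataclass(frozen=True)
class OverlapReport:
    universe_size: int   # N
    bound_total: int     # K
    deg_total: int       # n
    overlap: int         # k
    fraction: float | None
    p_hyper: float | None
    printed_percent: int | None
    label: str = ""

    def __post_init__(self) -> None:
        N, K, n, k = self.universe_size, self.bound_total, self.deg_total, self.overlap
        if not (0 <= k <= min(K, n) and K <= N and n <= N):
            raise ValueError(f"inconsistent overlap counts N={N} K={K} n={n} k={k}")


def percent_half_up(numerator: int, denominator: int) -> int:
    """Whole-number percent with ties rounded up (51.69 -> 52, 36.5 -> 37)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact via log-gamma."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_overlap(
    universe: Iterable[str],
    bound: Iterable[str],
    deg: Iterable[str],
    label: str = "",
    normal_approximation: bool = False,
) -> OverlapReport:
    """Overlap of a bound-gene set with a differential set within a universe.

    Empty differential sets yield an explicit NA report (fraction, percent
    and p set to None), never a silent zero. `normal_approximation` switches
    to the N(mean, var) tail with continuity correction, for comparison only.
    """
    universe_set = set(universe)
    bound_set = set(bound)
    deg_set = set(deg)
    if not bound_set <= universe_set:
        raise ValueError("bound genes must be a subset of the universe")
    if not deg_set <= universe_set:
        raise ValueError("differential genes must be a subset of the universe")
    N, K, n = len(universe_set), len(bound_set), len(deg_set)
    k = len(bound_set & deg_set)
    if n == 0:
        return OverlapReport(N, K, n, k, None, None, None, label=label)
    if normal_approximation:
        mean = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / max(N - 1, 1)
        p = float(stats.norm.sf(k - 0.5, loc=mean, scale=math.sqrt(var))) if var > 0 else float(k > mean)
    else:
        p = hypergeom_upper_tail(N, K, n, k)
    return OverlapReport(N, K, n, k, fraction=k / n, p_hyper=p,
                         printed_percent=percent_half_up(k, n), label=label)


def feature_cooccurrence_test(contingency: np.ndarray | Sequence[Sequence[int]]
                              ) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (conditional-MLE odds ratio, p). The odds ratio is inf when a
    discordant off-diagonal is empty. Zero margins are an error.
    """
    table = np.asarray(contingency, dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin: co-occurrence test undefined")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    orr = _odds_ratio(table, kind="conditional").statistic
    return float(orr), float(p)


def overlap_report_table(reports: Sequence[OverlapReport]) -> pd.DataFrame:
    """TSV-ready summary: N, K, n, k, whole-number percent, p."""
    rows = []
    for r in reports:
        rows.append({
            "label": r.label,
            "universe_N": r.universe_size,
            "bound_K": r.bound_total,
            "set_n": r.deg_total,
            "overlap_k": r.overlap,
            "percent": r.printed_percent if r.printed_percent is not None else "NA",
            "p_hyper": r.p_hyper if r.p_hyper is not None else "NA",
        })
    return pd.DataFrame(rows)
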