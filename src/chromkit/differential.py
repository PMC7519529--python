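"""Composition-robust normalization and moderated differential testing.

Counts (RNA-seq genes, ChIP/ATAC region counts, or spike-in-normalized
promoter signal) are normalized by the trimmed mean of M-values (TMM): one
sample serves as reference, per-gene log-ratios (M) and average abundances
(A) are doubly trimmed, and the scale factor is the precision-weighted mean
of the retained M values. Group differences are then assessed on log2-CPM
with a moderated two-group t-test: per-feature residual variances are
shrunk toward a common prior estimated by moment matching on the log scale
(a scaled-inverse-chi-square prior, as in the empirical-Bayes linear-model
tradition), gaining degrees of freedom at small sample sizes. Calls use
FDR < 0.05 and fold change > 2 by default.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TmmConfig:
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    a_cutoff: float = -1e10

    def __post_init__(self) -> None:
        if not (0 <= self.logratio_trim < 0.5 and 0 <= self.abs_trim < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
                     cfg: TmmConfig) -> float:
    """TMM factor of one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        log_r = np.log2(p_obs / p_ref)                  # M
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2.0  # A
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > cfg.a_cutoff)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or not np.any(finite):
        raise ValueError("sample shares no positive features with the reference")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * cfg.logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * cfg.abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not np.any(keep):
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, cfg: TmmConfig | None = None) -> pd.Series:
    """Per-sample TMM scale factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile (of library-size-
    scaled counts) is closest to the mean upper-quartile. Genes with a zero
    in either the sample or the reference are excluded from M/A.
    """
    cfg = cfg or TmmConfig()
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair_factor(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], cfg)
        for j in range(x.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log2_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
             prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on effective (TMM-scaled) library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    return np.log2((counts + prior_count).div(lib + 1.0, axis=1) * 1e6)


# ---------------------------------------------------------------- moderated test


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-inverse-chi-square prior (s0^2, d0) to residual variances.

    Works on log variances: the excess variance of log(s2) beyond the
    trigamma(df/2) sampling component determines the prior degrees of
    freedom; zero or negative excess gives an infinite-d0 (fully pooled)
    prior.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >= 2 positive residual variances to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(e_mean))
    return s0, d0


def moderated_test(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    reference_group: str = "WT",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test on a features x samples log2 matrix.

    log2fc is (non-reference mean) - (reference mean). Residual variances
    are shrunk toward the moment-matched prior; `prior_df` forces d0 (np.inf
    gives the pooled z-test limit). Raises if either group has < 2 samples.
    """
    samples = list(matrix.columns)
    labels = [groups[s] for s in samples]
    level_set = sorted(set(labels))
    if len(level_set) != 2:
        raise ValueError(f"need exactly two groups, got {level_set}")
    if reference_group not in level_set:
        raise ValueError(f"reference group {reference_group!r} not among {level_set}")
    other = next(g for g in level_set if g != reference_group)
    idx_ref = [i for i, g in enumerate(labels) if g == reference_group]
    idx_alt = [i for i, g in enumerate(labels) if g == other]
    n1, n2 = len(idx_ref), len(idx_alt)
    df_resid = n1 + n2 - 2
    if min(n1, n2) < 2 or df_resid <= 0:
        raise ValueError("moderated test requires >= 2 replicates per group")

    x = matrix.to_numpy(dtype=float)
    m_ref = x[:, idx_ref].mean(axis=1)
    m_alt = x[:, idx_alt].mean(axis=1)
    lfc = m_alt - m_ref
    ss = ((x[:, idx_ref] - m_ref[:, None]) ** 2).sum(axis=1) + \
         ((x[:, idx_alt] - m_alt[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        s0, d0 = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0 = float(np.exp(np.mean(np.log(s2[s2 > 0])))) if np.isinf(d0) else \
            fit_variance_prior(s2, df_resid)[0]
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = lfc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    p = np.where(np.isnan(p), 1.0, p)

    result = pd.DataFrame({
        "feature_id": matrix.index,
        "log2fc": lfc,
        "mean_expr": x.mean(axis=1),
        "t": t_stat,
        "p_value": p,
    })
    result["fdr"] = bh_fdr(result["p_value"].to_numpy())
    return result


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def threshold_calls(
    results: pd.DataFrame,
    fdr_max: float = 0.05,
    min_fold: float = 2.0,
) -> tuple[set[str], set[str]]:
    """Significance calls: up/down at fdr < fdr_max and |fold| > min_fold (strict).

    Adds a 'call' column in place and returns (up feature ids, down feature ids).
    """
    cut = np.log2(min_fold)
    up = (results["fdr"] < fdr_max) & (results["log2fc"] > cut)
    down = (results["fdr"] < fdr_max) & (results["log2fc"] < -cut)
    results["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    ids = results["feature_id"]
    return set(ids[up]), set(ids[down])


def run_differential(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    reference_group: str = "WT",
    fdr_max: float = 0.05,
    min_fold: float = 2.0,
    tmm_cfg: TmmConfig | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """TMM -> log2-CPM -> moderated test -> BH -> threshold calls."""
    factors = tmm_factors(counts, tmm_cfg)
    logcpm = log2_cpm(counts, factors, prior_count=prior_count)
    results = moderated_test(logcpm, groups, reference_group=reference_group)
    threshold_calls(results, fdr_max=fdr_max, min_fold=min_fold)
    return results
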