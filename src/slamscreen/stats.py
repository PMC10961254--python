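"""Perturbation significance testing.

Two complementary screens sit on top of the kinetic solver:

* a per-gene randomization test — because perturbations have very different
  cell numbers, each observed pseudobulk rate is compared against a
  background built by resampling cell subsets of the same size from the
  pooled perturbed + NTC cells, re-aggregating and re-solving rates each
  time (500 iterations by default).  Resampled pseudo-cells whose counts are
  all-nascent or all-pre-existing cannot be solved ("invalid samplings");
  they contribute rate 0 to the background, and genes with 10% or more
  invalid samplings are dropped as untestable.
* a global Kolmogorov-Smirnov screen — per-perturbation distributions of
  gene-level rates (over the top 1,000 NTC-expressed genes) or of per-cell
  fractions (exonic share of nascent reads, mitochondrial nascent turnover)
  are compared with NTC by two-sample KS tests, Benjamini-Hochberg corrected,
  and called significant at FDR <= 0.05 with the direction taken from the
  sign of the log2 median ratio.

The empirical two-sided p-value uses a +1 correction so p is never 0:
``p = min(1, 2 * min(1 + #{bg >= obs}, 1 + #{bg <= obs}) / (n_iter + 1))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinetics import solve_rates_arrays


@dataclass
class RateTestResult:
    gene: str
    perturbation: str
    rate_type: str  # "synthesis" | "degradation"
    observed: float
    background_mean: float
    p_empirical: float
    direction: str  # "up" | "down"
    n_invalid: int
    testable: bool


def empirical_two_sided_p(
    background: np.ndarray, observed: float, n_iter: int
) -> float:
    ge = int(np.sum(background >= observed))
    le = int(np.sum(background <= observed))
    return min(1.0, 2.0 * min(1 + ge, 1 + le) / (n_iter + 1))


def _resample_indices(
    rng: np.random.Generator, n_pool: int, k: int, n_iter: int, replace: bool
) -> np.ndarray:
    if replace:
        return rng.integers(0, n_pool, size=(n_iter, k))
    # argsort of uniform rows = independent permutations; take first k
    return np.argsort(rng.random((n_iter, n_pool)), axis=1)[:, :k]


def randomization_test(
    pert_whole: np.ndarray,
    pert_nascent: np.ndarray,
    ntc_whole: np.ndarray,
    ntc_nascent: np.ndarray,
    gene: str = "",
    perturbation: str = "",
    t: float = 2.0,
    n_iter: int = 500,
    seed: int = 0,
    min_cells: int = 50,
    replace: bool = False,
    invalid_fraction: float = 0.10,
) -> tuple[RateTestResult, RateTestResult]:
    """Randomization test of one gene's rates in one perturbation.

    Inputs are per-cell whole/nascent counts of the tested gene for the
    perturbed cells and the NTC cells.  Returns (synthesis, degradation)
    results; an untestable result carries ``p_empirical = nan``.
    """
    pw = np.asarray(pert_whole, dtype=float)
    pn = np.asarray(pert_nascent, dtype=float)
    nw = np.asarray(ntc_whole, dtype=float)
    nn = np.asarray(ntc_nascent, dtype=float)
    k = pw.size
    if k < min_cells:
        raise ValueError(
            f"perturbation has {k} cells; at least {min_cells} required"
        )
    rng = np.random.default_rng(seed)

    obs_alpha, obs_beta, obs_valid, _ = solve_rates_arrays(
        np.array([pw.sum()]), np.array([pn.sum()]), t
    )

    pool_w = np.concatenate([pw, nw])
    pool_n = np.concatenate([pn, nn])
    idx = _resample_indices(rng, pool_w.size, k, n_iter, replace)
    R = pool_w[idx].sum(axis=1)
    Rn = pool_n[idx].sum(axis=1)
    bg_alpha, bg_beta, valid, _ = solve_rates_arrays(R, Rn, t)
    n_invalid = int((~valid).sum())
    bg_alpha = np.where(valid, bg_alpha, 0.0)
    bg_beta = np.where(valid, bg_beta, 0.0)
    testable = n_invalid < math.ceil(invalid_fraction * n_iter)

    out = []
    for rate_type, obs, bg in (
        ("synthesis", float(obs_alpha[0]), bg_alpha),
        ("degradation", float(obs_beta[0]), bg_beta),
    ):
        ok = testable and bool(obs_valid[0])
        mean = float(bg.mean())
        out.append(
            RateTestResult(
                gene=gene,
                perturbation=perturbation,
                rate_type=rate_type,
                observed=obs if ok else float("nan"),
                background_mean=mean,
                p_empirical=(
                    empirical_two_sided_p(bg, obs, n_iter)
                    if ok
                    else float("nan")
                ),
                direction="up" if ok and obs > mean else "down",
                n_invalid=n_invalid,
                testable=ok,
            )
        )
    return out[0], out[1]


def rate_tests_table(results: Sequence[RateTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class GlobalScreenResult:
    perturbation: str
    metric: str
    ks_statistic: float
    p: float
    fdr: float
    significant: bool
    direction: str
    log2_median_ratio: float


def global_ks_screen(
    values_by_perturbation: Mapping[str, np.ndarray],
    ntc_values: np.ndarray,
    metric: str,
    fdr_threshold: float = 0.05,
    min_values: int = 10,
) -> pd.DataFrame:
    """Two-sample KS screen of one metric across perturbations vs NTC.

    ``values_by_perturbation`` maps each perturbation to its value
    distribution (gene-level rates or per-cell fractions); non-finite values
    are dropped.  Perturbations with fewer than ``min_values`` finite values
    on either side stay untested (NaN statistics, not significant).
    """
    ntc = np.asarray(ntc_values, dtype=float)
    ntc = ntc[np.isfinite(ntc)]
    rows = []
    for pert, vals in values_by_perturbation.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < min_values or ntc.size < min_values:
            rows.append(
                dict(
                    perturbation=pert, metric=metric, ks_statistic=np.nan,
                    p=np.nan, log2_median_ratio=np.nan,
                )
            )
            continue
        ks = sps.ks_2samp(v, ntc, method="asymp")
        med_p, med_n = np.median(v), np.median(ntc)
        with np.errstate(divide="ignore", invalid="ignore"):
            lmr = float(np.log2(med_p / med_n)) if med_n > 0 else np.nan
        rows.append(
            dict(
                perturbation=pert, metric=metric,
                ks_statistic=float(ks.statistic), p=float(ks.pvalue),
                log2_median_ratio=lmr,
            )
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["fdr"].le(fdr_threshold).fillna(False)
    df["direction"] = np.where(df["log2_median_ratio"] > 0, "up", "down")
    return df[
        [
            "perturbation", "metric", "ks_statistic", "p", "fdr",
            "significant", "direction", "log2_median_ratio",
        ]
    ]


def top_expressed_genes(
    ntc_pseudobulk: pd.Series | Mapping[str, float], k: int = 1000
) -> list[str]:
    """Top-k genes by NTC pseudobulk expression (ties by gene id)."""
    s = pd.Series(ntc_pseudobulk)
    return (
        s.sort_values(ascending=False, kind="stable")
        .head(k)
        .index.tolist()
    )


def deg_filter(
    table: pd.DataFrame, confidence: str = "loose", fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Post-filter a differential-expression table.

    Keeps rows with ``fdr < 0.05``, a >= 1.5-fold expression difference
    (``fc`` as max/min >= 1), and CPM >= 5 (loose) or >= 50 (strict) in at
    least one of the two tested groups.
    """
    if confidence not in ("loose", "strict"):
        raise ValueError("confidence must be 'loose' or 'strict'")
    min_cpm = 5.0 if confidence == "loose" else 50.0
    keep = (
        (table["fdr"] < fdr_threshold)
        & (table["fc"] >= 1.5)
        & (table[["cpm_perturbed", "cpm_ntc"]].max(axis=1) >= min_cpm)
    )
    return table[keep]


def simple_deg_test(
    pert_counts: np.ndarray,
    ntc_counts: np.ndarray,
    pert_totals: np.ndarray,
    ntc_totals: np.ndarray,
) -> tuple[float, float, float, float]:
    """Rank-sum differential test for one gene; stand-in expression engine.

    Compares per-cell CPM-scaled expression with a two-sided Wilcoxon
    rank-sum test and reports (p, fc, cpm_perturbed, cpm_ntc) with ``fc``
    the pseudobulk CPM ratio folded to max/min >= 1.  With zero counts on
    both sides p = 1 and fc = 1.
    """
    pc = np.asarray(pert_counts, dtype=float)
    nc = np.asarray(ntc_counts, dtype=float)
    if pc.size < 2 or nc.size < 2:
        raise ValueError("need at least two cells per group")
    cpm_p = pc.sum() * 1e6 / np.asarray(pert_totals, dtype=float).sum()
    cpm_n = nc.sum() * 1e6 / np.asarray(ntc_totals, dtype=float).sum()
    if pc.sum() == 0 and nc.sum() == 0:
        return 1.0, 1.0, 0.0, 0.0
    x = pc * 1e6 / np.asarray(pert_totals, dtype=float)
    y = nc * 1e6 / np.asarray(ntc_totals, dtype=float)
    stat = sps.mannwhitneyu(x, y, alternative="two-sided")
    lo, hi = sorted([cpm_p, cpm_n])
    fc = hi / lo if lo > 0 else float("inf")
    return float(stat.pvalue), float(fc), float(cpm_p), float(cpm_n)


def select_embedding_features(
    perturbation_cpms: pd.DataFrame,
    ntc_cpm: pd.Series,
    n_bins: int = 10,
    top_fraction: float = 0.03,
) -> list[str]:
    """Expression-binned top-FC feature selection for pseudo-cell embedding.

    Genes expressed in NTC (CPM > 0) are split into ``n_bins`` equal-count
    bins of NTC expression; within each bin and each perturbation (columns
    of ``perturbation_cpms``), genes are ranked by fold change over NTC and
    the top ``ceil(top_fraction * bin_size)`` kept.  Ties break by higher
    NTC CPM then gene id.  The union over perturbations is returned sorted.
    """
    ntc = ntc_cpm[ntc_cpm > 0]
    if ntc.empty:
        return []
    cpms = perturbation_cpms.loc[ntc.index]
    n_bins = min(n_bins, len(ntc))
    bins = pd.qcut(ntc.rank(method="first"), q=n_bins, labels=False)
    selected: set[str] = set()
    for pert in cpms.columns:
        fc = cpms[pert] / ntc
        frame = pd.DataFrame(
            {"fc": fc, "ntc": ntc, "bin": bins, "gene": ntc.index}
        )
        for _, grp in frame.groupby("bin"):
            n_take = math.ceil(top_fraction * len(grp))
            top = grp.sort_values(
                ["fc", "ntc", "gene"], ascending=[False, False, True]
            ).head(n_take)
            selected.update(top["gene"])
    return sorted(selected)
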