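"""Steady-state RNA kinetics from whole/nascent pseudobulk counts.

Model
-----
Each gene's mRNA follows first-order decay with zero-order synthesis,

    dR/dt = alpha - beta * R,

and perturbations are assumed to have reached a new steady state before
labeling, so R = alpha / beta.  With 100% labeling efficiency every molecule
made during the labeling window of length ``t`` is nascent, giving

    Rn = (alpha / beta) * (1 - exp(-beta * t)),
    Rp = (alpha / beta) * exp(-beta * t).

Since whole counts R and nascent counts Rn are both measured, the decay
constant has the closed form

    beta = -ln(1 - Rn / R) / t,    alpha = R * beta.

Rates are computed on raw pseudobulk counts, so alpha carries pseudobulk
count units per hour; all downstream use is relative (fold changes between a
perturbation and the non-targeting control), which cancels the scale.

Genes whose pseudobulk is all-nascent (Rn = R, beta diverges) or has no
nascent counts (Rn = 0, beta = 0 exactly only as t -> infinity) cannot be
solved and are flagged degenerate rather than smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID = "none"
NO_NASCENT = "no_nascent"
ONLY_NASCENT = "only_nascent"
ZERO_COUNTS = "zero_counts"


@dataclass
class PerturbationPseudobulk:
    """Summed whole (R) and nascent (Rn) counts over one cell group."""

    group: str
    n_cells: int
    genes: np.ndarray  # gene ids, shape (G,)
    R: np.ndarray  # whole counts, shape (G,)
    Rn: np.ndarray  # nascent counts, shape (G,)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.R = np.asarray(self.R, dtype=float)
        self.Rn = np.asarray(self.Rn, dtype=float)
        if self.n_cells < 1:
            raise ValueError("pseudobulk needs at least one cell")
        if self.R.shape != self.Rn.shape or self.R.shape != self.genes.shape:
            raise ValueError("genes, R and Rn must have matching shapes")
        if (self.Rn > self.R).any() or (self.Rn < 0).any():
            raise ValueError("need 0 <= Rn <= R for every gene")


@dataclass
class KineticEstimate:
    """Per-gene synthesis (alpha) and degradation (beta) rate at time t."""

    gene: str
    alpha: float
    beta: float
    t: float
    valid: bool
    degenerate_reason: str = VALID


def solve_rates_arrays(
    R: np.ndarray, Rn: np.ndarray, t: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised closed-form solver.

    Returns ``(alpha, beta, valid, reason)``; alpha/beta are NaN where the
    estimate is degenerate (R = 0, Rn = 0, or Rn = R).
    """
    if t <= 0:
        raise ValueError("labeling time t must be positive")
    R = np.asarray(R, dtype=float)
    Rn = np.asarray(Rn, dtype=float)
    if R.shape != Rn.shape:
        raise ValueError("R and Rn must have the same shape")
    if (Rn < 0).any() or (Rn > R).any():
        raise ValueError("need 0 <= Rn <= R elementwise")

    reason = np.full(R.shape, VALID, dtype=object)
    reason[R == 0] = ZERO_COUNTS
    reason[(R > 0) & (Rn == 0)] = NO_NASCENT
    reason[(R > 0) & (Rn == R)] = ONLY_NASCENT
    valid = reason == VALID

    beta = np.full(R.shape, np.nan)
    alpha = np.full(R.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(valid, Rn / np.where(R > 0, R, 1.0), np.nan)
        beta = np.where(valid, -np.log1p(-frac) / t, np.nan)
        alpha = np.where(valid, R * beta, np.nan)
    return alpha, beta, valid, reason


def solve_rates(R: float, Rn: float, t: float) -> KineticEstimate:
    """Solve one gene's rates; see module docstring for the closed form."""
    alpha, beta, valid, reason = solve_rates_arrays(
        np.array([R]), np.array([Rn]), t
    )
    return KineticEstimate(
        gene="",
        alpha=float(alpha[0]),
        beta=float(beta[0]),
        t=t,
        valid=bool(valid[0]),
        degenerate_reason=str(reason[0]),
    )


def aggregate_pseudobulk(
    whole: pd.DataFrame | np.ndarray,
    nascent: pd.DataFrame | np.ndarray,
    groups: Iterable[str],
    genes: Iterable[str] | None = None,
) -> dict[str, PerturbationPseudobulk]:
    """Sum per-cell whole/nascent counts (cells x genes) within each group.

    ``groups`` gives one label per cell (row).  Returns a pseudobulk per
    distinct label; empty groups cannot occur by construction.
    """
    W = np.asarray(whole, dtype=float)
    N = np.asarray(nascent, dtype=float)
    if W.shape != N.shape:
        raise ValueError("whole and nascent must have the same shape")
    if (N > W).any():
        raise ValueError("nascent counts exceed whole counts")
    labels = np.asarray(list(groups))
    if labels.shape[0] != W.shape[0]:
        raise ValueError("one group label per cell required")
    if genes is None:
        if isinstance(whole, pd.DataFrame):
            genes = np.asarray(whole.columns)
        else:
            genes = np.array([f"g{i}" for i in range(W.shape[1])])
    genes = np.asarray(genes)

    out: dict[str, PerturbationPseudobulk] = {}
    for label in np.unique(labels):
        mask = labels == label
        out[str(label)] = PerturbationPseudobulk(
            group=str(label),
            n_cells=int(mask.sum()),
            genes=genes,
            R=W[mask].sum(axis=0),
            Rn=N[mask].sum(axis=0),
        )
    return out


def rates_table(
    pb: PerturbationPseudobulk, t: float
) -> pd.DataFrame:
    """Solve rates for every gene of one pseudobulk; tidy per-gene table."""
    alpha, beta, valid, reason = solve_rates_arrays(pb.R, pb.Rn, t)
    return pd.DataFrame(
        {
            "gene": pb.genes,
            "group": pb.group,
            "n_cells": pb.n_cells,
            "R": pb.R,
            "Rn": pb.Rn,
            "alpha": alpha,
            "beta": beta,
            "valid": valid,
            "degenerate_reason": reason,
        }
    )


def rate_fold_changes(
    perturbed: pd.DataFrame,
    ntc: pd.DataFrame,
    normalize_depth: bool = True,
) -> pd.DataFrame:
    """Per-gene expression/synthesis/degradation fold changes vs NTC.

    Both inputs are :func:`rates_table` outputs.  Rate fold changes are
    defined only where both estimates are valid; log2 values are reported
    alongside.  Because count-scale alpha (and R) grow with the number of
    cells aggregated, expression and synthesis ratios are put on a common
    per-million scale by default (``normalize_depth``); degradation is a
    count ratio and needs no normalization.  With identical pseudobulks the
    normalization factor is 1 and every fold change is exactly 1.
    """
    merged = perturbed.merge(
        ntc[["gene", "R", "alpha", "beta", "valid"]],
        on="gene",
        suffixes=("", "_ntc"),
    )
    scale = (
        ntc["R"].sum() / perturbed["R"].sum() if normalize_depth else 1.0
    )
    both = (merged["valid"] & merged["valid_ntc"]).to_numpy()
    synth_fc = np.where(
        both, scale * merged["alpha"] / merged["alpha_ntc"], np.nan
    )
    deg_fc = np.where(both, merged["beta"] / merged["beta_ntc"], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        expr_fc = np.where(
            merged["R_ntc"] > 0, scale * merged["R"] / merged["R_ntc"], np.nan
        )
        out = pd.DataFrame(
            {
                "gene": merged["gene"],
                "group": merged["group"],
                "expression_fc": expr_fc,
                "synthesis_fc": synth_fc,
                "degradation_fc": deg_fc,
                "log2_expression_fc": np.log2(expr_fc),
                "log2_synthesis_fc": np.log2(synth_fc),
                "log2_degradation_fc": np.log2(deg_fc),
                "defined": both,
            }
        )
    return out
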