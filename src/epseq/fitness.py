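"""Expression / activity fitness estimation from binned read counts.

The estimator chain:

* reads -> cells: within a bin, a variant's sorted-cell count is its
  read share times the number of cells sorted into that bin,
  ``c_v = r_v * c_tot / r_tot`` (kept fractional);
* beta: the bin-median-fluorescence-weighted mean of the variant's cell
  counts, ``beta = sum(omega_i * c_vi) / sum(c_vi)``;
* fitness: ``F = log2(beta_v / beta_wt)``, zero for wild type by
  construction;
* replicate consensus: cell-count-weighted mean of per-replicate scores,
  ``F_fin = sum(F_vj * c_vj) / sum(c_vj)``.

Also here: variant classification from codons, the synonymous neutral
range, single-clone scores from gate summaries (non-log ratio), the
normalized (non-logarithmic) activity that deconvolves catalytic effects
from expression, and the minimum-cell support filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._genetics import STOP, translate_codon
from .counts import BinCountTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_CELLS = 10.0


def reads_to_cells(r_v, r_tot: float, c_tot: float):
    """Convert read counts to (fractional) sorted-cell counts for one bin."""
    if c_tot < 0:
        raise ValueError("c_tot must be >= 0")
    if r_tot == 0:
        logger.warning("bin with r_tot=0: cell counts undefined, set to 0")
        return np.zeros_like(np.asarray(r_v, dtype=float)) if np.ndim(r_v) else 0.0
    if r_tot < 0 or np.any(np.asarray(r_v) < 0) or np.any(np.asarray(r_v) > r_tot):
        raise ValueError("need 0 <= r_v <= r_tot")
    out = np.asarray(r_v, dtype=float) * c_tot / r_tot
    return out if np.ndim(r_v) else float(out)


def weighted_mean_beta(c_v: Sequence[float], omega: Sequence[float]) -> float:
    """Bin-median-weighted mean fluorescence of a variant's cells."""
    c = np.asarray(c_v, dtype=float)
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise ValueError("all omega must be > 0")
    total = c.sum()
    if total <= 0:
        raise ValueError("variant unobserved: all cell counts are zero")
    return float((w * c).sum() / total)


def fitness_score(beta_v: float, beta_wt: float) -> float:
    """Log2 fitness of a variant relative to wild type."""
    if beta_v <= 0 or beta_wt <= 0:
        raise ValueError("beta values must be > 0")
    return math.log2(beta_v / beta_wt)


def consensus_score(f_vj: Sequence[float], c_vj: Sequence[float]) -> float:
    """Cell-weighted consensus of per-replicate fitness scores."""
    f = np.asarray(f_vj, dtype=float)
    c = np.asarray(c_vj, dtype=float)
    if np.any(c < 0):
        raise ValueError("cell weights must be >= 0")
    if c.sum() <= 0:
        raise ValueError("no replicate with positive cell support")
    return float((f * c).sum() / c.sum())


def classify_variant(wt_codon: str, mut_codon: str) -> str:
    """synonymous / nonsense / missense from a codon substitution."""
    wt_aa = translate_codon(wt_codon)
    mut_aa = translate_codon(mut_codon)
    if mut_aa == STOP:
        return "nonsense"
    if mut_aa == wt_aa:
        return "synonymous"
    return "missense"


def neutral_range(synonymous_scores: Sequence[float]) -> tuple[float, float]:
    """Mean and SD of synonymous fitness scores: the assay's neutral range."""
    values = np.asarray(synonymous_scores, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 synonymous scores")
    return float(values.mean()), float(values.std(ddof=1))


def is_neutral(f: float, center: float, sd: float, k: float = 1.0) -> bool:
    return abs(f - center) <= k * sd


# ---------------------------------------------------------------------------
# Table-level scoring


def score_replicate(table: BinCountTable, wt_id: str) -> pd.DataFrame:
    """Score every variant in one replicate's count table.

    Returns a frame indexed by variant_id with columns ``beta``, ``F``
    and ``cells`` (the variant's total reads-derived cell count, the
    consensus weight).  ``r_tot`` per bin is the table's own column sum,
    so unassigned reads never dilute the conversion.
    """
    bins = table.bin_ids
    omega = np.array([table.metas[b].omega for b in bins])
    cells = np.zeros((len(table.reads), len(bins)))
    for j, b in enumerate(bins):
        r = table.reads[b].to_numpy()
        cells[:, j] = reads_to_cells(r, float(r.sum()), table.metas[b].c_tot)

    totals = cells.sum(axis=1)
    observed = totals > 0
    if not observed.all():
        logger.warning("%d unobserved variants excluded", int((~observed).sum()))
    beta = np.full(len(totals), np.nan)
    beta[observed] = (cells[observed] * omega).sum(axis=1) / totals[observed]

    out = pd.DataFrame(
        {"beta": beta, "cells": totals}, index=table.reads.index
    ).loc[observed]
    if wt_id not in out.index:
        raise ValueError(f"wild-type reference {wt_id!r} not observed")
    beta_wt = float(out.loc[wt_id, "beta"])
    out["F"] = np.log2(out["beta"] / beta_wt)
    return out


def consensus_table(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-replicate scores into the consensus fitness table.

    Input frames are ``score_replicate`` outputs.  Output columns:
    ``F_rep{j}``/``cells_rep{j}`` per replicate, ``cells_total`` and the
    cell-weighted consensus ``F_fin``.  A variant must be observed in at
    least one replicate to appear.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    pieces = []
    for j, rep in enumerate(replicates, start=1):
        pieces.append(rep[["F", "cells"]].rename(
            columns={"F": f"F_rep{j}", "cells": f"cells_rep{j}"}
        ))
    merged = pd.concat(pieces, axis=1)
    f_cols = [f"F_rep{j}" for j in range(1, len(replicates) + 1)]
    c_cols = [f"cells_rep{j}" for j in range(1, len(replicates) + 1)]
    f = merged[f_cols].to_numpy()
    c = merged[c_cols].fillna(0).to_numpy()
    c = np.where(np.isnan(f), 0.0, c)
    weight = c.sum(axis=1)
    merged["cells_total"] = weight
    with np.errstate(invalid="ignore"):
        merged["F_fin"] = np.nansum(f * c, axis=1) / weight
    return merged[weight > 0]


def replicate_support_filter(
    records: pd.DataFrame, min_cells: float = DEFAULT_MIN_CELLS,
    cells_column: str = "cells_total",
) -> pd.DataFrame:
    """Keep variants supported by at least ``min_cells`` total cells."""
    return records[records[cells_column] >= min_cells]


# ---------------------------------------------------------------------------
# Single-clone flow-cytometry scores


@dataclass(frozen=True)
class SingleCloneGateSummary:
    """Per-gate median fluorescence and percent of cells for one clone."""

    omegas: tuple[float, ...]
    pct_cells: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.omegas) != len(self.pct_cells):
            raise ValueError("omegas and pct_cells must have equal length")
        if any(w <= 0 for w in self.omegas):
            raise ValueError("gate medians must be > 0")
        if any(np.diff(self.omegas) <= 0):
            raise ValueError("gate medians must be strictly increasing")
        if any(p < 0 for p in self.pct_cells):
            raise ValueError("pct_cells must be >= 0")
        if sum(self.pct_cells) > 100 + 1e-6:
            raise ValueError("pct_cells sum exceeds 100")

    def beta(self) -> float:
        total = sum(self.pct_cells)
        if total <= 0:
            raise ValueError("no cells in any gate")
        return sum(w * p for w, p in zip(self.omegas, self.pct_cells)) / total


def single_clone_expression(
    gates: SingleCloneGateSummary, wt_gates: SingleCloneGateSummary
) -> float:
    """Non-logarithmic single-clone score: beta_v / beta_wt."""
    return gates.beta() / wt_gates.beta()


# ---------------------------------------------------------------------------
# Normalized activity


def expression_floor(nonsense_scores: Sequence[float]) -> float:
    """Upper limit of the nonsense expression distribution: mean + 1 SD."""
    values = np.asarray(nonsense_scores, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 nonsense scores")
    return float(values.mean() + values.std(ddof=1))


def normalized_activity(
    f_act, f_exp, floor: float
) -> pd.DataFrame:
    """Non-logarithmic activity normalized by expression.

    ``na = 2**F_act / 2**F_exp``; defined only for variants whose
    expression fitness clears ``floor`` (the upper limit of the nonsense
    distribution), since below it the variant is effectively not
    displayed and its activity reading is noise.  ``na > 1`` marks
    expression-independent activity enhancement.
    """
    f_act = np.asarray(f_act, dtype=float)
    f_exp = np.asarray(f_exp, dtype=float)
    passes = (f_exp > floor) & ~np.isnan(f_act) & ~np.isnan(f_exp)
    na = np.where(passes, np.exp2(f_act - f_exp), np.nan)
    return pd.DataFrame({"na": na, "passes_expression_floor": passes})
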