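"""Joint analysis of fitness landscapes and structural features.

Joins the per-variant expression/activity fitness table with per-residue
structural features, conservation and (optionally) external ΔΔG
predictions, and provides the statistical summaries of a
deep-mutational-scanning study: per-position averages, feature
correlations, spatial subgroup contrasts, conserved-site screens,
heatmap export and activity-hotspot ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def library_coverage(
    n_observed: int, n_positions: int, n_substitutions: int = 19
) -> float:
    """Percent of possible single substitutions observed in the library."""
    possible = n_positions * n_substitutions
    if possible <= 0:
        raise ValueError("n_positions and n_substitutions must be positive")
    return 100.0 * n_observed / possible


def mutagenized_positions(first_codon: int, last_codon: int) -> int:
    """Number of codons in an inclusive mutagenized window."""
    if last_codon < first_codon:
        raise ValueError("last_codon must be >= first_codon")
    return last_codon - first_codon + 1


def join_tables(
    fitness: pd.DataFrame,
    features: pd.DataFrame | None = None,
    conservation: pd.DataFrame | None = None,
    ddg: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per variant with fitness plus position-level annotations.

    ``fitness`` needs ``variant_id``/``position``; ``features`` and
    ``conservation`` are joined on ``position``, ``ddg`` on
    ``variant_id``.  Variants whose position is missing from the feature
    table are kept and flagged ``has_features=False``.
    """
    joined = fitness.copy()
    if features is not None:
        joined = joined.merge(features, on="position", how="left",
                              suffixes=("", "_feat"))
        probe = [c for c in features.columns if c != "position"][0]
        joined["has_features"] = joined[probe].notna()
        n_missing = int((~joined["has_features"]).sum())
        if n_missing:
            logger.warning("%d variants lack structural features", n_missing)
    if conservation is not None:
        cols = ["position", "cons"]
        joined = joined.merge(conservation[cols], on="position", how="left",
                              suffixes=("", "_cons"))
    if ddg is not None:
        joined = joined.merge(ddg, on="variant_id", how="left")
    return joined


def position_summaries(
    joined: pd.DataFrame,
    exp_column: str = "F_exp",
    act_column: str = "F_act",
    na_column: str = "na",
) -> pd.DataFrame:
    """Per-position arithmetic means over missense variants.

    Synonymous and nonsense variants are excluded from position
    averages (stop rows live separately in the heatmap export).
    """
    if joined.empty:
        raise ValueError("joined table is empty")
    missense = joined[joined["variant_class"] == "missense"]
    rows = []
    for pos, grp in missense.groupby("position"):
        row = {"position": pos}
        for name, col in (("F_exp", exp_column), ("F_act", act_column),
                          ("na", na_column)):
            if col in grp:
                vals = grp[col].dropna()
                row[f"mean_{name}"] = vals.mean() if len(vals) else np.nan
                row[f"n_variants_{name}"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("position").reset_index(drop=True)


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str
    defined: bool = True


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pairwise-complete Pearson or Spearman correlation with two-sided p."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, method, defined=False)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), n, method)


def subgroup_contrast(
    joined: pd.DataFrame, mask: pd.Series, value_column: str
) -> dict[str, float]:
    """Mean of a score inside a feature-defined subgroup vs the whole set.

    Percent difference is reported against the absolute overall mean, so
    a subgroup twice as deleterious as the average reads -100%.
    """
    values = joined[value_column]
    sub = values[mask.reindex(values.index, fill_value=False)].dropna()
    allv = values.dropna()
    if sub.empty:
        raise ValueError("empty subgroup")
    overall = float(allv.mean())
    sub_mean = float(sub.mean())
    pct = 100.0 * (sub_mean - overall) / abs(overall) if overall != 0 else np.nan
    return {
        "subgroup_mean": sub_mean,
        "overall_mean": overall,
        "percent_difference": pct,
        "n_subgroup": int(len(sub)),
        "n_overall": int(len(allv)),
    }


def conserved_site_screen(
    position_table: pd.DataFrame,
    cons_threshold: float = 100.0,
    exp_floor: float = 0.0,
    exp_column: str = "mean_F_exp",
    distance_column: str = "d_active",
) -> dict[str, object]:
    """Screen fully conserved positions for tolerated (positive) scores.

    ``position_table`` carries one row per position with ``cons``, the
    mean expression score and the distance to the active site.  Returns
    the conserved positions, the subset clearing the expression floor,
    and the correlation of score with active-site distance over the
    conserved set (None when fewer than 3 conserved positions).
    """
    conserved = position_table[position_table["cons"] >= cons_threshold]
    positive = conserved[conserved[exp_column] > exp_floor]
    corr = None
    if len(conserved) >= 3 and distance_column in conserved:
        try:
            corr = correlate(conserved[exp_column], conserved[distance_column])
        except ValueError:
            corr = None
    return {
        "conserved_positions": conserved["position"].tolist(),
        "positive_positions": positive["position"].tolist(),
        "n_conserved": int(len(conserved)),
        "n_positive": int(len(positive)),
        "distance_correlation": corr,
    }


def hotspot_ranking(
    joined: pd.DataFrame, top_n: int = 1000, k: int = 6,
    na_column: str = "na",
) -> pd.DataFrame:
    """Positions most represented among the top-normalized-activity variants.

    Variants are ranked by normalized activity (ties broken by
    variant_id for determinism), the top ``top_n`` retained, and the
    ``k`` positions contributing the most variants returned with their
    frequencies.
    """
    eligible = joined.dropna(subset=[na_column])
    if len(eligible) < top_n:
        logger.warning("only %d eligible variants (< top_n=%d): using all",
                       len(eligible), top_n)
    top = eligible.sort_values(
        [na_column, "variant_id"], ascending=[False, True]
    ).head(top_n)
    freq = (
        top.groupby("position").size().rename("frequency").reset_index()
        .sort_values(["frequency", "position"], ascending=[False, True])
    )
    return freq.head(k).reset_index(drop=True)


def heatmap_matrix(records: pd.DataFrame, value_column: str) -> pd.DataFrame:
    """Position x amino-acid fitness matrix (rows: 20 aa + stop).

    Missing combinations stay NaN (missing, not zero).  Duplicate
    (position, mut_aa) rows mean the input was not consensus-scored and
    are rejected.
    """
    from ._genetics import AMINO_ACIDS, STOP

    subs = records[records["variant_class"].isin(
        ["missense", "nonsense", "synonymous"]
    )]
    dup = subs.duplicated(subset=["position", "mut_aa"])
    if dup.any():
        raise ValueError("duplicate (position, mut_aa) rows: provide "
                         "consensus-scored input")
    matrix = subs.pivot(index="mut_aa", columns="position", values=value_column)
    matrix = matrix.reindex(index=AMINO_ACIDS + [STOP])
    matrix.index.name = "mut_aa"
    return matrix


def write_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path)


def read_heatmap(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, index_col=0)
    matrix.columns = matrix.columns.astype(int)
    matrix.columns.name = "position"
    return matrix
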