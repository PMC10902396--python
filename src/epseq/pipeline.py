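"""End-to-end glue: simulate -> LUT -> count -> score in memory.

These helpers run the whole estimator chain on synthetic experiments
without touching disk; the CLI wraps the same functions around files.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import counts, fitness, lut as lut_mod, simdata


def count_replicate(
    replicate: simdata.SortSeqReplicate, lut: lut_mod.LookupTable
) -> counts.BinCountTable:
    """Tag and count every bin of one simulated replicate."""
    per_bin: dict[int, pd.Series] = {}
    metas = []
    for meta in replicate.metas:
        rs = replicate.read_sets[meta.bin_id]
        r_v, _tags = counts.count_reads_vectorized(rs.umis, rs.mean_q, lut)
        per_bin[meta.bin_id] = r_v
        metas.append(meta)
    return counts.build_count_table(per_bin, metas)


def score_replicates(
    tables: Sequence[counts.BinCountTable], wt_id: str = simdata.WT_ID
) -> pd.DataFrame:
    """Per-replicate scoring plus cell-weighted consensus."""
    reps = [fitness.score_replicate(t, wt_id) for t in tables]
    return fitness.consensus_table(reps)


def simulate_and_score(
    config: simdata.SimConfig,
    n_replicates: int = 2,
    assay: str = "expression",
    library: simdata.SimLibrary | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Run the full synthetic experiment and return every intermediate.

    Returns a dict with the library, the resolved LUT, the per-replicate
    sort/sequence results and count tables, and the consensus fitness
    frame (joined with the ground truth for recovery checks).
    """
    rng = rng or np.random.default_rng(config.seed)
    if library is None:
        library = simdata.generate_library(config)
    table = lut_mod.build_lut(library.prelut_records)

    replicates, count_tables = [], []
    for _ in range(n_replicates):
        rep = simdata.simulate_sort_and_sequence(
            library.truths, config, rng, assay=assay
        )
        replicates.append(rep)
        count_tables.append(count_replicate(rep, table))
    scores = score_replicates(count_tables)

    truth = library.truth_frame().set_index("variant_id")
    joined = scores.join(truth, how="left")
    return {
        "library": library,
        "lut": table,
        "replicates": replicates,
        "count_tables": count_tables,
        "scores": scores,
        "joined": joined,
    }
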