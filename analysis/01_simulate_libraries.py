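#!/usr/bin/env python
"""Simulate the two-library experiment and the homology-hit inputs.

Stands in for the raw bacteriocyte and whole-body RNA-seq libraries at desk
scale (depths 524,000 / 518,000 fragments, 1:100 of the published totals)
with 10% enriched and 10% depleted transcripts at a 4-fold effect, plus a
hit table with 10 planted bacterial-origin genes and 50 decoys.  Writes
counts, hits, FPKM and truth tables under results/simulated/.
"""

from pathlib import Path

import pandas as pd

from symbioscreen.io import write_hit_table, write_tsv
from symbioscreen.synthetic import (
    SimCountParams,
    SimHgtParams,
    simulate_count_table,
    simulate_hit_table,
)

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    count_params = SimCountParams(seed=SEED)
    counts, truth = simulate_count_table(count_params)
    write_tsv(counts, OUT / "counts.tsv")
    write_tsv(truth.rename_axis("transcript_id").reset_index(), OUT / "counts_truth.tsv")
    print(f"simulated {len(counts)} transcripts "
          f"({(truth == 'enriched').sum()} enriched, {(truth == 'depleted').sum()} depleted); "
          f"library totals {counts['count_lib1'].sum():,} / {counts['count_lib2'].sum():,}")

    hit_params = SimHgtParams(seed=SEED)
    sim = simulate_hit_table(hit_params)
    write_hit_table(sim.hits, OUT / "hits.tsv")
    write_tsv(sim.truth.rename_axis("query_id").reset_index(), OUT / "hits_truth.tsv")
    write_tsv(pd.DataFrame(sorted(sim.fpkm.items()), columns=["query_id", "fpkm"]),
              OUT / "hits_fpkm.tsv")
    n_planted = (sim.truth == "planted_htg").sum()
    print(f"simulated hit table: {len(sim.hits)} rows, {n_planted} planted HTGs, "
          f"{(sim.truth != 'planted_htg').sum()} decoys -> {OUT}")


if __name__ == "__main__":
    main()
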