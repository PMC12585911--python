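"""Quantify transcription-coupled repair as TS/NTS strand asymmetry.

Counts repair reads per gene on the transcribed strand (reads opposite
the gene) and non-transcribed strand (same strand), converts to RPKM,
stratifies genes into expression quartiles, and tests TS vs NTS with a
paired Wilcoxon signed-rank test per quartile (BH-corrected). The
planted bias rises from 0.5 (lowest quartile) to 0.75 (highest).
"""

import numpy as np
import pandas as pd

from repairscape import (
    SimConfig,
    build_toy_genome,
    compare_strands,
    count_in_bins,
    rpkm_from_counts,
    simulate_xr_reads,
    stratify,
)

cfg = SimConfig(n_reads=100_000, seed=5)
toy = build_toy_genome(cfg)
reads, _, _ = simulate_xr_reads(toy.genome, toy.genes, toy.expression, cfg)

ivs = [g.interval for g in toy.genes]
lengths = np.array([g.length for g in toy.genes])
ids = [g.gene_id for g in toy.genes]
lib = len(reads)
ts = rpkm_from_counts(count_in_bins(reads, ivs, "opposite"), lengths, lib)
nts = rpkm_from_counts(count_in_bins(reads, ivs, "same"), lengths, lib)

sg = stratify(
    toy.expression.index.to_numpy(), toy.expression.to_numpy(), 4,
    exclude_zero=True,
)
groups = {f"q{i}": list(sg.members(i)) for i in range(4)}
table = compare_strands(pd.Series(ts, index=ids), pd.Series(nts, index=ids), groups)
print(table[["n_genes", "mean_ts_fraction", "wilcoxon_p", "q_bh"]].round(4))
# mean_ts_fraction is TS/(TS+NTS); 0.5 = no asymmetry, the planted bias
# grows with expression quartile, the hallmark of transcription-coupled repair
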