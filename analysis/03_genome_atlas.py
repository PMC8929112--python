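#!/usr/bin/env python
"""Windowed distribution and clustering of the identified NLRs.

Reports how many 200 kb windows hold NLRs, the clustered fraction under
the at-least-two rule, the subgenome split, and the telomere proximity of
NLRs versus all genes (the planted placement bias).
"""

import numpy as np
import pandas as pd
from common import RUN_DIR, stage_config

from nlr_atlas import io
from nlr_atlas.pipeline import run


def main():
    run(stage_config("atlas"))
    clusters = pd.read_csv(RUN_DIR / "clusters.tsv", sep="\t", comment="#")
    summary = pd.read_csv(RUN_DIR / "subgenome_summary.tsv", sep="\t",
                          comment="#")
    genes, chrom_lengths = io.read_gff3(RUN_DIR / "genes.gff3")
    nlr_ids = set((RUN_DIR / "nlr_ids.txt").read_text().split())

    def mean_end_distance(subset):
        return np.mean([
            min(g.start - 1, chrom_lengths[g.chrom] - g.end) for g in subset
        ])

    nlrs = [g for g in genes if g.gene_id in nlr_ids]
    others = [g for g in genes if g.gene_id not in nlr_ids]
    row2 = clusters[clusters.min_count == 2].iloc[0]
    print(f"atlas -> {RUN_DIR / 'clusters.tsv'}")
    print(f"  clustered NLRs at min_count=2: {row2.nlr_in_clusters} "
          f"({100 * row2.clustered_fraction:.2f}% of total)")
    print("  subgenome split:")
    print(summary.to_string(index=False))
    print(f"  mean distance to chromosome end: NLRs "
          f"{mean_end_distance(nlrs) / 1e3:.0f} kb vs other genes "
          f"{mean_end_distance(others) / 1e3:.0f} kb (telomere bias)")


if __name__ == "__main__":
    main()
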