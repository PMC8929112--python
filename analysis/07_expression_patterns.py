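#!/usr/bin/env python
"""Expression-pattern clustering and responsive/broad-spectrum calls.

Finding: row-scaled complete-linkage clustering splits the NLRs into the
configured number of patterns, and the four genes planted with an 8-fold
inoculation response are called responsive in both experiments, hence
broad-spectrum.
"""

import pandas as pd
from common import RUN_DIR, stage_config

from nlr_atlas.pipeline import run


def main():
    run(stage_config("express"))
    patterns = pd.read_csv(RUN_DIR / "patterns.tsv", sep="\t", comment="#")
    sizes = patterns.pattern.value_counts().sort_index().to_dict()
    print(f"express -> {RUN_DIR / 'patterns.tsv'}")
    print(f"  {len(patterns)} genes in {patterns.pattern.nunique()} patterns "
          f"(sizes {sizes})")
    for exp in ("fhb", "powdery_mildew"):
        path = RUN_DIR / f"responsive_{exp}.txt"
        calls = path.read_text().split() if path.exists() else []
        print(f"  responsive in {exp}: {len(calls)} ({', '.join(calls[:6])})")
    broad = (RUN_DIR / "broad_spectrum.txt").read_text().split()
    print(f"  broad-spectrum (>=2 experiments): {broad}")


if __name__ == "__main__":
    main()
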