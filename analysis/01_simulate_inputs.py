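#!/usr/bin/env python
"""Generate the study's synthetic inputs.

Builds a two-contig genome with 60 annotated genes, implants an AP-1-like
TGASTCA consensus at a background rate of 0.5 copies/promoter and 6
copies/promoter in 10 designated target genes, and simulates a BeadChip-style
differential-expression table (two tissues x three age comparisons, three
animals per group) in which the motif's transcription factor and its targets
are planted down-regulated in the thymus young-vs-old comparison, alongside
10 up-regulated decoys. Everything lands under results/inputs/.
"""

from pathlib import Path

import pandas as pd

from senescan.synthetic import make_fixtures

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    paths = make_fixtures(OUT, seed=20260920 % 2**31, n_genes=60, n_targets=10)
    truth = pd.read_csv(paths["truth_implants"], sep="\t")
    planted = pd.read_csv(paths["truth_planted"], sep="\t")
    print(f"wrote synthetic dataset to {OUT}")
    print(f"  implanted motif copies: {len(truth)} across "
          f"{truth.gene_id.nunique()} promoters")
    print(f"  planted expression effects: {len(planted)} "
          f"({(planted.direction == 'down').sum()} down, "
          f"{(planted.direction == 'up').sum()} up)")
    print(f"  pipeline config: {paths['config']}")


if __name__ == "__main__":
    main()
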