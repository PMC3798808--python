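#!/usr/bin/env python
"""Extract promoters and scan them for transcription-factor binding sites.

Takes 1000 bases upstream of every annotated TSS (strand-aware, TSS base
excluded), scans both strands for each IUPAC consensus with no mismatches,
and writes the genes x motifs occurrence-count matrix plus the per-motif
genome-background profile (mean, sample SD, mean +/- SD band).
"""

import dataclasses
from pathlib import Path

import pandas as pd

from senescan.enrichment import background_profiles
from senescan.io_formats import (read_annotation, read_genome, read_motifs)
from senescan.motif_scan import scan_promoters
from senescan.promoters import extract_promoters

ROOT = Path(__file__).resolve().parent.parent / "results"
WINDOW = 1000


def main() -> None:
    inputs = ROOT / "inputs"
    genome = read_genome(inputs / "genome.fa")
    genes = read_annotation(inputs / "genes.bed", "BED6")
    motifs = read_motifs(inputs / "motifs.tsv")
    promoters = extract_promoters(genome, genes, WINDOW)
    print(f"extracted {len(promoters)} promoters "
          f"({sum(p.effective_length < WINDOW for p in promoters)} truncated)")
    matrix = scan_promoters(promoters, motifs, "both")
    matrix.total.rename_axis("gene_id").to_csv(ROOT / "count_matrix.tsv", sep="\t")
    profiles = background_profiles(matrix)
    pd.DataFrame([dataclasses.asdict(profiles[m]) for m in sorted(profiles)]
                 ).to_csv(ROOT / "profiles.tsv", sep="\t", index=False)
    for m, p in sorted(profiles.items()):
        print(f"  {m}: mean {p.mean:.2f}, sd {p.sd:.2f}, "
              f"band ({p.lo_threshold:.2f}, {p.hi_threshold:.2f}) "
              f"over {p.n_promoters} promoters")


if __name__ == "__main__":
    main()
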