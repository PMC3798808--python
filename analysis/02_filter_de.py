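#!/usr/bin/env python
"""Filter the differential-expression table and summarize the gene sets.

Applies the p <= 0.05, |log2FC| >= 0.4 filter per tissue/comparison, writes
the up/down gene sets and the tissue overlap partition of the young-vs-old
comparison (the cross-organ Venn).
"""

from pathlib import Path

import pandas as pd

from senescan.de_analysis import filter_de, overlap_sets
from senescan.io_formats import read_de_table
from senescan.types import AnalysisConfig

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_de_table(ROOT / "inputs" / "de_table.tsv")
    sets = filter_de(records, AnalysisConfig())
    rows = [{"tissue": t, "comparison": c, "n_up": len(s.up),
             "n_down": len(s.down), "n_total": len(s.genes)}
            for (t, c), s in sorted(sets.items())]
    out = ROOT / "de_sets_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")
    for row in rows:
        if row["n_total"]:
            print(f"  {row['tissue']} {row['comparison']}: "
                  f"{row['n_up']} up, {row['n_down']} down")

    thymus = sets[("thymus", "y-o")].genes
    spleen = sets[("spleen", "y-o")].genes
    part = overlap_sets(thymus, spleen)
    print(f"young-vs-old overlap: {len(part.a_only)} thymus-specific, "
          f"{len(part.common)} shared, {len(part.b_only)} spleen-specific")
    pd.DataFrame([{"thymus_only": len(part.a_only), "common": len(part.common),
                   "spleen_only": len(part.b_only)}]
                 ).to_csv(ROOT / "overlap_y_o.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
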