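#!/usr/bin/env python
"""Functional-category and aging-signature summaries of the DE sets.

Counts up/down DE genes per functional category (with percent down over both
the DE subset and all category genes on the table) and scores concordance of
the filtered genes with the expected age-direction signature.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from senescan.de_analysis import (filter_de, signature_concordance,
                                  summarize_categories)
from senescan.io_formats import (read_categories, read_de_table, read_signature)
from senescan.types import AnalysisConfig

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = AnalysisConfig()
    records = read_de_table(ROOT / "inputs" / "de_table.tsv")
    categories = read_categories(ROOT / "inputs" / "categories.tsv")
    signature = read_signature(ROOT / "inputs" / "signature.tsv")
    sets = filter_de(records, config)
    table_genes = sorted({r.gene_id for r in records})

    rows = []
    for key in sorted(sets):
        for s in summarize_categories(sets[key], categories,
                                      table_genes=table_genes, split_roles=True):
            row = dataclasses.asdict(s)
            row["tissue"], row["comparison"] = key
            rows.append(row)
    out = ROOT / "category_summary.tsv"
    pd.DataFrame(rows, columns=["tissue", "comparison", "category", "n_up",
                                "n_down", "pct_down", "pct_down_of_table"]
                 ).to_csv(out, sep="\t", index=False)
    interesting = [r for r in rows if r["n_up"] + r["n_down"] > 0]
    print(f"wrote {out}; non-empty category rows:")
    for r in interesting:
        pct = "-" if r["pct_down"] is None else f"{r['pct_down']:.0f}%"
        print(f"  {r['tissue']} {r['comparison']} {r['category']}: "
              f"{r['n_up']} up / {r['n_down']} down ({pct} down)")

    conc = {}
    for tissue, comparison in sorted(sets):
        subset = [r for r in records
                  if r.tissue == tissue and r.comparison == comparison]
        result = signature_concordance(subset, signature, config)
        if result.n_evaluated:
            conc[f"{tissue}-{comparison}"] = {
                "n_consistent": result.n_consistent,
                "n_evaluated": result.n_evaluated,
                "fraction": result.fraction}
            print(f"signature concordance {tissue} {comparison}: "
                  f"{result.n_consistent} of {result.n_evaluated} consistent")
    with open(ROOT / "concordance.json", "w") as fh:
        json.dump(conc, fh, indent=2, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
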