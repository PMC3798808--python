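"""Strand-aware promoter extraction.

A promoter is the fixed-width window immediately upstream of the TSS,
excluding the TSS base itself. On the plus strand with TSS t the genomic
interval is [max(0, t - window), t); on the minus strand it is
[t + 1, min(L, t + 1 + window)) and the emitted sequence is the reverse
complement, so that every promoter reads 5'->3' in gene orientation.
Promoters truncated at contig edges are retained with their shorter length.
Soft-masked (lower-case) bases are upper-cased; 'N' runs are kept and never
match any motif downstream.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .types import GeneModel, Promoter, reverse_complement


def extract_promoters(genome: Mapping[str, str],
                      genes: Iterable[GeneModel],
                      window: int) -> list[Promoter]:
    if window < 1:
        raise ValueError(f"promoter window must be >= 1, got {window}")
    genes = list(genes)
    missing = sorted({g.contig for g in genes} - set(genome))
    if missing:
        raise ValueError(f"gene contigs absent from genome: {', '.join(missing)}")
    promoters = []
    for gene in genes:
        contig_seq = genome[gene.contig]
        length = len(contig_seq)
        if gene.tss >= length:
            raise ValueError(
                f"TSS {gene.tss} of gene {gene.gene_id!r} beyond contig "
                f"{gene.contig!r} length {length}")
        if gene.strand == "+":
            start, end = max(0, gene.tss - window), gene.tss
            seq = contig_seq[start:end].upper()
        else:
            start, end = gene.tss + 1, min(length, gene.tss + 1 + window)
            seq = reverse_complement(contig_seq[start:end].upper())
        promoters.append(Promoter(gene_id=gene.gene_id, contig=gene.contig,
                                  start=start, end=end, strand=gene.strand,
                                  sequence=seq))
    return promoters
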