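"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators:

* :func:`generate_genome` builds a multi-contig genome of i.i.d. bases at a
  requested GC content, places non-overlapping genes on random strands with a
  full promoter window of clearance, and implants motif occurrences into each
  promoter — Poisson(lambda_bg) copies for background genes, Poisson(lambda_target)
  for designated target genes — at uniform non-overlapping offsets, each on a
  uniformly chosen strand, with degenerate positions resolved uniformly over
  the allowed set. A truth table records every implant.

* :func:`generate_de_table` simulates per-gene log2-expression for two groups
  (Normal(baseline, noise_sd), with +/- effect_size added to the second group
  for planted genes), and emits log2FC = difference of group means and a
  two-sided two-sample t-test p-value. noise_sd = 0 degenerates to exact
  planted effects with p = 0 (planted) / 1 (null).

Expression is simulated directly on the log2 scale (the pipeline's input
contract); the baseline (8.0) cancels in log2FC. Neither generator attempts
realistic genome mimicry (repeats, CpG islands) or probe-level microarray
noise. All outputs are pure functions of their configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_scan import compile_pattern
from .types import DERecord, GeneModel, MotifDef, reverse_complement

_BASES = np.array(list("ACGT"))
_BASELINE_LOG2_EXPR = 8.0
_GENE_SPACER = 10  # bases between adjacent promoter slots


@dataclass
class SynthGenomeConfig:
    n_genes: int = 200
    contigs: int = 2
    promoter_window: int = 1000
    gc_content: float = 0.42
    lambda_bg: float = 1.0
    lambda_target: float = 5.0
    target_gene_ids: frozenset = frozenset()
    motif: Optional[MotifDef] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0,1)")
        if self.lambda_bg < 0 or self.lambda_target < self.lambda_bg:
            raise ValueError("need 0 <= lambda_bg <= lambda_target")
        if self.motif is not None and self.promoter_window < len(self.motif.pattern):
            raise ValueError("promoter_window must be >= motif length")


@dataclass
class SynthGenome:
    genome: dict[str, str]
    genes: list[GeneModel]
    #: one row per implant: gene_id, offset (within the gene-oriented
    #: promoter), strand (relative to the promoter), sequence (as realized,
    #: promoter orientation)
    truth: pd.DataFrame


@dataclass
class SynthExprConfig:
    genes: Sequence[str] = ()
    tissues: Sequence[str] = ("thymus", "spleen")
    comparisons: Sequence[str] = ("y-m", "y-o", "m-o")
    #: gene -> (tissue, comparison) -> "up"/"down"/"null"
    planted: Mapping[str, Mapping[tuple, str]] = field(default_factory=dict)
    effect_size: float = 1.0
    n_per_group: int = 3
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 when noise_sd > 0")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _realize(rng: np.random.Generator, motif: MotifDef) -> str:
    compiled = compile_pattern(motif)
    return "".join(rng.choice(sorted(s)) for s in compiled.allowed)


def _draw_offsets(rng: np.random.Generator, k: int, window: int, mlen: int) -> list[int]:
    """k non-overlapping implant offsets in [0, window - mlen].

    Sorted draws from the free space shifted by i*mlen give a uniform sample
    over all non-overlapping configurations without rejection.
    """
    if k == 0:
        return []
    free = window - k * mlen
    if free < 0:
        raise ValueError(
            f"promoter of {window} bp cannot hold {k} non-overlapping {mlen}-mers")
    slack = np.sort(rng.integers(0, free + 1, size=k))
    return [int(s + i * mlen) for i, s in enumerate(slack)]


def generate_genome(config: SynthGenomeConfig) -> SynthGenome:
    """Build a synthetic genome + annotation + implant truth table.

    Genes are laid out in non-overlapping slots of (window + 1) bases plus a
    spacer, so every promoter is extractable at full length. The promoter is
    synthesized in gene orientation (background bases, then implants written
    over them) and written to the contig directly for plus-strand genes or
    reverse-complemented for minus-strand genes.
    """
    rng = np.random.default_rng(config.seed)
    window = config.promoter_window
    slot = window + 1 + _GENE_SPACER
    per_contig = -(-config.n_genes // config.contigs)  # ceil
    contig_len = per_contig * slot + _GENE_SPACER

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    gene_index = 0
    for ci in range(config.contigs):
        contig_name = f"chr{ci + 1}"
        contig = _random_bases(rng, contig_len, config.gc_content)
        n_here = min(per_contig, config.n_genes - gene_index)
        for gi in range(n_here):
            gene_id = f"g{gene_index + 1:05d}"
            gene_index += 1
            region = gi * slot + _GENE_SPACER // 2
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss = region + window
                prom_start = region
            else:
                tss = region
                prom_start = region + 1

            lam = (config.lambda_target if gene_id in config.target_gene_ids
                   else config.lambda_bg)
            promoter = None
            if config.motif is not None and lam > 0:
                k = int(rng.poisson(lam))
                if k:
                    mlen = len(config.motif.pattern)
                    promoter = list(contig[prom_start:prom_start + window])
                    if strand == "-":
                        promoter = list(reverse_complement("".join(promoter)))
                    for offset in _draw_offsets(rng, k, window, mlen):
                        instance = _realize(rng, config.motif)
                        inst_strand = "+" if rng.random() < 0.5 else "-"
                        placed = instance if inst_strand == "+" else reverse_complement(instance)
                        promoter[offset:offset + mlen] = list(placed)
                        truth_rows.append({"gene_id": gene_id, "offset": offset,
                                           "strand": inst_strand, "sequence": placed})
            if promoter is not None:
                genomic = "".join(promoter)
                if strand == "-":
                    genomic = reverse_complement(genomic)
                contig[prom_start:prom_start + window] = list(genomic)
            genes.append(GeneModel(gene_id=gene_id, contig=contig_name,
                                   strand=strand, tss=tss))
        genome[contig_name] = "".join(contig)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "offset", "strand", "sequence"])
    return SynthGenome(genome=genome, genes=genes, truth=truth)


def annotation_rows(genes: Sequence[GeneModel], gene_length: int = 1) -> list[tuple]:
    """BED6 rows for the gene models (a gene body of ``gene_length`` bases)."""
    rows = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss, g.tss + gene_length
        else:
            start, end = g.tss - gene_length + 1, g.tss + 1
        rows.append((g.contig, start, end, g.gene_id, 0, g.strand))
    return rows


def make_fixtures(out_dir, seed: int = 0, n_genes: int = 60,
                  n_targets: int = 10, promoter_window: int = 1000) -> dict:
    """Materialize a complete demo dataset (every format io_formats reads).

    One motif (an AP-1-like TGASTCA consensus) whose transcription factor is
    the first annotated gene; ``n_targets`` genes get elevated implant rates
    and are planted down-regulated together with the TF in (thymus, y-o), so
    the default pipeline recovers them as concordant enriched targets. An
    equal number of decoy genes is planted up-regulated (discordant). Returns
    the path map, including a ready-to-run pipeline config.json.
    """
    from pathlib import Path

    from .io_formats import (write_bed6, write_de_table, write_genome,
                             write_motifs)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tf_gene = "g00001"
    motif = MotifDef(motif_id="AP1", tf_gene_id=tf_gene, pattern="TGASTCA")
    targets = frozenset(f"g{i + 2:05d}" for i in range(n_targets))
    gcfg = SynthGenomeConfig(n_genes=n_genes, contigs=2,
                             promoter_window=promoter_window,
                             lambda_bg=0.5, lambda_target=6.0,
                             target_gene_ids=targets, motif=motif, seed=seed)
    synth = generate_genome(gcfg)

    gene_ids = [g.gene_id for g in synth.genes]
    decoys = gene_ids[1 + n_targets:1 + 2 * n_targets]
    planted: dict = {tf_gene: {("thymus", "y-o"): "down"}}
    for g in sorted(targets):
        planted[g] = {("thymus", "y-o"): "down"}
    for g in decoys:
        planted[g] = {("thymus", "y-o"): "up"}
    ecfg = SynthExprConfig(genes=gene_ids, planted=planted, effect_size=1.5,
                           n_per_group=3, noise_sd=0.3, seed=seed + 1)
    records = generate_de_table(ecfg)

    paths = {k: out / v for k, v in {
        "genome": "genome.fa", "annotation": "genes.bed", "motifs": "motifs.tsv",
        "de_table": "de_table.tsv", "categories": "categories.tsv",
        "signature": "signature.tsv", "truth_implants": "truth_implants.tsv",
        "truth_planted": "truth_planted.tsv", "config": "config.json"}.items()}
    write_genome(synth.genome, paths["genome"])
    write_bed6(annotation_rows(synth.genes), paths["annotation"])
    write_motifs([motif], paths["motifs"])
    write_de_table(records, paths["de_table"])
    synth.truth.to_csv(paths["truth_implants"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "tissue": t, "comparison": c, "direction": d}
         for g, m in sorted(planted.items()) for (t, c), d in sorted(m.items())]
    ).to_csv(paths["truth_planted"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "category": "S phase progression", "role": "na"}
         for g in sorted(targets)] +
        [{"gene_id": g, "category": "cell cycle progression", "role": "activator"}
         for g in decoys]
    ).to_csv(paths["categories"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "expected_direction": "down"} for g in sorted(targets)] +
        [{"gene_id": g, "expected_direction": "up"} for g in decoys]
    ).to_csv(paths["signature"], sep="\t", index=False)

    import json
    config = {"de_table": str(paths["de_table"]), "genome": str(paths["genome"]),
              "annotation": str(paths["annotation"]),
              "annotation_dialect": "BED6", "motifs": str(paths["motifs"]),
              "categories": str(paths["categories"]),
              "signature": str(paths["signature"]),
              "out_dir": str(out / "reports"),
              "promoter_window": promoter_window, "seed": seed}
    with open(paths["config"], "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def generate_de_table(config: SynthExprConfig) -> list[DERecord]:
    """Simulate a differential-expression table with planted directions."""
    rng = np.random.default_rng(config.seed)
    records = []
    for gene in config.genes:
        for tissue in config.tissues:
            for comparison in config.comparisons:
                direction = config.planted.get(gene, {}).get((tissue, comparison), "null")
                delta = {"up": config.effect_size, "down": -config.effect_size,
                         "null": 0.0}[direction]
                if config.noise_sd == 0.0:
                    lfc = delta
                    p = 0.0 if direction != "null" else 1.0
                else:
                    g1 = rng.normal(_BASELINE_LOG2_EXPR, config.noise_sd,
                                    config.n_per_group)
                    g2 = rng.normal(_BASELINE_LOG2_EXPR + delta, config.noise_sd,
                                    config.n_per_group)
                    lfc = float(g2.mean() - g1.mean())
                    p = float(stats.ttest_ind(g2, g1).pvalue)
                records.append(DERecord(gene_id=gene, tissue=tissue,
                                        comparison=comparison, log2fc=lfc,
                                        p_value=p))
    return records
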