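"""Genome-background enrichment calling and TF-target concordance.

For each motif the per-promoter occurrence counts over *all* annotated genes
define a background band: mean +/- sd_multiplier * sample SD. A DE gene's
promoter is called enriched when its count is strictly above the band,
depleted when strictly below, and typical otherwise (counts equal to a
threshold are typical — "higher or lower than" is read strictly). The band is
a dispersion criterion, not a statistical test; no multiple-testing
correction applies.

A candidate (non-typical) promoter becomes a target assignment when both the
motif's transcription factor gene and the target gene pass the DE filter in
the same tissue and comparison; the assignment is concordant when their
change directions agree. The default report keeps concordant, enriched
assignments only; depleted and discordant ones are available under flags.
Direction is never inferred across tissues (the same TF can move in opposite
directions in different organs).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from .de_analysis import filter_de
from .motif_scan import CountMatrix
from .types import (AnalysisConfig, CandidateCall, DERecord, MotifDef,
                    OccurrenceProfile, TargetAssignment)

logger = logging.getLogger(__name__)


def background_profile(matrix: CountMatrix, motif_id: str,
                       sd_multiplier: float = 1.0,
                       promoter_lengths: Optional[Mapping[str, int]] = None,
                       full_length: Optional[int] = None) -> OccurrenceProfile:
    """Mean/SD occurrence profile of one motif over all promoters in the matrix.

    ``matrix`` must cover the full gene annotation, not only DE genes. With
    ``promoter_lengths`` and ``full_length`` given, promoters shorter than
    ``full_length`` (truncated at contig edges) are excluded from the
    background.
    """
    if motif_id not in matrix.total.columns:
        raise KeyError(f"motif {motif_id!r} not in count matrix")
    counts = matrix.total[motif_id]
    if promoter_lengths is not None and full_length is not None:
        keep = [g for g in counts.index if promoter_lengths.get(g, 0) >= full_length]
        counts = counts.loc[keep]
    n = len(counts)
    if n < 2:
        raise ValueError(f"need >= 2 promoters for a background SD, got {n}")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    return OccurrenceProfile(motif_id=motif_id, n_promoters=n, mean=mean, sd=sd,
                             hi_threshold=mean + sd_multiplier * sd,
                             lo_threshold=mean - sd_multiplier * sd)


def background_profiles(matrix: CountMatrix, sd_multiplier: float = 1.0,
                        **kwargs) -> dict[str, OccurrenceProfile]:
    return {m: background_profile(matrix, m, sd_multiplier, **kwargs)
            for m in matrix.motif_ids}


def call_candidates(matrix: CountMatrix,
                    profiles: Mapping[str, OccurrenceProfile],
                    de_genes: Optional[Iterable[str]] = None
                    ) -> tuple[list[CandidateCall], list[str]]:
    """Classify each (DE gene, motif) count against its background band.

    Returns (calls, skipped_genes); DE genes without a promoter in the matrix
    are skipped, not fatal. With ``de_genes`` None, every gene in the matrix
    is called (the matrix should then already be restricted to DE genes).
    """
    if de_genes is None:
        genes: list[str] = matrix.gene_ids
        skipped: list[str] = []
    else:
        de_genes = list(dict.fromkeys(de_genes))
        present = set(matrix.total.index)
        genes = [g for g in de_genes if g in present]
        skipped = [g for g in de_genes if g not in present]
        if skipped:
            logger.warning("%d DE gene(s) lack a promoter and were skipped", len(skipped))
    calls = []
    for motif_id in matrix.motif_ids:
        profile = profiles[motif_id]
        for gene in genes:
            count = int(matrix.total.at[gene, motif_id])
            if count > profile.hi_threshold:
                call = "enriched"
            elif count < profile.lo_threshold:
                call = "depleted"
            else:
                call = "typical"
            calls.append(CandidateCall(gene_id=gene, motif_id=motif_id,
                                       count=count, call=call))
    return calls, skipped


def tf_target_concordance(calls: Iterable[CandidateCall],
                          de_records: Sequence[DERecord],
                          motifs: Iterable[MotifDef],
                          config: AnalysisConfig,
                          include_depleted: bool = False,
                          keep_all: bool = False) -> list[TargetAssignment]:
    """Pair non-typical candidate promoters with their motif's TF.

    An assignment is emitted for every (tissue, comparison) in which BOTH the
    TF gene and the target gene pass the DE filter. By default only
    concordant, enriched assignments are returned; ``include_depleted`` admits
    depleted candidates and ``keep_all`` returns discordant assignments too
    (with their concordant flag set accordingly). A motif whose TF never
    appears in the DE table is skipped with a warning. A TF is never its own
    target.
    """
    de_sets = filter_de(de_records, config)
    direction: dict[tuple[str, str], dict[str, str]] = {}
    for key, de_set in de_sets.items():
        d = {g: "up" for g in de_set.up}
        d.update({g: "down" for g in de_set.down})
        direction[key] = d
    de_genes_all = {r.gene_id for r in de_records}

    motif_to_tf = {}
    for m in motifs:
        if m.tf_gene_id not in de_genes_all:
            logger.warning("motif %s: TF gene %r absent from the DE table, skipped",
                           m.motif_id, m.tf_gene_id)
            continue
        motif_to_tf[m.motif_id] = m.tf_gene_id

    wanted_calls = {"enriched"} | ({"depleted"} if include_depleted else set())
    assignments = []
    for call in calls:
        if call.call not in wanted_calls:
            continue
        tf = motif_to_tf.get(call.motif_id)
        if tf is None or call.gene_id == tf:
            continue
        for key in sorted(direction):
            dirs = direction[key]
            if tf not in dirs or call.gene_id not in dirs:
                continue
            concordant = dirs[tf] == dirs[call.gene_id]
            if not concordant and not keep_all:
                continue
            assignments.append(TargetAssignment(
                tf_gene_id=tf, target_gene_id=call.gene_id,
                motif_id=call.motif_id, tissue=key[0], comparison=key[1],
                tf_direction=dirs[tf], target_direction=dirs[call.gene_id],
                concordant=concordant, candidate_call=call.call))
    return assignments
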