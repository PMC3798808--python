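"""Differential-expression set summaries.

Filtering keeps genes passing both the p-value and the absolute log2
fold-change thresholds (inclusive boundaries: p <= cutoff and |log2FC| >=
cutoff pass). Downstream summaries are set-level: overlap partitions between
comparisons, per-category up/down counts, and concordance with an expected
age-direction signature.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional

from .types import (AnalysisConfig, CategorySummary, ConcordanceResult,
                    DEGeneSet, DERecord, OverlapPartition)


def _passes(record: DERecord, config: AnalysisConfig) -> bool:
    p = record.adj_p if config.use_adjusted_p else record.p_value
    if p is None:
        return False
    return p <= config.p_cutoff and abs(record.log2fc) >= config.lfc_cutoff


def _direction(log2fc: float) -> Optional[str]:
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    return None  # exactly zero: neither up nor down


def filter_de(records: Iterable[DERecord],
              config: AnalysisConfig) -> dict[tuple[str, str], DEGeneSet]:
    """Partition records into per-(tissue, comparison) up/down gene sets."""
    up: dict[tuple[str, str], set] = defaultdict(set)
    down: dict[tuple[str, str], set] = defaultdict(set)
    keys: list[tuple[str, str]] = []
    for r in records:
        key = (r.tissue, r.comparison)
        if key not in up:
            keys.append(key)
            up[key]  # touch so key order is stable
            down[key]
        if not _passes(r, config):
            continue
        direction = _direction(r.log2fc)
        if direction == "up":
            up[key].add(r.gene_id)
        elif direction == "down":
            down[key].add(r.gene_id)
    return {key: DEGeneSet(tissue=key[0], comparison=key[1],
                           up=frozenset(up[key]), down=frozenset(down[key]))
            for key in keys}


def overlap_sets(a: Iterable[str], b: Iterable[str]) -> OverlapPartition:
    """Partition two gene sets into A-only / B-only / common (gene identity only)."""
    a, b = frozenset(a), frozenset(b)
    return OverlapPartition(a_only=a - b, b_only=b - a, common=a & b)


def overlap_sets_directional(a: DEGeneSet, b: DEGeneSet) -> dict[str, OverlapPartition]:
    """Direction-aware variant: separate partitions of the up and down sets."""
    return {"up": overlap_sets(a.up, b.up), "down": overlap_sets(a.down, b.down)}


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den > 0 else None


def summarize_categories(de_set: DEGeneSet,
                         categories: Mapping[str, tuple[str, str]],
                         table_genes: Optional[Iterable[str]] = None,
                         split_roles: bool = False) -> list[CategorySummary]:
    """Count DE genes up/down per functional category.

    Genes in the DE set but absent from the category map land in an
    "unassigned" bucket. ``pct_down`` uses the DE genes of the category as
    denominator; when ``table_genes`` (all genes on the analysed expression
    table) is given, ``pct_down_of_table`` divides by the number of category
    genes present on that table instead. With ``split_roles`` the counts are
    additionally broken out per (category, role), e.g. "G1 progression
    [inhibitor]".
    """
    def key_of(gene: str) -> list[str]:
        if gene not in categories:
            return ["unassigned"]
        cat, role = categories[gene]
        out = [cat]
        if split_roles and role != "na":
            out.append(f"{cat} [{role}]")
        return out

    n_up: dict[str, int] = defaultdict(int)
    n_down: dict[str, int] = defaultdict(int)
    for gene in de_set.up:
        for k in key_of(gene):
            n_up[k] += 1
    for gene in de_set.down:
        for k in key_of(gene):
            n_down[k] += 1

    table_size: dict[str, int] = defaultdict(int)
    if table_genes is not None:
        for gene in table_genes:
            for k in key_of(gene):
                table_size[k] += 1

    summaries = []
    for cat in sorted(set(n_up) | set(n_down)):
        nu, nd = n_up[cat], n_down[cat]
        summaries.append(CategorySummary(
            category=cat, n_up=nu, n_down=nd,
            pct_down=_pct(nd, nu + nd),
            pct_down_of_table=(_pct(nd, table_size[cat])
                               if table_genes is not None else None),
        ))
    return summaries


def signature_concordance(records: Iterable[DERecord],
                          signature: Mapping[str, str],
                          config: AnalysisConfig) -> ConcordanceResult:
    """Fraction of filtered DE genes whose change direction matches an
    expected aging signature.

    Only genes that pass the DE filter and have an expected direction of
    "up"/"down" enter the denominator; "na" entries are ignored. A gene with
    log2fc exactly 0 is inconsistent with any expected direction.
    """
    n_eval = 0
    n_consistent = 0
    for r in records:
        expected = signature.get(r.gene_id)
        if expected not in ("up", "down"):
            continue
        if not _passes(r, config):
            continue
        n_eval += 1
        if _direction(r.log2fc) == expected:
            n_consistent += 1
    return ConcordanceResult(n_consistent=n_consistent, n_evaluated=n_eval)
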