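"""Exact matching of IUPAC-degenerate patterns against promoter sequences.

A pattern position matches a sequence base iff the base (a literal A/C/G/T)
is in the position's allowed set; ambiguity codes in the *sequence* (N and
friends) never match. No mismatches are tolerated. Overlapping occurrences
are all counted: the scanner is position-complete, like an all-offsets
search. Minus-strand hits are plus-strand hits of the reverse-complemented
pattern on the same sequence, reported at the leftmost base of the site.

The scanner compiles each pattern to a regular expression of character
classes wrapped in a zero-width lookahead, which enumerates every offset;
tests pin exact agreement with a naive per-offset oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .types import IUPAC_CODES, MotifDef, Promoter

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CompiledPattern:
    """An IUPAC consensus expanded to per-position allowed-base sets."""

    motif_id: str
    allowed: tuple[frozenset, ...]

    @property
    def length(self) -> int:
        return len(self.allowed)

    def reverse_complement(self) -> "CompiledPattern":
        rc = tuple(frozenset(_COMPLEMENT_BASE[b] for b in s)
                   for s in reversed(self.allowed))
        return CompiledPattern(motif_id=self.motif_id, allowed=rc)

    def is_palindromic(self) -> bool:
        return self.allowed == self.reverse_complement().allowed


@dataclass(frozen=True)
class ScanResult:
    plus_count: int
    minus_count: int
    #: (offset, strand) of every hit, offset = leftmost base on the scanned sequence
    positions: tuple[tuple[int, str], ...]

    @property
    def total(self) -> int:
        return self.plus_count + self.minus_count


@dataclass
class CountMatrix:
    """Per-promoter occurrence counts, genes x motifs, with per-strand split."""

    total: pd.DataFrame
    plus: pd.DataFrame
    minus: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.total.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.total.columns)


def compile_pattern(motif: MotifDef) -> CompiledPattern:
    allowed = tuple(frozenset(IUPAC_CODES[ch]) for ch in motif.pattern.upper())
    return CompiledPattern(motif_id=motif.motif_id, allowed=allowed)


def _regex(pattern: CompiledPattern) -> re.Pattern:
    body = "".join("[" + "".join(sorted(s)) + "]" for s in pattern.allowed)
    return re.compile(f"(?=(?:{body}))")


def _offsets(sequence: str, pattern: CompiledPattern) -> list[int]:
    if pattern.length == 0 or pattern.length > len(sequence):
        return []
    return [m.start() for m in _regex(pattern).finditer(sequence)]


def scan_sequence(sequence: str, pattern: CompiledPattern,
                  strands: str = "both") -> ScanResult:
    """Count occurrences of ``pattern`` in ``sequence`` on the requested strands."""
    if strands not in ("plus", "minus", "both"):
        raise ValueError(f"strands must be plus/minus/both, got {strands!r}")
    sequence = sequence.upper()
    positions: list[tuple[int, str]] = []
    plus_count = minus_count = 0
    if strands in ("plus", "both"):
        hits = _offsets(sequence, pattern)
        plus_count = len(hits)
        positions.extend((i, "+") for i in hits)
    if strands in ("minus", "both"):
        hits = _offsets(sequence, pattern.reverse_complement())
        minus_count = len(hits)
        positions.extend((i, "-") for i in hits)
    positions.sort()
    return ScanResult(plus_count=plus_count, minus_count=minus_count,
                      positions=tuple(positions))


def scan_promoters(promoters: Sequence[Promoter],
                   motifs: Iterable[MotifDef],
                   strands: str = "both") -> CountMatrix:
    """Build the genes x motifs occurrence-count matrix.

    Deterministic and independent of iteration order beyond the row/column
    order, which follows the input order. Duplicate promoter gene_ids are an
    error.
    """
    gene_ids = [p.gene_id for p in promoters]
    dupes = {g for g in gene_ids if gene_ids.count(g) > 1} if len(set(gene_ids)) != len(gene_ids) else set()
    if dupes:
        raise ValueError(f"duplicate promoter gene_id(s): {', '.join(sorted(dupes))}")
    motifs = list(motifs)
    compiled = [compile_pattern(m) for m in motifs]
    motif_ids = [m.motif_id for m in motifs]
    plus_rows, minus_rows = [], []
    for p in promoters:
        seq = p.sequence.upper()
        plus_rows.append([len(_offsets(seq, c)) if strands in ("plus", "both") else 0
                          for c in compiled])
        minus_rows.append([len(_offsets(seq, c.reverse_complement()))
                           if strands in ("minus", "both") else 0
                           for c in compiled])
    plus = pd.DataFrame(plus_rows, index=gene_ids, columns=motif_ids, dtype=int)
    minus = pd.DataFrame(minus_rows, index=gene_ids, columns=motif_ids, dtype=int)
    return CountMatrix(total=plus + minus, plus=plus, minus=minus)


def hit_table(promoters: Sequence[Promoter], motifs: Iterable[MotifDef],
              strands: str = "both") -> pd.DataFrame:
    """Hit-level output: one row per (gene, motif, offset, strand)."""
    rows = []
    for m in motifs:
        c = compile_pattern(m)
        for p in promoters:
            for offset, strand in scan_sequence(p.sequence, c, strands).positions:
                rows.append({"gene_id": p.gene_id, "motif_id": m.motif_id,
                             "offset": offset, "strand": strand})
    return pd.DataFrame(rows, columns=["gene_id", "motif_id", "offset", "strand"])
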