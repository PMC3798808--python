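"""Domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open. Promoter sequences are stored
5'->3' in gene orientation (minus-strand promoters are reverse-complemented on
extraction), so every downstream consumer can treat promoters uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

COMPARISONS = ("y-m", "y-o", "m-o")

#: IUPAC nucleotide ambiguity codes -> allowed bases.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Complement over the full IUPAC alphabet (R<->Y, K<->M, B<->V, D<->H; S,W,N fixed).
IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                                 "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(IUPAC_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class DERecord:
    """One gene's expression change in one tissue/comparison."""

    gene_id: str
    tissue: str
    comparison: str
    log2fc: float
    p_value: float
    adj_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise FormatError(
                f"p_value out of [0,1] for gene {self.gene_id!r}: {self.p_value}")
        if self.adj_p is not None and not 0.0 <= self.adj_p <= 1.0:
            raise FormatError(
                f"adj_p out of [0,1] for gene {self.gene_id!r}: {self.adj_p}")


@dataclass(frozen=True)
class GeneModel:
    """A gene's location: contig, strand and transcription start site (0-based)."""

    gene_id: str
    contig: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"strand must be '+' or '-' for gene {self.gene_id!r}, got {self.strand!r}")
        if self.tss < 0:
            raise FormatError(f"negative TSS for gene {self.gene_id!r}: {self.tss}")


@dataclass(frozen=True)
class MotifDef:
    """A transcription factor's binding-site consensus as an IUPAC pattern."""

    motif_id: str
    tf_gene_id: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise FormatError(f"empty pattern for motif {self.motif_id!r}")
        for ch in self.pattern:
            if ch.upper() not in IUPAC_CODES:
                raise FormatError(
                    f"invalid IUPAC symbol {ch!r} in motif {self.motif_id!r}")


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the pipeline.

    p_cutoff/lfc_cutoff gate differential expression (inclusive boundaries);
    promoter_window is the number of bases upstream of the TSS; sd_multiplier
    scales the mean +/- SD enrichment band (1.0 = one standard deviation).
    """

    p_cutoff: float = 0.05
    use_adjusted_p: bool = False
    lfc_cutoff: float = 0.4
    promoter_window: int = 1000
    strands: str = "both"
    sd_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff <= 1.0:
            raise ValueError(f"p_cutoff must be in (0,1], got {self.p_cutoff}")
        if self.lfc_cutoff < 0:
            raise ValueError(f"lfc_cutoff must be >= 0, got {self.lfc_cutoff}")
        if self.promoter_window < 1:
            raise ValueError(f"promoter_window must be >= 1, got {self.promoter_window}")
        if self.strands not in ("plus", "minus", "both"):
            raise ValueError(f"strands must be plus/minus/both, got {self.strands!r}")
        if self.sd_multiplier <= 0:
            raise ValueError(f"sd_multiplier must be > 0, got {self.sd_multiplier}")


@dataclass(frozen=True)
class Promoter:
    """A strand-aware upstream window; sequence is in gene orientation."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str

    @property
    def effective_length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"interval length {self.end - self.start} != sequence length "
                f"{len(self.sequence)} for promoter of {self.gene_id!r}")


@dataclass(frozen=True)
class DEGeneSet:
    tissue: str
    comparison: str
    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down gene sets overlap")

    @property
    def genes(self) -> frozenset:
        return self.up | self.down


@dataclass(frozen=True)
class OverlapPartition:
    a_only: frozenset
    b_only: frozenset
    common: frozenset


@dataclass(frozen=True)
class CategorySummary:
    category: str
    n_up: int
    n_down: int
    pct_down: Optional[float]
    #: percentage down over all category genes present on the analysed table
    #: (alternative denominator; None when no table gene list was supplied).
    pct_down_of_table: Optional[float] = None


@dataclass(frozen=True)
class ConcordanceResult:
    n_consistent: int
    n_evaluated: int

    @property
    def fraction(self) -> Optional[float]:
        if self.n_evaluated == 0:
            return None
        return self.n_consistent / self.n_evaluated


@dataclass(frozen=True)
class OccurrenceProfile:
    """Genome-background occurrence statistics of one motif.

    mean/sd are over per-promoter counts of all annotated genes; sd uses the
    sample (n-1) denominator. The enrichment band is mean +/- multiplier * sd.
    """

    motif_id: str
    n_promoters: int
    mean: float
    sd: float
    hi_threshold: float
    lo_threshold: float


@dataclass(frozen=True)
class CandidateCall:
    gene_id: str
    motif_id: str
    count: int
    call: str  # enriched | depleted | typical


@dataclass(frozen=True)
class TargetAssignment:
    tf_gene_id: str
    target_gene_id: str
    motif_id: str
    tissue: str
    comparison: str
    tf_direction: str
    target_direction: str
    concordant: bool
    candidate_call: str
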