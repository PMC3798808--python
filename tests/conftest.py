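import pytest

from senescan.types import AnalysisConfig, DERecord, MotifDef

BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# IUPAC table restated independently of the package for oracle use.
IUPAC_ORACLE = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def revcomp_oracle(seq: str) -> str:
    return "".join(BASE_COMPLEMENT[b] for b in reversed(seq))


def naive_scan(seq: str, pattern: str):
    """All-offsets oracle: plus hits of the pattern and of its reverse
    complement (= minus-strand hits), on an upper-cased sequence."""
    seq = seq.upper()
    sets = [IUPAC_ORACLE[c] for c in pattern.upper()]
    rc_sets = [{BASE_COMPLEMENT[b] for b in s} for s in reversed(sets)]

    def offsets(position_sets):
        k = len(position_sets)
        return [i for i in range(len(seq) - k + 1)
                if all(seq[i + j] in position_sets[j] for j in range(k))]

    return offsets(sets), offsets(rc_sets)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def ap1_motif():
    return MotifDef(motif_id="AP1", tf_gene_id="Jun", pattern="TGASTCA")


def de(gene, tissue="thymus", comparison="y-o", lfc=1.0, p=0.01, adj=None):
    return DERecord(gene_id=gene, tissue=tissue, comparison=comparison,
                    log2fc=lfc, p_value=p, adj_p=adj)
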