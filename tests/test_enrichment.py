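import math

import numpy as np
import pandas as pd
import pytest

from senescan.enrichment import (background_profile, background_profiles,
                                 call_candidates, tf_target_concordance)
from senescan.motif_scan import CountMatrix, scan_promoters
from senescan.types import AnalysisConfig, MotifDef, Promoter

from conftest import de, revcomp_oracle


def matrix_from(counts: dict) -> CountMatrix:
    total = pd.DataFrame(counts)
    zero = total * 0
    return CountMatrix(total=total, plus=total, minus=zero)


class TestBackgroundProfile:
    def test_hand_computed_mean_sd(self):
        m = matrix_from({"m1": pd.Series([0, 1, 2, 3, 4],
                                         index=list("abcde"))})
        p = background_profile(m, "m1")
        assert p.mean == 2
        assert p.sd == pytest.approx(math.sqrt(2.5))
        assert p.hi_threshold == pytest.approx(2 + math.sqrt(2.5))
        assert p.lo_threshold == pytest.approx(2 - math.sqrt(2.5))
        assert p.n_promoters == 5

    def test_zero_variance(self):
        m = matrix_from({"m1": pd.Series([3, 3, 3], index=list("abc"))})
        p = background_profile(m, "m1")
        assert (p.mean, p.sd, p.hi_threshold, p.lo_threshold) == (3, 0, 3, 3)

    def test_too_few_promoters(self):
        m = matrix_from({"m1": pd.Series([3], index=["a"])})
        with pytest.raises(ValueError, match=">= 2"):
            background_profile(m, "m1")

    def test_poisson_mean_recovered(self):
        rng = np.random.default_rng(7)
        lam, n = 4.0, 3000
        counts = pd.Series(rng.poisson(lam, n),
                           index=[f"g{i}" for i in range(n)])
        p = background_profile(matrix_from({"m1": counts}), "m1")
        assert abs(p.mean - lam) < 3 * math.sqrt(lam / n)
        assert abs(p.sd - math.sqrt(lam)) < 0.15

    def test_sd_multiplier_scales_band(self):
        m = matrix_from({"m1": pd.Series([0, 1, 2, 3, 4], index=list("abcde"))})
        p2 = background_profile(m, "m1", sd_multiplier=2.0)
        assert p2.hi_threshold == pytest.approx(2 + 2 * math.sqrt(2.5))


class TestCallCandidates:
    @pytest.fixture
    def profile_setup(self):
        bg = pd.Series([0, 1, 2, 3, 4], index=[f"b{i}" for i in range(5)])
        m = matrix_from({"m1": bg})
        return background_profiles(m, 1.0)

    @pytest.mark.parametrize("count, expected", [
        (4, "enriched"),   # 4 > 3.581
        (0, "depleted"),   # 0 < 0.419
        (2, "typical"),    # equals the mean
        (3, "typical"),    # inside the band
    ])
    def test_classification(self, profile_setup, count, expected):
        m = matrix_from({"m1": pd.Series([count], index=["g"])})
        calls, skipped = call_candidates(m, profile_setup, de_genes=["g"])
        assert calls[0].call == expected and not skipped

    def test_count_equal_to_threshold_is_typical(self):
        # integer band edges: mean 2, sd 1 -> hi=3, lo=1; strict inequalities
        m = matrix_from({"m1": pd.Series([1, 2, 3], index=list("abc"))})
        profiles = background_profiles(m, 1.0)
        assert profiles["m1"].hi_threshold == 3
        calls, _ = call_candidates(m, profiles)
        assert [c.call for c in calls] == ["typical"] * 3

    def test_missing_de_gene_skipped_not_fatal(self, profile_setup):
        m = matrix_from({"m1": pd.Series([4], index=["g"])})
        calls, skipped = call_candidates(m, profile_setup,
                                         de_genes=["g", "absent"])
        assert skipped == ["absent"]
        assert len(calls) == 1

    def test_raising_sd_multiplier_never_adds_calls(self):
        rng = np.random.default_rng(3)
        counts = pd.Series(rng.poisson(2.0, 400),
                           index=[f"g{i}" for i in range(400)])
        m = matrix_from({"m1": counts})
        previous = None
        for mult in (0.5, 1.0, 1.5, 2.0, 3.0):
            profiles = background_profiles(m, mult)
            calls, _ = call_candidates(m, profiles)
            n_nontypical = sum(c.call != "typical" for c in calls)
            if previous is not None:
                assert n_nontypical <= previous
            previous = n_nontypical

    def test_strand_mode_stability(self):
        """Plus-only calls on forward promoters equal minus-only calls after
        reverse-complementing every promoter."""
        rng = np.random.default_rng(11)
        motif = MotifDef("m", "tf", "TGASTCA")
        seqs = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(40)]
        fwd = [Promoter(f"g{i}", "c", 0, 300, "+", s)
               for i, s in enumerate(seqs)]
        rev = [Promoter(f"g{i}", "c", 0, 300, "+", revcomp_oracle(s))
               for i, s in enumerate(seqs)]
        m_plus = scan_promoters(fwd, [motif], "plus")
        m_minus = scan_promoters(rev, [motif], "minus")
        assert (m_plus.total == m_minus.total).all().all()
        calls_a, _ = call_candidates(m_plus, background_profiles(m_plus))
        calls_b, _ = call_candidates(m_minus, background_profiles(m_minus))
        assert calls_a == calls_b


class TestTFTargetConcordance:
    @pytest.fixture
    def motif(self):
        return MotifDef(motif_id="m1", tf_gene_id="tf1", pattern="ACGT")

    def make_calls(self, genes, call="enriched"):
        from senescan.types import CandidateCall
        return [CandidateCall(gene_id=g, motif_id="m1", count=5, call=call)
                for g in genes]

    def test_concordant_pair_retained(self, motif, config):
        records = [de("tf1", lfc=-1.0), de("t1", lfc=-0.8)]
        out = tf_target_concordance(self.make_calls(["t1"]), records, [motif],
                                    config)
        (a,) = out
        assert a.concordant and a.tf_direction == a.target_direction == "down"
        assert a.candidate_call == "enriched"

    def test_discordant_excluded_by_default(self, motif, config):
        records = [de("tf1", lfc=-1.0), de("t1", lfc=0.8)]
        assert tf_target_concordance(self.make_calls(["t1"]), records,
                                     [motif], config) == []
        out = tf_target_concordance(self.make_calls(["t1"]), records, [motif],
                                    config, keep_all=True)
        assert len(out) == 1 and not out[0].concordant

    def test_depleted_excluded_unless_flagged(self, motif, config):
        records = [de("tf1", lfc=-1.0), de("t1", lfc=-0.8)]
        calls = self.make_calls(["t1"], call="depleted")
        assert tf_target_concordance(calls, records, [motif], config) == []
        out = tf_target_concordance(calls, records, [motif], config,
                                    include_depleted=True)
        assert out[0].candidate_call == "depleted"

    def test_same_tissue_comparison_only(self, motif, config):
        # TF moves in opposite directions per tissue; pairing never crosses
        records = [de("tf1", tissue="thymus", lfc=-1.0),
                   de("tf1", tissue="spleen", lfc=1.0),
                   de("t1", tissue="spleen", lfc=-0.8)]
        out = tf_target_concordance(self.make_calls(["t1"]), records, [motif],
                                    config, keep_all=True)
        assert [a.tissue for a in out] == ["spleen"]
        assert not out[0].concordant  # spleen TF is up, target down

    def test_motif_without_tf_in_table_skipped(self, motif, config):
        records = [de("t1", lfc=-0.8)]
        assert tf_target_concordance(self.make_calls(["t1"]), records,
                                     [motif], config) == []

    def test_planted_targets_exactly_recovered(self, motif, config):
        """100 down-regulated enriched targets of a down-regulated TF are all
        retained; 100 up-regulated (discordant) decoys are all dropped."""
        targets = [f"t{i}" for i in range(100)]
        decoys = [f"d{i}" for i in range(100)]
        records = ([de("tf1", lfc=-1.0)] +
                   [de(g, lfc=-0.8) for g in targets] +
                   [de(g, lfc=0.8) for g in decoys])
        calls = self.make_calls(targets + decoys)
        out = tf_target_concordance(calls, records, [motif], config)
        assert sorted(a.target_gene_id for a in out) == sorted(targets)
        assert all(a.concordant for a in out)
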