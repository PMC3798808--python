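"""Calibration experiments that validate the pipeline against closed-form
oracles on synthetic data.

* :func:`planted_target_recovery` — the enrichment caller's operating
  characteristics. Promoters carry Poisson(lambda_bg) background implants and
  a designated subset Poisson(lambda_target); the mean +/- SD band is computed
  from the realized full-genome counts and compared against exact Poisson tail
  probabilities evaluated at the realized thresholds: sensitivity =
  P(Poisson(lambda_target) > hi) and background false-call rate =
  P(Poisson(lambda_bg) > hi) + P(Poisson(lambda_bg) < lo). Counts are
  integers, so the strict-inequality tails are evaluated at floor(hi) and
  ceil(lo) - 1.

* :func:`de_filter_calibration` — the DE simulator + filter. Null genes'
  p <= alpha rate should match alpha; planted genes' detection rate should
  match the two-sided noncentral-t power of the two-sample test (the extra
  |log2FC| requirement is negligible at the default effect size, see
  docs/methods.md).

Both return measured and oracle values side by side; tests and the
acceptance script assert on the gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .enrichment import background_profile, call_candidates
from .motif_scan import scan_promoters
from .promoters import extract_promoters
from .synthetic import (SynthExprConfig, SynthGenomeConfig, generate_de_table,
                        generate_genome)
from .types import AnalysisConfig, MotifDef
from .de_analysis import filter_de

RECOVERY_MOTIF = MotifDef(motif_id="M1", tf_gene_id="tf", pattern="TGACTCAG")


@dataclass
class RecoveryResult:
    sensitivity: float
    sensitivity_oracle: float
    false_call_rate: float
    false_call_rate_oracle: float
    n_replicates: int
    n_promoters: int


def _poisson_tail_above(lam: float, hi: float) -> float:
    """P(X > hi) for integer X ~ Poisson(lam), strict inequality."""
    return float(stats.poisson.sf(math.floor(hi), lam))


def _poisson_tail_below(lam: float, lo: float) -> float:
    """P(X < lo) for integer X ~ Poisson(lam), strict inequality."""
    k = math.ceil(lo) - 1
    return float(stats.poisson.cdf(k, lam)) if k >= 0 else 0.0


def planted_target_recovery(seed: int = 0, n_replicates: int = 20,
                            n_promoters: int = 2000, n_targets: int = 100,
                            lambda_bg: float = 1.0, lambda_target: float = 5.0,
                            sd_multiplier: float = 1.0,
                            promoter_window: int = 1000) -> RecoveryResult:
    """Replicate-averaged enriched-call sensitivity and background false-call
    rate versus the Poisson tail oracle at the realized thresholds."""
    rng = np.random.default_rng(seed)
    targets = frozenset(f"g{i + 1:05d}" for i in range(n_targets))
    sens, sens_o, fcr, fcr_o = [], [], [], []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SynthGenomeConfig(n_genes=n_promoters, contigs=4,
                                promoter_window=promoter_window,
                                lambda_bg=lambda_bg, lambda_target=lambda_target,
                                target_gene_ids=targets, motif=RECOVERY_MOTIF,
                                seed=rep_seed)
        synth = generate_genome(cfg)
        promoters = extract_promoters(synth.genome, synth.genes, promoter_window)
        matrix = scan_promoters(promoters, [RECOVERY_MOTIF], "both")
        profile = background_profile(matrix, RECOVERY_MOTIF.motif_id, sd_multiplier)
        calls, _ = call_candidates(matrix, {RECOVERY_MOTIF.motif_id: profile})
        by_gene = {c.gene_id: c.call for c in calls}
        n_enriched_targets = sum(1 for g in targets if by_gene[g] == "enriched")
        background = [g for g in by_gene if g not in targets]
        n_false = sum(1 for g in background if by_gene[g] != "typical")
        sens.append(n_enriched_targets / len(targets))
        fcr.append(n_false / len(background))
        sens_o.append(_poisson_tail_above(lambda_target, profile.hi_threshold))
        fcr_o.append(_poisson_tail_above(lambda_bg, profile.hi_threshold)
                     + _poisson_tail_below(lambda_bg, profile.lo_threshold))
    return RecoveryResult(
        sensitivity=float(np.mean(sens)),
        sensitivity_oracle=float(np.mean(sens_o)),
        false_call_rate=float(np.mean(fcr)),
        false_call_rate_oracle=float(np.mean(fcr_o)),
        n_replicates=n_replicates, n_promoters=n_promoters)


@dataclass
class CalibrationResult:
    null_pass_rate: float
    nominal_alpha: float
    null_se: float
    detection_rate: float
    power_oracle: float
    n_null: int
    n_planted: int


def t_test_power(effect: float, noise_sd: float, n_per_group: int,
                 alpha: float = 0.05) -> float:
    """Two-sided power of the equal-variance two-sample t-test."""
    df = 2 * n_per_group - 2
    ncp = effect / (noise_sd * math.sqrt(2.0 / n_per_group))
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp))


def de_filter_calibration(seed: int = 0, n_null: int = 1000, n_planted: int = 500,
                          effect: float = 1.0, noise_sd: float = 0.3,
                          n_per_group: int = 3) -> CalibrationResult:
    """Type-I rate of null genes and detection rate of planted genes under the
    default filter, with the noncentral-t power oracle."""
    config = AnalysisConfig()
    null_genes = [f"n{i:05d}" for i in range(n_null)]
    planted_genes = [f"u{i:05d}" for i in range(n_planted)]
    planted = {g: {("thymus", "y-o"): "up"} for g in planted_genes}
    ecfg = SynthExprConfig(genes=null_genes + planted_genes,
                           tissues=("thymus",), comparisons=("y-o",),
                           planted=planted, effect_size=effect,
                           n_per_group=n_per_group, noise_sd=noise_sd, seed=seed)
    records = generate_de_table(ecfg)
    null_pass = sum(1 for r in records
                    if r.gene_id.startswith("n") and r.p_value <= config.p_cutoff)
    de_sets = filter_de(records, config)
    detected = de_sets[("thymus", "y-o")].up & frozenset(planted_genes)
    alpha = config.p_cutoff
    return CalibrationResult(
        null_pass_rate=null_pass / n_null,
        nominal_alpha=alpha,
        null_se=math.sqrt(alpha * (1 - alpha) / n_null),
        detection_rate=len(detected) / n_planted,
        power_oracle=t_test_power(effect, noise_sd, n_per_group, alpha),
        n_null=n_null, n_planted=n_planted)
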