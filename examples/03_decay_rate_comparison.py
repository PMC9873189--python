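"""Compare decay rates between iron recovery and transcription arrest.

Iron-recovery decline mixes transcriptional shut-off with degradation;
actinomycin D enforces pure degradation.  A likelihood-ratio test on a
joint broken-line model (changepoints fixed per treatment, pre-changepoint
slopes tied under the null) asks whether the two declines share one rate.
A significant difference suggests regulation of mRNA stability, not just
of transcription.
"""

from ferrodecay import (
    HK_PROBE,
    DesignSpec,
    NormalizationConfig,
    compare_decay_rates,
    default_panel,
    estimate_attenuation_factor,
    log_transform,
    normalize_pipeline,
    simulate_experiment,
)

matrix, titration, truth = simulate_experiment(DesignSpec(seed=42), default_panel())
config = NormalizationConfig(
    hk_probe=HK_PROBE, attenuation_factors=estimate_attenuation_factor(titration)
)
normalized, _ = normalize_pipeline(matrix, config)
logc = log_transform(normalized)

print(f"{'gene':8s} {'k_rec':>9s} {'k_actd':>9s} {'LRT':>8s} {'p':>10s}")
for gene in ("FLDA1", "ISIP1", "FBA4", "FBA3", "ISIP3"):
    res, free, _ = compare_decay_rates(logc, normalized, gene, "rec", "actd")
    print(f"{gene:8s} {-free.beta1['rec']:9.4f} {-free.beta1['actd']:9.4f} "
          f"{res.statistic:8.2f} {res.p_value:10.3g}")
print("\nFLDA1/ISIP1/FBA4 were simulated with slower recovery decay "
      "(t1/2 16 min) than arrest decay (8 min): expect very small p-values.")
print("FBA3/ISIP3 share one true rate in both arms; note the test can "
      "still reject at moderate levels because each arm's changepoint is "
      "estimated first and then treated as known (see docs/methods.md).")

# the no-difference control: actD with vs without iron
res, free, _ = compare_decay_rates(logc, normalized, "FLDA1", "actd", "actd_fe")
print(f"\nFLDA1 actd vs actd_fe (same true rate): p = {res.p_value:.3f}")
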