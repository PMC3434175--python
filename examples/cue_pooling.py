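"""Diagnose the cue-integration regime from detection thresholds.

A single subject's thresholds are reduced to normalised threshold units
(u, v) = (T_am/T_a, T_am/T_m) and the Minkowski pooling exponent k solving
u^k + v^k = 1 is found.  k ~ 1 indicates early linear summation, k ~ 2
optimal reliability-weighted integration, k ~ 4 probability summation, and
very large k independent channels.  A cohort-level fit then recovers the
regime from a simulated group end to end.
"""

from cuefidelity import (
    PipelineConfig,
    ThresholdTriple,
    k_from_triple,
    normalize_thresholds,
    predict_combined_threshold,
    run_experiment1_replica,
)

# one subject with audio/motion/bimodal thresholds in collective inches
triple = ThresholdTriple("subject-4", T_a=0.27, T_m=0.21, T_am=0.16)
u, v = normalize_thresholds(triple)
k = k_from_triple(triple)
print(f"normalised thresholds: u = {u:.4f}, v = {v:.4f}")
print(f"pooling exponent k = {k:.2f}  (near 2: optimal integration)")
print(f"threshold predicted at k = 2: "
      f"{predict_combined_threshold([triple.T_a, triple.T_m], 2.0):.3f} in "
      f"(observed {triple.T_am} in)\n")

# group-level recovery from ten simulated optimal observers
report = run_experiment1_replica(PipelineConfig(seed=1))
print(report.summary())
print(
    "\nThe cohort was generated by inverse-variance (optimal) observers, and\n"
    "the group fit recovers a pooling exponent close to the Euclidean k = 2."
)
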