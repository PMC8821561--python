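"""Simulate a four-caller cohort and compare combination strategies.

Generates a labeled truth set and per-caller observed call sets, runs
the union and intersection-union strategies, and measures how each
trades sensitivity against positive predictive value.
"""

from cnvensemble import (
    SimulationConfig,
    default_caller_models,
    detection_rate,
    expected_strategy_stats,
    match_sets,
    run_strategy,
    simulate_cohort,
)

cfg = SimulationConfig(
    n_truth=500,
    callers=default_caller_models(sensitivity=0.9, fp_rate_per_mb=2.0),
    seed=42,
)
cohort = simulate_cohort(cfg)
print(f"truth CNVs: {len(cohort.truth)}")
for caller, cs in cohort.callsets.items():
    print(f"  {caller:9s} observed {len(cs):6d} calls")

union = run_strategy("union", cohort.callsets).calls
iu = run_strategy("intersection_union", cohort.callsets).calls
det = detection_rate(cohort.truth, [union, iu], ro_min=0.5)


def ppv(calls):
    return len(match_sets(calls, cohort.truth, 0.5).pairs) / len(calls)


print(f"\nunion:              {len(union):6d} calls, "
      f"sensitivity {det.per_set_fraction['union']:.3f}, ppv {ppv(union):.3f}")
print(f"intersection-union: {len(iu):6d} calls, "
      f"sensitivity {det.per_set_fraction['intersection_union']:.3f}, "
      f"ppv {ppv(iu):.3f}")
expected = expected_strategy_stats(cfg, "intersection_union").sensitivity
print(f"analytic intersection-union sensitivity (independence): {expected:.4f}")
print("\nThe union finds everything but drowns in false positives; the")
print("intersection-union gives up a few percent of sensitivity for a")
print("call set an order of magnitude cleaner.")
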