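"""Recovering a toxicity threshold from a dosing/outcome cohort.

Generates a synthetic cohort whose life-threatening labels track a true
steady-state-concentration threshold of 6 mg/L, simulates each patient's
regimen through the PBPK model, and fits a depth-1 classification tree
asking which exposure metric (Css or AUC) separates the outcomes and
where.  The stump should pick the concentration, near 6 mg/L.
"""

import fluoropk as fp

spec = fp.MaCohortSpec(n_life_threatening=30, n_other=20, seed=42)
records = fp.make_ma_like_cohort(spec)
print(f"generated {len(records)} synthetic patients "
      f"(true threshold {spec.true_css_threshold_mg_per_L} mg/L, "
      f"{spec.label_noise:.0%} label noise)")

result = fp.simulate_cohort(records)
stump = fp.fit_stump(result.rows)

print(f"selected feature : {stump.feature}  (css = steady-state concentration)")
print(f"threshold        : {stump.threshold:.2f} mg/L")
print(f"P(life-threatening) below / above: "
      f"{stump.prob_below:.2f} / {stump.prob_above:.2f}")

prediction = fp.predict_stump(stump, css=7.0, auc=40.0)
print(f"patient with Css 7.0 mg/L -> P(life-threatening) = "
      f"{prediction.probability:.2f}")
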