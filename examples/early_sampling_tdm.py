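"""Early-sampling therapeutic drug monitoring.

During a standard 24-h infusion, about half of the eventual steady-state
concentration is already reached one hour after the start.  A single
early sample ("dynamic concentration", C_dyn) therefore forecasts the
plateau as C_ss ~= C_dyn / 0.5 — early enough to cut the infusion rate
before toxic levels are reached.
"""

import fluoropk as fp

physiology = fp.default_physiology(body_weight_kg=49.0)
profile = fp.simulate_to_washout(
    fp.DosingRegimen.infusion(4612.0, 24.0), physiology
)

frac = fp.fraction_of_steady_state(profile, t=1.0)
cdyn = profile.venous_at(1.0)
plateau = fp.css_observed(profile).value

print(f"fraction of steady state at 1 h : {frac:.2f}  (about one half)")
print(f"concentration at 1 h (C_dyn)    : {cdyn:.2f} mg/L")
print(f"simulated plateau (C_ss)        : {plateau:.2f} mg/L")
print(f"forecast C_dyn/0.5              : {fp.predict_css_from_cdyn(cdyn):.2f} mg/L")

# clinical screening rules built on the halving
for cdyn_threshold in (1.5, 3.0):
    css = fp.predict_css_from_cdyn(cdyn_threshold)
    print(f"C_dyn above {cdyn_threshold} mg/L at 1 h forecasts "
          f"C_ss above {css:.0f} mg/L")
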