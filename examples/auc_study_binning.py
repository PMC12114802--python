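"""Concentration binning of a 24-h-infusion AUC study.

Generates a synthetic dataset of 321 whole-course AUCs (94 patients with
non-life-threatening toxicity, 227 without), converts each AUC to a
steady-state concentration via Css = AUC / infusion time, and tabulates
the fraction of toxic outcomes per 1-mg/L concentration bin.  The toxic
fraction should be low below 3 mg/L and rise steeply between 3 and
4 mg/L.
"""

import fluoropk as fp
from fluoropk.cohort import ExposureToxicityRow, Toxicity

df = fp.make_auc_study_like(fp.AucStudySpec(seed=7))
print(df.groupby("toxicity")["auc_mg_h_per_L"]
        .agg(["count", "mean", "median"]).round(1))

rows = [
    ExposureToxicityRow(
        id=str(i),
        css_mg_per_L=fp.css_from_auc(rec.auc_mg_h_per_L, rec.infusion_time_h),
        auc_mg_h_per_L=rec.auc_mg_h_per_L,
        toxicity=Toxicity.parse(rec.toxicity),
    )
    for i, rec in enumerate(df.itertuples())
]

table = fp.binned_fraction(rows, bin_width_mg_per_L=1.0)
print("\ntoxic fraction per Css bin:")
print(table.to_frame().round(2).to_string(index=False))
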