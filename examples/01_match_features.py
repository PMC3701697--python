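"""Match m/z features to metabolites through adduct/isotopologue forms.

Builds a tiny synthetic experiment, then shows the many-to-many tentative
match map for the reference feature list.
"""

from mzactivity import generate_toy_model, match_features, simulate_feature_table

model, skeleton = generate_toy_model(seed=7)
L_ref, L_sig, truth = simulate_feature_table(model, skeleton, seed=7)

mm = match_features(L_ref, model, mode="positive", ppm_tol=10.0)
print(f"{len(L_ref)} reference features; {len(mm.features)} matched "
      f"to {len(mm.metabolites)} tentative metabolites ({len(mm)} records)")
print(mm.to_dataframe().head(8).to_string(index=False))
# Most features match nothing (decoys), as in real data; each matched
# metabolite may be supported by several derivative forms, and one feature
# can support several metabolites — that ambiguity is resolved downstream.
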