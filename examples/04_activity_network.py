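"""Assemble and export the confidence-rated activity network.

Metabolites from significant modules/pathways are kept only when their
derivative-form evidence in L_ref qualifies them (primary ion and/or
multiple forms), then wired with their reference-network edges.
"""

from pathlib import Path

from mzactivity import export_network, generate_toy_model, simulate_feature_table
from mzactivity.pipeline import analyze

model, skeleton = generate_toy_model(seed=7)
L_ref, L_sig, truth = simulate_feature_table(model, skeleton, seed=7)

res = analyze(model, L_ref, L_sig, n_perm=100, seed=7)
net = res.activity_network
print(f"activity network: {len(net.metabolites)} metabolites, "
      f"{net.graph.number_of_edges()} edges, {len(net.isolates)} isolates")
for mid in sorted(net.metabolites):
    r = net.ratings[mid]
    print(f"  {mid}: rating={r.rating} forms={sorted(r.forms_present)}")
out = Path("scratch_example_net")
print("wrote:", export_network(net, "sif", out.with_suffix(".sif")))
# Ratings: high = primary ion + C13 partner; medium = primary alone or >=2
# other forms.  Edges are inherited from the reference metabolic network.
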