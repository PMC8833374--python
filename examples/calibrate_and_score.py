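"""Calibrate a frozen pathway model on a labelled cohort and score samples.

Builds a synthetic NFkB training cohort (20 active / 20 inactive samples,
2-log2-unit effect), calibrates a Bayesian target-gene model, freezes it,
and scores new samples with planted high and low activity.
"""

import stpscore as st

gs = st.default_gene_sets(n_genes=20, n_down=4, pathways=["NFkB"])[0]
train, labels = st.calibration_cohort(gs, n_per_class=20, seed=7)
model = st.calibrate_model(train, labels, gs, prior_active=0.5, pseudocount=1.0)
print(f"calibrated {model.pathway_name}: {len(model.gene_params)} genes, "
      f"frozen={model.frozen}")

specs = [
    st.ScenarioSpec("active_like", {"NFkB": 1.0}, 3),
    st.ScenarioSpec("resting_like", {"NFkB": 0.0}, 3),
]
cohort, _ = st.simulate_cohort(specs, [gs], seed=8)
for sid in cohort.sample_ids:
    s = st.score_sample(model, cohort.sample_values(sid), sid)
    print(f"{sid}: log2 odds = {s.log2_odds:+.2f}  P(active) = {s.prob_active:.3f}")

# Positive log2 odds = evidence for an active pathway relative to the prior;
# the planted active samples should score far above the resting ones.

foxo_activated, foxo_naive = -3.8, 10.3
call = st.infer_pi3k_from_foxo(foxo_activated, reference=foxo_naive)
print(f"FOXO {foxo_activated} vs naive reference {foxo_naive} -> PI3K is {call}")
# Low FOXO activity relative to the reference implies a *high* PI3K pathway
# activity (valid only without cellular oxidative stress).
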