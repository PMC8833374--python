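"""Screen a cohort with the 12-parameter microarray QC panel.

Simulates a QC metrics table with three gross planted failures, evaluates
every sample against the default Affymetrix-guidance rules, and filters a
matching expression cohort.
"""

import stpscore as st

table, planted = st.simulate_qc_table(n_samples=12, n_planted_failures=3, seed=5)
rules = st.default_rules()
reports = [st.evaluate_qc(m, rules) for m in table]
for r in reports:
    status = "PASS" if r.overall_pass else "FAIL: " + "; ".join(r.failure_reasons)
    print(f"{r.sample_id}: {status}")
print(f"planted failures: {planted}")
# Every planted failure (and nothing else) should fail: failures are planted
# far outside the bounds, so sensitivity and specificity are both 100%.

specs = [st.ScenarioSpec("grp", {"NFkB": 0.5}, 12)]
cohort, _ = st.simulate_cohort(specs, st.default_gene_sets(10, 2), seed=5)
# reuse the QC verdicts for the cohort's samples (same order)
reports = [
    st.QCReport(sid, r.verdicts, r.overall_pass, r.failure_reasons)
    for sid, r in zip(cohort.sample_ids, reports)
]
filtered = st.filter_cohort(cohort, reports)
print(f"cohort: {cohort.n_samples} samples -> {filtered.n_samples} after QC")

# the 3'/5' housekeeping ratio and RNA degradation slope can be computed
# from probe-summary inputs:
print("GAPDH 3'/5' ratio:", st.three_prime_ratio(300.0, 120.0))
print("degradation slope:", st.rna_degradation_slope([2, 3, 5, 4, 6]))
# Ratios > 3 or steep positive slopes indicate degraded RNA.
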