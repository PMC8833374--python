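import numpy as np
import pandas as pd
import pytest

import stpscore as st


@pytest.fixture(scope="session")
def gene_sets():
    return st.default_gene_sets(n_genes=15, n_down=3)


@pytest.fixture(scope="session")
def frozen_models(gene_sets):
    return st.calibrate_frozen_models(gene_sets, seed=11)


@pytest.fixture(scope="session")
def preset_cohort(gene_sets):
    specs = st.scenario_presets(n_replicates=6, n_patients=10, n_healthy=4)
    return st.simulate_cohort(specs, gene_sets, n_background_genes=30, seed=7)


@pytest.fixture(scope="session")
def preset_scores(frozen_models, preset_cohort):
    """Samples x pathways log2-odds table plus the scenario labels."""
    cohort, truth = preset_cohort
    profiles = st.score_cohort(frozen_models, cohort)
    table = pd.DataFrame({p.sample_id: p.log2_odds() for p in profiles}).T
    return table, truth.labels


def make_two_class_matrix(active_vals, inactive_vals, gene="g1"):
    """Tiny one-gene training matrix: samples a1.. active, i1.. inactive."""
    cols = {f"a{i+1}": [v] for i, v in enumerate(active_vals)}
    cols.update({f"i{i+1}": [v] for i, v in enumerate(inactive_vals)})
    values = pd.DataFrame(cols, index=[gene])
    labels = {c: ("active" if c.startswith("a") else "inactive") for c in cols}
    return st.ExpressionMatrix(values=values), labels
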