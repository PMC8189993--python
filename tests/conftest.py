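import pandas as pd
import pytest

import chelamorph as cm


@pytest.fixture(scope="session")
def reference():
    return cm.load_reference_summaries()


@pytest.fixture(scope="session")
def metadata():
    return cm.load_species_metadata()


@pytest.fixture(scope="session")
def species(reference):
    from chelamorph.reference import species_rows
    return species_rows(reference)


@pytest.fixture(scope="session")
def typical(reference):
    from chelamorph.reference import typical_row
    return typical_row(reference)


@pytest.fixture(scope="session")
def cohort(reference):
    """One default simulated cohort (47 species x 20 individuals, seed 1)."""
    return cm.simulate_cohort(cm.CohortSpec(summaries=reference, seed=1))


@pytest.fixture(scope="session")
def ordination_model(reference, cohort):
    """Default full ordination (lbf + 48 indicators) for the seed-1 cohort."""
    typ_ind, trow = cm.build_typical_reference(cohort)
    full = pd.concat([cohort, typ_ind], ignore_index=True)
    summaries = pd.concat([cm.summarize_cohort(cohort), trow.to_frame().T],
                          ignore_index=True)
    matrix = cm.build_divergence_matrix(full, summaries)
    return cm.decompose(matrix)
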