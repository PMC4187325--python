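import numpy as np
import pandas as pd
import pytest

from laterec import CohortSpec, ExpressionMatrix, generate_cohort


def make_matrix(values, control=None, study=None, tissue=None):
    """Build an ExpressionMatrix from a plain array with auto annotations."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = [f"P{i + 1:03d}" for i in range(n_probes)]
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    control = np.zeros(n_probes, dtype=bool) if control is None else np.asarray(control)
    probe_ann = pd.DataFrame(
        {"gene_symbol": probe_ids, "is_control": control},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    study = ["ST1"] * n_samples if study is None else list(study)
    tissue = ["bulk"] * n_samples if tissue is None else list(tissue)
    sample_ann = pd.DataFrame(
        {"study_id": study, "tissue": tissue},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=probe_ann.index, columns=sample_ann.index),
        probe_ann,
        sample_ann,
    )


@pytest.fixture(scope="session")
def cohort_seed11():
    """Low-noise cohort for batch-structure recovery checks."""
    return generate_cohort(
        CohortSpec(seed=11, noise_sd=0.1, stroma_pairs=0, n_stromal_genes=0)
    )


@pytest.fixture(scope="session")
def cohort_seed5():
    """Default-effect cohort (n=800 bulk) for screen recovery checks."""
    return generate_cohort(CohortSpec(seed=5, n_probes=500))


@pytest.fixture(scope="session")
def cohort_seed45():
    """Full default cohort, the end-to-end recovery condition."""
    return generate_cohort(CohortSpec(seed=45))
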