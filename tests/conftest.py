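import numpy as np
import pandas as pd
import pytest

from metaprog.dataio import LongitudinalDataset
from metaprog.synthetic_data import GeneratorSpec, default_truth, simulate_cohort


@pytest.fixture
def toy_dataset() -> LongitudinalDataset:
    """2 individuals x 2 visits x 2 lipids = 8 records."""
    rows = []
    for ind, offset in (("m1", 0.0), ("m2", 10.0)):
        for age in (3.0, 5.0):
            for j, lip in enumerate(["lipA", "lipB"]):
                rows.append((ind, age, lip, offset + age + j))
    records = pd.DataFrame(
        rows, columns=["individual", "age", "metabolite", "concentration"]
    )
    meta = pd.DataFrame(
        {
            "individual": ["m1", "m2"],
            "group": ["progressor", "non-progressor"],
            "sex": ["F", "F"],
            "iaa_status": ["negative", "positive"],
            "followup_end": [5.0, 5.0],
        }
    )
    return LongitudinalDataset(records, meta, ["lipA", "lipB"])


def separated_truth(n_metabolites: int, noise_sd: float = 1.0 / 3.0):
    """Truth HMMs whose adjacent states sit 3 noise SDs apart."""
    return {
        g: default_truth(
            n_metabolites, 3, g, noise_sd=noise_sd, state_step=3.0 * noise_sd
        )
        for g in ("progressor", "non-progressor")
    }


@pytest.fixture(scope="session")
def planted_cohort():
    """30 individuals x 30 visits x 10 metabolites, 3-SD state separation."""
    noise = 1.0 / 3.0
    spec = GeneratorSpec(
        n_progressors=15,
        n_nonprogressors=15,
        ages=np.arange(3.0, 33.0),
        n_metabolites=10,
        hmm_truth=separated_truth(10, noise),
        dropout_hazard=0.0,
        noise_sd=noise,
        seed=11,
    )
    dataset, paths = simulate_cohort(spec)
    return spec, dataset, paths


@pytest.fixture(scope="session")
def planted_fits(planted_cohort):
    """Per-group Baum-Welch fits on the planted cohort, shared across tests."""
    from metaprog.hmm import fit_baum_welch

    _, dataset, _ = planted_cohort
    return {
        g: fit_baum_welch(dataset.subset(dataset.individuals_in_group(g)))
        for g in ("progressor", "non-progressor")
    }
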