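import numpy as np
import pandas as pd
import pytest

from paraploid.simdata import ReadDataset, ScenarioSpec, simulate_dataset


def make_dataset(ref, alt, ploidy=4, dosage=None, populations=None):
    """Tiny hand-built ReadDataset for unit tests."""
    ref = np.atleast_2d(np.asarray(ref, dtype=int))
    alt = np.atleast_2d(np.asarray(alt, dtype=int))
    n = ref.shape[0]
    pops = populations or ["pop1"] * n
    meta = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n)],
            "population": pops,
            "drainage": ["D1"] * n,
            "ecotype": ["highland"] * n,
            "ploidy": [ploidy] * n if np.isscalar(ploidy) else list(ploidy),
        }
    )
    return ReadDataset(
        ref_depth=ref,
        alt_depth=alt,
        sample_meta=meta,
        true_dosage=None if dosage is None else np.atleast_2d(np.asarray(dosage)),
    )


@pytest.fixture(scope="session")
def contact_dataset():
    """One modest secondary-contact simulation shared across tests."""
    spec = ScenarioSpec(
        scenario="secondary_contact", n_loci=1200, n_per_pop=6, seed=11
    )
    ft, ds = simulate_dataset(spec)
    return spec, ft, ds
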