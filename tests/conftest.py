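import numpy as np
import pytest

import aidtrack as at


@pytest.fixture(scope="session")
def random_genome():
    """100-kb single-contig random genome at 40% GC."""
    cfg = at.SynthGenomeConfig(contig_lengths={"1": 100_000}, gc=0.4, seed=11)
    return at.generate_genome(cfg)


@pytest.fixture(scope="session")
def synth_data(random_genome):
    """Small mixed-process cohort with annotations and ground truth."""
    ann = at.generate_annotations(random_genome, seed=12)
    cfg = at.SynthCohortConfig(
        n_samples=8,
        muts_per_sample=300,
        mix={"aid": 0.1, "apobec": 0.1, "background": 0.8},
        seed=13,
    )
    data = at.generate_cohort(random_genome, ann, cfg)
    at.classify_aid(data["cohort"], random_genome)
    data["annotations"] = ann
    return data


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
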