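import numpy as np
import pytest

from tumortime.ccf import annotate_mutations
from tumortime.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """Six simulated tumors with the default study conditions."""
    return simulate_cohort(SimConfig(n_tumors=6, seed=3))


@pytest.fixture(scope="session")
def annotated_small(small_bundle):
    """Annotated mutation tables per tumor of the small cohort."""
    b = small_bundle
    meta = b.metadata.set_index("tumor_id")
    out = {}
    for tumor_id, muts in b.mutations.groupby("tumor_id"):
        segs = b.segments[b.segments["tumor_id"] == tumor_id]
        ann = annotate_mutations(muts, segs,
                                 float(meta.loc[tumor_id, "purity"]))
        out[tumor_id] = (ann, segs)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20230420)
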