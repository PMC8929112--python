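import numpy as np
import pandas as pd
import pytest

from nlr_atlas.core import GenotypeMatrix
from nlr_atlas.domain_scan import build_profile_hmm, load_seed_alignment


@pytest.fixture(scope="session")
def seed_hmm():
    return build_profile_hmm(load_seed_alignment())


@pytest.fixture(scope="session")
def seed_consensus(seed_hmm):
    return seed_hmm.consensus()


def make_genotype_matrix(records, panel_groups, metadata=None):
    """Hand-build a GenotypeMatrix.

    ``records``: list of (chrom, pos, [dosage per sample]);
    ``panel_groups``: list of group labels, one per sample.
    """
    samples = [f"s{i + 1}" for i in range(len(panel_groups))]
    sites = pd.DataFrame(
        [{"chrom": c, "pos": p, "ref": "A", "alt": "T"} for c, p, _ in records]
    ) if records else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    gt = (np.array([row for _, _, row in records], dtype=np.int8)
          if records else np.empty((0, len(samples)), dtype=np.int8))
    panel = pd.DataFrame({
        "sample": samples, "group": panel_groups,
        "lineage": panel_groups,
    }).set_index("sample")
    return GenotypeMatrix(sites, gt, samples, panel, metadata)


@pytest.fixture
def gm_factory():
    return make_genotype_matrix
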