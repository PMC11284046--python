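import numpy as np
import pytest

from caemgbdt.synthetic import FIXTURES, generate_multiomics


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small strong-signal multi-omics dataset: (blocks, labels, masks)."""
    return generate_multiomics(FIXTURES["tiny"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def write_tsv(path, feature_ids, sample_ids, values, sep="\t"):
    """Write a features-by-samples omics table the loaders consume."""
    with open(path, "w") as fh:
        fh.write("id" + sep + sep.join(sample_ids) + "\n")
        for fid, row in zip(feature_ids, values):
            fh.write(fid + sep + sep.join(str(v) for v in row) + "\n")
    return path
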