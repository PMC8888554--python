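import numpy as np
import pandas as pd
import pytest

from holodepth import synthetic as sy
from holodepth.tables import AsvTable, MetaboFeatureTable


@pytest.fixture(scope="session")
def metadata15():
    return sy.simulate_metadata(15, seed=2)


@pytest.fixture(scope="session")
def hma_dataset(metadata15):
    """Standard depth-structured HMA community with planted effects."""
    return sy.simulate_asv_table(
        metadata15, "HMA", n_asvs=300, frac_responsive=0.3,
        n_sister_pairs=3, seed=7,
    )


@pytest.fixture()
def tiny_asv_table():
    data = pd.DataFrame(
        [[2, 1, 0], [1, 1, 1], [0, 0, 4]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3"],
    )
    return AsvTable(data, kind="counts")


def make_feature_table(rt, cv_qc=None, annotations=None, pc_groups=None,
                       intensities=None, n_samples=4, n_qc=3,
                       mode=("HILIC", "positive")):
    """Small hand-built feature table; QC columns realise an exact CV."""
    n = len(rt)
    ids = [f"f{i+1}" for i in range(n)]
    if intensities is None:
        intensities = np.full((n, n_samples), 100.0)
    assert n_qc == 3, "exact-CV construction below assumes 3 QC injections"
    qc = np.full((n, n_qc), 10.0)
    if cv_qc is not None:
        # (10-d, 10, 10+d) has mean 10 and sample sd d, so CV = d/10
        for i, cv in enumerate(cv_qc):
            d = 10.0 * cv
            qc[i] = [10.0 - d, 10.0, 10.0 + d]
    cols = [f"s{j+1}" for j in range(n_samples)] + [f"QC{j+1}" for j in range(n_qc)]
    feats = pd.DataFrame(
        {
            "retention_time": rt,
            "mz": np.linspace(100, 500, n),
            "annotation": annotations if annotations is not None else [""] * n,
            "pc_group": pc_groups if pc_groups is not None else list(range(n)),
        },
        index=ids,
    )
    inten = pd.DataFrame(np.hstack([intensities, qc]), index=ids, columns=cols)
    return MetaboFeatureTable(inten, feats, qc_columns=[f"QC{j+1}" for j in range(n_qc)],
                              mode=mode)
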