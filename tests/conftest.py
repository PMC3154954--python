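import numpy as np
import pandas as pd
import pytest

import varcon


def make_design(samples, donors=None, groups=None, cell_types=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "donor_id": donors or [f"d{i}" for i in range(n)],
            "group_label": groups or ["G"] * n,
            "cell_type": cell_types or ["ct0"] * n,
            "replicate_id": [f"r{i}" for i in range(n)],
        },
        index=pd.Index(samples, name="sample_id"),
    )


def make_norm(matrix, samples=None, genes=None, strategy="log2"):
    """NormalizationResult from a raw log2 array."""
    arr = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return varcon.NormalizationResult(
        pd.DataFrame(arr, index=genes, columns=samples), strategy
    )


@pytest.fixture
def tiny_bundle():
    """3 probes x 4 samples, two donor groups of 2."""
    samples = ["s0", "s1", "s2", "s3"]
    expr = pd.DataFrame(
        [[2.0, 4.0, 6.0, 8.0], [5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 4.0, 8.0]],
        index=["g0", "g1", "g2"],
        columns=samples,
    )
    det = pd.DataFrame(0.001, index=expr.index, columns=samples)
    design = make_design(samples, donors=["a", "b", "c", "d"], groups=["X", "X", "Y", "Y"])
    return varcon.ExpressionBundle(expr, det, design)


@pytest.fixture(scope="session")
def disease_dataset():
    """Three-group dataset with the deflated/inflated variance structure."""
    cfg = varcon.SyntheticConfig(
        n_genes=1200,
        groups=(
            varcon.GroupSpec("Control", 10, 1.0),
            varcon.GroupSpec("SZ", 10, 0.5),
            varcon.GroupSpec("PD", 10, 1.6),
        ),
        n_celltypes=2,
        pathways=(
            varcon.PathwaySpec("shifted", 60, mean_shift=1.2),
            varcon.PathwaySpec("flat", 60, mean_shift=0.0),
        ),
        seed=11,
    )
    bundle, sets, truth = varcon.generate_dataset(cfg)
    return cfg, bundle, sets, truth


@pytest.fixture(scope="session")
def disease_profile(disease_dataset):
    _, bundle, _, _ = disease_dataset
    norm = varcon.normalize(bundle, "log2_quantile")
    profile = varcon.compute_cv(norm, bundle.design)
    return norm, profile
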