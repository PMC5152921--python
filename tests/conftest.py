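import numpy as np
import pandas as pd
import pytest

from vdrassay import AssayMatrix, ClusterPattern, simulate_assay_matrix
from vdrassay.reporter import COREGULATORS


@pytest.fixture
def toy_distance():
    """3-leaf metric with d(A,B)=1, d(A,C)=5, d(B,C)=4."""
    d = pd.DataFrame([[0.0, 1.0, 5.0], [1.0, 0.0, 4.0], [5.0, 4.0, 0.0]],
                     index=list("ABC"), columns=list("ABC"))
    return d


def make_matrix(values, species, assay_classes=None, ligands=None, coregs=None):
    """Hand-build a small annotated assay matrix."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = [f"a{i}" for i in range(n)]
    ann = pd.DataFrame({
        "assay_class": assay_classes or ["TT"] * n,
        "ligand": ligands or ["LCA"] * n,
    }, index=ids)
    for g in COREGULATORS:
        ann[g] = 0
    if coregs:
        for i, gs in enumerate(coregs):
            for g in gs:
                ann.loc[ids[i], g] = 1
    return AssayMatrix(pd.DataFrame(values, index=ids, columns=list(species)), ann)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def planted():
    """Default planted matrix (seed 0) with its reference pattern."""
    matrix, truth = simulate_assay_matrix(seed=0)
    groups = [sorted(g) for g in truth.true_partition]
    pattern = ClusterPattern.from_lists(groups, {"C1": groups[0], "C2": groups[1]})
    return matrix, truth, pattern


def pattern_for(truth):
    groups = [sorted(g) for g in truth.true_partition]
    return ClusterPattern.from_lists(groups, {"C1": groups[0], "C2": groups[1]})
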