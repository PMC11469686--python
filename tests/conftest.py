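import numpy as np
import pandas as pd
import pytest

from permap.map_model import UnitMatrix
from permap.synthgen import SimConfig, simulate


def make_units(features, perturbation, batch, is_control, is_expressed=None,
               qc=None):
    """Assemble a UnitMatrix from plain lists (test convenience)."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    index = pd.Index([f"unit{i}" for i in range(n)])
    feats = pd.DataFrame(features, index=index,
                         columns=[f"f{j}" for j in range(features.shape[1])])
    obs = pd.DataFrame({
        "perturbation": perturbation,
        "batch": batch,
        "is_control": is_control,
        "is_expressed": pd.array(
            is_expressed if is_expressed is not None else [None] * n,
            dtype="boolean"),
    }, index=index)
    qc_df = None
    if qc is not None:
        qc_df = pd.DataFrame(qc, index=index)
    return UnitMatrix(feats, obs, qc_df)


@pytest.fixture
def toy_units():
    """Six units, two features, two batches, two controls per batch."""
    return make_units(
        features=[[1.0, 2.0], [3.0, 6.0], [2.0, 1.0],
                  [10.0, 20.0], [14.0, 28.0], [12.0, 21.0]],
        perturbation=["ctrl", "ctrl", "geneA", "ctrl", "ctrl", "geneA"],
        batch=["b1", "b1", "b1", "b2", "b2", "b2"],
        is_control=[True, True, False, True, True, False],
        is_expressed=[None, None, True, None, None, True],
    )


@pytest.fixture(scope="session")
def strong_batch_screen():
    """Synthetic screen with strong affine batch artifacts and weak
    per-replicate effects: the regime where alignment choice matters."""
    cfg = SimConfig(
        n_genes=300, n_unexpressed=0, n_complexes=10, complex_size=12,
        dims=24, n_batches=6, replicates_per_gene=6, controls_per_batch=40,
        effect_scale=0.4, noise_sd=1.0, batch_shift_scale=8.0,
        batch_scale_spread=1.5, seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def mild_screen():
    """Small screen with mild batch artifacts, for fast functional tests."""
    cfg = SimConfig(
        n_genes=60, n_unexpressed=0, n_complexes=3, complex_size=12,
        dims=12, n_batches=3, replicates_per_gene=4, controls_per_batch=20,
        effect_scale=1.5, noise_sd=1.0, batch_shift_scale=1.0,
        batch_scale_spread=0.3, seed=5,
    )
    return simulate(cfg)
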