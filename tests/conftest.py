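import numpy as np
import pytest

from perturbcycle.data_io import (
    ExpressionDataset,
    PerturbationKind,
    PerturbationRecord,
)
from perturbcycle.model_core import ModelConfig, ModelState


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_tiny_model(
    n_genes=2,
    latent_dim=1,
    shared=False,
    batchnorm=False,
    seed=0,
    genetic_vocab=(),
):
    """Small model with no hidden layers: every map is a single affine layer."""
    cfg = ModelConfig(
        n_genes=n_genes,
        latent_dim=latent_dim,
        encoder_hidden=(),
        decoder_hidden=(),
        disc_hidden=(),
        gat_hidden=(4, 4),
        genetic_vocabulary=tuple(genetic_vocab),
        shared_autoencoder=shared,
        batchnorm=batchnorm,
    )
    return ModelState(cfg, seed=seed)


def set_affine(mlp, W, b):
    """Overwrite a single-layer MLP's weight matrix (in x out) and bias."""
    assert len(mlp.linears) == 1
    mlp.linears[0].W.data = np.asarray(W, dtype=np.float64)
    mlp.linears[0].b.data = np.asarray(b, dtype=np.float64)


@pytest.fixture
def tiny_model():
    """G=2, L=1 linear model with hand-set weights for scalar oracles.

    enc_control: z = [1, 2] . x        dec_treated: y = z * [1, -1] + [0.5, 0]
    enc_treated: z = [0.5, 0.5] . y    dec_control: x = z * [2, 1]
    disc_treated / disc_control: sigmoid(w . p + b)
    """
    m = make_tiny_model()
    set_affine(m.enc_control, [[1.0], [2.0]], [0.0])
    set_affine(m.dec_treated, [[1.0, -1.0]], [0.5, 0.0])
    set_affine(m.enc_treated, [[0.5], [0.5]], [0.0])
    set_affine(m.dec_control, [[2.0, 1.0]], [0.0, 0.0])
    set_affine(m.disc_treated, [[0.3], [-0.2]], [0.1])
    set_affine(m.disc_control, [[-0.1], [0.4]], [-0.2])
    m.eval()
    return m


def control_record(i=0, context="ctx"):
    return PerturbationRecord(
        sample_id=f"c{i}",
        perturbation_id="control",
        kind=PerturbationKind.CONTROL,
        context_id=context,
    )


def drug_record(i=0, pert="drugA", smiles="CC", dose=None, context="ctx"):
    return PerturbationRecord(
        sample_id=f"t{i}",
        perturbation_id=pert,
        kind=PerturbationKind.DRUG,
        smiles=smiles,
        dose=dose,
        context_id=context,
    )


@pytest.fixture
def small_dataset(rng):
    """4 controls + 6 treated over 2 drugs, 5 genes, explicit pairing."""
    matrix = rng.normal(size=(10, 5))
    records = [control_record(i) for i in range(4)]
    records += [drug_record(i, pert="drugA", smiles="CC") for i in range(3)]
    records += [drug_record(i + 3, pert="drugB", smiles="CCO") for i in range(3)]
    pairing = {4: 0, 5: 1, 6: 2, 7: 0, 8: 1, 9: 3}
    return ExpressionDataset(
        matrix, records, [f"g{i}" for i in range(5)], pairing=pairing
    )
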