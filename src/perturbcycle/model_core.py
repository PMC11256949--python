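"""Dual encoder-decoder model with latent-additive perturbation arithmetic.

Forward prediction encodes a control profile, adds the perturbation vector
in the latent space and decodes through the treated-side decoder; reverse
restoration encodes a treated profile, subtracts the perturbation vector
and decodes through the control-side decoder. Two discriminators score
realism of generated treated and control profiles for adversarial training
in the unpaired regime.

With ``shared_autoencoder=True`` the treated-side encoder/decoder are the
very same modules as the control-side ones (single-autoencoder ablation).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._nn import MLP, Module, Tensor, as_tensor
from .data_io import PerturbationKind, PerturbationRecord
from .drug_encoder import (
    DoseNet,
    DrugEncoder,
    DrugGraph,
    Featurization,
    GeneticEncoder,
    PerturbationEmbedding,
    smiles_to_graph,
)

__all__ = ["ModelConfig", "ModelState", "LatentVector", "ModelError",
           "add_perturbation", "remove_perturbation"]


class ModelError(ValueError):
    pass


@dataclasses.dataclass
class LatentVector:
    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ModelError("latent vector must be finite")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Shapes and switches for the full model."""

    n_genes: int
    latent_dim: int = 128
    encoder_hidden: tuple[int, ...] = (512, 256)
    decoder_hidden: tuple[int, ...] = (256, 512)
    disc_hidden: tuple[int, ...] = (256, 64)
    gat_hidden: tuple[int, int] = (64, 64)
    drug_feature_dim: Optional[int] = None  # default: SMILES featurization width
    genetic_vocabulary: tuple[str, ...] = ()
    shared_autoencoder: bool = False
    batchnorm: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("encoder_hidden", "decoder_hidden", "disc_hidden", "gat_hidden",
                  "genetic_vocabulary"):
            d[k] = list(d[k])
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("encoder_hidden", "decoder_hidden", "disc_hidden", "gat_hidden",
                  "genetic_vocabulary"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return ModelConfig(**d)


class ModelState(Module):
    """All trainable components plus the latent arithmetic."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        ss = np.random.SeedSequence(seed)
        keys = ss.spawn(8)
        rngs = [np.random.default_rng(k) for k in keys]
        G, L = config.n_genes, config.latent_dim
        bn = config.batchnorm

        enc_dims = (G, *config.encoder_hidden, L)
        dec_dims = (L, *config.decoder_hidden, G)
        disc_dims = (G, *config.disc_hidden, 1)

        self.enc_control = MLP(enc_dims, rng=rngs[0], batchnorm=bn)
        self.dec_treated = MLP(dec_dims, rng=rngs[1], batchnorm=bn)
        if config.shared_autoencoder:
            self.enc_treated = self.enc_control
            self.dec_control = self.dec_treated
        else:
            self.enc_treated = MLP(enc_dims, rng=rngs[2], batchnorm=bn)
            self.dec_control = MLP(dec_dims, rng=rngs[3], batchnorm=bn)
        self.disc_treated = MLP(disc_dims, rng=rngs[4], batchnorm=False, final="sigmoid")
        self.disc_control = MLP(disc_dims, rng=rngs[5], batchnorm=False, final="sigmoid")

        feat_dim = config.drug_feature_dim or Featurization().width
        self.drug_encoder = DrugEncoder(feat_dim, L, hidden_dims=config.gat_hidden, rng=rngs[6])
        self.genetic_encoder = (
            GeneticEncoder(config.genetic_vocabulary, L, rng=rngs[7])
            if config.genetic_vocabulary
            else None
        )
        self.dose_net = DoseNet(L, rng=rngs[7])
        self.eval()

    # parameters() walks __dict__; with a shared autoencoder the aliased
    # modules would be visited twice, so deduplicate by identity.
    def parameters(self) -> list[Tensor]:
        params = super().parameters()
        seen: set[int] = set()
        out = []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def generator_parameters(self) -> list[Tensor]:
        mods = [self.enc_control, self.dec_treated, self.enc_treated, self.dec_control,
                self.drug_encoder, self.dose_net]
        if self.genetic_encoder is not None:
            mods.append(self.genetic_encoder)
        seen: set[int] = set()
        out = []
        for m in mods:
            for p in m.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def discriminator_parameters(self) -> list[Tensor]:
        return self.disc_treated.parameters() + self.disc_control.parameters()

    # -- encoding / decoding (tensor level, used by losses and training) ------

    def _check_genes(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.config.n_genes:
            raise ModelError(
                f"profile has {x.shape[1]} genes, model expects {self.config.n_genes}"
            )
        return x

    def encode_control_t(self, x) -> Tensor:
        return self.enc_control(as_tensor(x))

    def encode_treated_t(self, y) -> Tensor:
        return self.enc_treated(as_tensor(y))

    def decode_treated_t(self, z) -> Tensor:
        return self.dec_treated(as_tensor(z))

    def decode_control_t(self, z) -> Tensor:
        return self.dec_control(as_tensor(z))

    # -- public single-profile API --------------------------------------------

    def encode_control(self, x: np.ndarray) -> LatentVector:
        x = self._check_genes(x)
        return LatentVector(self.encode_control_t(x).data[0])

    def encode_treated(self, y: np.ndarray) -> LatentVector:
        y = self._check_genes(y)
        return LatentVector(self.encode_treated_t(y).data[0])

    def resolve_embedding(
        self,
        pert: PerturbationRecord,
        graph: Optional[DrugGraph] = None,
        graphs: Optional[dict] = None,
    ) -> PerturbationEmbedding:
        """Map a perturbation record to its latent vector d_j.

        Control records map to the zero embedding, making reconstruction the
        d=0 special case of the forward path.
        """
        L = self.config.latent_dim
        if pert.kind == PerturbationKind.CONTROL:
            return PerturbationEmbedding(np.zeros(L), pert.perturbation_id)
        if pert.kind == PerturbationKind.GENETIC:
            if self.genetic_encoder is None:
                raise ModelError("model was built without a genetic vocabulary")
            emb = PerturbationEmbedding(
                self.genetic_encoder.forward(pert.target_gene).data, pert.perturbation_id
            )
        else:
            if graph is None and graphs is not None:
                graph = graphs.get(pert.perturbation_id)
            if graph is None:
                if not pert.smiles:
                    raise ModelError(
                        f"perturbation {pert.perturbation_id}: no graph and no SMILES"
                    )
                graph = smiles_to_graph(pert.smiles)
            emb = PerturbationEmbedding(
                self.drug_encoder.forward(graph).data, pert.perturbation_id
            )
        if pert.dose is not None:
            emb = PerturbationEmbedding(
                emb.vector * self.dose_net.embedding(pert.dose).data, emb.perturbation_id
            )
        return emb

    def predict_response(
        self,
        x: np.ndarray,
        pert: PerturbationRecord,
        graph: Optional[DrugGraph] = None,
        graphs: Optional[dict] = None,
    ) -> np.ndarray:
        """y_hat = G_phi(F_theta(x) + d_j)."""
        x = self._check_genes(x)
        d = self.resolve_embedding(pert, graph=graph, graphs=graphs)
        z = self.encode_control_t(x)
        z_plus = z + as_tensor(d.vector.reshape(1, -1))
        return self.decode_treated_t(z_plus).data[0]

    def restore_control(
        self,
        y: np.ndarray,
        pert: PerturbationRecord,
        graph: Optional[DrugGraph] = None,
        graphs: Optional[dict] = None,
    ) -> np.ndarray:
        """x_hat = G_phi'(F_theta'(y) - d_j)."""
        y = self._check_genes(y)
        d = self.resolve_embedding(pert, graph=graph, graphs=graphs)
        z = self.encode_treated_t(y)
        z_minus = z - as_tensor(d.vector.reshape(1, -1))
        return self.decode_control_t(z_minus).data[0]

    def discriminate(self, profile: np.ndarray, which: str) -> float:
        if which not in ("treated", "control"):
            raise ModelError(f"unknown discriminator '{which}'")
        profile = self._check_genes(profile)
        disc = self.disc_treated if which == "treated" else self.disc_control
        return float(disc(as_tensor(profile)).data[0, 0])

    # -- checkpointing --------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name in ("enc_control", "dec_treated", "disc_treated", "disc_control",
                     "drug_encoder", "dose_net"):
            arrays.update(getattr(self, name).state_arrays(prefix=name + "."))
        if not self.config.shared_autoencoder:
            arrays.update(self.enc_treated.state_arrays(prefix="enc_treated."))
            arrays.update(self.dec_control.state_arrays(prefix="dec_control."))
        if self.genetic_encoder is not None:
            arrays.update(self.genetic_encoder.state_arrays(prefix="genetic_encoder."))
        np.savez(path / "params.npz", **arrays)
        (path / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))

    @staticmethod
    def load(path) -> "ModelState":
        path = Path(path)
        config = ModelConfig.from_dict(json.loads((path / "config.json").read_text()))
        model = ModelState(config)
        with np.load(path / "params.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        for name in ("enc_control", "dec_treated", "disc_treated", "disc_control",
                     "drug_encoder", "dose_net"):
            getattr(model, name).load_state_arrays(arrays, prefix=name + ".")
        if not config.shared_autoencoder:
            model.enc_treated.load_state_arrays(arrays, prefix="enc_treated.")
            model.dec_control.load_state_arrays(arrays, prefix="dec_control.")
        if model.genetic_encoder is not None:
            model.genetic_encoder.load_state_arrays(arrays, prefix="genetic_encoder.")
        return model


# ---------------------------------------------------------------------------
# latent arithmetic
# ---------------------------------------------------------------------------


def add_perturbation(z: LatentVector, d: PerturbationEmbedding) -> LatentVector:
    """z(+) = z + d."""
    if z.vector.shape != d.vector.shape:
        raise ModelError(
            f"latent length {z.vector.shape} != embedding length {d.vector.shape}"
        )
    return LatentVector(z.vector + d.vector)


def remove_perturbation(z_prime: LatentVector, d: PerturbationEmbedding) -> LatentVector:
    """z(-) = z' - d."""
    if z_prime.vector.shape != d.vector.shape:
        raise ModelError(
            f"latent length {z_prime.vector.shape} != embedding length {d.vector.shape}"
        )
    return LatentVector(z_prime.vector - d.vector)
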