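"""Training objectives as pure functions of model outputs.

Conventions: every squared-error loss is the mean over the batch of the
per-sample sum of squared errors over genes, so loss weights are invariant
to batch size. Discriminator outputs are clamped to [1e-7, 1 - 1e-7]
before logarithms. The generator adversarial term uses the non-saturating
-log D(fake) form.

Perturbation embeddings are passed as an (n x L) array/tensor ``d`` aligned
with the batch rows; the training loop materializes them through the drug /
genetic encoders so that gradients reach the encoder parameters.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Union

import numpy as np

from ._nn import Tensor, as_tensor
from .model_core import ModelState

__all__ = [
    "LossWeights",
    "LossError",
    "reconstruction_loss",
    "paired_mse_loss",
    "adversarial_losses",
    "cycle_loss",
    "identity_loss",
    "total_loss",
    "CLAMP_EPS",
]

CLAMP_EPS = 1e-7

ArrayLike = Union[np.ndarray, Tensor]


class LossError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """Weights of the unpaired objective: alpha*L_reco + beta*L_GAN + lam*L_cyc."""

    alpha: float = 2.5
    beta: float = 2.0
    lam: float = 10.0
    identity_weight: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "lam", "identity_weight"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise LossError(f"{name} must be finite and nonnegative, got {v}")


def _batch(x: ArrayLike, name: str) -> Tensor:
    t = as_tensor(x)
    if t.ndim != 2:
        t = t.reshape(1, -1) if t.ndim == 1 else t
    if t.shape[0] == 0:
        raise LossError(f"empty batch for {name}")
    return t

def _sq_err(a: Tensor, b: Tensor) -> Tensor:
    """Mean over batch of sum over genes of squared error."""
    return ((a - b) ** 2).sum(axis=1).mean()


def reconstruction_loss(batch_x: ArrayLike, m: ModelState) -> Tensor:
    """Autoencoder reconstruction error of control profiles, forward AE."""
    x = _batch(batch_x, "reconstruction_loss")
    x_hat = m.decode_treated_t(m.encode_control_t(x))
    return _sq_err(x, x_hat)


def dual_reconstruction_loss(batch_x: ArrayLike, batch_y: ArrayLike, m: ModelState) -> Tensor:
    """Reconstruction error of both autoencoders on their own domains."""
    x = _batch(batch_x, "reconstruction_loss")
    y = _batch(batch_y, "reconstruction_loss")
    loss_x = _sq_err(x, m.decode_treated_t(m.encode_control_t(x)))
    loss_y = _sq_err(y, m.decode_control_t(m.encode_treated_t(y)))
    return loss_x + loss_y


def paired_mse_loss(
    x: ArrayLike, y: ArrayLike, d: ArrayLike, m: ModelState
) -> Tensor:
    """Two-term paired error: forward prediction and reverse restoration.

    ``x``/``y``/``d`` are row-aligned: the i-th control, its treated
    counterpart, and the embedding of the perturbation applied.
    """
    x = _batch(x, "paired_mse_loss")
    y = _batch(y, "paired_mse_loss")
    d = _batch(d, "paired_mse_loss")
    if not (x.shape[0] == y.shape[0] == d.shape[0]):
        raise LossError(
            f"unpaired input: batch sizes {x.shape[0]}, {y.shape[0]}, {d.shape[0]}"
        )
    y_hat = m.decode_treated_t(m.encode_control_t(x) + d)
    x_hat = m.decode_control_t(m.encode_treated_t(y) - d)
    return _sq_err(y, y_hat) + _sq_err(x, x_hat)


def _clamped(scores: Tensor) -> Tensor:
    return scores.clamp(CLAMP_EPS, 1.0 - CLAMP_EPS)


def adversarial_losses(
    controls: ArrayLike,
    treated: ArrayLike,
    d_for_controls: ArrayLike,
    d_for_treated: ArrayLike,
    m: ModelState,
    detach_fakes: bool = False,
) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """(gen_fwd, disc_fwd, gen_rev, disc_rev) adversarial terms.

    Forward: the treated-side discriminator judges real treated profiles
    against generated ones G_phi(F_theta(x) + d). Reverse: the control-side
    discriminator judges real controls against restored ones
    G_phi'(F_theta'(y) - d). Discriminator losses are the negated minimax
    value; generator losses are non-saturating.
    """
    x = _batch(controls, "adversarial_losses")
    y = _batch(treated, "adversarial_losses")
    dx = _batch(d_for_controls, "adversarial_losses")
    dy = _batch(d_for_treated, "adversarial_losses")

    fake_y = m.decode_treated_t(m.encode_control_t(x) + dx)
    fake_x = m.decode_control_t(m.encode_treated_t(y) - dy)
    if detach_fakes:
        fake_y = fake_y.detach()
        fake_x = fake_x.detach()

    real_y_score = _clamped(m.disc_treated(y))
    fake_y_score = _clamped(m.disc_treated(fake_y))
    real_x_score = _clamped(m.disc_control(x))
    fake_x_score = _clamped(m.disc_control(fake_x))

    disc_fwd = -(real_y_score.log().mean() + (1.0 - fake_y_score).log().mean())
    disc_rev = -(real_x_score.log().mean() + (1.0 - fake_x_score).log().mean())
    gen_fwd = -fake_y_score.log().mean()
    gen_rev = -fake_x_score.log().mean()
    return gen_fwd, disc_fwd, gen_rev, disc_rev


def cycle_loss(
    controls: ArrayLike,
    treated: ArrayLike,
    d_for_controls: ArrayLike,
    d_for_treated: ArrayLike,
    m: ModelState,
) -> Tensor:
    """Two-hop consistency: x -> y_hat -> x_hat and y -> x_hat -> y_hat.

    Each control row is cycled under the perturbation embedding in
    ``d_for_controls`` (in unpaired mode these are sampled from the batch's
    treated labels by the caller); each treated row under ``d_for_treated``.
    """
    x = _batch(controls, "cycle_loss")
    y = _batch(treated, "cycle_loss")
    dx = _batch(d_for_controls, "cycle_loss")
    dy = _batch(d_for_treated, "cycle_loss")
    if dx.shape[0] != x.shape[0] or dy.shape[0] != y.shape[0]:
        raise LossError("cycle_loss: perturbation rows must align with profile rows")

    y_mid = m.decode_treated_t(m.encode_control_t(x) + dx)
    x_cycled = m.decode_control_t(m.encode_treated_t(y_mid) - dx)
    x_mid = m.decode_control_t(m.encode_treated_t(y) - dy)
    y_cycled = m.decode_treated_t(m.encode_control_t(x_mid) + dy)
    return _sq_err(x, x_cycled) + _sq_err(y, y_cycled)


def identity_loss(treated: ArrayLike, m: ModelState) -> Tensor:
    """Penalty for the forward generator altering already-treated samples."""
    y = _batch(treated, "identity_loss")
    y_id = m.decode_treated_t(m.encode_control_t(y))
    return _sq_err(y, y_id)


def identity_loss_reverse(controls: ArrayLike, m: ModelState) -> Tensor:
    """Symmetric identity term: the reverse generator must leave real
    control samples unchanged (applied to both generators, cycleGAN-style)."""
    x = _batch(controls, "identity_loss_reverse")
    x_id = m.decode_control_t(m.encode_treated_t(x))
    return _sq_err(x, x_id)


def total_loss(
    mode: str,
    w: LossWeights,
    reco: Optional[ArrayLike] = None,
    paired_mse: Optional[ArrayLike] = None,
    gan: Optional[ArrayLike] = None,
    cyc: Optional[ArrayLike] = None,
    identity: Optional[ArrayLike] = None,
) -> tuple[Tensor, dict[str, float]]:
    """Combine loss components for the given regime.

    Paired: unweighted sum of reconstruction and paired MSE.
    Unpaired: alpha*reco + beta*gan + lam*cyc + identity_weight*identity.
    Returns the total plus a float breakdown for logging.
    """
    def _scalar(v, name):
        if v is None:
            raise LossError(f"total_loss({mode}): missing component '{name}'")
        return as_tensor(v)

    if mode == "paired":
        r = _scalar(reco, "reco")
        p = _scalar(paired_mse, "paired_mse")
        total = r + p
        breakdown = {"reco": float(r.data), "paired_mse": float(p.data)}
    elif mode == "unpaired":
        r = _scalar(reco, "reco")
        g = _scalar(gan, "gan")
        c = _scalar(cyc, "cyc")
        total = w.alpha * r + w.beta * g + w.lam * c
        breakdown = {"reco": float(r.data), "gan": float(g.data), "cyc": float(c.data)}
        if identity is not None:
            i = as_tensor(identity)
            total = total + w.identity_weight * i
            breakdown["identity"] = float(i.data)
    else:
        raise LossError(f"unknown mode '{mode}'")
    breakdown["total"] = float(total.data)
    return total, breakdown
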