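"""Loss functions against independent per-sample loop oracles.

The oracles re-implement every forward pass with explicit per-sample numpy
loops straight from the stored parameter arrays — they share no code with
the vectorized autodiff path they check.
"""

import numpy as np
import pytest

from perturbcycle.losses import (
    CLAMP_EPS,
    LossError,
    LossWeights,
    adversarial_losses,
    cycle_loss,
    identity_loss,
    paired_mse_loss,
    reconstruction_loss,
    total_loss,
)

from conftest import make_tiny_model, set_affine


# ---------------------------------------------------------------------------
# oracle forward passes (loop-based, parameter-array level)
# ---------------------------------------------------------------------------


def mlp_forward_single(mlp, v):
    """One sample through an MLP in eval mode, by explicit loops."""
    h = np.asarray(v, dtype=np.float64)
    n_layers = len(mlp.linears)
    for i, lin in enumerate(mlp.linears):
        out = np.zeros(lin.out_dim)
        for j in range(lin.out_dim):
            acc = lin.b.data[j]
            for k in range(lin.in_dim):
                acc += h[k] * lin.W.data[k, j]
            out[j] = acc
        h = out
        if i < n_layers - 1:
            if mlp.norms:
                bn = mlp.norms[i]
                h = (h - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
                h = h * bn.gamma.data + bn.beta.data
            h = np.maximum(h, 0.0)
    if mlp.final == "sigmoid":
        h = 1.0 / (1.0 + np.exp(-h))
    return h


def o_enc_c(m, x):
    return mlp_forward_single(m.enc_control, x)


def o_enc_t(m, y):
    return mlp_forward_single(m.enc_treated, y)


def o_dec_t(m, z):
    return mlp_forward_single(m.dec_treated, z)


def o_dec_c(m, z):
    return mlp_forward_single(m.dec_control, z)


def oracle_reconstruction(m, X):
    return float(np.mean([np.sum((x - o_dec_t(m, o_enc_c(m, x))) ** 2) for x in X]))


def oracle_paired_mse(m, X, Y, D):
    vals = []
    for x, y, d in zip(X, Y, D):
        t1 = np.sum((y - o_dec_t(m, o_enc_c(m, x) + d)) ** 2)
        t2 = np.sum((x - o_dec_c(m, o_enc_t(m, y) - d)) ** 2)
        vals.append(t1 + t2)
    return float(np.mean(vals))


def oracle_adversarial(m, X, Y, DX, DY):
    def clamp(s):
        return np.clip(s, CLAMP_EPS, 1 - CLAMP_EPS)

    real_y = [clamp(mlp_forward_single(m.disc_treated, y))[0] for y in Y]
    fake_ys = [o_dec_t(m, o_enc_c(m, x) + d) for x, d in zip(X, DX)]
    fake_y = [clamp(mlp_forward_single(m.disc_treated, f))[0] for f in fake_ys]
    real_x = [clamp(mlp_forward_single(m.disc_control, x))[0] for x in X]
    fake_xs = [o_dec_c(m, o_enc_t(m, y) - d) for y, d in zip(Y, DY)]
    fake_x = [clamp(mlp_forward_single(m.disc_control, f))[0] for f in fake_xs]

    disc_fwd = -(np.mean(np.log(real_y)) + np.mean(np.log1p(-np.array(fake_y))))
    disc_rev = -(np.mean(np.log(real_x)) + np.mean(np.log1p(-np.array(fake_x))))
    gen_fwd = -np.mean(np.log(fake_y))
    gen_rev = -np.mean(np.log(fake_x))
    return gen_fwd, disc_fwd, gen_rev, disc_rev


def oracle_cycle(m, X, Y, DX, DY):
    vals_x = []
    for x, d in zip(X, DX):
        y_mid = o_dec_t(m, o_enc_c(m, x) + d)
        x_hat = o_dec_c(m, o_enc_t(m, y_mid) - d)
        vals_x.append(np.sum((x - x_hat) ** 2))
    vals_y = []
    for y, d in zip(Y, DY):
        x_mid = o_dec_c(m, o_enc_t(m, y) - d)
        y_hat = o_dec_t(m, o_enc_c(m, x_mid) + d)
        vals_y.append(np.sum((y - y_hat) ** 2))
    return float(np.mean(vals_x) + np.mean(vals_y))


def oracle_identity(m, Y):
    return float(np.mean([np.sum((y - o_dec_t(m, o_enc_c(m, y))) ** 2) for y in Y]))


def random_model(rng, n_genes=3, latent_dim=2):
    m = make_tiny_model(n_genes=n_genes, latent_dim=latent_dim,
                        seed=int(rng.integers(1 << 30)))
    m.eval()
    return m


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def test_reconstruction_perfect_zero():
    m = make_tiny_model()
    set_affine(m.enc_control, [[1.0], [0.0]], [0.0])
    set_affine(m.dec_treated, [[1.0, 0.0]], [0.0, 0.0])
    X = np.array([[2.0, 0.0], [-1.0, 0.0]])
    assert float(reconstruction_loss(X, m).data) == pytest.approx(0.0, abs=1e-12)


def test_reconstruction_squared_norm():
    m = make_tiny_model()
    # x_hat = 0 for every input
    set_affine(m.enc_control, [[0.0], [0.0]], [0.0])
    set_affine(m.dec_treated, [[0.0, 0.0]], [0.0, 0.0])
    X = np.array([[1.0, 0.0]])
    assert float(reconstruction_loss(X, m).data) == pytest.approx(1.0)


def test_reconstruction_empty_batch():
    m = make_tiny_model()
    with pytest.raises(LossError):
        reconstruction_loss(np.zeros((0, 2)), m)


def test_reconstruction_matches_oracle(rng):
    for _ in range(10):
        m = random_model(rng)
        X = rng.normal(size=(5, 3))
        got = float(reconstruction_loss(X, m).data)
        assert got == pytest.approx(oracle_reconstruction(m, X), rel=1e-9)


# ---------------------------------------------------------------------------
# paired MSE
# ---------------------------------------------------------------------------


def test_paired_mse_perfect_linear_system():
    # enc z=x0; dec_t y=(z+d)->[z, 0]+... build exact inverse pair so loss=0
    m = make_tiny_model()
    set_affine(m.enc_control, [[1.0], [0.0]], [0.0])
    set_affine(m.dec_treated, [[1.0, 0.0]], [0.0, 0.0])
    set_affine(m.enc_treated, [[1.0], [0.0]], [0.0])
    set_affine(m.dec_control, [[1.0, 0.0]], [0.0, 0.0])
    X = np.array([[1.0, 0.0], [2.0, 0.0]])
    D = np.array([[0.5], [0.5]])
    Y = X + np.array([[0.5, 0.0]])
    assert float(paired_mse_loss(X, Y, D, m).data) == pytest.approx(0.0, abs=1e-10)


def test_paired_mse_single_triple_hand_value(tiny_model):
    x = np.array([[1.0, 1.0]])
    y = np.array([[2.0, 0.0]])
    d = np.array([[0.5]])
    # z = 1+2 = 3; y_hat = (3.5)*[1,-1] + [.5,0] = [4.0, -3.5]
    # term1 = (2-4)^2 + (0+3.5)^2 = 4 + 12.25 = 16.25
    # z' = .5*2+.5*0 = 1; x_hat = (1-0.5)*[2,1] = [1.0, 0.5]
    # term2 = (1-1)^2 + (1-0.5)^2 = 0.25
    got = float(paired_mse_loss(x, y, d, tiny_model).data)
    assert got == pytest.approx(16.5, abs=1e-9)


def test_paired_mse_quadratic_scaling(rng):
    m = make_tiny_model()
    # zero model: prediction is 0, so residual = targets; doubling targets x4
    for mlp in (m.enc_control, m.enc_treated):
        set_affine(mlp, np.zeros((2, 1)), [0.0])
    for mlp in (m.dec_treated, m.dec_control):
        set_affine(mlp, np.zeros((1, 2)), [0.0, 0.0])
    X = rng.normal(size=(4, 2))
    Y = rng.normal(size=(4, 2))
    D = np.zeros((4, 1))
    l1 = float(paired_mse_loss(X, Y, D, m).data)
    l2 = float(paired_mse_loss(2 * X, 2 * Y, D, m).data)
    assert l2 == pytest.approx(4 * l1, rel=1e-12)


def test_paired_mse_unpaired_input(rng):
    m = make_tiny_model()
    with pytest.raises(LossError, match="unpaired"):
        paired_mse_loss(rng.normal(size=(3, 2)), rng.normal(size=(2, 2)),
                        np.zeros((3, 1)), m)


def test_paired_mse_matches_oracle(rng):
    for _ in range(10):
        m = random_model(rng)
        X = rng.normal(size=(4, 3))
        Y = rng.normal(size=(4, 3))
        D = rng.normal(size=(4, 2))
        got = float(paired_mse_loss(X, Y, D, m).data)
        assert got == pytest.approx(oracle_paired_mse(m, X, Y, D), rel=1e-9)


# ---------------------------------------------------------------------------
# adversarial
# ---------------------------------------------------------------------------


def test_adversarial_half_scores_closed_form(rng):
    m = make_tiny_model(n_genes=3, latent_dim=2)
    # discriminators output exactly 0.5
    set_affine(m.disc_treated, np.zeros((3, 1)), [0.0])
    set_affine(m.disc_control, np.zeros((3, 1)), [0.0])
    X = rng.normal(size=(4, 3))
    Y = rng.normal(size=(4, 3))
    D = rng.normal(size=(4, 2))
    _, disc_fwd, _, disc_rev = adversarial_losses(X, Y, D, D, m)
    assert float(disc_fwd.data) == pytest.approx(-2 * np.log(0.5), rel=1e-12)
    assert float(disc_rev.data) == pytest.approx(-2 * np.log(0.5), rel=1e-12)


def test_adversarial_perfect_discriminator_limit(rng):
    m = make_tiny_model(n_genes=2, latent_dim=1)
    X = np.array([[100.0, 100.0]])
    Y = np.array([[100.0, 100.0]])
    D = np.zeros((1, 1))
    # big positive weights: D(real) -> 1; generator output goes through
    # decoders whose outputs we push very negative -> D(fake) -> 0
    set_affine(m.disc_treated, [[5.0], [5.0]], [0.0])
    set_affine(m.disc_control, [[5.0], [5.0]], [0.0])
    set_affine(m.enc_control, [[1.0], [0.0]], [0.0])
    set_affine(m.enc_treated, [[1.0], [0.0]], [0.0])
    set_affine(m.dec_treated, [[-10.0, -10.0]], [0.0, 0.0])
    set_affine(m.dec_control, [[-10.0, -10.0]], [0.0, 0.0])
    _, disc_fwd, _, disc_rev = adversarial_losses(X, Y, D, D, m)
    assert float(disc_fwd.data) == pytest.approx(0.0, abs=1e-4)
    assert float(disc_rev.data) == pytest.approx(0.0, abs=1e-4)


def test_adversarial_empty_pool(rng):
    m = make_tiny_model()
    with pytest.raises(LossError):
        adversarial_losses(np.zeros((0, 2)), np.ones((1, 2)),
                           np.zeros((0, 1)), np.zeros((1, 1)), m)


def test_adversarial_matches_oracle(rng):
    for _ in range(10):
        m = random_model(rng)
        X = rng.normal(size=(3, 3))
        Y = rng.normal(size=(4, 3))
        DX = rng.normal(size=(3, 2))
        DY = rng.normal(size=(4, 2))
        got = adversarial_losses(X, Y, DX, DY, m)
        exp = oracle_adversarial(m, X, Y, DX, DY)
        for g, e in zip(got, exp):
            assert float(g.data) == pytest.approx(e, rel=1e-7)


def test_adversarial_finite_under_clamp(rng):
    # saturated discriminators stay finite thanks to clamping
    m = make_tiny_model(n_genes=2, latent_dim=1)
    set_affine(m.disc_treated, [[100.0], [100.0]], [0.0])
    set_affine(m.disc_control, [[-100.0], [-100.0]], [0.0])
    X = np.ones((2, 2)) * 10
    Y = np.ones((2, 2)) * 10
    D = np.zeros((2, 1))
    out = adversarial_losses(X, Y, D, D, m)
    assert all(np.isfinite(float(t.data)) for t in out)


# ---------------------------------------------------------------------------
# cycle and identity
# ---------------------------------------------------------------------------


def test_cycle_identity_maps_zero():
    m = make_tiny_model()
    # all four maps the identity on gene 0 with gene 1 ignored/zero
    set_affine(m.enc_control, [[1.0], [0.0]], [0.0])
    set_affine(m.enc_treated, [[1.0], [0.0]], [0.0])
    set_affine(m.dec_treated, [[1.0, 0.0]], [0.0, 0.0])
    set_affine(m.dec_control, [[1.0, 0.0]], [0.0, 0.0])
    X = np.array([[1.0, 0.0], [3.0, 0.0]])
    Y = np.array([[2.0, 0.0]])
    DX = np.zeros((2, 1))
    DY = np.zeros((1, 1))
    assert float(cycle_loss(X, Y, DX, DY, m).data) == pytest.approx(0.0, abs=1e-12)


def test_cycle_hand_traced_two_hop(tiny_model):
    X = np.array([[1.0, 1.0]])
    Y = np.array([[2.0, 0.0]])
    DX = np.array([[0.5]])
    DY = np.array([[0.5]])
    # x-cycle: z=3 -> y_mid=(3.5)*[1,-1]+[.5,0]=[4,-3.5]
    #   z'=.5*4-.5*3.5=.25 -> z'-d=-0.25 -> x_hat=[-0.5,-0.25]
    #   err_x=(1+0.5)^2+(1+0.25)^2 = 2.25+1.5625 = 3.8125
    # y-cycle: z'=1 -> z'-d=0.5 -> x_mid=[1.0,0.5]
    #   z=1+2*0.5=2 -> z+d=2.5 -> y_hat=[3.0,-2.5]
    #   err_y=(2-3)^2+(0+2.5)^2 = 1+6.25 = 7.25
    got = float(cycle_loss(X, Y, DX, DY, tiny_model).data)
    assert got == pytest.approx(3.8125 + 7.25, abs=1e-9)


def test_cycle_batch_order_invariant(rng):
    m = random_model(rng)
    X = rng.normal(size=(5, 3))
    Y = rng.normal(size=(4, 3))
    DX = rng.normal(size=(5, 2))
    DY = rng.normal(size=(4, 2))
    l1 = float(cycle_loss(X, Y, DX, DY, m).data)
    px, py = rng.permutation(5), rng.permutation(4)
    l2 = float(cycle_loss(X[px], Y[py], DX[px], DY[py], m).data)
    assert l1 == pytest.approx(l2, rel=1e-12)


def test_cycle_misaligned_labels(rng):
    m = make_tiny_model()
    with pytest.raises(LossError):
        cycle_loss(np.zeros((3, 2)), np.zeros((2, 2)),
                   np.zeros((2, 1)), np.zeros((2, 1)), m)


def test_cycle_matches_oracle(rng):
    for _ in range(10):
        m = random_model(rng)
        X = rng.normal(size=(3, 3))
        Y = rng.normal(size=(4, 3))
        DX = rng.normal(size=(3, 2))
        DY = rng.normal(size=(4, 2))
        got = float(cycle_loss(X, Y, DX, DY, m).data)
        assert got == pytest.approx(oracle_cycle(m, X, Y, DX, DY), rel=1e-8)


def test_identity_perfect_autoencoder():
    m = make_tiny_model()
    set_affine(m.enc_control, [[1.0], [0.0]], [0.0])
    set_affine(m.dec_treated, [[1.0, 0.0]], [0.0, 0.0])
    Y = np.array([[4.0, 0.0]])
    assert float(identity_loss(Y, m).data) == pytest.approx(0.0, abs=1e-12)


def test_identity_nonnegative_and_oracle(rng):
    for _ in range(10):
        m = random_model(rng)
        Y = rng.normal(size=(5, 3))
        got = float(identity_loss(Y, m).data)
        assert got >= 0.0
        assert got == pytest.approx(oracle_identity(m, Y), rel=1e-9)


# ---------------------------------------------------------------------------
# total loss
# ---------------------------------------------------------------------------


def test_total_all_zero():
    t, b = total_loss("unpaired", LossWeights(), reco=0.0, gan=0.0, cyc=0.0)
    assert float(t.data) == 0.0


def test_total_weighted_arithmetic():
    w = LossWeights(alpha=1.0, beta=1.0, lam=1.0, identity_weight=1.0)
    t, b = total_loss("unpaired", w, reco=2.0, gan=3.0, cyc=4.0)
    assert float(t.data) == pytest.approx(9.0)
    t2, _ = total_loss("unpaired", w, reco=2.0, gan=3.0, cyc=4.0, identity=1.5)
    assert float(t2.data) == pytest.approx(10.5)


def test_total_paired_even_weighting():
    t, b = total_loss("paired", LossWeights(), reco=2.0, paired_mse=5.0)
    assert float(t.data) == pytest.approx(7.0)
    assert b["reco"] == 2.0 and b["paired_mse"] == 5.0


def test_total_linear_in_weights():
    comps = dict(reco=1.3, gan=0.7, cyc=2.1, identity=0.4)
    w1 = LossWeights(alpha=1.0, beta=2.0, lam=3.0, identity_weight=0.5)
    w2 = LossWeights(alpha=2.0, beta=4.0, lam=6.0, identity_weight=1.0)
    t1, _ = total_loss("unpaired", w1, **comps)
    t2, _ = total_loss("unpaired", w2, **comps)
    assert float(t2.data) == pytest.approx(2 * float(t1.data), rel=1e-12)


def test_total_missing_component():
    with pytest.raises(LossError):
        total_loss("paired", LossWeights(), reco=1.0)
    with pytest.raises(LossError):
        total_loss("unpaired", LossWeights(), reco=1.0, gan=1.0)


def test_single_cell_default_weights_in_stated_ranges():
    # fine-tuning ranges for the single-cell regime
    from perturbcycle.losses import LossWeights

    w = LossWeights()  # package defaults for unpaired training
    assert 1.5 <= w.alpha <= 5.0
    assert 1.0 <= w.beta <= 4.0


def test_weights_validation():
    with pytest.raises(LossError):
        LossWeights(alpha=-1.0)
    with pytest.raises(LossError):
        LossWeights(lam=float("inf"))
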