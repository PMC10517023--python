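"""Autoencoder: losses against independent oracles, ramp schedule, training."""

import numpy as np
import pytest

from dispred import dae
from dispred.data_io import Cohort


def brute_force_supcon(z, labels, tau, normalize=True):
    """Independent double-sum implementation of the supervised contrastive
    loss on the duplicated batch, written with explicit Python loops."""
    import math

    z2 = np.vstack([z, z]).astype(float)
    lab2 = list(labels) + list(labels)
    if normalize:
        z2 = np.array([v / np.linalg.norm(v) for v in z2])
    n2 = len(z2)
    total = 0.0
    for i in range(n2):
        positives = [
            s for s in range(n2) if s != i and lab2[s] == lab2[i]
        ]
        inner = 0.0
        for s in positives:
            denom = sum(
                math.exp(float(z2[i] @ z2[r]) / tau) for r in range(n2) if r != i
            )
            inner += math.log(math.exp(float(z2[i] @ z2[s]) / tau) / denom)
        total += -inner / len(positives)
    return total


class TestSupervisedContrastiveLoss:
    def test_matches_brute_force_on_random_batches(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            d = int(rng.integers(2, 6))
            z = rng.normal(size=(n, d))
            labels = rng.integers(0, int(rng.integers(2, 4)), size=n)
            for normalize in (True, False):
                got = dae.supervised_contrastive_loss(z, labels, 0.1, normalize)
                want = brute_force_supcon(z, labels, 0.1, normalize)
                assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_identical_embeddings_closed_form(self, n):
        z = np.tile(np.array([[1.0, 2.0, -1.0]]), (n, 1))
        labels = np.arange(n) % 2
        expected = 2 * n * np.log(2 * n - 1)
        assert dae.supervised_contrastive_loss(z, labels, 0.03) == pytest.approx(
            expected, abs=1e-6
        )

    def test_batch_permutation_invariance(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(6, 4))
        labels = np.array([0, 1, 0, 2, 1, 2])
        base = dae.supervised_contrastive_loss(z, labels, 0.05)
        perm = rng.permutation(6)
        assert dae.supervised_contrastive_loss(
            z[perm], labels[perm], 0.05
        ) == pytest.approx(base, abs=1e-9)

    def test_rotation_invariance_of_normalized_loss(self):
        """Joint rotation preserves dot products, hence the loss."""
        rng = np.random.default_rng(4)
        z = rng.normal(size=(5, 3))
        labels = np.array([0, 0, 1, 1, 1])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        base = dae.supervised_contrastive_loss(z, labels, 0.1)
        rotated = dae.supervised_contrastive_loss(z @ q, labels, 0.1)
        assert rotated == pytest.approx(base, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            dae.supervised_contrastive_loss(np.ones((1, 3)), [0], 0.1)
        with pytest.raises(ValueError):
            dae.supervised_contrastive_loss(
                np.array([[np.inf, 0.0], [1.0, 0.0]]), [0, 1], 0.1
            )

    def test_gradient_matches_finite_differences(self):
        from dispred.dae import _supcon_core

        rng = np.random.default_rng(8)
        z = rng.normal(size=(4, 3))
        labels = np.array([0, 1, 1, 0])
        for normalize in (True, False):
            _, grad = _supcon_core(z, labels, 0.07, normalize)
            eps = 1e-6
            for i in range(4):
                for j in range(3):
                    zp, zm = z.copy(), z.copy()
                    zp[i, j] += eps
                    zm[i, j] -= eps
                    num = (
                        dae.supervised_contrastive_loss(zp, labels, 0.07, normalize)
                        - dae.supervised_contrastive_loss(zm, labels, 0.07, normalize)
                    ) / (2 * eps)
                    assert grad[i, j] == pytest.approx(num, abs=1e-5)


class TestRampSchedule:
    @pytest.mark.parametrize(
        "epoch, expected", [(1, 0.0), (100, 0.0), (175, 0.5), (250, 1.0), (400, 1.0)]
    )
    def test_default_schedule_values(self, epoch, expected):
        assert dae.ramp_weight(epoch, 100, 250) == expected

    def test_monotone_and_clamped(self):
        values = [dae.ramp_weight(e, 30, 80) for e in range(1, 151)]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_invalid_ramp(self):
        with pytest.raises(ValueError):
            dae.ramp_weight(10, 50, 20)


def test_reconstruction_loss_oracle():
    assert dae.reconstruction_loss(np.ones((2, 3)), np.ones((2, 3))) == 0.0
    assert dae.reconstruction_loss(np.array([[1.0]]), np.array([[0.0]])) == 1.0

    rng = np.random.default_rng(1)
    x, xh = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    total = 0.0
    for i in range(3):
        row = 0.0
        for j in range(4):
            row += (x[i, j] - xh[i, j]) ** 2
        total += row / 4
    assert dae.reconstruction_loss(x, xh) == pytest.approx(total / 3, abs=1e-10)
    with pytest.raises(ValueError):
        dae.reconstruction_loss(np.empty((0, 2)), np.empty((0, 2)))


def test_total_loss_recomposition():
    rng = np.random.default_rng(2)
    x, xh = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
    za, zd = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
    y = np.array([0, 1, 0, 1, 1])
    a = np.array(["p1", "p2", "p1", "p1", "p2"])
    hp = dae.AEHyperparams(dim_za=3, dim_zd=3, alpha_d=1e-4, alpha_a=1e-4)
    total, parts = dae.total_loss(x, xh, za, zd, y, a, hp, epoch=300)
    recomposed = (
        parts["recon"]
        + parts["ramp"] * hp.alpha_d * parts["sc_d"]
        + parts["ramp"] * hp.alpha_a * parts["sc_a"]
    )
    assert total == pytest.approx(recomposed, abs=1e-9)

    hp0 = dae.AEHyperparams(dim_za=3, dim_zd=3, alpha_d=0.0, alpha_a=0.0)
    total0, parts0 = dae.total_loss(x, xh, za, zd, y, a, hp0, epoch=300)
    assert total0 == parts0["recon"]


def _tiny_hp(**kw):
    defaults = dict(
        dim_za=4, dim_zd=4, encoder_hidden=(16, 12, 8), decoder_hidden=(8, 16),
        n_epochs=30, ramp_start=5, ramp_end=15, batch_size=32,
        alpha_d=0.01, alpha_a=0.01, seed=0,
    )
    defaults.update(kw)
    defaults["ramp_start"] = min(defaults["ramp_start"], defaults["n_epochs"])
    defaults["ramp_end"] = min(defaults["ramp_end"], defaults["n_epochs"])
    return dae.AEHyperparams(**defaults)


@pytest.fixture(scope="module")
def trained(small_train):
    return dae.train_dae(small_train, None, _tiny_hp())


@pytest.fixture(scope="module")
def small_train():
    from dispred import data_io, sim

    cfg = sim.SimulationConfig(
        n_individuals=200, n_snps=50, missing_rate=0.0, seed=13
    )
    cohort = sim.simulate_cohort(cfg).cohort
    return data_io.impute_missing(cohort)


class TestTraining:
    def test_hyperparam_defaults_match_tuned_configuration(self):
        hp = dae.AEHyperparams()
        assert (hp.dim_zd, hp.dim_za, hp.tau, hp.alpha_d) == (40, 40, 0.03, 1e-4)
        assert (hp.n_epochs, hp.ramp_start, hp.ramp_end) == (500, 100, 250)
        assert (hp.batch_size, hp.learning_rate) == (256, 5e-3)

    def test_reconstruction_improves(self, trained):
        assert trained.history[-1]["recon"] < trained.history[0]["recon"]

    def test_history_length_is_epoch_count(self, trained):
        assert len(trained.history) == 30

    def test_seeded_determinism(self, small_train):
        m1 = dae.train_dae(small_train, None, _tiny_hp(n_epochs=5))
        m2 = dae.train_dae(small_train, None, _tiny_hp(n_epochs=5))
        for p1, p2 in zip(m1.encoder.parameters, m2.encoder.parameters):
            assert np.array_equal(p1, p2)

    def test_missing_labels_rejected(self, small_train):
        from dataclasses import replace

        unlabelled = replace(small_train, a=None)
        with pytest.raises(ValueError, match="ancestry"):
            dae.train_dae(unlabelled, None, _tiny_hp())


class TestForwardAndEmbed:
    def test_forward_shapes_and_determinism(self, trained, small_train):
        xb = small_train.x[:7]
        za, zd, xh = dae.forward(trained, xb)
        assert za.shape == (7, 4) and zd.shape == (7, 4)
        assert xh.shape == xb.shape
        za2, zd2, xh2 = dae.forward(trained, xb)
        assert np.array_equal(xh, xh2)
        with pytest.raises(ValueError):
            dae.forward(trained, np.zeros((3, 99)))

    def test_default_latent_widths(self):
        model = dae.build_model(100, dae.AEHyperparams())
        za, zd, _ = dae.forward(model, np.zeros((2, 100)))
        assert za.shape[1] == 40 and zd.shape[1] == 40

    def test_embed_without_ancestry_labels(self, trained, small_train):
        from dataclasses import replace

        unlabelled = replace(small_train, a=None, y=None)
        za, zd = dae.embed(trained, unlabelled)
        assert za.shape[0] == unlabelled.n
        za2, zd2 = dae.embed(trained, unlabelled)
        assert np.array_equal(zd, zd2)
        with pytest.raises(ValueError, match="SNP"):
            dae.embed(
                trained,
                Cohort(ids=["q"], x=np.zeros((1, 3))),
            )

    def test_unit_norm_latents_live_on_the_sphere(self, small_train):
        hp = _tiny_hp(n_epochs=3, unit_norm_latents=True)
        model = dae.train_dae(small_train, None, hp)
        za, zd = dae.embed(model, small_train)
        assert np.allclose(np.linalg.norm(za, axis=1), 1.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(zd, axis=1), 1.0, atol=1e-9)


def test_model_save_load_round_trip(tmp_path, trained, small_train):
    path = tmp_path / "m.npz"
    dae.save_model(trained, path)
    back = dae.load_model(path)
    za1, zd1 = dae.embed(trained, small_train)
    za2, zd2 = dae.embed(back, small_train)
    assert np.array_equal(za1, za2) and np.array_equal(zd1, zd2)
    assert back.snp_fingerprint == trained.snp_fingerprint
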