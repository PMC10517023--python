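"""PRS clumping/scoring, Gaussian-naive-Bayes PRS, supervised network."""

import numpy as np
import pytest

from dispred import baselines
from dispred.data_io import SnpMeta
from dispred.eval import auc


def brute_force_clump(snps, x, r2_threshold, window_bp, anchors):
    """Independent greedy clumping, coded from the verbal rule with loops."""
    anchor_idx = {j for j, s in enumerate(snps) if s.snp_id in set(anchors)}
    candidates = sorted(
        (j for j in range(len(snps)) if j not in anchor_idx),
        key=lambda j: (snps[j].gwas_p, j),
    )
    removed = set()
    retained = []
    for j in candidates:
        if j in removed:
            continue
        retained.append(j)
        for k in candidates:
            if k in removed or k in retained or k == j:
                continue
            if snps[k].chrom != snps[j].chrom:
                continue
            if abs(snps[k].pos_bp - snps[j].pos_bp) > window_bp:
                continue
            if np.std(x[:, j]) == 0 or np.std(x[:, k]) == 0:
                continue
            r = np.corrcoef(x[:, j], x[:, k])[0, 1]
            if r * r > r2_threshold:
                removed.add(k)
    return sorted(set(retained) | anchor_idx)


def _snp(i, chrom="1", pos=None, p=0.01, beta=0.1, sid=None):
    return SnpMeta(
        snp_id=sid or f"s{i}",
        chrom=chrom,
        pos_bp=pos if pos is not None else (i + 1) * 1000,
        gwas_p=p,
        gwas_beta=beta,
    )


class TestClump:
    def test_hand_worked_three_snp_case(self):
        """SNP2 is in LD with the more significant SNP1 inside 1 MB; SNP3 is
        correlated but beyond the window and survives."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=500)
        x = np.column_stack([
            base,
            base + 0.3 * rng.normal(size=500),   # r2 with base ~ 0.9
            base + 0.3 * rng.normal(size=500),
        ])
        x = np.clip(x - x.min(), 0, 2)
        snps = [
            _snp(0, pos=1, p=1e-8),
            _snp(1, pos=500_001, p=1e-6),
            _snp(2, pos=2_000_001, p=1e-4),
        ]
        assert np.corrcoef(x[:, 0], x[:, 1])[0, 1] ** 2 > 0.5
        result = baselines.clump(snps, x, anchors=())
        assert result.retained == ["s0", "s2"]
        assert result.pruned == {"s1": "s0"}

    def test_different_chromosomes_never_prune(self):
        x = np.tile(np.array([[0.0], [1.0], [2.0], [1.0]]), (1, 2))
        snps = [_snp(0, chrom="1", pos=100, p=1e-8),
                _snp(1, chrom="2", pos=100, p=1e-4)]
        result = baselines.clump(snps, x, anchors=())
        assert result.retained == ["s0", "s1"]

    def test_anchor_always_retained(self):
        x = np.tile(np.array([[0.0], [1.0], [2.0], [1.0]]), (1, 2))
        snps = [
            _snp(0, pos=100, p=0.9, sid="rs429358"),
            _snp(1, pos=200, p=1e-8),
        ]
        result = baselines.clump(snps, x)
        assert "rs429358" in result.retained
        assert "rs429358" in result.anchors

    def test_missing_p_value_errors(self):
        snps = [SnpMeta(snp_id="s0", pos_bp=1), SnpMeta(snp_id="s1", pos_bp=2)]
        with pytest.raises(ValueError, match="p-value"):
            baselines.clump(snps, np.zeros((4, 2)), anchors=())

    def test_zero_variance_column_warns_and_is_kept(self):
        x = np.column_stack([np.ones(6), np.arange(6) % 3])
        snps = [_snp(0, pos=1, p=1e-6), _snp(1, pos=2, p=1e-4)]
        with pytest.warns(UserWarning, match="zero-variance"):
            result = baselines.clump(snps, x, anchors=())
        assert result.retained == ["s0", "s1"]

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            m = int(rng.integers(4, 21))
            n = 80
            latent = rng.normal(size=(n, 3))
            x = latent[:, rng.integers(0, 3, m)] + 0.6 * rng.normal(size=(n, m))
            x = np.clip(x - x.min(), 0, 2)
            snps = [
                _snp(j,
                     chrom=str(rng.integers(1, 3)),
                     pos=int(rng.integers(1, 3_000_000)),
                     p=float(rng.uniform(1e-9, 0.1)))
                for j in range(m)
            ]
            got = baselines.clump(snps, x, anchors=())
            want = brute_force_clump(snps, x, 0.5, 1_000_000, ())
            assert got.retained == [snps[j].snp_id for j in want], f"trial {trial}"
            # retained same-chromosome pairs within 1 MB are uncorrelated
            idx = {s.snp_id: j for j, s in enumerate(snps)}
            for a in got.retained:
                for b in got.retained:
                    ja, jb = idx[a], idx[b]
                    if ja >= jb or snps[ja].chrom != snps[jb].chrom:
                        continue
                    if abs(snps[ja].pos_bp - snps[jb].pos_bp) > 1_000_000:
                        continue
                    if np.std(x[:, ja]) == 0 or np.std(x[:, jb]) == 0:
                        continue  # correlation undefined; pruning skips these
                    r = np.corrcoef(x[:, ja], x[:, jb])[0, 1]
                    assert r * r <= 0.5 + 1e-12


class TestPrsScore:
    def test_trivial_values(self):
        snps = [_snp(0, beta=0.3)]
        assert baselines.prs_score(np.zeros((3, 1)), snps, ["s0"]).tolist() == [0, 0, 0]
        assert baselines.prs_score(np.array([[2.0]]), snps, ["s0"])[0] == pytest.approx(0.6)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=(10, 5)).astype(float)
        snps = [_snp(j, beta=float(rng.normal())) for j in range(5)]
        retained = ["s1", "s3", "s4"]
        got = baselines.prs_score(x, snps, retained)
        for i in range(10):
            expected = sum(
                snps[j].gwas_beta * x[i, j] for j in (1, 3, 4)
            )
            assert got[i] == pytest.approx(expected, abs=1e-10)

    def test_absent_snp_errors(self):
        with pytest.raises(ValueError, match="nope"):
            baselines.prs_score(np.zeros((2, 1)), [_snp(0)], ["nope"])


class TestPrsBayes:
    def test_symmetric_midpoint_posterior(self):
        """Equal-prior symmetric class conditionals give posterior 1/2 midway."""
        x = np.concatenate([np.full(50, 0.0), np.full(50, 2.0)])[:, None]
        y = np.array([0] * 50 + [1] * 50)
        model = baselines.fit_prs_bayes(x, y)
        assert model.predict_scores(np.array([[1.0]]))[0] == pytest.approx(0.5, abs=1e-6)

    def test_separated_classes_high_auc(self):
        rng = np.random.default_rng(2)
        n = 250
        y = rng.integers(0, 2, 2 * n)
        x = rng.normal(loc=np.where(y, 5.0, -5.0)[:, None], scale=1.0, size=(2 * n, 3))
        model = baselines.fit_prs_bayes(x, y)
        assert auc(model.predict_scores(x), y) > 0.99

    def test_uses_every_feature(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 7))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        assert baselines.fit_prs_bayes(x, y).n_features == 7

    def test_feature_reordering_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(80, 5))
        y = (x[:, 0] > 0).astype(int)
        perm = rng.permutation(5)
        m1 = baselines.fit_prs_bayes(x, y)
        m2 = baselines.fit_prs_bayes(x[:, perm], y)
        probe = rng.normal(size=(10, 5))
        assert np.allclose(
            m1.predict_scores(probe), m2.predict_scores(probe[:, perm]), atol=1e-10
        )


class TestNN:
    def test_defaults(self):
        hp = baselines.NNHyperparams()
        assert (hp.epochs, hp.learning_rate, hp.batch_size) == (200, 5e-3, 64)

    def test_loss_decreases_on_separable_toy(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        x = np.clip(rng.normal(loc=np.where(y, 1.6, 0.4)[:, None], size=(200, 4)), 0, 2)
        hp = baselines.NNHyperparams(epochs=30, seed=1, hidden=(16,))
        model = baselines.train_nn(x, y, hp)
        assert model.history[-1] < model.history[0]
        assert auc(model.predict_scores(x), y) > 0.8

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        x = np.clip(rng.normal(1, 0.5, size=(50, 3)), 0, 2)
        y = rng.integers(0, 2, 50)
        hp = baselines.NNHyperparams(epochs=5, seed=9, hidden=(8,))
        m1 = baselines.train_nn(x, y, hp)
        m2 = baselines.train_nn(x, y, hp)
        for p1, p2 in zip(m1.net.parameters, m2.net.parameters):
            assert np.array_equal(p1, p2)
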