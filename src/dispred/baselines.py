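"""Comparison methods: PRS by clumping with APOE anchoring, PRS scoring,
Gaussian-naive-Bayes PRS, and a supervised feed-forward network.

Clumping thins the SNP set greedily by GWAS significance so that retained
SNPs are approximately independent: within a physical window on the same
chromosome, neighbours in strong linkage (squared Pearson correlation of
dosages above the threshold) with a more significant retained SNP are
dropped.  The two APOE variants (rs429358, rs7412) are kept unconditionally
as anchors of the Alzheimer's-disease score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from ._mlp import MLP, Adam
from .data_io import SnpMeta

__all__ = [
    "ClumpResult",
    "NNHyperparams",
    "PrsBayesModel",
    "NNModel",
    "clump",
    "prs_score",
    "fit_prs_bayes",
    "train_nn",
]

APOE_SNPS = ("rs429358", "rs7412")


@dataclass
class ClumpResult:
    retained: list[str]
    anchors: list[str]
    pruned: dict[str, str] = field(default_factory=dict)  # removed -> remover


@dataclass(frozen=True)
class NNHyperparams:
    epochs: int = 200
    learning_rate: float = 5e-3
    batch_size: int = 64
    hidden: tuple[int, ...] = (64, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden widths must be positive")


def clump(
    snps: list[SnpMeta],
    dosage_matrix: np.ndarray,
    r2_threshold: float = 0.5,
    window_bp: int = 1_000_000,
    anchors: tuple[str, ...] = APOE_SNPS,
    anchors_prune: bool = False,
) -> ClumpResult:
    """Greedy LD clumping with unconditionally retained anchor SNPs.

    Non-anchor SNPs are processed in ascending GWAS p-value order: the most
    significant SNP still unremoved is retained, and every not-yet-processed
    SNP on the same chromosome within ``window_bp`` whose squared Pearson
    correlation with it exceeds ``r2_threshold`` is removed.  Anchors are
    always retained; by default they do not themselves prune neighbours
    (``anchors_prune=True`` makes them act as the first, most significant
    index SNPs).  Zero-variance dosage columns have undefined correlation
    and are skipped from pruning with a warning.
    """
    x = np.asarray(dosage_matrix, dtype=float)
    if x.shape[1] != len(snps):
        raise ValueError("dosage columns must align with the SNP list")
    anchor_idx = [j for j, s in enumerate(snps) if s.snp_id in set(anchors)]
    others = [j for j in range(len(snps)) if j not in set(anchor_idx)]
    for j in others:
        if snps[j].gwas_p is None:
            raise ValueError(f"SNP {snps[j].snp_id} lacks a GWAS p-value")

    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance dosage columns skipped "
            "from LD pruning",
            stacklevel=2,
        )
    xc = x - x.mean(axis=0)
    safe_sd = np.where(degenerate, 1.0, sd)

    def r2(i: int, j: int) -> float:
        if degenerate[i] or degenerate[j]:
            return 0.0
        r = (xc[:, i] @ xc[:, j]) / (len(x) * safe_sd[i] * safe_sd[j])
        return r * r

    removed: dict[int, int] = {}
    retained: list[int] = []
    queue = sorted(others, key=lambda j: (snps[j].gwas_p, j))
    if anchors_prune:
        # Anchors lead the queue as index SNPs but are retained regardless.
        queue = anchor_idx + queue
    for j in queue:
        if j in removed:
            continue
        retained.append(j)
        for k in queue:
            if k == j or k in removed or k in retained or k in anchor_idx:
                continue
            if snps[k].chrom != snps[j].chrom:
                continue
            if abs(snps[k].pos_bp - snps[j].pos_bp) > window_bp:
                continue
            if r2(j, k) > r2_threshold:
                removed[k] = j
    if not anchors_prune:
        retained = anchor_idx + retained
    kept_order = sorted(set(retained))
    return ClumpResult(
        retained=[snps[j].snp_id for j in kept_order],
        anchors=[snps[j].snp_id for j in anchor_idx],
        pruned={snps[k].snp_id: snps[j].snp_id for k, j in removed.items()},
    )


def prs_score(
    dosage_matrix: np.ndarray, snps: list[SnpMeta], retained: list[str]
) -> np.ndarray:
    """Weighted sum of risk-allele dosages over the retained SNPs."""
    x = np.asarray(dosage_matrix, dtype=float)
    index = {s.snp_id: j for j, s in enumerate(snps)}
    missing = [sid for sid in retained if sid not in index]
    if missing:
        raise ValueError(f"retained SNPs absent from the cohort: {missing}")
    cols = [index[sid] for sid in retained]
    betas = []
    for sid, j in zip(retained, cols):
        if snps[j].gwas_beta is None:
            raise ValueError(f"SNP {sid} lacks a GWAS effect size")
        betas.append(snps[j].gwas_beta)
    return x[:, cols] @ np.asarray(betas, dtype=float)


@dataclass
class PrsBayesModel:
    """Gaussian naive Bayes over all SNPs; scores are case posteriors."""

    clf: GaussianNB
    var_smoothing: float
    n_features: int

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(np.asarray(x, dtype=float))[:, 1]


def fit_prs_bayes(
    x: np.ndarray, y: np.ndarray, cv_folds: int = 5, seed: int = 0
) -> PrsBayesModel:
    """Gaussian naive Bayes with CV-selected variance smoothing.

    The only free hyperparameter is the variance-smoothing floor (which also
    guards zero-variance features); it is chosen on a small logarithmic grid
    by mean 5-fold cross-validated AUC.  All SNPs enter the model — no
    sparsity is induced.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit")
    grid = np.logspace(-11, -3, 5)
    folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_vs, best_auc = grid[0], -np.inf
    for vs in grid:
        fold_aucs = []
        for tr, te in folds.split(x, y):
            clf = GaussianNB(var_smoothing=vs).fit(x[tr], y[tr])
            fold_aucs.append(roc_auc_score(y[te], clf.predict_proba(x[te])[:, 1]))
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_auc:
            best_vs, best_auc = float(vs), mean_auc
    clf = GaussianNB(var_smoothing=best_vs).fit(x, y)
    return PrsBayesModel(clf=clf, var_smoothing=best_vs, n_features=x.shape[1])


@dataclass
class NNModel:
    net: MLP
    hyperparams: NNHyperparams
    history: list[float] = field(default_factory=list)  # per-epoch mean loss

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        logits = self.net.forward(np.asarray(x, dtype=float))[:, 0]
        return 1.0 / (1.0 + np.exp(-logits))


def train_nn(x: np.ndarray, y: np.ndarray, hp: NNHyperparams) -> NNModel:
    """Supervised feed-forward classifier on raw dosages.

    ReLU hidden layers, a scalar sigmoid output, binary cross-entropy, Adam
    with a constant learning rate, shuffled mini-batches; fully seeded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any():
        raise ValueError("dosages must be imputed before training")
    rng = np.random.default_rng(hp.seed)
    net = MLP((x.shape[1], *hp.hidden, 1), rng)
    opt = Adam(net.parameters, net.gradients, lr=hp.learning_rate)
    model = NNModel(net=net, hyperparams=hp)
    n = len(y)
    for _ in range(hp.epochs):
        order = rng.permutation(n)
        total, n_batches = 0.0, 0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb = x[idx], y[idx]
            logits = net.forward(xb)[:, 0]
            s = 1.0 / (1.0 + np.exp(-logits))
            eps = 1e-12
            loss = -np.mean(yb * np.log(s + eps) + (1 - yb) * np.log(1 - s + eps))
            net.zero_grad()
            net.backward(((s - yb) / len(yb))[:, None])
            opt.step()
            total += float(loss)
            n_batches += 1
        model.history.append(total / max(n_batches, 1))
    return model
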