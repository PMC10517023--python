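"""Canned synthetic-cohort experiments.

Two study designs drive validation of the disentangling pipeline, both on
simulated three-population admixed cohorts:

* :func:`probe_recovery_trial` — the latent-recovery design: train the
  autoencoder, then measure with linear probes whether population structure
  concentrates in the ancestry block z_a and stays out of the phenotype
  block z_d, and whether z_d still predicts the phenotype.

* :func:`crosspop_trial` — the transfer design: train every model only on
  individuals assignable to two source populations, evaluate on the held-out
  admixed individuals, and compare the ensemble's AUC with the raw-dosage
  Lasso's.

The autoencoder settings used here (latent weights 0.01, temperature 0.03,
250 epochs with the contrastive ramp over epochs 30-80, unit-norm latent
blocks) are the package's tuned configuration for cohorts of this scale;
see the methods note for how they were chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dae, data_io, predict, sim
from .eval import auc, probe_disentanglement

__all__ = ["ProbeRecoveryResult", "CrossPopResult", "probe_recovery_trial", "crosspop_trial"]

SYNTHETIC_DAE = dict(
    tau=0.03,
    alpha_d=0.01,
    alpha_a=0.01,
    n_epochs=250,
    ramp_start=30,
    ramp_end=80,
    unit_norm_latents=True,
)


@dataclass
class ProbeRecoveryResult:
    ancestry_acc_za: float
    ancestry_acc_zd: float
    phenotype_acc_zd: float
    ancestry_chance: float
    phenotype_chance: float

    @property
    def recovered(self) -> bool:
        """Ancestry clusters in z_a, not in z_d; z_d still carries phenotype."""
        return (
            self.ancestry_acc_za >= 0.9
            and self.ancestry_acc_zd <= self.ancestry_chance + 0.15
            and self.phenotype_acc_zd > self.phenotype_chance
        )


@dataclass
class CrossPopResult:
    auc_dispred: float
    auc_lasso: float
    n_train: int
    n_test: int


def _prepare(config: sim.SimulationConfig):
    cohort = sim.simulate_cohort(config).cohort
    cohort = data_io.filter_by_missingness(cohort)
    return data_io.impute_missing(cohort)


def probe_recovery_trial(
    seed: int,
    config: sim.SimulationConfig | None = None,
    n_epochs: int = SYNTHETIC_DAE["n_epochs"],
) -> ProbeRecoveryResult:
    """Train on one simulated cohort and probe both latent blocks.

    Chance levels are the majority-class fractions of the test labels.
    """
    if config is None:
        config = sim.SimulationConfig(seed=seed)
    cohort = _prepare(config)
    train, val, test = data_io.stratified_split(
        cohort, data_io.SplitSpec(seed=seed)
    )
    hp = dae.AEHyperparams(**{**SYNTHETIC_DAE, "n_epochs": n_epochs}, seed=seed)
    model = dae.train_dae(train, val, hp)
    za, zd = dae.embed(model, test)
    _, anc_counts = np.unique(test.a, return_counts=True)
    return ProbeRecoveryResult(
        ancestry_acc_za=probe_disentanglement(za, test.a, seed),
        ancestry_acc_zd=probe_disentanglement(zd, test.a, seed),
        phenotype_acc_zd=probe_disentanglement(zd, test.y, seed),
        ancestry_chance=float(anc_counts.max() / anc_counts.sum()),
        phenotype_chance=float(max(test.y.mean(), 1.0 - test.y.mean())),
    )


def crosspop_trial(
    seed: int,
    n_individuals: int = 1500,
    n_snps: int = 300,
    n_epochs: int = 120,
    cutoff: float = 0.9,
) -> CrossPopResult:
    """Two-population training, admixed-individual testing.

    Individuals whose ancestry proportion exceeds ``cutoff`` for population
    1 or 2 form the training pool (split into train/validation, phenotype-
    stratified); the admixed group — no proportion above the cutoff — is the
    test set.  The ensemble (latent OLS + raw Lasso, grid-searched weights)
    is compared against the Lasso alone on the admixed test AUC.
    """
    config = sim.SimulationConfig(
        n_individuals=n_individuals, n_snps=n_snps, seed=seed
    )
    cohort = _prepare(config)
    groups = data_io.ancestry_groups(cohort.proportions, cutoff)
    pool_idx = np.flatnonzero((groups == "pop1") | (groups == "pop2"))
    test_idx = np.flatnonzero(groups == "admixed")
    pool = cohort.subset(pool_idx)
    test = cohort.subset(test_idx)

    spec = data_io.SplitSpec(train=0.8, validation=0.15, test=0.05, seed=seed)
    train, val, _ = data_io.stratified_split(pool, spec)

    hp = dae.AEHyperparams(**{**SYNTHETIC_DAE, "n_epochs": n_epochs}, seed=seed)
    model = dae.train_dae(train, val, hp)
    _, zd_tr = dae.embed(model, train)
    _, zd_va = dae.embed(model, val)
    _, zd_te = dae.embed(model, test)

    latent = predict.fit_latent_regressor(zd_tr, train.y)
    lasso = predict.fit_lasso_raw(train.x, train.y)
    weights = predict.grid_search_weights(
        latent.predict(zd_va), lasso.predict(val.x), val.y
    )
    p_e = predict.ensemble_predict(
        latent.predict(zd_te), lasso.predict(test.x), weights.alpha, weights.beta
    )
    return CrossPopResult(
        auc_dispred=auc(p_e, test.y),
        auc_lasso=auc(lasso.predict(test.x), test.y),
        n_train=train.n,
        n_test=test.n,
    )
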