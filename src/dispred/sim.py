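"""Synthetic admixed cohorts: Balding–Nichols drift, Dirichlet admixture,
liability-threshold phenotypes, and injected missingness.

The generator produces the structure that cross-ancestry risk prediction has
to contend with: K source populations whose allele frequencies have drifted
apart (Balding–Nichols with per-population FST), individuals whose genomes
mix those populations in Dirichlet-distributed proportions, a polygenic
liability shared across populations, and an optional per-population liability
shift that confounds ancestry with disease status.  Every stage is seeded
independently (fixed offsets from the config seed) so cohorts are bit-
reproducible and stages can be rerun in isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .data_io import Cohort, SnpMeta, write_cohort_dir

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "draw_population_frequencies",
    "draw_admixture",
    "simulate_genotypes",
    "simulate_phenotype",
    "inject_missingness",
    "simulate_cohort",
    "write_simulated_cohort",
]

# Fixed offsets added to the config seed, one per random stage.
_SEED_FREQS = 11
_SEED_ADMIX = 23
_SEED_GENO = 37
_SEED_EFFECTS = 53
_SEED_PHENO = 71
_SEED_MISS = 89

# SNPs are laid out on one synthetic chromosome at this spacing so that
# physical-window operations (clumping) see realistic within-window pairs.
_BP_SPACING = 100_000


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic admixed cohort.

    ``fst`` may be a single drift value shared by all populations or a
    per-population sequence.  ``dirichlet_alpha`` likewise accepts a scalar
    (symmetric Dirichlet) or a length-K vector.  ``confound_strength`` scales
    a fixed per-population liability shift; at 0 ancestry carries no signal
    about the phenotype beyond the causal SNPs.
    """

    n_individuals: int = 2000
    n_snps: int = 500
    n_populations: int = 3
    fst: float | tuple[float, ...] = 0.1
    dirichlet_alpha: float | tuple[float, ...] = 0.2
    n_causal: int = 20
    effect_sd: float = 0.35
    prevalence: float = 0.5
    confound_strength: float = 1.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_snps", "n_populations", "n_causal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if np.any(np.asarray(self.fst_vector) <= 0) or np.any(
            np.asarray(self.fst_vector) >= 1
        ):
            raise ValueError(f"fst must lie in (0, 1), got {self.fst}")
        if np.any(np.asarray(self.alpha_vector) <= 0):
            raise ValueError(f"dirichlet_alpha must be strictly positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be non-negative")

    @property
    def fst_vector(self) -> np.ndarray:
        v = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if v.size == 1:
            v = np.repeat(v, self.n_populations)
        if v.size != self.n_populations:
            raise ValueError("fst must be scalar or length n_populations")
        return v

    @property
    def alpha_vector(self) -> np.ndarray:
        v = np.atleast_1d(np.asarray(self.dirichlet_alpha, dtype=float))
        if v.size == 1:
            v = np.repeat(v, self.n_populations)
        if v.size != self.n_populations:
            raise ValueError("dirichlet_alpha must be scalar or length n_populations")
        return v


@dataclass
class SimulatedCohort:
    """A cohort with its generative ground truth attached."""

    cohort: Cohort
    admixture_q: np.ndarray
    pop_freqs: np.ndarray
    causal_effects: np.ndarray
    liabilities: np.ndarray


def draw_population_frequencies(config: SimulationConfig) -> np.ndarray:
    """Draw a K x m matrix of drifted allele frequencies.

    Ancestral frequencies are uniform on [0.05, 0.95]; each population's
    frequency is Balding–Nichols, i.e. Beta(p(1-F)/F, (1-p)(1-F)/F) with the
    population's drift parameter F, then clipped to [0.01, 0.99] so no SNP is
    monomorphic (degenerate columns would break correlation-based clumping).
    """
    rng = np.random.default_rng(config.seed + _SEED_FREQS)
    p = rng.uniform(0.05, 0.95, size=config.n_snps)
    fst = config.fst_vector
    freqs = np.empty((config.n_populations, config.n_snps))
    for k in range(config.n_populations):
        f = fst[k]
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        freqs[k] = rng.beta(a, b)
    return np.clip(freqs, 0.01, 0.99)


def draw_admixture(config: SimulationConfig) -> np.ndarray:
    """Draw per-individual ancestry proportions, i.i.d. Dirichlet rows."""
    if config.n_populations == 1:
        return np.ones((config.n_individuals, 1))
    rng = np.random.default_rng(config.seed + _SEED_ADMIX)
    q = rng.dirichlet(config.alpha_vector, size=config.n_individuals)
    return q


def simulate_genotypes(
    pop_freqs: np.ndarray, admixture_q: np.ndarray, seed: int
) -> np.ndarray:
    """Draw dosages: Binomial(2, mixture frequency) independently per entry.

    Individual i's frequency at SNP j is the admixture-weighted average of
    the population frequencies, q_i . p_j.
    """
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    if pop_freqs.min() < 0 or pop_freqs.max() > 1:
        raise ValueError("population frequencies must lie in [0, 1]")
    if admixture_q.shape[1] != pop_freqs.shape[0]:
        raise ValueError("admixture columns must match the number of populations")
    rng = np.random.default_rng(seed)
    mix = admixture_q @ pop_freqs
    return rng.binomial(2, mix).astype(float)


def draw_causal_effects(config: SimulationConfig) -> np.ndarray:
    """Pick the causal set and draw N(0, effect_sd^2) effects; zeros elsewhere."""
    rng = np.random.default_rng(config.seed + _SEED_EFFECTS)
    beta = np.zeros(config.n_snps)
    causal = rng.choice(config.n_snps, size=config.n_causal, replace=False)
    beta[causal] = rng.normal(0.0, config.effect_sd, size=config.n_causal)
    return beta


def _population_shifts(k: int) -> np.ndarray:
    """Fixed per-population liability shifts, evenly spaced and centred at 0."""
    if k == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, k)


def simulate_phenotype(
    dosage_matrix: np.ndarray,
    causal_effects: np.ndarray,
    admixture_q: np.ndarray,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Liability-threshold phenotype with an optional ancestry confounder.

    liability_i = sum_j beta_j g_ij + confound_strength * (q_i . c) + eps_i,
    eps ~ N(0, 1), with c a fixed per-population shift.  Cases are the
    individuals above the empirical (1 - prevalence) liability quantile, so
    the realised case fraction matches the target exactly up to rounding.
    """
    if np.isnan(dosage_matrix).any():
        raise ValueError("phenotype simulation requires complete dosages")
    rng = np.random.default_rng(config.seed + _SEED_PHENO)
    c = _population_shifts(admixture_q.shape[1])
    liab = (
        dosage_matrix @ causal_effects
        + config.confound_strength * (admixture_q @ c)
        + rng.standard_normal(dosage_matrix.shape[0])
    )
    threshold = np.quantile(liab, 1.0 - config.prevalence)
    labels = (liab > threshold).astype(int)
    return labels, liab


def inject_missingness(
    dosage_matrix: np.ndarray, missing_rate: float, seed: int
) -> np.ndarray:
    """Set each entry to nan independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError(f"missing_rate must be in [0, 1], got {missing_rate}")
    rng = np.random.default_rng(seed)
    out = dosage_matrix.astype(float).copy()
    mask = rng.random(out.shape) < missing_rate
    out[mask] = np.nan
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generative chain and package the result as a Cohort.

    Self-reported ancestry labels are the argmax of each admixture row,
    mirroring how self-report tracks majority ancestry.  Missingness is
    injected after the phenotype is computed from complete genotypes.
    """
    pop_freqs = draw_population_frequencies(config)
    q = draw_admixture(config)
    g = simulate_genotypes(pop_freqs, q, config.seed + _SEED_GENO)
    beta = draw_causal_effects(config)
    y, liab = simulate_phenotype(g, beta, q, config)
    x = inject_missingness(g, config.missing_rate, config.seed + _SEED_MISS)
    n, m = x.shape
    ids = [f"ind{i:06d}" for i in range(n)]
    snps = [
        SnpMeta(
            snp_id=f"snp{j:05d}",
            chrom="1",
            pos_bp=(j + 1) * _BP_SPACING,
            effect_allele="A",
        )
        for j in range(m)
    ]
    a = np.array([f"pop{k + 1}" for k in q.argmax(axis=1)], dtype=object)
    cohort = Cohort(ids=ids, x=x, y=y, a=a, proportions=q, snps=snps)
    return SimulatedCohort(
        cohort=cohort,
        admixture_q=q,
        pop_freqs=pop_freqs,
        causal_effects=beta,
        liabilities=liab,
    )


def write_simulated_cohort(sim: SimulatedCohort, outdir: str | os.PathLike) -> None:
    """Write the cohort files plus the ground-truth effect table."""
    import pandas as pd

    write_cohort_dir(sim.cohort, outdir)
    truth = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in sim.cohort.snps],
            "beta": sim.causal_effects,
        }
    )
    truth.to_csv(
        os.path.join(str(outdir), "truth.tsv"), sep="\t", index=False,
        float_format="%.10g",
    )
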