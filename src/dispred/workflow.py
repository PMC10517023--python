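"""End-to-end orchestration: simulate or load a cohort, QC, split, train the
disentangling autoencoder, build the three-stage predictor, run the
baselines, and evaluate stratified by ancestry and along the heterogeneity
windows — all driven by one YAML-able config and one global seed.

Per-stage seeds are derived from the global seed with fixed offsets so any
stage can be rerun in isolation and the full run is bit-reproducible.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import baselines, dae, data_io, predict, sim
from .baselines import NNHyperparams
from .dae import AEHyperparams
from .eval import EvalReport, auc, heterogeneity_order, probe_disentanglement, sliding_window_eval

__all__ = ["RunConfig", "run_dispred", "load_run_config", "gwas_from_training"]

logger = logging.getLogger("dispred")

_SEED_SPLIT = 101
_SEED_DAE = 211
_SEED_NN = 307
_SEED_PROBE = 401


@dataclass
class RunConfig:
    """One reproduction run: data source, QC, model and evaluation settings.

    Exactly one of ``simulation`` (a :class:`~dispred.sim.SimulationConfig`)
    or ``input_dir`` (a cohort directory on disk) must be given.
    """

    simulation: sim.SimulationConfig | None = None
    input_dir: str | None = None
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    max_missing: float = 0.10
    ancestry_cutoff: float = 0.90
    dae: AEHyperparams = field(default_factory=AEHyperparams)
    lasso_n_alphas: int = 10
    weight_search: str = "grid"  # or "gradient"
    baselines: tuple[str, ...] = ("prs_clumping", "prs_bayes", "prs_lasso", "nn")
    nn: NNHyperparams = field(default_factory=NNHyperparams)
    window: int = 750
    stride: int = 50
    seed: int = 0
    out_dir: str = "dispred_run"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of 'simulation' and 'input_dir' must be set"
            )


def load_run_config(path: str) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = dict(raw)
    if "simulation" in kwargs and kwargs["simulation"] is not None:
        sim_kw = dict(kwargs["simulation"])
        for key in ("fst", "dirichlet_alpha"):
            if isinstance(sim_kw.get(key), list):
                sim_kw[key] = tuple(sim_kw[key])
        kwargs["simulation"] = sim.SimulationConfig(**sim_kw)
    if "dae" in kwargs:
        dae_kw = dict(kwargs["dae"])
        for key in ("encoder_hidden", "decoder_hidden"):
            if isinstance(dae_kw.get(key), list):
                dae_kw[key] = tuple(dae_kw[key])
        kwargs["dae"] = dae.AEHyperparams(**dae_kw)
    if "nn" in kwargs:
        nn_kw = dict(kwargs["nn"])
        if isinstance(nn_kw.get("hidden"), list):
            nn_kw["hidden"] = tuple(nn_kw["hidden"])
        kwargs["nn"] = baselines.NNHyperparams(**nn_kw)
    for key in ("split", "baselines"):
        if isinstance(kwargs.get(key), list):
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def gwas_from_training(train: data_io.Cohort) -> list[data_io.SnpMeta]:
    """Marginal per-SNP association on the training cohort.

    Fills each SNP's ``gwas_beta``/``gwas_p`` with the slope and two-sided
    p-value of the simple linear regression of the phenotype on that SNP's
    dosage — the individual-level analogue of an external GWAS weight table,
    used by the PRS baselines when no published table is supplied.
    """
    from scipy import stats

    x = train.x
    y = train.y.astype(float)
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (n * np.where(sx == 0, np.inf, sx) * sy)
        beta = r * sy / np.where(sx == 0, np.inf, sx)
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    out = []
    for j, s in enumerate(train.snps):
        out.append(
            data_io.SnpMeta(
                snp_id=s.snp_id,
                chrom=s.chrom,
                pos_bp=s.pos_bp,
                effect_allele=s.effect_allele,
                gwas_beta=float(np.nan_to_num(beta[j])),
                gwas_p=float(p[j]),
            )
        )
    return out


def _derive(cfg: RunConfig, offset: int) -> int:
    return (cfg.seed + offset) % (2**31 - 1)


def run_dispred(cfg: RunConfig) -> EvalReport:
    """Execute the full pipeline and write every artifact under ``out_dir``.

    Stages: simulate/load -> missingness filter -> mean imputation ->
    phenotype-stratified split -> autoencoder training -> latent OLS (p_z)
    -> raw-dosage Lasso (p_x) -> ensemble weight search on validation ->
    ensemble on test -> enabled baselines -> ancestry-stratified and
    sliding-window evaluation.  Rerunning with the same config is
    byte-identical.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    _log_to(os.path.join(cfg.out_dir, "run.log"))

    stage = "simulate/load"
    try:
        if cfg.simulation is not None:
            simulated = sim.simulate_cohort(cfg.simulation)
            cohort = simulated.cohort
            sim.write_simulated_cohort(simulated, os.path.join(cfg.out_dir, "cohort"))
        else:
            cohort = data_io.read_cohort_dir(cfg.input_dir)
        logger.info("stage=%s n=%d m=%d", stage, cohort.n, cohort.m)

        stage = "qc"
        cohort = data_io.filter_by_missingness(cohort, cfg.max_missing)
        cohort = data_io.impute_missing(cohort)
        logger.info("stage=%s m_after_filter=%d", stage, cohort.m)

        stage = "split"
        spec = data_io.SplitSpec(*cfg.split, seed=_derive(cfg, _SEED_SPLIT))
        train, val, test = data_io.stratified_split(cohort, spec)
        logger.info(
            "stage=%s train=%d val=%d test=%d", stage, train.n, val.n, test.n
        )

        stage = "train_dae"
        hp = dae.AEHyperparams(
            **{**asdict(cfg.dae), "seed": _derive(cfg, _SEED_DAE)}
        )
        model = dae.train_dae(train, val, hp)
        dae.save_model(model, os.path.join(cfg.out_dir, "model.ckpt.npz"))
        for i, rec in enumerate(model.history):
            if (i + 1) % 25 == 0 or i == 0:
                logger.info(
                    "stage=%s epoch=%d recon=%.5f sc_d=%.2f sc_a=%.2f",
                    stage, i + 1, rec["recon"], rec["sc_d"], rec["sc_a"],
                )

        stage = "embed"
        za_tr, zd_tr = dae.embed(model, train)
        za_va, zd_va = dae.embed(model, val)
        za_te, zd_te = dae.embed(model, test)

        stage = "fit_latent_regressor"
        latent_model = predict.fit_latent_regressor(zd_tr, train.y)

        stage = "fit_lasso_raw"
        lasso = predict.fit_lasso_raw(
            train.x, train.y, n_alphas=cfg.lasso_n_alphas
        )

        stage = "weight_search"
        pz_val = latent_model.predict(zd_va)
        px_val = lasso.predict(val.x)
        if cfg.weight_search == "grid":
            weights = predict.grid_search_weights(pz_val, px_val, val.y)
        else:
            weights = predict.gradient_search_weights(pz_val, px_val, val.y)
        logger.info(
            "stage=%s alpha=%.3f beta=%.3f val_auc=%.4f",
            stage, weights.alpha, weights.beta, weights.achieved_validation_auc,
        )

        stage = "score_test"
        pz_te = latent_model.predict(zd_te)
        px_te = lasso.predict(test.x)
        pe_te = predict.ensemble_predict(pz_te, px_te, weights.alpha, weights.beta)
        scores: dict[str, np.ndarray] = {"dispred": pe_te, "prs_lasso": px_te}

        stage = "baselines"
        if "prs_clumping" in cfg.baselines:
            gwas = gwas_from_training(train)
            clumped = baselines.clump(gwas, train.x)
            scores["prs_clumping"] = baselines.prs_score(
                test.x, gwas, clumped.retained
            )
        if "prs_bayes" in cfg.baselines:
            bayes = baselines.fit_prs_bayes(train.x, train.y, seed=cfg.seed)
            scores["prs_bayes"] = bayes.predict_scores(test.x)
        if "nn" in cfg.baselines:
            nn_hp = baselines.NNHyperparams(
                **{
                    **{k: getattr(cfg.nn, k) for k in cfg.nn.__dataclass_fields__},
                    "hidden": tuple(cfg.nn.hidden),
                    "seed": _derive(cfg, _SEED_NN),
                }
            )
            nn = baselines.train_nn(train.x, train.y, nn_hp)
            scores["nn"] = nn.predict_scores(test.x)

        stage = "evaluate"
        report = EvalReport(overall_auc={})
        for name, s in scores.items():
            report.overall_auc[name] = auc(s, test.y)
        if test.proportions is not None:
            groups = data_io.ancestry_groups(test.proportions, cfg.ancestry_cutoff)
            for g in sorted(set(groups)):
                mask = groups == g
                if len(np.unique(test.y[mask])) < 2:
                    continue
                report.group_auc[g] = {
                    name: auc(s[mask], test.y[mask]) for name, s in scores.items()
                }
            order = heterogeneity_order(test.proportions)
            window = min(cfg.window, test.n)
            report.windows = sliding_window_eval(
                order, scores, test.y, test.proportions,
                window=window, stride=cfg.stride,
            )

        stage = "probes"
        probe_seed = _derive(cfg, _SEED_PROBE)
        probes = {}
        if test.a is not None:
            probes["ancestry_on_za"] = probe_disentanglement(za_te, test.a, probe_seed)
            probes["ancestry_on_zd"] = probe_disentanglement(zd_te, test.a, probe_seed)
        probes["phenotype_on_zd"] = probe_disentanglement(zd_te, test.y, probe_seed)

        stage = "write_artifacts"
        _write_outputs(cfg, test, scores, pz_te, weights, report, probes)
        return report
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_outputs(cfg, test, scores, pz_te, weights, report, probes) -> None:
    out = cfg.out_dir
    df = pd.DataFrame({"id": test.ids, "p_z": pz_te})
    df["p_x"] = scores["prs_lasso"]
    df["p_e"] = scores["dispred"]
    for name, s in scores.items():
        if name not in ("dispred", "prs_lasso"):
            df[name] = s
    df.to_csv(os.path.join(out, "scores.tsv"), sep="\t", index=False,
              float_format="%.10g")
    with open(os.path.join(out, "weights.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "alpha": round(weights.alpha, 10),
                "beta": round(weights.beta, 10),
                "search_method": weights.search_method,
                "achieved_validation_auc": round(
                    weights.achieved_validation_auc, 10
                ),
            },
            fh, sort_keys=True,
        )
    summary = {
        "overall_auc": {k: round(v, 10) for k, v in report.overall_auc.items()},
        "group_auc": {
            g: {k: round(v, 10) for k, v in d.items()}
            for g, d in report.group_auc.items()
        },
        "probes": {k: round(v, 10) for k, v in probes.items()},
        "seed": cfg.seed,
    }
    with open(os.path.join(out, "report.yaml"), "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    if report.windows:
        rows = []
        for w in report.windows:
            row = {"window": w["window"], "start": w["start"]}
            for i, q in enumerate(w["mean_proportions"]):
                row[f"q{i + 1}"] = q
            for name, v in w["auc"].items():
                row[f"auc_{name}"] = v
            rows.append(row)
        pd.DataFrame(rows).to_csv(
            os.path.join(out, "windows.tsv"), sep="\t", index=False,
            float_format="%.10g", na_rep="NA",
        )


def _log_to(path: str) -> None:
    # Reconfigure the file handler per run so concurrent runs don't mix.
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            logger.removeHandler(h)
            h.close()
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
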