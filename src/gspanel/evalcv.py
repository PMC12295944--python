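"""Repeated k-fold cross-validation of genomic prediction.

The evaluation harness mirrors a standard genomic-selection benchmark: the
population is split into 5 approximately equal folds, each fold serves as
the validation set once, and the whole scheme is repeated (default 20
times) with fresh random splits.  For every repeat x fold the harness can
rebuild trait-aware panels from a GWAS fitted on the training samples only
(``within_fold`` leakage mode), fit each requested model, predict
validation GEBVs, and score them with:

* accuracy — Pearson correlation between phenotype and GEBV;
* bias     — slope of the regression of phenotype on GEBV (1 = unbiased);
* MSE, MAE — squared / absolute error of the GEBV as a phenotype predictor.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, impute_mean
from .gwas import GwasModelSpec, assoc_scan
from .linmodels import (
    BayesPrior,
    GblupFit,
    McmcConfig,
    RemlNonConvergence,
    aireml,
    bayes_sample,
)
from .mlmodels import MlSpec, predict as ml_predict, tune_and_fit
from .panels import Panel, select_gwas, select_ld, select_random
from .popstruct import GRM, compute_grm

logger = logging.getLogger(__name__)

LINEAR_MARKER_MODELS = {"BayesA": "A", "BayesB": "B", "BayesCpi": "Cpi", "BayesLasso": "Lasso"}
ML_MODELS = ("SVR", "RF", "KRR", "XGB")


def derive_seed(base: int, *tokens) -> int:
    """Deterministic per-stage seed from a global seed and context tokens."""
    h = zlib.crc32("/".join(str(t) for t in tokens).encode())
    return int((base * 1_000_003 + h) % 2**31)


@dataclass
class CvScheme:
    n_folds: int = 5
    n_repeats: int = 20
    seed: int = 0
    leakage_mode: str = "within_fold"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.leakage_mode not in ("within_fold", "whole_data"):
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")


@dataclass
class Metrics:
    accuracy: float
    bias: float
    mse: float
    mae: float

    def __post_init__(self) -> None:
        if np.isfinite(self.accuracy) and abs(self.accuracy) > 1 + 1e-9:
            raise ValueError("|accuracy| cannot exceed 1")
        if self.mse < 0 or self.mae < 0:
            raise ValueError("mse and mae must be non-negative")


@dataclass
class CvReport:
    rows: pd.DataFrame
    scheme: CvScheme
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD over repeats for each trait/strategy/density/model."""
        ok = self.rows[~self.rows["failed"]]
        per_repeat = (
            ok.groupby(["trait", "strategy", "density", "model", "repeat"])[
                ["accuracy", "bias", "mse", "mae"]
            ].mean().reset_index()
        )
        agg = per_repeat.groupby(["trait", "strategy", "density", "model"]).agg(
            accuracy_mean=("accuracy", "mean"), accuracy_sd=("accuracy", "std"),
            bias_mean=("bias", "mean"), bias_sd=("bias", "std"),
            mse_mean=("mse", "mean"), mae_mean=("mae", "mean"),
            n_repeats=("repeat", "nunique"),
        )
        return agg.reset_index()

    def write_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


@dataclass
class ExperimentConfig:
    traits: list[str] | None = None
    strategies: tuple = ("gwas", "ld", "random")
    densities: tuple = (1000,)
    models: tuple = ("GBLUP",)
    scheme: CvScheme = field(default_factory=CvScheme)
    n_pcs: int = 10
    include_full_gblup: bool = True
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    ml_inner_repeats: int = 2
    ld_window: int = 100
    ld_step: int = 25


def make_folds(sample_ids: list[str], scheme: CvScheme) -> np.ndarray:
    """Fold index per sample, per repeat: (n_repeats, n) int array.

    Fold sizes differ by at most one (e.g. 971 samples in 5 folds gives one
    fold of 195 and four of 194).
    """
    n = len(sample_ids)
    if n < scheme.n_folds:
        raise ValueError("fewer samples than folds")
    out = np.empty((scheme.n_repeats, n), dtype=np.int64)
    for rep in range(scheme.n_repeats):
        rng = np.random.default_rng(derive_seed(scheme.seed, "folds", rep))
        perm = rng.permutation(n)
        base, extra = divmod(n, scheme.n_folds)
        start = 0
        for f in range(scheme.n_folds):
            size = base + (1 if f < extra else 0)
            out[rep, perm[start : start + size]] = f
            start += size
    return out


def compute_metrics(y_obs: np.ndarray, gebv: np.ndarray) -> Metrics:
    """Accuracy, bias, MSE and MAE of GEBVs against observed phenotypes.

    Constant GEBVs leave accuracy and bias undefined (NaN); MSE and MAE are
    always computed.
    """
    y = np.asarray(y_obs, dtype=float)
    g = np.asarray(gebv, dtype=float)
    if y.size != g.size or y.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    resid = y - g
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    if np.std(g) == 0 or np.std(y) == 0:
        return Metrics(np.nan, np.nan, mse, mae)
    cov = float(np.cov(y, g, ddof=1)[0, 1])
    accuracy = cov / (np.std(y, ddof=1) * np.std(g, ddof=1))
    bias = cov / float(np.var(g, ddof=1))
    return Metrics(float(np.clip(accuracy, -1.0, 1.0)), bias, mse, mae)


# ---------------------------------------------------------------------------
# model dispatch


def _center_by_train(d: np.ndarray, train_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = d[train_idx].mean(axis=0)
    return d - means[None, :], means


def _fit_predict(
    model: str,
    geno_panel: GenotypeMatrix,
    grm_panel: GRM | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
    mcmc: McmcConfig,
    ml_inner_repeats: int,
) -> np.ndarray:
    """Fit one model on the training fold, return test-set GEBV/predictions."""
    y_train = y[train_idx]
    d = geno_panel.dosages.astype(float)
    if model == "GBLUP":
        assert grm_panel is not None
        g_tt = grm_panel.submatrix(train_idx)
        sub = GRM(g_tt, [grm_panel.sample_ids[i] for i in train_idx], grm_panel.n_markers_used)
        try:
            vc = aireml(y_train, sub)
        except RemlNonConvergence as exc:
            vc = exc.vc
        fit: GblupFit = _gblup(y_train, grm_panel, train_idx, test_idx, vc)
        return fit.gebv[test_idx] + fit.mu
    if model in LINEAR_MARKER_MODELS:
        z, _ = _center_by_train(d, train_idx)
        prior = BayesPrior(model=LINEAR_MARKER_MODELS[model])
        run = McmcConfig(mcmc.n_iter, mcmc.burn_in, mcmc.thin, seed)
        mf = bayes_sample(y_train, z[train_idx], prior, run)
        return z[test_idx] @ mf.effects + mf.mu
    if model in ML_MODELS:
        spec = MlSpec(model=model, seed=seed, inner_cv_repeats=ml_inner_repeats)
        fitted = tune_and_fit(d[train_idx], y_train, spec)
        return ml_predict(fitted, d[test_idx])
    raise ValueError(f"unknown model {model!r}")


def _gblup(y_train, grm, train_idx, test_idx, vc):
    from .linmodels import gblup_predict

    return gblup_predict(y_train, grm, train_idx, test_idx, vc)


# ---------------------------------------------------------------------------
# experiment driver


def run_experiment(
    geno: GenotypeMatrix, phenos: pd.DataFrame, config: ExperimentConfig
) -> CvReport:
    """Full factorial CV run: traits x strategies x densities x models.

    Trait-aware stages (GWAS panel selection, variance components,
    hyperparameter tuning) only ever see training-fold phenotypes in
    ``within_fold`` mode; ``whole_data`` mode instead runs the GWAS once on
    everything, mimicking pipelines that select markers before validation.
    A full-marker GBLUP baseline arm (strategy ``full``) is included by
    default.  Failures are confined to their fold and flagged.
    """
    scheme = config.scheme
    geno = impute_mean(geno)
    phenos = phenos.reindex(geno.sample_ids)
    traits = config.traits or list(phenos.columns)
    missing_traits = [t for t in traits if t not in phenos.columns]
    if missing_traits:
        raise ValueError(f"traits not in phenotype table: {missing_traits}")

    grm_full = compute_grm(geno)
    folds = make_folds(geno.sample_ids, scheme)

    # trait-blind panels are shared across folds and traits
    ld_panels: dict[int, Panel] = {}
    for dens in config.densities:
        if "ld" in config.strategies:
            ld_panels[dens] = select_ld(geno, dens, config.ld_window, config.ld_step)

    whole_gwas: dict[str, pd.DataFrame] = {}
    if scheme.leakage_mode == "whole_data" and "gwas" in config.strategies:
        for trait in traits:
            y = phenos[trait].to_numpy(dtype=float)
            whole_gwas[trait] = assoc_scan(
                geno, y, GwasModelSpec(grm_full, config.n_pcs, trait)
            )

    panel_grms: dict[tuple, GRM] = {}

    def grm_for(panel_key: tuple, sub: GenotypeMatrix) -> GRM:
        if panel_key not in panel_grms:
            panel_grms[panel_key] = compute_grm(sub)
        return panel_grms[panel_key]

    rows: list[dict] = []
    n_failed = 0
    for trait in traits:
        y = phenos[trait].to_numpy(dtype=float)
        for rep in range(scheme.n_repeats):
            for fold in range(scheme.n_folds):
                test_idx = np.flatnonzero(folds[rep] == fold)
                train_idx = np.flatnonzero(folds[rep] != fold)
                assert np.intersect1d(train_idx, test_idx).size == 0

                fold_gwas: pd.DataFrame | None = None
                arms: list[tuple[str, int, Panel | None]] = []
                if config.include_full_gblup:
                    arms.append(("full", geno.n_variants, None))
                for strategy in config.strategies:
                    for dens in config.densities:
                        try:
                            if strategy == "gwas":
                                if scheme.leakage_mode == "whole_data":
                                    table = whole_gwas[trait]
                                else:
                                    if fold_gwas is None:
                                        sub_geno = geno.subset_samples(train_idx)
                                        sub_grm = GRM(
                                            grm_full.submatrix(train_idx),
                                            [geno.sample_ids[i] for i in train_idx],
                                            grm_full.n_markers_used,
                                        )
                                        # only training phenotypes reach the scan
                                        fold_gwas = assoc_scan(
                                            sub_geno, y[train_idx],
                                            GwasModelSpec(sub_grm, config.n_pcs, trait),
                                        )
                                    table = fold_gwas
                                panel = select_gwas(table, dens, scheme.leakage_mode)
                            elif strategy == "ld":
                                panel = ld_panels[dens]
                            elif strategy == "random":
                                if scheme.leakage_mode == "whole_data":
                                    rseed = derive_seed(scheme.seed, "random", dens)
                                else:
                                    rseed = derive_seed(scheme.seed, "random", dens, rep, fold)
                                panel = select_random(geno.variants, dens, rseed)
                            else:
                                raise ValueError(f"unknown strategy {strategy!r}")
                            arms.append((strategy, dens, panel))
                        except Exception:
                            logger.exception(
                                "panel %s/%d failed (trait=%s rep=%d fold=%d)",
                                strategy, dens, trait, rep, fold,
                            )
                            for model in config.models:
                                rows.append(_failed_row(trait, strategy, dens, model, rep, fold))
                                n_failed += 1

                for strategy, dens, panel in arms:
                    if panel is None:
                        sub = geno
                        key = ("full",)
                    else:
                        sub = geno.subset_variants(np.asarray(panel.variant_ids, dtype=object))
                        if strategy == "ld" or (
                            strategy == "random" and scheme.leakage_mode == "whole_data"
                        ):
                            key = (strategy, dens)  # fold-independent panel, cache GRM
                        else:
                            key = (strategy, dens, trait, rep, fold)
                    models = ("GBLUP",) if strategy == "full" else config.models
                    grm_panel = grm_full if strategy == "full" else None
                    for model in models:
                        try:
                            if model == "GBLUP" and grm_panel is None:
                                grm_panel = grm_for(key, sub)
                            seed = derive_seed(scheme.seed, "fit", trait, strategy, dens, model, rep, fold)
                            pred = _fit_predict(
                                model, sub, grm_panel if model == "GBLUP" else None,
                                y, train_idx, test_idx, seed,
                                config.mcmc, config.ml_inner_repeats,
                            )
                            m = compute_metrics(y[test_idx], pred)
                            rows.append({
                                "trait": trait, "strategy": strategy, "density": dens,
                                "model": model, "repeat": rep, "fold": fold,
                                "accuracy": m.accuracy, "bias": m.bias,
                                "mse": m.mse, "mae": m.mae, "failed": False,
                            })
                        except Exception:
                            logger.exception(
                                "model %s failed (trait=%s strategy=%s density=%d rep=%d fold=%d)",
                                model, trait, strategy, dens, rep, fold,
                            )
                            rows.append(_failed_row(trait, strategy, dens, model, rep, fold))
                            n_failed += 1

    report = CvReport(pd.DataFrame(rows), scheme, n_failed)
    if n_failed:
        logger.warning("run_experiment: %d failed fold-arms", n_failed)
    return report


def _failed_row(trait, strategy, dens, model, rep, fold) -> dict:
    return {
        "trait": trait, "strategy": strategy, "density": dens, "model": model,
        "repeat": rep, "fold": fold, "accuracy": np.nan, "bias": np.nan,
        "mse": np.nan, "mae": np.nan, "failed": True,
    }
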