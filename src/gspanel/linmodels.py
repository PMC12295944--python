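"""Linear genomic-prediction models: GBLUP (AI-REML) and the Bayesian alphabet.

GBLUP treats the vector of genetic values as ``g ~ N(0, G sigma_a2)`` with
the VanRaden GRM ``G``; variance components come from average-information
REML and breeding values for unphenotyped individuals from the
``G(test,train)`` projection of the training-set mixed-model solution.

The marker-effect models (BayesA, BayesB, BayesCpi, Bayesian Lasso) share
``y = 1 mu + sum_i Z_i g_i + e`` and differ only in the prior mixture on
effect sizes:

* BayesA    — every marker has its own variance, scaled-inv-chi2(nu, S);
* BayesB    — as A, but a point mass pi = 0.95 of markers are excluded;
* BayesCpi  — common slab variance, pi sampled with a uniform prior;
* Lasso     — Park-Casella double-exponential (exponential mixture of
  normals) with the rate lambda^2 given a Gamma hyperprior.

All four run as single-site Gibbs samplers (numba kernel) with 18,000
cycles and 3,000 burn-in by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _gibbs
from .gwas import VarianceComponents
from .popstruct import GRM

_MODEL_CODES = {"A": _gibbs.MODEL_A, "B": _gibbs.MODEL_B,
                "Cpi": _gibbs.MODEL_CPI, "Lasso": _gibbs.MODEL_LASSO}

MAX_MARKERS = 50_000  # panel-scale by design; WGS-scale marker models refused

_GRM_JITTER = 1e-8


class RemlNonConvergence(RuntimeError):
    def __init__(self, message: str, vc: VarianceComponents):
        super().__init__(message)
        self.vc = vc


@dataclass
class GblupFit:
    mu: float
    vc: VarianceComponents
    gebv: np.ndarray  # per-sample genetic values, grm order
    sample_ids: list[str]


@dataclass
class BayesPrior:
    """Prior configuration for the Bayesian-alphabet samplers.

    ``pi`` is the zero-mass: 0 for BayesA/Lasso, 0.95 fixed for BayesB, and
    the initial value (uniform prior, sampled) for BayesCpi.  ``S`` defaults
    to None and is then solved so the prior expected genetic variance
    matches an AI-REML pre-estimate.  ``fixed_sigma_e2``/``fixed_sigma_g2``
    pin those parameters instead of sampling them — validation hooks that
    make closed-form conditional posteriors exact.
    """

    model: str = "A"
    pi: float | None = None
    nu: float = 4.2
    S: float | None = None
    fixed_sigma_e2: float | None = None
    fixed_sigma_g2: float | None = None
    lambda2_shape: float = 1.0
    lambda2_rate: float | None = None

    def __post_init__(self) -> None:
        if self.model not in _MODEL_CODES:
            raise ValueError(f"unknown model {self.model!r} (A, B, Cpi, Lasso)")
        if self.pi is None:
            self.pi = 0.95 if self.model == "B" else (0.5 if self.model == "Cpi" else 0.0)
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must be in [0, 1)")
        if self.nu <= 2.0:
            raise ValueError("nu must exceed 2")


@dataclass
class McmcConfig:
    n_iter: int = 18_000
    burn_in: int = 3_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class MarkerFit:
    mu: float
    effects: np.ndarray          # posterior-mean marker effects
    effects_sd: np.ndarray       # posterior SDs (MC diagnostics)
    pi_mean: float
    sigma_e2_mean: float
    gebv: np.ndarray             # Z_train @ effects
    n_saved: int
    draws: np.ndarray | None = None  # thinned effect draws when m is small
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# AI-REML


def _reml_loglik(lam, ystar, xstar, sa2, se2):
    d = sa2 * lam + se2
    w = 1.0 / d
    xtwx = (xstar.T * w) @ xstar
    beta = np.linalg.solve(xtwx, (xstar.T * w) @ ystar)
    r = ystar - xstar @ beta
    sign, logdet_x = np.linalg.slogdet(xtwx)
    return -0.5 * (np.sum(np.log(d)) + logdet_x + float(np.sum(w * r * r)))


def aireml(
    y: np.ndarray,
    grm: GRM,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> VarianceComponents:
    """Average-information REML for ``y = 1 mu + g + e``, g ~ N(0, G sa2).

    Works in the eigenbasis of G so every iteration is O(n).  When an AI
    step leaves the parameter space, an EM-REML step is taken instead;
    components are floored at 1e-8 * var(y).  Convergence is declared when
    the REML log-likelihood changes by less than ``tol``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 30:
        raise ValueError("aireml requires n >= 30")
    if grm.n != n:
        raise ValueError("GRM and y disagree on n")
    gmat = grm.matrix + _GRM_JITTER * np.eye(n)
    lam, u = np.linalg.eigh(gmat)
    if lam.min() < -1e-6:
        raise ValueError("GRM not positive semidefinite beyond jitter")
    lam = np.clip(lam, 0.0, None)
    ystar = u.T @ y
    xstar = (u.T @ np.ones((n, 1)))

    vy = float(np.var(y))
    floor = 1e-8 * max(vy, 1e-30)
    sa2, se2 = 0.5 * vy, 0.5 * vy
    ll = _reml_loglik(lam, ystar, xstar, sa2, se2)

    for _ in range(max_iter):
        d = sa2 * lam + se2
        w = 1.0 / d
        xtwx = float(np.sum(w * xstar[:, 0] ** 2))
        xtwy = float(np.sum(w * xstar[:, 0] * ystar))
        beta = xtwy / xtwx
        r = ystar - beta * xstar[:, 0]
        # Py in the eigenbasis: P = W - W x (x'Wx)^-1 x' W
        py = w * r
        # tr(P V_i): V_a -> diag(lam), V_e -> I
        tr_p_va = float(np.sum(w * lam) - np.sum((w * xstar[:, 0]) ** 2 * lam) / xtwx)
        tr_p_ve = float(np.sum(w) - np.sum((w * xstar[:, 0]) ** 2) / xtwx)

        def apply_p(v: np.ndarray) -> np.ndarray:
            wv = w * v
            return wv - (w * xstar[:, 0]) * (float(np.sum(xstar[:, 0] * wv)) / xtwx)

        va_py = lam * py
        ve_py = py
        p_va_py = apply_p(va_py)
        p_ve_py = apply_p(ve_py)

        score_a = -0.5 * (tr_p_va - float(ystar @ p_va_py))
        score_e = -0.5 * (tr_p_ve - float(ystar @ p_ve_py))
        ai_aa = 0.5 * float(va_py @ p_va_py)
        ai_ae = 0.5 * float(va_py @ p_ve_py)
        ai_ee = 0.5 * float(ve_py @ p_ve_py)
        ai = np.array([[ai_aa, ai_ae], [ai_ae, ai_ee]])

        try:
            step = np.linalg.solve(ai, np.array([score_a, score_e]))
        except np.linalg.LinAlgError:
            step = None

        sa2_new = se2_new = -1.0
        if step is not None:
            # step-halve an AI proposal that leaves the parameter space or
            # degrades the likelihood (AI overshoots when G carries little
            # information and the surface is flat)
            t = 1.0
            for _ in range(8):
                cand_a, cand_e = sa2 + t * step[0], se2 + t * step[1]
                if cand_a >= floor and cand_e >= floor and (
                    _reml_loglik(lam, ystar, xstar, cand_a, cand_e) >= ll
                ):
                    sa2_new, se2_new = cand_a, cand_e
                    break
                t *= 0.5

        if sa2_new < floor or se2_new < floor:
            # EM-REML fallback: theta_i += theta_i^2 (y'P V_i P y - tr(P V_i)) / n
            sa2_new = sa2 + sa2 * sa2 * (float(ystar @ p_va_py) - tr_p_va) / n
            se2_new = se2 + se2 * se2 * (float(ystar @ p_ve_py) - tr_p_ve) / n
            sa2_new = max(sa2_new, floor)
            se2_new = max(se2_new, floor)

        # boundary case: likelihood still decreasing in sa2 while sa2 is
        # negligible -> the REML optimum is at sa2 = 0; pin it and close
        # the residual variance in one step instead of letting EM creep
        if score_a < 0.0 and sa2_new < 1e-3 * vy:
            beta0 = float(np.sum(ystar * xstar[:, 0])) / float(np.sum(xstar[:, 0] ** 2))
            r0 = ystar - beta0 * xstar[:, 0]
            return VarianceComponents(0.0, float(r0 @ r0) / (n - 1))

        ll_new = _reml_loglik(lam, ystar, xstar, sa2_new, se2_new)
        sa2, se2 = sa2_new, se2_new
        if abs(ll_new - ll) < tol:
            return VarianceComponents(max(sa2, 0.0), max(se2, floor))
        ll = ll_new

    raise RemlNonConvergence(
        f"AI-REML did not converge in {max_iter} iterations",
        VarianceComponents(max(sa2, 0.0), max(se2, floor)),
    )


# ---------------------------------------------------------------------------
# GBLUP


def gblup_predict(
    y_train: np.ndarray,
    grm_full: GRM,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    vc: VarianceComponents,
) -> GblupFit:
    """GEBVs for all samples from a training-set mixed-model solve.

    Solves ``(G_tt + lambda I) a = y_train - mu`` with
    ``lambda = sigma_e2 / sigma_a2`` and GLS intercept ``mu``; GEBVs are
    ``G[:, train] a`` (the training block reproduces the classical BLUP,
    test samples get the relationship-projection prediction).
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    y_train = np.asarray(y_train, dtype=float)
    if y_train.size != train_idx.size:
        raise ValueError("y_train and train_idx disagree")
    if vc.sigma_a2 <= 0:
        # complete shrinkage limit: lambda -> inf, all GEBVs -> 0
        mu = float(y_train.mean())
        return GblupFit(mu, vc, np.zeros(grm_full.n), list(grm_full.sample_ids))

    lam = vc.sigma_e2 / vc.sigma_a2
    gtt = grm_full.submatrix(train_idx)
    a_mat = gtt + lam * np.eye(train_idx.size)
    try:
        chol = np.linalg.cholesky(a_mat + _GRM_JITTER * np.eye(train_idx.size))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular MME coefficient matrix") from exc

    def solve(b: np.ndarray) -> np.ndarray:
        return np.linalg.solve(chol.T, np.linalg.solve(chol, b))

    ones = np.ones(train_idx.size)
    ainv_1 = solve(ones)
    ainv_y = solve(y_train)
    mu = float(ones @ ainv_y) / float(ones @ ainv_1)
    alpha = solve(y_train - mu)
    gebv = grm_full.matrix[:, train_idx] @ alpha
    return GblupFit(mu, vc, gebv, list(grm_full.sample_ids))


# ---------------------------------------------------------------------------
# Bayesian alphabet


def _auto_scale(y: np.ndarray, Z: np.ndarray, prior: BayesPrior) -> tuple[float, float, float]:
    """Solve (S, sigma_e2 prior scale, lambda2 init) from an REML pre-estimate.

    The slab scale S is set so the prior expected genetic variance,
    (1 - pi) * c * E[sigma_g2] with c = sum_j var(Z_j), matches the additive
    variance of a GBLUP fit on the same markers.
    """
    n = y.size
    c = float(np.sum(Z.var(axis=0)))
    if c <= 0:
        raise ValueError("all markers constant")
    vy = float(np.var(y))
    if n >= 30:
        try:
            g = (Z @ Z.T) / c
            vc = aireml(y, GRM(g, [str(i) for i in range(n)], Z.shape[1]))
            sa2, se2 = vc.sigma_a2, vc.sigma_e2
        except RemlNonConvergence as exc:
            sa2, se2 = exc.vc.sigma_a2, exc.vc.sigma_e2
    else:
        sa2, se2 = 0.5 * vy, 0.5 * vy
    sa2 = max(sa2, 1e-4 * vy)
    sg2_target = sa2 / ((1.0 - prior.pi) * c)
    S = sg2_target * (prior.nu - 2.0) / prior.nu
    lambda2_init = 2.0 * se2 / sg2_target
    return S, max(se2, 1e-8 * vy), lambda2_init


def bayes_sample(
    y_train: np.ndarray,
    Z_train: np.ndarray,
    prior: BayesPrior,
    mcmc: McmcConfig | None = None,
) -> MarkerFit:
    """Run the Gibbs sampler for one Bayesian-alphabet model.

    ``Z_train`` must be the centered dosage matrix (training-set means).
    Returns posterior-mean effects, intercept and fitted GEBVs; thinned
    effect draws are retained when m <= 16 for convergence diagnostics.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    y = np.ascontiguousarray(y_train, dtype=float)
    Z = np.ascontiguousarray(Z_train, dtype=float)
    n, m = Z.shape
    if y.size != n:
        raise ValueError("y_train and Z_train disagree on n")
    if m > MAX_MARKERS:
        raise ValueError(
            f"{m} markers exceeds the panel-scale limit {MAX_MARKERS}; "
            "marker-effect samplers are not intended for WGS-scale input"
        )

    if prior.S is None or prior.fixed_sigma_e2 is None:
        S_auto, se2_prior, lambda2_init = _auto_scale(y, Z, prior)
    else:
        S_auto, se2_prior, lambda2_init = prior.S, prior.fixed_sigma_e2, 1.0
    S = prior.S if prior.S is not None else S_auto
    nu_e = 4.0
    S_e = se2_prior * (nu_e - 2.0) / nu_e
    lambda2_rate = (
        prior.lambda2_rate
        if prior.lambda2_rate is not None
        else prior.lambda2_shape / max(lambda2_init, 1e-12)
    )

    out = _gibbs.gibbs_kernel(
        y, Z, _MODEL_CODES[prior.model],
        float(prior.pi), float(prior.nu), float(S),
        nu_e, S_e,
        int(mcmc.seed) % 2**31, int(mcmc.n_iter), int(mcmc.burn_in), int(mcmc.thin),
        -1.0 if prior.fixed_sigma_e2 is None else float(prior.fixed_sigma_e2),
        -1.0 if prior.fixed_sigma_g2 is None else float(prior.fixed_sigma_g2),
        float(lambda2_init), float(prior.lambda2_shape), float(lambda2_rate),
        16,
    )
    g_sum, g_sumsq, mu_sum, pi_sum, se2_sum, n_saved, draws, bad_iter = out
    if bad_iter:
        raise RuntimeError(f"Gibbs chain diverged (non-finite state) at iteration {bad_iter}")
    if n_saved == 0:
        raise RuntimeError("no post-burn-in samples saved; check mcmc config")

    effects = g_sum / n_saved
    var = np.clip(g_sumsq / n_saved - effects**2, 0.0, None)
    fit = MarkerFit(
        mu=mu_sum / n_saved,
        effects=effects,
        effects_sd=np.sqrt(var),
        pi_mean=pi_sum / n_saved,
        sigma_e2_mean=se2_sum / n_saved,
        gebv=Z @ effects,
        n_saved=int(n_saved),
        draws=draws if m <= 16 else None,
        meta={"model": prior.model, "nu": prior.nu, "S": float(S),
              "seed": mcmc.seed, "n_iter": mcmc.n_iter, "burn_in": mcmc.burn_in,
              "thin": mcmc.thin},
    )
    return fit


def marker_gebv(fit: MarkerFit, Z_any: np.ndarray) -> np.ndarray:
    """GEBVs for arbitrary samples: centered dosages times posterior means."""
    Z_any = np.asarray(Z_any, dtype=float)
    if Z_any.shape[1] != fit.effects.size:
        raise ValueError("marker sets not aligned")
    return Z_any @ fit.effects
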