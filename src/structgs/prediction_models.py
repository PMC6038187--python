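"""The four genomic prediction methods behind one fit/predict contract.

* kin-BLUP (GBLUP): single-kernel REML on the realized relationship matrix;
  predictions for unphenotyped individuals flow through their kinship with
  the training set.
* PLS: univariate-response partial least squares on the centered dosage
  matrix with a fixed number of latent variables (default 15).
* SPLS: sparse PLS — soft-thresholded direction vectors zero out low-weight
  markers; the threshold and component count are tuned by inner
  cross-validation.
* BayesB: Gibbs sampling of a point-mass/normal mixture over marker effects
  with marker-specific variances (a proportion pi of markers carry effects).

All four consume the same (X, y, K) inputs on the standardized trait scale
and emit comparable predictions, so the cross-validation harness treats
them interchangeably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .quantitative_genetics import KinshipMatrix, MixedModelFit, reml_single_kernel

METHODS = ("KINBLUP", "PLS", "SPLS", "BAYESB")


@dataclass
class ModelSpec:
    """Method name plus method-specific hyperparameters."""

    method: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method == "PLS" and self.params.get("n_latent", 15) < 1:
            raise ValueError("PLS needs n_latent >= 1")
        if self.method == "BAYESB":
            pi = self.params.get("pi", 0.05)
            if not 0.0 < pi <= 1.0:
                raise ValueError("BayesB pi must be in (0, 1]")
            if self.params.get("burn_in", 1500) >= self.params.get("n_iter", 5000):
                raise ValueError("burn_in must be < n_iter")


@dataclass
class MarkerEffects:
    effects: np.ndarray
    inclusion_freq: np.ndarray | None = None


@dataclass
class FittedModel:
    """Learned state of any of the four methods, with a uniform predict path."""

    method: str
    intercept: float
    coef: np.ndarray | None = None          # marker effects (PLS/SPLS/BAYESB)
    x_mean: np.ndarray | None = None        # training column means for centering
    mixed: MixedModelFit | None = None      # KINBLUP state
    kinship: KinshipMatrix | None = None
    selected: dict[str, Any] = field(default_factory=dict)

    def marker_effects(self) -> MarkerEffects:
        if self.coef is None:
            raise ValueError(f"{self.method} has no explicit marker effects")
        return MarkerEffects(effects=self.coef, inclusion_freq=self.selected.get("inclusion_freq"))


# ----------------------------------------------------------------------
# kin-BLUP
# ----------------------------------------------------------------------

def fit_kinblup(y: np.ndarray, K: KinshipMatrix) -> FittedModel:
    """GBLUP via spectral REML; ``y`` is length n with NaN outside the training set."""
    y = np.asarray(y, dtype=float)
    n_train = int(np.isfinite(y).sum())
    if n_train < 3:
        raise ValueError("kin-BLUP needs >= 3 training individuals")
    if n_train < 10:
        warnings.warn(f"only {n_train} training individuals; variance components will be noisy")
    fit = reml_single_kernel(y, K)
    return FittedModel(method="KINBLUP", intercept=float(fit.beta[0]), mixed=fit, kinship=K)


# ----------------------------------------------------------------------
# PLS
# ----------------------------------------------------------------------

def _pls_rank(X: np.ndarray) -> int:
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    return int(np.sum(s > max(s[0], 1e-300) * 1e-10)) if len(s) else 0


def fit_pls(X: np.ndarray, y: np.ndarray, n_latent: int = 15) -> FittedModel:
    """Univariate-response PLS regression with ``n_latent`` latent variables.

    Components beyond the rank of the centered predictor matrix are
    truncated with a warning; prediction is the fixed linear map
    yhat = (X - x_mean) @ coef + intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rank = _pls_rank(X)
    if n_latent > rank:
        warnings.warn(f"n_latent {n_latent} exceeds predictor rank {rank}; truncating")
        n_latent = rank
    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(X, y)
    scores = pls.x_scores_
    return FittedModel(
        method="PLS",
        intercept=float(y.mean()),
        coef=pls.coef_.reshape(-1),
        x_mean=X.mean(axis=0),
        selected={"n_latent": n_latent, "scores": scores},
    )


# ----------------------------------------------------------------------
# SPLS
# ----------------------------------------------------------------------

def _spls_coef(X: np.ndarray, y: np.ndarray, eta: float, n_comp: int) -> tuple[np.ndarray, np.ndarray]:
    """Sparse PLS coefficients for a univariate response.

    At each step the direction vector X'r is soft-thresholded at
    ``eta * max|X'r|``; markers surviving at any step join the active set,
    and a plain PLS fit on the active set gives the current coefficients
    before deflating the response.  Returns (coef, active_mask) on the
    centered-X scale.
    """
    n, m = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    active = np.zeros(m, dtype=bool)
    coef = np.zeros(m)
    r = yc.copy()
    for k in range(1, n_comp + 1):
        z = Xc.T @ r
        zmax = np.max(np.abs(z))
        if zmax <= 0:
            break
        w = np.sign(z) * np.maximum(np.abs(z) - eta * zmax, 0.0)
        new = w != 0.0
        if not new.any():
            break
        active |= new
        idx = np.flatnonzero(active)
        n_fit = min(k, _pls_rank(Xc[:, idx]))
        if n_fit < 1:
            break
        pls = PLSRegression(n_components=n_fit, scale=False)
        pls.fit(Xc[:, idx], yc)
        coef = np.zeros(m)
        coef[idx] = pls.coef_.reshape(-1)
        r = yc - Xc[:, idx] @ coef[idx]
    return coef, active


def fit_spls(
    X: np.ndarray,
    y: np.ndarray,
    threshold_grid: np.ndarray | None = None,
    component_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Sparse PLS with (threshold, components) chosen by seeded inner CV on MSE.

    Default grids: eta in {0.1, ..., 0.9} and 1..10 components.  A grid
    point whose support is empty on the full data is skipped.  Ties in the
    inner-CV MSE break toward the sparser/simpler model (larger eta, fewer
    components), deterministically for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if threshold_grid is None:
        threshold_grid = np.round(np.arange(0.1, 0.95, 0.1), 10)
    if component_grid is None:
        component_grid = np.arange(1, 11)
    threshold_grid = np.atleast_1d(np.asarray(threshold_grid, dtype=float))
    component_grid = np.atleast_1d(np.asarray(component_grid, dtype=int))
    if threshold_grid.size == 0 or component_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")

    rng = np.random.default_rng(seed)
    n = len(y)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv_folds)

    best = None
    for eta in threshold_grid:
        for ncomp in component_grid:
            errs = []
            for f in folds:
                tr = np.setdiff1d(perm, f, assume_unique=True)
                coef, act = _spls_coef(X[tr], y[tr], eta, int(ncomp))
                if not act.any():
                    errs = None
                    break
                pred = (X[f] - X[tr].mean(axis=0)) @ coef + y[tr].mean()
                errs.append(np.mean((y[f] - pred) ** 2))
            if errs is None:
                warnings.warn(f"SPLS threshold {eta:.2f} gives empty support; skipped")
                continue
            mse = float(np.mean(errs))
            key = (mse, -eta, ncomp)
            if best is None or key < best[0]:
                best = (key, float(eta), int(ncomp))
    if best is None:
        raise ValueError("no SPLS grid point produced a non-empty support")
    _, eta, ncomp = best
    coef, active = _spls_coef(X, y, eta, ncomp)
    return FittedModel(
        method="SPLS",
        intercept=float(y.mean()),
        coef=coef,
        x_mean=X.mean(axis=0),
        selected={"eta": eta, "n_latent": ncomp, "support": np.flatnonzero(active)},
    )


# ----------------------------------------------------------------------
# BayesB
# ----------------------------------------------------------------------

def fit_bayesb(
    X: np.ndarray,
    y: np.ndarray,
    pi: float = 0.05,
    n_iter: int = 5000,
    burn_in: int = 1500,
    thin: int = 5,
    seed: int = 0,
    nu_b: float = 5.0,
    nu_e: float = 5.0,
    r2_prior: float = 0.5,
) -> FittedModel:
    """BayesB: mixture prior with marker-specific variances, by Gibbs sampling.

    ``pi`` is the prior probability that a marker HAS an effect (0.05 is
    sparse).  Hyper-scales follow the usual heuristic: the residual scale
    puts the prior mode at (1 - r2_prior) * var(y), and the marker-variance
    scale spreads r2_prior * var(y) over the expected pi * m contributing
    markers weighted by their dosage variances.  Posterior-mean effects and
    inclusion frequencies come from the thinned post-burn-in samples; the
    chain is bit-reproducible from ``seed``.
    """
    from ._bayesb import bayesb_gibbs

    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")
    if not 0.0 < pi <= 1.0:
        raise ValueError("pi must be in (0, 1]")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("response has zero variance")
    msx = float(np.mean(np.var(Xc, axis=0)))
    m = X.shape[1]
    target_b = r2_prior * vary / max(pi * m * msx, 1e-12)
    s_b = target_b * (nu_b + 2.0) / nu_b       # prior mode at target_b
    s_e = (1.0 - r2_prior) * vary * (nu_e + 2.0) / nu_e

    eff, incl, mu, s2e, n_kept = bayesb_gibbs(
        Xc, y, float(pi), int(n_iter), int(burn_in), int(thin),
        float(nu_b), float(s_b), float(nu_e), float(s_e), int(seed) & 0x7FFFFFFF,
    )
    return FittedModel(
        method="BAYESB",
        intercept=float(mu),
        coef=eff,
        x_mean=x_mean,
        selected={"inclusion_freq": incl, "sigma2_e": float(s2e), "n_samples_kept": int(n_kept), "pi": pi},
    )


# ----------------------------------------------------------------------
# Unified entry points
# ----------------------------------------------------------------------

def fit_model(
    spec: ModelSpec,
    y_train: np.ndarray,
    X: np.ndarray | None = None,
    K: KinshipMatrix | None = None,
    train_idx: np.ndarray | None = None,
) -> FittedModel:
    """Fit any method from a ModelSpec.

    ``y_train`` is aligned with rows of ``X``/``K``; ``train_idx`` selects
    the calibration rows (default: all finite entries of ``y_train``).
    """
    y_train = np.asarray(y_train, dtype=float)
    if train_idx is None:
        train_idx = np.flatnonzero(np.isfinite(y_train))
    if spec.method == "KINBLUP":
        if K is None:
            raise ValueError("KINBLUP requires a kinship matrix")
        y_masked = np.full(K.n, np.nan)
        y_masked[train_idx] = y_train[train_idx]
        return fit_kinblup(y_masked, K)
    if X is None:
        raise ValueError(f"{spec.method} requires the genotype matrix")
    Xt, yt = X[train_idx], y_train[train_idx]
    if spec.method == "PLS":
        return fit_pls(Xt, yt, n_latent=spec.params.get("n_latent", 15))
    if spec.method == "SPLS":
        return fit_spls(
            Xt, yt,
            threshold_grid=spec.params.get("threshold_grid"),
            component_grid=spec.params.get("component_grid"),
            cv_folds=spec.params.get("cv_folds", 5),
            seed=spec.params.get("seed", 0),
        )
    return fit_bayesb(
        Xt, yt,
        pi=spec.params.get("pi", 0.05),
        n_iter=spec.params.get("n_iter", 5000),
        burn_in=spec.params.get("burn_in", 1500),
        thin=spec.params.get("thin", 5),
        seed=spec.params.get("seed", 0),
    )


def predict(model: FittedModel, X: np.ndarray | None = None, idx: np.ndarray | None = None) -> np.ndarray:
    """Predict with a fitted model.

    Marker-based methods take the genotype rows ``X`` (same SNP set and
    order as training); kin-BLUP takes ``idx``, the positions of the target
    individuals within the kinship matrix it was fitted on.
    """
    if model.method == "KINBLUP":
        if idx is None:
            raise ValueError("kin-BLUP prediction needs kinship row indices")
        return model.intercept + model.mixed.u[np.asarray(idx)]
    if X is None:
        raise ValueError(f"{model.method} prediction needs genotypes")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.x_mean):
        raise ValueError(
            f"SNP-set mismatch: model was trained on {len(model.x_mean)} markers, got {X.shape[1]}"
        )
    return (X - model.x_mean) @ model.coef + model.intercept
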