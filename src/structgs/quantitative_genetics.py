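"""Phenotype BLUPs, the realized relationship matrix, REML and heritability partition.

The genomic stage works on per-genotype BLUP phenotypes from a one-way
random-genotype model fitted across replicated plots.  Genomic analyses use
the VanRaden realized additive relationship matrix

    A = W W' / (2 sum_i p_i (1 - p_i)),   W = dosage column-centered by 2p,

and the single-kernel mixed model y = X beta + u + e with u ~ N(0, A s2_g),
fitted by REML on the spectral decomposition of A (profiling the likelihood
over the variance ratio on the rotated data).

Genomic heritability is split into across- and within-population components
by rewriting the model on the eigenvectors of A:  y = 1 mu + U alpha + e
with alpha ~ N(0, D s2_G).  The leading ``d`` principal components absorb
population structure, so

    s2_gA = (1/(n-1)) sum_{i<=d} alpha_i^2,
    s2_gW = (1/(n-1)) sum_{i>d}  alpha_i^2,

and the total s2 = s2_gA + s2_gW holds exactly by construction.  Because
alpha is not observed, the sums are evaluated at its BLUP (the default) or
at the posterior second moment E[alpha_i^2 | y] = blup_i^2 + PEV_i, which
compensates the shrinkage of the weakly informed trailing components at the
price of adding their prediction-error variance even when a component
carries no signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotype_qc import GenotypeMatrix


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Long-format replicated phenotype records.

    ``data`` columns: ``genotype_id, replicate_id, trait, value``.
    ``standardization`` maps trait -> (mean, sd) recorded by
    :func:`standardize_trait` for back-transformation.
    """

    data: pd.DataFrame
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"genotype_id", "replicate_id", "trait", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")

    def traits(self) -> list[str]:
        return list(pd.unique(self.data["trait"]))

    def trait_records(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not in table")
        return sub

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))


def standardize_trait(p: PhenotypeTable, trait: str) -> PhenotypeTable:
    """Center and scale one trait to unit standard deviation over records."""
    sub = p.trait_records(trait)
    mean = float(sub["value"].mean())
    sd = float(sub["value"].std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"trait {trait!r} has zero variance; cannot standardize")
    data = p.data.copy()
    sel = data["trait"] == trait
    data.loc[sel, "value"] = (data.loc[sel, "value"] - mean) / sd
    meta = dict(p.standardization)
    prev = meta.get(trait)
    if prev is not None:  # compose so back_transform always reaches raw scale
        mean = prev[0] + prev[1] * mean
        sd = prev[1] * sd
    meta[trait] = (mean, sd)
    return PhenotypeTable(data, meta)


def back_transform(p: PhenotypeTable, trait: str, values: np.ndarray) -> np.ndarray:
    mean, sd = p.standardization[trait]
    return np.asarray(values) * sd + mean


@dataclass
class TraitBLUPs:
    """Per-genotype predicted values and the variance components behind them."""

    trait: str
    values: pd.Series            # genotype_id -> mu + BLUP(g_i)
    sigma2_g: float
    sigma2_e: float
    n_reps_mean: float           # average replicates per genotype (arithmetic)
    mu: float

    @property
    def repeatability(self) -> float:
        """Line-based repeatability H^2 = s2_G / (s2_G + s2_e / n)."""
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e / self.n_reps_mean)


def fit_genotype_blups(p: PhenotypeTable, trait: str) -> TraitBLUPs:
    """Fit y_ij = mu + g_i + e_ij with random genotype effects by REML.

    Returns shrunken genotype predictions (mu + BLUP), the variance
    components, the arithmetic mean number of replicates per genotype and
    the repeatability they imply.
    """
    import statsmodels.api as sm

    sub = p.trait_records(trait)
    counts = sub.groupby("genotype_id")["value"].count()
    if len(counts) < 2:
        raise ValueError("need >= 2 genotypes")
    if (counts < 2).all():
        raise ValueError("residual variance unidentifiable: no genotype has >= 2 replicates")
    n_mean = float(counts.mean())
    y = sub["value"].to_numpy(dtype=float)
    groups = sub["genotype_id"].to_numpy()

    pooled_within = sub.groupby("genotype_id")["value"].var(ddof=1).dropna()
    if len(pooled_within) and pooled_within.max() < 1e-12:
        # degenerate noiseless data: REML boundary, solve directly
        means = sub.groupby("genotype_id")["value"].mean()
        mu = float(means.mean())
        return TraitBLUPs(trait, means, float(means.var(ddof=1)), 0.0, n_mean, mu)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups)
        fit = model.fit(reml=True)
    sigma2_g = float(np.asarray(fit.cov_re)[0, 0])
    sigma2_e = float(fit.scale)
    if not np.isfinite(sigma2_g) or not np.isfinite(sigma2_e):
        raise ValueError("REML variance components did not converge")
    mu = float(fit.fe_params[0])
    re = fit.random_effects
    values = pd.Series({gid: mu + float(np.squeeze(re[gid])) for gid in counts.index}, name=trait)
    return TraitBLUPs(trait, values, sigma2_g, sigma2_e, n_mean, mu)


# ----------------------------------------------------------------------
# Kinship
# ----------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Realized additive relationship matrix with cached spectral decomposition."""

    A: np.ndarray
    samples: list[str]
    denominator: float
    _U: np.ndarray | None = None
    _lam: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.samples)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvectors U (n x n-1) and eigenvalues (descending), dropping the
        null direction introduced by column centering; small negative
        eigenvalues are clipped to zero (tolerance 1e-8 * lambda_1)."""
        if self._U is None:
            lam, U = np.linalg.eigh(self.A)
            order = np.argsort(lam)[::-1]
            lam, U = lam[order], U[:, order]
            lam = lam[:-1]          # drop the centering null eigenvalue
            U = U[:, :-1]
            lam = np.where(lam < 1e-8 * max(lam[0], 1e-300), 0.0, lam)
            if lam[-1] < 0:
                raise ValueError("kinship matrix is not PSD beyond tolerance")
            self._lam, self._U = lam, U
        return self._U, self._lam

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.A, index=self.samples, columns=self.samples).to_csv(path, sep="\t")


def compute_grm(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden realized relationship matrix A = WW' / (2 sum p(1-p)).

    Requires an imputed (complete) matrix; monomorphic SNPs contribute
    nothing to either numerator or denominator.
    """
    if np.isnan(g.dosage).any():
        raise ValueError("GRM requires a complete (imputed) genotype matrix")
    p = g.dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic SNPs for a relationship matrix")
    W = g.dosage[:, poly] - 2.0 * p[poly]
    denom = float(2.0 * np.sum(p[poly] * (1.0 - p[poly])))
    A = (W @ W.T) / denom
    A = (A + A.T) / 2.0
    return KinshipMatrix(A=A, samples=list(g.samples), denominator=denom)


# ----------------------------------------------------------------------
# Spectral REML
# ----------------------------------------------------------------------

@dataclass
class MixedModelFit:
    beta: np.ndarray
    u: np.ndarray                # BLUP of the genetic effect for ALL individuals in K
    sigma2_g: float
    sigma2_e: float
    loglik: float                # restricted log-likelihood at the optimum
    delta: float                 # sigma2_e / sigma2_g at the optimum
    boundary: bool
    train_idx: np.ndarray

    def fitted(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta + self.u


def _restricted_ll(delta: float, lam: np.ndarray, Uy: np.ndarray, UX: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Profiled restricted log-likelihood for variance ratio delta = s2_e/s2_g.

    Returns (logREML up to a constant, sigma2_g_hat, beta_hat)."""
    v = lam + delta
    XtVX = UX.T @ (UX / v[:, None])
    XtVy = UX.T @ (Uy / v)
    beta = np.linalg.solve(XtVX, XtVy)
    r = Uy - UX @ beta
    nt, p = UX.shape
    ss = float(np.sum(r * r / v))
    sigma2_g = ss / (nt - p)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    ll = -0.5 * ((nt - p) * np.log(sigma2_g) + np.sum(np.log(v)) + logdet_xvx + (nt - p))
    return ll, sigma2_g, beta


def reml_single_kernel(
    y: np.ndarray,
    K: KinshipMatrix,
    X: np.ndarray | None = None,
    delta_bounds: tuple[float, float] = (1e-5, 1e5),
) -> MixedModelFit:
    """REML fit of y = X beta + u + e, u ~ N(0, A s2_g), via the spectrum of A.

    ``y`` has length n with NaN for unphenotyped individuals; those receive
    genomic predictions through their kinship with the training set.  The
    likelihood is profiled over delta = s2_e/s2_g on the rotated training
    data and optimized by bounded scalar search on log(delta), started from
    the best point of a coarse grid.  Estimates pinned at the bounds are
    returned with ``boundary=True``.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != K.n:
        raise ValueError("y length must match kinship dimension")
    train = np.flatnonzero(np.isfinite(y))
    if len(train) < 3:
        raise ValueError("need >= 3 phenotyped individuals")
    if X is None:
        X = np.ones((K.n, 1))
    Kt = K.A[np.ix_(train, train)]
    lam, U = np.linalg.eigh(Kt)
    lam = np.maximum(lam, 0.0)
    Uy = U.T @ y[train]
    UX = U.T @ X[train]

    logb = (np.log(delta_bounds[0]), np.log(delta_bounds[1]))
    grid = np.linspace(logb[0], logb[1], 25)
    lls = [_restricted_ll(np.exp(t), lam, Uy, UX)[0] for t in grid]
    t0 = grid[int(np.argmax(lls))]
    lo = max(logb[0], t0 - np.diff(grid)[0] * 1.5)
    hi = min(logb[1], t0 + np.diff(grid)[0] * 1.5)
    res = minimize_scalar(lambda t: -_restricted_ll(np.exp(t), lam, Uy, UX)[0], bounds=(lo, hi), method="bounded")
    t_opt = float(res.x)
    delta = float(np.exp(t_opt))
    ll, sigma2_g, beta = _restricted_ll(delta, lam, Uy, UX)
    sigma2_e = delta * sigma2_g
    boundary = t_opt <= logb[0] + 1e-6 or t_opt >= logb[1] - 1e-6

    # BLUP for everyone in K: u = A[:, train] (A_tt + delta I)^-1 (y_t - X_t beta)
    r = y[train] - X[train] @ beta
    w = U @ ((U.T @ r) / (lam + delta))
    u = K.A[:, train] @ w
    return MixedModelFit(
        beta=beta, u=u, sigma2_g=sigma2_g, sigma2_e=sigma2_e,
        loglik=float(ll), delta=delta, boundary=boundary, train_idx=train,
    )


# ----------------------------------------------------------------------
# Heritability partition
# ----------------------------------------------------------------------

@dataclass
class HeritabilityPartition:
    d: int
    sigma2_gA: float
    sigma2_gW: float
    sigma2: float
    sigma2_e: float
    h2_gA: float
    h2_gW: float
    h2_g: float

    @property
    def fraction_across(self) -> float:
        return self.sigma2_gA / self.sigma2 if self.sigma2 > 0 else np.nan

    @property
    def fraction_within(self) -> float:
        return self.sigma2_gW / self.sigma2 if self.sigma2 > 0 else np.nan


def partition_heritability(
    y: np.ndarray,
    K: KinshipMatrix,
    d: int = 3,
    estimator: str = "blup",
) -> HeritabilityPartition:
    """Split genomic variance between the top ``d`` principal components and the rest.

    Fits the rotated model y = 1 mu + U alpha + e (alpha ~ N(0, D s2_G)) by
    REML — numerically identical to the kinship model — then evaluates the
    across/within sums at the BLUP of alpha (``estimator="blup"``, the
    default) or at its posterior second moment (``estimator="posterior"``,
    which adds each component's prediction-error variance to the squared
    BLUP).  The identities s2_gA + s2_gW = s2 and h2_gA + h2_gW = h2_g hold
    exactly for either choice.
    """
    y = np.asarray(y, dtype=float)
    n = K.n
    if not 0 <= d < n - 1:
        raise ValueError(f"d must satisfy 0 <= d < n-1 = {n - 1}")
    if not np.all(np.isfinite(y)):
        raise ValueError("heritability partition requires complete phenotypes")
    if estimator not in ("posterior", "blup"):
        raise ValueError("estimator must be 'posterior' or 'blup'")

    fit = reml_single_kernel(y, K)
    U, lam = K.eig()
    mu = fit.beta[0] if fit.beta.size == 1 else (np.ones(n) @ fit.beta) / n
    yt = U.T @ (y - mu)
    shrink = lam / (lam + fit.delta)
    alpha_blup = shrink * yt
    m2 = alpha_blup**2
    if estimator == "posterior":
        pev = fit.sigma2_g * lam * fit.delta / (lam + fit.delta)
        m2 = m2 + pev

    s_all = float(np.sum(m2)) / (n - 1)
    s_across = float(np.sum(m2[:d])) / (n - 1)
    s_within = s_all - s_across
    denom = s_all + fit.sigma2_e
    return HeritabilityPartition(
        d=d,
        sigma2_gA=s_across,
        sigma2_gW=s_within,
        sigma2=s_all,
        sigma2_e=fit.sigma2_e,
        h2_gA=s_across / denom,
        h2_gW=s_within / denom,
        h2_g=s_all / denom,
    )


def partition_table(partitions: dict[str, HeritabilityPartition]) -> pd.DataFrame:
    """Summary table: one row per trait with components and fractions of total."""
    rows = []
    for trait, p in partitions.items():
        rows.append(
            {
                "trait": trait,
                "h2_gA": p.h2_gA,
                "frac_gA": p.fraction_across,
                "h2_gW": p.h2_gW,
                "frac_gW": p.fraction_within,
                "h2_g": p.h2_g,
                "sigma2_gA": p.sigma2_gA,
                "sigma2_gW": p.sigma2_gW,
                "sigma2_e": p.sigma2_e,
                "d": p.d,
            }
        )
    return pd.DataFrame(rows)
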