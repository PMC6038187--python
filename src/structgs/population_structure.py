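"""Population differentiation and linkage disequilibrium.

Implements the Weir–Cockerham variance-components estimator of F_ST for
pairs (or relabeled unions) of populations, fixed-difference counting,
genotype PCA for visualizing structure, and LD-decay analysis: pairwise
dosage r^2 within chromosomes, an exponential decay fit r^2(d) = a e^{-d/c}
(+ optional asymptote), and the distance at which the fitted curve crosses a
reference r^2 (conventionally 0.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genotype_qc import GenotypeMatrix, pairwise_complete_r2

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Weir–Cockerham F_ST
# ----------------------------------------------------------------------

@dataclass
class FstEstimate:
    pair: tuple[str, str]
    theta: float
    se: float
    per_locus: pd.DataFrame       # columns a, b, c per polymorphic locus
    defined: bool = True


def _wc_components(counts: np.ndarray, het: np.ndarray, freq: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components for r populations.

    ``counts``: (r, L) called individuals per population; ``het``: (r, L)
    observed heterozygote proportion; ``freq``: (r, L) allele frequency.
    Returns arrays (a, b, c) of shape (L,).
    """
    r = counts.shape[0]
    n_bar = counts.mean(axis=0)
    n_c = (r * n_bar - (counts**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (counts * freq).sum(axis=0) / (r * n_bar)
    s2 = (counts * (freq - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (counts * het).sum(axis=0) / (r * n_bar)

    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (pq - (r - 1) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
    c = h_bar / 2.0
    return a, b, c


def weir_cockerham_fst(
    g: GenotypeMatrix, labels: np.ndarray, pair: tuple[str, str]
) -> FstEstimate:
    """Multi-locus weighted Weir–Cockerham theta for one pair of populations.

    theta = sum(a) / sum(a + b + c) over loci polymorphic in the pooled pair
    (ratio of sums, never a mean of per-locus ratios); missing calls are
    handled by per-locus sample sizes.  The standard error comes from a
    delete-one-locus jackknife.  Group comparisons (e.g. all lowland vs
    upland) are obtained by relabeling before the call.
    """
    labels = np.asarray(labels)
    idx = [np.flatnonzero(labels == p) for p in pair]
    for p, i in zip(pair, idx):
        if len(i) < 2:
            raise ValueError(f"population {p} needs >= 2 individuals")

    counts, het, freq = [], [], []
    for i in idx:
        dos = g.dosage[i]
        called = np.isfinite(dos)
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq.append(np.nansum(dos, axis=0) / (2.0 * n))
            het.append(np.nansum(dos == 1, axis=0) / n)
        counts.append(n)
    counts = np.stack(counts).astype(float)
    het = np.stack(het)
    freq = np.stack(freq)

    ok = (counts >= 1).all(axis=0) & (counts.mean(axis=0) > 1)
    pooled_p = (counts * freq).sum(axis=0) / counts.sum(axis=0)
    ok &= (pooled_p > 0) & (pooled_p < 1)
    if not ok.any():
        return FstEstimate(pair=tuple(pair), theta=np.nan, se=np.nan, per_locus=pd.DataFrame(), defined=False)

    a, b, c = _wc_components(counts[:, ok], het[:, ok], freq[:, ok])
    num = a
    den = a + b + c
    theta = float(num.sum() / den.sum())

    L = len(a)
    if L > 1:
        theta_j = (num.sum() - num) / (den.sum() - den)
        theta_j = theta_j[np.isfinite(theta_j)]
        nj = len(theta_j)
        se = float(np.sqrt((nj - 1) / nj * np.sum((theta_j - theta_j.mean()) ** 2))) if nj > 1 else np.nan
    else:
        se = np.nan
    per_locus = pd.DataFrame({"locus": np.flatnonzero(ok), "a": a, "b": b, "c": c})
    return FstEstimate(pair=tuple(pair), theta=theta, se=se, per_locus=per_locus)


def pairwise_fst_table(g: GenotypeMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Weighted theta and jackknife SE for every pair of population labels."""
    pops = list(pd.unique(np.asarray(labels)))
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            est = weir_cockerham_fst(g, labels, (pops[i], pops[j]))
            rows.append({"pop1": pops[i], "pop2": pops[j], "theta": est.theta, "se": est.se})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Fixed differences
# ----------------------------------------------------------------------

@dataclass
class FixedDifferenceReport:
    d_f: int
    fixed_in_one_segregating_in_other: int


def count_fixed_differences(g: GenotypeMatrix, group_a: np.ndarray, group_b: np.ndarray) -> FixedDifferenceReport:
    """Count sites fixed for alternate alleles between two index groups (d_f),
    and sites monomorphic in exactly one group while segregating in the other."""
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) == 0 or len(group_b) == 0 or np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be non-empty and disjoint")

    def span(dos):
        with np.errstate(all="ignore"):
            lo = np.nanmin(dos, axis=0)
            hi = np.nanmax(dos, axis=0)
        return lo, hi

    lo_a, hi_a = span(g.dosage[group_a])
    lo_b, hi_b = span(g.dosage[group_b])
    mono_a = lo_a == hi_a
    mono_b = lo_b == hi_b
    # alternate fixation: each group homozygous-monomorphic for a different allele
    d_f = int(np.sum(mono_a & mono_b & (np.abs(lo_a - lo_b) == 2) & np.isin(lo_a, (0, 2)) & np.isin(lo_b, (0, 2))))
    one_sided = int(np.sum(mono_a ^ mono_b))
    return FixedDifferenceReport(d_f=d_f, fixed_in_one_segregating_in_other=one_sided)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    loadings: np.ndarray          # individuals x components
    variance_explained: np.ndarray
    scaled: bool


def genotype_pca(g: GenotypeMatrix, n_components: int = 8, scale: bool = False) -> PCAResult:
    """PCA of the column-centered dosage matrix (optionally frequency-scaled).

    Deterministic sign convention: within each component the loading of
    largest magnitude is positive.  Requested components beyond the matrix
    rank are truncated with a warning.
    """
    if np.isnan(g.dosage).any():
        raise ValueError("PCA requires a complete (imputed) genotype matrix")
    X = g.dosage - g.dosage.mean(axis=0)
    if scale:
        p = g.allele_frequency()
        sd = np.sqrt(2.0 * p * (1.0 - p))
        keep = sd > 0
        X = X[:, keep] / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    if n_components > rank:
        logger.warning("requested %d components but rank is %d; truncating", n_components, rank)
        n_components = rank
    total_var = float(np.sum(s**2))
    loadings = U[:, :n_components] * s[:n_components]
    for j in range(n_components):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAResult(
        loadings=loadings,
        variance_explained=s[:n_components] ** 2 / total_var,
        scaled=scale,
    )


# ----------------------------------------------------------------------
# LD decay
# ----------------------------------------------------------------------

def ld_r2_pairs(g: GenotypeMatrix, max_dist_bp: int = 1000) -> pd.DataFrame:
    """Pairwise dosage r^2 for all same-chromosome SNP pairs within ``max_dist_bp``.

    Returns a frame (chrom, pos1, pos2, dist, r2) sorted by ascending
    distance.  Pairs involving a monomorphic site (undefined r^2) are
    skipped with a logged count.  r^2 uses pairwise-complete observations,
    so pre-imputation matrices are handled too.
    """
    frames = []
    n_skipped = 0
    for chrom, grp in g.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        if len(idx) < 2:
            continue
        r2 = pairwise_complete_r2(g.dosage[:, idx])
        ii, jj = np.triu_indices(len(idx), k=1)
        dist = np.abs(pos[jj] - pos[ii])
        within = dist <= max_dist_bp
        ii, jj, dist = ii[within], jj[within], dist[within]
        vals = r2[ii, jj]
        good = np.isfinite(vals)
        n_skipped += int((~good).sum())
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos1": pos[ii[good]], "pos2": pos[jj[good]], "dist": dist[good], "r2": vals[good]}
            )
        )
    if n_skipped:
        logger.info("ld_r2_pairs: skipped %d pairs with undefined r2", n_skipped)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos1", "pos2", "dist", "r2"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("dist", kind="stable").reset_index(drop=True)


@dataclass
class LDDecayFit:
    alpha: float
    scale_bp: float
    floor: float
    threshold_r2: float
    threshold_bp: float | None    # None when the fitted curve never crosses
    crossing: str                 # "ok", "above" (never decays below) or "below" (starts under)
    rss: float
    n_pairs: int

    def predict(self, dist: np.ndarray) -> np.ndarray:
        return self.alpha * np.exp(-np.asarray(dist, float) / self.scale_bp) + self.floor


def fit_ld_decay(
    pairs: pd.DataFrame,
    threshold_r2: float = 0.2,
    fit_floor: bool = False,
    n_restarts: int = 5,
) -> LDDecayFit:
    """Fit r^2(d) = a exp(-d / c) (+ floor) by nonlinear least squares.

    Initialized from a log-linear regression on distance-bin means; on
    failure the fit is restarted from perturbed initial values.  The
    threshold distance solves the fitted curve = ``threshold_r2``; a curve
    that never crosses reports ``threshold_bp=None`` with the side flagged.
    """
    d = pairs["dist"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if len(d) < 20 or len(np.unique(d)) < 2:
        raise ValueError("need >= 20 pairs spanning >= 2 distinct distances")

    # initialization from binned means on the log scale
    nbins = min(10, len(np.unique(d)))
    edges = np.quantile(d, np.linspace(0, 1, nbins + 1))
    bins = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, nbins - 1)
    bd = np.array([d[bins == b].mean() for b in range(nbins) if (bins == b).any()])
    br = np.array([r2[bins == b].mean() for b in range(nbins) if (bins == b).any()])
    pos = br > 1e-6
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(bd[pos], np.log(br[pos]), 1)
        c0 = -1.0 / slope if slope < 0 else max(d.max(), 1.0)
        a0 = float(np.clip(np.exp(intercept), 1e-3, 1.5))
    else:
        c0, a0 = max(d.mean(), 1.0), max(r2.mean(), 1e-3)
    c0 = float(np.clip(c0, 1e-3, 100 * d.max()))

    if fit_floor:
        model = lambda x, a, c, f: a * np.exp(-x / c) + f
        p0 = [a0, c0, max(float(br.min()), 0.0)]
        bounds = ([0.0, 1e-6, 0.0], [1.5, np.inf, 1.0])
    else:
        model = lambda x, a, c: a * np.exp(-x / c)
        p0 = [a0, c0]
        bounds = ([0.0, 1e-6], [1.5, np.inf])

    rng = np.random.default_rng(0)
    last_err = None
    for attempt in range(n_restarts):
        try:
            start = list(p0)
            if attempt:
                start = [v * float(rng.uniform(0.3, 3.0)) for v in p0]
                start[0] = min(start[0], 1.4)
            popt, _ = curve_fit(model, d, r2, p0=start, bounds=bounds, maxfev=20000)
            break
        except RuntimeError as err:  # pragma: no cover - exercised only on hard fits
            last_err = err
    else:
        raise RuntimeError(f"LD decay fit failed after {n_restarts} starts: {last_err}")

    a, c = float(popt[0]), float(popt[1])
    f = float(popt[2]) if fit_floor else 0.0
    rss = float(np.sum((model(d, *popt) - r2) ** 2))

    if f >= threshold_r2:
        threshold, crossing = None, "above"
    elif a + f <= threshold_r2:
        threshold, crossing = None, "below"
    else:
        threshold, crossing = float(c * np.log(a / (threshold_r2 - f))), "ok"
    return LDDecayFit(
        alpha=a, scale_bp=c, floor=f, threshold_r2=threshold_r2,
        threshold_bp=threshold, crossing=crossing, rss=rss, n_pairs=len(d),
    )
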