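"""Genotype containers, file I/O, the SNP filtering cascade and LD-kNNi imputation.

The central object is :class:`GenotypeMatrix`: individuals x biallelic SNPs
coded as minor-allele dosage {0, 1, 2} with ``NaN`` marking missing calls and
an optional per-call read depth, as produced by reduced-representation
sequencing (GBS) pipelines.  The QC cascade applied to such data runs, in
order:

1. mask calls with read depth below a threshold (shallow GBS calls are
   unreliable single-read genotypes),
2. drop individuals with excessive missingness,
3. drop sites with low minor-allele frequency or low call rate,
4. prune sites in complete LD with an earlier site on the same chromosome.

Missing genotypes are then completed with LD-kNN imputation (LD-kNNi): for
each missing call the ``l`` sites in strongest LD with the target site define
a distance between individuals, and the ``k`` nearest individuals with a
known genotype vote, weighted by inverse distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: value used in TSV output for a missing dosage
MISSING_TOKEN = "NA"

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix with map and depth.

    Parameters
    ----------
    samples
        Ordered individual identifiers (length n).
    snps
        SNP map with columns ``snp_id, chrom, pos, ref, alt`` (length m);
        positions are 1-based and strictly increasing within a chromosome.
    dosage
        ``(n, m)`` float array with entries in {0, 1, 2} and ``NaN`` for
        missing calls.
    depth
        Optional ``(n, m)`` integer read-depth array; 0 where the call is
        missing.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.depth is not None and self.depth.shape != self.dosage.shape:
            raise ValueError("depth shape does not match dosage shape")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def missing_fraction(self) -> float:
        return float(np.mean(np.isnan(self.dosage)))

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted (dosage) allele per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.copy(),
            dosage=self.dosage.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays (order kept)."""
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            dosage=self.dosage[np.ix_(sample_idx, snp_idx)],
            depth=None if self.depth is None else self.depth[np.ix_(sample_idx, snp_idx)],
        )


@dataclass
class FilterReport:
    """Record of one QC step: thresholds used and what was removed."""

    step: str
    thresholds: dict
    removed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": self.step, "quantity": k, "count": v, **{f"thr_{a}": b for a, b in self.thresholds.items()}}
            for k, v in self.removed.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class ImputationResult:
    completed: GenotypeMatrix
    k: int
    l: int
    masked_accuracy: float | None = None


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _polarize_minor(dosage: np.ndarray, snps: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip dosage at sites where the counted allele is the major one.

    Polarity is decided over the whole file: a site is flipped when the
    frequency of the counted allele strictly exceeds 0.5, so that dosage
    always counts the minor allele.  The flip is recorded in a ``flipped``
    column so file writers can restore the original REF/ALT orientation.
    """
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosage, axis=0) / 2.0
    flip = p > 0.5
    dosage = dosage.copy()
    dosage[:, flip] = 2.0 - dosage[:, flip]
    snps = snps.copy()
    snps["flipped"] = flip
    return dosage, snps


def polarize_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy coded so dosage counts the minor allele (observed calls).

    Composes with any existing ``flipped`` flags so that file writers can
    always restore the original REF/ALT orientation.  A site at exactly 0.5
    frequency is canonicalized to the original (unflipped) orientation so
    that write/read round trips are unambiguous.
    """
    out = g.copy()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(out.dosage, axis=0) / 2.0
    prev = out.snps["flipped"].to_numpy() if "flipped" in out.snps.columns else np.zeros(g.n_snps, bool)
    flip = (p > 0.5) | ((p == 0.5) & prev)
    out.dosage[:, flip] = 2.0 - out.dosage[:, flip]
    out.snps = out.snps.copy()
    out.snps["flipped"] = prev ^ flip
    return out


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read an (uncompressed or bgzipped) VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNPs enter the matrix; multi-allelic records and indels
    are dropped with a logged count.  Dosage counts the minor allele as
    determined over the whole file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no samples in VCF {path}")
    rows = []
    dosages = []
    depths = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        try:
            dp_raw = var.format("DP")
        except KeyError:
            dp_raw = None
        dp = np.zeros(len(samples), dtype=int) if dp_raw is None else np.maximum(dp_raw.reshape(-1).astype(int), 0)
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosages.append(dos)
        depths.append(dp)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    dosage = np.column_stack(dosages)
    depth = np.column_stack(depths)
    dosage, snps = _polarize_minor(dosage, snps)
    if not np.any(depth > 0):
        depth = None
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage, depth=depth)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF with GT:DP fields, restoring REF/ALT orientation."""
    flip = g.snps["flipped"].to_numpy() if "flipped" in g.snps.columns else np.zeros(g.n_snps, bool)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(g.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples) + "\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(g.n_snps):
            rec = g.snps.iloc[j]
            dos = g.dosage[:, j]
            if flip[j]:
                dos = 2.0 - dos
            cells = []
            for i in range(g.n_samples):
                gt = "./." if np.isnan(dos[i]) else gt_codes[dos[i]]
                dp = 0 if g.depth is None else int(g.depth[i, j])
                cells.append(f"{gt}:{dp}")
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.ref}\t{rec.alt}\t.\t.\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def read_dosage_tsv(path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a dosage TSV (rows = individuals, header = SNP ids) plus a map TSV.

    The map TSV must have columns ``snp_id, chrom, pos`` (``ref``/``alt``
    optional).  Dosages are taken as given — a TSV matrix is assumed to be
    minor-allele coded already since no allele labels accompany the counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    if df.empty:
        raise ValueError(f"empty dosage matrix {path}")
    m = pd.read_csv(map_path, sep="\t")
    m = m.rename(columns={"pos_bp": "pos"})
    m.columns = [str(c) for c in m.columns]
    if not {"snp_id", "chrom", "pos"}.issubset(m.columns):
        raise ValueError(f"map {map_path} must have snp_id, chrom, pos columns")
    m = m.set_index("snp_id").loc[df.columns]
    m.index.name = "snp_id"
    m = m.reset_index()
    for col in ("ref", "alt"):
        if col not in m.columns:
            m[col] = "N"
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        snps=m[SNP_COLUMNS],
        dosage=df.to_numpy(dtype=float),
    )


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path, map_path: str | Path) -> None:
    df = pd.DataFrame(g.dosage, index=g.samples, columns=g.snps["snp_id"])
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="sample")
    g.snps.rename(columns={"pos": "pos_bp"}).to_csv(map_path, sep="\t", index=False)


def read_genotypes(path: str | Path, fmt: str = "vcf", map_path: str | Path | None = None) -> GenotypeMatrix:
    """Dispatching reader: ``fmt`` is ``"vcf"`` or ``"tsv"`` (dosage matrix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        if map_path is None:
            raise ValueError("dosage TSV requires a sidecar map TSV")
        return read_dosage_tsv(path, map_path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ----------------------------------------------------------------------
# Filtering cascade
# ----------------------------------------------------------------------

def mask_low_depth(g: GenotypeMatrix, min_depth: int = 2) -> tuple[GenotypeMatrix, FilterReport]:
    """Set calls with read depth below ``min_depth`` to missing."""
    if min_depth <= 1:
        return g.copy(), FilterReport("mask_low_depth", {"min_depth": min_depth}, {"calls_masked": 0})
    if g.depth is None:
        raise ValueError("depth field required to mask low-depth calls")
    out = g.copy()
    low = (out.depth < min_depth) & ~np.isnan(out.dosage)
    out.dosage[low] = np.nan
    out.depth[low] = 0
    report = FilterReport("mask_low_depth", {"min_depth": min_depth}, {"calls_masked": int(low.sum())})
    return out, report


def filter_individuals(g: GenotypeMatrix, max_missing: float = 0.75) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove individuals with missing fraction strictly greater than ``max_missing``."""
    frac = np.mean(np.isnan(g.dosage), axis=1)
    keep = frac <= max_missing
    if not keep.any():
        raise ValueError("all individuals removed by missingness filter")
    out = g.subset(sample_idx=np.flatnonzero(keep))
    report = FilterReport(
        "filter_individuals",
        {"max_missing": max_missing},
        {"individuals_removed": int((~keep).sum())},
    )
    return out, report


def filter_sites(
    g: GenotypeMatrix, maf_min: float = 0.025, call_rate_min: float = 0.5
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove sites with MAF < ``maf_min`` or call rate < ``call_rate_min`` (both strict)."""
    maf = g.maf()
    cr = g.call_rate()
    low_maf = maf < maf_min
    low_cr = cr < call_rate_min
    keep = ~(low_maf | low_cr)
    if not keep.any():
        raise ValueError("all sites removed by site filters")
    out = g.subset(snp_idx=np.flatnonzero(keep))
    report = FilterReport(
        "filter_sites",
        {"maf_min": maf_min, "call_rate_min": call_rate_min},
        {
            "sites_low_maf": int(low_maf.sum()),
            "sites_low_call_rate": int(low_cr.sum()),
            "sites_removed": int((~keep).sum()),
        },
    )
    return out, report


def pairwise_complete_r2(dosage: np.ndarray, min_obs: int = 2) -> np.ndarray:
    """All-pairs squared Pearson correlation of dosage columns, pairwise complete.

    Uses mask matrix products so the cost is a handful of dense matmuls.
    Entries with fewer than ``min_obs`` shared observations or zero variance
    are ``NaN``.
    """
    M = np.isfinite(dosage).astype(float)
    X = np.where(np.isfinite(dosage), dosage, 0.0)
    X2 = X * X
    n = M.T @ M
    sx = X.T @ M          # sum of column a over calls shared with column b
    sxx = X2.T @ M
    sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_a = n * sxx - sx**2
        var_b = var_a.T
        r2 = cov**2 / (var_a * var_b)
    r2[n < min_obs] = np.nan
    with np.errstate(invalid="ignore"):
        r2[(var_a <= 0) | (var_b <= 0)] = np.nan
    return r2


def prune_complete_ld(g: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterReport]:
    """Prune sites in complete LD (r^2 = 1) with an earlier site on the same chromosome.

    Among mutually identical (up to linear transform) sites only the one with
    the lowest map position survives.  r^2 is computed on pairwise-complete
    observations.
    """
    keep = np.ones(g.n_snps, dtype=bool)
    tol = 1e-9
    for chrom, grp in g.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            continue
        r2 = pairwise_complete_r2(g.dosage[:, idx])
        kept_local: list[int] = []
        for a in range(len(idx)):
            complete = False
            for b in kept_local:
                v = r2[a, b]
                if np.isfinite(v) and v >= 1.0 - tol:
                    complete = True
                    break
            if complete:
                keep[idx[a]] = False
            else:
                kept_local.append(a)
    out = g.subset(snp_idx=np.flatnonzero(keep))
    report = FilterReport("prune_complete_ld", {}, {"sites_pruned": int((~keep).sum())})
    return out, report


def run_qc_cascade(
    g: GenotypeMatrix,
    min_depth: int = 2,
    max_ind_missing: float = 0.75,
    maf_min: float = 0.025,
    call_rate_min: float = 0.5,
    prune_ld: bool = True,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """Apply the full QC cascade in its canonical order.

    Order: depth masking -> individual missingness -> site MAF/call-rate ->
    complete-LD pruning.  Rerunning the cascade on its own output is a no-op.
    """
    reports = []
    if g.depth is not None and min_depth > 1:
        g, rep = mask_low_depth(g, min_depth)
        reports.append(rep)
    g, rep = filter_individuals(g, max_ind_missing)
    reports.append(rep)
    g, rep = filter_sites(g, maf_min, call_rate_min)
    reports.append(rep)
    if prune_ld:
        g, rep = prune_complete_ld(g)
        reports.append(rep)
    return g, reports


# ----------------------------------------------------------------------
# LD-kNNi imputation
# ----------------------------------------------------------------------

_DIST_EPS = 1e-5


def impute_ldknni(g: GenotypeMatrix, k: int = 13, l: int = 8, seed: int = 0) -> ImputationResult:
    """Complete missing dosages with LD-kNN imputation.

    For each site with missing calls, the ``l`` sites with highest r^2 to the
    target site define a per-individual profile; distances between the target
    individual and candidate donors are mean absolute dosage differences over
    the shared non-missing entries of that profile.  The ``k`` nearest donors
    with a known call at the target site vote with weight 1/max(d, eps) and
    the weighted mean is rounded half-to-even to {0, 1, 2}.

    All tie-breaks are deterministic (higher r^2 then lower map index for LD
    sites; smaller distance then lower sample index for neighbors), so the
    result does not depend on ``seed``; the argument is kept so callers can
    treat imputation uniformly with stochastic stages.
    """
    del seed  # deterministic; see docstring
    if k < 1 or l < 1:
        raise ValueError("k and l must be >= 1")
    miss = np.isnan(g.dosage)
    if not miss.any():
        return ImputationResult(completed=g.copy(), k=k, l=l)
    if np.all(miss, axis=0).any():
        raise ValueError("site with no non-missing calls cannot be imputed")
    out = g.copy()
    r2 = pairwise_complete_r2(g.dosage)
    np.fill_diagonal(r2, np.nan)
    order_key = np.where(np.isfinite(r2), r2, -np.inf)
    n, m = g.dosage.shape
    for j in np.flatnonzero(miss.any(axis=0)):
        # l sites most in LD with the target site (ties: lower index first)
        top = np.lexsort((np.arange(m), -order_key[:, j]))[: min(l, m - 1)]
        profile = g.dosage[:, top]
        targets = np.flatnonzero(miss[:, j])
        donors = np.flatnonzero(~miss[:, j])
        T = profile[targets]           # (t, l)
        D = profile[donors]            # (d, l)
        both = np.isfinite(T)[:, None, :] & np.isfinite(D)[None, :, :]
        diff = np.abs(np.where(both, T[:, None, :] - D[None, :, :], 0.0))
        shared = both.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = diff.sum(axis=2) / shared
        dist[shared == 0] = np.inf
        kk = min(k, len(donors))
        # nearest donors; ties by sample index
        nn = np.lexsort((np.broadcast_to(np.arange(len(donors)), dist.shape), dist), axis=1)[:, :kk]
        nd = np.take_along_axis(dist, nn, axis=1)
        with np.errstate(divide="ignore"):
            w = np.where(np.isfinite(nd), 1.0 / np.maximum(nd, _DIST_EPS), 0.0)
        # a target missing at every LD site has no usable distances; fall
        # back to the unweighted mean of the k donors
        dead = w.sum(axis=1) == 0
        w[dead] = 1.0
        vals = g.dosage[donors[nn], j]
        est = (w * vals).sum(axis=1) / w.sum(axis=1)
        out.dosage[targets, j] = np.clip(np.round(est), 0.0, 2.0)
    return ImputationResult(completed=out, k=k, l=l)


def estimate_imputation_accuracy(
    g: GenotypeMatrix, n_mask: int = 10000, k: int = 13, l: int = 8, seed: int = 0
) -> float:
    """Mask ``n_mask`` known calls, impute, and return the fraction recovered exactly."""
    known = np.flatnonzero(~np.isnan(g.dosage).ravel())
    if len(known) < n_mask:
        raise ValueError(f"only {len(known)} known calls available, need {n_mask}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(known, size=n_mask, replace=False)
    masked = g.copy()
    flat = masked.dosage.ravel()
    truth = flat[chosen].copy()
    flat[chosen] = np.nan
    # a site fully masked by chance cannot be imputed; restore one call there
    dead = np.flatnonzero(np.all(np.isnan(masked.dosage), axis=0))
    restored = np.zeros(len(chosen), dtype=bool)
    for j in dead:
        hit = np.flatnonzero(chosen % masked.n_snps == j)[:1]
        flat[chosen[hit]] = truth[hit]
        restored[hit] = True
    result = impute_ldknni(masked, k=k, l=l, seed=seed)
    imputed = result.completed.dosage.ravel()[chosen]
    use = ~restored
    return float(np.mean(imputed[use] == truth[use]))
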