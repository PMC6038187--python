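"""Simulation of structured multi-population genotype panels and replicated traits.

The generator emulates the kind of germplasm panel used in perennial-grass
genomic selection: a handful of differentiated populations (two ecotype
groups plus an admixed hybrid cohort), shallow GBS genotyping with
substantial missingness, and quantitative traits whose genetic variance
splits between an across-population component (population mean differences)
and a within-population component (segregating QTL).

Allele frequencies follow a Balding–Nichols hierarchy: an ancestral
frequency per SNP drawn Uniform(0.05, 0.95); optionally a group-level
frequency drawn Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral value; and
a population-level frequency drawn the same way around its group value with
the population's differentiation parameter F.

Local LD is induced by Markov allele copying along each gamete: within a
haplotype block a site copies the previous site's allele with probability
``copy_prob`` and draws fresh from its population frequency otherwise.
Marginal site frequencies become a deterministic geometric smooth of the
population frequencies along the block — a per-population constant, so the
mechanism adds no drift variance and leaves the realized differentiation at
its design value — while r^2 between neighboring sites approaches
copy_prob^2 and decays geometrically with marker distance; blocks are
independent.  Optional full-sib family structure (parents drawn from the
population, progeny recombining parental haplotypes at block boundaries)
emulates the within-population relatedness of polycross-derived seed lots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_qc import SNP_COLUMNS, GenotypeMatrix, polarize_minor
from .quantitative_genetics import PhenotypeTable

_RETRY_CAP = 100


@dataclass
class PopulationDesign:
    """Panel composition: population labels, sizes and differentiation.

    ``fst`` gives each population's drift parameter from its group (or from
    the ancestral pool if it has no group); ``group_fst`` gives each group's
    drift from the ancestral pool.  With two groups at F_g and member
    populations at small F_k this produces low within-group and high
    between-group pairwise differentiation, the classic upland/lowland
    pattern.  ``admixed`` maps a hybrid population to its two (non-admixed)
    parents and the probability that a gamete comes from the first parent.
    ``family_size`` (optional) organizes each non-admixed population into
    full-sib families of that size, emulating polycross seed lots.
    """

    pop_ids: list[str]
    sizes: dict[str, int]
    fst: dict[str, float]
    admixed: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    group_fst: dict[str, float] = field(default_factory=dict)
    family_size: int | None = None

    def __post_init__(self) -> None:
        for pid in self.pop_ids:
            if self.sizes.get(pid, 0) < 2:
                raise ValueError(f"population {pid} needs >= 2 individuals")
        for pid, f in {**self.fst, **self.group_fst}.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"differentiation parameter for {pid} must be in [0, 1)")
        for hybrid, (pa, pb, prop) in self.admixed.items():
            if hybrid not in self.pop_ids:
                raise ValueError(f"admixed population {hybrid} not in design")
            for parent in (pa, pb):
                if parent not in self.pop_ids or parent in self.admixed:
                    raise ValueError(f"admixture parent {parent} must be a non-admixed design population")
            if not 0.0 <= prop <= 1.0:
                raise ValueError("mixing proportion must be in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return sum(self.sizes[p] for p in self.pop_ids)


@dataclass
class GenomeLayout:
    """Marker map used by the simulator.

    ``positions`` maps chromosome name -> strictly increasing 1-based bp
    coordinates.  ``block_length`` (bp) bounds the haplotype blocks inside
    which the Markov copula runs; ``copy_prob`` is the probability that a
    site's latent uniform is copied from the previous site of its block
    (``None`` or 0 gives fully independent sites).
    """

    positions: dict[str, np.ndarray]
    block_length: int = 500
    copy_prob: float | None = 0.9

    def __post_init__(self) -> None:
        if self.block_length <= 0:
            raise ValueError("block_length must be > 0")
        if self.copy_prob is not None and not 0.0 <= self.copy_prob < 1.0:
            raise ValueError("copy_prob must be in [0, 1)")
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            self.positions[chrom] = pos

    @classmethod
    def regular(
        cls,
        n_chromosomes: int = 1,
        snps_per_chromosome: int = 1000,
        spacing_bp: int = 100,
        block_length: int = 500,
        copy_prob: float | None = 0.9,
    ) -> "GenomeLayout":
        positions = {
            f"chr{c + 1}": (np.arange(snps_per_chromosome) + 1) * spacing_bp
            for c in range(n_chromosomes)
        }
        return cls(positions=positions, block_length=block_length, copy_prob=copy_prob)

    @property
    def n_snps(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def snp_map(self) -> pd.DataFrame:
        rows = []
        for chrom, pos in self.positions.items():
            for p in pos:
                rows.append((f"{chrom}_{p}", chrom, int(p), "A", "C"))
        return pd.DataFrame(rows, columns=SNP_COLUMNS)

    def blocks(self) -> list[np.ndarray]:
        """Global SNP-index arrays, one per haplotype block."""
        out = []
        offset = 0
        for chrom, pos in self.positions.items():
            block_id = (np.asarray(pos) - 1) // self.block_length
            for b in np.unique(block_id):
                out.append(offset + np.flatnonzero(block_id == b))
            offset += len(pos)
        return out


@dataclass
class TraitArchitecture:
    """Target genetic architecture for a simulated trait.

    ``h2_across``/``h2_within`` are the target across- and within-population
    genomic heritabilities on the genotype-mean phenotype scale (total
    phenotypic variance 1).  ``plot_error_sd`` is the per-replicate residual
    standard deviation; left ``None`` it is derived so that the genotype-mean
    residual variance equals the remaining 1 - h2_across - h2_within.
    """

    n_qtl: int = 100
    h2_within: float = 0.25
    h2_across: float = 0.25
    n_reps: int = 2
    plot_error_sd: float | None = None
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.h2_within < 0 or self.h2_across < 0 or self.h2_within + self.h2_across >= 1:
            raise ValueError("need h2_within + h2_across < 1 with both non-negative")


@dataclass
class SimulatedDataset:
    """Simulation truth bookkeeping for parameter-recovery tests."""

    genotypes: GenotypeMatrix
    labels: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    phenotypes: PhenotypeTable
    realized: dict


def _beta_around(
    rng: np.random.Generator, p: np.ndarray, f: float, quantiles: np.ndarray | None = None
) -> np.ndarray:
    """Balding–Nichols draw around parent frequencies ``p`` with drift ``f``.

    With ``quantiles`` given (one uniform per site, typically shared within a
    haplotype block), the draw is the Beta quantile function evaluated there:
    per-site marginals are unchanged but drift becomes locally correlated, the
    way linked sites drift together in real genomes.
    """
    if f <= 0.0:
        return p.copy()
    p = np.clip(p, 1e-6, 1.0 - 1e-6)  # a parent frequency drawn at the boundary stays drawable
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    if quantiles is None:
        return rng.beta(a, b)
    from scipy.stats import beta as beta_dist

    return beta_dist.ppf(np.clip(quantiles, 1e-12, 1 - 1e-12), a, b)


def _population_frequencies(
    design: PopulationDesign, m: int, rng: np.random.Generator, block_of: np.ndarray | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw ancestral and per-population frequencies, resampling SNPs that
    come out monomorphic across every population.

    With ``block_of`` given (site -> haplotype-block index), the drift
    quantile of each Beta draw is shared by all sites of a block, so linked
    sites drift in the same direction (marginals unchanged)."""
    founders = [p for p in design.pop_ids if p not in design.admixed]
    p_anc = rng.uniform(0.05, 0.95, size=m)
    freqs = {p: np.empty(m) for p in founders}
    todo = np.arange(m)

    def block_quantiles():
        if block_of is None:
            return None
        n_blocks = int(block_of.max()) + 1
        return rng.random(n_blocks)[block_of[todo]]

    for attempt in range(_RETRY_CAP):
        group_freq: dict[str, np.ndarray] = {}
        for grp, f in design.group_fst.items():
            group_freq[grp] = _beta_around(rng, p_anc[todo], f, block_quantiles())
        for pop in founders:
            base = group_freq.get(design.groups.get(pop), p_anc[todo])
            freqs[pop][todo] = _beta_around(rng, base, design.fst.get(pop, 0.0), block_quantiles())
        stacked = np.stack([freqs[p][todo] for p in founders])
        eps = 1e-9
        mono = np.all(stacked < eps, axis=0) | np.all(stacked > 1 - eps, axis=0)
        if not mono.any():
            break
        todo = todo[mono]
        p_anc[todo] = rng.uniform(0.05, 0.95, size=len(todo))
    else:
        raise RuntimeError("could not draw polymorphic frequencies within the retry cap")
    return p_anc, freqs


def simulate_structured_genotypes(
    design: PopulationDesign, layout: GenomeLayout, seed: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate a complete (no-missing) dosage panel and population labels.

    Fully reproducible from ``seed``.  With ``layout.copy_prob`` set, a
    Markov copula correlates sites within each haplotype block (marginal
    frequencies stay exact, so realized differentiation tracks the design
    parameters); otherwise sites are independent Binomial(2, p) draws.
    Admixed individuals draw each gamete's origin population per the mixing
    proportion; with ``design.family_size`` the non-admixed populations are
    organized into full-sib families whose progeny recombine the parental
    haplotypes at block boundaries.
    """
    rng = np.random.default_rng(seed)
    m = layout.n_snps
    copy_prob = layout.copy_prob or 0.0
    blocks = layout.blocks()
    block_of = np.empty(m, dtype=int)
    for bi, b in enumerate(blocks):
        block_of[b] = bi
    block_start = np.zeros(m, dtype=bool)
    for b in blocks:
        block_start[b[0]] = True

    # with LD on, drift is block-correlated so the chain smoothing below
    # does not average independent drift away
    _, freqs = _population_frequencies(design, m, rng, block_of if copy_prob > 0 else None)

    n_total = design.n_individuals
    dosage = np.zeros((n_total, m))
    labels = np.empty(n_total, dtype=object)

    def draw_gametes(popname: str, count: int) -> np.ndarray:
        """count haploid genomes from one founder population."""
        p = freqs[popname]
        if copy_prob <= 0.0:
            return (rng.random((count, m)) < p).astype(float)
        hap = np.empty((count, m))
        fresh = (rng.random((count, m)) < p).astype(float)
        keep = rng.random((count, m)) < copy_prob
        for j in range(m):
            if block_start[j]:
                hap[:, j] = fresh[:, j]
            else:
                hap[:, j] = np.where(keep[:, j], hap[:, j - 1], fresh[:, j])
        return hap

    def recombine(hapA: np.ndarray, hapB: np.ndarray) -> np.ndarray:
        """One gamete per row: per block, inherit from hapA or hapB."""
        pick = rng.random((hapA.shape[0], len(blocks))) < 0.5
        choose = pick[:, block_of]
        return np.where(choose, hapA, hapB)

    def draw_family_population(popname: str, size: int) -> np.ndarray:
        fam = design.family_size
        n_fam = int(np.ceil(size / fam))
        out = np.empty((size, m))
        done = 0
        for _ in range(n_fam):
            k = min(fam, size - done)
            parents = draw_gametes(popname, 4)  # mother (0,1), father (2,3)
            mom = np.broadcast_to(parents[0], (k, m)), np.broadcast_to(parents[1], (k, m))
            dad = np.broadcast_to(parents[2], (k, m)), np.broadcast_to(parents[3], (k, m))
            out[done : done + k] = recombine(*mom) + recombine(*dad)
            done += k
        return out

    row = 0
    for popname in design.pop_ids:
        size = design.sizes[popname]
        labels[row : row + size] = popname
        if popname in design.admixed:
            pa, pb, prop = design.admixed[popname]
            for gamete in range(2):
                origin = rng.random(size) < prop
                ga = draw_gametes(pa, int(origin.sum()))
                gb = draw_gametes(pb, int((~origin).sum()))
                hap = np.empty((size, m))
                hap[origin] = ga
                hap[~origin] = gb
                dosage[row : row + size] += hap
        elif design.family_size:
            dosage[row : row + size] = draw_family_population(popname, size)
        else:
            dosage[row : row + size] = draw_gametes(popname, size) + draw_gametes(popname, size)
        row += size

    g = GenotypeMatrix(
        samples=[f"{labels[i]}_{i:04d}" for i in range(n_total)],
        snps=layout.snp_map(),
        dosage=dosage,
    )
    return polarize_minor(g), labels


def simulate_trait(
    genotypes: GenotypeMatrix, labels: np.ndarray, arch: TraitArchitecture, seed: int
) -> SimulatedDataset:
    """Simulate a replicated trait with controlled across/within architecture.

    QTL are sampled uniformly among SNPs with standard-normal effects; the
    raw genetic value is split into its population-mean part and its
    within-population deviation, and each part is rescaled so the realized
    variances equal ``h2_across`` and ``h2_within`` exactly (the two parts
    are orthogonal by construction).  Replicate phenotypes add independent
    Gaussian plot noise.
    """
    if np.isnan(genotypes.dosage).any():
        raise ValueError("trait simulation requires a complete genotype matrix")
    labels = np.asarray(labels)
    pops = pd.unique(labels)
    if arch.h2_across > 0 and len(pops) < 2:
        raise ValueError("h2_across > 0 requires at least two populations")

    rng = np.random.default_rng(seed)
    m = genotypes.n_snps
    qtl = np.sort(rng.choice(m, size=min(arch.n_qtl, m), replace=False))
    effects = rng.normal(size=len(qtl))
    g_raw = genotypes.dosage[:, qtl] @ effects

    pop_mean = pd.Series(g_raw).groupby(labels).transform("mean").to_numpy()
    g_within = g_raw - pop_mean
    g_across = pop_mean - pop_mean.mean()

    def rescale(x: np.ndarray, target_var: float) -> np.ndarray:
        if target_var == 0.0:
            return np.zeros_like(x)
        v = x.var()
        if v <= 0:
            raise ValueError("requested variance component is unattainable (no variation in that part)")
        return x * np.sqrt(target_var / v)

    tbv = rescale(g_across, arch.h2_across) + rescale(g_within, arch.h2_within)
    resid_var = 1.0 - arch.h2_across - arch.h2_within
    plot_sd = arch.plot_error_sd if arch.plot_error_sd is not None else float(np.sqrt(resid_var * arch.n_reps))

    n = genotypes.n_samples
    noise = rng.normal(scale=plot_sd, size=(n, arch.n_reps)) if plot_sd > 0 else np.zeros((n, arch.n_reps))
    records = pd.DataFrame(
        {
            "genotype_id": np.repeat(genotypes.samples, arch.n_reps),
            "replicate_id": np.tile(np.arange(1, arch.n_reps + 1), n),
            "trait": arch.trait,
            "value": (tbv[:, None] + noise).ravel(),
        }
    )
    realized = {
        "var_across": float(np.var(rescale(g_across, arch.h2_across))),
        "var_within": float(np.var(rescale(g_within, arch.h2_within))),
        "var_tbv": float(np.var(tbv)),
        "plot_error_sd": plot_sd,
        "genotype_mean_residual_var": plot_sd**2 / arch.n_reps,
    }
    return SimulatedDataset(
        genotypes=genotypes,
        labels=labels,
        qtl_indices=qtl,
        qtl_effects=effects,
        true_breeding_values=tbv,
        phenotypes=PhenotypeTable(records),
        realized=realized,
    )


def apply_gbs_missingness(
    genotypes: GenotypeMatrix, mean_depth: float = 4.0, missing_rate: float = 0.29, seed: int = 0
) -> GenotypeMatrix:
    """Overlay GBS-like missingness and per-call read depths on a complete panel.

    Calls are masked independently at ``missing_rate``; retained calls get a
    depth drawn from a Poisson(``mean_depth``) truncated at >= 1 (a stand-in
    for the unspecified depth distribution of real GBS runs — the depth-1
    mass can be matched to an observed shallow-call rate by choosing
    ``mean_depth``).  The input matrix is not modified.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    out = genotypes.copy()
    shape = out.dosage.shape
    depth = rng.poisson(mean_depth, size=shape)
    zero = depth == 0
    while zero.any():  # truncate at >= 1 by redrawing
        depth[zero] = rng.poisson(mean_depth, size=int(zero.sum()))
        zero = depth == 0
    mask = rng.random(shape) < missing_rate
    out.dosage = np.where(mask, np.nan, out.dosage)
    depth = np.where(mask, 0, depth)
    out.depth = depth
    return out


def mean_depth_for_depth1_fraction(target: float) -> float:
    """Solve for the truncated-Poisson mean whose P(depth = 1) equals ``target``.

    P(D = 1 | D >= 1) = mu e^-mu / (1 - e^-mu); useful to calibrate the depth
    model against an observed fraction of single-read calls.
    """
    from scipy.optimize import brentq

    if not 0.0 < target < 1.0:
        raise ValueError("target fraction must be in (0, 1)")
    f = lambda mu: mu * np.exp(-mu) / (1.0 - np.exp(-mu)) - target
    return float(brentq(f, 1e-9, 60.0))


def write_labels_tsv(labels: np.ndarray, samples: list[str], path) -> None:
    pd.DataFrame({"sample": samples, "population": labels}).to_csv(path, sep="\t", index=False)


def write_truth_tsv(ds: SimulatedDataset, path) -> None:
    pd.DataFrame(
        {"sample": ds.genotypes.samples, "population": ds.labels, "tbv": ds.true_breeding_values}
    ).to_csv(path, sep="\t", index=False)
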