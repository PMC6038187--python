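import numpy as np
import pandas as pd
import pytest

import structgs as s


def make_matrix(dosage, depth=None, chrom=None, pos=None, samples=None):
    """Build a GenotypeMatrix from a plain array for hand-constructed fixtures."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    chrom = ["chr1"] * m if chrom is None else list(chrom)
    pos = list(range(1, m + 1)) if pos is None else list(pos)
    snps = pd.DataFrame(
        {
            "snp_id": [f"{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "C",
        }
    )
    samples = [f"ind{i}" for i in range(n)] if samples is None else samples
    return s.GenotypeMatrix(
        samples=samples,
        snps=snps,
        dosage=dosage,
        depth=None if depth is None else np.asarray(depth, dtype=int),
    )


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two well-differentiated populations, independent sites."""
    design = s.PopulationDesign(
        pop_ids=["A", "B"], sizes={"A": 100, "B": 100}, fst={"A": 0.3, "B": 0.3}
    )
    layout = s.GenomeLayout.regular(1, 800, copy_prob=None)
    g, labels = s.simulate_structured_genotypes(design, layout, seed=11)
    return g, labels


@pytest.fixture(scope="session")
def block_ld_panel():
    """Single unstructured population with strong within-block LD."""
    design = s.PopulationDesign(pop_ids=["A"], sizes={"A": 180}, fst={"A": 0.0})
    layout = s.GenomeLayout.regular(
        1, 400, spacing_bp=100, block_length=1000, copy_prob=0.95
    )
    g, labels = s.simulate_structured_genotypes(design, layout, seed=13)
    return g, labels


@pytest.fixture(scope="session")
def structured_trait_panel():
    """Three populations with a trait split between across and within variance."""
    design = s.PopulationDesign(
        pop_ids=["P1", "P2", "P3"],
        sizes={"P1": 70, "P2": 70, "P3": 70},
        fst={"P1": 0.2, "P2": 0.2, "P3": 0.2},
    )
    layout = s.GenomeLayout.regular(1, 900, copy_prob=None)
    g, labels = s.simulate_structured_genotypes(design, layout, seed=17)
    arch = s.TraitArchitecture(n_qtl=120, h2_within=0.25, h2_across=0.25, n_reps=2)
    ds = s.simulate_trait(g, labels, arch, seed=18)
    y = (
        ds.phenotypes.data.groupby("genotype_id", sort=False)["value"]
        .mean()
        .loc[g.samples]
        .to_numpy()
    )
    return g, labels, y, ds
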