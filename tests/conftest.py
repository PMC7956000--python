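"""Shared fixtures: in-memory matrices, noisy VCF fixtures, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from inbredfm import GenotypeMatrix, StrainPanel, VariantRecord
from inbredfm.simulate import FixtureSpec, PlantedVariant, albinism_example, generate_vcf

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent compatibility oracle (plain loops, no package predicate logic)

def oracle_compatible(g1, g2, thr1, thr2, null_is_mismatch=True) -> bool:
    """Exhaustively try both allele assignments and count mismatches."""
    for a1, a2 in ((0, 1), (1, 0)):
        bad1 = bad2 = 0
        for g in g1:
            if g == -1:
                bad1 += 1 if null_is_mismatch else 0
            elif g != a1:
                bad1 += 1
        for g in g2:
            if g == -1:
                bad2 += 1 if null_is_mismatch else 0
            elif g != a2:
                bad2 += 1
        if bad1 <= thr1 and bad2 <= thr2:
            return True
    return False


def oracle_scan(matrix, group1, group2, thr1, thr2) -> set:
    """Brute-force full scan: positions of all compatible variants."""
    i1 = [matrix.panel.index(s) for s in group1]
    i2 = [matrix.panel.index(s) for s in group2]
    return {
        (r.chrom, r.pos)
        for r in matrix.records
        if oracle_compatible([int(r.genotypes[i]) for i in i1],
                             [int(r.genotypes[i]) for i in i2], thr1, thr2)
    }


def random_matrix(n_variants, n_strains, seed, null_frac=0.05) -> GenotypeMatrix:
    """In-memory matrix of random {0,1,NULL} genotypes (no all-NULL rows)."""
    rng = np.random.default_rng(seed)
    panel = StrainPanel(tuple(f"S{i:02d}" for i in range(n_strains)))
    records = []
    for i in range(n_variants):
        g = rng.choice([0, 1], size=n_strains)
        g[rng.random(n_strains) < null_frac] = -1
        if np.all(g == -1):
            g[0] = 0
        records.append(VariantRecord("1", i + 1, f"v{i}", "A", "C",
                                     g.astype(np.int8)))
    return GenotypeMatrix(panel, records)


# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def albinism():
    """(matrix, albino strains, non-albino strains) worked example."""
    return albinism_example()


NOISY_STRAINS = tuple(f"S{i}" for i in range(10))


@pytest.fixture(scope="session")
def noisy_fixture(tmp_path_factory):
    """A 400-site noise-planted VCF with its truth table, written once."""
    path = tmp_path_factory.mktemp("noisy") / "fixture.vcf"
    spec = FixtureSpec(
        strains=NOISY_STRAINS,
        n_variants=400,
        planted=(
            PlantedVariant(alt_strains=("S0", "S1", "S2", "S3"),
                           consequence="missense_variant", gene_id="GENE1"),
            PlantedVariant(alt_strains=("S0", "S1", "S2", "S3"), discord2=1,
                           consequence="intron_variant", gene_id="GENE1"),
        ),
        null_rate=0.06,
        multiallelic_rate=0.03,
        het_rate=0.03,
        low_conf_rate=0.03,
        seed=11,
    )
    truth = generate_vcf(spec, path)
    return path, spec, truth
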