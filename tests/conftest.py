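import numpy as np
import pytest

from longstr.catalog import load_catalog
from longstr.simulate import SimSpec, simulate_locus


@pytest.fixture(scope="session")
def noiseless_het(tmp_path_factory):
    """Noiseless heterozygous fixture: (CAG)x10 / (CAG)x30, depth 10x."""
    outdir = tmp_path_factory.mktemp("noiseless_het")
    spec = SimSpec(
        seed=1,
        allele_structures=[[("CAG", 10)], [("CAG", 30)]],
        depth=10,
    )
    paths = simulate_locus(spec, outdir)
    paths["locus"] = load_catalog(paths["catalog"])[0]
    paths["spec"] = spec
    return paths


@pytest.fixture(scope="session")
def noisy_het(tmp_path_factory):
    """Noisy heterozygous fixture with 2/1/1% sub/ins/del errors."""
    outdir = tmp_path_factory.mktemp("noisy_het")
    spec = SimSpec(
        seed=7,
        allele_structures=[[("CAG", 10)], [("CAG", 30)]],
        depth=12,
        error_rates=(0.02, 0.01, 0.01),
        hp_tag_fraction=0.5,
    )
    paths = simulate_locus(spec, outdir)
    paths["locus"] = load_catalog(paths["catalog"])[0]
    paths["spec"] = spec
    return paths


@pytest.fixture(scope="session")
def haploid_fixture(tmp_path_factory):
    """Haploid fixture: single (CGG)x25 allele, 6 reads."""
    outdir = tmp_path_factory.mktemp("haploid")
    spec = SimSpec(
        seed=3,
        allele_structures=[[("CGG", 25)]],
        depth=6,
        haploid=True,
    )
    paths = simulate_locus(spec, outdir)
    paths["locus"] = load_catalog(paths["catalog"])[0]
    paths["spec"] = spec
    return paths


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def levenshtein(a: str, b: str) -> int:
    """Plain dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ca != cb),
            )
        prev = cur
    return prev[-1]
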