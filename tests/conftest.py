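import numpy as np
import pandas as pd
import pytest

from oysterpanel.core import GenomeLayout, GenotypeMatrix, Pedigree
from oysterpanel.simdata import SimulationConfig, simulate_dataset, write_outputs


@pytest.fixture(scope="session")
def tiny_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (60_000, 40_000))


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        n_founder_pops=3, founders_per_pop=8, fst=0.1,
        n_f1_crosses=4, n_f2_crosses=5, offspring_per_cross=6,
        n_sites=200, null_locus_fraction=0.1, null_allele_freq=0.3,
        genotyping_error_rate=0.002, missing_rate=0.02, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg, tiny_layout):
    return simulate_dataset(small_cfg, tiny_layout)


@pytest.fixture(scope="session")
def sim_files(small_dataset, tiny_layout, tmp_path_factory):
    matrix, pedigree, _, _ = small_dataset
    outdir = tmp_path_factory.mktemp("simout")
    return write_outputs(matrix, pedigree, tiny_layout, outdir, reference_seed=11)


def matrix_from_dosages(dosages, chrom="chr1", start_pos=100, spacing=100,
                        ref="A", alt="G") -> GenotypeMatrix:
    """Helper: wrap a raw dosage array (individuals x sites) in a matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_sites = dosages.shape
    sites = pd.DataFrame({
        "id": [f"s{j}" for j in range(n_sites)],
        "chrom": chrom,
        "pos": [start_pos + spacing * j for j in range(n_sites)],
        "ref": ref,
        "alt": alt,
    })
    return GenotypeMatrix([f"i{k}" for k in range(n_ind)], sites, dosages)


def matrix_from_counts(n_aa: int, n_ab: int, n_bb: int) -> GenotypeMatrix:
    """Helper: one-site matrix with the given genotype counts."""
    dosages = np.array([[0]] * n_aa + [[1]] * n_ab + [[2]] * n_bb, dtype=np.int8)
    return matrix_from_dosages(dosages)


def trio_pedigree(n_trios: int, dam_known=None) -> Pedigree:
    """Helper: n independent trios s{k}, d{k} -> c{k}."""
    rows = []
    for k in range(n_trios):
        rows.append((f"s{k}", "0", "0", "founder"))
        if dam_known is None or dam_known[k]:
            rows.append((f"d{k}", "0", "0", "founder"))
    for k in range(n_trios):
        dam = f"d{k}" if (dam_known is None or dam_known[k]) else "0"
        rows.append((f"c{k}", f"s{k}", dam, "F1"))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "generation"]))
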