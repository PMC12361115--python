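from __future__ import annotations

import numpy as np
import pytest

from nuoscan.formats_io import GeneCall, HmmHit, RepliconType
from nuoscan.synthetic_data import SimulationConfig, simulate_dataset
from nuoscan.variant_classification import nuo_scheme


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str = "+",
    genome: str = "G1",
    replicon: str = "chr",
    plen: int | None = None,
    rtype: RepliconType = RepliconType.UNKNOWN,
) -> GeneCall:
    return GeneCall(
        gene_id=gene_id,
        genome_id=genome,
        replicon_id=replicon,
        start=start,
        end=end,
        strand=strand,
        protein_length=plen if plen is not None else max(1, (end - start + 1) // 3 - 1),
        replicon_type=rtype,
    )


def make_hit(
    gene_id: str,
    profile: str,
    evalue: float = 1e-50,
    env: tuple[int, int] | None = None,
) -> HmmHit:
    return HmmHit(
        gene_id=gene_id,
        profile=profile,
        evalue=evalue,
        bitscore=100.0,
        env_from=env[0] if env else None,
        env_to=env[1] if env else None,
    )


def random_instance(rng: np.random.Generator, max_genes: int = 50):
    """A random clustering instance: genes (possibly overlapping) plus hits."""
    n = int(rng.integers(1, max_genes + 1))
    genes, hits = [], []
    for i in range(n):
        replicon = f"rep{int(rng.integers(0, 3))}"
        start = int(rng.integers(1, 20000))
        length = int(rng.integers(30, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            make_gene(f"g{i:03d}", start, start + length - 1, strand, replicon=replicon)
        )
        hits.append(make_hit(f"g{i:03d}", "NuoB", evalue=10.0 ** -rng.uniform(5, 80)))
    return genes, hits


@pytest.fixture(scope="session")
def scheme():
    return nuo_scheme()


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic population (seed 0), shared across tests."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_fixture_dir(default_dataset, tmp_path_factory):
    from nuoscan.synthetic_data import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    write_fixture(default_dataset, out)
    return out
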