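import numpy as np
import pytest
import scipy.sparse as sp

from junctionscope.model import Junction, JunctionTable, SampleMeta
from junctionscope.simulate import CohortConfig, generate_annotation, generate_cohort


def random_junction(rng: np.random.Generator, chroms=("chr1", "chr2")) -> Junction:
    start = int(rng.integers(1, 100_000))
    return Junction(
        chrom=str(rng.choice(chroms)),
        start=start,
        end=start + int(rng.integers(50, 5_000)),
        strand="+" if rng.integers(2) else "-",
    )


def random_table(
    rng: np.random.Generator, n_junctions=30, n_samples=8, density=0.4
) -> JunctionTable:
    juncs = []
    seen = set()
    while len(juncs) < n_junctions:
        j = random_junction(rng)
        if j.key not in seen:
            seen.add(j.key)
            juncs.append(j)
    mask = rng.random((n_junctions, n_samples)) < density
    counts = np.where(mask, rng.integers(1, 50, size=mask.shape), 0)
    sids = [f"s{k}" for k in range(n_samples)]
    return JunctionTable(juncs, sids, sp.csr_matrix(counts))


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded synthetic cohort shared by aggregation/discovery/PCA tests."""
    cfg = CohortConfig(seed=11)
    ann = generate_annotation(cfg)
    table, meta = generate_cohort(cfg, ann)
    return cfg, ann, table, meta


@pytest.fixture()
def simple_meta():
    return [
        SampleMeta(f"s{k}", project_id=f"p{k % 2}", mapped_reads=100_000,
                   read_length=76)
        for k in range(8)
    ]
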