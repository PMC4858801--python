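import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wildrecomb.pedigree import GenotypePanel, Pedigree
from wildrecomb.simulate import SimConfig, gene_drop, simulate_pedigree

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_pedigree():
    """Founders P, Q; their daughter F; unrelated male M; F x M offspring O."""
    return Pedigree(pd.DataFrame([
        dict(id="P", sire=None, dam=None, sex="M"),
        dict(id="Q", sire=None, dam=None, sex="F"),
        dict(id="F", sire="P", dam="Q", sex="F"),
        dict(id="M", sire=None, dam=None, sex="M"),
        dict(id="O", sire="M", dam="F", sex="U"),
    ]))


def make_panel(genos: dict, bp=None, chrom=None):
    """Panel from {id: list of calls}; one chromosome unless chrom given."""
    ids = list(genos)
    g = np.array([genos[i] for i in ids], dtype=np.int8)
    m = g.shape[1]
    markers = pd.DataFrame(dict(
        snp=[f"s{j}" for j in range(m)],
        chrom=chrom if chrom is not None else [1] * m,
        bp=bp if bp is not None else np.arange(1, m + 1) * 1000,
        allele_a="A", allele_b="B",
    ))
    return GenotypePanel(markers, ids, g)


@pytest.fixture(scope="session")
def small_sim():
    """Shared error-free gene-drop: 3 x 60 Mb chromosomes, ~200 gametes."""
    cfg = SimConfig(
        n_founders=64, offspring_per_pair=3,
        chromosome_lengths_bp=(60_000_000, 50_000_000, 40_000_000),
        snp_density_per_mb=6.0, map_male_cm=260, map_female_cm=200,
        male_subtelomeric_factor=1.0, v_a_acc=0.2, v_r_acc=0.6,
        genotyping_error_rate=0.0, genotyping_missing_rate=0.0, seed=17,
    )
    ped = simulate_pedigree(cfg)
    drop = gene_drop(ped, cfg)
    return cfg, ped, drop
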