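import numpy as np
import pandas as pd
import pytest

from convergescan import pipeline, simdata
from convergescan.model import GenotypeTable, StudyDesign


@pytest.fixture(scope="session")
def conv_fixture(tmp_path_factory):
    """The standard convergent fixture (both species), simulated once."""
    d = tmp_path_factory.mktemp("convfix")
    result = simdata.make_convergent_fixture(d, seed=101)
    return d, result


@pytest.fixture(scope="session")
def conv_run(conv_fixture):
    """Full pipeline over the convergent fixture, annotation universe."""
    d, result = conv_fixture
    ds = pipeline.load_dataset(d)
    cfg = pipeline.ScanConfig(universe="annotation")
    full = pipeline.run_all(ds, cfg)
    return ds, result, full


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small no-sweep dataset for IO-level tests."""
    d = tmp_path_factory.mktemp("smallsim")
    cfg = simdata.SimulationConfig(seed=7, n_snps=4000, n_genes=80)
    result = simdata.simulate_dataset(cfg, d)
    return d, result


def make_table(dosages, scaffold="sc1", start_pos=100, spacing=10,
               refs=None, alts=None):
    """GenotypeTable from a raw dosage matrix (individuals x sites)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_sites = dosages.shape
    refs = refs or ["A"] * n_sites
    alts = alts or ["G"] * n_sites
    sites = pd.DataFrame({
        "scaffold": [scaffold] * n_sites,
        "pos": start_pos + spacing * np.arange(n_sites),
        "ref": refs,
        "alt": alts,
        "variant_class": ["snp" if len(r) == len(a) else "indel"
                          for r, a in zip(refs, alts)],
    })
    individuals = [f"ind{i:02d}" for i in range(n_ind)]
    return GenotypeTable(sites=sites, dosages=dosages, individuals=individuals)


def make_design(pop_sizes, species="halleri"):
    """StudyDesign for one species with two M/NM pairs.

    pop_sizes: list of 4 individual counts for (M1, NM1, M2, NM2).
    """
    pops = [(f"{species}_Mias", "Mias", "M", "pair1"),
            (f"{species}_Zapa", "Zapa", "NM", "pair1"),
            (f"{species}_Klet", "Klet", "M", "pair2"),
            (f"{species}_Kowa", "Kowa", "NM", "pair2")]
    rows = []
    i = 0
    for (pop, site, soil, pair), n in zip(pops, pop_sizes):
        for _ in range(n):
            rows.append({"individual": f"ind{i:02d}", "population": pop,
                         "site": site, "soil_class": soil,
                         "species": species, "pair": pair})
            i += 1
    return StudyDesign.from_table(pd.DataFrame(rows))
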