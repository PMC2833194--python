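import numpy as np
import pandas as pd
import pytest

from rhoscan.formats_io import HaplotypePanel, SnpEntry, SnpMap


def make_map(n_sites, length=None, subsegments=None, start=1):
    """Evenly spaced synthetic SnpMap for tests."""
    length = length or max(10 * n_sites, 100)
    positions = np.linspace(start, start + length - 1, n_sites).astype(int)
    positions = np.maximum.accumulate(positions)
    for i in range(1, n_sites):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + 1
    if subsegments is None:
        quarters = np.linspace(0, n_sites, 5).astype(int)
        names = ("PreAlu", "Alu", "PostAlu", "PostExon")
        subsegments = []
        for i in range(n_sites):
            k = int(np.searchsorted(quarters[1:4], i, side="right"))
            subsegments.append(names[k])
    entries = tuple(
        SnpEntry(f"S{i + 1}", ".", int(positions[i]), "A", "G",
                 subsegments[i]) for i in range(n_sites))
    return SnpMap(entries, (start, start + length - 1))


def make_panel(matrix, snp_map=None, population=pd.NA, phenotype=pd.NA,
               sex=pd.NA, length=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    snp_map = snp_map or make_map(matrix.shape[1], length=length)
    n = matrix.shape[0]
    meta = pd.DataFrame({
        "individual": [f"H{i + 1}" for i in range(n)],
        "chromosome": 1,
        "population": population, "phenotype": phenotype, "sex": sex,
    })
    return HaplotypePanel(snp_map, matrix, meta)


def random_panel(rng, n, s, snp_map=None):
    """Random 0/1 panel guaranteed polymorphic at every site."""
    while True:
        m = (rng.random((n, s)) < rng.uniform(0.1, 0.9, size=s)).astype(
            np.int8)
        if ((m.min(axis=0) == 0) & (m.max(axis=0) == 1)).all():
            return make_panel(m, snp_map=snp_map)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
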