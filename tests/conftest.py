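import numpy as np
import pandas as pd
import pytest

from epitree.datatypes import Dataset, SampleTable, SNPRecord, VariableSchema


def make_dataset(
    genotypes,
    class_label,
    race=None,
    sex=None,
    chromosomes=None,
    extra_continuous=None,
):
    """Hand-build a small Dataset from a genotype matrix and labels."""
    G = np.asarray(genotypes, dtype=np.int8)
    n, p = G.shape
    snps = [
        SNPRecord(
            f"rs{j + 1}",
            str(chromosomes[j]) if chromosomes is not None else "1",
            (j + 1) * 100,
            "A",
            "C",
        )
        for j in range(p)
    ]
    levels = {}
    cols = {}
    if race is not None:
        levels["race"] = ["AA", "EA"]
        cols["race"] = np.asarray(race, dtype=np.int16)
    if sex is not None:
        levels["sex"] = ["F", "M"]
        cols["sex"] = np.asarray(sex, dtype=np.int16)
    continuous = []
    for name, vals in (extra_continuous or {}).items():
        continuous.append(name)
        cols[name] = np.asarray(vals, dtype=float)
    schema = VariableSchema(
        levels=levels,
        continuous=continuous,
        race="race" if race is not None else None,
        sex="sex" if sex is not None else None,
    )
    demo = pd.DataFrame(cols, columns=schema.variables)
    if demo.empty:
        demo = pd.DataFrame(index=range(n), columns=[])
    samples = SampleTable(
        [f"S{i + 1}" for i in range(n)],
        np.asarray(class_label, dtype=np.int8),
        demo,
        schema,
    )
    return Dataset(snps, G, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def null_dataset():
    """Class independent of everything: 40 SNPs, race + sex, n = 400."""
    rng = np.random.default_rng(7)
    n, p = 400, 40
    freqs = rng.uniform(0.1, 0.5, size=p)
    G = rng.binomial(2, freqs, size=(n, p)).astype(np.int8)
    y = np.repeat([0, 1], n // 2)
    race = rng.integers(0, 2, size=n)
    sex = rng.integers(0, 2, size=n)
    return make_dataset(G, y, race=race, sex=sex)
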