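import dendropy
import numpy as np
import pandas as pd
import pytest

from fruitscent.voctable import ClassMap, ScentTable


def make_table(amounts: dict[str, dict[str, float]], species: dict[str, str],
               ripeness: str = "ripe") -> ScentTable:
    """Build a ScentTable from {sample: {compound: amount}} and sample->species."""
    df = pd.DataFrame(amounts).T.fillna(0.0)
    meta = pd.DataFrame({
        "species": pd.Series(species),
        "individual": {s: s for s in species},
        "ripeness": ripeness,
        "site": "TEST",
    })
    return ScentTable(df, meta)


@pytest.fixture
def three_taxon_tree() -> dendropy.Tree:
    """((A:1,B:1):1,C:2) — the worked-instance tree."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def star_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data="(A:1,B:1,C:1,D:1,E:1);", schema="newick")


@pytest.fixture
def toy_table() -> ScentTable:
    """10 samples, 2 species x 5, engineered around the filtering rules."""
    rng = np.random.default_rng(42)
    samples = [f"s{i}" for i in range(10)]
    species = {s: ("alpha" if i < 5 else "beta") for i, s in enumerate(samples)}
    amounts = {}
    for i, s in enumerate(samples):
        row = {
            "everywhere": 1.0 + rng.random(),          # present in 10/10
            "X": 2.0 if i == 0 else 0.0,               # 1 sample, 1 species
            "Y": 1.5 if i in (0, 1, 2) else 0.0,       # 3/5 samples of alpha
            "shared": 5.0 if i % 2 == 0 else 0.0,      # both species
            "tiny": 0.001,                             # never > share threshold
        }
        amounts[s] = row
    return make_table(amounts, species)


@pytest.fixture
def classmap7() -> ClassMap:
    return ClassMap({
        "everywhere": "aliphatics",
        "X": "aromatics",
        "Y": "terpenoids",
        "shared": "aliphatics",
        "tiny": "unknown",
    })
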