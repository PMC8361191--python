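import numpy as np
import pandas as pd
import pytest

from scfc.atlas import default_parcellation
from scfc.datatypes import Connectome, Parcellation, Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def parc392():
    return default_parcellation()


@pytest.fixture
def parc12():
    """12 regions, 3 networks, mixed hemispheres, fixed centroids."""
    rows = []
    nets = ["VIS"] * 5 + ["DMN"] * 4 + ["SUB"] * 3
    hemis = (["left", "right"] * 6)[:12]
    g = np.random.default_rng(7)
    for i in range(12):
        rows.append(
            {
                "region_id": i,
                "label": f"r{i}",
                "hemisphere": hemis[i],
                "network": nets[i],
                "x": float(g.uniform(-60, 60)),
                "y": float(g.uniform(-90, 60)),
                "z": float(g.uniform(-50, 70)),
            }
        )
    return Parcellation(pd.DataFrame(rows))


def random_connectome_pair(n, rng, density=0.6):
    """Unstructured random SC/FC pair for oracle-equivalence fixtures."""
    sc = rng.lognormal(0.0, 1.0, (n, n)) * (rng.random((n, n)) < density)
    sc = np.triu(sc, 1)
    sc = sc + sc.T
    fc = np.tanh(rng.normal(0.1, 0.4, (n, n)))
    fc = (fc + fc.T) / 2
    np.fill_diagonal(fc, 1.0)
    return (
        Connectome(sc, "SC", subject_id="X"),
        Connectome(fc, "FC", subject_id="X"),
    )


@pytest.fixture
def tiny_pedigree():
    """2 MZ pairs, 1 DZ pair, one 3-sibship, 2 singletons (11 subjects)."""
    rows = []
    rows += [
        ("m1a", "famA", "MZ_twin", "pA"),
        ("m1b", "famA", "MZ_twin", "pA"),
        ("m2a", "famB", "MZ_twin", "pB"),
        ("m2b", "famB", "MZ_twin", "pB"),
        ("d1a", "famC", "DZ_twin", "pC"),
        ("d1b", "famC", "DZ_twin", "pC"),
        ("s1", "famD", "full_sibling", ""),
        ("s2", "famD", "full_sibling", ""),
        ("s3", "famD", "full_sibling", ""),
        ("u1", "famE", "singleton", ""),
        ("u2", "famF", "singleton", ""),
    ]
    return Pedigree(
        pd.DataFrame(
            rows, columns=["subject_id", "family_id", "relationship", "twin_pair_id"]
        )
    )
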