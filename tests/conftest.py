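"""Shared fixtures: ideal-helix chains, random descriptors, tiny datasets."""

import numpy as np
import pytest

from tmpot.aminoacids import AMINO_ACIDS
from tmpot.descriptors import ProteinDescriptor
from tmpot.structure_io import ChainStructure, ResidueAtoms
from tmpot.synthetic import build_backbone


def make_helix_chain(n: int = 8, phi: float = -57.0, psi: float = -47.0,
                     aa: str = "A") -> ChainStructure:
    """Poly-residue chain built by exact forward kinematics."""
    bb = build_backbone([phi] * n, [psi] * n)
    residues = [ResidueAtoms(aa=aa, backbone=dict(b),
                             sidechain_heavy=[b["CA"] + np.array([1.5, 0, 0])])
                for b in bb]
    return ChainStructure(chain_id="A", residues=residues, source_id="helix")


@pytest.fixture
def helix_chain() -> ChainStructure:
    return make_helix_chain()


def random_descriptor(rng: np.random.Generator, n: int | None = None,
                      protein_id: str = "rnd") -> ProteinDescriptor:
    """Random descriptor with undefined domains and NaN distances mixed in."""
    n = n if n is not None else int(rng.integers(3, 13))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    domains = "".join(rng.choice(list("ACBPGEO-"), size=n,
                                 p=[0.2, 0.1, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1]))
    pts = rng.uniform(0, 12, size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    bad = rng.random(n) < 0.15
    d[bad, :] = np.nan
    d[:, bad] = np.nan
    np.fill_diagonal(d, np.nan)
    return ProteinDescriptor(protein_id=protein_id, sequence=seq,
                             domains=domains, distances=d)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared across tests."""
    from tmpot.synthetic import GeneratorConfig, generate

    return generate(GeneratorConfig(seed=11))
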