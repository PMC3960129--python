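"""Per-protein structural descriptors consumed by the potentials.

A :class:`ProteinDescriptor` holds everything the counting stage needs:
the sequence, the torsion-domain string and the matrix of side-chain-center
distances.  Residues whose torsion angles or side chains are unusable are
flagged, not dropped, so sequence indexing stays aligned with the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .geometry import (DEFAULT_BINNING, DEFAULT_DOMAIN_TABLE, DistanceBinning,
                       TorsionDomainTable, torsion_angles)
from .structure_io import ChainStructure, IncompleteResidueError, sidechain_center


@dataclass
class ProteinDescriptor:
    """Structural facts of one protein chain.

    ``domains`` uses the table's fallback label where (φ,ψ) is undefined;
    ``distances[i, j]`` is NaN where either side-chain center is unusable.
    """

    protein_id: str
    sequence: str
    domains: str
    distances: np.ndarray  # (N, N) Å, NaN where undefined

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if len(self.domains) != n or self.distances.shape != (n, n):
            raise ValueError("descriptor fields have inconsistent lengths")

    def __len__(self) -> int:
        return len(self.sequence)


def extract_descriptor(chain: ChainStructure,
                       table: TorsionDomainTable = DEFAULT_DOMAIN_TABLE,
                       binning: DistanceBinning = DEFAULT_BINNING,
                       ) -> ProteinDescriptor:
    """Compute sequence, torsion-domain string and distance matrix."""
    n = len(chain)
    if n == 0:
        raise ValueError("empty chain")
    angles = torsion_angles(chain)
    domains = "".join(table.assign(phi, psi) for phi, psi in angles)

    centers = np.full((n, 3), np.nan)
    for i, res in enumerate(chain.residues):
        try:
            centers[i] = sidechain_center(res)
        except IncompleteResidueError:
            pass  # stays NaN; pairs involving it are skipped in counting
    if n > 1:
        dist = squareform(pdist(centers))
    else:
        dist = np.zeros((1, 1))
    bad = ~np.all(np.isfinite(centers), axis=1)
    dist[bad, :] = np.nan
    dist[:, bad] = np.nan
    np.fill_diagonal(dist, np.nan)
    return ProteinDescriptor(protein_id=chain.source_id or chain.chain_id,
                             sequence=chain.sequence, domains=domains,
                             distances=dist)
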