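"""Folding free-energy features: scoring proteins with potential sets.

Each protein scored against a :class:`~tmpot.potentials.PotentialSet`
yields four per-residue-normalized energy terms (tor1, tor2, dist1, dist2,
in kT units).  Scoring against the mesostable-, thermostable- and
average-derived sets gives the three folding free energies dG_M, dG_T and
dG_A of the prediction stage; the difference features ddG = dG_M - dG_T
carry the temperature dependence of the interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import ProteinDescriptor
from .geometry import DEFAULT_BINNING, DistanceBinning
from .potentials import (DEFAULT_MIN_SEP, DEFAULT_WINDOW, POTENTIAL_KINDS,
                         CountTable, PotentialError, PotentialSet,
                         count_protein)

FEATURE_NAMES = POTENTIAL_KINDS  # (tor1, tor2, dist1, dist2)


@dataclass
class EnergyVector:
    """Per-residue-normalized energy terms of one protein at one t_set."""

    protein_id: str
    t_set: float | None
    terms: np.ndarray  # shape (4,), order tor1, tor2, dist1, dist2

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, map(float, self.terms)))


def score_counts(counts_by_kind: dict[str, CountTable], n_residues: int,
                 pset: PotentialSet, protein_id: str = "") -> EnergyVector:
    """Contract pre-computed per-protein counts with the potential tables."""
    if n_residues < 1:
        raise PotentialError("empty protein")
    terms = np.zeros(len(POTENTIAL_KINDS))
    for k, kind in enumerate(POTENTIAL_KINDS):
        ct = counts_by_kind[kind]
        table = pset[kind]
        if ct.counts.shape != table.values.shape:
            raise PotentialError(f"{kind}: count/potential shape mismatch")
        terms[k] = float(np.sum(ct.counts * table.values)) / n_residues
    return EnergyVector(protein_id=protein_id, t_set=pset.t_set, terms=terms)


def score_protein(desc: ProteinDescriptor, pset: PotentialSet,
                  window: int = DEFAULT_WINDOW,
                  min_sep: int = DEFAULT_MIN_SEP,
                  binning: DistanceBinning = DEFAULT_BINNING,
                  tor2_domain_of: str = "i") -> EnergyVector:
    """Sum the table entries over the protein's motif occurrences, / N.

    ``window`` and ``min_sep`` must match the values used when the
    potential's counts were accumulated; motifs absent from the table
    contribute zero by construction (their table entry is zero).
    """
    if len(desc) == 0:
        raise PotentialError("empty descriptor")
    counts = {kind: count_protein(desc, kind, window=window, min_sep=min_sep,
                                  binning=binning,
                                  tor2_domain_of=tor2_domain_of)
              for kind in POTENTIAL_KINDS}
    return score_counts(counts, len(desc), pset, protein_id=desc.protein_id)


def energy_features(desc: ProteinDescriptor,
                    triple_potentials: dict[str, PotentialSet],
                    **score_kw) -> dict[str, EnergyVector | np.ndarray]:
    """Score against the M/T/A potential sets and form ddG = dG_M - dG_T.

    ``triple_potentials`` maps the set labels "meso", "thermo", "average"
    to their PotentialSets.
    """
    required = {"meso", "thermo", "average"}
    if not required <= set(triple_potentials):
        raise PotentialError(
            f"need potential sets {sorted(required)}, got "
            f"{sorted(triple_potentials)}")
    out: dict[str, EnergyVector | np.ndarray] = {}
    for label, pset in triple_potentials.items():
        out[label] = score_protein(desc, pset, **score_kw)
    out["ddg"] = out["meso"].terms - out["thermo"].terms
    return out
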