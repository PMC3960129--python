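"""Backbone torsion angles, torsion-angle domains and distance binning.

The structural motifs of the potentials are (i) one of seven discrete
regions of the backbone (φ,ψ) plane and (ii) one of 27 bins of the
side-chain-center distance: 25 core bins of 0.2 Å width covering
[3.0, 8.0) Å plus an underflow (<3.0 Å) and an overflow (≥8.0 Å) bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import ChainStructure

UNDEFINED = None  # sentinel for torsion angles that cannot be computed


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees, IUPAC sign convention, in [-180, 180)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang >= 180.0:
        ang -= 360.0
    return float(ang)


def torsion_angles(chain: ChainStructure) -> list[tuple[float | None, float | None]]:
    """Per-residue (φ, ψ) in degrees; ``None`` where undefined.

    φ_i = dihedral(C_{i-1}, N_i, CA_i, C_i) — undefined at the N-terminus;
    ψ_i = dihedral(N_i, CA_i, C_i, N_{i+1}) — undefined at the C-terminus;
    both undefined where any required backbone atom is missing.
    """
    res = chain.residues
    out: list[tuple[float | None, float | None]] = []
    for i, r in enumerate(res):
        phi = psi = UNDEFINED
        if r.has_backbone():
            if i > 0 and "C" in res[i - 1].backbone:
                phi = dihedral(res[i - 1].backbone["C"], r.backbone["N"],
                               r.backbone["CA"], r.backbone["C"])
            if i + 1 < len(res) and "N" in res[i + 1].backbone:
                psi = dihedral(r.backbone["N"], r.backbone["CA"],
                               r.backbone["C"], res[i + 1].backbone["N"])
        out.append((phi, psi))
    return out


# ---------------------------------------------------------------------------
# torsion-angle domains

Interval = tuple[float, float]  # half-open [lo, hi) in degrees


@dataclass(frozen=True)
class DomainRegion:
    """A union of (φ,ψ) boxes carrying one domain label."""

    label: str
    boxes: tuple[tuple[Interval, Interval], ...]

    def contains(self, phi: float, psi: float) -> bool:
        return any(plo <= phi < phi_hi and slo <= psi < psi_hi
                   for (plo, phi_hi), (slo, psi_hi) in self.boxes)


@dataclass(frozen=True)
class TorsionDomainTable:
    """A disjoint 7-way partition of the (φ,ψ) plane plus a fallback label.

    The published seven-domain partition is not reproduced in accessible
    form; this default table is a consistent stand-in with the familiar
    helical (A), extended (B), polyproline (P) and left-handed (G) regions.
    All downstream code is agnostic to the exact boundaries.
    """

    regions: tuple[DomainRegion, ...]
    fallback_label: str = "-"

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.regions)

    def assign(self, phi: float | None, psi: float | None) -> str:
        if phi is None or psi is None:
            return self.fallback_label
        for region in self.regions:
            if region.contains(phi, psi):
                return region.label
        # the last region is the catch-all; reaching here means the table
        # does not cover the plane
        raise ValueError(f"({phi}, {psi}) not covered by domain table")


def _default_regions() -> tuple[DomainRegion, ...]:
    full = (-180.0, 180.0)
    regs = [
        DomainRegion("A", ((( -120.0, 0.0), (-90.0, 30.0)),)),
        DomainRegion("C", ((( -120.0, 0.0), (30.0, 90.0)),)),
        DomainRegion("B", ((( -180.0, -120.0), (60.0, 180.0)),
                           ((-180.0, -120.0), (-180.0, -150.0)))),
        DomainRegion("P", ((( -120.0, -30.0), (90.0, 180.0)),)),
        DomainRegion("G", (((0.0, 120.0), (-30.0, 90.0)),)),
        DomainRegion("E", (((0.0, 180.0), (90.0, 180.0)),
                           ((0.0, 180.0), (-180.0, -150.0)))),
    ]
    # O: everything not claimed by the six explicit regions
    covered = list(regs)

    class _Other(DomainRegion):
        def contains(self, phi, psi):  # noqa: D102
            return not any(r.contains(phi, psi) for r in covered)

    regs.append(_Other("O", (((full), (full)),)))
    return tuple(regs)


DEFAULT_DOMAIN_TABLE = TorsionDomainTable(regions=_default_regions())


def assign_domain(phi: float | None, psi: float | None,
                  table: TorsionDomainTable = DEFAULT_DOMAIN_TABLE) -> str:
    """Map a (φ,ψ) pair to its domain label (fallback if undefined)."""
    return table.assign(phi, psi)


# ---------------------------------------------------------------------------
# distance binning


@dataclass(frozen=True)
class DistanceBinning:
    """27-bin layout: underflow | 25 core bins of 0.2 Å on [3,8) | overflow."""

    low: float = 3.0
    high: float = 8.0
    width: float = 0.2
    n_core: int = 25

    @property
    def n_bins(self) -> int:
        return self.n_core + 2

    @property
    def underflow_index(self) -> int:
        return 0

    @property
    def overflow_index(self) -> int:
        return self.n_core + 1

    def core_index(self, k: int) -> int:
        """Global bin index of core bin k (0-based, [low+k·w, low+(k+1)·w))."""
        if not 0 <= k < self.n_core:
            raise IndexError(f"core bin {k} out of range")
        return k + 1

    @property
    def core_slice(self) -> slice:
        return slice(1, self.n_core + 1)


DEFAULT_BINNING = DistanceBinning()


def bin_distance(d: float, binning: DistanceBinning = DEFAULT_BINNING) -> int:
    """Bin a side-chain-center distance (Å); half-open core intervals."""
    if not np.isfinite(d) or d < 0:
        raise ValueError(f"invalid distance {d!r}")
    if d < binning.low:
        return binning.underflow_index
    if d >= binning.high:
        return binning.overflow_index
    k = int((d - binning.low) / binning.width)
    k = min(k, binning.n_core - 1)  # guard float edge at high boundary
    return binning.core_index(k)


def bin_distances(d: np.ndarray, binning: DistanceBinning = DEFAULT_BINNING) -> np.ndarray:
    """Vectorized :func:`bin_distance`; NaNs map to -1 (caller must mask)."""
    d = np.asarray(d, dtype=float)
    edges = binning.low + binning.width * np.arange(binning.n_core + 1)
    idx = np.searchsorted(edges, d, side="right")  # 0 => underflow
    idx = np.where(d >= binning.high, binning.overflow_index, idx)
    idx = np.where(np.isnan(d), -1, idx)
    return idx.astype(int)
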