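"""Temperature-dependent statistical potentials.

Four knowledge-based potentials are derived from a protein dataset of
average melting temperature ``t_set``:

* ``tor1`` — propensity of amino acid a_i to see torsion domain t_{i+k},
  for signed offsets |k| <= window (local interactions along the chain);
* ``tor2`` — propensity of the ordered amino-acid pair (a_i, a_j),
  1 <= j-i <= window, to see the torsion domain of residue i;
* ``dist1`` — propensity of amino acid a to be at a binned side-chain-center
  distance from an arbitrary residue;
* ``dist2`` — propensity of the unordered amino-acid pair {a_i, a_j},
  j-i >= min_sep, to be at a binned distance.

Counts are Boltzmann-inverted into energies (kT units):

    dW(c, s) = -ln[ f~(s|c) / f(s) ]

with the sparse-data shrinkage f~(s|c) = (sigma·f(s) + m_c·f(s|c)) /
(sigma + m_c), which tends to the plain inversion -ln[f(c,s)/(f(c)f(s))]
for abundant counts and to zero energy when motif c is rarely observed.
Distance counts are first smoothed by summing neighbouring core bins with
geometrically decreasing weight lambda^|k|, renormalised per motif.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .aminoacids import AA_INDEX, AMINO_ACIDS
from .descriptors import ProteinDescriptor
from .geometry import DEFAULT_BINNING, DistanceBinning, bin_distances

TOR1, TOR2, DIST1, DIST2 = "tor1", "tor2", "dist1", "dist2"
POTENTIAL_KINDS = (TOR1, TOR2, DIST1, DIST2)
TORSION_KINDS = (TOR1, TOR2)
DISTANCE_KINDS = (DIST1, DIST2)

DEFAULT_WINDOW = 8
DEFAULT_MIN_SEP = 2
DEFAULT_SIGMAS = (10.0, 50.0)
DEFAULT_LAMBDA = 0.5


class PotentialError(ValueError):
    pass


# ---------------------------------------------------------------------------
# motif index spaces


def motif_labels(kind: str, window: int = DEFAULT_WINDOW,
                 domain_labels: tuple[str, ...] | None = None,
                 ) -> tuple[list, list]:
    """(sequence-motif labels, structure-motif labels) for a potential kind."""
    doms = list(domain_labels) if domain_labels else list("ACBPGEO")
    if kind == TOR1:
        seq = [(a, k) for a in AMINO_ACIDS for k in range(-window, window + 1)]
        return seq, doms
    if kind == TOR2:
        seq = [(a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS]
        return seq, doms
    if kind == DIST1:
        return list(AMINO_ACIDS), list(range(DEFAULT_BINNING.n_bins))
    if kind == DIST2:
        seq = [(a, b) for a, b in
               itertools.combinations_with_replacement(AMINO_ACIDS, 2)]
        return seq, list(range(DEFAULT_BINNING.n_bins))
    raise PotentialError(f"unknown potential kind {kind!r}")


@dataclass
class CountTable:
    """Occurrence counts n(c, s): sequence motifs (rows) x structure motifs."""

    potential_kind: str
    counts: np.ndarray  # (n_motifs, n_struct), non-negative reals
    seq_labels: list
    struct_labels: list

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "CountTable") -> "CountTable":
        if (self.potential_kind != other.potential_kind
                or self.counts.shape != other.counts.shape):
            raise PotentialError("incompatible count tables")
        return replace(self, counts=self.counts + other.counts)

    def __sub__(self, other: "CountTable") -> "CountTable":
        out = replace(self, counts=self.counts - other.counts)
        if out.counts.min() < -1e-9:
            raise PotentialError("count subtraction went negative")
        out.counts = np.clip(out.counts, 0.0, None)
        return out


@dataclass
class PotentialTable:
    """Energies dW(c, s) in kT units, same axes as the source CountTable."""

    potential_kind: str
    values: np.ndarray
    seq_labels: list
    struct_labels: list
    t_set: float | None = None      # °C, mean Tm of the source dataset
    sigma: float | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class PotentialSet:
    """The four potentials derived from one dataset at one temperature."""

    tor1: PotentialTable
    tor2: PotentialTable
    dist1: PotentialTable
    dist2: PotentialTable
    t_set: float | None = None

    def __getitem__(self, kind: str) -> PotentialTable:
        if kind not in POTENTIAL_KINDS:
            raise KeyError(kind)
        return getattr(self, kind)

    def tables(self) -> dict[str, PotentialTable]:
        return {k: getattr(self, k) for k in POTENTIAL_KINDS}


# ---------------------------------------------------------------------------
# counting


def _empty_counts(kind: str, window: int) -> CountTable:
    seq, struct = motif_labels(kind, window)
    return CountTable(kind, np.zeros((len(seq), len(struct))), seq, struct)


def count_motifs(descriptors: list[ProteinDescriptor], kind: str,
                 window: int = DEFAULT_WINDOW, min_sep: int = DEFAULT_MIN_SEP,
                 binning: DistanceBinning = DEFAULT_BINNING,
                 tor2_domain_of: str = "i") -> CountTable:
    """Accumulate motif occurrences over a list of protein descriptors.

    Undefined torsion domains (fallback label) and residue pairs with an
    unusable side-chain center are skipped.  ``tor2_domain_of`` selects
    whether the pair potential conditions on the torsion domain of the
    first ("i") or second ("j") residue of the pair.
    """
    if not descriptors:
        raise PotentialError("no descriptors to count")
    table = _empty_counts(kind, window)
    dom_index = {d: i for i, d in enumerate(table.struct_labels)} \
        if kind in TORSION_KINDS else None
    for desc in descriptors:
        if kind == TOR1:
            _count_tor1(table, desc, window, dom_index)
        elif kind == TOR2:
            _count_tor2(table, desc, window, dom_index, tor2_domain_of)
        else:
            _count_dist(table, desc, min_sep, binning, kind)
    return table


def _count_tor1(table, desc, window, dom_index):
    n = len(desc)
    for i, a in enumerate(desc.sequence):
        ai = AA_INDEX.get(a)
        if ai is None:
            continue
        for k in range(-window, window + 1):
            j = i + k
            if not 0 <= j < n:
                continue
            d = dom_index.get(desc.domains[j])
            if d is None:
                continue
            row = ai * (2 * window + 1) + (k + window)
            table.counts[row, d] += 1


def _count_tor2(table, desc, window, dom_index, domain_of):
    n = len(desc)
    for i, a in enumerate(desc.sequence):
        ai = AA_INDEX.get(a)
        if ai is None:
            continue
        for j in range(i + 1, min(i + window, n - 1) + 1):
            bj = AA_INDEX.get(desc.sequence[j])
            if bj is None:
                continue
            t = desc.domains[i] if domain_of == "i" else desc.domains[j]
            d = dom_index.get(t)
            if d is None:
                continue
            table.counts[ai * 20 + bj, d] += 1


_PAIR_ROW = {}
for _r, (_a, _b) in enumerate(
        itertools.combinations_with_replacement(AMINO_ACIDS, 2)):
    _PAIR_ROW[(_a, _b)] = _r
    _PAIR_ROW[(_b, _a)] = _r


def _count_dist(table, desc, min_sep, binning, kind):
    n = len(desc)
    if n <= min_sep:
        return
    iu, ju = np.triu_indices(n, k=min_sep)
    d = desc.distances[iu, ju]
    ok = np.isfinite(d)
    iu, ju, d = iu[ok], ju[ok], d[ok]
    bins = bin_distances(d, binning)
    for i, j, b in zip(iu, ju, bins):
        a, c = desc.sequence[i], desc.sequence[j]
        if a not in AA_INDEX or c not in AA_INDEX:
            continue
        if kind == DIST2:
            table.counts[_PAIR_ROW[(a, c)], b] += 1
        else:  # DIST1: each pair counted once per member
            table.counts[AA_INDEX[a], b] += 1
            table.counts[AA_INDEX[c], b] += 1


def count_protein(desc: ProteinDescriptor, kind: str, **kw) -> CountTable:
    """Counts of a single protein (additive building block of a dataset)."""
    return count_motifs([desc], kind, **kw)


# ---------------------------------------------------------------------------
# smoothing


def smooth_distance_counts(table: CountTable,
                           lam: float = DEFAULT_LAMBDA,
                           binning: DistanceBinning = DEFAULT_BINNING,
                           ) -> CountTable:
    """Sum neighbouring core bins with weight lambda^|k|, conserving mass.

    Underflow/overflow bins are left untouched; after the weighted sum each
    motif row is rescaled so its total core mass is unchanged.
    """
    if table.potential_kind not in DISTANCE_KINDS:
        raise PotentialError("smoothing applies to distance tables only")
    if not 0.0 <= lam < 1.0:
        raise PotentialError(f"lambda must be in [0, 1), got {lam}")
    core = table.counts[:, binning.core_slice]
    nb = core.shape[1]
    offsets = np.arange(nb)
    kernel = lam ** np.abs(offsets[:, None] - offsets[None, :])
    smoothed = core @ kernel  # row-wise weighted neighbour sum
    old_mass = core.sum(axis=1)
    new_mass = smoothed.sum(axis=1)
    scale = np.divide(old_mass, new_mass,
                      out=np.ones_like(old_mass), where=new_mass > 0)
    out = table.counts.copy()
    out[:, binning.core_slice] = smoothed * scale[:, None]
    return replace(table, counts=out)


# ---------------------------------------------------------------------------
# Boltzmann inversion with sparse-data correction


def boltzmann_potential(table: CountTable, sigma: float = 0.0,
                        t_set: float | None = None,
                        provenance: dict | None = None) -> PotentialTable:
    """Invert relative frequencies into energies with shrinkage ``sigma``.

    With f(c,s) = n(c,s)/n_tot, marginals f(c), f(s) and motif occurrence
    count m_c, the corrected conditional frequency is

        f~(s|c) = (sigma·f(s) + m_c·f(s|c)) / (sigma + m_c)

    and dW(c,s) = -ln[f~(s|c)/f(s)].  Cells with f(s) = 0 (and rows with
    m_c = 0) are set to 0 by convention.
    """
    if sigma < 0:
        raise PotentialError(f"sigma must be >= 0, got {sigma}")
    n_tot = table.n_total
    if n_tot <= 0:
        raise PotentialError("empty count table")
    counts = table.counts
    m_c = counts.sum(axis=1)                      # motif occurrences
    f_s = counts.sum(axis=0) / n_tot              # structure marginal
    safe_m = np.where(m_c > 0, m_c, 1.0)[:, None]
    f_s_given_c = np.where(m_c[:, None] > 0, counts / safe_m, 0.0)
    denom = sigma + m_c[:, None]
    safe_denom = np.where(denom > 0, denom, 1.0)
    f_tilde = np.where(
        denom > 0,
        (sigma * f_s[None, :] + m_c[:, None] * f_s_given_c) / safe_denom,
        f_s[None, :])                              # m_c = 0 and sigma = 0
    safe_fs = np.where(f_s > 0, f_s, 1.0)[None, :]
    ratio = np.where(f_s[None, :] > 0, f_tilde / safe_fs, 1.0)
    # sigma = 0 with an unobserved (c, s) for a present motif gives ratio 0;
    # -ln(0) is capped as if half an occurrence had been seen
    cap = np.log(2.0 * n_tot)
    with np.errstate(divide="ignore"):
        values = np.where(ratio > 0, -np.log(np.where(ratio > 0, ratio, 1.0)),
                          cap)
    values[:, f_s == 0] = 0.0
    values[m_c == 0, :] = 0.0
    return PotentialTable(
        potential_kind=table.potential_kind, values=values,
        seq_labels=table.seq_labels, struct_labels=table.struct_labels,
        t_set=t_set, sigma=sigma, provenance=provenance or {})


# ---------------------------------------------------------------------------
# six-variant derivation


def derive_potential_set(descriptors_by_method: dict[str, list[ProteinDescriptor]],
                         t_set: float,
                         sigmas: tuple[float, ...] = DEFAULT_SIGMAS,
                         lam: float = DEFAULT_LAMBDA,
                         window: int = DEFAULT_WINDOW,
                         min_sep: int = DEFAULT_MIN_SEP,
                         binning: DistanceBinning = DEFAULT_BINNING,
                         tor2_domain_of: str = "i") -> PotentialSet:
    """Average the |methods| x |sigmas| potential variants cell-wise.

    ``descriptors_by_method`` maps each Tm-estimation method label to the
    descriptor list of the dataset members selected under that method (the
    membership of the meso/thermo/average sets depends on the estimated
    Tm's, hence on the method).
    """
    if not descriptors_by_method or not any(descriptors_by_method.values()):
        raise PotentialError("no descriptors supplied")
    tables: dict[str, PotentialTable] = {}
    for kind in POTENTIAL_KINDS:
        variants = []
        for method, descs in descriptors_by_method.items():
            if not descs:
                continue
            counts = count_motifs(descs, kind, window=window, min_sep=min_sep,
                                  binning=binning,
                                  tor2_domain_of=tor2_domain_of)
            if kind in DISTANCE_KINDS:
                counts = smooth_distance_counts(counts, lam, binning)
            for sigma in sigmas:
                variants.append(boltzmann_potential(
                    counts, sigma=sigma, t_set=t_set,
                    provenance={"method": method, "sigma": sigma,
                                "lambda": lam, "n_proteins": len(descs)}))
        mean_vals = np.mean([v.values for v in variants], axis=0)
        tables[kind] = PotentialTable(
            potential_kind=kind, values=mean_vals,
            seq_labels=variants[0].seq_labels,
            struct_labels=variants[0].struct_labels,
            t_set=t_set, sigma=None,
            provenance={"n_variants": len(variants), "sigmas": list(sigmas),
                        "lambda": lam,
                        "methods": list(descriptors_by_method)})
    return PotentialSet(t_set=t_set, **tables)


def potential_set_from_counts(counts_by_kind: dict[str, CountTable],
                              t_set: float | None = None,
                              sigmas: tuple[float, ...] = DEFAULT_SIGMAS,
                              lam: float = DEFAULT_LAMBDA,
                              binning: DistanceBinning = DEFAULT_BINNING,
                              ) -> PotentialSet:
    """Build a set from pre-accumulated counts (averaging over sigmas)."""
    tables = {}
    for kind, ct in counts_by_kind.items():
        if kind in DISTANCE_KINDS:
            ct = smooth_distance_counts(ct, lam, binning)
        variants = [boltzmann_potential(ct, sigma=s, t_set=t_set)
                    for s in sigmas]
        tables[kind] = PotentialTable(
            potential_kind=kind,
            values=np.mean([v.values for v in variants], axis=0),
            seq_labels=ct.seq_labels, struct_labels=ct.struct_labels,
            t_set=t_set, provenance={"sigmas": list(sigmas), "lambda": lam})
    return PotentialSet(t_set=t_set, **tables)


# ---------------------------------------------------------------------------
# serialization: TSV per table + JSON sidecar


def save_potential_set(pset: PotentialSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"t_set": pset.t_set, "tables": {}}
    for kind, table in pset.tables().items():
        rows = []
        for i, c in enumerate(table.seq_labels):
            motif = c if isinstance(c, str) else "|".join(map(str, c))
            for j, s in enumerate(table.struct_labels):
                rows.append((motif, s, table.values[i, j]))
        pd.DataFrame(rows, columns=["motif", "struct", "energy_kt"]).to_csv(
            directory / f"{kind}.tsv", sep="\t", index=False)
        meta["tables"][kind] = {"sigma": table.sigma, "t_set": table.t_set,
                                "provenance": table.provenance}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_potential_set(directory: str | Path,
                       window: int = DEFAULT_WINDOW) -> PotentialSet:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    tables = {}
    for kind in POTENTIAL_KINDS:
        seq_labels, struct_labels = motif_labels(kind, window)
        df = pd.read_csv(directory / f"{kind}.tsv", sep="\t",
                         dtype={"motif": str})
        idx = {}
        for i, c in enumerate(seq_labels):
            motif = c if isinstance(c, str) else "|".join(map(str, c))
            idx[motif] = i
        sidx = {str(s): j for j, s in enumerate(struct_labels)}
        values = np.zeros((len(seq_labels), len(struct_labels)))
        for row in df.itertuples(index=False):
            values[idx[row.motif], sidx[str(row.struct)]] = row.energy_kt
        tmeta = meta["tables"][kind]
        tables[kind] = PotentialTable(
            potential_kind=kind, values=values, seq_labels=seq_labels,
            struct_labels=struct_labels, t_set=tmeta.get("t_set"),
            sigma=tmeta.get("sigma"), provenance=tmeta.get("provenance", {}))
    return PotentialSet(t_set=meta.get("t_set"), **tables)
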