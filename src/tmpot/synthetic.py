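"""Self-contained synthetic protein families with planted thermal signals.

The generator emulates the data situation of the melting-temperature
method without any external downloads: homologous families whose members
have (i) a melting temperature drawn from a known model, (ii) a host
environmental temperature linked to Tm by a linear relation with noise,
(iii) sequences mutated from a family ancestor along an identity ladder
(so redundancy culling is exercised on both sides of the 25% cutoff), and
(iv) idealized structures whose torsion-domain composition and whose
side-chain contact counts in chosen (amino-acid pair, distance) cells
scale linearly with Tm.

Planted contacts are realized exactly: each contact occupies a dedicated
residue pair whose side-chain centers are placed at the prescribed
distance on an isolated "island", all remaining inter-residue distances
falling in the overflow bin (> 8 Å).  Two complementary contact windows
(up-slope and down-slope in Tm, same amino-acid pair) keep the *total*
planted contact count independent of Tm, so the temperature signal lives
in the meso-vs-thermo potential difference, not in the overall energy —
the synthetic analogue of thermal stabilization without thermodynamic
stabilization.  Glycine is excluded from synthetic sequences because its
side-chain center falls back to CA, which would couple contact geometry
to the backbone.

Structures are physically idealized, not realistic: no sterics, no
packing, side chains decoupled from the backbone.  Only binned distances
and torsion domains — the quantities the potentials consume — are
guaranteed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .aminoacids import ONE_TO_THREE
from .datasets import MEASURED, ProteinRecord, write_metadata
from .structure_io import ChainStructure, ResidueAtoms

# ideal backbone geometry (Å, degrees)
BOND_N_CA, BOND_CA_C, BOND_C_N = 1.458, 1.525, 1.329
ANGLE_N_CA_C, ANGLE_CA_C_N, ANGLE_C_N_CA = 111.2, 116.2, 121.7
OMEGA_TRANS = 180.0


class GeometryRequestError(ValueError):
    """Raised when a planted-contact plan cannot be realized."""


# ---------------------------------------------------------------------------
# forward kinematics (natural extension reference frame)


def place_atom(a, b, c, bond_length: float, bond_angle: float,
               torsion: float) -> np.ndarray:
    """Place atom D so that angle(b,c,D)=bond_angle, dihedral(a,b,c,D)=torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi),
         np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omega: float = OMEGA_TRANS,
                   ) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C coordinates from per-residue (φ, ψ) dihedrals.

    ``phis[0]`` and ``psis[-1]`` are accepted but geometrically unused
    (no flanking residue defines them).
    """
    n = len(phis)
    if len(psis) != n or n < 1:
        raise ValueError("phis and psis must have equal positive length")
    out = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    out.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n):
        prev = out[-1]
        N1 = place_atom(prev["N"], prev["CA"], prev["C"],
                        BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CA1 = place_atom(prev["CA"], prev["C"], N1,
                         BOND_N_CA, ANGLE_C_N_CA, omega)
        C1 = place_atom(prev["C"], N1, CA1,
                        BOND_CA_C, ANGLE_N_CA_C, phis[i])
        out.append({"N": N1, "CA": CA1, "C": C1})
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PlantedContact:
    """A (amino-acid pair, distance) cell whose count scales with Tm.

    count = base + slope · (Tm − mid(tm_range)), in contacts per protein.
    """

    aa_pair: tuple[str, str]
    distance: float          # Å, realized exactly
    base: float
    slope: float             # contacts per °C


@dataclass(frozen=True)
class GeneratorConfig:
    n_families: int = 3
    proteins_per_family: int = 8
    residues_per_protein: int = 80
    tm_range: tuple[float, float] = (40.0, 90.0)
    tm_grid: float = 5.0          # Tm levels spacing; slope·grid integral
    tenv_model: tuple[float, float, float] = (1.0, 25.0, 4.0)  # slope, icpt, sd
    tm_noise: float = 2.0         # measurement noise on reported Tm, °C
    planted_pairs: tuple[PlantedContact, ...] = (
        PlantedContact(("D", "R"), 4.1, 5.0, 0.2),
        PlantedContact(("D", "R"), 6.9, 5.0, -0.2),
    )
    # shares R with the planted pair so that the single-residue distance
    # rows are not informationally redundant with the pair rows (which
    # would make the dist1/dist2 features exactly collinear)
    background_pair: tuple[str, str] = ("A", "R")
    background_distance: float = 5.1
    background_count_range: tuple[int, int] = (2, 5)
    torsion_slope: float = 0.004  # helix-propensity change per °C
    mutation_ladder: tuple[float, ...] = (0.0, 0.05, 0.15, 0.3, 0.5,
                                          0.7, 0.9)
    measured_fraction: float = 0.75
    min_sep: int = 2
    deterministic_layout: bool = False
    seed: int = 0

    @property
    def tm_mid(self) -> float:
        return 0.5 * (self.tm_range[0] + self.tm_range[1])

    @property
    def tm_levels(self) -> np.ndarray:
        lo, hi = self.tm_range
        return np.arange(lo, hi + 0.5 * self.tm_grid, self.tm_grid)

    @classmethod
    def noise_free(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """The fully deterministic-signal variant.

        No Tm measurement noise, no mutations, every protein measured, a
        two-level background-contact count, a deterministic contact layout
        and a single family: the energy features are then exact affine
        functions of the planted latent variables (shared potential tables,
        shared ancestor composition), so the melting temperature is
        perfectly recoverable by the linear predictor.
        """
        kw = dict(tm_noise=0.0, measured_fraction=1.0,
                  mutation_ladder=(0.0,), background_count_range=(4, 5),
                  deterministic_layout=True, n_families=1,
                  proteins_per_family=14, seed=seed)
        kw.update(overrides)
        return cls(**kw)


# glycine excluded: its side-chain center falls back to CA
_ALPHABET = "ACDEFHIKLMNPQRSTVWY"


def _free_alphabet(config: "GeneratorConfig") -> list[str]:
    """Alphabet of non-contact residues.

    The amino acids of the planted and background pairs are reserved for
    the contact islands, so the planted cells of the distance tables are
    populated exclusively by the prescribed contacts.
    """
    reserved = {a for pc in config.planted_pairs for a in pc.aa_pair}
    reserved |= set(config.background_pair)
    return [a for a in _ALPHABET if a not in reserved]

# φ/ψ sampling boxes inside the default domain regions (margins off edges)
_DOMAIN_BOXES = {
    "A": ((-110.0, -10.0), (-80.0, 20.0)),
    "B": ((-170.0, -130.0), (70.0, 170.0)),
    "P": ((-110.0, -40.0), (100.0, 170.0)),
    "G": ((10.0, 110.0), (-20.0, 80.0)),
}
_DOMAIN_BASE_P = {"A": 0.45, "B": 0.35, "P": 0.12, "G": 0.08}

_SIDECHAIN_OFFSETS = {
    1: [np.array([0.0, 0.0, 0.0])],
    2: [np.array([0.75, 0.0, 0.0]), np.array([-0.75, 0.0, 0.0])],
    3: [np.array([0.8, 0.0, 0.0]), np.array([-0.4, 0.6, 0.0]),
        np.array([-0.4, -0.6, 0.0])],
}

_SIDECHAIN_NAMES = {1: ["CB"], 2: ["CB", "CG"], 3: ["CB", "CG", "CD"]}

# successive free-residue spacings (Å): one per core-bin region, with only
# the smallest two-step sum (3.3 + 4.1) still inside the 8 Å cutoff
_RULER_SPACINGS = (3.3, 4.1, 4.7, 5.3, 5.9, 6.5, 6.9, 7.7)


def _n_sidechain_atoms(aa: str) -> int:
    # small/medium/large classes exercise multi-atom centroid averaging
    if aa in "ACSTV":
        return 1
    if aa in "DILNP":
        return 2
    return 3


@dataclass
class SyntheticProtein:
    record: ProteinRecord
    chain: ChainStructure
    tm_true: float
    planted_counts: tuple[int, ...]    # per planted window
    background_count: int


@dataclass
class SyntheticDataset:
    proteins: list[SyntheticProtein]
    config: GeneratorConfig

    @property
    def records(self) -> list[ProteinRecord]:
        return [p.record for p in self.proteins]

    @property
    def chains(self) -> dict[str, ChainStructure]:
        return {p.record.id: p.chain for p in self.proteins}

    def write(self, outdir: str | Path) -> None:
        """Write PDB files, a FASTA and a metadata TSV (real-data schema)."""
        outdir = Path(outdir)
        (outdir / "structures").mkdir(parents=True, exist_ok=True)
        records = []
        fasta_lines = []
        for p in self.proteins:
            rel = f"structures/{p.record.id}.pdb"
            write_chain_pdb(p.chain, outdir / rel)
            # path relative to the metadata file: output is relocatable and
            # byte-identical across runs
            records.append(dataclasses.replace(p.record, structure_path=rel))
            fasta_lines.append(f">{p.record.id}\n{p.record.sequence}\n")
        (outdir / "sequences.fasta").write_text("".join(fasta_lines))
        write_metadata(records, outdir / "metadata.tsv")


# ---------------------------------------------------------------------------
# generation


def generate(config: GeneratorConfig,
             outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate all families of the configured dataset."""
    rng = np.random.default_rng(config.seed)
    proteins: list[SyntheticProtein] = []
    for f in range(config.n_families):
        proteins.extend(generate_family(config, f"F{f:02d}", rng))
    ds = SyntheticDataset(proteins=proteins, config=config)
    if outdir is not None:
        ds.write(outdir)
    return ds


def generate_family(config: GeneratorConfig, family: str,
                    rng: np.random.Generator) -> list[SyntheticProtein]:
    """Generate one homologous family from a common ancestor sequence."""
    L = config.residues_per_protein
    alphabet = _free_alphabet(config)
    ancestor = rng.choice(alphabet, size=L)
    out = []
    for i in range(config.proteins_per_family):
        pid = f"{family}P{i:02d}"
        tm_true = float(rng.choice(config.tm_levels))
        mut_frac = config.mutation_ladder[i % len(config.mutation_ladder)]
        seq = _mutate(ancestor, mut_frac, rng, alphabet)
        prot = _build_protein(pid, family, seq, tm_true, config, rng)
        out.append(prot)
    return out


def _mutate(ancestor: np.ndarray, frac: float, rng: np.random.Generator,
            alphabet: list[str]) -> np.ndarray:
    seq = ancestor.copy()
    n_mut = int(round(frac * len(seq)))
    if n_mut:
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        for p in pos:
            choices = [a for a in alphabet if a != seq[p]]
            seq[p] = rng.choice(choices)
    return seq


def _contact_plan(config: GeneratorConfig, tm_true: float,
                  rng: np.random.Generator,
                  ) -> tuple[list[tuple[PlantedContact, int]], int]:
    planted = []
    for pc in config.planted_pairs:
        n = pc.base + pc.slope * (tm_true - config.tm_mid)
        n_int = int(round(n))
        if n_int < 0:
            raise GeometryRequestError(
                f"planted count {n:.2f} negative at Tm={tm_true}")
        planted.append((pc, n_int))
    lo, hi = config.background_count_range
    n_bg = int(rng.integers(lo, hi + 1))
    return planted, n_bg


def _assign_pairs(n_pairs: int, L: int, min_sep: int,
                  rng: np.random.Generator,
                  deterministic: bool = False) -> list[tuple[int, int]]:
    """Disjoint residue index pairs with |i-j| >= min_sep."""
    if 2 * n_pairs > L:
        raise GeometryRequestError(
            f"{n_pairs} contacts need {2 * n_pairs} residues, chain has {L}")
    if deterministic:
        # interleaved blocks: pair k = (k, k + n_pairs), separation n_pairs
        if n_pairs and n_pairs < min_sep:
            raise GeometryRequestError("too few pairs for deterministic layout")
        return [(k, k + n_pairs) for k in range(n_pairs)]
    for _ in range(200):
        perm = rng.permutation(L)
        pairs = [(int(perm[2 * k]), int(perm[2 * k + 1]))
                 for k in range(n_pairs)]
        if all(abs(i - j) >= min_sep for i, j in pairs):
            return [(min(i, j), max(i, j)) for i, j in pairs]
    raise GeometryRequestError("could not place disjoint contact pairs")


def _build_protein(pid: str, family: str, seq: np.ndarray, tm_true: float,
                   config: GeneratorConfig,
                   rng: np.random.Generator) -> SyntheticProtein:
    L = len(seq)
    planted, n_bg = _contact_plan(config, tm_true, rng)
    n_pairs = sum(n for _, n in planted) + n_bg
    pairs = _assign_pairs(n_pairs, L, config.min_sep, rng,
                          deterministic=config.deterministic_layout)

    # overwrite contact positions with the planted amino-acid types and
    # assign each pair its island center
    centers = np.zeros((L, 3))
    free = np.ones(L, dtype=bool)
    island = 0
    k = 0
    planted_realized = []
    for pc, n in planted:
        for _ in range(n):
            i, j = pairs[k]; k += 1
            seq[i], seq[j] = pc.aa_pair
            base = np.array([0.0, 1000.0 + 50.0 * island, 0.0])
            centers[i] = base
            centers[j] = base + np.array([pc.distance, 0.0, 0.0])
            free[i] = free[j] = False
            island += 1
        planted_realized.append(n)
    a_bg, b_bg = config.background_pair
    for _ in range(n_bg):
        i, j = pairs[k]; k += 1
        seq[i], seq[j] = a_bg, b_bg
        base = np.array([0.0, 1000.0 + 50.0 * island, 0.0])
        centers[i] = base
        centers[j] = base + np.array([config.background_distance, 0.0, 0.0])
        free[i] = free[j] = False
        island += 1
    # free residues: a "ruler" line whose successive spacings cycle through
    # the core distance bins.  This fills every column of the distance
    # tables with Tm-independent mass from many amino-acid pairs, so the
    # bin marginals f(s) are not dominated by the planted contacts (as in
    # real structure datasets, where any one pair type is a small fraction
    # of a bin).  Slots are interleaved so that ruler neighbours are at
    # least min_sep apart in sequence and their distances are counted.
    free_idx = np.flatnonzero(free)
    order = np.concatenate([free_idx[::2], free_idx[1::2]])
    x = 0.0
    for slot, i in enumerate(order):
        centers[i] = np.array([x, 500.0, 0.0])
        x += _RULER_SPACINGS[slot % len(_RULER_SPACINGS)]

    # torsion-domain composition drifts with Tm through the helix propensity
    shift = config.torsion_slope * (tm_true - config.tm_mid)
    probs = dict(_DOMAIN_BASE_P)
    probs["A"] = float(np.clip(probs["A"] + shift, 0.02, 0.95))
    probs["B"] = float(np.clip(probs["B"] - shift, 0.02, 0.95))
    labels = list(_DOMAIN_BOXES)
    pvec = np.array([probs[l] for l in labels])
    pvec /= pvec.sum()
    doms = rng.choice(labels, size=L, p=pvec)
    phis, psis = np.empty(L), np.empty(L)
    for i, d in enumerate(doms):
        (plo, phi_), (slo, shi) = _DOMAIN_BOXES[d]
        phis[i] = rng.uniform(plo, phi_)
        psis[i] = rng.uniform(slo, shi)
    backbone = build_backbone(phis, psis)

    residues = []
    for i, aa in enumerate(seq):
        n_at = _n_sidechain_atoms(aa)
        atoms = [centers[i] + off for off in _SIDECHAIN_OFFSETS[n_at]]
        residues.append(ResidueAtoms(aa=str(aa), backbone=dict(backbone[i]),
                                     sidechain_heavy=atoms))
    chain = ChainStructure(chain_id="A", residues=residues, source_id=pid)

    slope, icpt, sd = config.tenv_model
    tenv = (tm_true - icpt) / slope + float(rng.normal(0.0, sd)) if sd > 0 \
        else (tm_true - icpt) / slope
    measured = bool(rng.random() < config.measured_fraction)
    tm_obs = tm_true + float(rng.normal(0.0, config.tm_noise)) \
        if config.tm_noise > 0 else tm_true
    record = ProteinRecord(
        id=pid, family=family,
        tm=tm_obs if measured else None,
        tenv=float(tenv),
        tm_source=MEASURED if measured else None,
        sequence="".join(seq), chain_id="A")
    return SyntheticProtein(record=record, chain=chain, tm_true=tm_true,
                            planted_counts=tuple(planted_realized),
                            background_count=n_bg)


# ---------------------------------------------------------------------------
# PDB output


def write_chain_pdb(chain: ChainStructure, path: str | Path) -> None:
    """Write a ChainStructure as a single-chain PDB file via Bio.PDB."""
    builder = StructureBuilder()
    builder.init_structure(chain.source_id or "SYN")
    builder.init_model(0)
    builder.init_chain(chain.chain_id)
    builder.init_seg("    ")
    serial = 1
    for i, res in enumerate(chain.residues, start=1):
        builder.init_residue(ONE_TO_THREE[res.aa], " ", i, " ")
        names = ([("N", res.backbone.get("N")), ("CA", res.backbone.get("CA")),
                  ("C", res.backbone.get("C"))]
                 + list(zip(_SIDECHAIN_NAMES[len(res.sidechain_heavy)]
                            if res.sidechain_heavy else [],
                            res.sidechain_heavy)))
        for name, coord in names:
            if coord is None:
                continue
            builder.init_atom(name, np.asarray(coord, dtype=float), 0.0, 1.0,
                              " ", f"{name:^4s}", serial, element=name[0])
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# feature-level linear benchmark (predictor validation)


def make_linear_benchmark(n: int = 60,
                          beta: tuple[float, ...] = (8.0, -5.0, 3.0, -2.0),
                          intercept: float = 60.0, tau: float = 5.0,
                          seed: int | np.random.Generator = 0,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Features X ~ N(0,1) and Tm = intercept + X·beta + N(0, tau)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(n, len(beta)))
    tm = intercept + X @ np.asarray(beta) + rng.normal(0.0, tau, size=n)
    return X, tm
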