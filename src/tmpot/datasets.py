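"""Protein metadata, Tm estimation from host temperature, and dataset splits.

Melting temperatures are scarce; proteins with only a host environmental
temperature Tenv get a rough Tm estimate by one of three rules — a global
Tm–Tenv regression, a within-family regression, or transfer from the
highest-identity family member with a measured Tm.  Each family-enlarged
dataset is then split at the median Tm into a mesostable and a thermostable
half, and each half (and the unsplit "average" set) is culled so that no
within-set pair exceeds a sequence-identity cutoff (default 25%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from statistics import fmean

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy import stats

MEASURED = "measured"
EST_GLOBAL = "est_global_regression"
EST_FAMILY = "est_family_regression"
EST_IDENTITY = "est_seq_identity"
ESTIMATION_METHODS = (EST_GLOBAL, EST_FAMILY, EST_IDENTITY)


class DatasetError(ValueError):
    pass


class EstimationError(DatasetError):
    """Raised when the context required by an estimation rule is missing."""


@dataclass
class ProteinRecord:
    id: str
    family: str | None = None
    tm: float | None = None          # °C
    tenv: float | None = None        # °C
    tm_source: str | None = None
    sequence: str | None = None
    structure_path: str | None = None
    chain_id: str = "A"

    @property
    def has_measured_tm(self) -> bool:
        return self.tm is not None and self.tm_source == MEASURED


@dataclass(frozen=True)
class RegressionLine:
    """OLS line Tm = slope·Tenv + intercept with Pearson r over n points."""

    slope: float
    intercept: float
    r: float
    n: int

    def predict(self, tenv: float) -> float:
        return self.slope * tenv + self.intercept


@dataclass
class DatasetTriple:
    """Mesostable / thermostable / average subsets and their mean Tm's."""

    meso: list[ProteinRecord]
    thermo: list[ProteinRecord]
    average: list[ProteinRecord]
    t_meso: float
    t_thermo: float
    t_avg: float
    tm0: float


# ---------------------------------------------------------------------------
# Tm ~ Tenv regression


def fit_tm_tenv_regression(records: list[ProteinRecord]) -> RegressionLine:
    """OLS regression of measured Tm on Tenv over the given records."""
    pts = [(r.tenv, r.tm) for r in records
           if r.tm is not None and r.tenv is not None]
    if len(pts) < 2:
        raise EstimationError(
            f"need >=2 records with both Tm and Tenv, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise EstimationError("zero Tenv variance: regression undefined")
    res = stats.linregress(x, y)
    return RegressionLine(slope=float(res.slope), intercept=float(res.intercept),
                          r=float(res.rvalue), n=len(pts))


# ---------------------------------------------------------------------------
# pairwise sequence identity


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring used for identity computation.

    Affine gaps: a gap of length L costs open + (L-1)·extend, end gaps
    included, matching the aligner's convention.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


DEFAULT_SCORING = AlignmentScoring()
_ALIGNER_CACHE: dict[AlignmentScoring, Align.PairwiseAligner] = {}


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(scoring)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
        aligner.open_gap_score = -scoring.gap_open
        aligner.extend_gap_score = -scoring.gap_extend
        _ALIGNER_CACHE[scoring] = aligner
    return aligner


def pairwise_identity(a: str, b: str,
                      scoring: AlignmentScoring = DEFAULT_SCORING) -> float:
    """Fraction of identical positions in the optimal global alignment.

    The denominator is the full alignment length, gap columns included.
    """
    if not a or not b:
        raise DatasetError("cannot align an empty sequence")
    aln = _aligner(scoring).align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


# ---------------------------------------------------------------------------
# Tm estimation rules


def estimate_tm(record: ProteinRecord, method: str,
                family_records: list[ProteinRecord] | None = None,
                global_line: RegressionLine | None = None,
                scoring: AlignmentScoring = DEFAULT_SCORING,
                identity_fn=None) -> ProteinRecord:
    """Return a copy of ``record`` with tm filled in by the chosen rule.

    ``identity_fn(seq_a, seq_b)`` overrides :func:`pairwise_identity` for
    the identity-transfer rule (e.g. a memoized wrapper).
    """
    if method not in ESTIMATION_METHODS:
        raise EstimationError(f"unknown estimation method {method!r}")

    if method == EST_GLOBAL:
        if global_line is None:
            raise EstimationError("global regression line missing")
        if record.tenv is None:
            raise EstimationError(f"{record.id}: Tenv missing")
        tm = global_line.predict(record.tenv)

    elif method == EST_FAMILY:
        if record.tenv is None:
            raise EstimationError(f"{record.id}: Tenv missing")
        members = [r for r in (family_records or [])
                   if r.has_measured_tm and r.tenv is not None
                   and r.id != record.id]
        if len(members) < 2:
            raise EstimationError(
                f"{record.id}: family regression needs >=2 measured members")
        line = fit_tm_tenv_regression(members)
        tm = line.predict(record.tenv)

    else:  # EST_IDENTITY
        if not record.sequence:
            raise EstimationError(f"{record.id}: sequence missing")
        candidates = [r for r in (family_records or [])
                      if r.has_measured_tm and r.sequence and r.id != record.id]
        if not candidates:
            raise EstimationError(
                f"{record.id}: no measured family member with sequence")
        ident = identity_fn or (lambda a, b: pairwise_identity(a, b, scoring))
        best = max(candidates,
                   key=lambda r: (ident(record.sequence, r.sequence),
                                  _neg_id_key(r.id)))
        tm = best.tm

    return dataclasses.replace(record, tm=float(tm), tm_source=method)


def _neg_id_key(s: str) -> tuple:
    # max() tie-break helper: prefer lexicographically smaller id
    return tuple(-ord(c) for c in s)


# ---------------------------------------------------------------------------
# median split + identity culling


def split_and_cull(records: list[ProteinRecord], identity_cutoff: float = 0.25,
                   scoring: AlignmentScoring = DEFAULT_SCORING,
                   identity_fn=None) -> DatasetTriple:
    """Split at the median Tm and cull each subset below the identity cutoff.

    Culling repeatedly resolves the currently most-similar pair: the record
    with a measured Tm survives over one with an estimated Tm; otherwise
    the higher-Tm record survives in the thermostable set, the lower-Tm in
    the mesostable set, and the record with Tm closest to the pre-culling
    mean survives in the average set.
    """
    if len(records) < 4:
        raise DatasetError(f"need >=4 records to split, got {len(records)}")
    if any(r.tm is None for r in records):
        raise DatasetError("all records must have a (measured or estimated) Tm")

    ordered = sorted(records, key=lambda r: (r.tm, r.id))
    tm0 = float(ordered[len(ordered) // 2].tm)
    meso = [r for r in ordered if r.tm < tm0]
    thermo = [r for r in ordered if r.tm >= tm0]
    pre_mean = fmean(r.tm for r in records)

    ident = identity_fn or (lambda a, b: pairwise_identity(a, b, scoring))
    meso = _cull(meso, identity_cutoff, "meso", ident)
    thermo = _cull(thermo, identity_cutoff, "thermo", ident)
    average = _cull(list(ordered), identity_cutoff, "average", ident,
                    ref_mean=pre_mean)

    return DatasetTriple(
        meso=meso, thermo=thermo, average=average,
        t_meso=fmean(r.tm for r in meso) if meso else float("nan"),
        t_thermo=fmean(r.tm for r in thermo) if thermo else float("nan"),
        t_avg=fmean(r.tm for r in average) if average else float("nan"),
        tm0=tm0,
    )


def _cull(records: list[ProteinRecord], cutoff: float, mode: str,
          identity_fn, ref_mean: float | None = None,
          ) -> list[ProteinRecord]:
    if len(records) < 2:
        return records
    alive = {r.id: r for r in records}
    ids = sorted(alive)
    ident: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if alive[a].sequence and alive[b].sequence:
                ident[(a, b)] = identity_fn(alive[a].sequence,
                                            alive[b].sequence)
    while True:
        live_pairs = [(idy, pair) for pair, idy in ident.items()
                      if pair[0] in alive and pair[1] in alive
                      and idy > cutoff]
        if not live_pairs:
            break
        # worst offender first; ties by lexicographic id pair
        live_pairs.sort(key=lambda t: (-t[0], t[1]))
        _, (a, b) = live_pairs[0]
        ra, rb = alive[a], alive[b]
        loser = _pick_loser(ra, rb, mode, ref_mean)
        del alive[loser.id]
    return [r for r in records if r.id in alive]


def _pick_loser(ra: ProteinRecord, rb: ProteinRecord, mode: str,
                ref_mean: float | None) -> ProteinRecord:
    # rule (1): a measured Tm always survives over an estimated one
    if ra.has_measured_tm != rb.has_measured_tm:
        return rb if ra.has_measured_tm else ra
    # rule (2): mode-specific Tm preference, ties to the smaller id
    if mode == "thermo":
        keys = {ra.id: (-ra.tm, ra.id), rb.id: (-rb.tm, rb.id)}
    elif mode == "meso":
        keys = {ra.id: (ra.tm, ra.id), rb.id: (rb.tm, rb.id)}
    elif mode == "average":
        keys = {ra.id: (abs(ra.tm - ref_mean), ra.id),
                rb.id: (abs(rb.tm - ref_mean), rb.id)}
    else:
        raise ValueError(f"unknown culling mode {mode!r}")
    keeper = ra if keys[ra.id] <= keys[rb.id] else rb
    return rb if keeper is ra else ra


# ---------------------------------------------------------------------------
# metadata I/O

METADATA_COLUMNS = ("id", "family", "tm_measured", "tenv",
                    "structure_path", "chain_id")


def read_metadata(tsv_path: str | Path,
                  fasta_path: str | Path | None = None) -> list[ProteinRecord]:
    """Load a metadata TSV (and sequences from a FASTA keyed by record id)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"id": str, "family": str})
    missing = {"id"} - set(df.columns)
    if missing:
        raise DatasetError(f"metadata table lacks columns: {sorted(missing)}")
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path),
                                                            "fasta")}
    base = Path(tsv_path).parent
    records = []
    for row in df.itertuples(index=False):
        tm = getattr(row, "tm_measured", None)
        tm = None if tm is None or pd.isna(tm) else float(tm)
        tenv = getattr(row, "tenv", None)
        tenv = None if tenv is None or pd.isna(tenv) else float(tenv)
        spath = str(getattr(row, "structure_path", "") or "")
        if spath and not Path(spath).is_absolute():
            spath = str(base / spath)  # relative to the metadata file
        records.append(ProteinRecord(
            id=str(row.id),
            family=str(row.family) if getattr(row, "family", None) is not None
            and not pd.isna(row.family) else None,
            tm=tm, tenv=tenv,
            tm_source=MEASURED if tm is not None else None,
            sequence=seqs.get(str(row.id)),
            structure_path=spath or None,
            chain_id=str(getattr(row, "chain_id", "A") or "A"),
        ))
    return records


def write_metadata(records: list[ProteinRecord], tsv_path: str | Path) -> None:
    rows = [{
        "id": r.id, "family": r.family,
        "tm_measured": r.tm if r.has_measured_tm else None,
        "tenv": r.tenv, "structure_path": r.structure_path,
        "chain_id": r.chain_id,
    } for r in records]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        tsv_path, sep="\t", index=False)
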