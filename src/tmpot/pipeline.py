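"""End-to-end workflow: from structures and metadata to Tm predictions.

For each homologous family F the workflow builds the family-enlarged
dataset D_F (all proteins with a measured Tm, plus the family's members
whose Tm is only estimated), splits it into mesostable / thermostable /
average subsets under each of the three Tm-estimation rules, culls each
subset at the sequence-identity cutoff, derives the four statistical
potentials per subset (averaging the 3-method x 2-sigma variants), and
scores the family's measured proteins against the three potential sets.
The resulting feature table feeds the two Tm regressions (ddG- and
dG_A-based), with jack-knife cross-validation, optionally strict (all
potentials and features re-derived without the held-out protein).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from statistics import fmean

import numpy as np
import pandas as pd

from . import datasets as ds
from . import potentials as pot
from .descriptors import ProteinDescriptor, extract_descriptor
from .energy import score_counts
from .geometry import DEFAULT_BINNING, DEFAULT_DOMAIN_TABLE
from .predictor import MODE_DDG, TmRegression
from .structure_io import ChainStructure

logger = logging.getLogger(__name__)

SET_LABELS = ("meso", "thermo", "average")

DDG_COLS = [f"ddg_{k}" for k in pot.POTENTIAL_KINDS]
DGA_COLS = [f"dga_{k}" for k in pot.POTENTIAL_KINDS]


@dataclass(frozen=True)
class WorkflowConfig:
    identity_cutoff: float = 0.25
    methods: tuple[str, ...] = ds.ESTIMATION_METHODS
    sigmas: tuple[float, ...] = pot.DEFAULT_SIGMAS
    lam: float = pot.DEFAULT_LAMBDA
    window: int = pot.DEFAULT_WINDOW
    min_sep: int = pot.DEFAULT_MIN_SEP
    tor2_domain_of: str = "i"
    scoring: ds.AlignmentScoring = field(default_factory=ds.AlignmentScoring)


class TmWorkflow:
    """Orchestrates the full melting-temperature prediction pipeline."""

    def __init__(self, records: list[ds.ProteinRecord],
                 chains: dict[str, ChainStructure],
                 config: WorkflowConfig | None = None,
                 domain_table=DEFAULT_DOMAIN_TABLE,
                 binning=DEFAULT_BINNING):
        self.cfg = config or WorkflowConfig()
        self.records = [r for r in records if r.id in chains]
        self.binning = binning
        self.descriptors: dict[str, ProteinDescriptor] = {
            r.id: extract_descriptor(chains[r.id], domain_table, binning)
            for r in self.records}
        # per-protein counts: the additive building blocks of every dataset
        self._counts: dict[str, dict[str, pot.CountTable]] = {
            r.id: {kind: pot.count_motifs(
                [self.descriptors[r.id]], kind, window=self.cfg.window,
                min_sep=self.cfg.min_sep, binning=binning,
                tor2_domain_of=self.cfg.tor2_domain_of)
                for kind in pot.POTENTIAL_KINDS}
            for r in self.records}
        scoring = self.cfg.scoring

        @lru_cache(maxsize=None)
        def _ident(a: str, b: str) -> float:
            if b < a:
                a, b = b, a
            return ds.pairwise_identity(a, b, scoring)

        self._identity = _ident

    # -- dataset assembly ---------------------------------------------------

    @property
    def families(self) -> list[str]:
        return sorted({r.family for r in self.records if r.family})

    def measured_records(self, exclude: str | None = None,
                         ) -> list[ds.ProteinRecord]:
        return [r for r in self.records
                if r.has_measured_tm and r.id != exclude]

    def estimated_records(self, method: str, family: str,
                          exclude: str | None = None,
                          ) -> list[ds.ProteinRecord]:
        """The family-enlarged dataset D_F under one Tm-estimation rule.

        Measured proteins of every family enter as-is; the unmeasured
        members of family F get their Tm from the requested rule.
        Proteins whose estimation context is missing are skipped (logged).
        """
        measured = self.measured_records(exclude)
        line = None
        if method == ds.EST_GLOBAL:
            line = ds.fit_tm_tenv_regression(measured)
        out = list(measured)
        fam_measured = [r for r in measured if r.family == family]
        for r in self.records:
            if r.has_measured_tm or r.id == exclude or r.family != family:
                continue
            try:
                out.append(ds.estimate_tm(
                    r, method, family_records=fam_measured, global_line=line,
                    identity_fn=self._identity))
            except ds.EstimationError as err:
                logger.debug("skipping %s under %s: %s", r.id, method, err)
        return out

    def family_triple(self, family: str, method: str,
                      exclude: str | None = None) -> ds.DatasetTriple:
        recs = self.estimated_records(method, family, exclude)
        return ds.split_and_cull(recs, self.cfg.identity_cutoff,
                                 identity_fn=self._identity)

    # -- potentials ---------------------------------------------------------

    def _set_counts(self, member_ids: list[str]) -> dict[str, pot.CountTable]:
        out = {}
        for kind in pot.POTENTIAL_KINDS:
            total = self._counts[member_ids[0]][kind]
            for pid in member_ids[1:]:
                total = total + self._counts[pid][kind]
            out[kind] = total
        return out

    def potentials_for_family(self, family: str, exclude: str | None = None,
                              ) -> dict[str, pot.PotentialSet]:
        """The meso/thermo/average PotentialSets of family F.

        Each table is the cell-wise mean of the |methods| x |sigmas|
        variants, computed from cached per-protein counts.
        """
        members: dict[str, dict[str, list[str]]] = {s: {} for s in SET_LABELS}
        t_sets: dict[str, list[float]] = {s: [] for s in SET_LABELS}
        for method in self.cfg.methods:
            triple = self.family_triple(family, method, exclude)
            for label, recs, t in (("meso", triple.meso, triple.t_meso),
                                   ("thermo", triple.thermo, triple.t_thermo),
                                   ("average", triple.average, triple.t_avg)):
                members[label][method] = [r.id for r in recs]
                t_sets[label].append(t)
        out = {}
        for label in SET_LABELS:
            t_set = fmean(t_sets[label])
            tables: dict[str, pot.PotentialTable] = {}
            for kind in pot.POTENTIAL_KINDS:
                variants = []
                for method, ids in members[label].items():
                    if not ids:
                        continue
                    counts = self._set_counts(ids)[kind]
                    if kind in pot.DISTANCE_KINDS:
                        counts = pot.smooth_distance_counts(
                            counts, self.cfg.lam, self.binning)
                    for sigma in self.cfg.sigmas:
                        variants.append(pot.boltzmann_potential(
                            counts, sigma=sigma, t_set=t_set,
                            provenance={"family": family, "set": label,
                                        "method": method}))
                tables[kind] = pot.PotentialTable(
                    potential_kind=kind,
                    values=np.mean([v.values for v in variants], axis=0),
                    seq_labels=variants[0].seq_labels,
                    struct_labels=variants[0].struct_labels,
                    t_set=t_set,
                    provenance={"family": family, "set": label,
                                "n_variants": len(variants)})
            out[label] = pot.PotentialSet(t_set=t_set, **tables)
        return out

    # -- features -----------------------------------------------------------

    def feature_table(self, exclude: str | None = None) -> pd.DataFrame:
        """Per measured protein: ddG and dG_A energy features plus Tm.

        ``exclude`` removes a protein from every dataset (and from the
        table) before potentials are derived — the strict jack-knife fold.
        """
        rows = []
        for family in self.families:
            fam_measured = [r for r in self.measured_records(exclude)
                            if r.family == family]
            if not fam_measured:
                continue
            psets = self.potentials_for_family(family, exclude)
            for r in fam_measured:
                rows.append(self._feature_row(r, psets))
        return pd.DataFrame(rows)

    def _feature_row(self, record: ds.ProteinRecord,
                     psets: dict[str, pot.PotentialSet]) -> dict:
        n = len(self.descriptors[record.id])
        vecs = {label: score_counts(self._counts[record.id], n, psets[label],
                                    protein_id=record.id)
                for label in SET_LABELS}
        ddg = vecs["meso"].terms - vecs["thermo"].terms
        row = {"id": record.id, "family": record.family, "tm": record.tm}
        row.update({c: v for c, v in zip(DDG_COLS, ddg)})
        row.update({c: v for c, v in zip(DGA_COLS, vecs["average"].terms)})
        return row

    # -- prediction ---------------------------------------------------------

    def model(self, mode: str = MODE_DDG,
              features: pd.DataFrame | None = None) -> TmRegression:
        feats = features if features is not None else self.feature_table()
        cols = DDG_COLS if mode == MODE_DDG else DGA_COLS
        return TmRegression.from_dataframe(feats, cols, tm_col="tm",
                                           id_col="id", family_col="family",
                                           mode=mode)

    def strict_feature_provider(self, mode: str,
                                base_features: pd.DataFrame):
        """A jack-knife feature provider that re-derives everything per fold."""
        cols = DDG_COLS if mode == MODE_DDG else DGA_COLS
        ids = base_features["id"].tolist()

        def provider(i: int):
            held = ids[i]
            fold = self.feature_table(exclude=held)
            train_ids = [p for p in ids if p != held]
            fold = fold.set_index("id").loc[train_ids]
            X_tr = fold[cols].to_numpy(dtype=float)
            # the held-out protein scored against leave-one-out potentials
            fam = next(r.family for r in self.records if r.id == held)
            psets = self.potentials_for_family(fam, exclude=held)
            rec = next(r for r in self.records if r.id == held)
            row = self._feature_row(rec, psets)
            x_te = np.array([row[c] for c in cols])
            return X_tr, x_te

        return provider

    def run(self, mode: str = MODE_DDG, jackknife: bool = True,
            strict: bool = False, exclude_worst: int = 0):
        """Fit the requested predictor; returns results (or a WorstKTrace)."""
        feats = self.feature_table()
        model = self.model(mode, feats)
        if exclude_worst:
            return model.worst_k_exclusion(exclude_worst)
        if not jackknife:
            return model.fit()
        provider = self.strict_feature_provider(mode, feats) if strict \
            else None
        return model.jackknife(feature_provider=provider)
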