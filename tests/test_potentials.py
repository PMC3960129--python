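"""Counting, smoothing, Boltzmann inversion and variant averaging."""

import numpy as np
import pytest

from tmpot.aminoacids import AA_INDEX
from tmpot.descriptors import ProteinDescriptor
from tmpot.geometry import DEFAULT_BINNING
from tmpot.potentials import (DIST1, DIST2, POTENTIAL_KINDS,
                              TOR1, TOR2, CountTable, PotentialError,
                              boltzmann_potential, count_motifs,
                              derive_potential_set, motif_labels,
                              smooth_distance_counts)

from .conftest import random_descriptor

# ---------------------------------------------------------------------------
# independent brute-force recount oracle (naive double loops, no shared code)


def oracle_counts(desc: ProteinDescriptor, kind: str, window: int = 8,
                  min_sep: int = 2) -> np.ndarray:
    seq_labels, struct_labels = motif_labels(kind, window)
    counts = np.zeros((len(seq_labels), len(struct_labels)))
    row = {lab: i for i, lab in enumerate(seq_labels)}
    n = len(desc.sequence)
    doms = "ACBPGEO"

    def dom_col(d):
        return doms.index(d) if d in doms else None

    if kind == TOR1:
        for i in range(n):
            for j in range(n):
                if abs(j - i) <= window and desc.sequence[i] in AA_INDEX:
                    c = dom_col(desc.domains[j])
                    if c is not None:
                        counts[row[(desc.sequence[i], j - i)], c] += 1
    elif kind == TOR2:
        for i in range(n):
            for j in range(i + 1, n):
                if j - i <= window and desc.sequence[i] in AA_INDEX \
                        and desc.sequence[j] in AA_INDEX:
                    c = dom_col(desc.domains[i])
                    if c is not None:
                        counts[row[(desc.sequence[i], desc.sequence[j])],
                               c] += 1
    else:
        for i in range(n):
            for j in range(i + min_sep, n):
                d = desc.distances[i, j]
                if not np.isfinite(d):
                    continue
                a, b = desc.sequence[i], desc.sequence[j]
                if a not in AA_INDEX or b not in AA_INDEX:
                    continue
                if d < 3.0:
                    col = 0
                elif d >= 8.0:
                    col = 26
                else:
                    col = 1 + int((d - 3.0) / 0.2)
                if kind == DIST2:
                    counts[row[tuple(sorted((a, b)))], col] += 1
                else:
                    counts[AA_INDEX[a], col] += 1
                    counts[AA_INDEX[b], col] += 1
    return counts


class TestCountMotifs:
    @pytest.mark.parametrize("kind", POTENTIAL_KINDS)
    def test_matches_brute_force_recount(self, kind):
        rng = np.random.default_rng(42)
        for rep in range(25):
            desc = random_descriptor(rng, protein_id=f"p{rep}")
            got = count_motifs([desc], kind)
            expected = oracle_counts(desc, kind)
            np.testing.assert_array_equal(got.counts, expected,
                                          err_msg=f"{kind} rep {rep}")

    def test_single_residue_tor1_counts_self_only(self):
        desc = ProteinDescriptor("p", "W", "A",
                                 np.full((1, 1), np.nan))
        got = count_motifs([desc], TOR1)
        assert got.n_total == 1
        row = got.seq_labels.index(("W", 0))
        assert got.counts[row, got.struct_labels.index("A")] == 1

    def test_three_residue_dist2_single_pair(self):
        d = np.full((3, 3), np.nan)
        d[0, 2] = d[2, 0] = 5.0
        d[0, 1] = d[1, 0] = d[1, 2] = d[2, 1] = 4.0  # excluded by min_sep
        desc = ProteinDescriptor("p", "ADA", "AAA", d)
        got = count_motifs([desc], DIST2, min_sep=2)
        assert got.n_total == 1

    def test_counts_additive_over_proteins(self):
        rng = np.random.default_rng(1)
        d1, d2 = random_descriptor(rng), random_descriptor(rng)
        both = count_motifs([d1, d2], DIST2)
        single = count_motifs([d1], DIST2) + count_motifs([d2], DIST2)
        np.testing.assert_array_equal(both.counts, single.counts)

    def test_empty_input_rejected(self):
        with pytest.raises(PotentialError):
            count_motifs([], TOR1)


class TestSmoothing:
    def _table(self, counts):
        seq, struct = motif_labels(DIST1)
        full = np.zeros((len(seq), len(struct)))
        full[:counts.shape[0], :] = counts
        return CountTable(DIST1, full, seq, struct)

    def test_lambda_zero_is_identity(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.integers(0, 9, size=(5, 27)).astype(float))
        out = smooth_distance_counts(t, 0.0)
        np.testing.assert_array_equal(out.counts, t.counts)

    def test_single_count_spreads_geometrically(self):
        counts = np.zeros((1, 27))
        core_bin_10 = DEFAULT_BINNING.core_index(10)
        counts[0, core_bin_10] = 1.0
        out = smooth_distance_counts(self._table(counts), 0.5)
        core = out.counts[0, DEFAULT_BINNING.core_slice]
        # direct evaluation of the weighted sum, renormalized to mass 1
        raw = 0.5 ** np.abs(np.arange(25) - 10)
        np.testing.assert_allclose(core, raw / raw.sum(), atol=1e-12)
        assert out.counts[0].sum() == pytest.approx(1.0)

    def test_uniform_row_almost_unchanged_except_edges(self):
        counts = np.zeros((1, 27))
        counts[0, DEFAULT_BINNING.core_slice] = 1.0
        out = smooth_distance_counts(self._table(counts), 0.4)
        core = out.counts[0, DEFAULT_BINNING.core_slice]
        # oracle: constant convolved with the truncated kernel, rescaled
        kern = 0.4 ** np.abs(np.arange(25)[:, None] - np.arange(25)[None, :])
        expect = kern.sum(axis=1)
        expect *= 25.0 / expect.sum()
        np.testing.assert_allclose(core, expect, atol=1e-10)
        interior = core[9:16]  # edge effects decay like lam^distance
        assert np.allclose(interior, interior[0], atol=1e-3)

    def test_mass_conserved_per_motif(self):
        rng = np.random.default_rng(9)
        t = self._table(rng.uniform(0, 5, size=(20, 27)))
        for lam in (0.1, 0.5, 0.9):
            out = smooth_distance_counts(t, lam)
            np.testing.assert_allclose(out.counts.sum(axis=1),
                                       t.counts.sum(axis=1), rtol=1e-9)

    def test_underflow_overflow_untouched(self):
        rng = np.random.default_rng(4)
        t = self._table(rng.uniform(0, 5, size=(20, 27)))
        out = smooth_distance_counts(t, 0.7)
        np.testing.assert_array_equal(out.counts[:, 0], t.counts[:, 0])
        np.testing.assert_array_equal(out.counts[:, 26], t.counts[:, 26])

    def test_invalid_inputs(self):
        t = self._table(np.ones((2, 27)))
        with pytest.raises(PotentialError):
            smooth_distance_counts(t, 1.0)
        with pytest.raises(PotentialError):
            smooth_distance_counts(t, -0.1)
        tor = count_motifs([random_descriptor(np.random.default_rng(0))],
                           TOR1)
        with pytest.raises(PotentialError):
            smooth_distance_counts(tor, 0.5)


def _toy_table(counts: np.ndarray) -> CountTable:
    seq = [f"c{i}" for i in range(counts.shape[0])]
    struct = [f"s{j}" for j in range(counts.shape[1])]
    return CountTable(DIST2, counts.astype(float), seq, struct)


class TestBoltzmannInversion:
    def test_factorized_counts_give_zero_potential(self):
        # n(c,s) = outer product -> independence -> dW identically 0
        row = np.array([3.0, 1.0, 6.0])
        col = np.array([2.0, 5.0])
        table = _toy_table(np.outer(row, col))
        out = boltzmann_potential(table, sigma=0.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)

    def test_unobserved_motif_rows_are_zero(self):
        counts = np.array([[4.0, 2.0], [0.0, 0.0], [1.0, 3.0]])
        for sigma in (0.0, 10.0):
            out = boltzmann_potential(_toy_table(counts), sigma=sigma)
            np.testing.assert_array_equal(out.values[1], 0.0)

    def test_hand_computed_two_by_two(self):
        counts = np.array([[3.0, 1.0], [1.0, 3.0]])
        out = boltzmann_potential(_toy_table(counts), sigma=0.0)
        # f(s1|A) = 3/4, f(s1) = 1/2 -> dW = -ln(1.5)
        assert out.values[0, 0] == pytest.approx(-np.log(1.5))
        assert out.values[0, 1] == pytest.approx(-np.log(0.5))
        assert out.values[1, 0] == pytest.approx(-np.log(0.5))
        assert out.values[1, 1] == pytest.approx(-np.log(1.5))

    def test_sigma_zero_equals_plain_inversion_on_abundant_counts(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(50, 500, size=(6, 5)).astype(float)
        out = boltzmann_potential(_toy_table(counts), sigma=0.0)
        n = counts.sum()
        f_cs = counts / n
        f_c = f_cs.sum(axis=1, keepdims=True)
        f_s = f_cs.sum(axis=0, keepdims=True)
        plain = -np.log(f_cs / (f_c * f_s))
        np.testing.assert_allclose(out.values, plain, atol=1e-12)

    def test_sigma_to_infinity_drives_potential_to_zero_monotonically(self):
        rng = np.random.default_rng(23)
        counts = rng.integers(1, 30, size=(5, 4)).astype(float)
        prev = None
        for sigma in (0.0, 1.0, 10.0, 100.0, 1e4, 1e6):
            vals = boltzmann_potential(_toy_table(counts), sigma=sigma).values
            if prev is not None:
                assert np.all(np.abs(vals) <= np.abs(prev) + 1e-12)
            prev = vals
        assert np.max(np.abs(prev)) < 1e-3

    def test_negative_sigma_rejected(self):
        with pytest.raises(PotentialError):
            boltzmann_potential(_toy_table(np.ones((2, 2))), sigma=-1.0)


class TestDerivePotentialSet:
    def test_identical_variants_average_to_single(self):
        rng = np.random.default_rng(3)
        descs = [random_descriptor(rng, n=10) for _ in range(3)]
        one = derive_potential_set({"m1": descs}, t_set=50.0,
                                   sigmas=(10.0, 10.0))
        ref = derive_potential_set({"m1": descs}, t_set=50.0,
                                   sigmas=(10.0,))
        for kind in POTENTIAL_KINDS:
            np.testing.assert_allclose(one[kind].values, ref[kind].values,
                                       atol=1e-14)

    def test_average_matches_explicit_variant_mean(self):
        rng = np.random.default_rng(8)
        by_method = {m: [random_descriptor(rng, n=10) for _ in range(2)]
                     for m in ("global", "family", "identity")}
        sigmas = (5.0, 40.0)
        got = derive_potential_set(by_method, t_set=60.0, sigmas=sigmas,
                                   lam=0.5)
        for kind in POTENTIAL_KINDS:
            variants = []
            for descs in by_method.values():
                counts = count_motifs(descs, kind)
                if kind in (DIST1, DIST2):
                    counts = smooth_distance_counts(counts, 0.5)
                for s in sigmas:
                    variants.append(boltzmann_potential(counts, s).values)
            np.testing.assert_allclose(got[kind].values,
                                       np.mean(variants, axis=0), atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(PotentialError):
            derive_potential_set({}, t_set=50.0)


class TestDatasetSensitivity:
    def test_planted_enrichment_shifts_potential_sign(self):
        """A pair enriched in one dataset gets a more favourable energy there."""
        rng = np.random.default_rng(17)
        pair_row = None
        kind = DIST2

        def dataset(extra_dr_contacts):
            descs = []
            for _ in range(6):
                desc = random_descriptor(rng, n=12)
                seq = list(desc.sequence)
                d = desc.distances.copy()
                for k in range(extra_dr_contacts):
                    i, j = 2 * k, 2 * k + 5
                    if j < 12:
                        seq[i], seq[j] = "D", "R"
                        d[i, j] = d[j, i] = 4.1
                descs.append(ProteinDescriptor(desc.protein_id,
                                               "".join(seq), desc.domains, d))
            return count_motifs(descs, kind)

        enriched = boltzmann_potential(dataset(3), sigma=5.0)
        depleted = boltzmann_potential(dataset(0), sigma=5.0)
        pair_row = enriched.seq_labels.index(("D", "R"))
        col = DEFAULT_BINNING.core_index(5)  # 4.0-4.2 Å
        assert enriched.values[pair_row, col] < depleted.values[pair_row, col]
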