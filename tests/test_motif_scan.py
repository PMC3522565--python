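"""Similarity scores, exact site probabilities and scanning invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phylofoot as pf
from phylofoot.errors import InputError
from phylofoot.motif_scan import SCORE_TOL

from conftest import make_matrix


def _promoter(seq, gene_id="g", ws=-1000):
    return pf.PromoterSequence(
        gene_id=gene_id, species="Os", lineage="monocot", role="ortholog",
        cog_id="C1", seq=seq, window_start_rel=ws, window_end_rel=ws + len(seq),
    )


def _score_oracle(freqs, window):
    """Independent spreadsheet-style evaluation of the similarity formula."""
    ln4 = math.log(4.0)
    ci = [
        (100.0 / ln4) * (ln4 + sum(f * math.log(f) for f in row if f > 0))
        for row in freqs
    ]
    num = sum(c * row["ACGT".index(b)] for c, row, b in zip(ci, freqs, window))
    den = sum(c * max(row) for c, row in zip(ci, freqs))
    return num / den


class TestConservationVector:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.0),  # entropy maximum
            ([1, 0, 0, 0], 100.0),  # invariant position
            ([0.5, 0.5, 0, 0], 50.0),  # (100/ln4)(ln4 - ln2)
        ],
    )
    def test_closed_form_values(self, row, expected):
        ci = pf.conservation_vector(np.array([row] * 4))
        assert ci == pytest.approx([expected] * 4, abs=1e-9)

    def test_range_and_validation(self):
        with pytest.raises(InputError):
            pf.conservation_vector(np.array([[0.5, 0.5, 0.5, 0.5]] * 4))


class TestSimilarity:
    def test_consensus_scores_one(self, toy_matrix):
        assert pf.matrix_similarity(toy_matrix, toy_matrix.consensus) == pytest.approx(1.0)
        assert pf.core_similarity(toy_matrix, toy_matrix.consensus) == pytest.approx(1.0)

    def test_uniform_matrix_scores_zero(self):
        m = make_matrix([[0.25] * 4] * 5, id="U_01")
        assert pf.matrix_similarity(m, "ACGTA") == 0.0

    def test_hand_oracle_value(self):
        rows = [[0.8, 0.2, 0, 0], [0, 0, 1, 0], [0.25] * 4, [0.6, 0.2, 0.1, 0.1]]
        m = make_matrix(rows, id="H_01")
        window = "CGAT"
        assert pf.matrix_similarity(m, window) == pytest.approx(
            _score_oracle(rows, window), abs=1e-12
        )

    def test_core_restriction_property(self, toy_matrix):
        # mismatch outside the core leaves core_sim at 1 but lowers mat_sim
        assert toy_matrix.core_start == 1
        w = list(toy_matrix.consensus)
        w[0] = "ACGT"[(("ACGT".index(w[0])) + 1) % 4]
        w = "".join(w)
        assert pf.core_similarity(toy_matrix, w) == pytest.approx(1.0)
        assert pf.matrix_similarity(toy_matrix, w) < 1.0

    def test_core_similarity_hand_oracle(self, toy_matrix):
        rows = toy_matrix.freqs[1:5]  # the core positions
        window = "ATGCTA"
        assert pf.core_similarity(toy_matrix, window) == pytest.approx(
            _score_oracle(rows.tolist(), window[1:5]), abs=1e-12
        )

    def test_leftmost_core_on_ties(self):
        m = make_matrix([[1, 0, 0, 0]] * 6, id="T_01")
        assert m.core_start == 0

    def test_n_bases_contribute_zero(self, toy_matrix):
        w = "N" + toy_matrix.consensus[1:]
        full = pf.matrix_similarity(toy_matrix, toy_matrix.consensus)
        assert pf.matrix_similarity(toy_matrix, w) < full

    def test_length_mismatch_is_error(self, toy_matrix):
        with pytest.raises(InputError):
            pf.matrix_similarity(toy_matrix, "ACGT")

    @given(st.integers(0, 2**31 - 1))
    def test_similarities_bounded(self, seed):
        rng = np.random.default_rng(seed)
        freqs = rng.dirichlet(np.ones(4), size=6)
        m = make_matrix(freqs, id="R_01")
        w = "".join(rng.choice(list("ACGTN"), size=6))
        s = pf.matrix_similarity(m, w)
        c = pf.core_similarity(m, w)
        assert 0.0 <= s <= 1.0 + 1e-12 and 0.0 <= c <= 1.0 + 1e-12


def brute_force_pvalue(matrix, bg=(0.25,) * 4, thresholds=None):
    """Exhaustive 4^L enumeration oracle (vectorized, independent formula)."""
    ct, mt = thresholds or (matrix.core_threshold, matrix.matrix_threshold)
    L = matrix.length
    f = matrix.freqs
    ln4 = math.log(4.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log(f), 0.0)
    ci = np.clip((100.0 / ln4) * (ln4 + plogp.sum(axis=1)), 0, 100)
    W = ci[:, None] * f
    den = (ci * f.max(axis=1)).sum()
    a, b = matrix.core_start, matrix.core_start + matrix.core_len
    den_c = (ci[a:b] * f[a:b].max(axis=1)).sum()
    wins = np.indices((4,) * L).reshape(L, -1).T  # all 4^L windows
    mat = W[np.arange(L), wins].sum(axis=1) / den
    core = W[np.arange(a, b), wins[:, a:b]].sum(axis=1) / den_c
    probs = np.prod(np.asarray(bg)[wins], axis=1)
    sel = (mat >= mt - SCORE_TOL) & (core >= ct - SCORE_TOL)
    return float(probs[sel].sum())


class TestSiteMatchPvalue:
    def test_zero_thresholds_pass_everything(self, toy_matrix):
        assert pf.site_match_pvalue(toy_matrix, thresholds=(0, 0)) == 1.0

    def test_unreachable_matrix_threshold(self, toy_matrix):
        assert pf.site_match_pvalue(toy_matrix, thresholds=(0, 1.1)) == 0.0

    def test_small_matrix_equals_exhaustive_enumeration(self):
        m = make_matrix(
            [[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1],
             [0.25] * 4, [0.1, 0.1, 0.1, 0.7]],
            id="P_01",
        )
        dp = pf.site_match_pvalue(m, thresholds=(0.75, 0.85))
        assert dp == pytest.approx(brute_force_pvalue(m, thresholds=(0.75, 0.85)),
                                   abs=1e-14)

    @pytest.mark.parametrize("bg", [(0.25,) * 4, (0.3, 0.2, 0.2, 0.3)])
    def test_library_matrices_match_enumeration(self, library, bg):
        for m in list(library)[:6]:
            dp = pf.site_match_pvalue(m, background=bg)
            bf = brute_force_pvalue(m, bg=bg)
            assert dp == pytest.approx(bf, abs=1e-14), m.id

    def test_invalid_background(self, toy_matrix):
        with pytest.raises(InputError):
            pf.site_match_pvalue(toy_matrix, background=(0.5, 0.5, 0.5, 0.5))


class TestScanPromoter:
    @pytest.fixture
    def planted(self):
        m = make_matrix(
            [[0.03 if i != b else 0.91 for i in range(4)]
             for b in [1, 1, 2, 2, 3, 1, 2, 1]],
            id="CCGGTCGC_01".replace("CCGGTCGC", "PLNT"),
        )
        seq = list("A" * 1200)
        pos = -500 - (-1000)
        seq[pos : pos + 8] = m.consensus
        return m, _promoter("".join(seq))

    def test_planted_consensus_single_hit(self, planted):
        m, prom = planted
        hits = pf.scan_promoter(m, prom, thresholds=(0.95, 0.95), evalue_cutoff=None)
        assert [(h.start_rel, h.strand) for h in hits] == [(-500, "+")]
        assert hits[0].mat_sim == pytest.approx(1.0)

    def test_reverse_planted_site_found_on_minus_strand(self, planted):
        m, prom = planted
        seq = list("A" * 1200)
        seq[500 : 500 + 8] = pf.reverse_complement(m.consensus)
        prom_rc = _promoter("".join(seq))
        hits = pf.scan_promoter(m, prom_rc, thresholds=(0.95, 0.95), evalue_cutoff=None)
        assert [(h.start_rel, h.strand) for h in hits] == [(-500, "-")]
        # cross-check: scanning the reverse-complemented promoter finds the
        # site on the plus strand at the mirrored position
        flipped = _promoter(pf.reverse_complement(prom_rc.seq))
        mirror = pf.scan_promoter(m, flipped, thresholds=(0.95, 0.95), evalue_cutoff=None)
        assert [(h.start_rel, h.strand) for h in mirror] == [
            (-1000 + (1200 - 8 - 500), "+")
        ]

    def test_open_thresholds_count_all_windows(self, planted):
        m, prom = planted
        hits = pf.scan_promoter(m, prom, thresholds=(0, 0), evalue_cutoff=None)
        assert len(hits) == 2 * (1200 - 8 + 1)

    def test_expected_count_evalue_reported(self, planted):
        m, prom = planted
        p = pf.site_match_pvalue(m, thresholds=(0.95, 0.95))
        hits = pf.scan_promoter(m, prom, thresholds=(0.95, 0.95), evalue_cutoff=None)
        assert hits[0].evalue == pytest.approx(p * 2 * (1200 - 8 + 1))

    def test_promoter_scale_cutoff_is_stricter(self, planted):
        # a 1,200-nt window cannot yield expected chance-hit counts below
        # ~0.04 for an 8-nt matrix, so the promoter-scale cutoff at 1e-3
        # discards the matrix while the per-site scale retains it
        m, prom = planted
        site = pf.scan_promoter(m, prom, thresholds=(0.95, 0.95),
                                evalue_cutoff=1e-3, cutoff_scale="site")
        promoter = pf.scan_promoter(m, prom, thresholds=(0.95, 0.95),
                                    evalue_cutoff=1e-3, cutoff_scale="promoter")
        assert site and not promoter

    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        m = make_matrix(
            [[0.05 if i != b else 0.85 for i in range(4)]
             for b in rng.integers(0, 4, size=6)],
            id="S_01",
        )
        fwd = pf.scan_promoter(m, _promoter(seq, ws=-60), thresholds=(0.6, 0.7),
                               evalue_cutoff=None)
        rev = pf.scan_promoter(m, _promoter(pf.reverse_complement(seq), ws=-60),
                               thresholds=(0.6, 0.7), evalue_cutoff=None)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (-60 + (80 - 6 - (h.start_rel + 60)), flip[h.strand],
             round(h.mat_sim, 9), round(h.core_sim, 9))
            for h in rev
        }
        assert {
            (h.start_rel, h.strand, round(h.mat_sim, 9), round(h.core_sim, 9))
            for h in fwd
        } == mirrored

    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        m = make_matrix(rng.dirichlet(np.ones(4) * 0.4, size=6), id="M_01")
        prom = _promoter(seq, ws=-100)
        counts = [
            len(pf.scan_promoter(m, prom, thresholds=(c, t), evalue_cutoff=None))
            for c, t in [(0.2, 0.3), (0.4, 0.5), (0.6, 0.7), (0.8, 0.9)]
        ]
        assert counts == sorted(counts, reverse=True)


class TestOccurrenceMatrix:
    def _prom(self, gid, species="Os", role="ortholog"):
        return pf.PromoterSequence(
            gene_id=gid, species=species, lineage="monocot", role=role,
            cog_id="C1", seq="A" * 20, window_start_rel=-10, window_end_rel=10,
        )

    def _hit(self, gene, cls, mid=None, start=-5):
        return pf.MotifHit(
            matrix_id=mid or f"{cls}_01", class_label=cls, gene_id=gene,
            start_rel=start, strand="+", core_sim=1.0, mat_sim=1.0, evalue=1e-4,
        )

    def test_multi_copy_binarizes_to_one(self):
        hits = [self._hit("g1", "GBOX", start=s) for s in (-5, -2, 3)]
        occ = pf.build_occurrence_matrix(hits, [self._prom("g1")], {"GBOX_01": "GBOX"})
        assert occ.data.loc["GBOX", "g1"] == 1

    def test_no_hits_yields_zero_classes(self):
        occ = pf.build_occurrence_matrix([], [self._prom("g1")], {"GBOX_01": "GBOX"})
        assert occ.classes == []
        assert occ.dropped_classes == ("GBOX",)

    def test_class_collapsing_across_matrices(self):
        hits = [
            self._hit("g1", "GBOX", mid="GBOX_01"),
            self._hit("g2", "GBOX", mid="GBOX_02"),
        ]
        occ = pf.build_occurrence_matrix(
            hits, [self._prom("g1"), self._prom("g2")],
            {"GBOX_01": "GBOX", "GBOX_02": "GBOX"},
        )
        assert occ.data.shape == (1, 2)
        assert occ.data.loc["GBOX"].tolist() == [1, 1]

    def test_unknown_class_is_error(self):
        with pytest.raises(InputError, match="unknown class"):
            pf.build_occurrence_matrix(
                [self._hit("g1", "WEIRD")], [self._prom("g1")], {"GBOX_01": "GBOX"}
            )

    def test_tsv_round_trip(self, analysis):
        occ = analysis["occ"]
        back = pf.OccurrenceMatrix.from_tsv(occ.to_tsv())
        assert back.data.equals(occ.data)
        assert list(back.gene_meta["species"]) == list(occ.gene_meta["species"])
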