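"""Generator determinism, planting mechanics and manifest consistency."""

import numpy as np
import pytest
from scipy import stats as sps

import phylofoot as pf
from phylofoot.errors import InputError, PhylofootError
from phylofoot.synthetic_data import (
    LIBRARY_THRESHOLDS,
    SingletonSpec,
    _sample_site,
    scrub_background,
)


class TestBackground:
    def test_deterministic_given_seed(self):
        a = pf.generate_background(1200, seed=7)
        b = pf.generate_background(1200, seed=7)
        assert a == b and len(a) == 1200

    def test_degenerate_composition_gives_poly_a(self):
        assert pf.generate_background(50, (1, 0, 0, 0), seed=0) == "A" * 50

    def test_composition_recovered_within_three_standard_errors(self):
        n = 100_000
        comp = (0.3, 0.2, 0.2, 0.3)
        seq = pf.generate_background(n, comp, seed=11)
        for base, p in zip("ACGT", comp):
            se = (p * (1 - p) / n) ** 0.5
            assert abs(seq.count(base) / n - p) < 3 * se

    def test_invalid_composition_is_error(self):
        with pytest.raises(InputError):
            pf.generate_background(10, (0.5, 0.5, 0.5, 0.5))

    def test_order1_chain(self):
        trans = np.array(
            [[0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0]], float
        )
        seq = pf.generate_background(12, (1, 0, 0, 0), seed=1, order1=trans)
        assert seq == "ACGT" * 3


class TestPlanting:
    def _module(self, **kw):
        kw.setdefault("classes", ("GBOX", "MYBS"))
        kw.setdefault("strands", ("+", "-"))
        kw.setdefault("gaps", (40,))
        return pf.ModuleSpec(**kw)

    def test_zero_jitter_realizes_exact_gaps(self, library):
        rng = np.random.default_rng(0)
        seq = pf.generate_background(1200, seed=0)
        _, recs = pf.plant_module(seq, self._module(), rng, library)
        assert recs[1].start_rel - recs[0].start_rel == 40

    def test_minus_strand_site_written_as_reverse_complement(self, library):
        rng = np.random.default_rng(1)
        seq = pf.generate_background(1200, seed=1)
        out, recs = pf.plant_module(
            seq, self._module(), rng, library, site_mode="consensus"
        )
        site = recs[1]
        assert site.strand == "-"
        i = site.start_rel + 1000
        planted = out[i : i + len(site.site_seq)]
        assert planted == pf.reverse_complement(site.site_seq)

    def test_jitter_mean_within_clt_bound(self, library):
        rng = np.random.default_rng(2)
        seq = pf.generate_background(1200, seed=2)
        gaps = []
        spec = self._module(jitter_sd=3.0)
        for _ in range(1000):
            _, recs = pf.plant_module(seq, spec, rng, library)
            gaps.append(recs[1].start_rel - recs[0].start_rel)
        se = 3.0 / np.sqrt(len(gaps))
        assert abs(np.mean(gaps) - 40) < 3 * se

    def test_overlap_rejection_reuses_occupied_list(self, library):
        rng = np.random.default_rng(3)
        seq = pf.generate_background(1200, seed=3)
        occupied: list[tuple[int, int]] = []
        spec = self._module(anchor_window=(-500, -500))  # single placement
        pf.plant_module(seq, spec, rng, library, occupied=occupied)
        with pytest.raises(PhylofootError, match="could not place"):
            pf.plant_module(seq, spec, rng, library, occupied=occupied, max_tries=20)

    def test_threshold_mode_sites_pass_thresholds(self, library):
        rng = np.random.default_rng(4)
        m = library["GBOX_01"]
        for _ in range(25):
            s = _sample_site(m, rng, "threshold", (0.9, 0.95))
            assert pf.core_similarity(m, s) >= 0.9
            assert pf.matrix_similarity(m, s) >= 0.95

    def test_module_spec_validation(self):
        with pytest.raises(InputError):
            pf.ModuleSpec(classes=("A",), strands=("+",), gaps=())
        with pytest.raises(InputError):
            pf.ModuleSpec(classes=("A", "B"), strands=("+",), gaps=(40,))
        with pytest.raises(InputError):
            pf.ModuleSpec(classes=("A", "B"), strands=("+", "x"), gaps=(40,))


class TestDesignValidation:
    def test_class_planted_twice_is_contradictory(self, library):
        design = pf.example_design(seed=0, n_cogs=1)
        cog = design.cogs[0]
        cog.singletons.append(SingletonSpec(cog.singletons[0].class_label, "IV", "Os"))
        with pytest.raises(InputError, match="twice"):
            design.validate()

    def test_unknown_class_is_error(self, library):
        design = pf.example_design(seed=0, n_cogs=1)
        design.cogs[0].singletons.append(SingletonSpec("NOPE", "II"))
        with pytest.raises(InputError, match="NOPE"):
            design.validate()

    def test_paralog_categories_need_paralogs(self):
        design = pf.example_design(seed=0, n_cogs=1)
        design.cogs[0].n_paralogs = 0
        with pytest.raises(InputError, match="paralog"):
            design.validate()


class TestSimulatedDataset:
    def test_same_seed_gives_identical_fasta(self):
        d1 = pf.simulate_cog_dataset(pf.example_design(seed=31, n_cogs=1))
        d2 = pf.simulate_cog_dataset(pf.example_design(seed=31, n_cogs=1))
        assert pf.promoters_to_fasta(d1.promoters) == pf.promoters_to_fasta(d2.promoters)

    def test_different_seed_differs(self):
        d1 = pf.simulate_cog_dataset(pf.example_design(seed=31, n_cogs=1))
        d2 = pf.simulate_cog_dataset(pf.example_design(seed=32, n_cogs=1))
        assert pf.promoters_to_fasta(d1.promoters) != pf.promoters_to_fasta(d2.promoters)

    def test_manifest_consistent_with_fasta(self, dataset):
        pf.verify_manifest(dataset.promoters, dataset.manifest)

    def test_category_patterns_realized(self, dataset):
        by_gene = {p.gene_id: p for p in dataset.promoters}
        for cog_id, cats in dataset.manifest.expected_categories.items():
            for cls, (cat, detail) in cats.items():
                carriers = {
                    s.gene_id
                    for s in dataset.manifest.sites
                    if s.cog_id == cog_id and s.class_label == cls
                }
                roles = {by_gene[g].role for g in carriers}
                if cat in ("II", "III", "IV"):
                    assert roles == {"ortholog"}
                if cat == "III":
                    assert {by_gene[g].lineage for g in carriers} == {detail}
                if cat == "IV":
                    assert {by_gene[g].species for g in carriers} == {detail}
                if cat == "P":
                    assert roles == {"paralog"}
                if cat == "I":
                    assert "ortholog" in roles and "paralog" in roles

    def test_cog_table_matches_promoters(self, dataset):
        assert set(dataset.cog_table["gene_id"]) == {
            p.gene_id for p in dataset.promoters
        }

    def test_manifest_json_round_trip(self, dataset):
        back = pf.TruthManifest.from_json(dataset.manifest.to_json())
        assert back.expected_module_keys == dataset.manifest.expected_module_keys
        assert back.expected_categories == dataset.manifest.expected_categories
        assert back.sites == dataset.manifest.sites


def test_scrubbed_background_has_no_library_matches(library):
    rng = np.random.default_rng(9)
    seq = pf.generate_background(1200, seed=9)
    clean = scrub_background(seq, library, rng)
    prom = pf.PromoterSequence(
        gene_id="g", species="", lineage="", role="unknown", cog_id=None,
        seq=clean, window_start_rel=-1000, window_end_rel=200,
    )
    hits = pf.scan_promoters(library, [prom], background=(0.25,) * 4,
                             evalue_cutoff=None)
    assert hits == []


def test_unscrubbed_false_class_rate_within_poisson_bounds(library):
    """Stringent scan of pure background: the count of chance TFBS-class
    presences sits inside the 99% Poisson band implied by the summed
    per-matrix expected hit counts."""
    thresholds = (0.9, 0.95)
    n_prom, length = 4, 1200
    lam = 0.0
    for m in library:
        p = pf.site_match_pvalue(m, thresholds=thresholds)
        lam += p * 2 * (length - m.length + 1)
    lam *= n_prom
    proms = [
        pf.PromoterSequence(
            gene_id=f"g{i}", species="", lineage="", role="unknown", cog_id=None,
            seq=pf.generate_background(length, seed=100 + i),
            window_start_rel=-1000, window_end_rel=200,
        )
        for i in range(n_prom)
    ]
    hits = pf.scan_promoters(library, proms, thresholds=thresholds,
                             background=(0.25,) * 4, evalue_cutoff=None)
    observed = len({(h.gene_id, h.class_label) for h in hits})
    lo, hi = sps.poisson.ppf([0.005, 0.995], lam)
    assert lo <= observed <= hi


def test_genome_embedding_round_trips_extraction(dataset):
    genome, tss = pf.embed_in_genome(dataset.promoters, seed=5)
    proms = pf.extract_promoters(
        genome, tss, dataset.cog_table, window=dataset.manifest.window
    )
    by_id = {p.gene_id: p for p in proms}
    for orig in dataset.promoters:
        assert by_id[orig.gene_id].seq == orig.seq
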