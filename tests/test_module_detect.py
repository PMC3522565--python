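"""Core-module detection: chain enumeration, emission rules, oracle parity."""

import itertools

import numpy as np
import pytest

import phylofoot as pf
from phylofoot.errors import GuardError, InputError
from phylofoot.module_detect import Site, sites_from_hits


def S(start, cls, strand="+"):
    return Site(start_rel=start, class_label=cls, strand=strand)


def keys(chains_or_modules):
    return {c.key for c in chains_or_modules}


class TestEnumerateSiteChains:
    BASE = [S(-900, "A"), S(-850, "B"), S(-700, "C", "-")]

    def test_example_with_wide_gap(self):
        chains = pf.enumerate_site_chains(
            self.BASE, k_range=(2, 3), max_gap=200, max_span=400
        )
        assert keys(chains) == {
            (("A", "+"), ("B", "+")),
            (("B", "+"), ("C", "-")),
            (("A", "+"), ("C", "-")),  # gap 200 <= 200
            (("A", "+"), ("B", "+"), ("C", "-")),
        }

    def test_example_with_narrow_gap(self):
        chains = pf.enumerate_site_chains(
            self.BASE, k_range=(2, 3), max_gap=100, max_span=400
        )
        assert keys(chains) == {(("A", "+"), ("B", "+"))}

    def test_random_instances_match_combinations_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            sites = sites_from_hits(
                S(int(p), c, s)
                for p, c, s in zip(
                    rng.choice(np.arange(-950, 150), size=10, replace=False),
                    rng.choice(list("ABCD"), size=10),
                    rng.choice(["+", "-"], size=10),
                )
            )
            got = pf.enumerate_site_chains(sites, (2, 4), max_gap=120, max_span=300)
            want = []
            for k in (2, 3, 4):
                for combo in itertools.combinations(sites, k):
                    starts = [x.start_rel for x in combo]
                    gaps = [b - a for a, b in zip(starts, starts[1:])]
                    if any(g < 1 for g in gaps):
                        continue
                    if max(gaps) <= 120 and starts[-1] - starts[0] <= 300:
                        want.append(combo)
            assert {c.sites for c in got} == set(want)

    def test_strictly_increasing_invariant(self):
        for c in pf.enumerate_site_chains(self.BASE, (2, 3), 200, 400):
            starts = [s.start_rel for s in c.sites]
            assert starts == sorted(starts) and len(set(starts)) == len(starts)


def planted_hits(anchor_by_gene, gaps=(40,), classes=("GBOX", "MYBS"),
                 strands=("+", "+")):
    out = {}
    for gene, anchor in anchor_by_gene.items():
        starts = [anchor]
        for g in gaps:
            starts.append(starts[-1] + g)
        out[gene] = [S(p, c, s) for p, c, s in zip(starts, classes, strands)]
    return out


class TestDetectCoreModules:
    def test_planted_two_class_module_detected(self):
        cog = planted_hits({"o1": -600, "o2": -500, "o3": -450})
        mods = pf.detect_core_modules(cog, {"p1": []}, cog_id="C1")
        assert len(mods) == 1
        m = mods[0]
        assert m.class_sequence == ("GBOX", "MYBS")
        assert m.strand_pattern == ("+", "+")
        assert m.spacing == (40,)
        assert set(m.instances) == {"o1", "o2", "o3"}
        assert m.anchor_positions == {"o1": -600, "o2": -500, "o3": -450}

    def test_chain_in_paralog_suppresses_module(self):
        cog = planted_hits({"o1": -600, "o2": -500, "o3": -450})
        par = planted_hits({"p1": -300})
        assert pf.detect_core_modules(cog, par, cog_id="C1") == []

    def test_paralog_chain_outside_tolerance_does_not_suppress(self):
        cog = planted_hits({"o1": -600, "o2": -500})
        par = planted_hits({"p1": -300}, gaps=(90,))
        assert len(pf.detect_core_modules(cog, par, gap_tolerance=10)) == 1

    def test_maximality_suppresses_contiguous_subchains(self):
        cog = planted_hits(
            {"o1": -600, "o2": -500}, gaps=(40, 40),
            classes=("A", "B", "C"), strands=("+", "+", "+"),
        )
        maximal = pf.detect_core_modules(cog, {})
        got = keys(maximal)
        assert (("A", "+"), ("B", "+"), ("C", "+")) in got
        # contiguous sub-chains are suppressed; the non-contiguous A-C
        # arrangement (its own conserved spacing) may still be emitted
        assert (("A", "+"), ("B", "+")) not in got
        assert (("B", "+"), ("C", "+")) not in got
        full = pf.detect_core_modules(cog, {}, maximal_only=False)
        assert (("A", "+"), ("B", "+")) in keys(full)
        assert (("B", "+"), ("C", "+")) in keys(full)

    def test_spacing_conservation_enforced(self):
        cog = planted_hits({"o1": -600, "o2": -500})
        cog["o2"] = [S(-500, "GBOX"), S(-445, "MYBS")]  # gap 55 vs 40
        assert pf.detect_core_modules(cog, {}, gap_tolerance=10) == []
        assert len(pf.detect_core_modules(cog, {}, gap_tolerance=15)) == 1

    def test_needs_two_orthologs(self):
        with pytest.raises(InputError):
            pf.detect_core_modules({"o1": []}, {})

    def test_empty_hits_warns(self):
        with pytest.warns(UserWarning):
            assert pf.detect_core_modules({"o1": [], "o2": []}, {}) == []

    def test_strand_flip_mirrors_modules(self):
        cog = planted_hits(
            {"o1": -600, "o2": -500}, gaps=(30, 50),
            classes=("A", "B", "C"), strands=("+", "-", "+"),
        )
        mods = pf.detect_core_modules(cog, {})

        def flip(sites):
            return [
                S(-1000 + 199 - s.start_rel, s.class_label,
                  "-" if s.strand == "+" else "+")
                for s in sites
            ]

        flipped = {g: flip(h) for g, h in cog.items()}
        mirror = pf.detect_core_modules(flipped, {})
        want = {
            tuple((c, "-" if s == "+" else "+") for c, s in m.key[::-1])
            for m in mods
        }
        assert keys(mirror) == want


class TestBruteForceOracle:
    def _random_instance(self, rng):
        def gene_sites(n):
            pos = rng.choice(np.arange(-950, 150, 5), size=n, replace=False)
            return [
                S(int(p), str(c), str(s))
                for p, c, s in zip(pos, rng.choice(list("ABCDE"), size=n),
                                   rng.choice(["+", "-"], size=n))
            ]

        cog = {f"o{i}": gene_sites(rng.integers(3, 9)) for i in range(3)}
        # half the instances share a planted arrangement across orthologs
        if rng.random() < 0.5:
            anchors = rng.integers(-800, -200, size=3)
            for i, a in enumerate(anchors):
                cog[f"o{i}"] += [S(int(a), "Z", "+"), S(int(a) + 40, "Y", "-")]
        par = {f"p{i}": gene_sites(rng.integers(0, 7)) for i in range(2)}
        return cog, par

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            cog, par = self._random_instance(rng)
            fast = pf.detect_core_modules(cog, par, max_gap=120, max_span=350)
            slow = pf.brute_force_core_modules(cog, par, max_gap=120, max_span=350)
            assert [m.to_dict() for m in fast] == [m.to_dict() for m in slow]

    def test_guard_on_site_count(self):
        sites = [S(-900 + 7 * i, "A") for i in range(26)]
        with pytest.raises(GuardError):
            pf.brute_force_core_modules({"o1": sites, "o2": sites}, {})

    def test_no_paralogs_means_vacuous_absence(self):
        cog = planted_hits({"o1": -600, "o2": -500})
        assert len(pf.brute_force_core_modules(cog, None)) == 1


def test_monotonicity_in_gap_parameters():
    """Without paralogs and maximality, enlarging max_gap or gap_tolerance
    never removes a detected signature."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        cog = {
            f"o{i}": [
                S(int(p), str(c), "+")
                for p, c in zip(
                    sorted(rng.choice(np.arange(-900, 100, 10), size=6, replace=False)),
                    rng.choice(list("ABC"), size=6),
                )
            ]
            for i in range(2)
        }
        base = keys(pf.detect_core_modules(cog, {}, max_gap=80, gap_tolerance=5,
                                           maximal_only=False))
        wider_gap = keys(pf.detect_core_modules(cog, {}, max_gap=140, gap_tolerance=5,
                                                maximal_only=False))
        wider_tol = keys(pf.detect_core_modules(cog, {}, max_gap=80, gap_tolerance=30,
                                                maximal_only=False))
        assert base <= wider_gap
        assert base <= wider_tol


def test_detected_modules_match_manifest(dataset, analysis):
    recovered, expected = pf.score_module_recovery(
        dataset.manifest, analysis["modules"]
    )
    assert expected > 0 and recovered == expected
    # every emitted signature is built from classes of a planted module
    planted_classes = {
        frozenset(c for c, _ in key)
        for keys_ in dataset.manifest.expected_module_keys.values()
        for key in keys_
    }
    for mods in analysis["modules"].values():
        for m in mods:
            assert any(set(m.class_sequence) <= pc for pc in planted_classes)


def test_render_alignment_mentions_sites(analysis):
    mods = [m for mm in analysis["modules"].values() for m in mm]
    text = pf.render_module_alignment(mods[0])
    for cls in mods[0].class_sequence:
        assert cls in text
    for gene in mods[0].instances:
        assert gene in text
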