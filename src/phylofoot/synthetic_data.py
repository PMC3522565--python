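"""Synthetic promoter sets with planted sites and a ground-truth manifest.

The generator emulates the statistical structure the comparative analysis
assumes: groups of 1,200-nt promoter windows (three ortholog species, two
of them forming a monocot lineage, plus non-orthologous paralogs), with

* spatially conserved core modules — 2-4 binding-site classes planted
  with identical order and strand and near-identical start-to-start
  spacing in every ortholog, absent from paralogs;
* singleton elements planted in shared (I), ortholog-specific (II),
  lineage-specific (III), species-specific (IV) or paralog-specific (P)
  presence patterns.

Planted truth is exact by construction: background sequence is scrubbed
of chance matrix matches at the scan thresholds before planting, planted
site sequences are drawn from the matrix distribution conditional on
exceeding those thresholds (consensus and unconditional sampling are
switches), and every finished promoter is verified against the manifest —
a residual spurious or shifted match triggers a bounded re-draw.  The
manifest therefore lists exactly the sites a scan at the design
thresholds recovers, which is what makes planted-recovery rates
meaningful quantities.

The bundled default matrix library is synthetic: class names follow
familiar plant cis-element family mnemonics, but the consensus sequences
are generated (pairwise-dissimilar by construction) and stand in for
proprietary plant PWM collections.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, PhylofootError
from .motif_scan import (
    BASES,
    MotifMatrix,
    core_similarity,
    matrix_similarity,
    scan_promoter,
    site_match_pvalue,
)
from .promoter_io import MatrixLibrary, PromoterSequence, TSSRecord, reverse_complement

DEFAULT_SPECIES = {"Os": "monocot", "Sb": "monocot", "At": "dicot"}

#: Default per-matrix thresholds of the synthetic library.  The matrix
#: threshold 0.88 admits single-mismatch windows for 8-nt matrices only,
#: so sampled sites exercise score variation while shorter matrices stay
#: consensus-strict.
LIBRARY_THRESHOLDS = (0.75, 0.88)

_CLASS_NAMES = [
    "GBOX", "ABRE", "MYBS", "MYBL", "AHBP", "DOFF", "GTBX", "MADS", "GARP",
    "MYCL", "NCS1", "CAAT", "IBOX", "OPAQ", "AGP1", "CE1F", "EINL", "LREM",
    "ERSE", "BRRE", "LEGB", "TCPF", "CGCG", "PALA", "CNAC", "SALT",
]
#: Classes represented by a second, weaker matrix (class-level grouping).
_DOUBLED_CLASSES = ("GBOX", "MYBS", "CAAT")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _consensi_compatible(new: str, accepted: Sequence[str]) -> bool:
    """Reject a candidate consensus that another consensus (or its own
    reverse complement, or itself at a shift) could ride along with.

    Every sliding alignment with an overlap of at least 4 bases must carry
    at least 2 mismatches, on both strands.  Bases hanging outside the
    overlap are random background when a site is planted, so the overlap
    itself must defeat the most permissive scan threshold (one mismatch
    for 8-nt matrices)."""
    for is_self, other in [(False, a) for a in accepted] + [(True, new)]:
        for orient, b in (("+", other), ("-", reverse_complement(other))):
            for shift in range(-(len(b) - 4), len(new) - 3):
                if is_self and orient == "+" and shift == 0:
                    continue  # identity alignment of the candidate with itself
                a_lo, a_hi = max(0, shift), min(len(new), shift + len(b))
                seg_a = new[a_lo:a_hi]
                seg_b = b[a_lo - shift : a_hi - shift]
                if _hamming(seg_a, seg_b) < 2:
                    return False
    return True


def _make_freqs(consensus: str, strength: float) -> np.ndarray:
    off = (1.0 - strength) / 3.0
    freqs = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        freqs[i, BASES.index(b)] = strength
    return freqs


def default_matrix_library(strength: float = 0.85) -> MatrixLibrary:
    """The synthetic plant-style PWM library (26 classes, 29 matrices).

    Consensus sequences (6-8 nt) are generated from a fixed internal seed
    under a pairwise-dissimilarity constraint, so no consensus can be
    mistaken for a window of another at the library thresholds.  Three
    classes carry a second, slightly weaker matrix to exercise class-level
    grouping.
    """
    rng = np.random.default_rng(799183)
    lengths = itertools.cycle((8, 6, 7))
    accepted: list[str] = []
    matrices: list[MotifMatrix] = []
    ct, mt = LIBRARY_THRESHOLDS
    for name in _CLASS_NAMES:
        L = next(lengths)
        for _ in range(10000):
            cand = "".join(rng.choice(list(BASES), size=L))
            if _consensi_compatible(cand, accepted):
                accepted.append(cand)
                break
        else:  # pragma: no cover - generation is deterministic and succeeds
            raise PhylofootError("could not generate a dissimilar consensus")
        matrices.append(
            MotifMatrix(
                id=f"{name}_01",
                class_label=name,
                freqs=_make_freqs(accepted[-1], strength),
                core_threshold=ct,
                matrix_threshold=mt,
            )
        )
        if name in _DOUBLED_CLASSES:
            matrices.append(
                MotifMatrix(
                    id=f"{name}_02",
                    class_label=name,
                    freqs=_make_freqs(accepted[-1], max(0.6, strength - 0.05)),
                    core_threshold=ct,
                    matrix_threshold=mt,
                )
            )
    return MatrixLibrary(tuple(matrices))


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass
class ModuleSpec:
    """A core module to plant in every ortholog of a COG.

    ``gaps`` are nominal start-to-start distances between consecutive
    sites; each member's realized gaps add rounded Gaussian jitter with
    standard deviation ``jitter_sd``.  The anchor (start of the first
    site) is drawn uniformly within ``anchor_window`` per member.
    """

    classes: tuple[str, ...]
    strands: tuple[str, ...]
    gaps: tuple[int, ...]
    jitter_sd: float = 0.0
    anchor_window: tuple[int, int] = (-700, -300)

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.strands = tuple(self.strands)
        self.gaps = tuple(int(g) for g in self.gaps)
        if not 2 <= len(self.classes) <= 4:
            raise InputError("a module combines 2-4 TFBS classes")
        if len(self.strands) != len(self.classes) or any(
            s not in "+-" for s in self.strands
        ):
            raise InputError("strand pattern must match the class count")
        if len(self.gaps) != len(self.classes) - 1:
            raise InputError("need one gap per consecutive site pair")
        if self.jitter_sd < 0:
            raise InputError("jitter_sd must be >= 0")

    @property
    def key(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.classes, self.strands))


@dataclass
class SingletonSpec:
    """A single TFBS class planted in a category presence pattern."""

    class_label: str
    category: str  # I, II, III, IV, P
    detail: str = ""  # lineage for III, species for IV
    position_window: tuple[int, int] = (-950, -20)

    def __post_init__(self) -> None:
        if self.category not in ("I", "II", "III", "IV", "P"):
            raise InputError(f"unknown category {self.category!r}")
        if self.category in ("III", "IV") and not self.detail:
            raise InputError(f"category {self.category} needs a detail label")


@dataclass
class COGSpec:
    cog_id: str
    modules: list[ModuleSpec] = field(default_factory=list)
    singletons: list[SingletonSpec] = field(default_factory=list)
    n_paralogs: int = 2
    group_label: str = ""


@dataclass
class SimulationDesign:
    """Full description of one synthetic promoter dataset."""

    cogs: list[COGSpec]
    species: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SPECIES))
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    order1: np.ndarray | None = None
    library: MatrixLibrary | None = None
    seed: int = 0
    window: tuple[int, int] = (-1000, 200)
    site_mode: str = "threshold"  # threshold | sample | consensus
    scan_thresholds: tuple[float, float] | None = None  # None: per-matrix
    scrub: bool = True
    max_retries: int = 30

    def resolved_library(self) -> MatrixLibrary:
        return self.library if self.library is not None else default_matrix_library()

    def validate(self) -> None:
        lib = self.resolved_library()
        classes = set(lib.classes)
        if self.site_mode not in ("threshold", "sample", "consensus"):
            raise InputError(f"unknown site_mode {self.site_mode!r}")
        lineages = set(self.species.values())
        for cog in self.cogs:
            used: dict[str, str] = {}
            for m in cog.modules:
                for c in m.classes:
                    if c not in classes:
                        raise InputError(f"COG {cog.cog_id}: unknown class {c!r}")
                    if c in used:
                        raise InputError(
                            f"COG {cog.cog_id}: class {c} planted twice "
                            f"({used[c]} and module)"
                        )
                    used[c] = "module"
            for s in cog.singletons:
                if s.class_label not in classes:
                    raise InputError(
                        f"COG {cog.cog_id}: unknown class {s.class_label!r}"
                    )
                if s.class_label in used:
                    raise InputError(
                        f"COG {cog.cog_id}: class {s.class_label} planted twice "
                        f"({used[s.class_label]} and {s.category})"
                    )
                used[s.class_label] = s.category
                if s.category == "III" and s.detail not in lineages:
                    raise InputError(
                        f"COG {cog.cog_id}: lineage {s.detail!r} not in design"
                    )
                if s.category == "IV" and s.detail not in self.species:
                    raise InputError(
                        f"COG {cog.cog_id}: species {s.detail!r} not in design"
                    )
                if s.category in ("I", "P") and cog.n_paralogs < 1:
                    raise InputError(
                        f"COG {cog.cog_id}: category {s.category} needs a paralog"
                    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    cog_id: str
    class_label: str
    matrix_id: str
    start_rel: int
    strand: str
    site_seq: str  # matrix-frame sequence (reverse-complemented on '-')
    origin: str  # "module:<index>" or "singleton:<category>"


@dataclass(eq=False)
class TruthManifest:
    """Machine-checkable record of everything that was planted."""

    sites: list[PlantedSite]
    expected_categories: dict[str, dict[str, tuple[str, str]]]
    expected_module_keys: dict[str, list[tuple[tuple[str, str], ...]]]
    seed: int
    window: tuple[int, int]

    def sites_for_gene(self, gene_id: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.gene_id == gene_id]

    def expected_classes(self, gene_id: str) -> set[str]:
        return {s.class_label for s in self.sites_for_gene(gene_id)}

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "window": list(self.window),
                "sites": [asdict(s) for s in self.sites],
                "expected_categories": {
                    cog: {c: list(v) for c, v in sorted(cats.items())}
                    for cog, cats in sorted(self.expected_categories.items())
                },
                "expected_module_keys": {
                    cog: [[list(pair) for pair in key] for key in keys]
                    for cog, keys in sorted(self.expected_module_keys.items())
                },
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)
        return cls(
            sites=[PlantedSite(**s) for s in raw["sites"]],
            expected_categories={
                cog: {c: tuple(v) for c, v in cats.items()}
                for cog, cats in raw["expected_categories"].items()
            },
            expected_module_keys={
                cog: [tuple(tuple(p) for p in key) for key in keys]
                for cog, keys in raw["expected_module_keys"].items()
            },
            seed=raw["seed"],
            window=tuple(raw["window"]),
        )


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def generate_background(
    length: int,
    composition: Sequence[float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    order1: np.ndarray | None = None,
) -> str:
    """Reproducible i.i.d. (or first-order Markov) background sequence."""
    comp = np.asarray(composition if composition is not None else [0.25] * 4, float)
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-6:
        raise InputError("composition must be 4 non-negative values summing to 1")
    comp = comp / comp.sum()
    if rng is None:
        rng = np.random.default_rng(seed)
    if order1 is None:
        codes = rng.choice(4, size=length, p=comp)
        return "".join(BASES[c] for c in codes)
    trans = np.asarray(order1, float)
    if trans.shape != (4, 4) or np.any(trans < 0) or np.any(
        np.abs(trans.sum(axis=1) - 1.0) > 1e-6
    ):
        raise InputError("order-1 model needs a 4x4 stochastic matrix")
    trans = trans / trans.sum(axis=1, keepdims=True)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.choice(4, p=comp)
    for i in range(1, length):
        out[i] = rng.choice(4, p=trans[out[i - 1]])
    return "".join(BASES[c] for c in out)


def _sample_site(
    matrix: MotifMatrix,
    rng: np.random.Generator,
    mode: str,
    thresholds: tuple[float, float],
) -> str:
    if mode == "consensus":
        return matrix.consensus
    ct, mt = thresholds
    for _ in range(2000):
        codes = [rng.choice(4, p=matrix.freqs[i]) for i in range(matrix.length)]
        s = "".join(BASES[c] for c in codes)
        if mode == "sample":
            return s
        if core_similarity(matrix, s) >= ct and matrix_similarity(matrix, s) >= mt:
            return s
    raise PhylofootError(
        f"matrix {matrix.id}: could not sample a site above thresholds "
        f"{thresholds} (matrix too weak for the requested stringency)"
    )


def plant_module(
    seq: str,
    module: ModuleSpec,
    rng: np.random.Generator,
    library: MatrixLibrary,
    window_start_rel: int = -1000,
    site_mode: str = "threshold",
    scan_thresholds: tuple[float, float] | None = None,
    occupied: list[tuple[int, int]] | None = None,
    gene_id: str = "",
    cog_id: str = "",
    origin: str = "module:0",
    max_tries: int = 100,
) -> tuple[str, list[PlantedSite]]:
    """Write one module instance into a background sequence.

    Gaps realize as ``spec gap + round(N(0, jitter_sd))``; minus-strand
    sites are written as reverse complements.  Placements overlapping
    previously planted sites (``occupied``, updated in place) are
    rejected and re-drawn, bounded by ``max_tries``.
    """
    occupied = occupied if occupied is not None else []
    matrices = [_first_matrix(library, c) for c in module.classes]
    lens = [m.length for m in matrices]
    wlen = len(seq)
    lo, hi = module.anchor_window
    for _ in range(max_tries):
        anchor = int(rng.integers(lo, hi + 1))
        gaps = [
            g + int(np.rint(rng.normal(0.0, module.jitter_sd))) if module.jitter_sd
            else g
            for g in module.gaps
        ]
        starts = [anchor]
        for g in gaps:
            starts.append(starts[-1] + g)
        spans = [(s, s + L) for s, L in zip(starts, lens)]
        if spans[0][0] < window_start_rel or spans[-1][1] > window_start_rel + wlen:
            continue
        if any(b1 > a2 for (a1, b1), (a2, b2) in zip(spans, spans[1:])):
            continue  # jitter made consecutive sites overlap
        if any(_overlaps(sp, occupied) for sp in spans):
            continue
        seq_list = list(seq)
        records = []
        thr = scan_thresholds
        for m, (a, b), strand in zip(matrices, spans, module.strands):
            site = _sample_site(
                m, rng, site_mode,
                thr if thr is not None else (m.core_threshold, m.matrix_threshold),
            )
            emitted = site if strand == "+" else reverse_complement(site)
            i = a - window_start_rel
            seq_list[i : i + m.length] = emitted
            records.append(
                PlantedSite(
                    gene_id=gene_id,
                    cog_id=cog_id,
                    class_label=m.class_label,
                    matrix_id=m.id,
                    start_rel=a,
                    strand=strand,
                    site_seq=site,
                    origin=origin,
                )
            )
        occupied.extend(spans)
        return "".join(seq_list), records
    raise PhylofootError(
        f"{gene_id}: could not place module {module.classes} within "
        f"{max_tries} tries"
    )


def _first_matrix(library: MatrixLibrary, class_label: str) -> MotifMatrix:
    for m in library:
        if m.class_label == class_label:
            return m
    raise InputError(f"no matrix with class label {class_label!r}")


def _overlaps(span: tuple[int, int], occupied: Iterable[tuple[int, int]]) -> bool:
    a, b = span
    return any(a < y and x < b for x, y in occupied)


def _plant_singleton(
    seq: str,
    spec: SingletonSpec,
    rng: np.random.Generator,
    library: MatrixLibrary,
    window_start_rel: int,
    site_mode: str,
    scan_thresholds: tuple[float, float] | None,
    occupied: list[tuple[int, int]],
    gene_id: str,
    cog_id: str,
    max_tries: int = 200,
) -> tuple[str, PlantedSite]:
    m = _first_matrix(library, spec.class_label)
    lo, hi = spec.position_window
    lo = max(lo, window_start_rel)
    hi = min(hi, window_start_rel + len(seq) - m.length)
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi + 1))
        span = (start, start + m.length)
        if _overlaps(span, occupied):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        thr = scan_thresholds
        site = _sample_site(
            m, rng, site_mode,
            thr if thr is not None else (m.core_threshold, m.matrix_threshold),
        )
        emitted = site if strand == "+" else reverse_complement(site)
        i = start - window_start_rel
        seq_list = list(seq)
        seq_list[i : i + m.length] = emitted
        occupied.append(span)
        return "".join(seq_list), PlantedSite(
            gene_id=gene_id,
            cog_id=cog_id,
            class_label=m.class_label,
            matrix_id=m.id,
            start_rel=start,
            strand=strand,
            site_seq=site,
            origin=f"singleton:{spec.category}",
        )
    raise PhylofootError(
        f"{gene_id}: could not place singleton {spec.class_label} within "
        f"{max_tries} tries"
    )


# ---------------------------------------------------------------------------
# Scrubbing and verification
# ---------------------------------------------------------------------------


def _temp_promoter(seq: str, window: tuple[int, int]) -> PromoterSequence:
    return PromoterSequence(
        gene_id="_tmp", species="", lineage="", role="unknown", cog_id=None,
        seq=seq, window_start_rel=window[0], window_end_rel=window[1],
    )


def _scan_all(seq, window, library, scan_thresholds, pcache):
    prom = _temp_promoter(seq, window)
    hits = []
    for m in library:
        thr = scan_thresholds if scan_thresholds is not None else (
            m.core_threshold, m.matrix_threshold,
        )
        key = (m.id, thr)
        if key not in pcache:
            pcache[key] = site_match_pvalue(m, thresholds=thr)
        hits.extend(
            scan_promoter(m, prom, thresholds=thr, evalue_cutoff=None,
                          _pvalue=pcache[key])
        )
    return hits


def scrub_background(
    seq: str,
    library: MatrixLibrary,
    rng: np.random.Generator,
    window: tuple[int, int] = (-1000, 200),
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    scan_thresholds: tuple[float, float] | None = None,
    max_rounds: int = 60,
    _pcache: dict | None = None,
) -> str:
    """Re-draw background windows until no library matrix matches anywhere."""
    comp = np.asarray(composition, float)
    comp = comp / comp.sum()
    pcache = _pcache if _pcache is not None else {}
    ws = window[0]
    lengths = {m.id: m.length for m in library}
    for _ in range(max_rounds):
        hits = _scan_all(seq, window, library, scan_thresholds, pcache)
        if not hits:
            return seq
        seq_list = list(seq)
        for h in hits:
            L = lengths[h.matrix_id]
            i = h.start_rel - ws
            codes = rng.choice(4, size=L, p=comp)
            seq_list[i : i + L] = (BASES[c] for c in codes)
        seq = "".join(seq_list)
    raise PhylofootError("background scrubbing did not converge")


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class SimulatedDataset:
    promoters: list[PromoterSequence]
    cog_table: pd.DataFrame
    manifest: TruthManifest
    library: MatrixLibrary
    design: SimulationDesign


def _gene_plan(design: SimulationDesign):
    """(gene_id, species, lineage, role, cog) rows plus planting targets."""
    rows = []
    species = list(design.species)
    for cog in design.cogs:
        for sp in species:
            rows.append((f"{cog.cog_id}_{sp}", sp, design.species[sp], "ortholog", cog))
        for i in range(cog.n_paralogs):
            sp = species[i % len(species)]
            rows.append(
                (f"{cog.cog_id}_P{i + 1}", sp, design.species[sp], "paralog", cog)
            )
    return rows


def _planting_targets(cog: COGSpec, design: SimulationDesign,
                      gene_id: str, species: str, role: str):
    """Which modules/singletons go into this particular promoter."""
    lineage = design.species[species]
    modules = []
    singles = []
    if role == "ortholog":
        modules = list(enumerate(cog.modules))
        for s in cog.singletons:
            if s.category in ("I", "II"):
                singles.append(s)
            elif s.category == "III" and lineage == s.detail:
                singles.append(s)
            elif s.category == "IV" and species == s.detail:
                singles.append(s)
    else:
        par_index = int(gene_id.rsplit("P", 1)[1])
        for s in cog.singletons:
            if s.category in ("I", "P") and par_index == 1:
                singles.append(s)
    return modules, singles


def simulate_cog_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Generate promoters, COG table and manifest for a full design.

    Deterministic in ``design.seed``: the same design yields byte-identical
    sequences.  Every pipeline stage is runnable on the output with no
    external data.
    """
    design.validate()
    library = design.resolved_library()
    window = design.window
    wlen = window[1] - window[0]
    root = np.random.SeedSequence(design.seed)
    plan = _gene_plan(design)
    gene_seeds = root.spawn(len(plan))
    pcache: dict = {}

    promoters = []
    sites: list[PlantedSite] = []
    rows = []
    for (gene_id, sp, lineage, role, cog), seed_seq in zip(plan, gene_seeds):
        rng = np.random.default_rng(seed_seq)
        modules, singles = _planting_targets(cog, design, gene_id, sp, role)
        for attempt in range(design.max_retries):
            seq = generate_background(
                wlen, design.background, rng=rng, order1=design.order1
            )
            if design.scrub:
                seq = scrub_background(
                    seq, library, rng, window=window,
                    composition=design.background,
                    scan_thresholds=design.scan_thresholds, _pcache=pcache,
                )
            occupied: list[tuple[int, int]] = []
            gene_sites: list[PlantedSite] = []
            try:
                for mi, mspec in modules:
                    seq, recs = plant_module(
                        seq, mspec, rng, library, window[0],
                        site_mode=design.site_mode,
                        scan_thresholds=design.scan_thresholds,
                        occupied=occupied, gene_id=gene_id, cog_id=cog.cog_id,
                        origin=f"module:{mi}",
                    )
                    gene_sites.extend(recs)
                for sspec in singles:
                    seq, rec = _plant_singleton(
                        seq, sspec, rng, library, window[0],
                        design.site_mode, design.scan_thresholds,
                        occupied, gene_id, cog.cog_id,
                    )
                    gene_sites.append(rec)
            except PhylofootError:
                continue  # crowded draw; retry with fresh background
            if design.scrub and not _verify_gene(
                seq, window, library, design.scan_thresholds, gene_sites,
                pcache, strict=design.site_mode != "sample",
            ):
                continue
            break
        else:
            raise PhylofootError(
                f"{gene_id}: could not realize a manifest-consistent promoter "
                f"in {design.max_retries} attempts"
            )
        promoters.append(
            PromoterSequence(
                gene_id=gene_id, species=sp, lineage=lineage, role=role,
                cog_id=cog.cog_id, seq=seq,
                window_start_rel=window[0], window_end_rel=window[1],
                source_contig="synthetic", source_strand="+",
            )
        )
        sites.extend(gene_sites)
        rows.append(
            {"gene_id": gene_id, "species": sp, "lineage": lineage,
             "role": role, "cog_id": cog.cog_id}
        )

    manifest = TruthManifest(
        sites=sites,
        expected_categories=_expected_categories(design),
        expected_module_keys={
            cog.cog_id: [m.key for m in cog.modules] for cog in design.cogs
        },
        seed=design.seed,
        window=window,
    )
    return SimulatedDataset(
        promoters=promoters,
        cog_table=pd.DataFrame(rows),
        manifest=manifest,
        library=library,
        design=design,
    )


def _verify_gene(seq, window, library, scan_thresholds, gene_sites, pcache,
                 strict: bool) -> bool:
    """Detected sites must coincide exactly with the planted ones."""
    detected = {
        (h.class_label, h.start_rel, h.strand)
        for h in _scan_all(seq, window, library, scan_thresholds, pcache)
    }
    planted = {(s.class_label, s.start_rel, s.strand) for s in gene_sites}
    if strict:
        return detected == planted
    return detected <= planted  # sampled sites may fall below thresholds


def _expected_categories(design: SimulationDesign):
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for cog in design.cogs:
        cats: dict[str, tuple[str, str]] = {}
        for m in cog.modules:
            for c in m.classes:
                cats[c] = ("II", "")
        for s in cog.singletons:
            cats[s.class_label] = (s.category, s.detail)
        out[cog.cog_id] = cats
    return out


# ---------------------------------------------------------------------------
# Genome embedding (round-trips the extraction stage)
# ---------------------------------------------------------------------------


def embed_in_genome(
    promoters: Sequence[PromoterSequence],
    seed: int = 0,
    flank: int = 60,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[dict[str, str], list[TSSRecord]]:
    """Place each promoter on its own contig (alternating strands) so that
    window extraction from the genome reproduces the promoter sequences."""
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    records = []
    for k, p in enumerate(promoters):
        left = generate_background(flank, composition, rng=rng)
        right = generate_background(flank, composition, rng=rng)
        plus = left + p.seq + right
        contig_id = f"ctg_{p.gene_id}"
        tss_plus = flank - p.window_start_rel
        if k % 2 == 0:
            genome[contig_id] = plus
            records.append(TSSRecord(p.gene_id, contig_id, tss_plus, "+", "synthetic"))
        else:
            genome[contig_id] = reverse_complement(plus)
            tss = len(plus) - 1 - tss_plus
            records.append(TSSRecord(p.gene_id, contig_id, tss, "-", "synthetic"))
    return genome, records


# ---------------------------------------------------------------------------
# Manifest checking and recovery scoring
# ---------------------------------------------------------------------------


def verify_manifest(promoters: Sequence[PromoterSequence], manifest: TruthManifest) -> None:
    """Assert planted site sequences can be re-read from the FASTA exactly."""
    by_id = {p.gene_id: p for p in promoters}
    for s in manifest.sites:
        p = by_id[s.gene_id]
        i = s.start_rel - p.window_start_rel
        sub = p.seq[i : i + len(s.site_seq)]
        expect = s.site_seq if s.strand == "+" else reverse_complement(s.site_seq)
        if sub != expect:
            raise PhylofootError(
                f"manifest mismatch at {s.gene_id}:{s.start_rel} "
                f"({sub} != {expect})"
            )


def score_module_recovery(
    manifest: TruthManifest,
    modules_by_cog: Mapping[str, Sequence],
) -> tuple[int, int]:
    """(recovered, expected) planted module signatures across COGs.

    A planted signature counts as recovered when it is emitted or is a
    contiguous sub-signature of an emitted module (maximality may absorb
    it into a longer arrangement).
    """
    from .module_detect import covered_keys

    recovered = expected = 0
    for cog_id, keys in manifest.expected_module_keys.items():
        got = covered_keys(modules_by_cog.get(cog_id, []))
        for key in keys:
            expected += 1
            if key in got:
                recovered += 1
    return recovered, expected


def score_category_recovery(
    manifest: TruthManifest,
    reports: Mapping[str, object],
) -> tuple[int, int]:
    """(correct, expected) planted category labels across COGs."""
    correct = expected = 0
    for cog_id, cats in manifest.expected_categories.items():
        rep = reports.get(cog_id)
        for cls, (cat, detail) in cats.items():
            expected += 1
            if rep is None or cls not in rep.assignments:
                continue
            a = rep.assignments[cls]
            if a.category == cat and (cat not in ("III", "IV") or a.detail == detail):
                correct += 1
    return correct, expected


# ---------------------------------------------------------------------------
# Ready-made designs
# ---------------------------------------------------------------------------


def example_design(
    seed: int,
    n_cogs: int = 2,
    module_sizes: Sequence[int] = (2, 3),
    jitter_sd: float = 0.0,
    n_paralogs: int = 2,
    scan_thresholds: tuple[float, float] | None = None,
    site_mode: str = "threshold",
    n_lineage_specific: int = 2,
    library: MatrixLibrary | None = None,
) -> SimulationDesign:
    """A representative design: per COG one planted module plus singleton
    classes realizing each conservation category.

    Classes rotate through the library across COGs so different COGs carry
    different (but possibly overlapping) signatures.  Module gaps default
    to 40 nt between consecutive sites with strand pattern alternating
    from '+'.
    """
    lib = library if library is not None else default_matrix_library()
    classes = lib.classes
    species = list(DEFAULT_SPECIES)
    cogs = []
    for i in range(n_cogs):
        size = module_sizes[i % len(module_sizes)]
        take = iter(classes[(7 * i) % len(classes) :] + classes[: (7 * i) % len(classes)])
        mod_classes = tuple(next(take) for _ in range(size))
        strands = tuple("+-"[j % 2] for j in range(size))
        module = ModuleSpec(
            classes=mod_classes,
            strands=strands,
            gaps=(40,) * (size - 1),
            jitter_sd=jitter_sd,
        )
        singles = [
            SingletonSpec(next(take), "I"),
            SingletonSpec(next(take), "II"),
        ]
        for _ in range(n_lineage_specific):
            singles.append(SingletonSpec(next(take), "III", "monocot"))
        for sp in species:
            singles.append(SingletonSpec(next(take), "IV", sp))
        singles.append(SingletonSpec(next(take), "P"))
        cogs.append(
            COGSpec(
                cog_id=f"C{i + 1}",
                modules=[module],
                singletons=singles,
                n_paralogs=n_paralogs,
            )
        )
    return SimulationDesign(
        cogs=cogs,
        seed=seed,
        scan_thresholds=scan_thresholds,
        site_mode=site_mode,
        library=lib,
    )
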