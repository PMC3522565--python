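"""Detection of spatially conserved cis-regulatory core modules.

A core module is an ordered combination of 2-4 TFBS classes whose order,
strand orientation and inter-site spacing recur in the promoter of every
ortholog of a COG while no equivalent arrangement exists in any paralog
promoter.  Candidate arrangements ("site chains") are subsequences of a
promoter's hit list — intervening extra sites are allowed — constrained
by a maximum consecutive start-to-start gap and a maximum overall span.

Spacing conservation is enforced pairwise against a reference instance
(the lexicographically first ortholog member): every other member must
carry a chain with the identical class/strand signature whose consecutive
gaps each differ from the reference gaps by at most ``gap_tolerance``.
Absolute distance from the TSS is reported per member but is not a
detection criterion.  ``brute_force_core_modules`` implements the same
contract by exhaustive search and serves as the testing oracle.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import GuardError, InputError

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = (2, 4)
DEFAULT_MAX_GAP = 150
DEFAULT_MAX_SPAN = 400
DEFAULT_GAP_TOLERANCE = 10


@dataclass(frozen=True, order=True)
class Site:
    """A deduplicated class-level site occurrence."""

    start_rel: int
    class_label: str
    strand: str


@dataclass(frozen=True)
class SiteChain:
    """An ordered run of sites in one promoter (strictly increasing starts)."""

    gene_id: str
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        starts = [s.start_rel for s in self.sites]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InputError("chain sites must have strictly increasing starts")

    @property
    def class_sequence(self) -> tuple[str, ...]:
        return tuple(s.class_label for s in self.sites)

    @property
    def strand_pattern(self) -> tuple[str, ...]:
        return tuple(s.strand for s in self.sites)

    @property
    def key(self) -> tuple[tuple[str, str], ...]:
        return tuple((s.class_label, s.strand) for s in self.sites)

    @property
    def gaps(self) -> tuple[int, ...]:
        starts = [s.start_rel for s in self.sites]
        return tuple(b - a for a, b in zip(starts, starts[1:]))

    @property
    def span(self) -> int:
        return self.sites[-1].start_rel - self.sites[0].start_rel

    @property
    def starts(self) -> tuple[int, ...]:
        return tuple(s.start_rel for s in self.sites)


def sites_from_hits(hits: Iterable) -> tuple[Site, ...]:
    """Collapse hits to unique (start, class, strand) sites, sorted."""
    uniq = {
        Site(start_rel=h.start_rel, class_label=h.class_label, strand=h.strand)
        if not isinstance(h, Site)
        else h
        for h in hits
    }
    return tuple(sorted(uniq))


def enumerate_site_chains(
    hits: Iterable,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    max_gap: int = DEFAULT_MAX_GAP,
    max_span: int = DEFAULT_MAX_SPAN,
    gene_id: str | None = None,
) -> list[SiteChain]:
    """All chains of k sites with consecutive gaps <= max_gap, span <= max_span.

    Chains are subsequences of the (deduplicated) site list: extra sites
    may lie between chain members.  Output is sorted by site positions.
    """
    sites = sites_from_hits(hits)
    if gene_id is None:
        gene_ids = {h.gene_id for h in hits if hasattr(h, "gene_id")}
        gene_id = gene_ids.pop() if len(gene_ids) == 1 else ""
    kmin, kmax = k_range
    chains: list[tuple[Site, ...]] = []

    def extend(prefix: tuple[Site, ...], last_idx: int) -> None:
        if kmin <= len(prefix):
            chains.append(prefix)
        if len(prefix) == kmax:
            return
        last = prefix[-1]
        first = prefix[0]
        for j in range(last_idx + 1, len(sites)):
            nxt = sites[j]
            gap = nxt.start_rel - last.start_rel
            if gap < 1:
                continue
            if gap > max_gap or nxt.start_rel - first.start_rel > max_span:
                continue
            extend(prefix + (nxt,), j)

    for i in range(len(sites)):
        extend((sites[i],), i)
    chains.sort(key=lambda c: tuple((s.start_rel, s.class_label, s.strand) for s in c))
    return [SiteChain(gene_id=gene_id, sites=c) for c in chains]


@dataclass(eq=False)
class CoreModule:
    """A conserved 2-4 class arrangement with one instance per ortholog."""

    cog_id: str
    class_sequence: tuple[str, ...]
    strand_pattern: tuple[str, ...]
    spacing: tuple[int, ...]  # consecutive gaps of the reference instance
    tolerance: int
    instances: dict[str, SiteChain]
    anchor_positions: dict[str, int]

    @property
    def key(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.class_sequence, self.strand_pattern))

    def to_dict(self) -> dict:
        return {
            "cog_id": self.cog_id,
            "class_sequence": list(self.class_sequence),
            "strand_pattern": list(self.strand_pattern),
            "spacing": list(self.spacing),
            "tolerance": self.tolerance,
            "anchor_positions": dict(sorted(self.anchor_positions.items())),
            "instances": {
                g: [[s.start_rel, s.class_label, s.strand] for s in ch.sites]
                for g, ch in sorted(self.instances.items())
            },
        }


def _gaps_within(a: Sequence[int], b: Sequence[int], tol: int) -> bool:
    return all(abs(x - y) <= tol for x, y in zip(a, b))


def _is_contiguous_subkey(small, big) -> bool:
    if len(small) >= len(big):
        return False
    return any(
        tuple(big[i : i + len(small)]) == tuple(small)
        for i in range(len(big) - len(small) + 1)
    )


def _emit_modules(
    orth_chains: dict[str, list[SiteChain]],
    paralog_chains: list[SiteChain],
    gap_tolerance: int,
    cog_id: str,
) -> list[CoreModule]:
    """Shared emission rule given pre-enumerated chains per gene.

    For each class/strand signature present in every ortholog, reference
    chains (from the lexicographically first ortholog, in positional
    order) are tried in turn; the first reference for which every member
    carries a gap-compatible chain and no paralog chain is gap-compatible
    defines the emitted module.
    """
    genes = sorted(orth_chains)
    by_key: dict[tuple, dict[str, list[SiteChain]]] = {}
    for g in genes:
        for ch in orth_chains[g]:
            by_key.setdefault(ch.key, {}).setdefault(g, []).append(ch)
    par_by_key: dict[tuple, list[SiteChain]] = {}
    for ch in paralog_chains:
        par_by_key.setdefault(ch.key, []).append(ch)

    modules = []
    for key in sorted(by_key):
        per_gene = by_key[key]
        if set(per_gene) != set(genes):
            continue
        ref_gene = genes[0]
        for ref in per_gene[ref_gene]:
            instances = {ref_gene: ref}
            ok = True
            for g in genes[1:]:
                match = next(
                    (c for c in per_gene[g] if _gaps_within(c.gaps, ref.gaps, gap_tolerance)),
                    None,
                )
                if match is None:
                    ok = False
                    break
                instances[g] = match
            if not ok:
                continue
            if any(
                _gaps_within(c.gaps, ref.gaps, gap_tolerance)
                for c in par_by_key.get(key, [])
            ):
                continue  # an equivalent arrangement exists in a paralog
            modules.append(
                CoreModule(
                    cog_id=cog_id,
                    class_sequence=tuple(k[0] for k in key),
                    strand_pattern=tuple(k[1] for k in key),
                    spacing=ref.gaps,
                    tolerance=gap_tolerance,
                    instances=instances,
                    anchor_positions={g: c.sites[0].start_rel for g, c in instances.items()},
                )
            )
            break
    return modules


def _apply_maximality(modules: list[CoreModule]) -> list[CoreModule]:
    keys = [m.key for m in modules]
    return [
        m
        for m in modules
        if not any(_is_contiguous_subkey(m.key, other) for other in keys)
    ]


def detect_core_modules(
    cog_hits: Mapping[str, Iterable],
    paralog_hits: Mapping[str, Iterable] | None = None,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    max_gap: int = DEFAULT_MAX_GAP,
    max_span: int = DEFAULT_MAX_SPAN,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    maximal_only: bool = True,
    cog_id: str = "",
) -> list[CoreModule]:
    """Detect core modules shared by all orthologs and absent from paralogs.

    ``cog_hits`` maps ortholog gene id -> hits (or sites); ``paralog_hits``
    likewise for the paralog contrast set.  With ``maximal_only`` a module
    whose class/strand signature is a contiguous sub-chain of another
    emitted module is suppressed.
    """
    if len(cog_hits) < 2:
        raise InputError("core-module detection needs >= 2 ortholog promoters")
    orth_chains = {
        g: enumerate_site_chains(h, k_range, max_gap, max_span, gene_id=g)
        for g, h in cog_hits.items()
    }
    if all(not c for c in orth_chains.values()):
        warnings.warn(f"COG {cog_id or '?'}: no candidate site chains", stacklevel=2)
        return []
    par_chains: list[SiteChain] = []
    for g, h in (paralog_hits or {}).items():
        par_chains.extend(enumerate_site_chains(h, k_range, max_gap, max_span, gene_id=g))
    modules = _emit_modules(orth_chains, par_chains, gap_tolerance, cog_id)
    if maximal_only:
        modules = _apply_maximality(modules)
    return modules


def brute_force_core_modules(
    cog_hits: Mapping[str, Iterable],
    paralog_hits: Mapping[str, Iterable] | None = None,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    max_gap: int = DEFAULT_MAX_GAP,
    max_span: int = DEFAULT_MAX_SPAN,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    maximal_only: bool = True,
    cog_id: str = "",
) -> list[CoreModule]:
    """Exhaustive-search oracle with the same result contract.

    Chains are generated by raw combinations of the deduplicated site list
    (no pruned search), guarded to <= 25 sites per promoter.
    """
    if len(cog_hits) < 2:
        raise InputError("core-module detection needs >= 2 ortholog promoters")

    def all_chains(gene_id: str, hits) -> list[SiteChain]:
        sites = sites_from_hits(hits)
        if len(sites) > 25:
            raise GuardError(
                f"{gene_id}: {len(sites)} sites exceed the brute-force guard (25)"
            )
        kmin, kmax = k_range
        out = []
        for k in range(kmin, kmax + 1):
            for combo in itertools.combinations(sites, k):
                starts = [s.start_rel for s in combo]
                if any(b <= a for a, b in zip(starts, starts[1:])):
                    continue
                gaps = [b - a for a, b in zip(starts, starts[1:])]
                if max(gaps) > max_gap or starts[-1] - starts[0] > max_span:
                    continue
                out.append(SiteChain(gene_id=gene_id, sites=combo))
        out.sort(key=lambda c: tuple((s.start_rel, s.class_label, s.strand) for s in c.sites))
        return out

    orth_chains = {g: all_chains(g, h) for g, h in cog_hits.items()}
    par_chains: list[SiteChain] = []
    for g, h in (paralog_hits or {}).items():
        par_chains.extend(all_chains(g, h))
    modules = _emit_modules(orth_chains, par_chains, gap_tolerance, cog_id)
    if maximal_only:
        modules = _apply_maximality(modules)
    return modules


def covered_keys(modules: Iterable[CoreModule]) -> set[tuple]:
    """Emitted signatures plus every contiguous sub-signature (length >= 2).

    Useful to check recovery of a planted arrangement that was absorbed
    into a longer maximal module.
    """
    keys = set()
    for m in modules:
        key = m.key
        for length in range(2, len(key) + 1):
            for i in range(len(key) - length + 1):
                keys.add(key[i : i + length])
    return keys


def render_module_alignment(module: CoreModule) -> str:
    """Plain-text alignment of a module's member instances.

    One line per promoter, sites at their TSS-relative positions with the
    consecutive start-to-start gaps spelled out, e.g.::

        Os_A1   -612 GBOX(+) --40-- MYBS(+)
    """
    header = (
        f"module {'-'.join(module.class_sequence)} "
        f"[{''.join(module.strand_pattern)}] spacing "
        f"{','.join(map(str, module.spacing))} +/-{module.tolerance}nt"
    )
    lines = [header]
    width = max(len(g) for g in module.instances)
    for gene in sorted(module.instances):
        chain = module.instances[gene]
        parts = []
        for site, nxt in zip(chain.sites, chain.sites[1:] + (None,)):
            parts.append(f"{site.class_label}({site.strand})")
            if nxt is not None:
                parts.append(f"--{nxt.start_rel - site.start_rel}--")
        lines.append(
            f"{gene:<{width}}  {chain.sites[0].start_rel:>6} " + " ".join(parts)
        )
    return "\n".join(lines) + "\n"
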