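"""Conservation-category partitioning of TFBS classes within ortholog groups.

Each TFBS class observed in the promoters of a cluster of orthologous
genes (COG) is assigned exactly one conservation category:

* ``I``   shared: present in every ortholog and in at least one paralog;
* ``II``  ortholog-specific: present in every ortholog, absent from all
          paralogs;
* ``III`` lineage-specific: present in every ortholog of exactly one
          multi-species lineage (e.g. both monocots), absent from the
          other lineage's ortholog(s) and from all paralogs;
* ``IV``  species-specific: present in the ortholog(s) of exactly one
          species, absent from all other orthologs and all paralogs;
* ``P``   paralog-specific: present only in paralogs;
* ``unclassified`` everything else (e.g. two species across lineages, or
          a single-species class that also occurs in a paralog).

The categories are mutually exclusive and exhaustive over the classes
present in the COG's promoters.  The paralog-absence condition applied to
IV mirrors the one stated for III, so "unique to a species" means unique
among all genes of the group, not just among orthologs.  When a COG has
no paralogs at all, categories I and P are undefined: every all-ortholog
class is reported as II.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError
from .motif_scan import OccurrenceMatrix

CATEGORY_SHARED = "I"
CATEGORY_ORTHOLOG_SPECIFIC = "II"
CATEGORY_LINEAGE_SPECIFIC = "III"
CATEGORY_SPECIES_SPECIFIC = "IV"
CATEGORY_PARALOG_SPECIFIC = "P"
CATEGORY_UNCLASSIFIED = "unclassified"


@dataclass(eq=False)
class COGDefinition:
    """Membership of one cluster of orthologous genes.

    ``members`` maps species -> ortholog gene id(s) (a species may carry
    several copies, e.g. a duplicated sorghum gene); ``paralogs`` lists
    the non-orthologous relatives used as the negative contrast set.
    """

    cog_id: str
    members: dict[str, tuple[str, ...]]
    paralogs: tuple[str, ...] = ()
    lineages: dict[str, str] = field(default_factory=dict)
    group_label: str = ""

    def __post_init__(self) -> None:
        self.members = {sp: tuple(g) if not isinstance(g, str) else (g,)
                        for sp, g in self.members.items()}
        self.paralogs = tuple(self.paralogs)
        if len(self.members) < 2:
            raise InputError(f"COG {self.cog_id}: needs members from >= 2 species")
        member_genes = {g for gs in self.members.values() for g in gs}
        overlap = member_genes & set(self.paralogs)
        if overlap:
            raise InputError(
                f"COG {self.cog_id}: genes {sorted(overlap)} listed as both "
                f"ortholog and paralog"
            )

    @property
    def ortholog_genes(self) -> tuple[str, ...]:
        return tuple(g for gs in self.members.values() for g in gs)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.members)

    def multi_species_lineages(self) -> dict[str, tuple[str, ...]]:
        """Lineage -> species tuple, restricted to lineages with >= 2 species."""
        by_lin: dict[str, list[str]] = {}
        for sp in self.members:
            by_lin.setdefault(self.lineages.get(sp, ""), []).append(sp)
        return {lin: tuple(sps) for lin, sps in by_lin.items() if len(sps) >= 2 and lin}


def cog_definitions_from_table(cog_table: pd.DataFrame) -> list[COGDefinition]:
    """Build COG definitions from the membership TSV (one per cog_id)."""
    defs = []
    for cog_id, sub in cog_table.dropna(subset=["cog_id"]).groupby("cog_id", sort=True):
        orth = sub[sub["role"] == "ortholog"]
        members = {
            sp: tuple(rows["gene_id"]) for sp, rows in orth.groupby("species", sort=True)
        }
        lineages = dict(zip(sub["species"], sub["lineage"]))
        defs.append(
            COGDefinition(
                cog_id=str(cog_id),
                members=members,
                paralogs=tuple(sub.loc[sub["role"] == "paralog", "gene_id"]),
                lineages=lineages,
            )
        )
    return defs


@dataclass(frozen=True)
class ClassAssignment:
    category: str
    detail: str = ""  # lineage for III, species for IV


@dataclass(eq=False)
class ConservationReport:
    """Category assignment per TFBS class for one COG, plus count summaries."""

    cog_id: str
    assignments: dict[str, ClassAssignment]
    paralogs_defined: bool
    all_species_count: int
    species_unique_counts: dict[str, int]

    def category_of(self, class_label: str) -> str:
        return self.assignments[class_label].category

    def classes_in_category(self, category: str, detail: str | None = None) -> list[str]:
        return sorted(
            c
            for c, a in self.assignments.items()
            if a.category == category and (detail is None or a.detail == detail)
        )

    def to_rows(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"cog_id": self.cog_id, "class": c, "category": a.category,
                 "detail": a.detail}
                for c, a in sorted(self.assignments.items())
            ]
        )


def _presence(occ: OccurrenceMatrix, class_label: str, genes: Sequence[str],
              require_all: bool) -> bool:
    if not genes:
        return False
    vals = [occ.presence(class_label, g) for g in genes]
    return all(vals) if require_all else any(vals)


def classify_categories(
    occ: OccurrenceMatrix,
    cog: COGDefinition,
    require_all_copies: bool = False,
) -> ConservationReport:
    """Assign every TFBS class seen in the COG's promoters to a category.

    ``require_all_copies`` switches species-level presence from "any gene
    copy of the species" (default) to "every copy".
    """
    needed = set(cog.ortholog_genes) | set(cog.paralogs)
    missing = needed - set(occ.genes)
    if missing:
        raise InputError(
            f"COG {cog.cog_id}: genes missing from occurrence matrix: "
            f"{sorted(missing)}"
        )
    lineage_map = cog.multi_species_lineages()
    paralogs_defined = bool(cog.paralogs)
    assignments: dict[str, ClassAssignment] = {}
    for cls in occ.classes:
        sp_present = {
            sp: _presence(occ, cls, genes, require_all_copies)
            for sp, genes in cog.members.items()
        }
        par_present = _presence(occ, cls, cog.paralogs, require_all=False)
        present_species = {sp for sp, v in sp_present.items() if v}
        if not present_species and not par_present:
            continue  # class absent from this COG entirely: not reported
        if present_species == set(cog.members):
            if par_present:
                assignments[cls] = ClassAssignment(CATEGORY_SHARED)
            else:
                assignments[cls] = ClassAssignment(CATEGORY_ORTHOLOG_SPECIFIC)
            continue
        lineage_hit = None
        for lin, sps in lineage_map.items():
            if present_species == set(sps):
                lineage_hit = lin
                break
        if lineage_hit is not None and not par_present:
            assignments[cls] = ClassAssignment(CATEGORY_LINEAGE_SPECIFIC, lineage_hit)
        elif len(present_species) == 1 and not par_present:
            assignments[cls] = ClassAssignment(
                CATEGORY_SPECIES_SPECIFIC, next(iter(present_species))
            )
        elif not present_species and par_present:
            assignments[cls] = ClassAssignment(CATEGORY_PARALOG_SPECIFIC)
        else:
            assignments[cls] = ClassAssignment(CATEGORY_UNCLASSIFIED)

    all_species_count = sum(
        1
        for a in assignments.values()
        if a.category in (CATEGORY_SHARED, CATEGORY_ORTHOLOG_SPECIFIC)
    )
    species_unique = {
        sp: sum(
            1
            for a in assignments.values()
            if a.category == CATEGORY_SPECIES_SPECIFIC and a.detail == sp
        )
        for sp in cog.members
    }
    return ConservationReport(
        cog_id=cog.cog_id,
        assignments=assignments,
        paralogs_defined=paralogs_defined,
        all_species_count=all_species_count,
        species_unique_counts=species_unique,
    )


def classify_cogs(
    occ: OccurrenceMatrix,
    cogs: Iterable[COGDefinition],
    require_all_copies: bool = False,
) -> dict[str, ConservationReport]:
    return {
        cog.cog_id: classify_categories(occ, cog, require_all_copies)
        for cog in cogs
    }


def summarize_counts(
    reports: Mapping[str, ConservationReport] | Sequence[ConservationReport],
    occ: OccurrenceMatrix,
    cogs: Mapping[str, COGDefinition] | Sequence[COGDefinition] | None = None,
    include_paralog_carriers: bool = False,
) -> pd.DataFrame:
    """Per-COG information-content count table.

    Rows are "TFBS in all species" (classes present in every member
    species' ortholog set) and "TFBS in <sp> only" (classes detected only
    in that species' ortholog).  By default a class that also occurs in a
    paralog does not count as species-unique (matching the
    species-specific category rule); ``include_paralog_carriers=True``
    counts it as long as it is unique among orthologs.
    """
    if not isinstance(reports, Mapping):
        reports = {r.cog_id: r for r in reports}
    if not reports:
        raise InputError("summarize_counts needs at least one report")
    cog_map: dict[str, COGDefinition] | None = None
    if cogs is not None:
        cog_map = cogs if isinstance(cogs, Mapping) else {c.cog_id: c for c in cogs}

    species_order: list[str] = []
    for rep in reports.values():
        for sp in rep.species_unique_counts:
            if sp not in species_order:
                species_order.append(sp)

    table: dict[str, dict[str, int]] = {}
    for cog_id, rep in sorted(reports.items()):
        col = {"TFBS in all species": rep.all_species_count}
        for sp in species_order:
            base = rep.species_unique_counts.get(sp, 0)
            if include_paralog_carriers and cog_map is not None:
                cog = cog_map[cog_id]
                if sp in cog.members:
                    # add classes unique to sp among orthologs but carried
                    # by >= 1 paralog (labelled unclassified by default)
                    for cls, a in rep.assignments.items():
                        if a.category != CATEGORY_UNCLASSIFIED:
                            continue
                        present = {
                            s
                            for s, genes in cog.members.items()
                            if _presence(occ, cls, genes, False)
                        }
                        if present == {sp} and _presence(occ, cls, cog.paralogs, False):
                            base += 1
            col[f"TFBS in {sp} only"] = base
        table[cog_id] = col
    index = ["TFBS in all species"] + [f"TFBS in {sp} only" for sp in species_order]
    return pd.DataFrame(table).reindex(index).fillna(0).astype(int)
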