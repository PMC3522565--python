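"""One-command orchestration: inputs -> scan -> occurrence -> classify ->
modules -> clustering, with caching and provenance.

The result bundle is a plain directory of TSV/JSON/FASTA/Newick files —
diff-able and self-describing: ``config.yaml`` echoes the configuration
verbatim, ``metadata.json`` records tool and score-formula versions, and
``checksums.json`` fingerprints every artifact.  Each stage stores a key
derived from its parameters, its inputs and the upstream stage key;
reruns with unchanged configuration are cache hits and leave the bundle
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import __version__
from .errors import InputError, PhylofootError
from .conservation_classify import (
    classify_cogs,
    cog_definitions_from_table,
    summarize_counts,
)
from .module_detect import detect_core_modules, render_module_alignment
from .motif_scan import (
    FORMULA_VERSION,
    build_occurrence_matrix,
    hits_to_bed,
    hits_to_jsonl,
    MotifHit,
    OccurrenceMatrix,
    scan_promoters,
)
from .promoter_io import (
    extract_promoters,
    parse_matrix_library,
    promoters_from_fasta,
    promoters_to_fasta,
    read_cog_table,
    read_genome_fasta,
    read_tss_table,
    write_matrix_library,
)
from .stats import cluster_occurrence, information_content_tests
from .synthetic_data import (
    SimulatedDataset,
    example_design,
    score_category_recovery,
    score_module_recovery,
    simulate_cog_dataset,
    TruthManifest,
)

logger = logging.getLogger(__name__)


class StageError(PhylofootError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline settings, serialized verbatim into the bundle."""

    seed: int = 0
    window: tuple[int, int] = (-1000, 200)
    scan: dict[str, Any] = field(
        default_factory=lambda: {
            "evalue_cutoff": 1e-3,
            "cutoff_scale": "site",
            "thresholds": None,
            "background": "auto",
        }
    )
    modules: dict[str, Any] = field(
        default_factory=lambda: {
            "k_min": 2,
            "k_max": 4,
            "max_gap": 150,
            "max_span": 400,
            "gap_tolerance": 10,
        }
    )
    cluster: dict[str, Any] = field(
        default_factory=lambda: {"metric": "jaccard", "linkage": "average"}
    )
    inputs: dict[str, Any] | None = None
    synthetic: dict[str, Any] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.window = tuple(self.window)  # type: ignore[assignment]
        if (self.inputs is None) == (self.synthetic is None):
            raise InputError("config needs exactly one of 'inputs' or 'synthetic'")
        ws, we = self.window
        if not ws < 0 <= we:
            raise InputError("window must straddle the TSS")
        if self.scan.get("cutoff_scale", "site") not in ("site", "promoter"):
            raise InputError("scan.cutoff_scale must be 'site' or 'promoter'")
        if self.inputs is not None:
            has_prom = "promoters_fasta" in self.inputs
            has_genome = "genome_fasta" in self.inputs and "annotations" in self.inputs
            if not (has_prom or has_genome):
                raise InputError(
                    "inputs need promoters_fasta or genome_fasta+annotations"
                )
            if "cog_table" not in self.inputs:
                raise InputError("inputs need a cog_table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "window": list(self.window),
            "scan": self.scan,
            "modules": self.modules,
            "cluster": self.cluster,
            "inputs": self.inputs,
            "synthetic": self.synthetic,
            "log_level": self.log_level,
        }

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _sha256_file(path: Path) -> str:
    return _sha256_bytes(path.read_bytes())


@dataclass
class _Stage:
    name: str
    params_key: str
    outputs: tuple[str, ...]
    run: Callable[[], None]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages into ``outdir`` and return a run summary.

    Stage outputs are reused when the stage key (parameters + inputs +
    upstream key) is unchanged and the outputs still exist; a stale key
    forces recomputation.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    paths = {
        "config": out / "config.yaml",
        "promoters": out / "promoters.fasta",
        "cog_table": out / "cog_table.tsv",
        "library": out / "matrix_library.transfac",
        "manifest": out / "manifest.json",
        "hits_jsonl": out / "hits.jsonl",
        "hits_bed": out / "hits.bed",
        "occurrence": out / "occurrence.tsv",
        "categories": out / "categories.tsv",
        "counts": out / "counts.tsv",
        "chisq": out / "chisq.tsv",
        "modules_json": out / "modules.json",
        "modules_txt": out / "modules.txt",
        "newick": out / "gene_dendrograms.newick",
        "recovery": out / "recovery.json",
        "metadata": out / "metadata.json",
        "checksums": out / "checksums.json",
        "keys": out / "stage_keys.json",
    }
    paths["config"].write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )

    old_keys: dict[str, str] = {}
    if paths["keys"].exists():
        try:
            old_keys = json.loads(paths["keys"].read_text())
        except json.JSONDecodeError:
            old_keys = {}
    new_keys: dict[str, str] = {}
    summary: dict[str, Any] = {"stages": {}, "outdir": str(out)}

    def external_input_hash() -> str:
        if config.synthetic is not None:
            return "synthetic"
        h = hashlib.sha256()
        for key in sorted(config.inputs):  # type: ignore[arg-type]
            val = config.inputs[key]  # type: ignore[index]
            h.update(key.encode())
            p = Path(str(val))
            if p.exists() and p.is_file():
                h.update(_sha256_file(p).encode())
            else:
                h.update(str(val).encode())
        return h.hexdigest()

    def do_stage(name: str, params: dict, upstream_key: str,
                 outputs: tuple[Path, ...], fn: Callable[[], None]) -> str:
        key = _sha256_bytes(
            json.dumps(
                {"stage": name, "params": params, "upstream": upstream_key},
                sort_keys=True,
            ).encode()
        )
        cached = old_keys.get(name) == key and all(p.exists() for p in outputs)
        if cached:
            logger.info("stage %s: cache hit", name)
        else:
            logger.info("stage %s: running", name)
            try:
                fn()
            except PhylofootError as exc:
                raise StageError(name, exc) from exc
        new_keys[name] = key
        summary["stages"][name] = "cached" if cached else "computed"
        return key

    # ---- stage: inputs -------------------------------------------------
    synthetic_manifest: TruthManifest | None = None

    def stage_inputs() -> None:
        if config.synthetic is not None:
            design = example_design(seed=config.seed, **{
                k: v for k, v in config.synthetic.items() if k != "seed"
            })
            ds: SimulatedDataset = simulate_cog_dataset(design)
            paths["promoters"].write_text(promoters_to_fasta(ds.promoters))
            ds.cog_table.to_csv(paths["cog_table"], sep="\t", index=False)
            paths["library"].write_text(write_matrix_library(ds.library, "transfac"))
            paths["manifest"].write_text(ds.manifest.to_json())
            return
        inp = config.inputs or {}
        lib_path = inp.get("matrix_library")
        if lib_path is None:
            raise InputError("inputs.matrix_library is required")
        lib = parse_matrix_library(
            Path(lib_path).read_text(), inp.get("matrix_format", "transfac")
        )
        paths["library"].write_text(write_matrix_library(lib, "transfac"))
        cog_table = read_cog_table(inp["cog_table"])
        cog_table.to_csv(paths["cog_table"], sep="\t", index=False)
        if "promoters_fasta" in inp:
            proms = promoters_from_fasta(Path(inp["promoters_fasta"]).read_text())
        else:
            genome = read_genome_fasta(inp["genome_fasta"])
            tss = read_tss_table(inp["annotations"], inp.get("annotations_format"))
            proms = extract_promoters(genome, tss, cog_table, window=config.window)
        paths["promoters"].write_text(promoters_to_fasta(proms))

    inputs_outputs = [paths["promoters"], paths["cog_table"], paths["library"]]
    if config.synthetic is not None:
        inputs_outputs.append(paths["manifest"])
    key_inputs = do_stage(
        "inputs",
        {"window": list(config.window), "seed": config.seed,
         "synthetic": config.synthetic, "inputs_hash": external_input_hash()},
        "",
        tuple(inputs_outputs),
        stage_inputs,
    )

    def load_promoters():
        return promoters_from_fasta(paths["promoters"].read_text())

    def load_library():
        return parse_matrix_library(paths["library"].read_text(), "transfac")

    def load_hits() -> list[MotifHit]:
        hits = []
        for line in paths["hits_jsonl"].read_text().splitlines():
            d = json.loads(line)
            hits.append(
                MotifHit(
                    matrix_id=d["matrix_id"], class_label=d["class"],
                    gene_id=d["gene_id"], start_rel=d["start_rel"],
                    strand=d["strand"], core_sim=d["core_sim"],
                    mat_sim=d["mat_sim"], evalue=d["evalue"],
                )
            )
        return hits

    # ---- stage: scan ---------------------------------------------------
    def stage_scan() -> None:
        proms = load_promoters()
        lib = load_library()
        thr = config.scan.get("thresholds")
        bg = config.scan.get("background", "auto")
        if isinstance(bg, list):
            bg = tuple(bg)
        hits = scan_promoters(
            lib, proms,
            thresholds=tuple(thr) if thr else None,
            background=bg,
            evalue_cutoff=config.scan.get("evalue_cutoff", 1e-3),
            cutoff_scale=config.scan.get("cutoff_scale", "site"),
        )
        paths["hits_jsonl"].write_text(hits_to_jsonl(hits))
        lengths = {m.id: m.length for m in lib}
        paths["hits_bed"].write_text(
            hits_to_bed(hits, lengths, shift=-config.window[0])
        )

    key_scan = do_stage(
        "scan", config.scan, key_inputs,
        (paths["hits_jsonl"], paths["hits_bed"]), stage_scan,
    )

    # ---- stage: occurrence --------------------------------------------
    def stage_occurrence() -> None:
        occ = build_occurrence_matrix(
            load_hits(), load_promoters(), load_library().class_map
        )
        paths["occurrence"].write_text(occ.to_tsv())

    key_occ = do_stage(
        "occurrence", {}, key_scan, (paths["occurrence"],), stage_occurrence
    )

    # ---- stage: classify ----------------------------------------------
    def stage_classify() -> None:
        occ = OccurrenceMatrix.from_tsv(paths["occurrence"].read_text())
        cog_table = read_cog_table(paths["cog_table"])
        cogs = cog_definitions_from_table(cog_table)
        reports = classify_cogs(occ, cogs)
        rows = pd.concat(
            [r.to_rows() for r in reports.values()], ignore_index=True
        ) if reports else pd.DataFrame(columns=["cog_id", "class", "category", "detail"])
        rows.to_csv(paths["categories"], sep="\t", index=False)
        counts = summarize_counts(reports, occ, cogs)
        counts.to_csv(paths["counts"], sep="\t", index_label="row")
        unique = counts.loc[[r for r in counts.index if r.endswith(" only")]]
        unique.index = [r.split()[2] for r in unique.index]
        chis = information_content_tests(unique)
        chis.to_csv(paths["chisq"], sep="\t", index=False, float_format="%.6g")

    key_cls = do_stage(
        "classify", {}, key_occ,
        (paths["categories"], paths["counts"], paths["chisq"]), stage_classify,
    )

    # ---- stage: modules -------------------------------------------------
    def stage_modules() -> None:
        hits = load_hits()
        cog_table = read_cog_table(paths["cog_table"])
        cogs = cog_definitions_from_table(cog_table)
        by_gene: dict[str, list[MotifHit]] = {}
        for h in hits:
            by_gene.setdefault(h.gene_id, []).append(h)
        mp = config.modules
        all_modules = []
        renders = []
        for cog in cogs:
            cog_hits = {g: by_gene.get(g, []) for g in cog.ortholog_genes}
            par_hits = {g: by_gene.get(g, []) for g in cog.paralogs}
            if len(cog_hits) < 2:
                continue
            mods = detect_core_modules(
                cog_hits, par_hits,
                k_range=(mp.get("k_min", 2), mp.get("k_max", 4)),
                max_gap=mp.get("max_gap", 150),
                max_span=mp.get("max_span", 400),
                gap_tolerance=mp.get("gap_tolerance", 10),
                cog_id=cog.cog_id,
            )
            all_modules.extend(mods)
            for m in mods:
                renders.append(f"# COG {cog.cog_id}\n" + render_module_alignment(m))
        paths["modules_json"].write_text(
            json.dumps([m.to_dict() for m in all_modules], indent=1, sort_keys=True)
        )
        paths["modules_txt"].write_text("\n".join(renders) + ("\n" if renders else ""))

    key_mod = do_stage(
        "modules", config.modules, key_cls,
        (paths["modules_json"], paths["modules_txt"]), stage_modules,
    )

    # ---- stage: cluster -------------------------------------------------
    def stage_cluster() -> None:
        occ = OccurrenceMatrix.from_tsv(paths["occurrence"].read_text())
        cog_table = read_cog_table(paths["cog_table"])
        cogs = cog_definitions_from_table(cog_table)
        lines = []
        for cog in cogs:
            genes = [g for g in (*cog.ortholog_genes, *cog.paralogs) if g in occ.genes]
            if len(genes) < 2:
                continue
            sub = occ.subset_genes(genes)
            if sub.data.size == 0 or sub.data.values.sum() == 0:
                continue
            dendro = cluster_occurrence(
                sub, axis="genes",
                metric=config.cluster.get("metric", "jaccard"),
                linkage=config.cluster.get("linkage", "average"),
            )
            lines.append(f"{cog.cog_id}\t{dendro.to_newick()}")
        paths["newick"].write_text("\n".join(lines) + ("\n" if lines else ""))

    key_clu = do_stage(
        "cluster", config.cluster, key_mod, (paths["newick"],), stage_cluster
    )

    # ---- stage: summary -------------------------------------------------
    def stage_summary() -> None:
        meta = {
            "tool": "phylofoot",
            "version": __version__,
            "formula_version": FORMULA_VERSION,
            "window": list(config.window),
            "evalue_cutoff": config.scan.get("evalue_cutoff", 1e-3),
            "cutoff_scale": config.scan.get("cutoff_scale", "site"),
            "config": config.to_dict(),
        }
        paths["metadata"].write_text(json.dumps(meta, indent=1, sort_keys=True))
        if paths["manifest"].exists() and config.synthetic is not None:
            manifest = TruthManifest.from_json(paths["manifest"].read_text())
            modules = json.loads(paths["modules_json"].read_text())
            by_cog: dict[str, list] = {}
            for m in modules:
                key = tuple(zip(m["class_sequence"], m["strand_pattern"]))

                class _K:  # minimal stand-in with a .key attribute
                    pass

                k = _K()
                k.key = key
                by_cog.setdefault(m["cog_id"], []).append(k)
            occ = OccurrenceMatrix.from_tsv(paths["occurrence"].read_text())
            cogs = cog_definitions_from_table(read_cog_table(paths["cog_table"]))
            reports = classify_cogs(occ, cogs)
            rec_m, exp_m = score_module_recovery(manifest, by_cog)
            rec_c, exp_c = score_category_recovery(manifest, reports)
            paths["recovery"].write_text(
                json.dumps(
                    {
                        "modules_recovered": rec_m,
                        "modules_expected": exp_m,
                        "categories_correct": rec_c,
                        "categories_expected": exp_c,
                    },
                    indent=1,
                    sort_keys=True,
                )
            )

    summary_outputs = [paths["metadata"]]
    if config.synthetic is not None:
        summary_outputs.append(paths["recovery"])
    do_stage("summary", {}, key_clu, tuple(summary_outputs), stage_summary)

    paths["keys"].write_text(json.dumps(new_keys, indent=1, sort_keys=True))
    _finalize_checksums(out, paths, summary)
    return summary


def _finalize_checksums(out: Path, paths: dict, summary: dict) -> None:
    checks = {
        p.name: _sha256_file(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("checksums.json",)
    }
    paths["checksums"].write_text(json.dumps(checks, indent=1, sort_keys=True))
    summary["files"] = sorted(checks)


def run_synthetic_replicate(design, detect_params: dict | None = None) -> dict:
    """Simulate one design, run the in-memory analysis and score recovery.

    Returns planted-module recall counts, category-label counts and the
    per-COG ortholog dendrogram first merges — the quantities the
    synthetic validation experiments summarize over replicates.
    """
    dp = {"gap_tolerance": 10}
    if detect_params:
        dp.update(detect_params)
    ds = simulate_cog_dataset(design)
    hits = scan_promoters(
        ds.library, ds.promoters, background=tuple(design.background)
    )
    occ = build_occurrence_matrix(hits, ds.promoters, ds.library.class_map)
    cogs = cog_definitions_from_table(ds.cog_table)
    reports = classify_cogs(occ, cogs)
    by_gene: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    modules_by_cog = {}
    for cog in cogs:
        modules_by_cog[cog.cog_id] = detect_core_modules(
            {g: by_gene.get(g, []) for g in cog.ortholog_genes},
            {g: by_gene.get(g, []) for g in cog.paralogs},
            cog_id=cog.cog_id,
            **dp,
        )
    rec_m, exp_m = score_module_recovery(ds.manifest, modules_by_cog)
    rec_c, exp_c = score_category_recovery(ds.manifest, reports)
    first_merges = {}
    for cog in cogs:
        sub = occ.subset_genes(list(cog.ortholog_genes))
        if sub.data.values.sum() == 0:
            continue
        dendro = cluster_occurrence(sub, axis="genes")
        first_merges[cog.cog_id] = frozenset(dendro.first_merge)
    return {
        "dataset": ds,
        "modules_recovered": rec_m,
        "modules_expected": exp_m,
        "categories_correct": rec_c,
        "categories_expected": exp_c,
        "first_merges": first_merges,
    }
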