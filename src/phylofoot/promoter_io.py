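"""Promoter extraction and file formats.

Coordinate conventions
----------------------
Internally all genomic coordinates are 0-based, half-open.  GFF3 input is
1-based inclusive; BED input is 0-based half-open.  The transcription
start site (TSS) is relative position 0, so the default window
``[-1000, +200)`` yields a 1,200-nt promoter with the TSS base as its
1,001st character.  Sequences are always reported 5'->3' in gene
orientation: minus-strand genes are reverse-complemented so the window
reads toward and into the transcript.

Formats handled here: FASTA genomes and promoter sets (Biopython),
GFF3/BED TSS records, a TSV ortholog-group (COG) membership table, and
binding-site matrix libraries in a TRANSFAC dialect or a plain TSV
position-frequency dialect.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .errors import InputError
from .motif_scan import MotifMatrix

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ROLES = ("ortholog", "paralog", "unknown")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterSequence:
    """A promoter window in gene orientation with TSS-relative coordinates."""

    gene_id: str
    species: str
    lineage: str
    role: str
    cog_id: str | None
    seq: str
    window_start_rel: int = -1000
    window_end_rel: int = 200
    source_contig: str = ""
    source_strand: str = "+"
    truncated: bool = False
    tss_source: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InputError(f"{self.gene_id}: role must be one of {ROLES}")
        if not (self.window_start_rel < 0 <= self.window_end_rel):
            raise InputError(
                f"{self.gene_id}: window must straddle the TSS "
                f"(start_rel < 0 <= end_rel)"
            )
        if len(self.seq) != self.window_end_rel - self.window_start_rel:
            raise InputError(
                f"{self.gene_id}: sequence length {len(self.seq)} does not "
                f"match window [{self.window_start_rel}, {self.window_end_rel})"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TSSRecord:
    """One annotated transcription start: 0-based TSS position on a contig."""

    gene_id: str
    contig: str
    tss: int
    strand: str
    source: str = ""


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Genome FASTA as a contig-id -> uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def parse_tss_gff3(text: str, feature_types: Sequence[str] = ("gene", "mRNA", "transcript")) -> list[TSSRecord]:
    """TSS records from GFF3 text (1-based inclusive coordinates).

    The TSS is the feature start on the plus strand and the feature end on
    the minus strand.  The gene id is the ``ID`` attribute (``Name`` as a
    fallback).
    """
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # malformed GFF line
            raise InputError(f"GFF3 line {lineno}: {exc}") from exc
        if feat.featuretype not in feature_types:
            continue
        gid = (feat.attributes.get("ID") or feat.attributes.get("Name") or [None])[0]
        if gid is None:
            raise InputError(f"GFF3 line {lineno}: feature has no ID/Name attribute")
        if feat.strand not in "+-":
            raise InputError(f"GFF3 line {lineno}: feature {gid} lacks a strand")
        tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
        records.append(
            TSSRecord(gene_id=gid, contig=feat.seqid, tss=tss, strand=feat.strand,
                      source=feat.source)
        )
    return records


def parse_tss_bed(text: str) -> list[TSSRecord]:
    """TSS records from 6-column BED (0-based half-open)."""
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise InputError(f"BED line {lineno}: expected 6 columns")
        contig, start, end, name, _score, strand = fields[:6]
        if strand not in "+-":
            raise InputError(f"BED line {lineno}: invalid strand {strand!r}")
        tss = int(start) if strand == "+" else int(end) - 1
        records.append(TSSRecord(gene_id=name, contig=contig, tss=tss, strand=strand,
                                 source="bed"))
    return records


def read_tss_table(path: str | Path, fmt: str | None = None) -> list[TSSRecord]:
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    text = path.read_text()
    if fmt == "gff3":
        return parse_tss_gff3(text)
    if fmt == "bed":
        return parse_tss_bed(text)
    raise InputError(f"unknown TSS table format {fmt!r}")


COG_COLUMNS = ["gene_id", "species", "lineage", "role", "cog_id"]


def read_cog_table(source: str | Path | io.StringIO) -> pd.DataFrame:
    """COG membership TSV with columns gene_id, species, lineage, role, cog_id."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in COG_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"COG table missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise InputError(f"COG table has duplicate gene ids: {dups}")
    bad = ~df["role"].isin(["ortholog", "paralog"])
    if bad.any():
        raise InputError(
            f"COG table roles must be ortholog/paralog; offending rows: "
            f"{df.loc[bad, 'gene_id'].tolist()}"
        )
    return df[COG_COLUMNS]


def extract_promoters(
    genome: Mapping[str, str],
    tss_records: Iterable[TSSRecord],
    cog_table: pd.DataFrame | None = None,
    window: tuple[int, int] = (-1000, 200),
) -> list[PromoterSequence]:
    """Cut a TSS-relative window out of the genome for every annotated gene.

    Minus-strand genes are reverse-complemented so the returned sequence
    reads 5'->3' toward the TSS and into the transcript.  Windows that
    run past a contig edge are truncated (the realized relative window is
    recorded and the ``truncated`` flag set).  Genes missing from the COG
    table get ``cog_id=None`` with a warning; a missing contig or a TSS
    outside its contig is a hard error.
    """
    ws, we = window
    if not ws < we:
        raise InputError("window start must be < window end")
    if not (ws < 0 <= we):
        raise InputError("window must straddle the TSS (start < 0 <= end)")
    meta = None
    if cog_table is not None:
        meta = cog_table.set_index("gene_id")
    out = []
    for rec in tss_records:
        if rec.contig not in genome:
            raise InputError(
                f"gene {rec.gene_id}: contig {rec.contig!r} not in genome"
            )
        contig = genome[rec.contig]
        if not 0 <= rec.tss < len(contig):
            raise InputError(
                f"gene {rec.gene_id}: TSS {rec.tss} outside contig "
                f"{rec.contig!r} (length {len(contig)})"
            )
        if rec.strand == "+":
            lo, hi = rec.tss + ws, rec.tss + we
        else:
            lo, hi = rec.tss - we + 1, rec.tss - ws + 1
        clo, chi = max(lo, 0), min(hi, len(contig))
        truncated = (clo, chi) != (lo, hi)
        piece = contig[clo:chi]
        if rec.strand == "+":
            seq = piece
            rws, rwe = clo - rec.tss, chi - rec.tss
        else:
            seq = reverse_complement(piece)
            rws, rwe = rec.tss - chi + 1, rec.tss - clo + 1
        if meta is not None and rec.gene_id in meta.index:
            row = meta.loc[rec.gene_id]
            species, lineage, role = row["species"], row["lineage"], row["role"]
            cog_id = row["cog_id"] if pd.notna(row["cog_id"]) else None
        else:
            if meta is not None:
                warnings.warn(
                    f"gene {rec.gene_id} absent from COG table; emitting with "
                    f"cog_id=None",
                    stacklevel=2,
                )
            species, lineage, role, cog_id = "", "", "unknown", None
        out.append(
            PromoterSequence(
                gene_id=rec.gene_id,
                species=species,
                lineage=lineage,
                role=role,
                cog_id=cog_id,
                seq=seq,
                window_start_rel=rws,
                window_end_rel=rwe,
                source_contig=rec.contig,
                source_strand=rec.strand,
                truncated=truncated,
                tss_source=rec.source,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Promoter FASTA with structured headers
# ---------------------------------------------------------------------------

_HEADER_FIELDS = (
    "species",
    "lineage",
    "role",
    "cog_id",
    "window_start_rel",
    "window_end_rel",
    "source_contig",
    "source_strand",
    "truncated",
    "tss_source",
)


def promoters_to_fasta(promoters: Iterable[PromoterSequence]) -> str:
    """FASTA text with ``key=value`` metadata in the description line."""
    chunks = []
    for p in promoters:
        fields = []
        for name in _HEADER_FIELDS:
            v = getattr(p, name)
            if v is None:
                v = ""
            elif isinstance(v, bool):
                v = int(v)
            fields.append(f"{name}={v}")
        chunks.append(f">{p.gene_id} " + " ".join(fields))
        for i in range(0, len(p.seq), 70):
            chunks.append(p.seq[i : i + 70])
    return "\n".join(chunks) + "\n"


def promoters_from_fasta(text: str) -> list[PromoterSequence]:
    out = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        kv = dict(
            f.split("=", 1) for f in rec.description.split()[1:] if "=" in f
        )
        out.append(
            PromoterSequence(
                gene_id=rec.id,
                species=kv.get("species", ""),
                lineage=kv.get("lineage", ""),
                role=kv.get("role", "unknown"),
                cog_id=kv.get("cog_id") or None,
                seq=str(rec.seq).upper(),
                window_start_rel=int(kv.get("window_start_rel", -1000)),
                window_end_rel=int(kv.get("window_end_rel", 200)),
                source_contig=kv.get("source_contig", ""),
                source_strand=kv.get("source_strand", "+"),
                truncated=bool(int(kv.get("truncated", 0))),
                tss_source=kv.get("tss_source", ""),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Matrix libraries
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class MatrixLibrary:
    """Ordered collection of binding-site matrices with a class mapping."""

    matrices: tuple[MotifMatrix, ...]

    def __post_init__(self) -> None:
        self.matrices = tuple(self.matrices)
        ids = [m.id for m in self.matrices]
        if len(set(ids)) != len(ids):
            raise InputError("matrix ids must be unique")

    @property
    def class_map(self) -> dict[str, str]:
        return {m.id: m.class_label for m in self.matrices}

    @property
    def classes(self) -> list[str]:
        return sorted({m.class_label for m in self.matrices})

    def __iter__(self):
        return iter(self.matrices)

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, matrix_id: str) -> MotifMatrix:
        for m in self.matrices:
            if m.id == matrix_id:
                return m
        raise KeyError(matrix_id)


def _normalize_rows(rows: list[list[float]], matrix_id: str, pseudocount: float,
                    first_line: int) -> np.ndarray:
    freqs = []
    for offset, row in enumerate(rows):
        arr = np.asarray(row, dtype=float)
        if np.any(arr < 0):
            raise InputError(
                f"matrix {matrix_id}, line {first_line + offset}: negative counts"
            )
        total = arr.sum()
        if total == 0:
            raise InputError(
                f"matrix {matrix_id}, line {first_line + offset}: zero-depth position"
            )
        if abs(total - 1.0) <= 1e-6:
            freqs.append(arr / total)  # already probabilities
        else:
            freqs.append((arr + pseudocount) / (total + 4 * pseudocount))
    return np.vstack(freqs)


def parse_matrix_library(
    text: str,
    fmt: str = "transfac",
    pseudocount: float = 0.5,
    core_len: int = 4,
    default_thresholds: tuple[float, float] = (0.75, 0.85),
) -> MatrixLibrary:
    """Parse a matrix library from TRANSFAC-dialect or plain TSV PFM text.

    Count rows get ``pseudocount`` added before normalization; rows that
    already sum to 1 are taken as probabilities verbatim (so written
    libraries round-trip).  The TFBS class label is the ID prefix before
    the first underscore in the TRANSFAC dialect, or the explicit class
    column in the TSV dialect.  Optional per-matrix optimized thresholds
    are honoured (``TH core matrix`` line / threshold columns).
    """
    if not text.strip():
        raise InputError("matrix library text is empty")
    if fmt == "transfac":
        return _parse_transfac(text, pseudocount, core_len, default_thresholds)
    if fmt == "pfm_tsv":
        return _parse_pfm_tsv(text, pseudocount, core_len, default_thresholds)
    raise InputError(f"unknown matrix library format {fmt!r}")


def _parse_transfac(text, pseudocount, core_len, default_thresholds) -> MatrixLibrary:
    matrices = []
    block: dict = {}
    rows: list[list[float]] = []
    first_row_line = 0

    def flush(lineno):
        if not block and not rows:
            return
        mid = block.get("AC") or block.get("ID")
        if mid is None:
            raise InputError(f"matrix block ending at line {lineno} has no AC/ID")
        if not rows:
            raise InputError(f"matrix {mid}: no count rows")
        name = block.get("ID", mid)
        class_label = block.get("class") or name.split("_")[0]
        ct, mt = block.get("TH", default_thresholds)
        matrices.append(
            MotifMatrix(
                id=name,
                class_label=class_label,
                freqs=_normalize_rows(rows, name, pseudocount, first_row_line),
                core_len=core_len,
                core_threshold=ct,
                matrix_threshold=mt,
            )
        )

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line == "XX":
            continue
        if line.startswith("//"):
            flush(lineno)
            block, rows, first_row_line = {}, [], 0
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag in ("AC", "ID", "DE", "BF"):
            block[tag] = rest
        elif tag == "CC":
            if rest.startswith("class="):
                block["class"] = rest.split("=", 1)[1].strip()
        elif tag == "TH":
            parts = rest.split()
            if len(parts) != 2:
                raise InputError(f"line {lineno}: TH expects two thresholds")
            block["TH"] = (float(parts[0]), float(parts[1]))
        elif tag == "P0" or tag == "PO":
            continue
        elif tag[:1].isdigit():
            tokens = line.split()
            vals = []
            for t in tokens[1:5]:
                try:
                    vals.append(float(t))
                except ValueError as exc:
                    raise InputError(f"line {lineno}: malformed count row") from exc
            if len(vals) != 4:
                raise InputError(f"line {lineno}: expected 4 base counts")
            if not rows:
                first_row_line = lineno
            rows.append(vals)
        else:
            raise InputError(f"line {lineno}: unrecognised TRANSFAC tag {tag!r}")
    flush(lineno if text.strip() else 0)
    return MatrixLibrary(tuple(matrices))


def _parse_pfm_tsv(text, pseudocount, core_len, default_thresholds) -> MatrixLibrary:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"matrix_id": str, "class": str})
    needed = ["matrix_id", "class", "pos", "A", "C", "G", "T"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(f"PFM TSV missing columns: {missing}")
    matrices = []
    for mid in df["matrix_id"].drop_duplicates():
        sub = df[df["matrix_id"] == mid].sort_values("pos")
        if list(sub["pos"]) != list(range(1, len(sub) + 1)):
            raise InputError(f"matrix {mid}: pos column must run 1..L")
        rows = sub[["A", "C", "G", "T"]].values.tolist()
        ct, mt = default_thresholds
        if "core_threshold" in sub.columns and sub["core_threshold"].notna().all():
            ct = float(sub["core_threshold"].iloc[0])
        if "matrix_threshold" in sub.columns and sub["matrix_threshold"].notna().all():
            mt = float(sub["matrix_threshold"].iloc[0])
        matrices.append(
            MotifMatrix(
                id=mid,
                class_label=str(sub["class"].iloc[0]),
                freqs=_normalize_rows(rows, mid, pseudocount, 0),
                core_len=core_len,
                core_threshold=ct,
                matrix_threshold=mt,
            )
        )
    return MatrixLibrary(tuple(matrices))


def write_matrix_library(library: MatrixLibrary, fmt: str = "transfac") -> str:
    """Serialize a library; frequencies are written at full precision so a
    parse of the output reproduces them to better than 1e-12."""
    if fmt == "transfac":
        chunks = []
        for m in library:
            chunks.append(f"AC {m.id}")
            chunks.append("XX")
            chunks.append(f"ID {m.id}")
            chunks.append(f"CC class={m.class_label}")
            chunks.append(f"TH {m.core_threshold:.6g} {m.matrix_threshold:.6g}")
            chunks.append("P0      A      C      G      T")
            for i, row in enumerate(m.freqs, start=1):
                chunks.append(
                    f"{i:02d} " + " ".join(f"{v:.17g}" for v in row)
                )
            chunks.append("XX")
            chunks.append("//")
        return "\n".join(chunks) + "\n"
    if fmt == "pfm_tsv":
        lines = [
            "matrix_id\tclass\tpos\tA\tC\tG\tT\tcore_threshold\tmatrix_threshold"
        ]
        for m in library:
            for i, row in enumerate(m.freqs, start=1):
                vals = "\t".join(f"{v:.17g}" for v in row)
                lines.append(
                    f"{m.id}\t{m.class_label}\t{i}\t{vals}\t"
                    f"{m.core_threshold:.6g}\t{m.matrix_threshold:.6g}"
                )
        return "\n".join(lines) + "\n"
    raise InputError(f"unknown matrix library format {fmt!r}")
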