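"""Conservation-weighted PWM scanning of promoter windows.

A binding-site model is a position frequency matrix over {A, C, G, T}.
Each position ``i`` carries a conservation weight

    ci(i) = (100 / ln 4) * (ln 4 + sum_b f(i, b) * ln f(i, b))

ranging from 0 (uninformative, uniform position) to 100 (invariant
position).  A candidate window ``s`` is scored by the weighted similarity

    mat_sim(s) = sum_i ci(i) * f(i, s_i) / sum_i ci(i) * max_b f(i, b)

so the per-position consensus scores exactly 1.  ``core_sim`` is the same
quantity restricted to the contiguous run of ``core_len`` positions with
the largest summed conservation weight (the matrix "core").  A window is a
hit when both similarities reach their thresholds.

Statistical filtering uses the exact probability, under an i.i.d.
background, that a random window of matrix length passes both thresholds
(``site_match_pvalue``).  The expected number of such chance hits in the
scanned promoter (both strands) is reported on every hit as its e-value.
By default the significance cutoff is applied to the per-site probability:
for 6-8 nt matrices the expected chance-hit count in a 1,200-nt window
cannot drop below ~0.04 even for a perfectly specific matrix, so a cutoff
of 1e-3 is only meaningful on the per-site scale (``cutoff_scale`` selects
the promoter-scale expected count instead).

TFBS occurrence is summarised per promoter as a binary class-by-gene
matrix: 1 for single- to multi-copy occurrence of any matrix of the class,
0 for absence.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

if TYPE_CHECKING:  # pragma: no cover
    from .promoter_io import PromoterSequence

logger = logging.getLogger(__name__)

BASES = "ACGT"
#: Encoding used throughout: A,C,G,T -> 0..3, N (and anything else) -> 4.
BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}

_LN4 = math.log(4.0)

#: Slack used in every ``score >= threshold`` comparison so that windows
#: sitting exactly on a threshold are treated identically regardless of
#: floating-point summation order.
SCORE_TOL = 1e-9

#: Identifier of the similarity-score formulation, recorded in output
#: metadata so result bundles are self-describing.
FORMULA_VERSION = "ci-weighted-similarity/1"

_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENC_TABLE[ord(_b)] = _i
    _ENC_TABLE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, N -> 4)."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def conservation_vector(freqs: np.ndarray) -> np.ndarray:
    """Per-position conservation weight in [0, 100].

    Uniform positions score 0; invariant positions score 100.  The
    convention 0 * ln 0 := 0 is applied.
    """
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 2 or f.shape[1] != 4:
        raise InputError("frequency table must have shape (L, 4)")
    if np.any(f < 0) or np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-6):
        raise InputError("frequency rows must be probabilities summing to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log(f), 0.0)
    ci = (100.0 / _LN4) * (_LN4 + plogp.sum(axis=1))
    return np.clip(ci, 0.0, 100.0)


@dataclass(eq=False)
class MotifMatrix:
    """A PWM with conservation weights, core positions and thresholds.

    Parameters
    ----------
    id : unique matrix identifier (e.g. ``"GBOX_01"``).
    class_label : TFBS class (family) the matrix belongs to.
    freqs : (L, 4) per-position nucleotide probabilities.
    core_len : length of the high-conservation core (default 4).
    core_threshold, matrix_threshold : minimum similarities for a hit.
    core_start : first core position; derived from the conservation
        weights (leftmost maximal-sum window) when not given explicitly.
    """

    id: str
    class_label: str
    freqs: np.ndarray
    core_len: int = 4
    core_threshold: float = 0.75
    matrix_threshold: float = 0.85
    core_start: int | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise InputError(f"matrix {self.id}: freqs must have shape (L, 4)")
        if self.length < 4:
            raise InputError(f"matrix {self.id}: length must be >= 4")
        if not 1 <= self.core_len <= self.length:
            raise InputError(f"matrix {self.id}: core_len out of range")
        sums = self.freqs.sum(axis=1)
        if np.any(self.freqs < 0) or np.any(np.abs(sums - 1.0) > 1e-6):
            raise InputError(f"matrix {self.id}: rows must sum to 1")
        self.freqs = self.freqs / sums[:, None]
        self.ci = conservation_vector(self.freqs)
        if self.core_start is None:
            window_sums = np.convolve(self.ci, np.ones(self.core_len), "valid")
            self.core_start = int(np.argmax(window_sums))  # leftmost on ties
        if not 0 <= self.core_start <= self.length - self.core_len:
            raise InputError(f"matrix {self.id}: core_start out of range")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def core_positions(self) -> range:
        return range(self.core_start, self.core_start + self.core_len)

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.freqs.argmax(axis=1))

    @cached_property
    def _weights5(self) -> np.ndarray:
        """(L, 5) table of ci * f contributions; the N column is zero."""
        w = self.ci[:, None] * self.freqs
        return np.hstack([w, np.zeros((self.length, 1))])

    @cached_property
    def matrix_denominator(self) -> float:
        return float((self.ci * self.freqs.max(axis=1)).sum())

    @cached_property
    def core_denominator(self) -> float:
        sl = slice(self.core_start, self.core_start + self.core_len)
        return float((self.ci[sl] * self.freqs[sl].max(axis=1)).sum())

    @cached_property
    def reverse_complement(self) -> "MotifMatrix":
        """The same matrix on the opposite strand (core positions mirrored)."""
        return MotifMatrix(
            id=self.id,
            class_label=self.class_label,
            freqs=self.freqs[::-1, ::-1],
            core_len=self.core_len,
            core_threshold=self.core_threshold,
            matrix_threshold=self.matrix_threshold,
            core_start=self.length - self.core_len - self.core_start,
        )


def _similarity(matrix: MotifMatrix, enc: np.ndarray, core_only: bool) -> float:
    if core_only:
        sl = slice(matrix.core_start, matrix.core_start + matrix.core_len)
        denom = matrix.core_denominator
        rows = np.arange(sl.start, sl.stop)
        enc = enc[sl]
    else:
        denom = matrix.matrix_denominator
        rows = np.arange(matrix.length)
    if denom == 0.0:
        return 0.0
    return float(matrix._weights5[rows, enc].sum() / denom)


def matrix_similarity(matrix: MotifMatrix, window_seq: str | np.ndarray) -> float:
    """Conservation-weighted similarity of ``window_seq`` to the full matrix.

    Returns 0 for an entirely uninformative (uniform) matrix.  ``N`` bases
    contribute 0 at their position.
    """
    enc = window_seq if isinstance(window_seq, np.ndarray) else encode_sequence(window_seq)
    if len(enc) != matrix.length:
        raise InputError(
            f"window length {len(enc)} != matrix length {matrix.length}"
        )
    return _similarity(matrix, enc, core_only=False)


def core_similarity(matrix: MotifMatrix, window_seq: str | np.ndarray) -> float:
    """Similarity restricted to the matrix core positions."""
    enc = window_seq if isinstance(window_seq, np.ndarray) else encode_sequence(window_seq)
    if len(enc) != matrix.length:
        raise InputError(
            f"window length {len(enc)} != matrix length {matrix.length}"
        )
    return _similarity(matrix, enc, core_only=True)


def _enumerate_sums(weights: np.ndarray, bg: np.ndarray):
    """Distribution of sum_i w[i, b_i] over i.i.d. base choices.

    Sums are accumulated in ascending position order so they agree bitwise
    with a direct per-window summation in the same order.  Returns
    (sums, probs) with duplicate sums merged.
    """
    sums = np.zeros(1)
    probs = np.ones(1)
    for row in weights:
        sums = (sums[:, None] + row[None, :]).ravel()
        probs = (probs[:, None] * bg[None, :]).ravel()
        if sums.size > 4096:
            uniq, inv = np.unique(sums, return_inverse=True)
            probs = np.bincount(inv, weights=probs)
            sums = uniq
    uniq, inv = np.unique(sums, return_inverse=True)
    return uniq, np.bincount(inv, weights=probs)


def site_match_pvalue(
    matrix: MotifMatrix,
    background: Sequence[float] | None = None,
    thresholds: tuple[float, float] | None = None,
    granularity: float | None = None,
) -> float:
    """Exact probability that a random window passes both thresholds.

    The null model draws each of the L bases i.i.d. from ``background``.
    The joint constraint (core similarity and matrix similarity) is
    evaluated by enumerating the 4**core_len core assignments exactly and
    convolving the non-core positions with a sparse-sum dynamic programme,
    so the result matches exhaustive 4**L enumeration bit-for-bit for the
    matrix lengths used here.  ``granularity``, when given, rounds partial
    sums to that resolution to bound the state space for long matrices.
    """
    bg = np.asarray(background if background is not None else [0.25] * 4, float)
    if bg.shape != (4,) or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-6:
        raise InputError("background must be 4 non-negative probabilities summing to 1")
    bg = bg / bg.sum()
    ct, mt = thresholds if thresholds is not None else (
        matrix.core_threshold,
        matrix.matrix_threshold,
    )

    denom_m = matrix.matrix_denominator
    if denom_m == 0.0:
        # Entirely uninformative matrix: every similarity is 0 by convention.
        return 1.0 if (0.0 >= ct - SCORE_TOL and 0.0 >= mt - SCORE_TOL) else 0.0

    L = matrix.length
    core = list(matrix.core_positions)
    noncore = [i for i in range(L) if i not in matrix.core_positions]
    wmat = matrix._weights5[:, :4] / denom_m
    wcore = matrix._weights5[core, :4] / matrix.core_denominator
    if granularity:
        wmat = np.round(wmat / granularity) * granularity
        wcore = np.round(wcore / granularity) * granularity

    # All 4**core_len core assignments: core similarity, the core part of the
    # matrix similarity, and their probabilities.
    core_sums = np.zeros(1)
    mat_parts = np.zeros(1)
    core_probs = np.ones(1)
    for k, i in enumerate(core):
        core_sums = (core_sums[:, None] + wcore[k][None, :]).ravel()
        mat_parts = (mat_parts[:, None] + wmat[i][None, :]).ravel()
        core_probs = (core_probs[:, None] * bg[None, :]).ravel()

    nc_sums, nc_probs = _enumerate_sums(wmat[noncore], bg)
    order = np.argsort(nc_sums)
    nc_sums = nc_sums[order]
    # suffix[i] = P(non-core sum >= nc_sums[i])
    suffix = np.concatenate([np.cumsum(nc_probs[order][::-1])[::-1], [0.0]])

    passing = core_sums >= ct - SCORE_TOL
    if not np.any(passing):
        return 0.0
    needed = (mt - SCORE_TOL) - mat_parts[passing]
    idx = np.searchsorted(nc_sums, needed, side="left")
    return float((core_probs[passing] * suffix[idx]).sum())


@dataclass(frozen=True)
class MotifHit:
    """One retained site occurrence on a promoter.

    ``start_rel`` is the TSS-relative position of matrix position 1 in the
    promoter (plus-strand) frame, for hits on either strand.  ``evalue``
    is the expected number of chance hits of this matrix in the scanned
    promoter (both strands).
    """

    matrix_id: str
    class_label: str
    gene_id: str
    start_rel: int
    strand: str
    core_sim: float
    mat_sim: float
    evalue: float


def _window_scores(matrix: MotifMatrix, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mat_sim, core_sim) for every window of the encoded sequence."""
    L = matrix.length
    wins = np.lib.stride_tricks.sliding_window_view(enc, L)
    w5 = matrix._weights5
    rows = np.arange(L)
    if matrix.matrix_denominator == 0.0:
        n = wins.shape[0]
        return np.zeros(n), np.zeros(n)
    mat = w5[rows, wins].sum(axis=1) / matrix.matrix_denominator
    sl = slice(matrix.core_start, matrix.core_start + matrix.core_len)
    core = w5[rows[sl], wins[:, sl]].sum(axis=1) / matrix.core_denominator
    return mat, core


def scan_promoter(
    matrix: MotifMatrix,
    promoter: "PromoterSequence",
    thresholds: tuple[float, float] | None = None,
    background: Sequence[float] | None = None,
    evalue_cutoff: float | None = 1e-3,
    cutoff_scale: str = "site",
    _pvalue: float | None = None,
) -> list[MotifHit]:
    """Scan both strands of a promoter window for significant matrix hits.

    Hits must pass the core and matrix similarity thresholds; the whole
    matrix is discarded for this promoter when its significance (per-site
    match probability, or promoter-scale expected hit count when
    ``cutoff_scale="promoter"``) exceeds ``evalue_cutoff``.  Overlapping
    hits are all reported.  Hits are sorted by position.
    """
    if cutoff_scale not in ("site", "promoter"):
        raise InputError("cutoff_scale must be 'site' or 'promoter'")
    L = matrix.length
    n = len(promoter.seq) - L + 1
    if n < 1:
        raise InputError(
            f"promoter {promoter.gene_id} shorter than matrix {matrix.id}"
        )
    ct, mt = thresholds if thresholds is not None else (
        matrix.core_threshold,
        matrix.matrix_threshold,
    )
    p = _pvalue if _pvalue is not None else site_match_pvalue(
        matrix, background=background, thresholds=(ct, mt)
    )
    evalue = p * 2.0 * n
    significance = p if cutoff_scale == "site" else evalue
    if evalue_cutoff is not None and significance > evalue_cutoff:
        return []

    enc = encode_sequence(promoter.seq)
    hits: list[MotifHit] = []
    for strand, m in (("+", matrix), ("-", matrix.reverse_complement)):
        mat, core = _window_scores(m, enc)
        sel = (mat >= mt - SCORE_TOL) & (core >= ct - SCORE_TOL)
        for i in np.flatnonzero(sel):
            hits.append(
                MotifHit(
                    matrix_id=matrix.id,
                    class_label=matrix.class_label,
                    gene_id=promoter.gene_id,
                    start_rel=promoter.window_start_rel + int(i),
                    strand=strand,
                    core_sim=float(core[i]),
                    mat_sim=float(mat[i]),
                    evalue=evalue,
                )
            )
    hits.sort(key=lambda h: (h.start_rel, h.strand, h.matrix_id))
    return hits


def estimate_background(promoters: Iterable["PromoterSequence"]) -> tuple[float, ...]:
    """Mononucleotide composition of a promoter set (N bases ignored)."""
    counts = np.zeros(4)
    for p in promoters:
        enc = encode_sequence(p.seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        raise InputError("cannot estimate background from empty sequences")
    return tuple(counts / counts.sum())


def scan_promoters(
    library,
    promoters: Sequence["PromoterSequence"],
    thresholds: tuple[float, float] | None = None,
    background: Sequence[float] | str | None = "auto",
    evalue_cutoff: float | None = 1e-3,
    cutoff_scale: str = "site",
) -> list[MotifHit]:
    """Scan every promoter against every matrix of a library.

    ``background="auto"`` estimates the i.i.d. null composition from the
    promoter set itself; pass a 4-tuple for a fixed composition (for
    example uniform 0.25).  Per-matrix site probabilities are computed
    once and shared across promoters.
    """
    matrices = getattr(library, "matrices", library)
    if background == "auto":
        bg: Sequence[float] | None = estimate_background(promoters)
    else:
        bg = background  # type: ignore[assignment]
    hits: list[MotifHit] = []
    for matrix in matrices:
        ct, mt = thresholds if thresholds is not None else (
            matrix.core_threshold,
            matrix.matrix_threshold,
        )
        p = site_match_pvalue(matrix, background=bg, thresholds=(ct, mt))
        for prom in promoters:
            hits.extend(
                scan_promoter(
                    matrix,
                    prom,
                    thresholds=(ct, mt),
                    background=bg,
                    evalue_cutoff=evalue_cutoff,
                    cutoff_scale=cutoff_scale,
                    _pvalue=p,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Binary occurrence matrix
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class OccurrenceMatrix:
    """Binary TFBS-class x gene presence table with gene metadata.

    ``data`` holds 0/1 values (classes as rows, genes as columns);
    ``gene_meta`` is indexed by gene id with columns species, lineage,
    role and cog_id.
    """

    data: pd.DataFrame
    gene_meta: pd.DataFrame
    dropped_classes: tuple[str, ...] = ()

    @property
    def classes(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def presence(self, class_label: str, gene_id: str) -> bool:
        if class_label not in self.data.index:
            return False
        return bool(self.data.at[class_label, gene_id])

    def subset_genes(self, genes: Sequence[str]) -> "OccurrenceMatrix":
        return OccurrenceMatrix(
            data=self.data[list(genes)],
            gene_meta=self.gene_meta.loc[list(genes)],
            dropped_classes=self.dropped_classes,
        )

    def to_tsv(self) -> str:
        """Serialize with a structured metadata header (``#meta`` lines)."""
        lines = []
        for gid, row in self.gene_meta.iterrows():
            fields = "\t".join(f"{k}={'' if pd.isna(v) else v}" for k, v in row.items())
            lines.append(f"#meta\t{gid}\t{fields}")
        lines.append(self.data.to_csv(sep="\t", index_label="class").rstrip("\n"))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "OccurrenceMatrix":
        meta_rows = {}
        body = []
        for line in text.splitlines():
            if line.startswith("#meta\t"):
                _, gid, *fields = line.split("\t")
                meta_rows[gid] = dict(f.split("=", 1) for f in fields)
            elif line.strip():
                body.append(line)
        from io import StringIO

        data = pd.read_csv(StringIO("\n".join(body)), sep="\t", index_col="class")
        data.index = data.index.astype(str)
        meta = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(data.columns)
        meta = meta.replace({"": None})
        return cls(data=data.astype(np.int8), gene_meta=meta)


def build_occurrence_matrix(
    hits: Iterable[MotifHit],
    genes: Sequence["PromoterSequence"],
    class_map: Mapping[str, str] | None = None,
) -> OccurrenceMatrix:
    """Binarize retained hits into a class x gene occurrence matrix.

    ``class_map`` (matrix id -> class label, e.g. ``library.class_map``)
    fixes the candidate class universe; classes never observed are dropped
    from the matrix but recorded in ``dropped_classes``.  Hits whose class
    label is not in the map raise an error.
    """
    gene_ids = [g.gene_id for g in genes]
    known_classes = sorted(set(class_map.values())) if class_map is not None else None
    hits = list(hits)
    hit_classes = sorted({h.class_label for h in hits})
    if known_classes is not None:
        unknown = set(hit_classes) - set(known_classes)
        if unknown:
            raise InputError(f"hits carry unknown class labels: {sorted(unknown)}")
        classes = known_classes
    else:
        classes = hit_classes
    data = pd.DataFrame(
        np.zeros((len(classes), len(gene_ids)), dtype=np.int8),
        index=pd.Index(classes, name="class"),
        columns=gene_ids,
    )
    missing = {h.gene_id for h in hits} - set(gene_ids)
    if missing:
        raise InputError(f"hits refer to genes absent from the gene list: {sorted(missing)}")
    for h in hits:
        data.at[h.class_label, h.gene_id] = 1
    present = data.sum(axis=1) > 0
    dropped = tuple(data.index[~present])
    if dropped:
        logger.info("dropping %d all-zero TFBS classes: %s", len(dropped), ", ".join(dropped))
    meta = pd.DataFrame(
        {
            "species": [g.species for g in genes],
            "lineage": [g.lineage for g in genes],
            "role": [g.role for g in genes],
            "cog_id": [g.cog_id for g in genes],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return OccurrenceMatrix(data=data.loc[present], gene_meta=meta, dropped_classes=dropped)


# ---------------------------------------------------------------------------
# Hit serialization
# ---------------------------------------------------------------------------


def hits_to_bed(hits: Iterable[MotifHit], matrix_lengths: Mapping[str, int], shift: int = 1000) -> str:
    """BED6-compatible hit table (positions shifted to be non-negative)."""
    lines = []
    for h in hits:
        start = h.start_rel + shift
        end = start + matrix_lengths[h.matrix_id]
        name = f"{h.class_label}:{h.matrix_id}"
        lines.append(
            f"{h.gene_id}\t{start}\t{end}\t{name}\t{round(1000 * h.mat_sim)}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_jsonl(hits: Iterable[MotifHit]) -> str:
    """JSON-lines dialect carrying the full hit record."""
    lines = []
    for h in hits:
        lines.append(
            json.dumps(
                {
                    "matrix_id": h.matrix_id,
                    "class": h.class_label,
                    "gene_id": h.gene_id,
                    "start_rel": h.start_rel,
                    "strand": h.strand,
                    "core_sim": round(h.core_sim, 6),
                    "mat_sim": round(h.mat_sim, 6),
                    "evalue": h.evalue,
                },
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
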