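"""Parsers and writers for the genomic file formats the network builders consume.

Every parser normalizes to a single internal coordinate convention:
**0-based, half-open** intervals, exactly as in BED.  Formats with 1-based
inclusive coordinates (FIMO text output, GTF) are converted at the parse
boundary; nothing downstream ever re-converts.

Supported inputs: BED3/BED6, ENCODE narrowPeak (BED6+4), FIMO tab-separated
text, GTF transcript records, one-TSS-per-row BED, and two-column
motif-matrix -> TF mapping TSVs.  The only writer is BED6 (plus the network
formats in :mod:`ddrnet.network_model`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import FormatError, ParseError

__all__ = [
    "GenomicFeature",
    "MotifHit",
    "TSSAnnotation",
    "MotifTFMap",
    "read_bed",
    "write_bed",
    "read_fimo_hits",
    "read_tss",
    "read_motif_tf_map",
]

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicFeature:
    """A located interval (peak, footprint, or motif hit), 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    feature_id: str = ""
    source_id: str = ""
    summit_offset: int | None = None  # narrowPeak column 10, when present

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer-floor midpoint, used for signed TSS distances."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class MotifHit:
    """A PWM scan hit with its match p-value (FIMO-style)."""

    feature: GenomicFeature
    matrix_id: str
    p_value: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value outside (0, 1]: {self.p_value}")


@dataclass(frozen=True)
class TSSAnnotation:
    """A gene's strand and its (possibly several) transcription start sites."""

    gene_id: str
    chrom: str
    strand: str
    tss_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not self.tss_positions:
            raise ValueError(f"gene {self.gene_id} has no TSS positions")
        object.__setattr__(self, "tss_positions", tuple(sorted(set(self.tss_positions))))


@dataclass
class MotifTFMap:
    """Many-to-many mapping between PWM matrix identifiers and TF gene ids."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def add(self, matrix_id: str, tf_gene_id: str) -> None:
        self.pairs.add((matrix_id, tf_gene_id))

    def tfs_for(self, matrix_id: str) -> list[str]:
        return sorted(tf for m, tf in self.pairs if m == matrix_id)

    def matrices_for(self, tf_gene_id: str) -> list[str]:
        return sorted(m for m, tf in self.pairs if tf == tf_gene_id)

    @property
    def matrix_ids(self) -> set[str]:
        return {m for m, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# BED / narrowPeak


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path: str | Path, source_id: str = "") -> list[GenomicFeature]:
    """Read BED3/BED6/narrowPeak records into features.

    BED is already 0-based half-open, so coordinates are taken verbatim.
    narrowPeak score (column 5) and summit offset (column 10) are preserved.
    """
    features: list[GenomicFeature] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"expected >=3 tab-separated columns, got {len(cols)}",
                             str(path), lineno)
        chrom = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(f"non-integer coordinates {cols[1]!r}, {cols[2]!r}",
                             str(path), lineno) from None
        if start < 0 or end <= start:
            raise ParseError(f"invalid interval [{start}, {end})", str(path), lineno)
        name = cols[3] if len(cols) > 3 else ""
        score: float | None = None
        if len(cols) > 4 and cols[4] not in {".", ""}:
            try:
                score = float(cols[4])
            except ValueError:
                raise ParseError(f"non-numeric score {cols[4]!r}", str(path), lineno) from None
        strand = cols[5] if len(cols) > 5 and cols[5] in VALID_STRANDS else "."
        summit: int | None = None
        if len(cols) >= 10:  # narrowPeak
            try:
                summit_val = int(cols[9])
            except ValueError:
                raise ParseError(f"non-integer summit offset {cols[9]!r}",
                                 str(path), lineno) from None
            summit = summit_val if summit_val >= 0 else None
        features.append(GenomicFeature(chrom, start, end, strand, score, name,
                                       source_id, summit))
    return features


def write_bed(features: Iterable[GenomicFeature], path: str | Path) -> None:
    """Write features as BED6 (score rendered as its shortest exact decimal)."""
    with open(path, "w") as fh:
        for f in features:
            score = "0" if f.score is None else f"{f.score:g}"
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t{score}\t{f.strand}\n")


# ---------------------------------------------------------------------------
# FIMO

_FIMO_MOTIF_COLS = ("motif_id", "pattern_name")
_FIMO_SEQ_COLS = ("sequence_name",)


def _norm_header(name: str) -> str:
    return re.sub(r"[\s\-]+", "_", name.strip().lstrip("#").lower())


def read_fimo_hits(path: str | Path, source_id: str = "") -> list[MotifHit]:
    """Read FIMO tab-separated text output.

    FIMO reports 1-based inclusive ``[start, stop]``; hits are converted to
    internal half-open ``[start-1, stop)`` so that ``stop - start + 1`` in the
    source equals ``end - start`` internally.  The sequence name is taken as
    the chromosome.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    header = [_norm_header(c) for c in lines[0].split("\t")]
    idx: dict[str, int] = {}
    for want, aliases in (("motif", _FIMO_MOTIF_COLS), ("seq", _FIMO_SEQ_COLS)):
        for a in aliases:
            if a in header:
                idx[want] = header.index(a)
                break
    for col in ("start", "stop", "strand", "score", "p_value"):
        if col in header:
            idx[col] = header.index(col)
    missing = {"motif", "seq", "start", "stop", "p_value"} - set(idx)
    if missing:
        raise FormatError(
            f"{path}: not FIMO tab-separated output (missing columns: {sorted(missing)})")

    hits: list[MotifHit] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        try:
            start1 = int(cols[idx["start"]])
            stop1 = int(cols[idx["stop"]])
            p_value = float(cols[idx["p_value"]])
        except (ValueError, IndexError):
            raise ParseError("malformed FIMO row", str(path), lineno) from None
        if not (0.0 < p_value <= 1.0):
            raise ParseError(f"p-value outside (0, 1]: {p_value}", str(path), lineno)
        strand = cols[idx["strand"]] if "strand" in idx and len(cols) > idx["strand"] else "."
        if strand not in VALID_STRANDS:
            strand = "."
        score = 0.0
        if "score" in idx and len(cols) > idx["score"]:
            try:
                score = float(cols[idx["score"]])
            except ValueError:
                score = 0.0
        matrix_id = cols[idx["motif"]]
        feat = GenomicFeature(cols[idx["seq"]], start1 - 1, stop1, strand,
                              score, matrix_id, source_id)
        hits.append(MotifHit(feat, matrix_id, p_value, score))
    return hits


# ---------------------------------------------------------------------------
# TSS annotations

_GTF_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_tss(path: str | Path, format: str = "bed") -> list[TSSAnnotation]:
    """Read TSS annotations from a TSS-BED or a GTF file.

    TSS-BED: one row per TSS, name column = gene id, ``start`` is the TSS.
    GTF: rows with feature type ``transcript``; the TSS of a 1-based
    inclusive transcript ``[start, end]`` is ``start - 1`` on ``+`` and
    ``end - 1`` on ``-``.  Duplicate TSS positions per gene are collapsed.
    """
    if format not in {"bed", "gtf"}:
        raise ValueError(f"unknown TSS format {format!r}")
    per_gene: dict[str, dict] = {}

    def _record(gene_id: str, chrom: str, strand: str, pos: int, lineno: int) -> None:
        entry = per_gene.setdefault(gene_id, {"chrom": chrom, "strand": strand, "pos": set()})
        if entry["chrom"] != chrom:
            raise ParseError(
                f"gene {gene_id} annotated on multiple chromosomes "
                f"({entry['chrom']} and {chrom})", str(path), lineno)
        if entry["strand"] != strand:
            raise ParseError(f"conflicting strands for gene {gene_id}", str(path), lineno)
        entry["pos"].add(pos)

    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if format == "bed":
            if len(cols) < 4:
                raise ParseError("TSS-BED needs >=4 columns (name = gene id)",
                                 str(path), lineno)
            try:
                start = int(cols[1])
            except ValueError:
                raise ParseError(f"non-integer TSS {cols[1]!r}", str(path), lineno) from None
            strand = cols[5] if len(cols) > 5 else "+"
            if strand not in {"+", "-"}:
                raise ParseError(f"TSS strand must be + or -, got {strand!r}",
                                 str(path), lineno)
            _record(cols[3], cols[0], strand, start, lineno)
        else:
            if len(cols) < 9:
                continue
            if cols[2] != "transcript":
                continue
            m = _GTF_GENE_ID_RE.search(cols[8])
            if not m:
                raise ParseError("transcript row without gene_id attribute",
                                 str(path), lineno)
            strand = cols[6]
            if strand not in {"+", "-"}:
                raise ParseError(f"transcript strand must be + or -, got {strand!r}",
                                 str(path), lineno)
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError("non-integer transcript coordinates",
                                 str(path), lineno) from None
            tss = start1 - 1 if strand == "+" else end1 - 1
            _record(m.group(1), cols[0], strand, tss, lineno)

    return [
        TSSAnnotation(gene_id, e["chrom"], e["strand"], tuple(sorted(e["pos"])))
        for gene_id, e in sorted(per_gene.items())
    ]


# ---------------------------------------------------------------------------
# Motif -> TF map


def read_motif_tf_map(path: str | Path) -> MotifTFMap:
    """Read a two-column (matrix_id, tf_gene_id) TSV; duplicates collapse."""
    mapping = MotifTFMap()
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(f"expected 2 columns, got {len(cols)}", str(path), lineno)
        mapping.add(cols[0], cols[1])
    return mapping
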