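"""Readers and writers for the text dialects the pipeline touches.

Peak tables follow the HOMER ``findPeaks`` tab-delimited dialect: comment
and header lines begin with ``#``, the last such line naming the columns,
and coordinates are 1-based inclusive.  Internally every interval is stored
0-based half-open so that ``length == end - start``.  Gene lists are plain
text, one identifier per line.  Scored-transcript tables are TSV with a
fixed header.  All output is UTF-8 with LF line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: default column holding the per-peak read count in HOMER-style tables
DEFAULT_COUNT_COLUMN = "Tag Count"
#: optional column holding the gene identifier; falls back to the peak id
DEFAULT_GENE_COLUMN = "Gene Name"

_REQUIRED_COLUMNS = ("chr", "start", "end", "strand")


class PeakTableFormatError(ValueError):
    """The peak table does not conform to the expected dialect."""


@dataclass(frozen=True)
class PeakRecord:
    """One called peak region, coordinates 0-based half-open."""

    peak_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    raw_reads: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.peak_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.raw_reads < 0:
            raise ValueError(f"peak {self.peak_id!r}: negative read count {self.raw_reads}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"peak {self.peak_id!r}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        """Span of the peak region in bases (end − start)."""
        return self.end - self.start


@dataclass
class PeakSet:
    """A sample's peak records plus its total-aligned-read metadata.

    ``total_aligned_reads`` is supplied by the caller (it comes from the
    alignment, not from the peak table itself).
    """

    sample_label: str
    total_aligned_reads: int
    records: list[PeakRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_aligned_reads <= 0:
            raise ValueError("total_aligned_reads must be positive")
        seen: set[str] = set()
        for rec in self.records:
            if rec.peak_id in seen:
                raise ValueError(f"duplicate peak_id {rec.peak_id!r} in sample {self.sample_label!r}")
            seen.add(rec.peak_id)

    def __len__(self) -> int:
        return len(self.records)


def _parse_header(comment_lines: list[str]) -> list[str] | None:
    """Return column names from the last '#' line that looks like a header."""
    for line in reversed(comment_lines):
        cells = line.lstrip("#").rstrip("\n").split("\t")
        if len(cells) >= 5:
            # HOMER appends command provenance to the first header cell
            cells[0] = cells[0].split(" (")[0].strip()
            return [c.strip() for c in cells]
    return None


def read_homer_peaks(
    path: str | Path,
    total_aligned_reads: int,
    sample_label: str,
    count_column: str = DEFAULT_COUNT_COLUMN,
    gene_column: str | None = None,
) -> PeakSet:
    """Read a HOMER ``findPeaks``-style peak table.

    Parameters
    ----------
    path
        Tab-delimited file; lines starting with ``#`` are comments, the last
        one of which (with ≥5 cells) names the columns.
    total_aligned_reads
        The sample's total aligned read (tag) count, used downstream for
        peak-score normalization.
    count_column
        Which column holds the per-peak read count (the dialect does not fix
        this; HOMER emits e.g. ``Normalized Tag Count`` or ``findPeaks Score``).
    gene_column
        Column holding the gene identifier.  Defaults to ``Gene Name`` when
        present, otherwise the peak id doubles as the gene id.

    Records whose 1-based inclusive coordinates satisfy ``end < start`` are
    rejected with a logged count; coordinates are converted to 0-based
    half-open on read.
    """
    path = Path(path)
    comment_lines: list[str] = []
    data_lines: list[tuple[int, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("#"):
                comment_lines.append(line)
            else:
                data_lines.append((lineno, line.rstrip("\n")))

    header = _parse_header(comment_lines)
    if header is None and data_lines:
        raise PeakTableFormatError(f"{path}: no '#'-prefixed header line naming the columns")

    records: list[PeakRecord] = []
    n_rejected = 0
    if data_lines:
        assert header is not None
        colidx = {name: i for i, name in enumerate(header)}
        for required in _REQUIRED_COLUMNS:
            if required not in colidx:
                raise PeakTableFormatError(f"{path}: missing required column {required!r}")
        if count_column not in colidx:
            raise PeakTableFormatError(f"{path}: missing required column {count_column!r}")
        if gene_column is not None and gene_column not in colidx:
            raise PeakTableFormatError(f"{path}: missing required column {gene_column!r}")
        gene_col = gene_column
        if gene_col is None and DEFAULT_GENE_COLUMN in colidx:
            gene_col = DEFAULT_GENE_COLUMN

        id_col = header[0]
        for lineno, line in data_lines:
            cells = line.split("\t")
            if len(cells) < len(header):
                raise PeakTableFormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, found {len(cells)}"
                )
            try:
                start_1based = int(cells[colidx["start"]])
                end_1based = int(cells[colidx["end"]])
            except ValueError as exc:
                raise PeakTableFormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
            try:
                raw_reads = float(cells[colidx[count_column]])
            except ValueError as exc:
                raise PeakTableFormatError(
                    f"{path}:{lineno}: non-numeric value in column {count_column!r}"
                ) from exc
            # 1-based inclusive -> 0-based half-open
            start = start_1based - 1
            end = end_1based
            if end <= start:
                n_rejected += 1
                continue
            peak_id = cells[colidx[id_col]]
            records.append(
                PeakRecord(
                    peak_id=peak_id,
                    gene_id=cells[colidx[gene_col]] if gene_col else peak_id,
                    chrom=cells[colidx["chr"]],
                    start=start,
                    end=end,
                    strand=cells[colidx["strand"]],
                    raw_reads=raw_reads,
                )
            )
    if n_rejected:
        log.warning("%s: rejected %d records with end <= start", path, n_rejected)
    return PeakSet(sample_label=sample_label, total_aligned_reads=total_aligned_reads, records=records)


def write_homer_peaks(peak_set: PeakSet, path: str | Path) -> None:
    """Write a PeakSet back to the 1-based inclusive HOMER-style dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sample={peak_set.sample_label} total_aligned_reads={peak_set.total_aligned_reads}\n")
        fh.write("#PeakID\tchr\tstart\tend\tstrand\tTag Count\tGene Name\n")
        for rec in peak_set.records:
            fh.write(
                f"{rec.peak_id}\t{rec.chrom}\t{rec.start + 1}\t{rec.end}\t{rec.strand}"
                f"\t{rec.raw_reads:.12g}\t{rec.gene_id}\n"
            )


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list: one identifier per line, blanks allowed.

    Returns the whitespace-stripped, de-duplicated set (case preserved).
    An empty file yields an empty set with a warning.
    """
    path = Path(path)
    genes: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            name = line.strip()
            if name:
                genes.add(name)
    if not genes:
        log.warning("%s: gene list is empty", path)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(genes):
            fh.write(name + "\n")


SCORED_TABLE_COLUMNS = ("gene", "peak_score", "length", "binding_surface_score", "is_target")


def write_scored_table(transcripts: Sequence, path: str | Path) -> None:
    """Write scored transcripts as TSV (header: gene, peak_score, length,
    binding_surface_score, is_target); round-trips via :func:`read_scored_table`
    to 12 significant digits."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(SCORED_TABLE_COLUMNS) + "\n")
        for t in transcripts:
            fh.write(
                f"{t.gene_id}\t{t.peak_score:.12g}\t{t.length}"
                f"\t{t.binding_surface_score:.12g}\t{int(t.is_target)}\n"
            )


def read_scored_table(path: str | Path) -> list:
    from .peaks import ScoredTranscript

    path = Path(path)
    out: list[ScoredTranscript] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SCORED_TABLE_COLUMNS:
            raise PeakTableFormatError(f"{path}: unexpected scored-table header {header}")
        for line in fh:
            if not line.strip():
                continue
            gene, score, length, bss, is_target = line.rstrip("\n").split("\t")
            out.append(
                ScoredTranscript(
                    gene_id=gene,
                    peak_score=float(score),
                    length=int(length),
                    binding_surface_score=float(bss),
                    is_target=bool(int(is_target)),
                )
            )
    return out


def write_bed(peak_set: PeakSet, path: str | Path) -> None:
    """Export peaks as BED6 (0-based half-open, as stored internally)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in peak_set.records:
            bed_score = min(1000, int(round(rec.raw_reads)))
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.peak_id}\t{bed_score}\t{rec.strand}\n"
            )


__all__ = [
    "PeakRecord",
    "PeakSet",
    "PeakTableFormatError",
    "read_homer_peaks",
    "write_homer_peaks",
    "read_gene_list",
    "write_gene_list",
    "write_scored_table",
    "read_scored_table",
    "write_bed",
    "DEFAULT_COUNT_COLUMN",
]
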