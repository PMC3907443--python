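"""Domain types, interval arithmetic and readers/writers.

Coordinate convention: everything in memory is 0-based half-open
(``[start, end)``), the natural convention for arithmetic; everything shown to
a user — and everything in the published binding-site tables — is 1-based
inclusive. :meth:`GenomicInterval.to_one_based` / :meth:`from_one_based`
convert between the two.

The 36 published binding-site rows (sequences, spans and per-factor q-scores
for 27 candidate genes) ship with the package as TSV fixtures and are parsed
by :func:`parse_site_tables`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TagCollection",
    "GeneAnnotation",
    "BindingSiteRecord",
    "read_tags",
    "write_tags",
    "read_genes",
    "write_genes_bed",
    "read_fasta",
    "write_fasta",
    "parse_site_tables",
    "parse_kd_outcomes",
    "length_consistency_report",
    "packaged_fixture",
]

SITE_TABLE_LABELS = ("equal", "A-specific", "A-dominant", "B-specific", "B-dominant")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on one chromosome (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}; "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def to_one_based(self) -> tuple[str, int, int]:
        """Return ``(chrom, start, end)`` in 1-based inclusive coordinates."""
        return (self.chrom, self.start + 1, self.end)

    @classmethod
    def from_one_based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (as printed in tables)."""
        return cls(chrom, start - 1, end)

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance in bp; 0 if the intervals overlap or touch.

        Raises ValueError when the intervals sit on different chromosomes.
        """
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass
class TagCollection:
    """Strand-less tag (read-midpoint) positions for one experiment.

    ``tags`` maps chromosome name to a sorted int64 array of midpoint
    positions; ``genome_length_by_chrom`` defines the reference the tags live
    on. Tags are reduced to midpoints and strand is ignored.
    """

    genome_length_by_chrom: dict[str, int]
    tags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, positions in self.tags.items():
            if chrom not in self.genome_length_by_chrom:
                raise ValueError(f"tags on unknown chromosome {chrom!r}")
            arr = np.asarray(positions, dtype=np.int64)
            arr = np.sort(arr)
            if arr.size and (arr[0] < 0 or arr[-1] >= self.genome_length_by_chrom[chrom]):
                raise ValueError(f"tag position out of range on {chrom}")
            self.tags[chrom] = arr

    @property
    def total_count(self) -> int:
        return int(sum(arr.size for arr in self.tags.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(self.genome_length_by_chrom.values()))

    def count_in(self, interval: GenomicInterval) -> int:
        """Number of tags with midpoint inside ``[start, end)``."""
        arr = self.tags.get(interval.chrom)
        if arr is None or arr.size == 0:
            return 0
        lo = np.searchsorted(arr, interval.start, side="left")
        hi = np.searchsorted(arr, interval.end, side="left")
        return int(hi - lo)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: identifier, span, strand ('+', '-' or '.')."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class BindingSiteRecord:
    """One row of the published site tables: sequence, span and q-scores.

    ``q_a``/``q_b`` are peak q-scores (−log10 of the FDR q-value) from the
    STAT5A and STAT5B ChIP experiments; ``None`` encodes the tables' "–"
    (no significant detection — censoring, not zero). ``table_label`` is the
    gene-level group the row was printed under.
    """

    gene_id: str
    site_index: int
    sequence: str
    interval: GenomicInterval
    q_a: float | None
    q_b: float | None
    table_label: str

    def __post_init__(self) -> None:
        if self.q_a is None and self.q_b is None:
            raise ValueError(f"{self.gene_id} site {self.site_index}: no q-score")
        if self.site_index < 1:
            raise ValueError("site_index must be >= 1")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"non-ACGT sequence {self.sequence!r}")
        if self.table_label not in SITE_TABLE_LABELS:
            raise ValueError(f"unknown table label {self.table_label!r}")


# ---------------------------------------------------------------------------
# BED / FASTA / GFF readers and writers
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Malformed record in an input file; carries the 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _bed_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_tags(path: str | Path, genome_length_by_chrom: Mapping[str, int]) -> TagCollection:
    """Read a BED3+ tag file into a :class:`TagCollection`.

    Each record contributes one tag at the floor midpoint of its interval.
    Records on chromosomes absent from ``genome_length_by_chrom`` are an
    error, as is any malformed line (reported with its line number).
    """
    positions: dict[str, list[int]] = {}
    for lineno, fields in _bed_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinates: {exc}") from None
        if start >= end:
            raise ParseError(path, lineno, f"start {start} >= end {end}")
        if chrom not in genome_length_by_chrom:
            raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
        positions.setdefault(chrom, []).append((start + end) // 2)
    return TagCollection(
        genome_length_by_chrom=dict(genome_length_by_chrom),
        tags={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
    )


def write_tags(tags: TagCollection, path: str | Path, tag_width: int = 1) -> None:
    """Write tag midpoints as BED3 with ``tag_width``-bp records."""
    with open(path, "w") as handle:
        for chrom in sorted(tags.tags):
            for pos in tags.tags[chrom]:
                handle.write(f"{chrom}\t{pos}\t{pos + tag_width}\n")


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from BED6 (``.bed``) or GFF3 (``.gff``/``.gff3``).

    For GFF3 only ``gene`` features are used; the identifier is the ``ID=``
    (or ``gene_id=``) attribute. GFF3 coordinates are 1-based inclusive.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_genes_gff3(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for lineno, fields in _bed_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, "BED gene records need >=4 columns")
        gene_id = fields[3]
        strand = fields[5] if len(fields) >= 6 else "."
        if gene_id in seen:
            raise ParseError(path, lineno, f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        genes.append(
            GeneAnnotation(gene_id, GenomicInterval(fields[0], int(fields[1]), int(fields[2])), strand)
        )
    return genes


def _read_genes_gff3(path: Path) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"GFF3 needs 9 columns, got {len(fields)}")
            if fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(path, lineno, "gene feature lacks ID attribute")
            if gene_id in seen:
                raise ParseError(path, lineno, f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            iv = GenomicInterval.from_one_based(fields[0], int(fields[3]), int(fields[4]))
            strand = fields[6] if fields[6] in ("+", "-") else "."
            genes.append(GeneAnnotation(gene_id, iv, strand))
    return genes


def write_genes_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as handle:
        for g in genes:
            iv = g.interval
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA genome into a chrom → sequence dict."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Published-table fixtures
# ---------------------------------------------------------------------------

def packaged_fixture(name: str) -> str:
    """Return the text of a fixture shipped in ``stat5kit/data``."""
    return resources.files("stat5kit.data").joinpath(name).read_text()


def _read_fixture_tsv(name_or_path: str | Path | None, default: str) -> pd.DataFrame:
    if name_or_path is None:
        text = packaged_fixture(default)
        return pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    return pd.read_csv(name_or_path, sep="\t", comment="#", dtype=str)


def _parse_q(value: str) -> float | None:
    value = value.strip()
    if value in ("-", "–", ""):
        return None
    return float(value)


def parse_site_tables(
    sites_path: str | Path | None = None,
    qscores_path: str | Path | None = None,
) -> list[BindingSiteRecord]:
    """Parse the published binding-site tables into records.

    With no arguments the packaged fixtures are used: the sequence/span table
    (36 rows over 27 genes) joined on (gene, site index) with the q-score
    table. "–" q-scores parse as absent (``None``); a row with neither
    q-score is an error.
    """
    sites = _read_fixture_tsv(sites_path, "tables_1_3_sites.tsv")
    qscores = _read_fixture_tsv(qscores_path, "table_4_qscores.tsv")
    qmap: dict[tuple[str, int], tuple[float | None, float | None]] = {}
    for row in qscores.itertuples(index=False):
        qmap[(row.gene, int(row.site_index))] = (_parse_q(row.q_a), _parse_q(row.q_b))

    records: list[BindingSiteRecord] = []
    for row in sites.itertuples(index=False):
        key = (row.gene, int(row.site_index))
        if key not in qmap:
            raise ValueError(f"no q-scores for {key[0]} site {key[1]}")
        q_a, q_b = qmap[key]
        records.append(
            BindingSiteRecord(
                gene_id=row.gene,
                site_index=int(row.site_index),
                sequence=row.sequence,
                interval=GenomicInterval.from_one_based(
                    row.chrom, int(row.start), int(row.end)
                ),
                q_a=q_a,
                q_b=q_b,
                table_label=row.table_label,
            )
        )
    return records


KD_OUTCOME_LABELS = ("A-specific", "B-specific", "redundant", "none")


def parse_kd_outcomes(path: str | Path | None = None) -> dict[str, str]:
    """Parse the knockdown-validation outcomes table (gene → label).

    With no argument the packaged fixture is used: the reported qPCR
    outcome for each of the 27 candidate genes (specifically regulated by
    one factor, redundantly by both, or not significantly changed).
    """
    df = _read_fixture_tsv(path, "fig3_kd_outcomes.tsv")
    outcomes: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.kd_label not in KD_OUTCOME_LABELS:
            raise ValueError(f"unknown knockdown label {row.kd_label!r}")
        if row.gene in outcomes:
            raise ValueError(f"duplicate gene {row.gene!r}")
        outcomes[row.gene] = row.kd_label
    return outcomes


def length_consistency_report(records: Sequence[BindingSiteRecord]) -> pd.DataFrame:
    """Compare each record's printed sequence length with its printed span.

    The published tables contain rows whose sequence length and coordinate
    span disagree; those rows are reported (``consistent == False``) exactly
    as printed, never silently corrected.
    """
    rows = []
    for rec in records:
        seq_len = len(rec.sequence)
        span_len = rec.interval.length
        rows.append(
            {
                "gene": rec.gene_id,
                "site_index": rec.site_index,
                "sequence_length": seq_len,
                "span_length": span_len,
                "consistent": seq_len == span_len,
            }
        )
    return pd.DataFrame(rows)
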