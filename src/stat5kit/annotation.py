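"""Peak-to-gene assignment and GAS-motif scanning.

Genes are assigned to a peak when the edge-to-edge distance between the
peak interval and the gene span is at most the window (10 kb by default;
overlap counts as distance 0) — the anchor is the nearest gene edge, not
the TSS. Sequences are scanned on both strands against a configurable set
of IUPAC consensus patterns (default: the canonical GAS 9-mer TTCNNNGAA);
sequences missing every full pattern but containing the TTC or GAA half-core
are reported as core-only. Because revcomp(TTC) = GAA, the either-strand
core check is equivalent to a forward-strand check for TTC or GAA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .core_io import BindingSiteRecord, GeneAnnotation
from .peaks import Peak

__all__ = [
    "MotifSet",
    "MotifVerdict",
    "assign_genes",
    "scan_sequence",
    "concordance_report",
    "read_motif_file",
]

ASSIGNMENT_WINDOW = 10_000
_IUPAC = set("ACGTRYSWKMBDHVN")


def _iupac_to_regex(pattern: str) -> re.Pattern[str]:
    parts = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in motif {pattern!r}")
        expansion = ambiguous_dna_values[ch]
        parts.append(ch if len(expansion) == 1 else f"[{expansion}]")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class MotifSet:
    """A set of IUPAC consensus patterns with the fixed TTC/GAA half-cores."""

    consensus_patterns: tuple[str, ...] = ("TTCNNNGAA",)
    core_prefix: str = "TTC"
    core_suffix: str = "GAA"

    def __post_init__(self) -> None:
        for pattern in self.consensus_patterns:
            _iupac_to_regex(pattern)  # validates

    @property
    def regexes(self) -> list[tuple[str, re.Pattern[str]]]:
        return [(p, _iupac_to_regex(p)) for p in self.consensus_patterns]


@dataclass(frozen=True)
class MotifVerdict:
    """Scan outcome for one sequence: full consensus, core only, or neither."""

    sequence: str
    status: str  # consensus | core_only | none
    matched_pattern: str | None = None
    scanned_strands: str = "both"

    def __post_init__(self) -> None:
        if self.status == "consensus" and self.matched_pattern is None:
            raise ValueError("consensus verdict requires a matched pattern")


def read_motif_file(path: str | Path) -> MotifSet:
    """Read a plain-text motif file, one IUPAC pattern per line."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            patterns.append(line.upper())
    return MotifSet(consensus_patterns=tuple(patterns))


def scan_sequence(seq: str, motifs: MotifSet | None = None) -> MotifVerdict:
    """Scan one DNA sequence against the motif set, both strands.

    status is 'consensus' when any pattern matches at any position on either
    strand, else 'core_only' when the TTC or GAA half-core occurs on either
    strand, else 'none'. Non-ACGT characters are an error.
    """
    if motifs is None:
        motifs = MotifSet()
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains non-DNA characters: {seq!r}")
    strands = (seq, reverse_complement(seq))
    for pattern, regex in motifs.regexes:
        if any(regex.search(s) for s in strands):
            return MotifVerdict(seq, "consensus", pattern)
    for s in strands:
        if motifs.core_prefix in s or motifs.core_suffix in s:
            return MotifVerdict(seq, "core_only")
    return MotifVerdict(seq, "none")


def assign_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    window: int = ASSIGNMENT_WINDOW,
) -> list[tuple[Peak, GeneAnnotation, int]]:
    """All (peak, gene, distance) assignments within the window.

    A gene is assigned to a peak iff the minimum edge-to-edge distance
    between the two intervals is ≤ window (0 when they overlap). One peak
    may collect zero, one or several genes — two genes flanking one site
    inside the window are both assigned.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    assignments = []
    for peak in peaks:
        for gene in genes:
            if gene.interval.chrom != peak.interval.chrom:
                continue
            dist = peak.interval.distance_to(gene.interval)
            if dist <= window:
                assignments.append((peak, gene, dist))
    return assignments


def assignments_to_frame(
    assignments: Iterable[tuple[Peak, GeneAnnotation, int]]
) -> pd.DataFrame:
    rows = [
        {
            "chrom": p.interval.chrom,
            "peak_start": p.interval.start,
            "peak_end": p.interval.end,
            "gene_id": g.gene_id,
            "distance_bp": d,
        }
        for p, g, d in assignments
    ]
    return pd.DataFrame(rows, columns=["chrom", "peak_start", "peak_end", "gene_id", "distance_bp"])


def concordance_report(
    records: Sequence[BindingSiteRecord],
    motifs: MotifSet | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Per-sequence motif verdicts over the published binding sequences.

    Returns ``(counts, detail)`` where counts maps status → number of
    sequences (summing to the record count). The consensus count is defined
    by the configured motif set — a single strict pattern by default — and
    is therefore not the published TRANSFAC-based consensus tally; the two
    are reported side by side elsewhere for comparison, never conflated.
    """
    verdicts = [scan_sequence(rec.sequence, motifs) for rec in records]
    counts = {"consensus": 0, "core_only": 0, "none": 0}
    for v in verdicts:
        counts[v.status] += 1
    detail = pd.DataFrame(
        {
            "gene": [r.gene_id for r in records],
            "site_index": [r.site_index for r in records],
            "sequence": [r.sequence for r in records],
            "status": [v.status for v in verdicts],
            "matched_pattern": [v.matched_pattern for v in verdicts],
        }
    )
    return counts, detail
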