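"""Pairing and classification of binding sites between two ChIP experiments.

A site detected by only one factor is *specific* to it; a site detected by
both is *dominant* for the factor whose peak q-score is more than 2-fold
higher (strictly — a ratio of exactly 2 is not dominance), and *equal*
otherwise. Genes aggregate their sites' classes: a gene whose sites all
favour one factor is specific (all one-sided) or dominant (at least one
site detected by both) for that factor; a gene with equal sites and no
factor-favouring ones is equal; any mixture of directions, or of equal with
one-sided sites, is flagged ambiguous and labelled by its highest-scoring
site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core_io import BindingSiteRecord, GenomicInterval, parse_site_tables
from .peaks import Peak

__all__ = [
    "SitePair",
    "SiteClass",
    "GeneClass",
    "pair_peaks",
    "classify_site",
    "aggregate_gene",
    "classify_table4",
    "DOMINANCE_RATIO",
]

#: Published dominance rule: "more than a 2-fold difference in q-score".
DOMINANCE_RATIO = 2.0

SITE_LABELS = ("equal", "A-dominant", "B-dominant", "A-specific", "B-specific")


@dataclass(frozen=True)
class SitePair:
    """Matched peaks from the two experiments at one genomic site.

    ``q_a``/``q_b`` are peak q-scores; ``None`` means the factor produced no
    accepted peak there (censoring below the acceptance threshold, not a
    score of zero).
    """

    site_id: str
    interval: GenomicInterval
    q_a: float | None
    q_b: float | None

    def __post_init__(self) -> None:
        if self.q_a is None and self.q_b is None:
            raise ValueError(f"site {self.site_id}: both q-scores absent")


@dataclass(frozen=True)
class SiteClass:
    """A site's label plus the q-score ratio backing it (absent for specific)."""

    site_id: str
    label: str
    ratio: float | None
    q_a: float | None = None
    q_b: float | None = None

    @property
    def favors(self) -> str | None:
        """'A', 'B' or None (equal)."""
        if self.label.startswith("A-"):
            return "A"
        if self.label.startswith("B-"):
            return "B"
        return None

    @property
    def max_q(self) -> float:
        return max(q for q in (self.q_a, self.q_b) if q is not None)


@dataclass(frozen=True)
class GeneClass:
    """Aggregated per-gene label with the site classes behind it."""

    gene_id: str
    label: str
    site_classes: tuple[SiteClass, ...]
    ambiguous: bool = False


def pair_peaks(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    max_summit_distance: int = 100,
) -> list[SitePair]:
    """Greedy nearest-summit matching of two coordinate-sorted peak lists.

    Peaks whose summits lie within ``max_summit_distance`` bp on the same
    chromosome are paired greedily by increasing summit distance, each peak
    used at most once; leftovers become single-sided pairs. The pair's
    interval is the union span of its member peaks.
    """
    candidates = []
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            if pa.interval.chrom != pb.interval.chrom:
                continue
            dist = abs(pa.summit - pb.summit)
            if dist <= max_summit_distance:
                candidates.append((dist, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[SitePair] = []
    for dist, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pa, pb = peaks_a[i], peaks_b[j]
        union = GenomicInterval(
            pa.interval.chrom,
            min(pa.interval.start, pb.interval.start),
            max(pa.interval.end, pb.interval.end),
        )
        pairs.append(SitePair(f"site_{len(pairs)}", union, pa.q_score, pb.q_score))
    for i, pa in enumerate(peaks_a):
        if i not in used_a:
            pairs.append(SitePair(f"site_{len(pairs)}", pa.interval, pa.q_score, None))
    for j, pb in enumerate(peaks_b):
        if j not in used_b:
            pairs.append(SitePair(f"site_{len(pairs)}", pb.interval, None, pb.q_score))
    pairs.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return [
        SitePair(f"site_{k}", p.interval, p.q_a, p.q_b) for k, p in enumerate(pairs)
    ]


def classify_site(pair: SitePair, rho: float = DOMINANCE_RATIO) -> SiteClass:
    """Classify one site as equal, dominant or specific.

    One-sided detection → specific for the detected factor. Both detected:
    the ratio max/min of the two q-scores must *exceed* rho (strictly) for
    dominance; a ratio of exactly rho — or a zero/zero tie — is equal.
    """
    if rho <= 1:
        raise ValueError("rho must be > 1")
    q_a, q_b = pair.q_a, pair.q_b
    if q_a is None:
        return SiteClass(pair.site_id, "B-specific", None, q_a, q_b)
    if q_b is None:
        return SiteClass(pair.site_id, "A-specific", None, q_a, q_b)
    if q_a == q_b:
        return SiteClass(pair.site_id, "equal", 1.0, q_a, q_b)
    hi, lo = (q_a, q_b) if q_a > q_b else (q_b, q_a)
    ratio = float("inf") if lo == 0 else hi / lo
    if ratio > rho:
        label = "A-dominant" if q_a > q_b else "B-dominant"
    else:
        label = "equal"
    return SiteClass(pair.site_id, label, ratio, q_a, q_b)


def aggregate_gene(gene_id: str, site_classes: Sequence[SiteClass]) -> GeneClass:
    """Aggregate a gene's site classes into one gene label.

    Rules: (i) equal sites only → equal; (ii) all sites favouring the same
    factor → that factor's specific label when every site is one-sided,
    dominant when at least one site was detected by both factors;
    (iii) sites favouring different factors, or equal sites mixed with
    one-sided ones → ambiguous, labelled by the site with the highest
    q-score.
    """
    if not site_classes:
        raise ValueError(f"gene {gene_id}: no site classes to aggregate")
    classes = tuple(site_classes)
    favors = {c.favors for c in classes}
    if favors == {None}:
        return GeneClass(gene_id, "equal", classes)
    if None not in favors and len(favors) == 1:
        factor = favors.pop()
        if all(c.label.endswith("-specific") for c in classes):
            return GeneClass(gene_id, f"{factor}-specific", classes)
        return GeneClass(gene_id, f"{factor}-dominant", classes)
    top = max(classes, key=lambda c: c.max_q)
    return GeneClass(gene_id, top.label, classes, ambiguous=True)


def _records_to_pairs(records: Sequence[BindingSiteRecord]) -> dict[str, list[SitePair]]:
    by_gene: dict[str, list[SitePair]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(
            SitePair(f"{rec.gene_id}_{rec.site_index}", rec.interval, rec.q_a, rec.q_b)
        )
    return by_gene


def classify_table4(
    records: Sequence[BindingSiteRecord] | None = None,
    rho: float = DOMINANCE_RATIO,
) -> tuple[dict[str, GeneClass], dict[str, int]]:
    """Run the site + gene classification over the published q-score table.

    Returns the per-gene classes and the group counts (equal, specific,
    dominant, plus the per-factor specific/dominant breakdown). With no
    argument the packaged fixture is used. Order-invariant in the input
    records.
    """
    if records is None:
        records = parse_site_tables()
    gene_classes: dict[str, GeneClass] = {}
    for gene_id, pairs in sorted(_records_to_pairs(records).items()):
        pairs = sorted(pairs, key=lambda p: int(p.site_id.rsplit("_", 1)[1]))
        gene_classes[gene_id] = aggregate_gene(gene_id, [classify_site(p, rho) for p in pairs])
    counts = {
        "equal": 0,
        "specific": 0,
        "dominant": 0,
        "A-specific": 0,
        "B-specific": 0,
        "A-dominant": 0,
        "B-dominant": 0,
    }
    for gc in gene_classes.values():
        counts[gc.label] = counts.get(gc.label, 0) + 1
        if gc.label.endswith("-specific"):
            counts["specific"] += 1
        elif gc.label.endswith("-dominant"):
            counts["dominant"] += 1
    return gene_classes, counts


def gene_classes_to_frame(gene_classes: Mapping[str, GeneClass]) -> pd.DataFrame:
    """Flatten gene classes to a table mirroring the published q-score layout."""
    rows = []
    for gene_id, gc in gene_classes.items():
        for sc in gc.site_classes:
            rows.append(
                {
                    "gene_id": gene_id,
                    "gene_label": gc.label,
                    "ambiguous": gc.ambiguous,
                    "site_id": sc.site_id,
                    "site_label": sc.label,
                    "q_a": sc.q_a,
                    "q_b": sc.q_b,
                    "ratio": sc.ratio,
                }
            )
    return pd.DataFrame(rows)
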