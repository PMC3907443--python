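"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-factor ChIP experiment on a desk-scale genome:
GAS motifs (TTCNNNGAA instances) are planted at well-separated positions,
each with an expected tag yield for factor A and factor B whose ratio places
it in one of five regimes (equal, A/B-dominant, A/B-specific); ChIP tag
positions are Gaussian around the site midpoint (fragment-position noise)
with Poisson counts over a uniform Poisson background, and the input control
is background only. Gene annotations are placed at configurable edge
distances from sites, and qPCR Cq tables are simulated per donor with
knockdown effects expressed as Cq shifts.

Regime contracts (relative to the classifier's strict 2-fold boundary):
equal sites have a λ ratio ≤ 1.5, dominant sites ≥ 4 with both factors
positive, specific sites have the minor factor's λ = 0 — placed safely on
either side of the 2-fold decision boundary so truth recovery is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, GenomicInterval, TagCollection

__all__ = [
    "SiteTruth",
    "RegulationTruth",
    "GenePlacement",
    "CqTable",
    "generate_genome",
    "plant_sites",
    "simulate_tags",
    "generate_gene_annotation",
    "simulate_qpcr",
]

SITE_CLASSES = ("equal", "A-dom", "B-dom", "A-sp", "B-sp")
KD_CONDITIONS = ("ctrl-siRNA", "A-KD", "B-KD")

#: Knockdown efficiencies in the regime reported for siRNA in primary T cells
#: (45% for one factor, 58% for the other) — used as realistic default effects.
DEFAULT_EFFECT_A = 0.45
DEFAULT_EFFECT_B = 0.58


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one planted binding site."""

    interval: GenomicInterval
    motif: str
    lambda_a: float
    lambda_b: float
    truth_class: str

    def __post_init__(self) -> None:
        if self.lambda_a < 0 or self.lambda_b < 0:
            raise ValueError("lambdas must be non-negative")
        if self.truth_class not in SITE_CLASSES:
            raise ValueError(f"unknown truth class {self.truth_class!r}")


@dataclass(frozen=True)
class RegulationTruth:
    """Ground truth for one gene's knockdown response.

    ``effect_a`` / ``effect_b`` are the fractional reductions in expression
    under A-knockdown / B-knockdown (0 = no effect, 0.5 = halved).
    """

    gene_id: str
    label: str  # A-specific | B-specific | redundant | none
    effect_a: float
    effect_b: float

    def __post_init__(self) -> None:
        for eff in (self.effect_a, self.effect_b):
            if not (0.0 <= eff <= 1.0):
                raise ValueError("effects must lie in [0, 1]")
        if self.label not in ("A-specific", "B-specific", "redundant", "none"):
            raise ValueError(f"unknown regulation label {self.label!r}")


@dataclass(frozen=True)
class GenePlacement:
    """Where to put one synthetic gene relative to a planted site.

    mode 'near' puts the gene edge within the 10-kb assignment window,
    'far' beyond it, and 'paired-near' plants a second gene (suffix
    ``_pair``) on the opposite side of the same site — the scenario in which
    two real genes flank one binding site inside the window.
    """

    gene_id: str
    site_index: int
    mode: str = "near"  # near | far | paired-near
    offset: int | None = None  # edge-to-edge distance in bp; drawn if None
    length: int = 2000
    side: int = +1

    def __post_init__(self) -> None:
        if self.mode not in ("near", "far", "paired-near"):
            raise ValueError(f"unknown placement mode {self.mode!r}")
        if self.side not in (+1, -1):
            raise ValueError("side must be +1 or -1")


class CqTable:
    """Per-donor, per-gene, per-condition quantification-cycle table.

    Thin validated wrapper over a DataFrame with columns
    donor, gene, condition, cq_target, cq_reference. Every (donor, gene)
    must carry all three conditions (ctrl-siRNA, A-KD, B-KD).
    """

    COLUMNS = ("donor", "gene", "condition", "cq_target", "cq_reference")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"CqTable missing columns {sorted(missing)}")
        if (df["cq_target"] <= 0).any() or (df["cq_reference"] <= 0).any():
            raise ValueError("Cq values must be positive")
        bad = set(df["condition"]) - set(KD_CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        counts = df.groupby(["donor", "gene"])["condition"].nunique()
        if (counts != len(KD_CONDITIONS)).any():
            raise ValueError("every (donor, gene) needs all three conditions")
        self.df = df.reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "CqTable":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    @property
    def donors(self) -> list:
        return sorted(self.df["donor"].unique())


# ---------------------------------------------------------------------------
# Genome and sites
# ---------------------------------------------------------------------------

def generate_genome(
    length: int, gc: float = 0.41, seed: int | None = None, chrom: str = "chr1"
) -> dict[str, str]:
    """Random single-chromosome genome with the given GC fraction.

    Bases are i.i.d. with P(G)=P(C)=gc/2. Deterministic for a fixed seed.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10,000 bp")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    return {chrom: bases.tobytes().decode()}


def _draw_motif(rng: np.random.Generator) -> str:
    """A concrete GAS 9-mer: TTC + 3 random bases + GAA."""
    middle = "".join(rng.choice(list("ACGT"), size=3))
    return "TTC" + middle + "GAA"


def plant_sites(
    genome: Mapping[str, str],
    n_per_class: Mapping[str, int],
    strength_params: Mapping[str, float] | None = None,
    min_gap: int = 5_000,
    seed: int | None = None,
    edge_margin: int = 20_000,
) -> tuple[dict[str, str], list[SiteTruth]]:
    """Plant GAS motifs with per-factor expected tag yields.

    ``n_per_class`` maps regime → count (classes from equal, A-dom, B-dom,
    A-sp, B-sp). ``strength_params`` may override ``lambda_major`` (expected
    tags for the stronger factor; the default 1000 keeps even the weakest
    dominant-site minor — lambda_major / dominant_ratio_max — clearly above
    the caller's strict 30-fold-vs-uniform acceptance line at the default
    background), ``equal_ratio_max`` (1.5), ``dominant_ratio_min`` (4.0)
    and ``dominant_ratio_max`` (5.0). Sites are non-overlapping, at least
    ``min_gap`` apart (``min_gap`` ≥ 2 kb) and away from chromosome edges;
    class order is shuffled so position does not encode class.
    """
    bad = set(n_per_class) - set(SITE_CLASSES)
    if bad:
        raise ValueError(f"unknown site classes {sorted(bad)}")
    if min_gap < 2_000:
        raise ValueError("min_gap must be >= 2000 bp")
    params = {
        "lambda_major": 1000.0,
        "equal_ratio_max": 1.5,
        "dominant_ratio_min": 4.0,
        "dominant_ratio_max": 5.0,
    }
    if strength_params:
        params.update(strength_params)
    rng = np.random.default_rng(seed)
    (chrom, seq), = genome.items()
    length = len(seq)

    labels = [c for c, n in sorted(n_per_class.items()) for _ in range(int(n))]
    rng.shuffle(labels)
    n_sites = len(labels)
    span = length - 2 * edge_margin
    if n_sites and span < (n_sites - 1) * min_gap + 9:
        raise ValueError("genome too short to place all sites with the given gap")

    # Cell-centred anchors with bounded jitter keep both the min-gap and the
    # edge-margin guarantees: |jitter| <= (spacing - min_gap)/2.
    positions = np.empty(0, dtype=int)
    if n_sites:
        spacing = span / n_sites
        anchors = edge_margin + spacing * (np.arange(n_sites) + 0.5)
        slack = max(0.0, (spacing - min_gap) / 2 - 10)
        jitter = rng.uniform(-slack, slack, size=n_sites)
        positions = (anchors + jitter).astype(int)

    mutable = np.frombuffer(seq.encode(), dtype="S1").copy()
    truths: list[SiteTruth] = []
    lam = params["lambda_major"]
    for label, pos in zip(labels, positions):
        motif = _draw_motif(rng)
        mutable[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")
        if label == "equal":
            ratio = rng.uniform(1.0, params["equal_ratio_max"])
            pair = (lam, lam / ratio) if rng.random() < 0.5 else (lam / ratio, lam)
        elif label in ("A-dom", "B-dom"):
            ratio = rng.uniform(params["dominant_ratio_min"], params["dominant_ratio_max"])
            pair = (lam, lam / ratio) if label == "A-dom" else (lam / ratio, lam)
        else:  # specific: minor factor absent entirely
            pair = (lam, 0.0) if label == "A-sp" else (0.0, lam)
        truths.append(
            SiteTruth(
                interval=GenomicInterval(chrom, int(pos), int(pos) + len(motif)),
                motif=motif,
                lambda_a=float(pair[0]),
                lambda_b=float(pair[1]),
                truth_class=label,
            )
        )
    return {chrom: mutable.tobytes().decode()}, truths


def simulate_tags(
    sites: Sequence[SiteTruth],
    factor: str,
    genome_length_by_chrom: Mapping[str, int],
    depth_scale: float = 1.0,
    frag_sigma: float = 75.0,
    background_rate: float = 0.005,
    seed: int | None = None,
) -> TagCollection:
    """Simulate one experiment's tag positions.

    Per site the tag count is Poisson(depth_scale·λ) for the requested
    factor and positions are Normal(site midpoint, frag_sigma) clipped to
    the chromosome; background tags are Poisson(background_rate·L) placed
    uniformly. ``factor='input'`` yields background only (λ=0 everywhere).
    """
    if factor not in ("A", "B", "input"):
        raise ValueError("factor must be 'A', 'B' or 'input'")
    if frag_sigma <= 0:
        raise ValueError("frag_sigma must be > 0")
    if background_rate < 0 or depth_scale < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    positions: dict[str, list[np.ndarray]] = {c: [] for c in genome_length_by_chrom}

    for site in sites:
        lam = 0.0 if factor == "input" else (site.lambda_a if factor == "A" else site.lambda_b)
        count = rng.poisson(depth_scale * lam)
        if count:
            chrom_len = genome_length_by_chrom[site.interval.chrom]
            pos = rng.normal(site.interval.midpoint, frag_sigma, size=count)
            pos = np.clip(np.rint(pos), 0, chrom_len - 1).astype(np.int64)
            positions[site.interval.chrom].append(pos)

    for chrom, chrom_len in genome_length_by_chrom.items():
        n_bg = rng.poisson(background_rate * chrom_len)
        if n_bg:
            positions[chrom].append(rng.integers(0, chrom_len, size=n_bg, dtype=np.int64))

    tags = {
        chrom: np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
        for chrom, parts in positions.items()
    }
    return TagCollection(genome_length_by_chrom=dict(genome_length_by_chrom), tags=tags)


def generate_gene_annotation(
    sites: Sequence[SiteTruth],
    placements: Sequence[GenePlacement],
    genome_length_by_chrom: Mapping[str, int],
    seed: int | None = None,
    window: int = 10_000,
) -> list[GeneAnnotation]:
    """Place synthetic genes at controlled edge distances from sites.

    'near' genes end up with edge-to-edge distance ≤ ``window`` from their
    site (drawn uniformly in [0, window] when no offset is given), 'far'
    genes strictly beyond it, and 'paired-near' additionally plants a
    ``_pair`` gene on the opposite side of the same site.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneAnnotation] = []

    def place(gene_id: str, site: SiteTruth, offset: int, side: int, length: int) -> None:
        chrom = site.interval.chrom
        chrom_len = genome_length_by_chrom[chrom]
        if side > 0:
            start = site.interval.end + offset
            end = start + length
        else:
            end = site.interval.start - offset
            start = end - length
        if start < 0 or end > chrom_len:
            raise ValueError(f"gene {gene_id!r} placement off chromosome")
        genes.append(GeneAnnotation(gene_id, GenomicInterval(chrom, start, end), "+"))

    for p in placements:
        site = sites[p.site_index]
        if p.mode == "far":
            offset = p.offset if p.offset is not None else int(rng.integers(window + 1, 3 * window))
            if offset <= window:
                raise ValueError("'far' placement requires offset > window")
        else:
            offset = p.offset if p.offset is not None else int(rng.integers(0, window + 1))
            if offset > window:
                raise ValueError("'near' placement requires offset <= window")
        place(p.gene_id, site, offset, p.side, p.length)
        if p.mode == "paired-near":
            place(p.gene_id + "_pair", site, offset, -p.side, p.length)
    return genes


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    truths: Sequence[RegulationTruth],
    n_donors: int = 6,
    sd_noise: float = 0.15,
    seed: int | None = None,
    base_target_cq: float = 24.0,
    base_reference_cq: float = 20.0,
    donor_sd: float = 0.5,
) -> CqTable:
    """Simulate a paired-design Cq table for the given regulation truths.

    Under knockdown the target's Cq shifts by −log2(1−effect) cycles
    (reduced expression ⇒ later amplification ⇒ higher Cq); the reference
    gene is unaffected. Donor-level random intercepts are shared between a
    donor's conditions so the paired design retains power; measurement noise
    is i.i.d. Gaussian with SD ``sd_noise`` cycles on every Cq read.
    """
    if n_donors < 3:
        raise ValueError("need at least 3 donors for a paired test")
    if sd_noise <= 0:
        raise ValueError("sd_noise must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    donor_intercepts = rng.normal(0.0, donor_sd, size=n_donors)
    for truth in truths:
        for eff in (truth.effect_a, truth.effect_b):
            if eff >= 1.0:
                raise ValueError(f"{truth.gene_id}: effect 1 implies infinite Cq shift")
        shift = {
            "ctrl-siRNA": 0.0,
            "A-KD": -np.log2(1.0 - truth.effect_a),
            "B-KD": -np.log2(1.0 - truth.effect_b),
        }
        gene_level = rng.normal(0.0, 1.0)  # gene-to-gene baseline variation
        for donor in range(n_donors):
            for cond in KD_CONDITIONS:
                rows.append(
                    {
                        "donor": f"donor{donor + 1}",
                        "gene": truth.gene_id,
                        "condition": cond,
                        "cq_target": base_target_cq
                        + gene_level
                        + donor_intercepts[donor]
                        + shift[cond]
                        + rng.normal(0.0, sd_noise),
                        "cq_reference": base_reference_cq
                        + donor_intercepts[donor]
                        + rng.normal(0.0, sd_noise),
                    }
                )
    return CqTable(pd.DataFrame(rows))
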