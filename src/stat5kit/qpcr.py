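"""ΔΔCq relative expression, paired testing, and regulation-class calls.

Per donor, ΔCq = Cq(target) − Cq(reference) within a condition; ΔΔCq is
ΔCq(knockdown) − ΔCq(control) and relative expression is 2^(−ΔΔCq), so the
control level is 1 by construction. The paired two-sided t-test runs on the
per-donor ΔCq differences (Cq-scale differences are closer to normal than
the exponentiated ratios). A gene is specifically regulated by a factor
when p < 0.01 under that factor's knockdown only; both → redundant,
neither → none. No multiple-testing correction is applied across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CqTable

__all__ = [
    "ExpressionResult",
    "RegulationCall",
    "relative_expression",
    "paired_test",
    "call_regulation",
    "summarize_gene",
    "validate_all",
    "crosscheck",
    "ALPHA_SPECIFIC",
]

#: Class-assignment threshold for "specifically regulated".
ALPHA_SPECIFIC = 0.01
#: Overall significance threshold (reported, not used for classing).
ALPHA_OVERALL = 0.05

_KD_CONDITIONS = ("A-KD", "B-KD")


@dataclass(frozen=True)
class ExpressionResult:
    """Relative expression of one gene under one knockdown condition."""

    gene_id: str
    condition: str
    ratios: tuple[float, ...]  # per-donor 2^(−ΔΔCq), control ≡ 1
    mean: float
    sem: float
    p_value: float
    degenerate: bool = False  # zero-variance paired differences


@dataclass(frozen=True)
class RegulationCall:
    """Regulation class from the two knockdown p-values."""

    gene_id: str
    label: str
    p_a: float
    p_b: float


def _delta_cq(cq: CqTable, gene: str, condition: str) -> pd.Series:
    df = cq.df
    sub = df[(df["gene"] == gene) & (df["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"no rows for gene {gene!r} condition {condition!r}")
    sub = sub.set_index("donor")
    return sub["cq_target"] - sub["cq_reference"]


def relative_expression(cq: CqTable, gene: str, condition: str) -> pd.Series:
    """Per-donor relative expression 2^(−ΔΔCq) of a gene under a knockdown.

    Donors must appear in both the knockdown and the control condition; a
    donor missing its control pairing is an error naming the donor.
    """
    dcq_kd = _delta_cq(cq, gene, condition)
    dcq_ctrl = _delta_cq(cq, gene, "ctrl-siRNA")
    missing = sorted(set(dcq_kd.index) - set(dcq_ctrl.index))
    if missing:
        raise ValueError(f"gene {gene!r}: no control ΔCq for donor(s) {missing}")
    ddcq = dcq_kd - dcq_ctrl.reindex(dcq_kd.index)
    return np.power(2.0, -ddcq)


def paired_test(dcq_condition: pd.Series, dcq_control: pd.Series) -> tuple[float, bool]:
    """Two-sided paired t on per-donor ΔCq (condition vs control).

    Returns ``(p_value, degenerate)``. With zero variance of the paired
    differences the t statistic is undefined: identical values (no effect)
    are reported as p = 1, a constant non-zero shift as the p → 0 limit;
    both carry the degenerate flag.
    """
    if len(dcq_condition) < 3:
        raise ValueError("paired test needs at least 3 donors")
    diffs = (dcq_condition - dcq_control.reindex(dcq_condition.index)).to_numpy()
    if np.allclose(diffs.std(ddof=1), 0.0):
        return (1.0, True) if np.allclose(diffs, 0.0) else (0.0, True)
    t = stats.ttest_rel(dcq_condition.to_numpy(),
                        dcq_control.reindex(dcq_condition.index).to_numpy())
    return float(t.pvalue), False


def summarize_gene(cq: CqTable, gene: str, condition: str) -> ExpressionResult:
    """Relative-expression summary and paired p-value for one gene/condition."""
    ratios = relative_expression(cq, gene, condition)
    p, degenerate = paired_test(_delta_cq(cq, gene, condition), _delta_cq(cq, gene, "ctrl-siRNA"))
    arr = ratios.to_numpy()
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return ExpressionResult(
        gene_id=gene,
        condition=condition,
        ratios=tuple(float(r) for r in arr),
        mean=float(arr.mean()),
        sem=sem,
        p_value=p,
        degenerate=degenerate,
    )


def call_regulation(
    gene_id: str, p_a: float, p_b: float, alpha_specific: float = ALPHA_SPECIFIC
) -> RegulationCall:
    """Regulation class from the two knockdown p-values (strict <)."""
    sig_a, sig_b = p_a < alpha_specific, p_b < alpha_specific
    if sig_a and sig_b:
        label = "redundant"
    elif sig_a:
        label = "A-specific"
    elif sig_b:
        label = "B-specific"
    else:
        label = "none"
    return RegulationCall(gene_id, label, p_a, p_b)


def _delta_cq_wide(cq: CqTable) -> pd.DataFrame:
    """ΔCq per (gene, donor) with one column per condition."""
    df = cq.df
    dcq = df["cq_target"] - df["cq_reference"]
    return (
        df.assign(dcq=dcq)
        .pivot_table(index=["gene", "donor"], columns="condition", values="dcq")
    )


def validate_all(
    cq: CqTable, alpha_specific: float = ALPHA_SPECIFIC
) -> tuple[pd.DataFrame, dict[str, RegulationCall]]:
    """Run the full validation over every gene in a Cq table.

    Returns a summary frame (mean ratio, sem and p per knockdown, plus the
    regulation label) and the per-gene calls. The ΔCq table is pivoted once
    so the cost is linear in the number of genes.
    """
    wide = _delta_cq_wide(cq)
    rows = []
    calls: dict[str, RegulationCall] = {}

    def summarize(gene: str, sub: pd.DataFrame, condition: str) -> ExpressionResult:
        dcq_kd = sub[condition]
        dcq_ctrl = sub["ctrl-siRNA"]
        ratios = np.power(2.0, -(dcq_kd - dcq_ctrl).to_numpy())
        p, degenerate = paired_test(dcq_kd, dcq_ctrl)
        sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size)) if ratios.size > 1 else float("nan")
        return ExpressionResult(
            gene, condition, tuple(float(r) for r in ratios),
            float(ratios.mean()), sem, p, degenerate,
        )

    for gene, sub in wide.groupby(level="gene", sort=True):
        sub = sub.droplevel("gene")
        res_a = summarize(gene, sub, "A-KD")
        res_b = summarize(gene, sub, "B-KD")
        call = call_regulation(gene, res_a.p_value, res_b.p_value, alpha_specific)
        calls[gene] = call
        rows.append(
            {
                "gene": gene,
                "mean_ratio_A_KD": res_a.mean,
                "sem_A_KD": res_a.sem,
                "p_a": res_a.p_value,
                "mean_ratio_B_KD": res_b.mean,
                "sem_B_KD": res_b.sem,
                "p_b": res_b.p_value,
                "label": call.label,
            }
        )
    return pd.DataFrame(rows), calls


_CHIP_TO_KD = {
    "equal": "redundant",
    "A-specific": "A-specific",
    "A-dominant": "A-specific",
    "B-specific": "B-specific",
    "B-dominant": "B-specific",
}


def crosscheck(
    chip_labels: dict[str, str], kd_labels: dict[str, str]
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Contingency of ChIP class × knockdown class over shared genes.

    A gene is concordant when its knockdown class matches the expectation
    of its ChIP class (equal → redundant, factor-specific/dominant → that
    factor's specific regulation). Discordant genes are listed, never
    suppressed — binding without a transcriptional consequence is a real
    outcome of the assay pair.
    """
    shared = sorted(set(chip_labels) & set(kd_labels))
    table = pd.crosstab(
        pd.Series({g: chip_labels[g] for g in shared}, name="chip"),
        pd.Series({g: kd_labels[g] for g in shared}, name="kd"),
    )
    concordant = [g for g in shared if _CHIP_TO_KD.get(chip_labels[g]) == kd_labels[g]]
    discordant = [g for g in shared if g not in set(concordant)]
    return table, concordant, discordant
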