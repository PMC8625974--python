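"""Per-comparison differential expression gating and cross-comparison pooling.

The stage-vs-stage test is Welch's two-sided t-test on log2(abundance +
pseudocount) — a documented, pluggable substitute for count-model GLMs,
appropriate because the pipeline consumes FPKM/TPM abundances rather than
raw counts.  Genes are flagged DE when fdr < ``fdr_threshold`` AND
|log2FC| > ``lfc_threshold`` (both strict), and DE sets are pooled by
union across all pairwise stage comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, ValidationError
from .io_core import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.05
DEFAULT_LFC = 1.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class DEResult:
    gene_id: str
    comparison: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    fdr: float
    is_de: bool


@dataclass
class ComparisonPlan:
    """Ordered (stage A, stage B) pairs to test."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"self-comparison {a!r} vs {b!r}")

    @classmethod
    def all_pairwise(cls, stage_order: Sequence[str]) -> "ComparisonPlan":
        """Every unordered stage pair, in stage order (4 stages -> 6 pairs)."""
        return cls(list(combinations(stage_order, 2)))


def log2_fold_change(
    mean_a: float, mean_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2((mean_b + pseudocount) / (mean_a + pseudocount))."""
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    if mean_a < 0 or mean_b < 0:
        raise ParameterError("group means must be >= 0")
    return float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def welch_log_t_test(a: np.ndarray, b: np.ndarray, pseudocount: float) -> float:
    """Two-sided Welch t-test on log2(x + pseudocount); p in [0, 1].

    Degenerate zero-variance groups get p = 1 when the transformed means
    are equal and p = 0 otherwise.
    """
    la = np.log2(np.asarray(a, dtype=float) + pseudocount)
    lb = np.log2(np.asarray(b, dtype=float) + pseudocount)
    if np.var(la) == 0.0 and np.var(lb) == 0.0:
        return 1.0 if np.isclose(la.mean(), lb.mean()) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(la, lb, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


TestFunc = Callable[[np.ndarray, np.ndarray, float], float]


def de_test(
    expr: ExpressionMatrix,
    design: SampleDesign,
    comparison: tuple[str, str],
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    test: TestFunc = welch_log_t_test,
) -> list[DEResult]:
    """Test every gene between two stages; BH-adjust within the comparison."""
    stage_a, stage_b = comparison
    for stage in comparison:
        if stage not in design.stage_order:
            raise ParameterError(f"stage {stage!r} absent from design")
    design.check_matrix(expr)
    cols_a = [s for s in expr.sample_ids if s in design.samples_for_stage(stage_a)]
    cols_b = [s for s in expr.sample_ids if s in design.samples_for_stage(stage_b)]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ParameterError(
            f"comparison {stage_a} vs {stage_b} needs >= 2 replicates per stage"
        )
    label = f"{stage_a}_vs_{stage_b}"
    a = expr.values[cols_a].to_numpy(dtype=float)
    b = expr.values[cols_b].to_numpy(dtype=float)
    p_values = [test(a[i], b[i], pseudocount) for i in range(a.shape[0])]
    fdrs = bh_adjust(p_values)
    results = []
    for i, gene in enumerate(expr.gene_ids):
        mean_a, mean_b = float(a[i].mean()), float(b[i].mean())
        lfc = log2_fold_change(mean_a, mean_b, pseudocount)
        is_de = fdrs[i] < fdr_threshold and abs(lfc) > lfc_threshold
        results.append(
            DEResult(gene, label, mean_a, mean_b, lfc, p_values[i], fdrs[i], is_de)
        )
    return results


def pool_de_genes(results: Iterable[Sequence[DEResult]]) -> set[str]:
    """Union of DE gene ids over all comparisons."""
    pooled: set[str] = set()
    n_comparisons = 0
    for comparison_results in results:
        n_comparisons += 1
        pooled |= {r.gene_id for r in comparison_results if r.is_de}
    if n_comparisons == 0 or not pooled:
        warnings.warn("no DE genes in any comparison", stacklevel=2)
    return pooled


def run_de(
    expr: ExpressionMatrix,
    design: SampleDesign,
    plan: ComparisonPlan | None = None,
    **kwargs,
) -> tuple[dict[str, list[DEResult]], set[str]]:
    """All planned comparisons plus the pooled DE id set."""
    if plan is None:
        plan = ComparisonPlan.all_pairwise(design.stage_order)
    per_comparison = {
        f"{a}_vs_{b}": de_test(expr, design, (a, b), **kwargs) for a, b in plan.pairs
    }
    pooled = pool_de_genes(per_comparison.values())
    logger.info(
        "%s: %d/%d genes DE across %d comparisons",
        expr.gene_class, len(pooled), len(expr.gene_ids), len(plan.pairs),
    )
    return per_comparison, pooled
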