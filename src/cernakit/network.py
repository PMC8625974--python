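"""Core ceRNA inference: correlation gates, the shared-sponge test, and
triplet assembly.

Pipeline order: miRNA-target pairs are first gated on Spearman rank
correlation (retain rho < -0.85, strict); candidate (lncRNA, mRNA) pairs
are formed for every pair with >= 1 shared retained miRNA; candidates are
then gated on Pearson co-expression (> 0.9, strict), the hypergeometric
shared-sponge tail test (p < 0.05, strict, no multiplicity correction by
default) and lncRNA cytoplasmic localization; each surviving pair expands
into one triplet per shared miRNA.

Hypergeometric universe convention: N = number of distinct miRNAs
appearing in ANY retained (post-correlation) miRNA-ceRNA pair; K and n
are the lncRNA's and mRNA's retained partner counts, so the test is
conditioned on the same filtered pair sets that define the overlap k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .de import bh_adjust
from .errors import DegenerateInputError, ParameterError, UnknownIdError, ValidationError
from .graph import GeneNetwork, Triplet
from .io_core import ExpressionMatrix, LocalizationTable, TargetTable

logger = logging.getLogger(__name__)

DEFAULT_RHO_NEG = -0.85
DEFAULT_PCC_POS = 0.9
DEFAULT_SPONGE_ALPHA = 0.05


# -- correlation primitives ------------------------------------------------


def _check_vectors(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("inputs must be 1-d vectors of equal length")
    if x.size < 3:
        raise ParameterError("correlation requires at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("correlation inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant vector has undefined correlation")
    return x, y


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation on raw values."""
    x, y = _check_vectors(x, y)
    return float(stats.pearsonr(x, y).statistic)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mean ranks for ties)."""
    x, y = _check_vectors(x, y)
    return float(stats.spearmanr(x, y).statistic)


# -- hypergeometric sponge test --------------------------------------------


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k shared miRNAs between a lncRNA with K retained partners and an mRNA
    with n retained partners out of a universe of N miRNAs.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ParameterError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ParameterError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    # scipy's sf is exclusive: P(X > k-1) = P(X >= k); log-gamma based
    return float(stats.hypergeom.sf(k - 1, N, K, n))


# -- pair filtering --------------------------------------------------------


@dataclass(frozen=True)
class MirnaCeRNAPair:
    """One retained anti-correlated miRNA-ceRNA relation."""

    mirna_id: str
    partner_id: str
    partner_class: str
    rho: float


@dataclass
class CeRNAPair:
    """One candidate/retained lncRNA-mRNA ceRNA relation."""

    lnc_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    K: int  # lncRNA's retained miRNA partner count
    n: int  # mRNA's retained miRNA partner count
    N: int  # miRNA universe size
    pcc: float = math.nan
    p_sponge: float = math.nan
    p_sponge_adj: float = math.nan

    @property
    def k(self) -> int:
        return len(self.shared_mirnas)


def filter_mirna_cerna_pairs(
    targets: TargetTable,
    mirna_expr: ExpressionMatrix,
    partner_expr: ExpressionMatrix,
    threshold_neg: float = DEFAULT_RHO_NEG,
) -> list[MirnaCeRNAPair]:
    """Retain target pairs whose Spearman rho < threshold (strict).

    Pairs with a constant expression vector on either side are skipped
    with a logged warning (their correlation is undefined).
    """
    if threshold_neg >= 0:
        raise ParameterError("threshold_neg must be negative (anti-correlation)")
    if mirna_expr.sample_ids != partner_expr.sample_ids:
        raise ValidationError("matrices must share identical sample columns")
    retained = []
    for row in targets.frame.itertuples():
        mid, tid = row.mirna_id, row.target_id
        if mid not in mirna_expr.values.index:
            raise UnknownIdError(f"miRNA {mid!r} absent from miRNA matrix")
        if tid not in partner_expr.values.index:
            raise UnknownIdError(f"target {tid!r} absent from partner matrix")
        try:
            rho = spearman_rho(mirna_expr.row(mid), partner_expr.row(tid))
        except DegenerateInputError:
            logger.warning("skipping pair (%s, %s): constant expression", mid, tid)
            continue
        if rho < threshold_neg:
            retained.append(
                MirnaCeRNAPair(mid, tid, partner_expr.gene_class, rho)
            )
    retained.sort(key=lambda p: (p.mirna_id, p.partner_id))
    return retained


def candidate_cerna_pairs(
    lnc_pairs: list[MirnaCeRNAPair], mrna_pairs: list[MirnaCeRNAPair]
) -> list[CeRNAPair]:
    """One candidate per (lncRNA, mRNA) sharing >= 1 retained miRNA."""
    lnc_partners: dict[str, set[str]] = {}
    for p in lnc_pairs:
        lnc_partners.setdefault(p.partner_id, set()).add(p.mirna_id)
    mrna_partners: dict[str, set[str]] = {}
    for p in mrna_pairs:
        mrna_partners.setdefault(p.partner_id, set()).add(p.mirna_id)
    universe = {p.mirna_id for p in lnc_pairs} | {p.mirna_id for p in mrna_pairs}
    N = len(universe)
    candidates = []
    for lnc in sorted(lnc_partners):
        for mrna in sorted(mrna_partners):
            shared = lnc_partners[lnc] & mrna_partners[mrna]
            if shared:
                candidates.append(
                    CeRNAPair(
                        lnc_id=lnc,
                        mrna_id=mrna,
                        shared_mirnas=frozenset(shared),
                        K=len(lnc_partners[lnc]),
                        n=len(mrna_partners[mrna]),
                        N=N,
                    )
                )
    return candidates


@dataclass
class NetworkBuildResult:
    retained_pairs: list[CeRNAPair]
    triplets: list[Triplet]
    network: GeneNetwork
    funnel: dict[str, int] = field(default_factory=dict)


def build_cerna_network(
    candidates: list[CeRNAPair],
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    localization: LocalizationTable,
    threshold_pos: float = DEFAULT_PCC_POS,
    alpha: float = DEFAULT_SPONGE_ALPHA,
    keep_unlocalized: bool = False,
    adjust_sponge_p: bool = False,
) -> NetworkBuildResult:
    """Apply the co-expression, sponge-test and localization gates.

    Surviving pairs expand into one triplet per shared miRNA; the funnel
    dict records survivor counts at each gate for run reporting.
    """
    if not -1 <= threshold_pos <= 1:
        raise ParameterError("threshold_pos must be within [-1, 1]")
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must be within (0, 1]")
    if lnc_expr.sample_ids != mrna_expr.sample_ids:
        raise ValidationError("matrices must share identical sample columns")

    funnel = {"candidate_pairs": len(candidates)}

    coexpressed: list[CeRNAPair] = []
    for pair in candidates:
        if pair.lnc_id not in lnc_expr.values.index:
            raise UnknownIdError(f"lncRNA {pair.lnc_id!r} absent from matrix")
        if pair.mrna_id not in mrna_expr.values.index:
            raise UnknownIdError(f"mRNA {pair.mrna_id!r} absent from matrix")
        try:
            pair.pcc = pearson_r(lnc_expr.row(pair.lnc_id), mrna_expr.row(pair.mrna_id))
        except DegenerateInputError:
            logger.warning(
                "skipping pair (%s, %s): constant expression", pair.lnc_id, pair.mrna_id
            )
            continue
        if pair.pcc > threshold_pos:
            coexpressed.append(pair)
    funnel["coexpression_gated"] = len(coexpressed)

    for pair in coexpressed:
        pair.p_sponge = hypergeom_sf(pair.k, pair.K, pair.n, pair.N)
    if coexpressed:
        adj = bh_adjust([p.p_sponge for p in coexpressed])
        for pair, q in zip(coexpressed, adj):
            pair.p_sponge_adj = q
    sponge_p = (
        (lambda p: p.p_sponge_adj) if adjust_sponge_p else (lambda p: p.p_sponge)
    )
    sponge_gated = [p for p in coexpressed if sponge_p(p) < alpha]
    funnel["sponge_gated"] = len(sponge_gated)

    final: list[CeRNAPair] = []
    for pair in sponge_gated:
        cyto = localization.is_cytoplasmic(pair.lnc_id)
        if cyto is None:
            if keep_unlocalized:
                final.append(pair)
            else:
                logger.warning(
                    "lncRNA %s has no localization label; excluded", pair.lnc_id
                )
        elif cyto:
            final.append(pair)
    funnel["localization_gated"] = len(final)

    triplets = sorted(
        {
            Triplet(pair.lnc_id, mirna, pair.mrna_id)
            for pair in final
            for mirna in pair.shared_mirnas
        }
    )
    funnel["triplets"] = len(triplets)
    network = GeneNetwork.from_triplets(triplets)
    logger.info("ceRNA funnel: %s", funnel)
    return NetworkBuildResult(final, triplets, network, funnel)
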