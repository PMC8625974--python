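"""Short time-series trend clustering over stage means.

Candidate profiles are all integer step sequences over T ordered
timepoints starting at 0 with per-step change bounded by c, minus the
all-flat profile: (2c+1)**(T-1) - 1 candidates.  Model profiles are picked
by greedy farthest-point selection under correlation distance
d = 1 - Pearson, seeded at the most-decreasing profile, then re-indexed
0..m-1 by ascending lexicographic order of their value vectors — so with
the defaults (T=4, c=1, m=20) profile 0 is the monotone decrease
(0,-1,-2,-3) and profile 19 the monotone increase (0,1,2,3).

Genes are assigned to the closest profile by correlation distance of
their stage means; profile significance uses the exact permutation null
over all T! stage orderings and a binomial tail on observed counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations, product

import numpy as np
from scipy import stats

from .errors import ParameterError, UnknownIdError
from .io_core import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

DEFAULT_UNIT_CHANGE = 1
DEFAULT_MODEL_COUNT = 20
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TrendProfile:
    profile_id: int
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.values[0] != 0:
            raise ParameterError("profile values must start at 0")
        if all(v == 0 for v in self.values):
            raise ParameterError("all-flat profile is not a trend")


def enumerate_candidate_profiles(T: int, c: int = DEFAULT_UNIT_CHANGE) -> list[tuple[int, ...]]:
    """All (2c+1)**(T-1) - 1 non-flat step sequences, lexicographically."""
    if T < 2:
        raise ParameterError("T must be >= 2")
    if c < 1:
        raise ParameterError("c must be >= 1")
    out = []
    for steps in product(range(-c, c + 1), repeat=T - 1):
        if all(s == 0 for s in steps):
            continue
        values = (0, *np.cumsum(steps).tolist())
        out.append(values)
    return out


def _corr_distance(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = math.sqrt(float(ac @ ac) * float(bc @ bc))
    return 1.0 - float(ac @ bc) / denom


def select_model_profiles(
    candidates: list[tuple[int, ...]], m: int = DEFAULT_MODEL_COUNT
) -> list[TrendProfile]:
    """Greedy max-min farthest-point selection under 1 - Pearson distance.

    Seeded at the most-decreasing candidate (lexicographically smallest
    value vector); ties during selection resolve to the earliest candidate
    in enumeration order.  The selected set is re-indexed by ascending
    lexicographic order of value vectors.
    """
    if m > len(candidates):
        raise ParameterError(
            f"cannot select {m} model profiles from {len(candidates)} candidates"
        )
    if m < 1:
        raise ParameterError("m must be >= 1")
    arrs = [np.asarray(v, dtype=float) for v in candidates]
    seed_idx = min(range(len(candidates)), key=lambda i: candidates[i])
    selected = [seed_idx]
    min_dist = np.array([_corr_distance(arrs[seed_idx], a) for a in arrs])
    while len(selected) < m:
        nxt = int(np.argmax(min_dist))  # argmax takes the first maximum
        selected.append(nxt)
        dist_to_new = np.array([_corr_distance(arrs[nxt], a) for a in arrs])
        min_dist = np.minimum(min_dist, dist_to_new)
    chosen = sorted(candidates[i] for i in selected)
    return [TrendProfile(pid, values) for pid, values in enumerate(chosen)]


@dataclass
class ProfileAssignment:
    """Gene-to-profile assignments with per-profile enrichment statistics."""

    assignments: dict[str, tuple[int, float]]  # gene -> (profile id, distance)
    unassigned: list[str] = field(default_factory=list)  # constant stage means
    observed: dict[int, int] = field(default_factory=dict)
    expected: dict[int, float] = field(default_factory=dict)
    p_values: dict[int, float] = field(default_factory=dict)
    significant: dict[int, bool] = field(default_factory=dict)


def stage_means(
    expr: ExpressionMatrix, design: SampleDesign
) -> dict[str, np.ndarray]:
    """Per-gene mean abundance per stage, in stage order."""
    design.check_matrix(expr)
    cols_per_stage = [
        [s for s in expr.sample_ids if s in design.samples_for_stage(stage)]
        for stage in design.stage_order
    ]
    means = np.column_stack(
        [expr.values[cols].to_numpy(dtype=float).mean(axis=1) for cols in cols_per_stage]
    )
    return {g: means[i] for i, g in enumerate(expr.gene_ids)}


def _closest_profile(
    vec: np.ndarray, profiles: list[TrendProfile]
) -> tuple[int, float]:
    best_id, best_d = -1, math.inf
    for prof in profiles:
        d = _corr_distance(vec, np.asarray(prof.values, dtype=float))
        if d < best_d - 1e-12:
            best_id, best_d = prof.profile_id, d
    return best_id, best_d


def assign_genes(
    expr: ExpressionMatrix, design: SampleDesign, profiles: list[TrendProfile]
) -> ProfileAssignment:
    """Assign each gene to the profile minimizing 1 - Pearson on stage means.

    Ties go to the lower profile id; constant-stage-mean genes are
    excluded and logged.
    """
    T = len(design.stage_order)
    for prof in profiles:
        if len(prof.values) != T:
            raise ParameterError(
                f"profile {prof.profile_id} has {len(prof.values)} values for "
                f"{T} stages"
            )
    means = stage_means(expr, design)
    ordered = sorted(profiles, key=lambda p: p.profile_id)
    assignments: dict[str, tuple[int, float]] = {}
    unassigned: list[str] = []
    for gene in expr.gene_ids:
        vec = means[gene]
        if np.all(vec == vec[0]):
            unassigned.append(gene)
            continue
        assignments[gene] = _closest_profile(vec, ordered)
    if unassigned:
        logger.info("excluded %d constant-trend genes from assignment", len(unassigned))
    observed: dict[int, int] = {p.profile_id: 0 for p in ordered}
    for pid, _ in assignments.values():
        observed[pid] += 1
    return ProfileAssignment(assignments, unassigned, observed=observed)


def profile_significance(
    assignment: ProfileAssignment,
    expr: ExpressionMatrix,
    design: SampleDesign,
    profiles: list[TrendProfile],
    alpha: float = DEFAULT_ALPHA,
) -> ProfileAssignment:
    """Exact stage-permutation null; binomial tail on observed counts.

    For every assignable gene, all T! orderings of its stage means are
    assigned; e_j is the mean null count for profile j and
    p_j = P(Binomial(G, e_j / G) >= o_j) with G assignable genes.
    """
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must be within (0, 1]")
    ordered = sorted(profiles, key=lambda p: p.profile_id)
    means = stage_means(expr, design)
    T = len(design.stage_order)
    perms = list(permutations(range(T)))
    null_counts = {p.profile_id: 0 for p in ordered}
    genes = sorted(assignment.assignments)
    for gene in genes:
        vec = means[gene]
        for perm in perms:
            pid, _ = _closest_profile(vec[list(perm)], ordered)
            null_counts[pid] += 1
    G = len(genes)
    n_perm = len(perms)
    expected = {pid: cnt / n_perm for pid, cnt in null_counts.items()}
    p_values, significant = {}, {}
    for prof in ordered:
        pid = prof.profile_id
        o = assignment.observed.get(pid, 0)
        e = expected[pid]
        if G == 0:
            p = 1.0
        else:
            p = float(stats.binom.sf(o - 1, G, min(e / G, 1.0)))
        p_values[pid] = p
        significant[pid] = p < alpha
    assignment.expected = expected
    assignment.p_values = p_values
    assignment.significant = significant
    return assignment


def classify_profiles(
    profiles: list[TrendProfile], significant_ids: list[int] | None = None
) -> dict[int, str]:
    """Label profiles by net change: end > 0 increasing, < 0 decreasing."""
    by_id = {p.profile_id: p for p in profiles}
    ids = sorted(by_id) if significant_ids is None else significant_ids
    labels = {}
    for pid in ids:
        if pid not in by_id:
            raise UnknownIdError(f"unknown profile id {pid}")
        end = by_id[pid].values[-1]
        labels[pid] = "increasing" if end > 0 else "decreasing" if end < 0 else "complex"
    return labels
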