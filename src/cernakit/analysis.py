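"""Degree/hub analysis, triplet subnetworks, and generic set enrichment."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .de import bh_adjust
from .errors import UnknownIdError, UsageError, ValidationError
from .graph import GeneNetwork, Triplet
from .io_core import AnnotationSets
from .network import hypergeom_sf

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 5

SUBNETWORK_MODES = ("hub_triplets", "mirna_filter")


def node_degrees(net: GeneNetwork) -> dict[str, int]:
    """Degree = count of distinct incident edges (sponge + target)."""
    return net.degrees()


def hub_lncrnas(net: GeneNetwork, top_k: int = DEFAULT_TOP_K) -> list[str]:
    """Top lncRNAs by degree, ties broken lexicographically by id."""
    degrees = net.degrees()
    lncs = net.nodes_of_class("lncRNA")
    ranked = sorted(lncs, key=lambda n: (-degrees[n], n))
    if top_k > len(ranked):
        warnings.warn(
            f"requested top {top_k} hub lncRNAs but only {len(ranked)} exist",
            stacklevel=2,
        )
        return ranked
    return ranked[:top_k]


def extract_subnetwork(
    net: GeneNetwork, seed_nodes: Iterable[str], mode: str
) -> GeneNetwork:
    """Triplet-level subnetwork around seed lncRNAs or seed miRNAs.

    ``hub_triplets`` keeps every triplet whose lncRNA is a seed;
    ``mirna_filter`` keeps every triplet whose miRNA is a seed.
    """
    if mode not in SUBNETWORK_MODES:
        raise UsageError(f"unknown mode {mode!r}; use one of {SUBNETWORK_MODES}")
    seeds = set(seed_nodes)
    for s in seeds:
        net.node_class(s)  # raises UnknownIdError for absent seeds
    if mode == "hub_triplets":
        kept = [t for t in net.triplets if t.lncrna in seeds]
    else:
        kept = [t for t in net.triplets if t.mirna in seeds]
    return GeneNetwork.from_triplets(kept)


@dataclass
class EnrichmentRow:
    set_id: str
    description: str
    k: int  # query genes in the set
    K: int  # set size within the universe
    n: int  # query size
    N: int  # universe size
    p: float
    fdr: float


def enrich_sets(
    query: Iterable[str],
    annotation: AnnotationSets,
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each set in the query list."""
    universe_set = set(universe)
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        raise ValidationError(f"query genes outside universe: {sorted(outside)[:5]}")
    N, n = len(universe_set), len(query_set)
    rows = []
    for sid in sorted(annotation.sets):
        desc, members = annotation.sets[sid]
        K = len(members & universe_set)
        k = len(members & query_set)
        p = hypergeom_sf(k, K, n, N) if K > 0 else 1.0
        rows.append(EnrichmentRow(sid, desc, k, K, n, N, p, fdr=1.0))
    fdrs = bh_adjust([r.p for r in rows])
    for row, q in zip(rows, fdrs):
        row.fdr = q
    rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


def count_triplets(triplets: Sequence[Triplet]) -> dict[str, int]:
    """Node-class tallies of a triplet list (for run reports)."""
    return {
        "lncRNAs": len({t.lncrna for t in triplets}),
        "miRNAs": len({t.mirna for t in triplets}),
        "mRNAs": len({t.mrna for t in triplets}),
        "triplets": len(triplets),
    }
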