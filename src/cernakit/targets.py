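"""Canonical seed-match miRNA target prediction and table intersection.

Site taxonomy follows the canonical seed classes: a target site matching
the reverse complement of miRNA positions 2-8 is an 8mer when followed by
an adenosine (opposite miRNA position 1) and a 7mer-m8 otherwise; a match
to positions 2-7 only is a 7mer-A1 with the trailing adenosine and a 6mer
without.  The adenosine requirement is on the target, regardless of the
miRNA's position-1 identity.  G:U wobble pairing is not considered.

Coordinates are 0-based half-open on the target's sense strand; the site
length (end - start) is 8, 7, 7 or 6 for 8mer, 7mer-m8, 7mer-A1 and 6mer
respectively (the trailing A is part of the site for A1 classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import AlphabetError, ParameterError, UsageError, ValidationError
from .io_core import TargetTable

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_nt(seq: str, name: str = "sequence") -> str:
    """Uppercase and map U->T; reject non-nucleotide characters."""
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in "ACGT":
            raise AlphabetError(f"non-nucleotide character {seq[i]!r} in {name} at position {i}")
    return out


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class SeedSite:
    """One seed-complement site on a target transcript."""

    mirna_id: str
    target_id: str
    start: int
    end: int
    site_class: str


def seed_patterns(mirna_seq: str) -> dict[str, str]:
    """Target-strand patterns for each site class of one miRNA.

    Keys are site classes, values the exact target subsequence required.
    """
    m = normalize_nt(mirna_seq, "miRNA")
    if len(m) < 8:
        raise ParameterError("miRNA sequence must be at least 8 nt")
    core7 = revcomp(m[1:8])  # complement of positions 2-8
    core6 = revcomp(m[1:7])  # complement of positions 2-7
    return {
        "8mer": core7 + "A",
        "7mer-m8": core7,
        "7mer-A1": core6 + "A",
        "6mer": core6,
    }


def seed_match_sites(
    mirna_seq: str,
    target_seq: str,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> list[SeedSite]:
    """Scan a target for canonical seed sites of one miRNA.

    Every start position is reported at most once, with its highest
    applicable class (8mer > 7mer-m8 > 7mer-A1 > 6mer); overlapping sites
    at distinct start positions are all reported.
    """
    t = normalize_nt(target_seq, "target")
    if len(t) < 6:
        raise ParameterError("target sequence must be at least 6 nt")
    pats = seed_patterns(mirna_seq)
    c7, c6 = pats["7mer-m8"], pats["6mer"]
    sites: list[SeedSite] = []
    for p in range(len(t) - 5):
        if t.startswith(c7, p):
            if p + 7 < len(t) and t[p + 7] == "A":
                sites.append(SeedSite(mirna_id, target_id, p, p + 8, "8mer"))
            else:
                sites.append(SeedSite(mirna_id, target_id, p, p + 7, "7mer-m8"))
        elif t.startswith(c6, p):
            if p + 6 < len(t) and t[p + 6] == "A":
                sites.append(SeedSite(mirna_id, target_id, p, p + 7, "7mer-A1"))
            else:
                sites.append(SeedSite(mirna_id, target_id, p, p + 6, "6mer"))
    return sites


_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}  # 0 is best


def predict_targets(
    mirna_seqs: Mapping[str, str],
    target_seqs: Mapping[str, str],
    target_class: str,
    source: str = "seedmatch",
) -> TargetTable:
    """All-vs-all seed scan; one row per (miRNA, target) with >= 1 site."""
    if not mirna_seqs:
        raise ValidationError("no miRNA sequences supplied")
    if not target_seqs:
        raise ValidationError("no target sequences supplied")
    rows = []
    for mid in sorted(mirna_seqs):
        for tid in sorted(target_seqs):
            sites = seed_match_sites(mirna_seqs[mid], target_seqs[tid], mid, tid)
            if sites:
                best = min(sites, key=lambda s: _CLASS_RANK[s.site_class])
                rows.append(
                    {
                        "mirna_id": mid,
                        "target_id": tid,
                        "target_class": target_class,
                        "site_class": best.site_class,
                        "source": source,
                    }
                )
    return TargetTable(pd.DataFrame(rows, columns=list(TargetTable.COLUMNS)))


def intersect_targets(tables: Sequence[TargetTable]) -> TargetTable:
    """Pairs present in every input table (the multi-tool consensus step)."""
    if len(tables) < 2:
        raise UsageError("intersection requires at least two target tables")
    common = tables[0].pairs()
    for t in tables[1:]:
        common &= t.pairs()
    if not common:
        warnings.warn("target table intersection is empty", stacklevel=2)
    base = tables[0].frame
    keep = base[
        [(m, t) in common for m, t in zip(base["mirna_id"], base["target_id"])]
    ].copy()
    keep["source"] = "intersection"
    keep = keep.drop_duplicates(subset=["mirna_id", "target_id"])
    return TargetTable(keep.reset_index(drop=True))
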