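"""Synthetic staged expression datasets with planted ceRNA triplets.

The generator plants, for each of ``n_triplets`` ceRNA pairs, a miRNA with
a monotone increasing geometric stage trend and a lncRNA/mRNA partner pair
with the opposite (decreasing) trend, so planted miRNA-partner Spearman
correlations are exactly -1 in the noise-free limit and planted
lncRNA-mRNA Pearson correlations are ~1.  All remaining genes are decoys:
stage-independent baseline plus noise.  Matched FASTA records carry seed
sites planted for every truth triplet (miRNA records use U, targets use T,
to exercise alphabet normalization downstream).

Noise is multiplicative on the log2 scale: ``x = mean * 2**(noise_sd * z)``
with standard-normal ``z``.  A fraction of the log-noise variance of each
planted lncRNA/mRNA pair is shared between the two partners (a triplet-
level co-regulation effect), which is what keeps raw-abundance Pearson
correlations of planted pairs near 1 under noise.

Accidental seed matches of *planted* miRNAs outside their own planted
sites are scrubbed (single-base edits outside planted windows), so the
planted target relationships are exactly the true ones; decoy miRNAs are
left untouched and may match anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundsError, ConfigError, ParameterError, ValidationError
from .graph import Triplet
from .io_core import (
    ExpressionMatrix,
    LocalizationTable,
    SampleDesign,
    write_expression_matrix,
    write_fasta,
    write_localization_table,
)
from .targets import SITE_CLASSES, normalize_nt, revcomp, seed_match_sites

DEFAULT_STAGES = ("E8", "E13", "D1", "D10")


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset."""

    n_lnc: int = 60
    n_mirna: int = 40
    n_mrna: int = 90
    n_triplets: int = 30
    stages: tuple[str, ...] = DEFAULT_STAGES
    reps_per_stage: int = 3
    noise_sd: float = 0.25
    base_abundance_range: tuple[float, float] = (5.0, 50.0)
    frac_cytoplasmic: float = 0.8
    seed: int = 0
    # miRNAs planted per ceRNA pair; >1 makes planted miRNAs shared across
    # pairs (cyclically) and drives the sponge test's k above 1
    shared_sponges_per_pair: int = 1
    stage_fold_change: float = 4.0
    coexpr_noise_share: float = 0.5
    mirna_length: int = 22
    target_length: int = 300

    def __post_init__(self) -> None:
        if self.n_triplets > min(self.n_lnc, self.n_mirna, self.n_mrna):
            raise ConfigError(
                "n_triplets must be <= min(n_lnc, n_mirna, n_mrna)"
            )
        if self.n_triplets < 0:
            raise ConfigError("n_triplets must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.frac_cytoplasmic <= 1:
            raise ConfigError("frac_cytoplasmic must be in [0, 1]")
        if len(self.stages) < 2:
            raise ConfigError("stages must list at least 2 stage labels")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError("stages must be unique")
        if self.reps_per_stage < 2:
            raise ConfigError("reps_per_stage must be >= 2")
        if not (0 < self.base_abundance_range[0] <= self.base_abundance_range[1]):
            raise ConfigError("base_abundance_range must be 0 < lo <= hi")
        if not 1 <= self.shared_sponges_per_pair <= max(self.n_triplets, 1):
            raise ConfigError(
                "shared_sponges_per_pair must be in [1, n_triplets]"
            )
        if self.stage_fold_change <= 1:
            raise ConfigError("stage_fold_change must be > 1")
        if not 0 <= self.coexpr_noise_share <= 1:
            raise ConfigError("coexpr_noise_share must be in [0, 1]")
        if self.mirna_length < 8:
            raise ConfigError("mirna_length must be >= 8")
        if self.target_length < 80:
            raise ConfigError("target_length must be >= 80")


@dataclass
class SyntheticDataset:
    """One generated dataset plus its ground truth."""

    config: SimConfig
    lnc_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    truth_triplets: list[Triplet]
    localization: LocalizationTable
    mirna_fasta: dict[str, str] = field(default_factory=dict)
    lnc_fasta: dict[str, str] = field(default_factory=dict)
    mrna_fasta: dict[str, str] = field(default_factory=dict)

    @property
    def design(self) -> SampleDesign:
        return SampleDesign.from_sample_ids(
            self.lnc_expr.sample_ids, list(self.config.stages)
        )


# -- sequence planting -----------------------------------------------------


def plant_seed_sites(
    mirna_seq: str, target_seq: str, site_class: str, position: int
) -> str:
    """Write the canonical seed site of ``site_class`` into ``target_seq``.

    The site text is the reverse complement of miRNA positions 2-8 (8mer,
    7mer-m8) or 2-7 (7mer-A1, 6mer), with a trailing A for the A1 classes.
    Only the site's own bases are replaced; coordinates are 0-based.
    """
    if site_class not in SITE_CLASSES:
        raise ParameterError(f"unknown site class {site_class!r}")
    m = normalize_nt(mirna_seq, "miRNA")
    if len(m) < 8:
        raise ParameterError("miRNA sequence must be at least 8 nt")
    t = normalize_nt(target_seq, "target")
    core7, core6 = revcomp(m[1:8]), revcomp(m[1:7])
    site = {
        "8mer": core7 + "A",
        "7mer-m8": core7,
        "7mer-A1": core6 + "A",
        "6mer": core6,
    }[site_class]
    if position < 0 or position + len(site) > len(t):
        raise BoundsError(
            f"site of length {len(site)} at position {position} exceeds "
            f"target of length {len(t)}"
        )
    return t[:position] + site + t[position + len(site):]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _pick_mirna_seqs(
    rng: np.random.Generator, n_planted: int, n_total: int, length: int
) -> list[str]:
    """miRNA sequences whose planted seed cores are mutually disjoint.

    For planted miRNAs the 6mer cores (positions 2-7) are distinct and no
    miRNA's full 8mer site pattern contains another planted miRNA's core,
    so planted sites never hide a foreign core that scrubbing cannot reach.
    """
    def contexts(core7: str) -> list[str]:
        return [core7 + x for x in "ACGT"]

    seqs: list[str] = []
    cores: list[str] = []
    core7s: list[str] = []
    while len(seqs) < n_planted:
        cand = _random_seq(rng, length)
        core6 = revcomp(cand[1:7])
        core7 = revcomp(cand[1:8])
        ok = core6 not in cores
        for other_core, other_core7 in zip(cores, core7s):
            if any(other_core in ctx for ctx in contexts(core7)):
                ok = False
            if any(core6 in ctx for ctx in contexts(other_core7)):
                ok = False
        if ok:
            seqs.append(cand)
            cores.append(core6)
            core7s.append(core7)
    while len(seqs) < n_total:
        seqs.append(_random_seq(rng, length))
    return seqs


def _scrub_foreign_cores(
    seq: str,
    cores: list[str],
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> str:
    """Destroy every occurrence of any planted core outside protected windows."""
    chars = list(seq)

    def in_protected(i: int) -> bool:
        return any(a <= i < b for a, b in protected)

    for _ in range(max_rounds):
        dirty = False
        text = "".join(chars)
        for core in cores:
            start = 0
            while True:
                p = text.find(core, start)
                if p < 0:
                    break
                window = range(p, p + len(core))
                if all(in_protected(i) for i in window):
                    start = p + 1
                    continue
                editable = [i for i in window if not in_protected(i)]
                i = editable[len(editable) // 2]
                choices = [c for c in "ACGT" if c != chars[i]]
                chars[i] = choices[int(rng.integers(len(choices)))]
                dirty = True
                break
            if dirty:
                break
        if not dirty:
            return "".join(chars)
    raise ValidationError("could not scrub planted seed cores from sequence")


# -- expression ------------------------------------------------------------


def _sample_ids(config: SimConfig) -> list[str]:
    return [
        f"{stage}_{rep + 1}"
        for stage in config.stages
        for rep in range(config.reps_per_stage)
    ]


def _noisy(
    means_per_stage: np.ndarray,
    config: SimConfig,
    z: np.ndarray,
) -> np.ndarray:
    """Expand per-stage means to per-sample values with log2-scale noise."""
    per_sample = np.repeat(means_per_stage, config.reps_per_stage)
    return per_sample * np.power(2.0, config.noise_sd * z)


def simulate_timecourse(config: SimConfig) -> SyntheticDataset:
    """Generate a dataset with planted ceRNA triplets and decoys."""
    rng = np.random.default_rng(config.seed)
    T = len(config.stages)
    n_samples = T * config.reps_per_stage
    samples = _sample_ids(config)
    lo, hi = config.base_abundance_range
    g = config.stage_fold_change
    P = config.n_triplets
    s = config.shared_sponges_per_pair

    up = g ** np.arange(T)          # planted miRNA stage trend
    down = g ** np.arange(T)[::-1]  # planted lncRNA/mRNA stage trend
    flat = np.ones(T)

    lnc_ids = [f"LNC{i:04d}" for i in range(config.n_lnc)]
    mirna_ids = [f"MIR{i:04d}" for i in range(config.n_mirna)]
    mrna_ids = [f"MRNA{i:04d}" for i in range(config.n_mrna)]

    def baseline() -> float:
        return float(rng.uniform(lo, hi))

    # shared log-noise per planted pair x sample (ceRNA co-regulation)
    w = config.coexpr_noise_share
    z_pair = rng.standard_normal((max(P, 1), n_samples))

    def planted_partner_z(pair_idx: int) -> np.ndarray:
        own = rng.standard_normal(n_samples)
        return np.sqrt(w) * z_pair[pair_idx] + np.sqrt(1.0 - w) * own

    def expr_matrix(ids: list[str], gene_class: str, planted_trend: np.ndarray,
                    partner: bool) -> pd.DataFrame:
        rows = np.empty((len(ids), n_samples))
        for i in range(len(ids)):
            trend = planted_trend if i < P else flat
            if partner and i < P:
                z = planted_partner_z(i)
            else:
                z = rng.standard_normal(n_samples)
            rows[i] = _noisy(baseline() * trend, config, z)
        return pd.DataFrame(rows, index=ids, columns=samples)

    lnc_df = expr_matrix(lnc_ids, "lncRNA", down, partner=True)
    mirna_df = expr_matrix(mirna_ids, "miRNA", up, partner=False)
    mrna_df = expr_matrix(mrna_ids, "mRNA", down, partner=True)

    # truth triplets: pair i sponges miRNAs i .. i+s-1 (mod P)
    truth = [
        Triplet(lnc_ids[i], mirna_ids[(i + j) % P], mrna_ids[i])
        for i in range(P)
        for j in range(s)
    ]

    # localization: planted lncRNAs cytoplasmic, decoys per frac_cytoplasmic
    other = ("Nucleus", "Ribosome", "Exosome")
    compartments: dict[str, str] = {}
    for i, lnc in enumerate(lnc_ids):
        if i < P or rng.uniform() < config.frac_cytoplasmic:
            compartments[lnc] = "Cytoplasm"
        else:
            compartments[lnc] = other[int(rng.integers(len(other)))]

    # sequences: miRNAs use U (RNA), targets use T (DNA)
    mirna_seqs = _pick_mirna_seqs(rng, P, config.n_mirna, config.mirna_length)
    mirna_fasta = {
        mid: seq.replace("T", "U") for mid, seq in zip(mirna_ids, mirna_seqs)
    }
    planted_cores = [revcomp(seq[1:7]) for seq in mirna_seqs[:P]]

    lnc_fasta = {lid: _random_seq(rng, config.target_length) for lid in lnc_ids}
    mrna_fasta = {mid: _random_seq(rng, config.target_length) for mid in mrna_ids}
    protected: dict[str, list[tuple[int, int]]] = {}
    planted_sites: list[tuple[str, str, int, str]] = []  # (fasta key, target, pos, class)

    for t_idx, trip in enumerate(truth):
        mirna_idx = mirna_ids.index(trip.mirna)
        site_class = SITE_CLASSES[t_idx % len(SITE_CLASSES)]
        # slot j of pair i: sites of the same pair's sponges never overlap
        slot = t_idx % s
        pos = 20 + 40 * slot + int(rng.integers(0, 10))
        for book, key in ((lnc_fasta, trip.lncrna), (mrna_fasta, trip.mrna)):
            book[key] = plant_seed_sites(mirna_seqs[mirna_idx], book[key],
                                         site_class, pos)
            seq = book[key]
            # pin context bases so the planted class is what a scan recovers
            if site_class == "7mer-m8" and pos + 7 < len(seq) and seq[pos + 7] == "A":
                seq = seq[: pos + 7] + "G" + seq[pos + 8:]
            if site_class == "6mer" and pos + 6 < len(seq) and seq[pos + 6] == "A":
                seq = seq[: pos + 6] + "G" + seq[pos + 7:]
            book[key] = seq
            span = {"8mer": 8, "7mer-m8": 8, "7mer-A1": 7, "6mer": 7}[site_class]
            protected.setdefault(key, []).append((pos, pos + span))
            planted_sites.append((key, trip.mirna, pos, site_class))

    for book in (lnc_fasta, mrna_fasta):
        for key in book:
            book[key] = _scrub_foreign_cores(
                book[key], planted_cores, protected.get(key, []), rng
            )

    # verify plant-then-scan round trip for every truth site
    seq_of = {**lnc_fasta, **mrna_fasta}
    for key, mirna, pos, site_class in planted_sites:
        hits = [
            st
            for st in seed_match_sites(mirna_fasta[mirna], seq_of[key])
            if st.start == pos and st.site_class == site_class
        ]
        if len(hits) != 1:
            raise ValidationError(
                f"planted {site_class} for {mirna} in {key} at {pos} not recovered"
            )

    return SyntheticDataset(
        config=config,
        lnc_expr=ExpressionMatrix(lnc_df, "lncRNA"),
        mirna_expr=ExpressionMatrix(mirna_df, "miRNA"),
        mrna_expr=ExpressionMatrix(mrna_df, "mRNA"),
        truth_triplets=sorted(set(truth)),
        localization=LocalizationTable(compartments),
        mirna_fasta=mirna_fasta,
        lnc_fasta=lnc_fasta,
        mrna_fasta=mrna_fasta,
    )


# -- persistence -----------------------------------------------------------

DATASET_FILES = (
    "lnc_expr.tsv",
    "mirna_expr.tsv",
    "mrna_expr.tsv",
    "lnc.fa",
    "mirna.fa",
    "mrna.fa",
    "truth_triplets.tsv",
    "localization.tsv",
)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> list[Path]:
    """Write the dataset as plain-text files; returns the manifest."""
    if ds.lnc_expr.values.empty or ds.mirna_expr.values.empty or ds.mrna_expr.values.empty:
        raise ValidationError("refusing to write a dataset with empty matrices")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(ds.lnc_expr, out / "lnc_expr.tsv")
    write_expression_matrix(ds.mirna_expr, out / "mirna_expr.tsv")
    write_expression_matrix(ds.mrna_expr, out / "mrna_expr.tsv")
    write_fasta(ds.lnc_fasta, out / "lnc.fa")
    write_fasta(ds.mirna_fasta, out / "mirna.fa")
    write_fasta(ds.mrna_fasta, out / "mrna.fa")
    pd.DataFrame(
        [(t.lncrna, t.mirna, t.mrna) for t in ds.truth_triplets],
        columns=["lnc_id", "mirna_id", "mrna_id"],
    ).to_csv(out / "truth_triplets.tsv", sep="\t", index=False)
    write_localization_table(ds.localization, out / "localization.tsv")
    return [out / name for name in DATASET_FILES]
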