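# cernakit

Inference of lncRNA–miRNA–mRNA competitive-endogenous-RNA (ceRNA) networks
from staged bulk expression data, plus a synthetic-data generator with
planted ceRNA triplets for end-to-end validation.

The pipeline follows the classic ceRNA construction recipe:

1. **Differential expression** per pairwise stage comparison (Welch's
   t-test on log2(abundance + 1), BH-FDR), gated at `FDR < 0.05` and
   `|log2FC| > 1`, pooled by union across comparisons.
2. **Target prediction**: canonical seed matching (8mer, 7mer-m8,
   7mer-A1, 6mer) of DE miRNAs against DE lncRNA/mRNA sequences, with
   optional intersection against externally supplied target tables.
3. **Anti-correlation gate**: retain miRNA–lncRNA / miRNA–mRNA pairs with
   Spearman ρ < −0.85 (strict) across all samples.
4. **Candidate ceRNA pairs**: every (lncRNA, mRNA) pair sharing ≥ 1
   retained miRNA.
5. **Co-expression gate**: Pearson r > 0.9 (strict).
6. **Shared-sponge test**: hypergeometric tail probability of the shared
   miRNA count (universe = all miRNAs in any retained pair), p < 0.05.
7. **Localization gate**: keep pairs whose lncRNA is cytoplasmic;
   unlabeled lncRNAs are dropped unless `--keep-unlocalized`.
8. Each surviving pair expands into one triplet per shared miRNA; hub
   lncRNAs are the top 5 by connectivity degree; network mRNAs are
   clustered into STEM-style trend profiles with exact stage-permutation
   significance.

## CLI

```bash
# one-shot pipeline on synthetic data
cat > run.yaml <<EOF
simulate: {n_lnc: 60, n_mirna: 40, n_mrna: 90, n_triplets: 30}
out_dir: my_run
EOF
cernakit run --config run.yaml --seed 1

# individual stages
cernakit simulate --out data --seed 1
cernakit de --lnc data/lnc_expr.tsv --mirna data/mirna_expr.tsv \
            --mrna data/mrna_expr.tsv --out de_out
cernakit targets --mirna data/mirna.fa --lnc data/lnc.fa --mrna data/mrna.fa \
                 --out targets_out
cernakit targets-intersect a.tsv b.tsv --out consensus.tsv
cernakit network --targets-lnc targets_out/targets_lnc.tsv \
                 --targets-mrna targets_out/targets_mrna.tsv \
                 --lnc data/lnc_expr.tsv --mirna data/mirna_expr.tsv \
                 --mrna data/mrna_expr.tsv --loc data/localization.tsv \
                 --out net_out
cernakit hubs --network net_out/cerna_network.gml --top 5
cernakit subnet --network my_run/cerna_network.gml --format gml \
                --mirnas MIR0001,MIR0002 --out sub.tsv
cernakit enrich --query genes.txt --sets sets.gmt --universe universe.txt
```

`cernakit run` writes every intermediate table, a GML network, trend
tables, and `run_report.json` (stage-by-stage survivor funnel, hub list,
significant profiles, manifest). Identical config + seed reproduces
byte-identical outputs.

## File formats

- Expression matrices: TSV, `gene_id` in column 1, header = sample ids of
  the form `STAGE_rep` (e.g. `E8_1`).
- Target tables: TSV with `mirna_id`, `target_id` (+ optional
  `target_class`, `site_class`, `source`).
- Localization: TSV `lnc_id`, `compartment` ∈ {Cytoplasm, Nucleus,
  Ribosome, Exosome} (case-insensitive).
- Annotation sets: GMT-like TSV (`set_id`, description, members...).
- Networks: GML / GraphML / edge TSV, nodes typed lncRNA/miRNA/mRNA,
  edges typed sponge (lncRNA–miRNA) / target (miRNA–mRNA).
- Sequence-site coordinates are 0-based half-open on the target's sense
  strand; miRNA FASTA may use U, targets T (normalized internally).

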