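# metscreen

Design, simulation and deconvolution of **pooled in vivo gain-of-function
metastasis screens**.

In such a screen, candidate open reading frames (ORFs) — each carried by a
lentiviral construct with a unique DNA barcode — are expressed individually
in tumor cells, pooled in groups of at most 12 together with a GFP
negative-control construct, and implanted orthotopically into the mammary
fat pads (MFPs) of 10 mice per pool. At endpoint, barcode qPCR on genomic
DNA from the frozen **reference pellet**, each **MFP tumor**, and each
mouse's **lung metastases** reveals which constructs drove cells into the
lung. `metscreen` provides, for screeners and methodologists:

- **screen design**: minimum-Hamming-distance DNA barcodes and
  shuffle-then-chunk pool partitioning;
- a **stochastic simulator** of barcode dynamics through the engraftment and
  lung-seeding bottlenecks, emitting ground-truthed long-format Cq tables;
- **ΔΔCt deconvolution**: replicate collapsing, total-DNA (DNA_REF)
  normalization, fold change versus the reference pellet, matched-pair
  lung-vs-mammary enrichment, per-gene aggregation with a ≥3-pair rule;
- **empirical-control hit calling**: a cutoff derived from GFP's mean lung
  enrichment (fallback 5), quadrant classification on the MFP and lung axes,
  an alternative two-fold mammary-depletion rule, and deterministic ranking;
- Monte-Carlo **pool-size power** and **library-complexity** experiments
  (why a driver is detectable at 1:10 dilution but masked at 1:19).

## The statistic at the core

For construct *i* in sample *s*, with Cq the qPCR quantification cycle:

    ΔCt_i(s)  = Cq_i(s) − Cq_DNA_REF(s)                 (total-DNA normalization)
    FC_i(s)   = 2^−(ΔCt_i(s) − ΔCt_i(reference pellet)) (ΔΔCt fold change)
    r_i(mouse) = FC_i(lung) / FC_i(MFP)                  (matched pair)

    enrichment score_i = mean of r_i over matched pairs   (requires ≥ 3 pairs)

A construct is a hit when its enrichment score reaches the empirical control
level — the mean score of GFP, ≈5 under the default conditions. Censored
("undetermined") wells carry an explicit flag; by default a censored lung
well means the barcode was absent from the lesion and voids the pair.

## Worked example

Design a 24-candidate library, simulate a screen in which `ORF010` carries
an 8-fold (2³) metastasis advantage, quantify, and call hits:

```bash
metscreen design --n-candidates 24 --barcode-length 12 --min-hamming 3 \
    --seed 7 -o pools.json --write-manifest manifest.tsv
cat > sim.yaml <<'EOF'
mice_per_pool: 10
effects:
  ORF010: [0.0, 3.0]   # [growth advantage g, metastasis advantage m], log2
EOF
metscreen simulate --pools pools.json --config sim.yaml --seed 7 -o cq.csv --truth truth
metscreen quantify --cq cq.csv -o enrichment.tsv
metscreen call --enrichment enrichment.tsv --manifest manifest.tsv -o hits.tsv
```

The top of `hits.tsv`:

```
 rank orf_id  enrichment_score  mean_fc_mfp     quadrant  n_pairs  is_hit
  1.0 ORF010          9.935037     1.068254 lung_and_mfp        5    True
  2.0 ORF008          8.578576     1.334766 lung_and_mfp        3    True
  3.0 ORF019          7.839826     1.121922 lung_and_mfp        3    True
  NaN ORF022         14.534938     0.949266    lung_only        1   False
```

The true driver ranks first: its barcode reached the lungs of 5 mice
(`n_pairs`) at ~10-fold over-representation relative to its MFP abundance.
ORF008 and ORF019 are neutral constructs that drifted through the
lung-seeding bottleneck in exactly 3 mice — the screen's intrinsic false
positives, indistinguishable on the score axis alone (see
`docs/methods.md`). ORF022 shows a huge score from a single lung and is
correctly excluded by the ≥3-pair rule (`rank` empty, `is_hit` False).

`metscreen run --seed 1 -o out/` executes the whole default-format pipeline
(230 candidates → 20 pools × 10 mice) and writes a `report.json` whose
artifact hashes are bit-stable per seed; `metscreen power` and
`metscreen complexity` run the pool-size experiments.

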