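# ripchip

Analysis pipeline for **RIP-chip** experiments — ribonucleoprotein
immunoprecipitation analysed with two-channel DNA microarrays.  A tagged bait
protein is purified together with its associated RNAs; the co-purified RNAs
are hybridised against a total-RNA reference, and the pipeline decides which
mRNAs are reproducibly enriched in the immunoprecipitate.  Applied to
polysome-associated proteins, this identifies mRNAs bound *cotranslationally*
(through the nascent peptide they encode), so the package also scores the
perturbations used to establish translation dependence: start-codon (−ATG)
mutants, puromycin and EDTA treatments.

It is aimed at anyone analysing two-channel pulldown arrays — or studying the
statistics of the enrichment-calling procedure itself — and ships a seeded
synthetic-data generator with ground truth so the whole pipeline can be
exercised and validated without any array data.

## Method

For each hybridisation:

1. **Spot QC** — a spot is kept when the fraction of foreground pixels above
   (median background + 2 SD) meets per-platform thresholds: on PCR-spotted
   arrays ≥ 55% in the IP channel *and* ≥ 90% in the total-RNA channel, or
   ≥ 90% in the IP channel alone; on oligonucleotide (Agilent-style) arrays
   the thresholds are 70%, 98% and 98%.  Scanner-flagged spots are dropped
   first.  Only probes annotated to coding sequences are analysed.
2. **Enrichment ratio** — per gene *g*, `R_g = median over probes of
   log10(IP / reference)`, dye-swap orientation resolved first.
3. **Scores** — with `m = mean(R)`, `Md = median(R)`, `σ = sd(R)` over all
   genes in the experiment: `z_g = (R_g − m)/σ` (plotting scale, mean 0 /
   SD 1) and `s_g = (R_g − Md)/σ` ("SD above the median enrichment", the
   selection scale).
4. **Calling** — gene *g* is enriched in one replicate when `s_g ≥ τ`
   (default τ = 2, inclusive).  Only genes enriched in **every** independent
   biological replicate enter the consensus; a blacklist of common
   non-specific contaminants is then subtracted.  Under replicate
   independence the expected false-positive fraction is `p^k` (default
   p = 0.05): 0.05 for k = 1, 2.5×10⁻³ for k = 2, 6.25×10⁻⁶ for k = 4.
5. **Classification** — each bait is `empty` (no enriched mRNA), `bait_only`
   (cognate mRNA only) or `targets` (non-cognate mRNAs called).
6. **Perturbations** — per (bait, mRNA, condition, replicate) the report
   carries the numeric `s`, or `ND` (not detectable in the IP) or `P`
   (present, but too few genes to compute the background).  A condition pair
   is `lost` when the mRNA is enriched in every baseline replicate and no
   treated replicate, `retained` when enriched throughout, otherwise
   `inconclusive`.

See `docs/methods.md` for the full model, the synthetic-data generator and
all numerical conventions.

## Worked example

Simulate a 3-replicate experiment (5,000 genes, one bait at 6 SD, two
planted targets at 5 and 3 SD, two sticky contaminants at 4 SD) and call
targets:

```sh
$ ripchip simulate --seed 1 --out demo
$ ripchip call demo --out demo/calls
bait=g2060 category=targets consensus=3 fp_expected=0.000125
$ head -8 demo/calls/callset.tsv
# ripchip callset v1
# bait=g2060
# category=targets
# k=3
# fp_expected=0.00012500000000000003
bait    gene_id   replicate_support  mean_s   is_bait_mrna  category
g2060   g1430     3/3                4.99864  0             targets
g2060   g2060     3/3                5.99837  1             targets
```

The consensus contains exactly the planted truth: the bait's own mRNA
(`g2060`, mean s ≈ 6), and the two targets (`g1430` at s ≈ 5; `g2078`, not
shown above, at s ≈ 3), each supported by 3/3 replicates.  The two planted
contaminants were called per replicate but removed by the blacklist the
generator emits, and `fp_expected = 0.05³` is the nominal false-positive
fraction of a 3-replicate consensus.  `ripchip qc`, `ripchip perturb` and
`ripchip report` expose the remaining stages (the last one prints per-bait
category counts and box-plot summary statistics of the enrichment
distribution).

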