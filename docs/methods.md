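# Methods

This note documents the statistical model behind `ripchip`, the synthetic
data it is validated on, and the numerical conventions chosen where the
procedure leaves room.

## The enrichment model

A RIP-chip hybridisation compares two channels per spot: the
immunoprecipitate (IP) and a total-RNA reference purified from the same
extract.  For a gene with no specific association to the bait, the IP
channel contains only non-specific carryover, roughly proportional to the
mRNA's abundance — the same proportionality that drives the reference
channel — so its log-ratio scatters around a common baseline.  A specific
association adds signal to the IP channel only, shifting the gene's
log-ratio to the right of the background distribution.  The analysis
therefore works entirely on the per-experiment distribution of per-gene
median log10 ratios `R_g`:

* `z_g = (R_g − mean)/σ` standardises the distribution to mean 0 / SD 1
  (used for plotting and cross-experiment comparison);
* `s_g = (R_g − median)/σ` measures "SD above the median enrichment" and is
  the selection statistic, because the median is robust to the small number
  of genuinely enriched genes in the upper tail.

Both scores share the same sample SD (n−1 denominator, computed about the
mean), so `s − z` is constant within an experiment.  Enrichment calls use
`s_g ≥ τ` with τ = 2 inclusive ("at least two standard deviations").

### Replicates and false positives

Calls must hold in every independent biological replicate.  Treating the
per-replicate false-positive fraction as a constant p, independence across
replicates gives an expected consensus false-positive fraction of `p^k`.
The conventional p = 0.05 is kept as the default for this arithmetic; note
that a one-sided threshold at 2 SD on a normal background corresponds to a
tail of ≈ 0.023 (two-sided: 0.0455).  The package exposes the calibrated
one-sided value as `target_calling.one_sided_normal_tail`, and the null
simulations below confirm the ≈ 0.023 per-replicate rate and its square for
a two-replicate consensus.  We implement the rule as one-sided (scores are
thresholded above the median only) and report both rates rather than decide
which rounding the conventional 0.05 reflects.

### Contaminant blacklist

Some mRNAs bind beads/tags non-specifically and pass the threshold across
unrelated baits.  `derive_contaminant_blacklist` reconstructs a blacklist
from a panel of call sets: a gene is blacklisted when called for at least
`min_fraction` (default 0.5) of baits other than its own (cognate mRNAs are
exempt for their own bait), requiring at least `min_baits` (default 4)
baits.  These two parameters are conventions of this package, exposed in
config; any practical panel should tune them against known controls.

## Spot quality control

The per-platform rule keeps a spot when `(ip_frac ≥ a AND ref_frac ≥ b) OR
ip_frac ≥ c`, with (a, b, c) = (0.55, 0.90, 0.90) for PCR-spotted arrays
and (0.70, 0.98, 0.98) for oligonucleotide arrays; all comparisons are
inclusive ("a minimum of 55%" includes 55%).  The parenthetical IP-alone
clause is read as an OR over the whole conjunction, identically structured
on both platforms.  `ip_detectable` (the IP channel alone clears c) is
recorded for every spot because the perturbation reports need it: an mRNA
with no detectable spot in the IP is coded `ND`.  The pipeline consumes
pre-computed pixel fractions; it never sees pixels, and it performs no
background subtraction or spatial normalisation.

## Perturbation reports

`score_or_code` emits, per (gene, scan): the numeric `s` when a background
distribution is available; `ND` when no spot of the gene is IP-detectable;
`P` when the gene is detectable but the background is not computable —
fewer than `min_background` genes (default 200) survive QC, or the
background has zero spread.  The numeric cutoff behind "clearly present" is
a reconstruction: we use the stand-alone IP detectability threshold.

Verdicts require unanimity across replicates: `lost` needs every baseline
replicate at or above τ and every treated replicate below; `retained` needs
all replicates in both arms at or above τ; anything else — including
baseline mRNAs that were never enriched — is `inconclusive`.  `ND` counts
as below threshold (an undetectable mRNA cannot be enriched).  A `P` cell
is substituted with both readings (above and below τ); the verdict stands
only if all substitutions agree.  There is no "gained" category; an
enrichment appearing only under treatment reports as `inconclusive`.

`compare_raw_expression` deliberately bypasses QC and normalisation: it
pairs raw reference-channel signals per probe between two designs, the
sanity check that an untranslatable (−ATG) mRNA is still expressed at
wild-type-like levels.

## Synthetic data generator

`synthetic_data.simulate_experiment` emulates the structure of real
two-channel pulldown data.  Per gene, abundance `A_g` is log-normal
(defaults: log10 mean 2.0, SD 0.6 — a realistic three-decade dynamic range
for a yeast transcriptome).  Per spot:

* reference signal `= A_g × 10^ε`, ε ~ N(0, 0.1²) in log10 units;
* IP signal `= A_g × carryover × gain × effect × 10^ε'`, with carryover
  0.01 (1% non-specific background), scanner gain 100 (PMT settings put
  both channels on a common scale), independent spot noise ε′.

Defaults follow the study design being emulated: 5,000 coding genes (the
order of the fission-yeast coding set), 3 probes per gene (array designs
carry a platform-determined probe multiplicity between 2 and 5; a per-gene
range is configurable), k = 3 biological replicates with the last replicate
dye-swapped (dye-swapped scans store exchanged channel columns, resolved
from metadata before analysis), one bait mRNA at 6 SD, two targets at 5 and
3 SD, two non-specific contaminants at 4 SD, and 50 non-coding control
probes that the annotation filter must exclude.

**Effect calibration.**  Effects are specified in SD units of the resulting
profile, not raw multipliers.  The generator applies the same QC rule the
pipeline will apply, computes the post-QC background median and SD, and
solves (three fixed-point iterations; the median log-ratio is linear in a
common per-gene boost) for the IP boost that lands each spiked gene's
`R_g` at `median + effect·σ`.  Realised `s` scores match the configured
values to < 0.01 SD, so recovery tests are robust to any noise settings.

**Pixel-quality model.**  Pixel fractions follow a logistic link from the
spot's *expected* log10 signal (midpoint 0.8, slope 4.0 in log10 units ⇒
a gene at signal 10^1.35 sits at the 90% detection point, leaving ~85% of
the default transcriptome detectable in the reference channel).  The
fractions carry no additional per-spot jitter, so all spots of a gene pass
or fail QC together.  This is a deliberate contract: surviving genes are
always measured with their full probe complement, per-gene measurement
precision stays homogeneous, and spurious genes enter a k-replicate
consensus at the rate (per-replicate tail)^k that the calling theory
assumes.  Real scans violate this mildly (partial probe dropout correlates
with abundance across replicates and thickens consensus tails), which is
one reason real panels additionally rely on a contaminant blacklist.

**Condition semantics.**  `minus_atg` removes the designated mRNA's
enrichment only, leaving its reference-channel abundance unchanged
(optionally scaled by `minus_atg_abundance_factor` to emulate degradation);
`puromycin` and `edta` remove bait and target enrichments (polysome
disassembly) while contaminants persist (non-ribosomal binding); `mock`
equals `control`.  Noise draws are condition-independent for a fixed seed,
so paired condition comparisons are spot-for-spot comparable.

**What the generator does not model** — and hence what passing tests do not
establish about real data: spatial artefacts and gridding errors, dye-
specific intensity bias (swaps exchange channels symmetrically), partial
within-gene probe dropout (above), sequence-dependent probe affinity,
correlated biological variation between replicates, and real noise
magnitudes, which are not published for the emulated data set; the defaults
are plausible placeholders exposed in config, not estimates.

## Numerical conventions and degenerate inputs

* Median of an even number of values = mean of the middle two.
* SD is always the sample SD (n−1).
* Box plots use linear-interpolation ("type 7") quartiles; whiskers are the
  most extreme data values within 1.5×IQR of the quartiles; everything
  beyond is reported individually.
* Spots with a non-positive signal in either channel are excluded before
  the log, never clamped; genes losing all spots drop out of the profile.
* A zero-spread background raises a degenerate-profile error; fewer than
  `min_background` genes raises a background-too-small error (mapped to
  code `P` in perturbation reports).
* QC reason codes use fixed precedence: flagged > low_ip_frac >
  low_ref_frac.
* All generator randomness flows through one integer seed
  (`numpy.random.SeedSequence`); a fixed seed yields byte-identical files.

## Problem sizes used in validation

The test suite and acceptance script run the generator at its default
5,000-gene scale for calibration and recovery (20 seeded runs for
recovery; 5 per perturbation condition), and at 600–2,000 genes for
unit-level checks.  With 3 probes per gene this is ~15,000 spots per scan,
chosen to keep per-gene probe statistics and background estimation
realistic while each simulated experiment runs in well under a second.

## Known limitations

* The pipeline consumes pre-quantified spot tables in a simplified TSV
  dialect; it does not parse native GenePix GPR/ATF or Agilent Feature
  Extraction files, and it performs no between-array normalisation (none is
  used by the calling procedure it implements).
* The p = 0.05 / p^k arithmetic is a nominal calculus, not an empirical
  FDR; no multiple-testing machinery (e.g. Benjamini–Hochberg) is applied
  beyond replicate intersection.
* Blacklist derivation parameters are conventions, not fitted values.
* The `P` / "clearly present" cutoff is a reconstruction via the
  stand-alone IP detectability threshold.
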