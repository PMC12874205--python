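# Methods

## Measurement model

A protein sample is split in half. One half ("treated") is incubated with
FUT8 and GDP-fucose so that every asparagine capable of carrying core
fucose becomes fucosylated; the other half ("control") retains the
physiological modification levels. Both halves are digested, Endo F3
truncation leaves a fucosyl-GlcNAc disaccharide (+349.1370 Da; theoretical
composition C14H23NO9 = 349.1373 Da) on each core-fucosylated asparagine,
and the six aliquots (3 control + 3 treated replicates) are labeled with TMT
sixplex and pooled. Within one glycopeptide spectrum, reporter intensity is
proportional to the number of tagged copies in each channel, so

- control channel expectation ∝ s (the physiological stoichiometry),
- treated channel expectation ∝ s + c·(1−s),

where c ∈ (0, 1] is the conversion completeness of the in-vitro reaction.
The estimator is the ratio of the summed control channels to the summed
treated channels; its expectation is s/(s + c·(1−s)), unbiased exactly when
c = 1 (`synthdata.closed_form_bias`). Because the stoichiometry is a ratio
within one spectrum, it is invariant to global spectrum scaling and to
between-run loading differences; no between-channel normalization is applied
by default (the control and treated halves intentionally differ in
composition, so loading normalization would be wrong; a median-ratio option
exists for diagnostics). Ionization-efficiency differences between
glycoforms are assumed to cancel because both halves carry the identical
truncated tag.

The six TMT reporter masses are taken from the channel-layout file; the
label's monoisotopic mass is recomputed from its elemental composition
(C8 13C4 H20 N 15N O2 → 229.1629 Da) rather than hard-coded.

## Identification

Selection order: (1) fucosyl-GlcNAc mass tag on N within ±0.01 Da of the
configured 349.1370 Da; (2) mapped protein site must satisfy the
N-glycosylation sequon — +2 residue S/T/C, and P excluded at +1 (the +1 rule
is the canonical sequon definition and can be disabled); (3) peptide length
strictly greater than 7 residues; (4) LDA rescoring and target-decoy FDR on
the surviving population.

The discriminant is a two-class Fisher LDA on standardized features with a
ridge term ε·I, ε = 1e−6·trace(Sw)/d (falling back to 1e−6 when the pooled
scatter is all-zero), oriented so targets score higher on average.
Degenerate (constant) features are dropped before fitting. The FDR estimate
at threshold t is #decoys(≥t)/#targets(≥t); the reported threshold is the
lowest one whose estimate is ≤ α (default 0.01), which maximizes the
accepted set, with score ties accepted or rejected as a block. The
uncorrected decoy/target ratio plus most-permissive-threshold selection is
mildly anti-conservative: on calibrated synthetic data the realized
false-discovery proportion at α = 1% averages ≈ 1.0–1.1%. A +1-corrected
estimator (conservative) and a peptide-level mode (threshold on the best PSM
per peptide) are available as options; defaults are PSM-level, uncorrected.

Peptides occurring more than once in their protein are mapped to the
leftmost occurrence and flagged `ambiguous`. Peptides carrying two or more
glyco tags contribute one quantification per site, flagged `multi-glyco`.
Peptides mapping to multiple proteins are reported under the first accession
alphabetically with a `shared` flag.

## Quantification

Per accepted PSM, the overall ratio is Σ(control)/Σ(treated) on the raw
reporter intensities — identical to the ratio of summed within-spectrum
relative intensities, with one fewer rounding step — and per-replicate
ratios pair channels by replicate index. Per unique glycopeptide (peptide
sequence × protein site; charge and missed-cleavage variants collapsed), the
stoichiometry is the median of PSM ratios, clipped to [0, 1] with a
`clipped` flag when the raw median exceeds 1 (the unclipped value is
retained). Replicate ratios are per-replicate medians across PSMs; the CV is
their sample standard deviation (n−1 denominator) over their mean. All-zero
spectra and zero-treated-signal spectra are excluded with a `low-intensity`
flag. Condition comparisons use Welch's t-test on the two replicate-ratio
triples (p = 1 when both sides have zero variance; p missing with fewer than
two finite replicates) and Benjamini–Hochberg adjustment across compared
keys.

## Site context

13-mer windows are the protein substring site ± 6, truncated without padding
at the termini for GRAVY/aromatic/pI computations; motif counting uses
'-'-padded 13-character windows, treating padded positions as missing (the
per-position count n shrinks accordingly). GRAVY uses the Kyte–Doolittle
scale; the aromatic set defaults to {F, W, Y} (H excluded, configurable);
the isoelectric point is a Henderson–Hasselbalch bisection to 1e−4 pH with
the EMBOSS pKa set — a standard pKa-model approximation, not a learned
predictor. Quartiles P1 (lowest) … P4 (highest) split the ascending stable
sort into contiguous groups; with n = 4q + r the first r groups take one
extra member, and ties straddling a boundary are flagged. Group differences
use the Mann–Whitney U test (midranks for ties; exact enumeration when the
pooled size is ≤ 12 with no ties, otherwise the normal approximation with
tie and continuity corrections, via scipy), with stars at
0.05/0.01/0.001/0.0001.

Motif enrichment is a binomial log-odds: for flanking position p and residue
r, with n foreground windows covering p, k of them carrying r, and q the
background frequency with a 0.5 pseudocount per residue
(q = (count + 0.5)/(N + 10)), the score is −log10 P(Binom(n,q) ≥ k) for
over-representation (k/n > q) and +log10 P(Binom(n,q) ≤ k) otherwise. At
the exact null k = n·q the magnitude is bounded by log10(2); with identical
foreground and background multisets the pseudocount perturbs q by O(10/N)
per cell, so the practical null bound carries a small allowance. The default
background is the position-specific frequencies over all quantified
glycosite windows.

## Synthetic data

The generator draws true stoichiometries from uniform(0,1) by default
(beta(a,b) and fixed lists available), quantized to multiples of 2⁻²⁰
(~1e−6) so that the noiseless measurement arithmetic is exactly
representable in binary floating point — at this granularity the prior is
unchanged in practice, and the noiseless end-to-end identity (estimate ≡
truth) holds bit-exactly. Peptides are tryptic-looking (K/R C-terminus,
occasional internal K/R driving the missed-cleavage feature), 9–18 residues,
with one embedded N-X(≠P)-[S/T/C] sequon, each placed uniquely in its own
synthetic protein with tryptic flanks. Reporter intensities follow the
measurement model around a base intensity of 2²⁰ (≈10⁶, a typical reporter
scale; a power of two so scaling is exact), perturbed per channel by
multiplicative log-normal noise exp(N(0, σ²)). The default σ = 0.07 puts
replicate-ratio CVs near 10% (a ratio of two log-normal channels has CV ≈
σ√2), matching the reproducibility regime of real triplicate TMT
experiments; this is a tuning default, not a reproduction claim.

Search-quality features (XCorr, ΔCorr, ppm error, fraction of ions matched,
mass accuracy) are drawn from per-class Gaussians; structural features
(length, missed cleavages, modification count, charge) come from the
generated peptides. Two presets exist: `overlapping` (realistic target/decoy
overlap, used for FDR-calibration studies) and `clean` (near-perfect
separation, used when a test isolates quantification behavior and must not
lose true targets at the FDR stage). Decoy PSMs — and, at a configurable
rate, "false target" PSMs drawn from the decoy feature distribution but
labeled as targets — carry valid sequons and lengths so the FDR stage is the
operative filter, enabling measurement of the realized false-discovery
proportion against known labels. All randomness flows from a single
mandatory seed; identical parameters give byte-identical output files.

What the generator does **not** emulate: glycan microheterogeneity beyond
the common truncated tag, ionization-efficiency differences between
peptides, chromatographic effects, reporter-ion isotope impurity
(an optional 6×6 correction-matrix hook exists but defaults to identity,
since impurity correction is not part of the core computation), co-isolation
interference, and protein-level inference. Passing tests therefore establish
the correctness of the computation given search results, not the accuracy of
any upstream search engine on real spectra.

## Problem sizes and numerical choices

Tests and the acceptance script use 20 seeds × ~10,000 PSMs for
FDR-calibration checks and 60–300 glycopeptides for recovery checks — sizes
at which the binomial sampling error of the FDP estimate (≈0.03% absolute at
134k accepted PSMs) is far below the 1% quantity being verified, chosen as
the package's own verification scale. Bisection tolerance for pI is 1e−4 pH;
binomial tails are floored at 1e−300 before log10; FDR candidate thresholds
are the observed scores (ties as a block); medians are numpy medians
(mean-of-two for even counts).

## Known limitations

- The realized FDP of the default uncorrected target-decoy estimator
  slightly exceeds the nominal α (see Identification); use the +1-corrected
  option when strict control matters more than sensitivity.
- The pI model is a generic pKa bisection and can deviate from learned
  predictors by >0.5 pH units for unusual compositions.
- Quartile grouping with heavy ties near boundaries is order-stable but
  arbitrary within the tied block (flagged).
- The pipeline begins at PSM tables: search-engine scores and reporter
  intensities are trusted inputs, and no spectrum-level site localization is
  performed.
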