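# fucostoich

Quantifying **core-fucosylation stoichiometry** of N-glycosylation sites from
split-and-treat TMT glycoproteomics data.

Core fucosylation — the α-1,6-fucose that FUT8 attaches to the innermost
GlcNAc of an N-glycan — regulates receptor signaling, adhesion, and antibody
effector function. Knowing *which fraction of the copies* of a site is
core-fucosylated (its stoichiometry, or occupancy) is far more informative
than a binary site list, but standard glycoproteomics only detects the
modified form. The split-and-treat design solves this: each sample is split
in half, one half is driven to **complete** core fucosylation in vitro
(FUT8 + GDP-fucose), both halves are truncated by Endo F3 — leaving a
fucosyl-GlcNAc tag (+349.1370 Da) on every core-fucosylated asparagine — and
the six halves (3 control + 3 treated replicates) are multiplexed in one TMT
sixplex. For every glycopeptide spectrum, the stoichiometry is then

```
s = Σ control reporter intensities / Σ treated reporter intensities
```

because the treated channels count *all possible* core-fucosylation events
while the control channels count only the physiological ones. Redundant PSMs
of the same unique glycopeptide (charge states, missed cleavages) are
aggregated by the median; per-replicate ratios give triplicate CVs. If the
in-vitro conversion is incomplete (completeness c < 1), the measured ratio
converges to `s / (s + c·(1−s))` — a closed form this package also uses as a
simulation oracle.

## What the package does

- **ingest** — PSM tables (TSV), protein FASTA, TMT channel-layout YAML,
  per-site annotation TSVs; peptide→protein site mapping.
- **identify** — selects PSMs carrying the fucosyl-GlcNAc tag on N, validates
  the N-X(≠P)-[S/T/C] sequon, requires peptide length > 7, rescores with a
  ridge-stabilized Fisher LDA over the search-engine quality features
  (XCorr, ΔCorr, missed cleavages, ppm error, fraction of ions matched, mass
  accuracy, length, modification count, charge), and applies target-decoy FDR
  control at 1%.
- **quantify** — per-PSM control/treated ratios, median aggregation per unique
  glycopeptide, replicate CVs, and cross-condition comparison (Welch t-test +
  Benjamini–Hochberg).
- **sitefeatures** — 13-mer site windows, GRAVY (Kyte–Doolittle), aromatic
  counts, isoelectric point, stoichiometry quartiles P1–P4, Mann–Whitney group
  tests, pLogo-style binomial log-odds motif enrichment, annotation-based
  group summaries.
- **synthdata** — a generator that inverts the measurement model with known
  ground truth (true stoichiometries, conversion completeness, log-normal
  reporter noise, decoys, and label-known "false target" PSMs), making the
  full pipeline verifiable end to end.

## Worked example

Simulate a 300-glycopeptide split-and-treat experiment and quantify it:

```bash
$ cat params.yaml
n_glycopeptides: 300
sigma: 0.07

$ fucostoich simulate --seed 42 --params params.yaml --out-dir sim --end-to-end
recovery: MAE=0.0187 over 295 glycopeptides
wrote 806 PSMs to sim/psms.tsv

$ fucostoich quantify --psms sim/psms.tsv --fasta sim/proteins.fasta \
      --layout sim/layout.yaml --out-dir quant
quantified 295 unique glycopeptides (586 accepted PSMs)

$ head -3 quant/stoichiometry.tsv | cut -f1-4,10,11
accession   site  peptide             stoichiometry  cv      n_psms
SYNT00060   20    AALADPQGTNFQNNLSGR  0.690393...    0.0487  2
SYNT00183   19    AHGNWTCFFNDCK       0.325602...    0.0479  2
```

Reading the output: the glycopeptide `AALADPQGTNFQNNLSGR` (asparagine 20 of
its protein) is ~69% core-fucosylated in the control sample, estimated from
2 PSMs with a 4.9% CV across the three replicate channel pairs. The
end-to-end mean absolute error of 0.019 against the known truth reflects the
simulated 7% log-normal reporter noise; with `sigma: 0` the recovery is
exact. Site-context analytics (windows, GRAVY, quartiles, motifs) follow
with:

```bash
$ fucostoich features --stoichiometry quant/stoichiometry.tsv \
      --fasta sim/proteins.fasta --out-dir feat
site context written for 295 sites
```

Two conditions are compared with `fucostoich compare --a ... --b ...`,
yielding per-site deltas, Welch p-values and BH q-values.

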