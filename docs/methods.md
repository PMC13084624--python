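# Methods

## Problem setting

Sulfur mustards — mustard gas (HD), sesquimustard (Q) and O-mustard (T) —
are alkylating chemical-warfare agents. In blood serum they form covalent
adducts on nucleophilic protein residues (Cys, Glu, Asp, His, Met and the
protein N-terminal amine), leaving hydroxyethylthioethyl-type chains:
HETE (Δ = C4H8SO, from HD), HETETE (Δ = C6H12S2O, from Q) and HETEOETE
(Δ = C8H16S2O2, from T). These adducted peptides are long-lived exposure
biomarkers. The package implements the computational workflow for
discovering and verifying such biomarkers: adduct mass chemistry, in
silico digestion, diagnostic-fragment-ion screening of MS2 spectra, a
synthetic-cohort generator with planted ground truth, and the statistical
biomarker-selection procedure. No instrument data is required; every
statistical claim the tests make is demonstrated on simulated cohorts
whose generative structure is described below.

## Mass calculus

Monoisotopic atomic masses are fixed at build time (CODATA/IUPAC values);
compositions are element→count mappings with element-wise arithmetic,
and peptide masses are residue sums plus one water plus modification
deltas. Cation m/z subtracts one electron mass — physically correct, and
both conventions round to the 2-decimal reporter values (HETE C4H9SO⁺ →
105.04, the HETET chain fragment C4H9S2O⁺ → 137.01). The HETETE reporter
C6H13S2O⁺ computes to 165.040; this is the value the screen uses.
I and L are distinct letters with equal mass. Modification positions are
1-based within the peptide; protein sites are 1-based in the FASTA
sequence as given (no N-terminal Met excision). The registry is
user-extensible through YAML (name, delta formula, target residues,
optional N-terminus flag, optional reporter composition) so other
electrophiles can be screened with the same machinery.

## Digestion

Trypsin: cleave after K/R, blocked by a following proline; the proline
rule is a flag because search engines differ on it. All peptides with up
to `max_missed` internal sites are enumerated (default 2). Proteinase K
is modelled as exhaustive substring generation in a short length window
(default 2–4 residues) rather than a kinetic model — its role here is
only to enumerate short adduct carriers such as the albumin Cys34
tripeptide CPF. Modified forms are enumerated combinatorially up to a
per-peptide cap, including the unmodified form; the protein N-terminal
amine is eligible for N-terminus-capable adducts regardless of the
residue letter.

## Spectral screening

The screen looks for the reporter cations in the low-mass region of each
MS2 spectrum within a ppm tolerance (default 20 ppm on both MS levels,
matching a manual-evaluation setting; a 15 ppm precursor / 0.05 Da
fragment engine-style mode is available through the config). A relative
intensity floor (default 1 % of the base peak) stands in for the
visibility threshold implicit in manual evaluation. Diagnostic ions are
always singly charged (small even-electron cations). Precursor matching
against candidate modified peptides is reported separately from the
reporter match so either detection policy — reporter alone, or reporter
plus precursor — can be applied downstream. The synthetic spectrum
generator plants singly charged b/y ions, one reporter per attached
adduct, Gaussian ppm jitter, and uniform decoy peaks, keeping per-peak
ground-truth labels.

## Cohort generator

The generator emulates a serum exposure experiment quantified by DIA.
All intensities are log2.

* **Background peptidome** (default 2000 features): per-feature baseline
  ~ N(20, 2), identical in expectation across groups.
* **Adduct features** (default 150 sites): each site carries one feature
  per exposure agent (that agent's chain). The latent intensity is
  anchored at a residual level (1.6) at a blank pseudo-dose of 1e-12 M —
  the essentially-zero adduct content of unexposed serum — and rises by
  `dose_slope_beta` (default 2.0) log2 units per decade of dose. Control
  samples carry the blank pseudo-dose. With the default detection floor
  of 14, an adduct sits at floor+1 at 5 µM, +3 at 50 µM, +7 at 5 mM and
  below the floor at 0.5 µM, reproducing the detectability ordering of
  the exposure series; in controls it is ~12 log2 units below the floor,
  so presence-only-in-exposed emerges from censoring rather than being
  hard-coded. With `dose_slope_beta = 0` adducts never leave the residual
  level anywhere — the no-effect null, under which the selection pipeline
  should (and does) find nothing.
* **Ionization efficiency**: per-(agent, site) additive log2 offsets.
  In multi-agent designs each site by default favours one agent with a
  +5 log2 offset (ionization preferences between chains span well over an
  order of magnitude in equimolar spike-ins); non-favoured offsets are
  N(0, 1). The offset is additive on the log scale — ionization scales
  signal multiplicatively — rather than a multiplier on the dose slope.
* **Hydrolysis shadows**: in single-agent Q designs, each site gains a
  paired HETE feature with probability `f_HETE` (default 0.16), one log2
  unit dimmer — the second hydrolysis pathway of the thiiranium
  intermediate, which eliminates thiirane and leaves an HETE chain where
  an HETETE chain was expected.
* **Batch and noise**: additive log2 batch shifts shared within batch
  (sd 0.05 — deliberately residual, visible as subclustering but not
  dominating PC1 over the exposure separation) and per-measurement noise
  sd 0.4 (~30 % CV, typical for normalized DIA of abundant serum
  peptides).
* **Censoring**: values below the detection floor become missing
  (missing-not-at-random), encoded NA, distinct from zero.
* **Sex**: donors carry a sex label with no planted effect — a
  negative-control covariate.

Everything is deterministic per seed; different seeds change values but
not dimensions or truth structure.

The enrichment simulator plants one albumin-like protein enriched in the
eluate, a named set depleted, and removes an exact count
`round(drop_fraction × n_proteins)` of sampled protein identities from
the eluate, making the planted count reduction (default 58 %) exactly
recoverable at any seed. It uses quadruplicate measurements by default
so the Welch/BH enrichment call is robust to variance-estimate noise at
small n. The spike-in simulator measures equimolar peptide–adduct
species through per-chain ionization factors plus noise and z-scores
within peptide, from which the factor ordering is recoverable.

### What the generator does not emulate

Chromatographic drift, interference/co-isolation, intensity-dependent
variance, correlated peptides from shared proteins, real ionization
physics, and any spectral-level structure of the cohort (spectra are
simulated only at per-peptide scale in the screening module). Passing the
recovery tests therefore shows the statistical machinery is implemented
correctly and calibrated under its stated model — not that the same
recall would be achieved on instrument data.

## Selection pipeline

Preprocessing: log2, left-censored values imputed with half the
per-feature observed minimum (−1 log2 unit), per-feature z-score;
all-missing and constant features dropped with a warning. PCA is computed
by SVD of the centered matrix; PC1's sign is fixed so the control-group
mean score is positive, which makes exposure-driven loadings negative.
The PCA arm selects features with PC1 loading < −0.01 (a magnitude
threshold on the exposure-pointing side; a |loading| mode is a flag) that
carry the configured adduct chain (HETETE by default). The forest arm
runs stratified 5-fold CV; one 500-tree Gini forest (sqrt(p) features per
split — unstated in the original analysis, so fixed as defaults with
config override) is fit per fold, importance is mean decrease in Gini
impurity averaged over folds, and selection keeps strictly positive
importance; held-out accuracy per fold is reported. Biomarkers are the
set intersection of the two arms. Recovery metrics compare the
intersection to the planted features carrying the configured chain —
HETE hydrolysis partners are found by site pairing afterwards, not
counted as selection targets.

## Downstream statistics

* **Hydrolysis pairs**: sites (protein, position) carrying both HETETE
  and HETE features, each site once.
* **Site distribution**: unique (protein, position) sites tabulated by
  protein × residue.
* **Anonymized clustering**: adduct forms of the same (protein, position,
  sequence) are merged by summing linear-scale intensities (summation
  preserves total site signal while hiding the chain identity), then Ward
  linkage on Euclidean distances of the preprocessed matrix, cut at k;
  purity is the fraction of samples whose cluster majority label matches
  their own.
* **Three-way volcano**: run on the adduct panel (the discovered
  modified-peptide features), not the full background matrix — with n = 3
  per agent, Welch tests have ~4 degrees of freedom, and
  Benjamini–Hochberg across a 2000-feature background pushes the
  effective per-test threshold to |t| ≈ 7–20, destroying power; the
  attribution question is asked of the biomarker panel anyway. Pairwise
  Welch t-tests and log2 fold changes between group means in sorted agent
  order (the triple sums to zero identically), BH at 0.05 across all
  tests, classes: primary when significantly higher in exactly one agent
  vs both others, secondary when higher in exactly two, none otherwise;
  2-D coordinates are the projection of the zero-sum triple onto the
  fixed orthonormal basis {(1,−1,0)/√2, (1,1,−2)/√6} of the plane
  x+y+z = 0 (the projection is a presentation choice and carries no
  inferential content).
* **Enrichment volcano**: per-protein Welch test of eluate vs binding
  replicates, BH at 0.05, enriched/depleted/unchanged calls; proteins
  absent from the eluate count toward the protein-count reduction
  1 − detected/total.
* **Detection calls**: detected iff mean(condition) > mean(blank) +
  3·sd(blank); blanks are control samples with missing values set to an
  LOD proxy (the observed matrix minimum). Welch tests are used
  throughout for robustness at n = 3; BH is the multiplicity procedure
  wherever "significant" is claimed.

## Numerical choices and degenerate inputs

Composition subtraction raising on negative counts; empty formula and
unknown symbols rejected at parse time; rank-0 matrices rejected by PCA;
single-class labels rejected by the forest arm; volcano groups require
≥ 2 replicates and detection calls ≥ 3 blanks; NaN p-values (zero
variance on both sides) are treated as 1. Ties in the screen resolve to
the smallest |ppm|. The global seed fans out to per-stage seeds by
`(seed × 10007 + stage) mod (2³¹ − 1)` so stages can be re-run in
isolation.

## Problem sizes

The bundled analyses use 15+15 samples with 2000 background and 150
planted sites for selection recovery (and 20 seeds of the same size for
the null), 50 seeds of small cohorts for hydrolysis-pair calibration,
3 agents × 3 replicates with a 500-feature background for clustering and
attribution, 500 spectra for screening recovery, and 300 proteins for
the enrichment simulation — sizes chosen to match the emulated study
designs while keeping a full run on a laptop CPU in a few minutes.

## Known limitations

Recall/precision of 1.0 on the default high-exposure cohort reflects the
qualitative presence/absence structure of adducts at 5 mM (as in the
real experiment, where exposed-only features separate cleanly); the
generator's trace-level designs are the harder regime. The forest's
"non-zero importance" rule is permissive on its own — nearly every
feature enters some tree — and is only selective in intersection with
the modification-filtered PCA arm; this mirrors the two-arm design
rather than improving on it. Multi-agent designs currently do not plant
hydrolysis shadows (an HD feature already occupies the HETE slot at each
site). Charge states above 3, isotope patterns, neutral losses other
than the defined reporters, and FDR-controlled peptide-spectrum matching
are out of scope.
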