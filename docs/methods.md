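# Methods

`anthonet` implements the analysis chain used in targeted anthocyanin studies
of flower pigmentation: identification of decorated anthocyanins from
high-resolution MS/MS peak lists, relative quantification against a spiked
internal standard, qRT-PCR standard-curve expression analysis, and
integration of the two data layers through a Pearson correlation network
summarized by node/network strength.  A synthetic-data generator with full
ground truth supports validation of every stage.

## Mass model

Anthocyanins are glycosylated (and often acylated) flavylium cations.  The
flavylium core is permanently charged, so positive-mode electrospray detects
the intact molecular cation [M]+ rather than a protonated adduct.  The
theoretical m/z of a composition is therefore

    m/z = Σ (count_e × monoisotopic mass_e)  −  m_e

summed over the elements of the total formula, minus one electron mass
(m_e = 0.00054858 Da).  Atomic masses are IUPAC monoisotopic values
hard-coded to ≥ 8 decimals (¹²C exact by definition).  Isotope envelopes,
multiple charging and other adducts are out of scope.

Condensation chemistry fixes the bookkeeping: a glycosyl or acyl building
block contributes its free molecule minus one water (the *residue mass*),
while the aglycone contributes its full cation formula.  The default library
holds the three base aglycones (pelargonidin, cyanidin, delphinidin —
orange→blue with increasing B-ring hydroxylation) and six decoration
residues: hexose 162.05282, deoxyhexose 146.05791, malonyl 86.00039,
coumaroyl 146.03678, caffeoyl 162.03169, feruloyl 176.04734 Da.  Libraries
serialize to versioned JSON carrying formulas only; residue masses are
always recomputed on load.

Compositions are multisets, not structures.  Mass decomposition cannot
distinguish glucose from galactose, attachment positions (3- vs 5-O-), E/Z
acyl isomers, or a rutinose disaccharide from separate hexose + deoxyhexose
attachments; display names (e.g. "rutinoside-type") are cosmetic labels over
the multiset and never enter any computation.

## Identification

`decompose_precursor` enumerates the full bounded lattice — every aglycone
plus up to `max_glycosyl` (default 4) glycosyl and `max_acyl` (default 3)
acyl residues — once per library, sorts it by cation m/z, and answers
queries by binary search within a ppm window.  The search is exhaustive
within bounds and verified in the test suite against an independently
written brute-force enumeration.

`explain_fragments` matches each fragment against (a) the precursor minus
*every sub-multiset* of the decoration multiset — linkage topology is
unknown, so any residue combination may depart as a neutral loss — and (b)
the free residue ions of the composition's glycosyls (e.g. rhamnose at
146.058).  The smallest-|ppm| match within `fragment_tol_ppm` (default 10)
wins; everything else is labelled unexplained.

Candidates are ranked by:

1. fragments-explained fraction (share of observed fragments explained),
2. predicted-fragment recall (share of the candidate's expected primary
   series — one ion per distinct single-residue loss plus the aglycone
   ion — actually observed),
3. absolute precursor ppm error,
4. block count (parsimony),
5. lexicographic block ids (determinism).

The recall term exists because of an exact isobaric degeneracy in the
decoration algebra: coumaroyl + hexose and caffeoyl + deoxyhexose have
identical elemental composition, so two candidates related by this swap tie
on explained fraction, ppm and size whenever the distinguishing single
losses are absent from the observed list.  Recall breaks the tie in favor of
the candidate whose own expected ions are present.  Without it, the
lexicographic tie-break would systematically prefer the caffeoyl variant.

Two further diagnostics are independent of decomposition:

* **Aglycone diagnostic.**  Each anthocyanin fragmentation series ends at
  the bare aglycone ion (pelargonidin at m/z 271.060).  A fragment within
  `aglycone_window_da` (default 10 mDa) of an aglycone cation mass
  identifies the pigment class even when the precursor is not decomposable —
  a *class-only* identification.  This fallback is first-class output: real
  identification tables contain typographic or calibration inconsistencies,
  and the engine reports them rather than repairing them (see the
  `consistent`/`decomposable` flags on the built-in reference records).
* **UV glycosylation rule.**  The absorbance ratio E440/Emax of
  3-O-glycosides is roughly twice that of 3,5-di-O-glycosides.  The
  published exemplars (52% vs 25%) are operationalized as thresholds:
  ≥ 40% → 3-glycoside, ≤ 30% → 3,5-glycoside, otherwise ambiguous.  The
  band width is a deliberate decision; the rule is qualitative in origin
  and a hard 2× cutoff would over-claim.

Default tolerances (5 ppm precursor, 10 ppm fragment) suit Orbitrap-class
data; the self-consistent rows of the built-in reference set sit within
2.5 ppm of theory.  Both are configurable.

## Quantification

Per compound and sample the quantifier is the **sum** of the two recorded
fragment-ion areas divided by the internal-standard area of the same sample
(formononetin by default — an isoflavone absent from petal tissue).  Sum vs
mean is arbitrary (a constant factor that cancels in percent composition);
sum is used and documented.  Undetected compounds are true zeros, not
missing.  The fold-over-IS table is exactly invariant to per-sample scaling
of all areas, IS included.

Stage summaries report replicate mean and sample SD (ddof = 1) per compound
and stage; percent composition divides each stage's mean vector by its sum.
Computing percentages on stage means (rather than pooled replicates) is a
documented choice.

Row-directed hierarchical clustering of compound profiles uses
1 − Pearson correlation distance with average linkage (the common
metabolomics heatmap choice; both configurable).  Rows are sorted by id
before clustering so leaf order is deterministic; constant rows are
rejected under correlation distance with a pointer to Euclidean.  The
dendrogram serializes to Newick with merge-height branch lengths.

## Expression

Standard-curve quantification, not ΔΔCt: each gene's dilution series
(conventionally 100–0.16 ng, ≥ 3 points spanning ≥ 2 decades) is fitted by
least squares as Ct = intercept + slope·log10(ng); amplification efficiency
is 10^(−1/slope) − 1.  Quantities interpolate as
10^((Ct − intercept)/slope).  Technical replicates are averaged on the
quantity scale (averaging Ct would weight geometrically); the housekeeping
gene's quantity in the same (tissue, biological replicate) divides each
gene's quantity, making the housekeeping level exactly 1 everywhere.
Normalized levels below 1e-6 of a gene's maximum are floored to zero so
that tissues genuinely lacking a transcript do not acquire meaningless
trace values from late nonspecific amplification; the floor is
configurable.

## Correlation network

All feature pairs (transcript–transcript, transcript–metabolite,
metabolite–metabolite) are correlated across stage × replicate samples
(9 columns in the default design; correlating across replicates rather
than stage means is a documented choice).  Two-sided p-values use the exact
t transform t = ρ√((n−2)/(1−ρ²)) with n−2 df.  Pairs with p ≤ α (default
0.05, raw — no multiple-testing correction by default, with a flag
available) form the significant set.

* node strength ns(i) = mean of |ρ| over i's significant partners
  (0 when it has none; the |ρ| convention keeps ns ∈ [0, 1]),
* network strength NS = mean of ns over all nodes,
* displayed edges: significant pairs with |ρ| ≥ 0.65 (threshold applies to
  |ρ| so anticorrelations are drawn as negative edges); ns/NS always use
  the full significant set, never just the drawn edges.

Flags switch ns to signed ρ and/or to all-pairs averaging.  The all-pairs
variant matters for calibration: with n = 9 and α = 0.05 the significance
boundary is |ρ| ≥ 0.666 (closed form t_crit/√(n−2+t_crit²)), so the mean of
*significant* |ρ| is a truncated mean with an irreducible upward bias of
roughly +0.07 near |ρ| ≈ 0.76.  The significant-pairs statistic is the
right descriptive summary of a reported network; the all-pairs statistic is
the right estimator of an unconditional design mean.

## Synthetic data

The generator emulates the study-shaped inputs with known truth.

**Spectra.**  Ground-truth fragmentation produces one ion per distinct
single-residue loss plus the aglycone ion (optionally free glycosyl residue
ions), with independent Gaussian relative mass error (default 2 ppm,
matching the ≤ 2.5 ppm errors of the reference set), a decreasing lognormal
intensity profile, and uniform-random decoy peaks.  The generator's
single-loss model is deliberately narrower than the annotator's
any-sub-multiset search model, so recovery experiments never test the code
against itself.

**Tables.**  Stages S1/S3/S5 (budlet, mature bud, open flower) × 3
biological replicates.  For each sample a Gaussian vector with a
configurable copula correlation (scalar equicorrelation or full PSD matrix)
perturbs per-stage trend means on the natural-log scale with σ = 0.25;
metabolite fold-over-IS and transcript quantities are the exponentials, so
one latent draw couples both data layers.  Peak areas follow from a noisy
internal-standard area split 60/40 into two fragment ions (IS run-to-run
noise cancels in normalization by construction; optional extra fragment-area
noise defaults to 0).  Ct values follow each gene's standard curve with
additive Gaussian cycle noise (default 0.2) per technical replicate
(default 3); the housekeeping gene has constant unit quantity.  Everything
is reproducible bit-for-bit from an integer seed.

The default design mirrors the emulated study qualitatively: most
metabolites and the core biosynthetic genes (DFR, ANS, 3GT) rise from
budlet to open flower, the 5-glucosyltransferase declines, the
5-acyltransferase stays flat, and late acylated compounds are essentially
absent at the budlet stage.

**Network-strength recovery.**  `ns_recovery_design` targets an
unconditional mean pairwise |ρ| of 0.76 over 16 features via a flat-trend
equicorrelation copula.  Measurement noise is excluded from this design
(ct_sigma = area_sigma = 0): Ct noise attenuates gene-pair correlations by
the classical reliability product √(λᵢλⱼ) (about 0.91 at the default noise,
pulling recovered NS to ~0.70), which is a property of the assay being
simulated, not of the correlation design the experiment calibrates.  The
recovery test runs the full table→normalize→express→correlate pipeline over
200 seeds at n = 9 samples and compares mean all-pairs NS to the 0.76
target within ±0.05; the expected shortfall is the lognormal-transform
attenuation (< 0.01 at σ = 0.25) plus the O(1/n) downward bias of the
sample correlation (≈ 0.02 at n = 9).

## Validation strategy and problem sizes

Every non-trivial operator is checked against an independent oracle:
elemental masses against pyteomics' mass tables; precursor decomposition
against a brute-force lattice enumeration (1000 random masses in
[250, 1200]); Pearson p-values against `scipy.stats.pearsonr`; clustering
merge heights against a naive O(n³) agglomerator; node strength against a
per-node loop.  Stochastic experiments use fixed seeds: 200 structures at
2 ppm for annotation accuracy (top-1 ≥ 0.95), 200 seeds for NS recovery.
These sizes make the whole suite run in well under a minute per module
while leaving Monte-Carlo standard errors far below the asserted margins.

What passing synthetic tests do **not** show: the generator has no
chromatographic peak shapes, isotope envelopes, co-eluting isomers,
instrument drift, or missing-value structure, so real-data performance on
those axes is untested by construction.

## Known limitations

* De-novo aglycone discovery is out of scope; identification is closed over
  the library.
* Compositions, not structures: positional and stereochemical isomers
  collapse; naming is heuristic.
* The UV rule thresholds interpolate two published exemplars; instruments
  and solvent systems shift these ratios.
* Quantification is relative (fold-over-IS); no calibration curves, limits
  of detection, or absolute amounts.
* Raw-file parsing (mzML) is out of scope; the pipeline starts from peak
  lists (MGF/CSV).
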