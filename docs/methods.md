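# Methods

## Overview

`bulb2de` re-implements a threshold-based differential 2DE proteome
workflow as five composable stages: synthetic cohort generation, spot
detection, cross-gel matching and normalization, SVQ differential
calling, and PMF identification. This note records the models behind
each stage, the defaults and why they were chosen, and what the
synthetic cohorts do and do not demonstrate about real gels.

## Protein physico-chemistry

pI is the root of the Henderson–Hasselbalch net-charge sum over the
ionizable side chains (D, E, C, Y, H, K, R) and the free termini, using
the EMBOSS pKa set (`data/pka.json`: N-term 8.6, C-term 3.6, D 3.9,
E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5). Net charge is strictly
decreasing in pH, so bisection on pH 0–14 converges unconditionally; it
is run to interval exhaustion (60 halvings), far past the |charge| <
1e-4 guarantee. Any consistent published pKa set would serve; the set is
a data file so it can be swapped. MW is the residue-mass sum plus one
water — monoisotopic residue masses from pyteomics, average masses
derived from Biopython's amino-acid weights. Average MW drives the gel
axis, monoisotopic masses drive PMF.

## Synthetic cohorts

**Catalog.** Random sequences with SwissProt-like letter frequencies,
lengths log-uniform in 90–880 residues; candidates outside the separable
window (pI 3–10, MW 10–100 kDa) are rejected and resampled, mimicking
that a gel only shows the separable subproteome. 85% of proteins yield
one spot; 15% yield 2–3 isoform spots (small pI offsets, shared MW),
exercising multi-spot aggregation. Each protein gets one of 13
functional categories.

**Effect design.** A comparison is defined by planted counts per class
(up, down, absent-in-comparison, absent-in-P90), an effect size (true
SVQ magnitude, default 2.5 — comfortably outside the 0.6/1.67 null band,
≥ 3 group-mean standard errors at the default noise), multiplicative
lognormal volume noise (CV 10%, plausible for Coomassie densitometry),
and per-gel spot dropout (5% — chosen so the ≥4-of-6 replication rule is
actually exercised by chance absences). `p7_design()` and
`p637_design()` carry the published compositions 63/51/9/6 and 25/14/4/4.
Effect sizes inside the null band are rejected at validation: such
effects are not callable by construction.

**Coordinates.** Continuous, origin top-left. x maps pI through a
piecewise-linear "nonlinear pH 3–10" gradient (pH 3–7 covers the left
70%, pH 7–10 compressed into the right 30%; configurable); y is linear
in log10(MW) with 100 kDa at the top, 10 kDa at the bottom — the
electrophoretic convention. Each gel carries a small random affine
distortion (rotation σ 0.003 rad, scale σ 0.002, translation σ 2 units)
plus 0.5-unit isotropic spot jitter, emulating gel-to-gel warping at a
magnitude an affine registration can invert.

**Rendering.** Spots are isotropic Gaussians (σ 2 units) whose
integrated intensity is gain × volume (gain 20), on a constant
background (100) with Gaussian read noise (σ 2), clipped to a 12-bit
range in a uint16 container — the dynamic range of a flatbed gel scan.
No streaks, dust or staining gradients are simulated.

**Groups.** All groups are generated identically; the pooling of the
youngest stage's samples before electrophoresis in the motivating study
design is not modeled (it affects biological, not technical, variance,
and only the technical chain is under test here).

## Spot detection

Background is a grayscale morphological opening (31 px window ≈ 15 spot
radii). The opening tracks the noise-floor minimum, so the residual is
re-zeroed at its median before thresholding; noise σ is the residual's
MAD. Local maxima above max(5σ, 1 intensity unit), at least 3 px apart,
seed a watershed constrained to pixels above ~2.5σ; a spot's volume is
its segment's summed residual and its centroid is intensity-weighted
(sub-pixel). Spots under 50 intensity units are discarded as specks.
Limits: co-migrating spots closer than roughly the Gaussian saddle limit
(~2σ, and up to ~3σ for unequal amplitudes) merge into one detected spot
— interactive packages resolve these by manual editing, which is out of
scope. Detector accuracy is therefore verified on resolvable-spot
layouts; on dense random layouts detection runs a few percent below the
planted count. Volumes within ~2% need amplitudes well clear of the
integer quantization floor and below saturation.

## Matching and normalization

The reference gel is the one with the most spots (ties: lexicographically
smallest id) — the countable part of the usual "best gel" criterion.
Every other gel is registered by an affine transform estimated with
RANSAC over mutual-nearest-neighbour candidate pairs (residual 2 units,
100 trials, fixed rng), then matched greedily in ascending distance to
unclaimed reference spots within a radius (default 3 units ≈ 3× the
median nearest-neighbour jitter). Affine is sufficient for the
simulator's distortion model; local (thin-plate) warps can be plugged in
by replacing the transform-estimation hook. Spots with no reference
partner seed new clusters that are themselves linked across gels by the
same greedy rule — necessary so a protein absent from the reference
gel's *group* is still tracked as one cluster. Gels are processed in
gel_id order, making the clustering independent of input order up to
labels.

Normalization divides each volume by the gel's total and scales to 100.
This is the simplest published convention; the original interactive
software does not document its formula, so the choice is isolated in
`normalize_volumes` for substitution.

## Differential calling

SVQ = P90-group mean ÷ comparison-group mean of normalized volumes, over
the gels where the spot is present. Direction semantics follow from the
quotient's numerator: SVQ ≤ 0.6 means *more* volume at the comparison
stage, i.e. up-regulated there. Boundaries are inclusive. Calls are
per-cluster: absence patterns first (≥ 4 present vs ≤ 1 present), then
thresholds; only non-unchanged calls require the ≥4-of-6 replication, so
a null-band spot with weak presence stays "unchanged" while a
threshold-crossing spot with 2–3 presences is "indeterminate" (the
original procedure gives no rule for that gray zone; excluding it is the
conservative reading). Protein aggregation averages defined spot SVQs,
flags conflicting directions `up_down` before any averaging, and
propagates absence only when unanimous. Exact up/down antisymmetry under
group exchange holds for exactly reciprocal thresholds (0.6, 1/0.6); the
printed 1.67 is the two-decimal rounding of 1/0.6, and a validation
warning fires if a user configures a non-reciprocal pair. No p-values or
multiple-testing control are computed — the procedure is deliberately
threshold-based; moderated statistics would be a natural extension.

## PMF identification

Digestion: cleave C-terminal to K/R except before P, 0–1 missed
cleavages, fixed carbamidomethyl-C (+57.021464 Da), 0..n oxidized Met
(+15.994915 Da each), peptides kept in 700–4000 Da (typical reflector
PMF window). Masses are monoisotopic, peaks singly protonated. Matching
is greedy nearest within 60 ppm after removing exclusion-list masses
(porcine trypsin autolysis, CHCA clusters; editable data file).

Score: −10·log10 of the binomial upper tail P(X ≥ matched | observed,
p_single). The per-peak random-match probability p_single is the
candidate's theoretical-mass density over the window, times one matching
window's width, times a mass-defect factor of 4: peptide monoisotopic
masses cluster in sub-Dalton bands occupying roughly a quarter of each
Dalton, and observed peptide peaks live in the same bands, so a uniform
density underestimates random matching about four-fold (measured
empirically on decoy searches). With the factor, false significant
identifications of true-negative decoys sit at or below the α-consistent
expectation while planted spectra still self-identify at ≥ 95%.

Significance: score > −10·log10(α/N) for an N-sequence database — the
Bonferroni-style identity that maps N = 42755 and α = 0.05 to the
integer cutoff 59. All entries above threshold are reported, since one
gel spot can contain several proteins. The score reproduces the
*semantics* of commercial probability-based scores (thresholding and
ranking), not any proprietary score's numerical values.

## Pipeline, determinism, problem sizes

A run is a pure function of its YAML-serializable config; the seed is
mandatory and every random stream derives from it. All intermediates are
plain CSV/JSON so any stage can run standalone on user data. The
shipped recovery runs use 850-protein catalogs with 6+6 gels through the
spot-table path (the image path — render, then detect — is exercised
separately and merges a few co-migrating spots); calibration runs render
six ~800-spot gels. Null-cohort specificity is estimated over 20 seeds
at reduced catalog size (the false-call rate is a per-protein property,
so the estimate only needs enough proteins for a stable denominator).

## Known limitations

- Dropout can, rarely, leave a genuinely differential spot in fewer than
  4 of 6 gels; the replication rule then reports it indeterminate, so
  planted-composition recovery is exact for most but not all seeds —
  this is a property of the published rule, not of the implementation.
- The affine registration cannot represent strongly local gel warping;
  real gels may need a local-warp plugin.
- Synthetic gels contain no streaks, crackling, or saturated smears, and
  the noise model is purely multiplicative-lognormal plus read noise;
  passing recovery tests bounds algorithmic correctness, not robustness
  to every real-world artifact.
- Identification links clusters to accessions via planted truth on the
  synthetic path; with real data the link comes from PMF of picked
  spots, whose error modes (mixed spots, contamination) are modeled only
  as contaminant peaks.
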