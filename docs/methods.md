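# Methods

## Enrichment scoring

Each protein carries one intensity per replicate per arm (bait, control);
the default design is 3 + 3. Arm summaries are arithmetic means of the
replicates (a geometric-mean switch exists for heavy-tailed data). A zero
replicate within an otherwise detected protein contributes 0 to the mean;
no imputation or cross-run normalization is performed. The enrichment
ratio is mean(bait)/mean(control), defined only when the control mean is
positive; a protein with positive bait signal and an all-zero control arm
is *bait-exclusive* and carries a flag instead of an infinite ratio, so no
sentinel value can leak into the null model. Proteins whose larger arm
mean does not exceed the intensity floor (default 1000, strict bound) are
excluded from null-model fitting but retained in the record list — the
floor removes near-noise ratios, nothing else.

Replicate quality is summarized as pairwise Pearson correlation on log10
intensities of proteins detected (> 0) in both members of each within-arm
pair. The acceptance rule is expressed as variation = 1 − min(r) < 0.10,
i.e. every pair must have r > 0.90. The default synthetic noise level
(multiplicative CV 0.25 against a between-protein log-SD of 1.5) yields
r ≈ 0.97.

## Background null model

Unspecific binders have a shared latent abundance in both arms, so their
log2 ratios are a zero-centered Gaussian whose spread reflects only
replicate noise. The model:

- **Binning.** Bin width 0.2 log2 units; edges anchored at integer
  multiples of the width; half-open bins [lo, hi) with edge values
  assigned upward (ties resolved with a 1e-9 relative guard against float
  rounding).
- **Fit.** Least squares of A·exp(−(x−μ)²/2σ²) against (bin center,
  count) pairs, via `scipy.optimize.curve_fit`, initialized from the
  modal bin and count-weighted moments. The fit is windowed to bins
  within ±3σ-estimates of the modal bin and the window is re-derived from
  the fitted σ once (two passes total). Windowing is what keeps the
  enriched right tail — the true interactors — from inflating σ: on a
  95%/5% mixture of N(0,1) and N(8,0.5) the fitted μ stays within 0.1 of
  the background mode. Non-convergence raises a model error carrying the
  initializer values.
- **Threshold.** Placed where the *fitted* curve (not the raw histogram,
  whose bin noise makes "10% of peak" ill-defined) decays to a fraction
  (default 0.10) of its peak height, upper flank only since the screen
  seeks enrichment: t = μ + σ·√(−2 ln fraction) = μ + 2.14597σ at 10%.
  The closed form agrees with a numerical root-finder to well below 1e-6.
- **Classification.** specific ⇔ log2 ratio ≥ t (closed bound);
  borderline ⇔ within one band (default one bin width — the "border zone"
  is drawn but not quantified in screen reports, so one bin is this
  package's choice) below t; unspecific otherwise; exclusive from the
  flag, bypassing the threshold by necessity.

## Evidence filters

Kept calls must be specific or exclusive, have ≥ 2 unique peptides
(single-peptide identifications are too weak to report, however enriched),
and pass an optional frequency filter: a user-supplied table of how often
each accession appears in unrelated control pulldowns, cutoff 0.5 by
default, absent accessions treated as frequency 0, skipped with a logged
notice when no library is given. Borderline calls are excluded by default
(flag to keep). Filters only ever flip `kept` to False and record the
first applicable reason in a fixed priority (class, peptides, frequency),
so the kept set is order-independent. The curated table is written in the
published layout — bait row first with its own statistics, then exclusives
(ratio cell "Only in CB2"), then by descending ratio printed to one
decimal (half-up).

## Sequence coverage

Tryptic digestion cleaves after K or R except before P; missed cleavages
m return all concatenations of ≤ m+1 adjacent fragments. Coverage is
exact substring matching (no I/L equivalence, no modifications — none are
modeled anywhere in the package), every occurrence marks its residues,
overlaps count once, percent is half-up to one decimal. Intervals are
0-based half-open internally.

The six peptides by which p62/SQSTM1 was identified are bundled as a text
fixture. The full p62 protein sequence is not bundled; instead a
synthetic 440-residue scaffold embeds the six peptides as exact tryptic
fragments (separator lysines; filler drawn from an alphabet without
K/R/P, so no spurious cleavage sites or peptide matches can arise). Every
quantity checked on the scaffold — digest behaviour and the 23.4%
coverage, which depends only on the summed peptide length (103) and the
total length (440) — is invariant to the identity of the filler residues.

## Network summary

Undirected simple graphs from two/three-column edge lists (self-loops
rejected, duplicate pairs collapsed), optional confidence scores in [0,1]
filtered at a closed ≥ 0.400 bound. Statistics: node/edge counts, average
degree 2E/N, mean local clustering with degree-<2 nodes contributing 0
and included in the mean, isolated-node count (an explicit node set lets
unconnected proteins count as nodes). Full precision is reported;
formatting is the report layer's business.

## Colocalization

Per channel, a constant background equal to a fraction of the channel's
peak intensity is subtracted (defaults 0.10 for the vesicular channel 1
and 0.05 for the receptor-like channel 2), clipping at zero. Segmentation
uses a locally variable threshold: a voxel is structure iff its intensity
exceeds max(floor, local mean + k·local SD) over a centered window
(default 9×9 laterally × 3 axially, matching the ~3× axial anisotropy of
a 100 nm / 300 nm voxel; k = 2). Windows are clipped at stack edges and
statistics taken over the intersection. This operator is this package's
concrete segmentation choice for isolating non-contiguous structures;
commercial 3D-rendering packages do not document theirs.

Manders coefficients are computed on background-subtracted intensities
restricted to the segmented regions: M1 = Σch1 over (mask1 ∧ mask2) /
Σch1 over mask1, M2 symmetric, 0/0 defined as 0, both always emitted
since which of the two a study reports is often ambiguous. Per-image
values aggregate as mean ± sample SD.

## Synthetic data

The generator is the test bed for everything above. Unspecific binders:
latent log-intensity N(14, 1.5²) (natural log — intensities ~1.2e6,
well above the floor) shared between arms; replicate noise multiplicative
log-normal with mean exactly 1 (σ² = ln(1+CV²), default CV 0.25), so arm
expectations are exact. Interactors: bait latent = control latent +
fc·ln 2, fc uniform in (3, 8) — the low end sits more than one log2 unit
above the threshold region implied by the default noise, which is what
makes sensitivity-by-construction checks meaningful. Exclusives: all-zero
control arm. Unique-peptide counts uniform in (1, 30), independent of
intensity. Optional sub-floor dropout is off by default. Fixed seeds give
byte-identical outputs.

Image pairs are solid spheres (radius 2, amplitude 1000) over a constant
additive background, placed with enough separation that supports stay
disjoint; a whole-vesicle fraction of channel-1 spheres is co-located
with channel-2 spheres and channel 2 carries its own disjoint spheres, so
the true fraction of channel-1 mass inside channel-2-positive territory
is exactly n_overlap/n.

What the generator does *not* emulate: intensity-dependent missingness,
peptide-count/intensity coupling, correlated contaminant structure across
runs, shot noise or PSF blur in images. Passing tests therefore validate
the algorithmic pipeline, not its robustness to those real-data features.

## Problem sizes and numerics

Default validation runs use 2 000 background proteins + 80 spiked
interactors + 6 exclusives, 50 000 draws for null-model recovery, and
24×96×96 stacks with 10 vesicles — sizes at which the stochastic checks
(fit recovery ±0.02/±0.03, spike-in sensitivity ≥ 0.95, false-positive
rate ≤ 2× the fitted Gaussian tail, Manders ±0.05) are comfortably
resolved. Degenerate inputs (empty tables, all-zero stacks, empty masks,
constant replicate columns) return empty/zero results or raise typed
errors rather than NaNs; the one deliberate warning path is the
empty-masks Manders case.

## Known limitations

- The exclusive class bypasses the ratio threshold by construction;
  nothing but the peptide and frequency filters protects it.
- The Gaussian null assumes a unimodal background; strongly bimodal
  backgrounds (e.g. two resin chemistries) would need a mixture model,
  which is out of scope.
- Frequency-library construction is the user's problem; only the lookup
  and cutoff are provided.
- Coverage is strictly exact-match tryptic; semi-tryptic or modified
  peptides will be reported unmatched.
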