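# Methods

This note documents the models, numerical choices and known limitations
behind each module, and what the synthetic-data generators do and do not
emulate.

## Mass calculus and derivatization (chem, targets)

Peptide neutral mass is the sum of monoisotopic residue masses (taken
from pyteomics' standard table), one water (18.010565 Da) and the
modification shifts; m/z adds z protons (1.007276 Da each) and divides by
z.  Modification shifts are full-precision monoisotopic values (propionyl
56.026215, methyl 14.015650, dimethyl 28.031300, trimethyl 42.046950,
phospho 79.966331, SILAC Arg10/Lys8/Pro6 10.008269/8.014199/6.013809 Da).
Two-decimal tags such as `Pr/56.03` that appear inside peptidoform
strings are treated as display labels only — parsing resolves the name
and discards the printed number, because five-decimal m/z agreement is
only achievable with the full-precision shifts.

A propionylated mono-methyl lysine is represented as one composite
modification key `propionyl-methyl` (70.041865 Da) so that the invariant
"at most one side-chain modification per residue" holds everywhere.
Coordinates are 1-based with `N-term`/`C-term` sentinels.

The derivatization model adds propionyl to every unmodified lysine,
converts mono-methyl to the composite (the mono-methylated ε-amine still
carries a derivatizable proton), and leaves di-/tri-methyl untouched.
N-terminal derivatization is a flag, off by default: the default H3K36
inclusion list is consistent with exactly three propionyl groups on the
me0 peptide and no α-amine derivatization, i.e. derivatization of intact
histones before digestion with no second round afterwards.  Workflows
that do a post-digest round can enable the flag.

Digestion is strict trypsin: cut after K/R, never before P, never after
a lysine whose side chain carries any of {propionyl, propionyl-methyl,
methyl, dimethyl, trimethyl}.  With 0 missed cleavages the products
concatenate exactly to the input; up to 5 retained internal sites are
supported (default 2).

The inclusion list enumerates forms in the order me0, me1-free,
me1-prop, me2, me3, each at the requested charges ascending, and writes
m/z to 5 decimals.  Only 2+ and 3+ are generated by default; the list is
deliberately minimal (label, sequence, modification string, charge, m/z)
with no retention-time windows or collision-energy columns.

## Occupancy and stoichiometry (occupancy)

Relative phosphorylation of a singly phosphorylated form is its area
over the sum of the unmodified area and all singly phosphorylated areas
of the same backbone/missed-cleavage group.  Choices that the area data
alone cannot dictate:

- **Zero total area** yields an explicit missing value, never 0: absence
  of signal is not evidence of zero occupancy.  Missing replicates are
  excluded from n in summaries.
- **Multiply phosphorylated forms** are excluded from the
  singly-phosphorylated denominator and reported as one pooled, flagged
  result against the unmodified form only.  The singly-form rule is the
  primary, documented contract; the pooled multi-form fraction is a
  descriptive extra.
- **Co-eluting or non-localizable forms** arrive as single rows carrying
  several site labels and stay pooled; the package never attempts
  re-localization.
- **Methyl stoichiometry** uses charge-3 areas by default (`charge=None`
  sums all charge states), sums the two me1 chemical forms into the me1
  state, and divides by the total across all five forms, so the state
  vector sums to 1 whenever any signal exists.

## SILAC label swap (silac)

"Normalization" is per-replicate median-centring of the log2 H/L ratios.
The minimal convention consistent with summarizing proteins by median
log2 ratios; it removes any global mixing offset exactly (the synthetic
generator plants ±0.3 offsets to exercise this).  Alternatives
(mean-centring, global centring) were not implemented: with two
replicates and a sign flip, the median is the only robust choice that
makes the orientation flip an involution on centred values.

Filtering removes contaminants/decoys (explicit flags, or `contam_`/
`rev_` id prefixes when flags are absent), proteins with <2 peptides in
*either* replicate, and proteins lacking a ratio in any replicate.
Exactly 2 peptides is retained.

The per-protein test is a two-sided one-sample t against 0.  With one
label swap there are two replicates and a single degree of freedom; the
pipeline emits a warning because power is then minimal — at realistic
noise essentially nothing reaches q < 0.05, which reproduces, as the
null-scenario behaviour, the outcome of running this design on a
proteome without true changes.  Zero-variance proteins (replicates
numerically identical) have p = q = NaN, are excluded from the BH family
and logged; they are never silently called.

Label QC: incorporation is the mean of H/(H+L) over K/R-containing
peptides of a heavy-labelled sample; proline conversion is the mean of
Pro6/(Pro6+Pro0) over proline-containing peptides.  Zero-sum peptides
are skipped.  These are definitions applied to a peptide table, not
spectral processing.

## Doubling time (growth)

The estimate is log10(2)/s where s is the maximum OLS slope of
log10(OD600) over every window of `window` consecutive retained points
(OD ≤ `od_floor`, default 0.02, is excluded first; the window start
shifts past excluded points).  Non-positive s flags the well as
non-growing rather than producing a negative time.  The estimate is
exact for pure exponential data at any window size and invariant to
rescaling OD.

**Window default.**  Taking a maximum over many noisy windows is an
extreme-value statistic: each window's slope error is roughly
σ_OD/(ln10·√Σ(t−t̄)²), and the selected maximum sits ~2 standard errors
above the true slope.  At 10-min sampling with 2 % multiplicative OD
noise, 6-point windows inflate the steepest slope enough to bias a
90-min doubling time downward by ~10 min (simulation, 500 draws), while
15-point windows (2.5 h) keep the per-curve error within about ±4 min
and still fit inside the exponential phase of a culture growing from the
OD floor to saturation (≈5 doublings).  The default window is therefore
15 points; noise-free data is insensitive to the choice.

Blank subtraction is left to the caller (the floor excludes near-blank
readings); log of non-positive OD is excluded, not clipped.  Lag time
and carrying capacity are not estimated, and no hypothesis testing is
done on doubling times — the per-replicate table is the export.

## Statistical kernels (stats)

- **BH FDR**: cumulative-minimum step-up formulation, order-preserving,
  ties handled by the standard q_(i) = min_{j≥i} p_(j)·m/j.
- **Hypergeometric enrichment**: one-sided upper tail P(X ≥ k) via
  scipy's survival function, BH across tested terms; terms with zero
  study hits are skipped (under-representation is out of scope); a study
  gene missing from the background is an error naming the gene, since a
  silent subset would change every test's universe.
- **Proportional odds**: the weighted cumulative-logit likelihood is
  maximized over (c₁, log-gaps, β), which enforces strictly ordered
  cutpoints by construction.  Optimization is quasi-Newton (BFGS) with
  analytic gradients, started from the empirical cumulative logits at
  β = 0, with one restart if the first line search stalls; convergence
  requires a small gradient norm and is reported truthfully in
  `converged`.  Standard errors come from the observed information
  (finite differences of the analytic gradient at the optimum) and feed
  a per-coefficient Wald test.  Observation weights may be fractional,
  so methyl-state fraction vectors can be used directly as weighted
  ordinal observations; integer-count expansion gives identical
  estimates (tested).  With two states the model reduces exactly to
  binary logistic regression (verified against an independent
  implementation to <1e-6).  Note that rescaling all weights by a
  constant changes the information but not the point estimate — Wald
  inference from fractional weights that do not represent real counts
  should be interpreted with care.
- **DE classification**: inclusive on the fold-change boundary
  (|log2 FC| ≥ 0.8), strict on adjusted p (< 0.05); missing adjusted p
  classifies as unchanged with a warning.  Low-count filtering removes
  genes whose summed count across samples is ≤ 1.

## Synthetic data (synthetic)

Generators emulate the *shape and noise structure* of each input: XIC
areas and OD values get multiplicative lognormal noise (positive,
signal-proportional); SILAC replicate ratios get additive Gaussian noise
on the log2 scale plus a global mixing offset; growth curves are
logistic with a lag and a stated exponential-phase doubling time;
annotation universes plant over-representation by weighted sampling of
term members.  Default study conditions mirror the assay designs the
package targets: 4 replicates and σ = 0.2 for phospho XICs, 3 replicates
for methyl profiles, one label swap (2 replicates, noise sd 0.2, offsets
±0.3) for SILAC, 10-min sampling for growth, 6-biological-replicate
plates.

They do **not** emulate: chromatographic peak shapes or integration
error structure, interference/co-isolation, missing-value mechanisms
(absent peptides), ratio compression, plate-edge effects, or biological
replicate-to-replicate variance beyond the stated noise.  Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every artefact of real
acquisitions.

Seeding: one root seed fans out through
`SeedSequence(seed, spawn_key=(counter,))` with a fixed counter per
scenario (xic=1, silac=2, growth=3, methyl=4, enrichment=5), so adding a
new scenario never perturbs existing ones, and identical seeds give
byte-identical tables.  Every generator returns its truth object beside
the data; tests read truth, never re-derive it.

A note on planted enrichment: with a study of 100 in a universe of
6000, a 20-gene term planted at odds ratio 10 yields only ~3 expected
study hits — detectable (p ≈ 0.004) but not reliably significant after
FDR across dozens of terms.  Positive-control tests therefore plant
stronger odds; the null-universe test checks that no term reaches
q < 0.05 when nothing is planted.

## Problem sizes

The test suite and acceptance script run: 200 groups × 4 replicates ×
3 occupancy levels; 10 profiles × 3 replicates for methyl recovery;
20 label-swap experiments of 3050 proteins plus one null experiment;
200 proportional-odds fits at n = 500; 1000 random BH vectors; 60-point
growth curves.  These sizes give recovery standard errors comfortably
below the stated tolerances while keeping the whole suite under a
minute.

## Known limitations

- Only trypsin digestion rules are implemented; average masses, isotope
  envelopes, fragment ions and retention-time prediction are out of
  scope.
- The occupancy module assumes localization and form assignment arrived
  with the data; it never rescores sites.
- The SILAC module consumes protein-level medians; peptide-to-protein
  aggregation happens upstream.
- The growth module does not fit parametric growth models; estimates for
  curves whose exponential phase is shorter than the window will be
  biased toward slower growth.
- Two-replicate designs cannot power a t-test; the package reports this
  rather than substituting a different test.
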