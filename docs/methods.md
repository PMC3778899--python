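# Methods

## Mass model

Two mass scales are deliberately kept apart.

**Nominal ladders (default).** A unit-resolution quadrupole centroids
lipid peaks ~0.2–0.3 Da above their monoisotopic mass and reports them
to one decimal. Forcing exact masses to reproduce such values would be
dishonest, so each class gets a one-decimal *anchor* — the dominant
species of that class at its reported position (PC 16:0/18:1 at 760.8,
PS 18:0/18:1 at 788.9) — and every other species sits on the integer
ladder `anchor + 14·Δcarbons − 2·Δdouble_bonds`, plus an integer label
shift (+9 D₉-choline, +6 D₆-inositol, +3 D₃-serine). The PI anchor has
no reported value, so it is derived once from atomic monoisotopic
masses: PI 18:0/20:4 [M−H]⁻ = 885.5499 → anchor 885.5. Anchors for the
remaining classes (PE, PG, PA, CL, SM, ceramides, sphingoid bases, TAG,
cholesterol) are derived the same way. One known ladder/report mismatch
exists: the D₃ channel of PS 16:0/18:1 ladders to 763.9 while 763.8 is
the reported form; this is sub-resolution rounding and the ladder is
not bent to absorb it.

**Monoisotopic mode.** Exact masses from elemental composition
(diacyl-glycerophospholipid formulas parameterised by total acyl
carbons and double bonds; ceramide/SM formulas on a d18:1 backbone with
the amide counted as a degree of unsaturation) for the standard adducts
([M+H]⁺ PC/SM/ceramides, [M−H]⁻ anionic phospholipids, [M+NH₄]⁺ TAG),
with deuterium shifts of n × 1.006277 Da. Atomic masses come from
pyteomics. Both modes are affine in (carbons, double bonds); they are
*not* offset by a class constant, because the nominal ladder steps
14/2 Da while the exact steps are 14.01565/2.01565 Da.

Species are handled at total acyl composition (PC 34:1); sn-resolved
names (PC 16:0/18:1) are display aliases — head-group scans cannot
resolve positional isomers — and compare equal to their totals.

## Isotope envelope and deisotoping

The number of ¹³C atoms in an *n*-carbon molecule is binomial(*n*, *p*)
with *p* = 0.0107; deuterium and heteroatom isotopes are neglected as
sub-percent at unit resolution. The envelope is truncated at M+2
(M+3 < 1 % of M0 at lipid carbon counts) and expressed relative to M0:
(1, *nq*, *n*(*n*−1)/2·*q*²), *q* = *p*/(1−*p*). Carbon counts are total
molecular carbons (acyls + backbone + head group): 42 for PC 34:1, 44
for PC 36:2.

Within a class channel, the M+2 of a species coincides exactly with
the monoisotopic peak of the species with one fewer double bond. Since
contamination only propagates upward in mass, one ascending sweep —
subtract `f₂(donor) × corrected(donor)` from each measured M0 — is
exactly forward substitution of the band-diagonal envelope system; the
test suite verifies equality with full matrix inversion to 1e−9 on
random ladders. Modelled rather than measured M+2 ratios are used (the
measured M+2 position is usually occupied by the next species).
Corrected intensities are floored at zero, with every subtraction and
flooring event recorded in an audit; noise-free simulations produce
zero flooring events. M+1 peaks are assigned but never used
quantitatively. Labelled and endogenous channels are separate
acquisitions with different diagnostics, so cross-channel contamination
does not arise.

Peak assignment matches each centroid to the nearest candidate
isotopologue position within ±0.5 m/z (configurable; one-decimal
centroids make larger windows pointless). Ties at equal distance prefer
the lower isotopologue index and then the lower expected m/z: a peak
sitting on a coincident M0/M+2 position must be read as monoisotopic or
the 2-Da correction could never apply to it. Candidate lattices contain
even-carbon species only (odd-carbon biological glycerophospholipids
are not expected); odd-carbon internal standards are whitelisted in
explicitly.

## Composition, incorporation, quantification

Mole-% assumes equal within-class ESI response (overridable per
species). The >2 % quantifiability rule is strict and affects reporting
and hypothesis-testing only: totals and incorporation always use all
species, and filtered tables are not renormalized, so retained species
need not sum to 100 %. Fractional incorporation
φ = 100·ΣL/(ΣL+ΣE) uses summed corrected intensities of the two
channels of a class and assumes equal scan gain between them.

MRM sphingolipid amounts are `(area / IS area) × spiked amount ×
response factor` per mg protein; response factors default to 1 and the
spiked amount is configuration (the bundled default, 40 pmol/mg for a
17-carbon-acyl ceramide, mirrors the shotgun spike mix because no MRM
spike amount is published for this design). Total ceramide excludes
dihydroceramides by default (configurable). Shotgun quantification is
deliberately single-step: classes with a spiked standard (PC 15,
PS 1, PG 4.2, PE 18.75 nmol/mg; ceramide 40 pmol/mg; TAG 10 nmol/mg)
are ratioed to it after deisotoping; classes without one (PA, CL, SM,
cholesterol) are simulated but omitted from absolute output with a
warning, and PI — which also carries no standard — is reported as
mole-% of the PI total. The two-step intrasource-separation refinement
of full MDMS-SL workflows is out of scope.

## Statistics

Pooled-variance Student *t* (the design's historical method; Welch
available behind a flag), two-tailed, df = n₁+n₂−2; paired variant =
one-sample *t* on differences where subject keys pair up, with
automatic unpaired fallback when they do not (the stimulated arms have
different n, so HC-vs-CD and unstim-vs-HkEc default to unpaired).
Significance is strict `p < α`: 0.05 for macrophage endpoints, 0.01 for
shotgun endpoints, no multiplicity correction; a labelled BH-adjusted
column is appended for modern readers but drives no flag. Zero-variance
cases are defined (t = 0, p = 1 at equal means; flagged degenerate at
unequal means) rather than raised. Species-level tests are restricted
to quantifiable species (study-wide mean mole-% > 2), which is both the
method's stated practice and necessary for calibrated type-I error —
trace lattice species populated only by noise are wildly non-normal.

## Synthetic data generator

The generator emulates the study conditions, not generic spectra. Its
defaults are fixed once: endogenous PC centred on 16:0/16:0, 16:0/18:1
and 18:0/18:2; PS dominated by 18:0/18:1 (42 % of the class);
endogenous PI dominated by 18:0/20:4 (42.9 %) while the newly
synthesised PI pool is diverse (18:0/20:4 only 12.3 %, twelve species);
φ_PI = 0.161. Values with no published counterpart were chosen once at
field-realistic levels and not revisited: φ_PC = 0.08, φ_PS = 0.05; the
MRM panel dominated by C16:0/C24:0/C24:1 ceramides (220/260/240 pmol/mg
protein); biopsy class totals of tens of nmol/mg. Encoded effects:
CD multiplies the newly-synthesised PI 16:0/18:1 fraction by 0.65 (and
the biopsy PI share by 0.6); HkEc multiplies φ_PC by 1.6, endogenous
PC 16:0/20:4 by 0.65, C16:0/C24:0 ceramide by 0.65, C24:1 by 0.6, and
dihydrosphingosine by 1.8. Sample sizes follow the emulated study: one
phospholipid arm (all six scans per sample; HC 7 / CD 9 unstimulated,
6 / 5 stimulated), a sphingolipid MRM arm (7/8 and 7/12), and a biopsy
shotgun arm (5/5, unstimulated only).

Noise: within-spectrum log-normal intensity CV 5 % per centroid,
m/z jitter SD 0.02, optional additive baseline (default 0);
between-subject log-normal CV 20 % on every fraction, φ and amount
(profiles renormalized afterwards), 10 % on protein mass. The 20 %/5 %
split reproduces SEMs of the magnitude the emulated study reports at
its n. The variance *structure* is an assumption — only SEM magnitudes,
not distributional shape, have an empirical anchor. Coincident
isotopologue positions are merged before noise, as an instrument would
centroid them. All randomness descends from one seed via
`numpy.random.SeedSequence` spawning: equal seeds are bit-identical,
and paired designs reuse a subject's perturbation seed across
conditions.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: chromatography/retention, profile-mode
peak shapes, intensity saturation, in-source fragmentation, response
differences between species of a class, isotope effects of deuterium,
and real biological covariance between lipid species (perturbations are
drawn independently per species).

## Operating characteristics

Because the emulated study's subject-level data do not exist, group
percentages are generator defaults, not reproduction targets; validation
is property-based (`lipidflux.calibration`, exercised by the test suite
and `scripts/acceptance.py`): noise-free round trips recover truth to
1e−6 relative; per-sample φ_PI recovery error at default noise is
~0.003 (mean absolute, 200 samples); 10,000 end-to-end null
species-level tests reject at ~5 % at α = 0.05; and each encoded effect
is detected, in the correct direction, in ≳90 % of 100 replicated
studies at the study's own sample sizes. Problem sizes in the default
runs (10,000 null tests, 100 replicates, 200 recovery samples) were
chosen to estimate these rates to about a percentage point on a single
CPU in well under a minute each.

## Known limitations

Single labelling window only — no kinetic modelling of incorporation
over multiple time points. No peak picking (input is centroided), no
recalibration, no charge deconvolution (CL is treated as singly
charged). Ether/plasmalogen subspecies have no mass rules. The shotgun
arm's IS-less classes have no absolute scale, as discussed above.
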