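# Methods

## Sequence encoding

A nucleobase is represented by the partial charges at its three
hydrogen-bonding sites (First/Second/Third), in elementary-charge units.
The four triples are fixed constants, stored exactly as printed to three
decimals and never re-derived from quantum chemistry; adenine's First-site
value is the average over its two amino hydrogens, and its weakly bonding
Third site is kept so every base has the same three-element shape (uracil's
Third site participates in G·U wobble pairing, which is why all three sites
are retained for every base). A sequence of length *n* maps to the
site-major ternary vector of 3n charges. T is silently read as U (one
warning per FASTA file) so DNA-alphabet inputs work; ambiguity codes are
rejected with the offending character and position.

## Torus geometry

The sequence is laid on a circle: anchors equally spaced in angle, with
12.9 Å of **arc** between neighbours, so R = n·12.9/2π. Treating 12.9 Å as
arc rather than chord keeps inter-base spacing exactly uniform for every n;
the two conventions differ by < 0.7% for n ≥ 18. Each base is a straight
8.6 Å segment with sites at offsets 1.915/4.300/6.685 Å from the anchor —
the 2×2.385 Å site span centred on the segment, the symmetric choice since
only the base length and site spacing are constrained. The First site is
innermost by default (`site_order` flips it; the figure convention is not
fully unambiguous). Structures A/B/C tilt the segment 0°/90°/45° out of the
torus plane; a `tilt_degrees` override exposes the continuum, and tests
verify C → A and C → B in the respective limits. Base 1 sits at angle 0 on
the +x axis with the origin at the circle centre. This fixes the rotational
gauge: field *norms* are gauge invariant (tested), individual x/y
components are not, so component-level comparisons between implementations
with different phase conventions may disagree even when all norms agree.
Sequences of length 1 are rejected — one base does not define a circle.

## Fields and scores

EV_C evaluates the proportional field Σ q·(p − r)/|p − r|³ at the circle
centre — reading "centre" literally also explains why the planar Structure
A yields exactly zero z components. EV_S sums the field over an 11×11×11
grid: per axis, 11 equally spaced values spanning the bounding box of the
sites inclusive. A degenerate axis (Structure A's z) keeps its 11 repeated
values; the resulting constant factor is absorbed by the proportional form.
All physical prefactors (1/4πε₀, the elementary charge, Å conversions) are
dropped; EV values are arbitrary units.

Because the grid spans the structure's own bounding box, boundary grid
points coincide *exactly* with extreme sites for most sequences. Sites
closer than 1e−9 Å to an evaluation point are skipped and counted in a
warning — this perturbs the sum minimally while avoiding infinities. The
vectorized evaluation is checked against plain brute-force loops at 1e−10
relative tolerance.

Duplicate analysis rounds score triples to 10 decimals before comparison so
floating-point noise cannot split true duplicates; a value shared by k
records counts k duplicates, so duplicate + unique = total always. Score
tables can optionally drop repeated sequences first (`unique_sequences`);
the default keeps all records.

## Regression conventions

Pairwise fits are ordinary least squares of one component on another,
cyclically x→y, y→z, z→x. Raw-score regressions default to fitting an
intercept; SMEL regressions default to passing through the origin, since
SMEL is an exact scalar multiple of the score and its regression line has
no intercept term. Both are flags. Note that on synthetic pools the
through-origin score-space slopes equal the per-site rms charge ratios
(x−y ≈ 1.06, y−z ≈ 0.86, z−x ≈ 1.10 for a uniform composition) with
uncentered r² ≈ 0.997, while the intercept fit attenuates the slopes when
composition noise dominates the length spread; the through-origin numbers
are the ratio-like quantities to compare across catalogues. "SD" of a slope
is its standard error; the signed fit statistic is sign(slope)·r² (plain r²
is also reported). A slope with zero residual variance gets p = 0 (p = 1
for a zero slope) rather than a divide-by-zero. Degenerate axes — a
predictor or response identically zero relative to the component scale,
as for the field methods under Structure A — are reported NA rather than
fitted. No multiple-testing correction is applied anywhere; the ±kσ
interval test is a descriptive screen, not a calibrated hypothesis test.

## Disease comparison

For each axis pair, every disease's SMEL cloud is regressed through the
origin and all disease pairs are compared: significant at ±kσ iff the
[slope ± k·SE] intervals are disjoint. Significance is monotone
non-increasing in k (nested intervals). The axis verdict is "O" only when
all pairs separate, "x" otherwise, "NA" when undefined. FC and log₂FC are
parallel tracks, never mixed in one regression; missing values are
completed by fc = 2^log2fc.

The FC outlier rule sorts a disease's FC values in descending order and
scans from the top: while a value is at least twice the next smaller one it
is removed, stopping at the first non-gap. The cumulative reading (default
`mode="cascade"`) removes every value passed before the stop; the wording
admits a reading that removes only the single largest value, provided as
`mode="first"`. The rule is idempotent and applies to FC only — log₂FC is
never filtered. Note the scan's quirk: several equally extreme outliers
cluster at the top without a 2× gap between them, and then nothing is
removed; tests therefore check the filter's trigger *frequency* under
outlier injection rather than per-seed guarantees.

## Synthetic data

The generator emulates literature-extracted expression panels. Defaults
(the study conditions): a pool of 2656 sequences at 18–25 nt with uniform
base composition; four disease panels of 80 records each — a plausible
yield of a per-disease literature sweep, as the actual extraction counts
are not machine-readable; log₂FC ~ Normal(0, 2), giving heavy-tailed
positive FC; 2% of records get their FC multiplied by 100 to mimic extreme
extractions; slope separation 1.0. Disease panels are *biased subsets*: a
disease with separation bias c samples miRNAs with weight exp(c·u), where u
is the rank-standardized second/first VS component ratio, so its
through-origin SMEL slope shifts by a controllable amount while log₂FC
remains exactly Normal(μ_d, σ_d). At zero separation all diseases sample
uniformly and discriminate only by chance. Because x is i.i.d. within a
panel, the expected SMEL slope equals the panel's unweighted score-space
ratio Σv₁v₂/Σv₁² — the recovery target the tests check within 3 SE.

What the generator does **not** model: real base-composition biases of the
mature catalogue (so absolute uniqueness percentages and intercept-fit
slopes differ from the real catalogue's), correlated multi-study
extractions of the same miRNA, disease co-morbidity, or any actual disease
biology. Passing tests show the machinery is correct and the statistics
behave as designed under controlled conditions, not that the biological
conclusions transfer.

## Problem sizes and determinism

The acceptance script runs the full pipeline at catalogue scale (2656
records, all four methods, all three structures, ~30 s on one CPU); the
test suite uses pools of 40–400 sequences and 100-seed sweeps for the
monotonicity studies, a size chosen to make the stochastic assertions
stable. All randomness flows from explicit seeds through
`numpy.random.default_rng`; repeated runs with the same configuration are
byte-identical.

## Known limitations

- The geometry is a deliberate idealization: no backbone atoms, no π–π
  stacking, no real secondary/tertiary structure, and real nucleobases are
  not tilted at exactly 0/45/90°.
- Component-level (x vs y) values depend on the rotational gauge and site
  ordering; only norms and slope statistics are convention-free.
- The ±kσ interval criterion ignores the joint sampling distribution of
  two slopes; it is stricter than a two-sample t-test at the same nominal
  level and carries no multiplicity control.
- EV scores are proportional forms; they cannot be compared across
  packages that keep physical constants without rescaling.
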