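# Methods

## The order index and its geometry

For a composition p = (a, c, g, t) on the 4-simplex, the genome order index
is S = Σ pᵢ² ∈ [0.25, 1], minimised at the uniform composition and
maximised at the four vertices.  The tetrahedron mapping sends p to

    x = (a+g) − (c+t),  y = (a+c) − (g+t),  z = (a+t) − (g+c)

in the *reduced* system (coordinates in [−1, 1]), or to (X, Y, Z) =
(3/4)(x, y, z) in the *original* system (coordinates in [−3/4, 3/4]).  The
mapping is affine and invertible: a = (1+x+y+z)/4 and cyclic analogues, so
each composition is a unique tetrahedron point and vice versa.

Expanding the squares gives the exact identity ρ² = 4S − 1, where ρ is the
Euclidean norm of the reduced-system point.  Membership of the inscribed
sphere is therefore equivalent to a threshold on S.

### Radius convention

With the vertex coordinates above, the *Euclidean* distance from the
centre to a face is √3/3 (reduced) and √3/4 (original), while the radii in
circulation for the two systems are 1/3 and 1/4.  Both radius statements,
and the equivalence of sphere membership with S < 1/3, hold simultaneously
if "distance" means the root-mean-square coordinate

    d = sqrt((x² + y² + z²)/3) = ρ/√3,

because then d² = (4S − 1)/3 and the face-touching compositions (one
frequency zero, the others equal — e.g. the pure-AT edge midpoints) sit at
d = 1/3 exactly in the reduced system.  The package implements
`rms_distance` as this RMS coordinate and exposes the Euclidean norm
separately; sphere verdicts are canonically decided by S < 1/3 (strict:
S = 1/3 counts as outside) so they never depend on the metric reading.
This reconciliation is a deliberate design choice — the alternative
(treating the 1/3 and 1/4 radii as Euclidean) cannot be squared with the
stated vertex coordinates.

The factor 4/3 converting the original radius into the reduced one is the
whole point of the two-system bookkeeping: applying the original-system
radius 1/4 to reduced-system coordinates understates the sphere and
misclassifies every composition with RMS distance in [1/4, 1/3) —
equivalently, via S = (3d² + 1)/4, every S in [0.296875, 1/3) — as
"outside" when it is not.  The
`sphere_census(radius_override=0.25)` mode reproduces that artefact on
demand.

## Entropy family

The Tsallis-form α-order entropy H_α = (Σ pᵅ − 1)/(1 − α) is implemented
for α > 0, α ≠ 1.  Its α → 1 limit is the natural-log Shannon entropy
(tested numerically at α = 1 ± 1e−6 against the direct summation), and
H₂ = 1 − S is the Gini–Simpson index.  Shannon entropy defaults to bits
(the sequence-analysis convention); nats are available, and the α-limit
identity is checked in nats since the Tsallis prefactor converges to the
natural-log form.  0·log 0 = 0 throughout.

Additivity separates S from H: for independent compositions p and q the
16-cell joint distribution has H(p⊗q) = H(p) + H(q) exactly, while
Σ(pᵢqⱼ)² = S(p)·S(q).  Since S ≤ 1, the product is always strictly below
the sum (their gap is at least 1 − (1 − S₁)(1 − S₂) ≥ 0.4375); the two
statistics transform differently under composition of sources and are not
interchangeable.

### PR2-collapsed forms

Under the three exact constraints a = t, c = g, a + c = ½, both S and H
collapse to functions of a alone: S_red(a) = 2a² + 2(½ − a)² and
H_red(a) = −2a log a − 2(½ − a) log(½ − a).  The closed form of S_red is
forced by substituting the constraints into S; it agrees with the full S
on the constrained grid to 1e−12.  `index_discrepancy` reports the signed
gap S_red(a) − S for an arbitrary composition; it vanishes exactly on the
constraint set and is, e.g., +0.008 for the Sirtuin-3 gene composition.
PR2 deviations themselves (`pr2_deviation`) are reported unthresholded —
treating them as zero is precisely the approximation the collapsed forms
embody, and the package keeps the two representations explicitly distinct.

## Z-curve

The Z-curve is kept as an integer object: cumulative count differences,
with per-base steps A → (+1,+1,+1), C → (−1,+1,−1), G → (+1,−1,−1),
T → (−1,−1,+1) (each step is the mapping evaluated on a single base).
This makes three invariants exact rather than approximate: every
coordinate shares the parity of the prefix length; every step has unit
components with sign product +1; and the endpoint divided by N equals the
reduced-system mapping point of the sequence composition, exactly in
rational arithmetic.  Frequency-normalized views are derived on demand;
the literature's frequency-of-prefix form differs only by division by n.

Reconstruction decodes each step's sign pattern; it is defined only for
strict tracks.  Ambiguous bases (anything outside A/C/G/T/U after
case-folding) step (0, 0, 0) so genomes with N runs remain mappable, but
they clear the strict flag and reconstruction is refused — uniqueness is
genuinely lost, and the contract says so rather than guessing.

Windowed profiles tile positions 1..N with a configurable window and step;
the trailing partial window is included only if it reaches `min_window`
(default: the full window length, so no partials).  All positions are
1-based inclusive.

## Cohort analysis

`variance_decomposition` reports both per-coordinate variance fractions
(var(x), var(y), var(z) over their sum) and the eigenvalue fractions of
the centered covariance matrix, because "variance accounted for by the z
coordinate" admits either reading; PCA uses the covariance (not
correlation) matrix since the three coordinates share units.  Under exact
PR2 the x and y coordinates are identically zero and the z fraction is
exactly 1; with a small PR2 skew (sd 0.005 in frequency units) the z
fraction still exceeds 0.99 — the regime observed across real bacterial
genome collections, where nearly all cross-genome compositional variance
is GC-content variance, reproduced here at desk scale.

The cross-genome distribution of S is modelled as a shifted exponential
with support anchored at the theoretical minimum 0.25 (not estimated —
the support bound is a mathematical fact, and anchoring it keeps the MLE
the simple reciprocal mean excess λ̂ = 1/mean(S − 0.25)).

`s_h_correlation` is the Pearson correlation of per-record S and H; it
accepts n ≥ 2 (two points give ±1 by construction) and rejects
zero-variance cohorts.

## Synthetic cohorts

`generate_cohort` draws each member's GC content uniformly on
[gc_low, gc_high] and applies zero-mean Gaussian PR2 perturbations within
the AT and GC pools: a = (1−gc)/2 + δ₁, t = (1−gc)/2 − δ₁ (likewise c, g
with δ₂), with δᵢ ~ N(0, skew_scale/2) so that sd(a − t) = sd(c − g) =
skew_scale exactly.  This isolates PR2 deviation (which moves x and y)
from GC variation (which moves z), mirroring how the two effects separate
in the mapping algebra.  Perturbations are truncated at the non-negativity
boundary with a logged warning rather than rejected, so extreme specs
still yield the requested cohort size.

Defaults (n per request; GC 0.25–0.75; skew_scale 0.005) emulate the wide
GC spread and small PR2 deviations of bacterial genome collections: the
GC range brackets the observed bacterial extremes, and 0.005 is of the
order of typical single-strand skews.  What the generator deliberately
does *not* model: codon structure, repeats, replichore-segmented skew
reversals, or any along-genome heterogeneity — members are i.i.d. draws
per base.  Passing tests on these cohorts therefore demonstrate the
compositional and geometric machinery, not realism of genome texture;
conclusions about along-genome Z-curve features (origin-associated skew
flips, gene-level signals) require real sequences, which the CLI accepts
but the test suite never downloads.

Problem sizes used by the suite — 10⁴ simplex draws for the identity
checks, 10³ random sequences (length ≤ 500) for inversion, a 235-member
cohort for the sphere census and variance regime, 10⁴ draws for rate
recovery — keep the whole suite in seconds while leaving the statistical
assertions comfortably powered.

## Numerical and interface choices

- Compositions renormalize on construction when |Σp − 1| > 1e−9 and log a
  warning when the deviation exceeds 1e−6 (typical of frequencies copied
  from tables printed at 3–4 figures, e.g. the X. fastidiosa values that
  sum to 0.9999); negative inputs are rejected.
- Ambiguity handling: IUPAC codes are excluded from frequency denominators
  rather than fractionally distributed, keeping the 4-symbol model exact;
  U counts as T so RNA input works transparently.
- Display rounding follows the field's presentation (3 decimals for S);
  full precision is retained internally and in TSV output by default.
- Stochastic commands take an explicit `--seed` defaulting to a fixed
  constant, never wall-clock.
- Known limitations: no codon-position or dinucleotide statistics; no
  segmentation, gene-finding or replication-origin calling on top of the
  Z-curve; plots are best-effort projections, not publication figures.
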