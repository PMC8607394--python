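# Methods

This note records the model, the numerical choices, and the boundaries of
what the test suite establishes.  It is the package's own account; the README
gives the user-facing summary.

## Data model

A 6ddp is one SNV observation `(cd, re, po, af, ph, pa)`.  The four
*independent* variables are always known; the two *outcome* variables may be
unknown (`ph = uk`, `pa = uk`), and a record is **fulfilled** when both are
known.  Residue substitutions are pooled by size/hydrophilicity/charge —
Arg,His→Lys; Asp→Glu; Ser→Thr; Asn→Gln; Ala,Val,Ile,Met,Phe,Trp→Leu — over a
21-letter alphabet (20 amino acids plus a stop symbol), yielding a 10-class
pooled alphabet and 100 ordered ref/sub pairs.  Identity-after-pooling pairs
are retained: nothing in the data model says they must be dropped, and
dropping them would silently change the CPT support.  Allele frequency is
binned at 1% with the boundary inclusive in category 0.  Provider conflicts
resolve per outcome to the strict majority (> half of submissions); every tie
or bare plurality becomes unknown — the simplest deterministic reading of
"clearly dominant".

## Population divergence proxy

Populations are ordered by migration distance from East Africa: haversine
great-circle legs (mean Earth radius 6371.0 km) summed along per-population
waypoint paths, admixture-weighted where a sampled population mixes several
origins, with optional pre-computed driving distances as upper bounds
(network routing is deliberately out of scope).  Lower/upper bounds are
widened symmetrically about their midpoints in 1% increments until a straight
line of distance versus rank threads every interval (an LP feasibility check
via `scipy.optimize.linprog`); the widening schedule is this package's
choice, since only the outcome of such a calibration is published.  After
ordering, only the equally spaced rank (Population Index k = 1..np) enters
the correlation engine — fitted distances never do.  Increasing migration
distance stands for decreasing genetic divergence throughout.

The packaged route table is an **approximate reconstruction** (flagged in the
file): waypoints follow the published narrative (origin Addis Ababa, Cairo
gateway, Istanbul/Caspian routes to Europe, Himalayan routes to Asia, Bering
crossing plus immigrant admixture for the Americas, Senegal for the enslaved
West-African diaspora, Tahiti for Hawaii), but coordinates, weights and
driving estimates are ours.  Its bound calibration converges at a factor
around 6 — far from the published ≈1.12/1.14, which are only reproducible
with the original supplementary waypoint set; treat the shipped table as a
demonstration default.  Default exclusions: GLO/OTH (not rankable) and TWC
(redundant with the larger UK cohort PCC).

## Imputation ensemble

Features are concatenated one-hot blocks for `cd`, the 100 pooled ref/sub
pairs, `po`, and `af` (two units).  Each candidate model has two independent
heads (phenotype, pathogenicity) — whether the real architecture chains them
is not published; independence is the default and the conservative choice.
Each head is a one-hidden-layer MLP (logistic activation, width defaulting
to the feature dimension, adam, cross-entropy) fitted by scikit-learn; the
package extracts the weights and predicts through its own forward pass so
that models serialized to the text bundle predict identically after reload.
A pool of 100 candidates (configurable) trains from distinct seeded
initializations on a stratified 80/20 split of the fulfilled records;
singleton outcome classes stay in training.  The score is **exact
reproduction**: both heads simultaneously correct on the held-out split.
The best 20 form the ensemble, and the best model must reach the 60% floor.
Imputation replaces only unknown outcomes, by plurality vote with ties going
to the lowest class index; independent fields and known outcomes are never
touched.

## Bayes model and probability matrices

CPTs are maximum-likelihood frequencies over the completed dataset.  The
domain×population probability sums conditional products over every
*observed* `(re, af, ph)` combination; unobserved conditioning tuples
contribute exactly 0 (no pseudocounts — pseudocounts would leak probability
into never-observed domains; a Laplace option exists but defaults off).  The
sum is the literal unweighted form — not frequency-weighted over
`(af, re, ph)` — so matrix entries are non-negative but not normalized over
domains; a weighted variant was considered and rejected as the default
because the printed formalism is unweighted.  Binarization sums `{lp, pt}`
(pathogenic) or `{lb, be}` (benign); the unknown class stays in the CPT
outcome axis (so normalization holds) but never contributes to either binary
matrix.

## 2D correlation

Φ and Ψ are evaluated on the **raw** probability profiles, exactly as the
defining sums are written — classical 2D correlation spectroscopy
mean-centers to "dynamic spectra" first, and a `center=True` option exists,
but the literal uncentered form is the default and the one used in every
acceptance-level check.  Consequence worth knowing: the uncentered Ψ carries
first-order baseline×deviation cross-terms, so it is not shift-invariant,
and the asynchronous signal of two trend profiles differs in magnitude (not
sign) between forward and backward phase shifts.  Lead/lag uses Noda's
standard rule — Ψ≈0 (|Ψ| ≤ 1e-12): in phase; Φ·Ψ > 0: i leads j; Φ·Ψ < 0:
j leads i; Φ≈0 with Ψ≠0: indeterminate — verified on constructed
phase-shifted profiles (positive shift of the partner toward lower
divergence ⇒ Φ·Ψ > 0 ⇒ first member leads).

## Amplitude, z-scores, significance

`a = |Φ| + π|Ψ|` (π balances the synchronous weight against the
nearest-neighbour asynchronous weight, |nf| = 1/π at unit gap).  The
"normal fit" to the ±a-symmetrized histogram is implemented as a moment fit:
the symmetrized set has mean exactly 0 by construction, so σ is the RMS of
the masked amplitudes — deterministic, and faithful to a distribution that
is only said to be *approximated* by a normal.  The default fit mask is all
unique off-diagonal pairs (which pairs entered the published fit is
unstated; a mask argument allows inter-protein-only).  Top-K (K = 6)
selection ranks unordered **inter-protein** pairs only, ties broken
lexicographically.  The relative p-value is `Q(z_u)/Q(z_c)` with Q the
standard-normal upper tail, z_u the least significant of the unknown
complex's top-6 and z_c the control's maximum; reading both tails in common
z units (rather than on per-complex refitted distributions) is adopted
because it reproduces both published values: Q(5.8)/Q(4.7) = 0.00255 → 0.003
and Q(3.7)/Q(2.7) = 0.0311 → 0.03.

## Synthetic world

The generator states: population uniform over the index; background domains
uniform; each planted pair's two domains follow a common logistic ramp
(center mid-axis, width np/8) rising from baseline to baseline×(1+effect),
the partner's ramp displaced by the phase shift; pathogenicity concentrated
on the planted class with 0.9 purity (background: 12/8/48/32% over
pt/lp/be/lb); substitutions uniform over the 100 pooled pairs; allele
category 0 with probability 0.9; phenotypes from a fixed skewed background
distribution (a few classes predominate, as in real submissions) and —
deliberately — independent of the features, since the default regime
emulates *post-imputation* data whose outcome structure the correlation
stages do not rely on.  A separate learnable generator plants a
deterministic domain→(ph, pa) rule for validating the imputation stage.

Default effect size 4.0 (planted SNV rate quintuples across the axis) and
phase ±3 index units: chosen so planted co-domains are dominant map features
with a clearly resolvable asynchronous sign (signal-to-noise ≈ 2 at 4×10⁴
records over 65 domains × 30 populations), mirroring the published regime in
which the top cross-peaks stand > 5.8 SD above the map RMS and all carry
definite directional calls.  A weaker world (effect 2) leaves the lead/lag
sign near the noise floor at this scale — a statement about that world's
detectability, not about the machinery.  A rank-skewed substitution
distribution was evaluated for realism and rejected: it shrinks the
distinct-conditioning-tuple count that the probability sums ride on.

For runtime, the null-versus-planted bracketing property runs at a reduced
world size (21 domains, 10 populations, 6×10³ records, 30 paired seeds); the
acceptance-level recovery check runs at the full stated scale with 20 seeds,
and the training checks use a 24–25-candidate pool (the ensemble is always
the configured 20).

What a green synthetic test establishes: the pipeline recovers planted
inter-protein structure and phase direction at the stated scale, and null
worlds score below planted ones.  What it does not establish: performance on
real SNV data with linkage, ascertainment bias, provider heterogeneity, or
realistic allele-frequency spectra — none of which are simulated.

## Degenerate inputs and tolerances

Φ/Ψ require np ≥ 2 (the 1/(np−1) normalization); z-scoring rejects an
all-zero amplitude map; top-K rejects K beyond the number of inter-protein
pairs; imputation of a dataset with no unknowns is the identity.  Symmetry
and antisymmetry are asserted to 1e-10, oracle equivalences to 1e-12,
CPT normalization to 1e-12.  All randomness flows from explicit integer
seeds; derived seeds stay below 2³¹.

## Known limitations

- The shipped route table is approximate; published widening factors and the
  published population order are not reproducible from it.
- The reduction of 420 raw ref/sub combinations to the published 59 is not
  derivable from the stated pooling map (which yields a 10-class alphabet and
  100 ordered pairs); the pooled pair count is therefore not hard-coded, and
  59 is recorded as a reference expectation only.
- The real architecture/training protocol of the published models is in
  earlier work and not reproduced; the defaults here are declared, not
  inferred.
- Full-complex reproduction (39,290 / 31,181 records; z thresholds 5.8/3.7
  vs 4.1/2.3) requires the supplementary datasets, which the package can read
  (CSV or xlsx) but cannot ship.
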