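# Methods

## Surface descriptors (CoMSA)

A molecule is represented as point charges on atoms with Bondi van der
Waals radii. Surface points are drawn uniformly on each atom's scaled vdW
sphere (`radius_scale`, default 1.0; `points_per_atom`, default 10–20) and
discarded when buried strictly inside any other atom's scaled sphere. The
molecular electrostatic potential at a surface point is the Coulomb sum
with a distance-dependent dielectric ε(r) = r,

    V(p) = k · Σᵢ qᵢ / rᵢ²,    k = 332.0636 kcal·Å/(mol·e²),

so V is in kcal/mol per unit probe charge. The distance-dependent
dielectric is the convention used by the force-field minimisations this
kind of data usually comes from; it also keeps the descriptor local, which
suits surface comparison.

A rectangular (planar, non-toroidal) Kohonen map with 3-element weight
vectors is trained on the *template* molecule's surface coordinates. The
winner for a point is the neuron minimizing squared Euclidean distance,
ties broken to the lowest row-major index. Training is winner-takes-most:
every neuron j moves by α·exp(−d_grid(j, winner)²/(2σ²))·(x − w_j), with α
decaying linearly 0.5 → 0.01 and σ from max(rows, cols)/2 → 0.5 over the
epochs (both schedules overridable). Weights initialize uniformly inside
the training points' bounding box, seeded; presentation order reshuffles
per epoch. These schedule constants are conventional SOM practice — the
maps here are used as a fixed spatial quantization, so the results are
insensitive to the exact schedule as long as it anneals.

Projection sends every surface point of a (counter-)template molecule to
its winning neuron *unless* its distance to that neuron's weight exceeds
the `winning_distance` (default 2.0 Å, meaningful range roughly 0.2–2.0):
distant points are discarded, so a molecule only marks map cells whose
template-surface neighbourhood it actually reaches. The discard radius is
applied at projection only, not during training. Cell value = arithmetic
mean of assigned point potentials; unoccupied cells are empty and unfold
to 0 (configurable), the neutral value for centered PLS. Row-major
unfolding of a rows×cols map gives the descriptor row (20×20 → 400,
50×50 → 2500).

Molecules must be pre-aligned on a common scaffold; alignment is an input
contract (the synthetic series is generated aligned), not something this
package performs.

## Field descriptors (CoMFA-style)

A regular lattice with `spacing` 2.0 Å covers the union of the series' vdW
envelopes plus a `margin` of 4.0 Å, bounds rounded *outward* to spacing
multiples — this makes the lattice independent of molecule order and
reproducible across runs. At each node, for each molecule:

* electrostatic: E = k·q_probe·Σᵢ qᵢ/rᵢ² (same ε(r) = r convention);
* steric: Lennard-Jones 6-12, S = Σᵢ εᵢₚ[(rminᵢₚ/rᵢ)¹² − 2(rminᵢₚ/rᵢ)⁶],
  with Lorentz–Berthelot combination (arithmetic mean of per-atom rmin,
  geometric mean of ε) against an sp³-carbon probe (+1 e, ε = 0.107
  kcal/mol, rmin = 3.40 Å). The bundled LJ table covers H, C, N, O, S, Cl
  with Tripos-like values and is overridable.

Energies are truncated at ±30 kcal/mol (`cutoff`); a node coinciding with
an atom is set to +cutoff and logged. The steric and electrostatic blocks
are concatenated column-wise per molecule. Columns with energy standard
deviation below `sigma` = 2.0 kcal/mol are discarded before modelling;
"σ as variance" is available behind a flag because the two readings differ
and both are seen in practice (the threshold value is 2.0 either way).

## PLS, cross-validation, IVE-PLS

PLS is univariate-response NIPALS on column-centered X and centered y
(no autoscaling), components capped at min(n−1, p, 7); the cap of 7
reflects the small-n regime the toolkit targets. The NIPALS core returns
the *nested* coefficient sequence b₁..b_A from one pass, which is what
makes the partition census affordable. Equivalence with
scikit-learn's PLSRegression and with ordinary least squares at full rank
is enforced in the test suite to 1e-8.

Cross-validated q²cv uses leave-one-out predictions and the total sum of
squares about the mean of all observed values; the optimal component count
is the smallest one attaining the maximal q². External predictions are
scored by q²test (total sum of squares about the *test-set* mean, exactly
as defined; the training-mean alternative exists behind a flag) and
SDEP = sqrt(Σ(pred−obs)²/n).

IVE-PLS: iterate (1) LOO cross-validation of the current matrix,
(2) removal of the single column with the lowest stability
|mean(b_j)/std(b_j)| over the LOO submodels (std with n−1 denominator;
ties → lower column index; a numerically constant nonzero coefficient is
perfectly stable, an all-zero one has stability 0), down to `min_columns`
(default 2). The q² component count is re-estimated after every
elimination because q² is the elimination objective. The stability score,
however, is computed from the submodel coefficients at the *capped*
component count rather than the per-iteration optimum: early in an
elimination over many noise columns the cross-validated optimum is itself
noisy, and ranking coefficients at full complexity (the classical UVE
convention) is markedly more reliable at flagging uninformative columns.
Both behaviors are available (`stability_components="max"|"optimal"`), as
is a bootstrap submodel ensemble (`ensemble="bootstrap:k"`), which
measured *less* reliable than LOO on the recovery benchmark and is kept
only as the documented alternative. The selected column set is the one at
the global q² maximum over the trace (earliest iteration on ties); the
trace keeps the no-elimination baseline as iteration 0 so "eliminate
nothing" is a representable outcome.

Backward elimination guided by cross-validation on the full data inflates
the q² of late, small column sets (selection bias); the planted-truth
tests quantify what the procedure can and cannot recover under this bias.

## Stochastic model validation

For a series of n compounds and test size k (default 6 of 20, the 2:1
split), every C(n, k) partition — or a seeded sample of distinct
partitions — is evaluated: LOO q²cv on the training block picks the
component count, the refit model predicts the held-out block, scored by
q²test and SDEP. Test blocks with zero activity variance are recorded with
q²test undefined (missing), not dropped. Exhaustive mode is guarded by a
10⁵-partition ceiling above which sampling is required; C(20,6) = 38,760
passes. Per-compound test-membership frequencies over the partitions with
q²cv ≥ 0.75 (against the unconditional k/n background) rank compounds by
how much their exclusion from training flatters the model.

Deterministic splitters: Kennard–Stone maximin on the dependent variable
(seeded with the most distant value pair, then repeatedly adding the
candidate with maximal minimum distance to the selected set; ties to the
lower index; an X-space variant exists but is off by default) and the
activity-ranked cyclic 2:1 split (sort, assign 2 to train / 1 to test
along the ranking, remainder to train).

## Receptor-array analysis

The dipeptide receptor library is the full Cartesian design: gating acid
H (heptanoic) or D (decanoic) × 20 proteinogenic residues attached to the
acid × {Ala, Phe, Pro} on the linker = 120 receptors, written
`<acid>-<XY>` (e.g. `D-EP`). Displacement intensity is the plain
difference I_D = I_Drd − I_Da on the 256-level gray scale; negative values
are kept and flagged, not clamped — a floor describes data, not a rule.
IC50 classes use half-open intervals [0,25) hA, [25,50) A, [50,100) IN,
[100,∞) hIN, resolving the boundary values that strict inequalities would
leave unassigned. The activity transform for correlations defaults to
pIC50 = −log10(IC50); the expression "−log(1/activity)" that sometimes
labels such plots algebraically equals +log(activity) and is available as
`transform="literal"` — the two are negatives of each other, which flips
every correlation sign. Correlation analyses on the "active only" subset
use classes hA/A (IC50 < 50) and require ≥ 3 compounds. Selection profiles
report counts, fractions, and enrichment (selected fraction ÷ library
background: 1/2 per acid, 1/20 per residue, 1/3 per linker).

## Synthetic data: what it emulates, and what it does not

`make_molecule_set` builds a congeneric series: one literally shared
scaffold (default 15 atoms — the aligned common core) plus per-molecule
substituent atoms; activity = 50 − 30·(total substituent charge) +
N(0, 0.05). Tying activity to substituent *charge* (not geometry) puts the
signal into the surface electrostatics by construction. Partial charges
are N(0, 0.2 e), typical of organic partial charges.

`make_response_dataset` builds the 20×120 response matrix: uninformative
cells are lognormal(μ_log = 2.2, σ_log = 0.9) — median ≈ 9, right-skewed,
like displacement readouts; decanoic columns get an additive +4 shift (the
longer lipid chain binds more strongly), which yields >50 response tails
of ≈ 3% (H) vs ≈ 4% (D). The three planted informative receptors (D-EP,
D-QP, H-CP — all Pro-linker, so linker enrichment is testable end to end)
are instead uniform over [1, 70]: an activity-informative receptor is
exactly one whose response *discriminates* the compounds across the
working range, and this large column variance is also what lets
covariance-driven (centered, unscaled) PLS find them against 117 noise
columns at n = 20. Activity = 75 − 0.5·R(D-EP) + 0.5·R(D-QP) −
0.5·R(H-CP) + N(0, 0.1); the coefficient geometry keeps activities
strictly positive (log transforms always defined) and spread across all
four potency classes. Everything is clipped to [0.001, 73.9] (clipping,
not rejection). At noise 0 the planted models are recovered by OLS to
machine precision.

What the generator does **not** emulate: real binding physics or
chemistry-specific response patterns, correlated receptor families,
compound-level response factors (e.g. lipophilicity gating), heteroscedastic
assay noise, or alignment error in the molecular series. Passing tests
demonstrate that the algorithms do what they claim under planted truth —
not that a particular real dataset is this well-behaved. In particular,
three *independent* informative columns with equal activity shares cap
each column's marginal correlation at √(1/3) ≈ 0.58, which is close to
the maximal spurious correlation among ~120 noise columns at n = 20; the
default generator avoids that marginal regime by giving informative
columns dominant variance. With comparable-variance informative columns,
recovery degrades to roughly 60–80% per run — a genuine limitation of
stability-guided backward elimination at this sample size, not an artifact.

## Numerical conventions

* Standard deviations use the n−1 denominator throughout (pre-filter
  threshold 1e-4; energy filter threshold 2.0 kcal/mol).
* All writers format floats as `%.17g` and all readers parse round-trip
  exactly, so write∘read is the identity and seeded pipeline reruns are
  byte-identical (SHA-256 digests in the run manifest).
* Every randomized operation requires an explicit integer seed in library
  code; the CLI defaults to seed 0. Per-molecule surface-sampling seeds
  derive from the master seed and a stable FNV-1a hash of the molecule id,
  so a descriptor row does not depend on batch composition or order.
* Ties break deterministically everywhere (lowest index / earliest
  iteration).
* PCA is SVD-based with the largest-magnitude loading entry of each
  component made positive; modes are `center` and `autoscale` (autoscaling
  refuses zero-variance columns and points to the pre-filter).
* Degenerate cases: all-points-discarded projections warn and return an
  empty map; a rank-deficient PLS fit warns and returns the achievable
  model; zero-variance y is an error wherever q² would be undefined.

## Problem sizes

The shipped configurations are sized for a laptop-class single CPU: the
exhaustive partition census (38,760 partitions × 15 LOO fits each at
≤ 3 components on a 20×30 matrix) runs in about a minute; the 120-column
eliminations run in ~0.5 s each; the full synthetic pipeline with a 20×20
map completes in seconds. Larger maps (50×50) and sampled SMV scale
linearly.
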