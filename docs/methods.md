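# Methods

## The model

A protein chain is reduced to an ordered set of typed unit vectors

    X = (v_1, ..., v_N),    s_i in {helix, strand},    L_i residues,

one vector per secondary-structure element (SSE), ordered as the SSEs occur
on the peptide sequence. The vector is the first principal component of the
element's C-alpha cloud, oriented N->C; translational placement and (by
default) length are discarded. Two representations X (N_x elements) and
Y (N_y elements) are compared by rotating X as a whole and scoring

    D_ij(R) = 1{s_i = s_j} * exp(-theta_ij(R)^2 / delta^2),
    F(R; X, Y) = - sum_ij D_ij(R),

where `theta_ij(R)` is the angle between `R v_i` and `w_j` and `delta`
(radians) controls how steeply credit decays with angular mismatch. F is
bounded by `-N_x N_y <= F <= 0`; for two identical substructures and
`delta -> 0` the minimum tends to minus the SSE count of the smaller
structure. Helix and strand vectors never match each other, and direction is
taken in the N->C sense: parallel and antiparallel arrangements are distinct
(`cos theta`, not `|cos theta|`).

Whether a minimum of F is deeper than chance is judged by the rotational
z-score

    z_F = (F - <F>_R) / std_R(F),

with moments taken over Haar-uniform rotations. For a uniform rotation the
angle between a rotated and a fixed vector has density `sin(theta)/2`, so
each same-type pair contributes the same mean, `(1/2) Int_0^pi
exp(-theta^2/delta^2) sin(theta) dtheta`; the mean of F is this quadrature
value times the (weighted) count of same-type pairs. No closed form is used
for the second moment: the standard deviation is estimated by seeded Monte
Carlo over `mc_samples` rotations drawn as normalized 4-D Gaussians (exact
Haar uniformity). Deep minima give z well below zero; minima with z above
`z_cut` (default -2) are discarded as achievable by chance orientation.
Both averages are taken over *all* rotations, not only those compatible
with a long alignment — an approximation that works well for discarding bad
solutions, which is the only use made of it here.

The optimal rotation is found by multi-start local optimization:

1. **Seeds.** For every ordered index pair (i, j), `i < j <= i + m`, in X
   and every type-matching ordered pair (k, l), `k < l <= k + m`, in Y, the
   seed rotation maps `v_i` onto `w_k` and the plane span(v_i, v_j) onto
   span(w_k, w_l). With m fixed (default 3) the seed count is O(N_x N_y).
   Pairs within 5 deg of (anti)collinear are skipped as ill-conditioned;
   near-duplicate seeds (< 1 deg apart) are removed. Optionally, nearly
   parallel same-type vectors are first merged by single-linkage grouping
   at angle `group_eps` (the compact set seeds the search; the alignment
   below always runs on the full, "unfolded" representations).
2. **Descent.** From each seed, steepest descent on F over unit
   quaternions: the tangent-space gradient is analytic
   (`dF/de = -sum_ij W_ij e^(-theta^2/delta^2) (2 theta/(delta^2 sin
   theta)) (u_i x w_j)`, with `u = R v`), steps use Armijo backtracking
   with the step capped at 0.5 rad, and the quaternion is re-normalized
   after every step. A seed stops when the gradient norm drops below
   `grad_tol` (default 1e-8), when an accepted step improves F by less
   than `f_tol` (default 1e-12), or after `max_iter` (default 500)
   iterations. F is monotone non-increasing by construction.
3. **Pruning.** Descending every seed is wasteful: seeds are ranked by
   their pre-descent F and only the `top_seeds` (default 32) most promising
   mutually distinct ones are refined. The planted-rotation experiments
   confirm this loses nothing at default settings: the basin of the true
   rotation always contains the best-scoring seeds.
4. **Collection.** Converged rotations closer than 5 deg are merged keeping
   the deeper F; surviving minima are z-scored, filtered at `z_cut`, and
   returned sorted by ascending z.

The minimum's similarity matrix `D(R_opt)` is then treated like a
substitution matrix and the SSE correspondence is the strictly
order-preserving partial map `M: i -> M(i)` (`i_1 < i_2 => M(i_1) < M(i_2)`)
maximizing `sum D_{i,M(i)}` minus gap penalties — Needleman-Wunsch/
Smith-Waterman dynamic programming over SSEs instead of residues. The gap
model charges `gap_open` (default -1) once per gap opening and nothing per
extension (Gotoh three-state recurrences). The reported total aligned score
`T(D)` is the pure sum of matched D entries; unmatched SSEs are ignored.
Modes: `global`, `semiglobal` (free end gaps in both sequences; default,
appropriate for substructure search), `local`. For non-negative D and
opening-only gaps the semiglobal and local optima coincide; both are kept
for interface completeness. Traceback ties are broken deterministically:
match over free start over gap-in-Y over gap-in-X.

Optionally each pair is down-weighted by SSE length mismatch,
`exp(-(dL_ij/len_tol)^2)`, applied inside D (so it affects both F and the
alignment) rather than as a separate alignment term.

**Flexible matches.** A hinge-type conformational relation is modeled as
two rotations, one per rigid domain: two significant minima whose angular
separation exceeds `min_separation_deg` (default 15 deg) are combined by
`D^max_ij = max(D_ij(R_1), D_ij(R_2))`, aligned, and scored with the
heuristic `((|z_1| + |z_2|)/2) * T(D^max)`. A candidate pair must be
*complementary* — each rotation must explain at least one matched pair
strictly better than the other — and its combined T must strictly exceed
the best single-rotation T, otherwise the relation is rigid and no flexible
match is reported. The pair search runs over the `top_minima` (default 10)
most significant minima and generalizes to n > 2 rotations in the obvious
way, but only n = 2 is exercised.

**Database scans.** A database holds one representation per chain with at
least four SSEs (structures with fewer carry too little signal to rank).
Rigid hits are sorted by descending T, flexible hits by descending
heuristic score; the best z is reported alongside so geometric-only and
order-constrained rankings can both be inspected. Reports are
tab-separated, carry the full parameter set in the header, and are
byte-reproducible given identical inputs and seed.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `delta` | 0.5 | rad | Gaussian width of the angular match; 0.5 suits classification-style scans, 0.3 (with length penalty) conformer search, 0.1 exact-match tests |
| `len_tol` | off | residues | length-mismatch tolerance; penalty `exp(-(dL/tol)^2)` |
| `m` | 3 | — | seed-pair index truncation `j <= i + m` |
| `group_eps` | off | rad | direction-grouping angle (single linkage) |
| `gap_open` | -1 | score | per-opening gap penalty in the alignment |
| `mc_samples` | 2000 | — | Monte-Carlo rotations for std(F); minimum 1000 |
| `seed` | 0 | — | seed for every random draw |
| `z_cut` | -2 | — | significance threshold on the rotational z-score |
| `align_mode` | semiglobal | — | alignment mode |
| `min_separation_deg` | 15 | deg | distinctness threshold for a two-rotation match |
| `top_seeds` | 32 | — | descent starts kept after pre-descent pruning |
| `top_minima` | 10 | — | minima pool for the flexible pair search |
| `max_iter`, `grad_tol`, `f_tol` | 500, 1e-8, 1e-12 | — | descent schedule |

Reduction-side defaults: SSE boundaries come from HELIX/SHEET records (or
an external assignment file); helices shorter than 4 residues and strands
shorter than 3 are discarded (shorter segments give unstable axes); each
strand is one vector even when bent; residue numbering is the author
numbering of the input file; coordinates are Angstrom, right-handed.

## Synthetic data

The generators draw SSE directions uniformly on the sphere, types helix
with probability 0.65 (a typical mixed-fold composition), and lengths
uniform over 6-20 residues (helices) and 3-10 (strands). Hinge conformer
pairs rotate the block of vectors past a split index about a fixed axis
and then tilt every vector by |N(0, sigma)| degrees about a random
perpendicular axis. Ideal-geometry PDB fixtures use textbook values:
1.5 A rise and 100 deg twist per helical residue at 2.3 A radius, 3.5 A
per extended-strand residue.

What the generators emulate is the combinatorial diversity of a structure
database, not real protein geometry: there are no packed parallel helix
bundles or twisted sheets, no fold topology, and no evolutionary
divergence. Consequently chance geometric matches are *rarer* here than in
real data — the self-scoring experiments pass comfortably, and the
degradation of z-only ranking at delta = 0.3, which is pronounced on real
structure sets, appears only weakly (one misranked query per hundred at
the study settings). Passing these tests shows the machinery is correct
and calibrated, not that real-database ROC performance is reproduced.

## Study conditions and problem sizes

The shipped experiments (tests/test_acceptance.py, scripts/acceptance.py)
use: a 100-entry decoy database with 4-20 SSEs per entry scanned all
against all at delta = 0.1 and 0.3; 50 planted-rotation cases (8 SSEs);
200 random alignment matrices up to 8x8 against exhaustive enumeration;
30 Monte-Carlo-versus-quadrature checks at 1e5 rotations each; 20 planted
hinge pairs (12 SSEs, split 6/6, angles 40/70/110 deg, 3 deg noise) plus
20 rigidly related pairs. Database scans use scan-grade optimizer effort
(`top_seeds=10`, `max_iter=60`, `grad_tol=1e-5`, `f_tol=1e-9`,
`mc_samples=1000`): the self-match seed starts at the exact optimum and
decoys only need approximate T, so scan rankings are insensitive to the
tighter defaults, which remain in force for the precision experiments.

## Numerical notes and edge cases

- `arccos` arguments are clipped to [-1, 1]; the gradient factor
  `theta/sin(theta)` is clamped at `sin >= 1e-9` (it tends to 1 at 0).
- Quaternions q and -q are the same rotation; all distances use
  `2 arccos(|q1 . q2|)` and every operation is sign-invariant.
- At very small delta (e.g. 0.01) the Gaussian underflows to exactly zero
  for every random rotation, so std(F) over rotations is 0 and the z-score
  is undefined; `z_score` raises in that case rather than returning
  infinity.
- Coincident C-alpha points have no principal axis and raise a
  degenerate-geometry error; collinear points are fine.
- Ties in the alignment traceback and in hit ranking (equal T) are broken
  deterministically (predecessor priority, then target id), making scan
  reports byte-stable.

## Known limitations

- SSE assignment is taken from file annotations or an external tool; there
  is no geometric DSSP-style assignment, no strand splitting at bends, and
  no handling of nucleic-acid chains.
- The representation drops translations entirely, so structures sharing
  SSE directions and order but differing in packing are indistinguishable
  by design.
- The second rotational moment has no closed form here; its Monte-Carlo
  estimate makes z-scores stochastic at the ~1/sqrt(mc_samples) level.
- Only two-rotation flexible matches are searched; n-domain decompositions
  and atomic-level superposition/refinement are out of scope.
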