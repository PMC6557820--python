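# Methods

This note documents the models, conventions and numerical choices behind
`tanglescan`, and what the synthetic generators do and do not emulate.

## Gaussian entanglement of open subchains

The core quantity is the discretized Gauss double sum over two
non-overlapping subchains of a Cα trace (see README for the formula). The
implementation details that matter:

* **Bond convention.** A residue range [a, b] contributes bonds a..b−1, so
  the double sum runs over i ∈ [i1, i2−1], j ∈ [j1, j2−1]. Midpoints and
  bond vectors are precomputed once per trace.
* **Kernel precomputation.** The (n−1)×(n−1) matrix of pairwise Gauss terms
  is symmetric with zero diagonal; a padded 2D prefix-sum table turns any
  subchain-pair score into an O(1) rectangle sum. Per trace the cost is
  O(n²) once, independent of how many loop–thread pairs are scored. The
  exactness of this reduction (to 1e-10) is pinned by a brute-force oracle
  test that re-evaluates the double sum term by term.
* **No closure.** Open subchains are never artificially closed; the score
  is a real number, not a topological invariant. On the closed-curve
  constructions (where a closing bond *is* included) the discrete sum
  reproduces integer linking numbers to ~0.2% at 128 points per curve, and
  the error falls at least quadratically with refinement.
* **Symmetries.** The score is invariant under rigid motions and under
  swapping the two subchains, flips sign under mirror reflection (the
  kernel is a pseudoscalar) and under reversing the orientation of exactly
  one subchain. All four are asserted in the test suite; the mirror flip is
  exact in floating point because it only negates kernel entries.

## Loops, threads and the per-protein scores

A loop is closed by a heavy-atom contact (any non-hydrogen atom pair within
4.5 Å) with sequence separation ≥ m0 = 10; potential-style counting uses
side-chain heavy atoms instead, with glycine falling back to all heavy
atoms so the 20×20 matrices keep all rows. Threads are all contiguous
ranges (j1, j2), j2 − j1 ≥ m0, entirely on one side of the loop, separated
by at least s_min = 1 residue — not merely the full arms. The argmax scan
is deterministic: N-side candidates are visited before C-side ones, each
side in lexicographic (j1, j2) order, and ties keep the first extremum.
Per-protein, G'_c is the largest-modulus per-loop score with its sign
retained, and L' is the analogous extremum over unordered pairs of disjoint
contact-closed loops. Loops with no admissible thread (too close to both
termini) are flagged rather than scored.

Chains with any consecutive Cα–Cα distance above 10 Å are rejected before
scanning: a straight virtual bond across missing density can thread loops
that do not exist in the real structure. Residues without a Cα are dropped
first, so the filter also guards the gaps they induce.

## Clustering and effective counts

Entangled loops within one protein are clustered greedily: repeatedly take
the loop with the most neighbors within d* = 20 under the index/score
distance (w_g = 10⁴), form a cluster from it and its neighbors, remove
them. Ties on the neighbor count are broken by the lowest (i1, i2, j1, j2);
this makes the procedure deterministic and, empirically, permutation
invariant on random sets. Weights 1/N_C make each cluster one effective
observation; downstream standard errors are binomial on n_eff = Σ weights.

## Thread-side asymmetry and the random reference

The side statistics answer: does the maximizing thread fall more often on
the loop's N-terminal side than chance predicts? "Chance" is made precise
by drawing, for each entangled loop, one putative thread uniformly over all
admissible segments — enumerated exactly in closed form (triangular
numbers), no rejection sampling — and comparing side fractions and
separation distributions. The weighted KS comparison uses the exact
supremum difference of the weighted empirical CDFs as the statistic; its
p-value evaluates the classical two-sample asymptotic distribution at the
clustering-effective counts. This treats each effective count as one
independent observation — an approximation, but one that (unlike
resampling) returns statistic 0 and p = 1 for identical inputs and has
calibrated null behavior in the tests.

## Contact potentials and enrichment

Counts are of unordered residue pairs at separation ≥ m0, each counted
once, accumulated per protein; frequencies are normalized by the same
convention in numerator and denominator so the convention cancels in the
scores. E_norm, E_GE and ΔE_enr = E_GE − E_norm are reported on the τ = 100
scale; the entrywise identity between ΔE_enr and the difference of the two
potentials holds to 1e-9 wherever both are defined. Zero-count entries stay
undefined (NaN) — no pseudocounts — mirroring the masked cells of the
score heat maps. Uncertainties come from bootstrapping whole proteins (101
resamples by default), which preserves within-protein correlations; the
significance mask flags |score| > stderr. The correlation report (Pearson,
Spearman, least-squares slope of ΔE_enr on E_norm) uses only jointly
defined unordered pairs.

One caveat worth stating: because entangled contacts are a subset of all
contacts, the sampling noise of f_c enters both ΔE_enr and E_norm with
opposite signs, inducing a spurious anticorrelation of roughly
−sqrt(N_c^G(a,b)/N_c(a,b)) between the two matrices even for null
sequences (≈ −0.1 under the default synthetic conditions). Null calibration
of the correlation statistic therefore uses independently simulated
matrices; ensemble-level null correlations should be read with this floor
in mind.

## Synthetic generators

The generators provide ground truth, not physical realism: no force field,
no secondary-structure propensities, Cα-only "heavy atom" proxies. What
each emulates:

* **Linked rings** — a planar circle and a torus curve winding L times
  poloidally around it; the linking number is exactly L by construction
  (each poloidal turn pierces the spanning disk once), with the poloidal
  direction chosen so positive L gives a positive Gauss sign under the
  right-hand convention.
* **Helix wrap** — one open chain: a straight thread, a connector, and a
  loop that winds `turns` times around the thread at radius ~8 Å before
  returning along a wide constant-azimuth path (which adds no net winding)
  to close at 4.0 Å. The connector feeds the loop start from the side the
  helix initially winds toward, where its final bonds run nearly
  perpendicular to the loop's local field; the measured score then matches
  the planted winding to ~1.3% across turns ∈ ±{1,2,3}, the residual being
  the finite thread length and small connector pickup. The C-side variant
  is the N-side chain traversed in reverse, which provably preserves the
  score (both subchain orientations flip) while swapping the terminus that
  precedes the loop. The closure is the only contact at separation ≥ 10 up
  to Cα cutoffs of ~6 Å.
* **Random backbones** — fixed-bond (3.8 Å) self-avoiding walks (minimum
  non-neighbor distance 4.0 Å) grown with backtracking inside a confinement
  sphere. Tight confinement (radius ≈ 11 Å at n = 60) yields protein-like
  compactness where ~2% of loops are entangled and ~12% of chains host one;
  loose confinement (≈ 14 Å) yields a low-entanglement reference. These
  stand in for a molecular-dynamics decoy ensemble only in the statistical
  sense (compactness-controlled entanglement), not energetically.
* **Planted sequence ensembles** — geometry drawn cyclically from a pool
  interleaving helix wraps (each contributing exactly one entangled
  closure) with loose backbones (contributing the bulk of normal
  contacts); labels i.i.d. from a base frequency vector, with each
  entangled closure redrawn jointly from the pair distribution multiplied
  by the requested enrichment factors. Because the entangled closures are
  themselves part of the normal-contact universe, a factor φ would be
  diluted by its own contribution to f_c; the draw distribution is
  corrected to q' = φp(1−ε)/(1−φε), ε being the entangled fraction of
  contacts in the pool, so the measured frequency ratio is φ in expectation
  and the ground-truth enrichment score is −τ log φ. Residual bias measured
  over six seeds at 2000 structures is ≤ 5% for φ ∈ {0.5, 2, 3}. Sequence
  statistics on these traces use a 6.0 Å Cα cutoff: with Cα-only proxies,
  ~6 Å plays the role that 4.5 Å between heavy atoms plays in full-atom
  structures (4.5 Å at Cα level would sit inside the excluded volume and
  leave almost no contacts).

All generators are deterministic under their seed, and specs serialize to
JSON. What passing tests on these ensembles does *not* show: recovery
rates on real structures with missing density, alternate conformations,
non-canonical chemistry, or contact networks denser than the generators
produce — the structure-reading layer handles those inputs, but the
statistical guarantees are calibrated on the synthetic conditions above.

## Problem sizes and tolerances

The shipped tests and the acceptance script use: 128–256 points per closed
curve; 60 helix-wrap fixtures (|turns| ≤ 3, both sides, jittered geometry);
500-structure side-planted ensembles (ratio 0.7, recovered within 2
binomial stderr); 2000-structure sequence ensembles over a 96-geometry
pool, with enrichment recovery asserted on the mean of six fixed seeds
(within 10% of −τ log φ) and null ΔE_enr coverage asserted at ≥ 90% within
2 bootstrap stderr; 100 simulated-matrix seeds for the null correlation
(|r| < 0.2 in ≥ 95%). Exhaustive oracle checks run on 15-residue traces
where every subchain pair can be enumerated. These sizes were chosen so
each statistical check has the power its tolerance implies while the whole
suite stays interactive.

## Known limitations

* Thread maximization on the engineered wrap fixtures prefers the straight
  thread segment (separation s ≈ 15–20) because the connector adds nothing;
  the small-separation concentration of maximized threads is therefore a
  property of statistically wound chains (compact backbones, real
  proteins), and is tested on those.
* The weighted-KS p-value and the binomial errors treat clustering-effective
  counts as independent observations; both are approximations whose error
  is unquantified beyond the null calibrations in the tests.
* L' is computed over unordered pairs of disjoint loops; a shared endpoint
  residue counts as overlap.
* Full-database reproduction (CATH/decoy ensembles) requires downloading
  the corresponding structure sets; the package reads them through the same
  `load_ensemble` interface but ships no structure data.
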