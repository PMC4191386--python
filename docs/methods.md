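# Methods

## The design problem

A type III hammerhead ribozyme is specified here entirely at the level of
secondary structure: a 54-nt target structure

```
.((((((.(((((...))))).......((((........))))...)))))).
```

(15 base pairs forming the three-helix hammerhead junction) together with
per-position IUPAC sequence constraints

```
HBVHBGUHVH VHDVBBHDBD BCUGAVGAGV DVBVHBBBVH BHBCGAAACV DBVB
```

Sixteen positions — the *conserved site* 6–8, 22–25, 27–29, 44–49
holding the catalytic core — carry the wild-type nucleotides (with the
cleavage site 8 relaxed to H = "not G", since cleavage requires an NUH
triplet); the remaining 38 positions are constrained to *differ* from
wild type through the three-letter complement codes (A→B, C→D, G→H,
U→V), so that any solution is guaranteed not to reuse wild-type identity
outside the core.  The bundled reference sequence is reconstructed by
inverting this constraint string (the codes determine the wild-type
nucleotide uniquely at every position); it is labelled as a
reconstruction, not an accession download, and — reassuringly — its MFE
structure under the Turner 1999 model is exactly the target.

## Complete inverse folding

`enumerate_designs` runs a depth-first branch-and-propagate search over
per-position nucleotide domains.  Propagation enforces arc consistency
across every base pair of the target and of any compatibility
structures (a surviving nucleotide must have an admissible
Watson–Crick/GU partner); a GC-content window prunes by attainable
min/max G+C counts; incompatibility ("must fail at least one pair of the
structure") and the MFE test are evaluated at leaves.  Because pruning
is sound and the space is otherwise exhausted, an empty search is a
*proof* of unsatisfiability.  Variable order (paired before unpaired,
smaller domains first, then position) and value order (A<C<G<U) are
fixed, making output streams byte-identical across runs; a node budget
with resume tokens supports checkpointed long enumerations.

The MFE-equality check is generate-and-test through the engine rather
than an energy-decomposition constraint; this preserves completeness over
the constrained space but not the speed of dedicated CP inverse folders.
The intended scale is small targets (toy model) and budget-limited runs
on the 54-nt problem.

GC-window semantics: a window "lo–hi%" admits G+C counts c with
lo ≤ 100·c/n < hi+1, so consecutive decade windows tile the counts with
no gaps.

## Thermodynamic backends

* **turner1999 / turner2004** delegate to ViennaRNA: MFE and structure
  energies from the standard nearest-neighbour model, pair probabilities
  from the McCaskill partition function, samples via stochastic
  backtracking.  Dangling-end treatment is part of the engine
  configuration because published ensemble quantities are sensitive to
  it (see Calibration).
* **toy** awards −1.0 kcal/mol per base pair (AU/UA/CG/GC/GU/UG, hairpin
  loops ≥ 3).  MFE by Nussinov recursion with a deterministic traceback,
  the partition function by the unambiguous first-position
  decomposition, pair probabilities by conditioning (Z with a pair
  forced, over Z), sampling by stochastic backtracking.  Every quantity
  is checked against an independent exhaustive enumerator (a different
  recursion, written from the definitions) on random sequences up to
  15 nt at 1e-9 tolerance.  RT is 0.61632 kcal/mol at 37 °C.

## Selection measures

With `p*(i,j)` the pair probability and `p*(i,i)` the unpaired
probability (each row sums to 1):

* full positional entropy `H(i) = −Σⱼ p*(i,j) log p*(i,j)` — the Shannon
  entropy of the pairing-state distribution.  A variant that sums binary
  entropies per state (`full_printed`) is provided for comparison; only
  the Shannon form attains the documented maximum `log n` at the uniform
  distribution, and only it reproduces the published selection table.
* binary positional entropy collapses states to paired/unpaired.
* ensemble defect `Σᵢ (1 − p*(i,π(i)))`, the expected number of
  positions whose pairing state differs from the target (π(i) = target
  partner, or i itself when unpaired); also per-site and normalized.
* expected base-pair distance
  `Σ_{(i,j)∈T}(1−p*) + Σ_{(i,j)∉T} p*`, with a per-position profile d(i)
  attributing each pair to both endpoints (so Σᵢ d(i) = 2·EBPD); the
  site-restricted value sums d(i) over the conserved site.
* Vienna diversity `Σ_{i<j} 2p*(1−p*)` (expected distance between two
  independent ensemble draws) and Morgan–Higgs diversity
  `Σᵢ (1 − Σⱼ p*(i,j)²)`.
* discrepancy measures: max over a position set of the absolute
  difference between a candidate's per-position profile (H, H_b, or
  d(i)) and the wild-type reference's.

Entropy defaults to bits in the API; the published-table reproduction
uses natural logarithms (below).

## Calibration against the published selection table

The published per-design table (ensemble defect, average positional
entropy) was produced with an older ViennaRNA release.  The calibration
routine recomputes both measures for all ten designs under each
partition-function dangle class (0 and 2 — classes 1/3 share class 2's
partition function) and both log bases, and selects the combination
minimizing the worst-case relative error: **dangles = 2, natural log**,
frozen in `fixtures.TABLE2_CALIBRATION` together with the achieved
worst-case errors (0.75 for entropy, 0.87 for defect).  Four designs
reproduce to within a few percent; the larger deviations on high-GC
designs are attributable to partition-function differences between
ViennaRNA releases, not to a formula choice — no configuration of the
current engine removes them.  All ten designs' MFE structures equal the
54-nt target in every dangle class except 0.

Two further reconciliations worth recording:

* the published *normalized* ensemble defect (0.025030862 for the
  smallest-defect design) is the whole-molecule defect 1.45179 divided
  by **58** — the 54-nt design plus the GG/CC ends added for
  transcription — although the accompanying text divides by 54;
* the published Pearson correlations between cleavage rate and the
  three headline measures cannot be recovered from the rounded printed
  columns (they evidently used unrounded laboratory values); the
  package recomputes correlations from whatever table it is given.

## Density of states and the two-peak screen

`p(k) = Z_k/Z` over base-pair distance k to a reference structure is
computed exactly by structure enumeration up to 20 nt (any backend
supplies the energies) and by seeded Boltzmann sampling beyond that; the
exact dynamic-programming computation of Z_k for long sequences is
deliberately out of scope, since the density is used only as a screen.
The screen passes when p(0) ≥ τ₀ and a smoothed local maximum at
k ≥ k_min carries mass ≥ τ₁ with a representative structure containing
every pair of the prescribed sequestering helix.  Defaults τ₀ = 0.1,
τ₁ = 0.05, k_min = 10, smoothing window 3 make the qualitative published
criterion ("pronounced peak") operational; raising either threshold can
only turn passes into failures.

## Cleavage kinetics

`F(t) = F_max − (F_max − F₀)·exp(−K_obs·t)` is fitted by bounded
nonlinear least squares over points pooled across technical replicates
(constant error model); the exponent's sign is the standard first-order
approach to plateau — the growing-exponential variant sometimes printed
diverges and cannot describe saturation data.  Initial values: F₀ = min
F, F_max = max F, K_obs from a log-linear fit of the residual amplitude.
The 95% band is first-order (delta method) from the Jacobian and the
residual variance with n−3 degrees of freedom.  On simulated data
(σ = 0.03, 10 time points × 3 replicates, rates spanning 0.01–1 min⁻¹)
the parameter CI covers the true rate in ≥ 90% of trials.

## Synthetic data

The alignment generator plants per-column conservation levels (top
nucleotide + frequency, remaining mass uniform) around an ungapped
reference row; it emulates column-wise composition only — no
phylogenetic correlation, no covariation between paired columns, no
indel structure — so tests built on it validate frequency thresholding
and pattern construction, not homology inference on real families.  The
kinetics generator draws i.i.d. Gaussian noise around the plateau model,
clipped to [0,1]; it does not model the heteroscedastic, gel-derived
errors of real cleavage assays.

## Numerical conventions and limitations

* 1-based closed intervals at every interface; hairpin loops ≥ 3.
* 0·log 0 := 0; probabilities clipped at 1e-300 before logs; probability
  matrices validated to row sums of 1 within 1e-6 (1e-9 for the toy DP).
* Co-optimal MFE structures: equality tests compare the backend's single
  canonical structure (deterministic traceback in the toy model, the
  delegated engine's report otherwise); ties are not enumerated.
* The toy backend is capped at 30 nt (its pair-probability conditioning
  is O(n⁵)).
* Search on the full 54-nt problem is complete but slow (leaf-level
  folding); use node budgets and resume tokens.
* Problem sizes used by the test-bench: oracle equivalence on 20 random
  sequences of 8–15 nt; search completeness on 20 constrained problems
  of 7–10 nt against brute force; density convergence at 50 000 samples;
  kinetics coverage at 100 trials per rate.
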