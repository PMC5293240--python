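# Methods

## The problem

Rigid-body docking searches (FFT-based tools such as FTDock) produce
thousands of candidate poses ("decoys") for a two-protein or two-domain
complex, of which only a handful are near-native.  `coevodock` re-ranks
such decoys using the evolutionary record of the complex: if two residues
interact across the interface, their alignment columns co-mutate, and a
decoy whose interface coincides with genuinely co-evolving residue pairs
is more likely to be the native arrangement.  The package targets the
regime of *small* concatenated alignments (a few hundred rows), where
residue-level coevolution signals are individually too noisy for contact
prediction and must be aggregated to interface level and combined with
structural scores.

## The coupling model and the correlated mutation measure

The concatenated MSA (M rows, N = N1 + N2 columns, q states; gap is a
first-class state in the 21-letter protein alphabet) is modelled by the
maximum-entropy pairwise distribution

    P(A) ∝ exp( −Σ_{i<j} e_ij(A_i, A_j) + Σ_i h_i(A_i) ),

the least-biased distribution whose single and pairwise marginals match
the (pseudocount-smoothed, λ = 0.01 per cell by default) column
frequencies f_i and f_ij.  Couplings are fitted for *all* pairs, including
intra-protein ones, because they are needed to absorb indirect correlation
chains; only cross-boundary pairs are scored downstream.  Sequence rows
are not reweighted by identity: the intended inputs are alignments already
clustered upstream.

Fitting uses non-persistent contrastive divergence (CD-1): each update
restarts Gibbs chains at (a seeded batch of) data rows, runs one
systematic-scan sweep, and moves the parameters along
(data moments − sample moments − L2 gradient) × learning rate.  Defaults:
learning rate 0.5 decaying as 1/√t, 2000 updates, L2 0.01 on couplings and
1e-4 on fields, h initialised to ln f_i, e to 0.  The initial rate is
deliberately aggressive: with a 1/√t schedule, the cumulative step budget
bounds how far couplings can travel from zero, and a rate an order of
magnitude smaller demonstrably stalls short of the penalised optimum
within the budget (verified against the exact fit below).  Early stopping
triggers when the max-norm parameter step stays below 1e-3 for 50
updates; exhausting the budget is logged, not an error.  All randomness
is owned by a mandatory seed, so fits are exactly reproducible.

From the fitted couplings, the direct pair distribution

    P^D_ij(a, b) ∝ f_i(a) f_j(b) exp(−e_ij(a, b))

isolates the pairwise coupling from the rest of the alignment, and the
residue-level correlated mutation measure (CMM)

    D(i, j) = KL( P^D_ij ‖ f_i ⊗ f_j )   [nats]

is zero iff the pair is directly uncoupled.  D is symmetric, non-negative,
invariant under joint relabelling of the alphabet and under uniform shifts
of a coupling block.

An exact-enumeration fit (`exact_fit_oracle`, L-BFGS on the full
likelihood with the partition function summed over all q^N ≤ 1e6
sequences) provides the independent reference for tiny instances; CD and
the exact fit are compared at matched ridge strength, where the exact
fit's marginal-matching residual equals ridge × |e| by stationarity.

## From residue couplings to an interface score

Geometry is computed from heavy atoms (non-hydrogen) only:

* **Relative accessibility** — Shrake–Rupley SASA (probe 1.4 Å, 1000
  sphere points by default) on each *undocked* chain, normalised by the
  theoretical Gly-X-Gly maximum ASA of the residue type (Tien et al.
  values, shipped as an editable 20-row TSV).  A residue is *surface* when
  its relative accessibility is at least 0.08.  The original work used
  WHATIF areas; Shrake–Rupley is a reproducible, dependency-free
  substitute and the 0.08 threshold is kept.
* **Interface set I** — unordered cross-chain surface pairs whose closest
  heavy atoms are strictly within 4.5 Å (recomputed per decoy pose).
* **Surface neighbourhood N_i** — same-chain surface residues within
  4.5 Å of i, including i itself; for a buried residue, the whole surface
  set.  Pose-invariant under rigid docking moves, so computed once per
  complex.

The interface-level CMM score of a decoy is built in four steps:
neighbour averaging χ(i, j) = mean_{k∈N_j} D(i, k) (a side chain near j
may carry the contact signal); per-residue standardisation
(χ(i, j) − μ_i)/σ_i; symmetrisation Z(i, j) = ½ of the two directed
standardised terms; and averaging over I.  The standardisation population
is, by default, *all* directed cross-chain surface pairs of the complex —
a pose-invariant population, so Z measures how a candidate pair's
smoothed coupling compares with every possible interaction.  The
alternative of standardising over the decoy's own interface is
implemented but degenerate as a score: averaging per-population
standardised values over exactly that population cancels identically, so
S^CMM would be zero for every decoy.  A standardisation set with fewer
than two values or zero spread contributes a neutral 0 (logged).

## The other components and the combined score

* **S^N** — number of distinct interface residues.
* **S^RP** — a residue-pair potential summed over interface pairs.  The
  matrix is a pluggable TSV; no default values are invented (the original
  values belong to the FTDock distribution), and synthetic tests use
  random symmetric matrices.
* **S^ent** — interaction-count-weighted mean column entropy (λ = 0
  frequencies, gap included) of the interface residues; equivalently
  Σ_{(i,j)∈I}(H_i + H_j) / (2|I|).
* **S^CT** — complementarity trace: residues are grouped as hydrophobic
  {A,V,L,I,M,F,P,G}, polar {S,T,N,Q,C,Y,W}, positive {K,R,H}, negative
  {D,E} (an editable assignment: only the four groups themselves are
  canonical); two residues are complementary when both hydrophobic, both
  polar, or oppositely charged; an interface pair counts as complementary
  in an MSA row if either member is complementary with the partner or
  with one of the partner's first/second structural neighbours (same
  chain, 4.5 Å); the pair is *preserved* when this holds in ≥ 95% of
  rows, and S^CT is the preserved fraction of I.  Gapped rows count
  against preservation.

The combined score
S = w0 + wN·S^N + wRP·S^RP + went·S^ent + wCT·S^CT + wCMM·S^CMM
is the logit of the near-native probability, fitted by logistic
regression (Newton/IRLS) with a tiny ridge (1e-6) on all weights so that
separable training sets stay finite — the plain glm of the original
formulation has no penalty, and the estimates are indistinguishable away
from separation (cross-checked against statsmodels GLM in the tests).
Near-native means interface backbone RMSD < 3 Å (strict), computed over
the native interface residues' N/CA/C/O atoms after least-squares
superposition (a `fit=False` mode gives docking-frame RMSD; whether the
original benchmark superposed is not documented, so both are provided).
Evaluation uses complex-level three-fold cross-validation (seeded
shuffle; decoys of one complex never straddle folds) and the top-k
success curve: the fraction of complexes with ≥ 1 near-native decoy among
the k best-scored poses (descending score, stable ties).  Decoys with an
empty interface have no defined scores and are excluded from the fitted
table.

## What the synthetic data emulates — and what it does not

The generator reproduces the statistical structure the method relies on,
at desk scale:

* MSAs are Gibbs-sampled from known maximum-entropy models with couplings
  *planted* at chosen cross-boundary column pairs (diagonal
  symbol-matching pattern, default strength 2) and optional conserved
  columns.  Default dimensions: q = 8 reduced alphabet (the model code is
  alphabet-size-agnostic; the reduction buys runtime), N1 = N2 = 10–40,
  M = 350–400 rows — the small-alignment regime the method targets.
* Toy complexes are two zigzag chains of compact 4-atom pseudo-residues
  (alanine-labelled so SASA and potential lookups work), one residue per
  MSA column, with a designated facing block as the native interface;
  every residue is solvent-exposed.  The zigzag (3 Å) keeps the backbone
  non-collinear — a straight chain would make rolls about the chain axis
  invisible to fitted RMSD.
* Decoys perturb chain 2 rigidly.  Near-native candidates use small
  perturbations (σ = 0.35 Å translation, ≤ 6° rotation).  Wrong poses
  mimic a grid search's failure modes: register shifts of 2–4 residues
  along the chain (wrong patch, realistic interface size), 180° face
  flips, and free misorientations (25–90°, σ = 8 Å); a pose that drifts
  out of contact is slid rigidly back until the chains touch, since
  docking searches only emit contacting poses.  Labels are always
  *computed* from interface RMSD, never assumed; roughly a fifth of the
  wrong poses land below 3 Å and are honestly labelled near-native.
* The 9-complex benchmark fixture plants couplings at each native's
  actual contact columns, samples an MSA, fits the CMM by CD (500
  updates, batch 128 — fixture-scale settings), generates 60 decoys per
  complex and assembles the full component table with a random symmetric
  residue-pair matrix.

What passing these tests shows: the estimator chain (CD fit → D →
interface aggregation → logistic combination → ranking) extracts a
planted coevolution signal and converts it into better decoy ranking.
What it does not show: performance on real complexes — real MSAs have
phylogenetic correlation, gaps and alignment error; real decoys have
side-chain packing, clashes and electrostatics; real interfaces are not
single contact blocks.  The paper-scale benchmark (79 complexes, 10,000
FTDock decoys each, Psi-BLAST alignments) is outside the package's data
and is deliberately not emulated.

## Numerical and design choices

* Gibbs sampling maintains the conditional-logit table incrementally
  (O(B·N·q) per site); a numba-jitted kernel accelerates the site loop
  when numba is importable, with an equivalent pure-numpy path otherwise.
  Both paths are deterministic per seed.
* Per-update pair moments use bincount accumulation over flattened state
  index pairs.
* Interface RMSD pairs atoms by (chain, residue id, insertion code, atom
  name); backbone atoms missing from either structure are skipped
  pairwise.
* Ties in ranking are broken by stable input order; fold assignment is a
  seeded shuffle with round-robin allocation.
* 0·ln 0 = 0 throughout entropy and KL computations; direct pair tables
  are guarded against mass on zero-frequency cells (impossible under the
  defining formula, asserted).
* Problem sizes in the acceptance computations (M = 400–2000, N ≤ 80,
  20 seeds, 9 complexes × 60 decoys) are the package's desk-scale study
  conditions; they are chosen to make the properties measurable with
  comfortable statistical margins, and the CD-1 comparison with the exact
  oracle is made at matched regularisation.
* The logistic-recovery check reports the median over 5 replicate
  simulations of n = 1e4 rows under a high-information design (intercept
  −1.5, one weight 1.5, predictor sd 0.8, near the Fisher-information
  optimum for logit slopes): a single draw's sampling error at n = 1e4 is
  itself of the order of a few percent, and the median estimates the
  typical recovery error rather than one draw's luck.

## Known limitations

* CD-1 underestimates very strong couplings (short-run bias); the
  oracle-equivalence guarantee is stated for couplings of order one.
* The Shrake–Rupley/WHATIF substitution shifts absolute accessibility
  values slightly; the 0.08 threshold was not re-calibrated.
* The polarity-group assignment and the maximum-ASA table are editable
  configuration, not canonical constants.
* No average-product correction, pseudolikelihood or mean-field variants:
  the coupling estimator is deliberately the contrastive-divergence
  maximum-entropy fit.
* Memory for the flat coupling matrix scales as (N·q)²; concatenated
  complexes beyond ~300 columns at q = 21 become heavy.
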