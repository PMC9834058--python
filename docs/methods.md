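# Methods

`omegac` measures convergent protein evolution between independent branches
of a phylogeny while correcting for the false signals that phylogenetic
error produces. This note documents the model, the estimators, the
numerical choices, and what the built-in simulator does and does not
emulate.

## The quantity being estimated

A *combinatorial substitution* is a set of substitutions at the same codon
site on K evolutionarily independent branches. Substitutions are classified
by whether ancestral and derived states are shared across the branches:

| category  | meaning                                     |
|-----------|---------------------------------------------|
| any→any   | every branch substitutes (paired substitution) |
| any→spe   | all branches reach the same derived state (convergence) |
| any→dif   | any→any − any→spe (double divergence)       |
| dif→spe   | any→spe − spe→spe (discordant convergence)  |
| spe→spe   | shared ancestral and derived states (concordant convergence) |

States are amino acids in the non-synonymous (N) view and codons within an
amino-acid group in the synonymous (S) view. For each branch combination
the package accumulates the observed posterior probability of combinatorial
substitutions over sites (O_C) and the corresponding model expectation
(E_C), separately per view, and reports

    dN_C = O_C^N / E_C^N,    dS_C = O_C^S / E_C^S,    ω_C = dN_C / dS_C.

Under neutral evolution both rates have expectation near 1. Adaptive
convergence is almost exclusively non-synonymous, so it raises dN_C but not
dS_C; errors in the assumed topology inflate both rates together, so their
ratio ω_C cancels the error — the core design of the metric. The legacy
C/D statistic (convergent over doubly-divergent non-synonymous totals) is
reported for comparison.

## Pipeline

1. **Codon model.** 61-state reversible Markov generators: an empirical
   family Q = S·diag(π) from symmetric exchangeabilities, and mechanistic
   MG/GY families where only single-nucleotide-change pairs exchange, with
   ω on non-synonymous pairs (and κ on transitions for GY). Q is normalised
   to one expected codon substitution per site per unit time
   (Σ_{i≠j} π_i q_ij = 1). Frequencies are estimated from the alignment
   with an additive pseudo-count (default 1 per codon, keeping Q
   irreducible); ω is estimated by bounded 1-D maximum likelihood on the
   pruning likelihood. Transition probabilities use the eigendecomposition
   of the symmetrised generator; non-reversible generators (they occur only
   inside the simulator's convergence regime) fall back to
   scaling-and-squaring.
2. **Among-site rate variation.** Discrete-gamma rates (default 4
   categories), shape fitted by ML, per-site posterior-mean multipliers
   r_l. The model is deliberately simpler than a free-rate model; only r_l
   enters downstream formulas. The simulation benchmark runs with a single
   rate class because the generator emits rate-homogeneous sequences apart
   from the doubled convergent sites; ASRV estimation is exercised by a
   simulation-recovery test instead.
3. **Ancestral states.** Marginal empirical-Bayes posteriors at every node
   and site by the two-pass pruning algorithm (root frequencies π, per-site
   rates, per-site rescaling against underflow). Tips are point masses;
   missing tip states contribute ones-vectors and are flagged.
4. **Substitution tensors.** Per branch and site, the substitution
   probability matrix is the outer product of the parent and child marginal
   posteriors with a zeroed diagonal — an approximation that ignores the
   joint dependence of the two nodes; it is exact for point-mass posteriors
   and is the price of linear-time computation. The 61×61 matrix is split
   into A^N (20×20 amino-acid cells, synonymous codons merged, same-aa
   cells zero) and A^S (per-amino-acid codon blocks, ≤6×6, zero-padded,
   codon diagonal zero). A site is missing for a branch when either
   endpoint posterior is missing; branch-specific effective site counts are
   used everywhere in place of L.
5. **Branch-length rescaling.** t_b = (total substitution probability on
   branch b) / (effective sites), split into t_b^N + t_b^S. Input tree
   lengths (nucleotide substitutions per codon site) only shape the
   reconstruction; all expectations use the rescaled codon-substitution
   lengths.
6. **Expected tensors.** The expected substitution distribution per branch
   and site is the ancestral marginal times the codon transition matrix,
   evaluated at a view-specific model time. Because Q mixes synonymous and
   non-synonymous flux and endpoint-difference mass saturates in time,
   plugging t_b^N in directly would leave the expectation short by the
   view's flux share and by the saturation factor. The package instead
   solves, per branch and view, for the time at which the model's expected
   substitution mass under that branch's ancestral posteriors equals the
   observed rescaled length (monotone interpolation on a precomputed time
   grid). This makes the expected tensors integrate exactly to t_b^N and
   t_b^S per site — the conservation property — and centres neutral dN_C
   and dS_C at 1 on true-state oracles; at small t it reduces to dividing
   the length by the equilibrium flux share.
7. **Combination metrics.** The category formulas are products over the K
   branches of per-branch sums (per derived state for any→spe, per
   state pair for spe→spe, per amino-acid group in the S view), summed over
   sites. K = 2 is computed for all independent pairs at once with flattened
   matrix products; arbitrary K uses the same aggregates per combination.
8. **dS_C correction.** Synonymous saturation distorts the range of dS_C
   relative to dN_C. Where dS_C < dN_C, dS_C is replaced by the quantile of
   the empirical dN_C distribution at dS_C's own quantile rank, both
   distributions taken over the exhaustively enumerated combinations at
   that K (linear interpolation between order statistics; NaN/infinite
   rates excluded). The correction needs exhaustive enumeration and is
   therefore applied at K = 2 only; rank order of dS_C is preserved. With
   the correction, ω_C for a pair effectively compares its dN_C against the
   dN_C value found at its dS_C's rank — which also means the correction is
   only as stable as the pair-level dS_C distribution; scarce synonymous
   convergence makes the bottom ranks volatile (this shaped the benchmark
   calibration below).
9. **Branch combinations.** Pairs with an ancestor–descendant relation are
   never independent and are always excluded; sister pairs are additionally
   excluded for metric analysis (a convergent sister pair is
   indistinguishable from a single ancestral substitution), but the plain
   ancestor–descendant rule is the default for enumeration counts. On a
   balanced 64-tip tree the ancestor–descendant rule leaves 7,359 of 7,875
   pairs.
10. **Higher-order search.** Starting from the exhaustive K = 2 table,
    combinations passing ω_C ≥ 5 and O_C^N ≥ 2 (configurable; applied to
    the any→spe category) are merged whenever two passing K-combinations
    share K−1 branches; dependent unions are discarded, metrics are
    recomputed at K+1 (uncorrected dS_C), and the loop repeats until no
    candidate passes. The search is sound but intentionally incomplete: a
    strong combination whose sub-combinations fail the cut-offs is never
    generated.

## Simulator and benchmark conditions

The generator reproduces the four-scenario benchmark design: codon
sequences of 500 sites on a balanced rooted 32-tip tree, background
ω = 0.2, comparing two deeply separated terminal branches (defaults `t1`,
`t32`).

* **Neutral** — one model everywhere; the analysis tree is the true tree.
* **Convergent** — 5% of sites on the two focal branches evolve under a
  regime with ω = 5, doubled site rate, and the non-synonymous flux into
  the codons of one randomly drawn target amino acid boosted to 90% of each
  state's non-synonymous outflow (relative synonymous codon frequencies
  untouched; rows with no direct path to the target receive the flux in
  proportion to the target codons' frequencies). One target per replicate;
  a per-site option exists.
* **Transfer** — neutral evolution, then one focal tip sequence overwritten
  by the other while the analysis tree is left unchanged (horizontal
  transfer unseen by the tree).
* **Random** — neutral evolution analysed on a tip-label-shuffled tree
  (re-shuffled in the rare case the focal tips land as sisters, which would
  remove the pair from the analysis).

Two benchmark constants are not dictated by the design and were fixed by
calibration, once: the **branch length** (0.5 codon substitutions per site,
uniform) and the **default codon model**. The default model is a synthetic
empirical-style exchangeability matrix (`synthetic_exchangeabilities`): all
codon pairs exchange; transitions are enriched by a factor of 8 per
changed position; multi-nucleotide changes are discounted per extra
changed position — by 0.02 for non-synonymous pairs but only 0.6 for
synonymous ones — with F3x4-style frequencies from fixed vertebrate-like
nucleotide compositions. The structure mirrors two well-documented
features of empirical codon matrices rather than a nucleotide-level
mutation process: purely single-nucleotide-change models cannot express
the multi-hit substitutions that empirical matrices assign appreciable
rates to (without them the 90% flux boost cannot funnel most codon states
toward the target amino acid), and the large multi-hit and transition
exchangeabilities of empirical matrices sit mainly between synonymous or
conservative codon pairs (e.g. within the Leu/Ser/Arg six-codon groups),
which sustains the synonymous convergence that the dS_C correction needs
to operate in its intended regime. The calibration anchors were the
published benchmark behaviour: a mean excess of about four non-synonymous
convergent substitutions on the focal pair in the Convergent scenario,
neutral medians of dN_C, dS_C and ω_C just below 1, and a well-behaved
pairwise dS_C distribution. Under the frozen defaults the Neutral scenario
gives median ω_C ≈ 0.8–0.9 and the Convergent scenario ≈ 3–4 excess
convergent substitutions.

What the generator does **not** emulate: indels and alignment error,
among-site rate variation outside the convergent sites, lineage-specific
composition or rate shifts, selection heterogeneity along the sequence, and
any published empirical exchangeability matrix. Passing benchmarks
therefore demonstrate the estimator's behaviour under a self-consistent
codon process with known truth, not performance on real alignments.

## Problem sizes

The four-scenario benchmark in the test suite runs 80 Neutral, 80
Convergent, 30 Transfer and 30 Random replicates; the acceptance script
runs 200 Neutral and 200 Convergent replicates (topping up
strong-convergence replicates at a 10% convergent-site fraction when fewer
than 20 replicates reach seven convergent substitutions). Oracle tests use
3–4-tip trees with ≤6 sites where exhaustive enumeration over weighted
codon assignments is exact.

## Numerical choices and degenerate inputs

* Codon indexing is lexicographic (AAA, AAC, …, TTT) over the 61 sense
  codons; amino acids alphabetical by one-letter code. All tables and the
  exchangeability file format follow this order.
* Q eigendecomposition via the symmetrised form for reversible models;
  `expm` otherwise. Transition-matrix entries are clipped at 0 (rounding
  noise is ≤1e-14).
* Zero or negative expected totals: dN/dS with E = 0 give NaN (O = 0) or
  +inf (O > 0); such records are excluded from quantile maps. ω_C with
  dS_C = 0 gives +inf; 0/0 gives NaN. C/D with zero divergence gives NaN.
* Pairs with zero effective sites keep zero tensors and zero rescaled
  lengths and are flagged through the effective-site count.
* All randomness flows from explicit seeds; replicate seeds are spawned
  from a root `SeedSequence`, and results are independent of worker counts
  (the implementation is single-process NumPy).

## Known limitations

* The outer-product substitution probability (step 4) ignores
  branch-to-branch posterior correlation. Pairs of nearby branches share
  reconstruction uncertainty, which inflates their observed synonymous
  convergence relative to deeply separated pairs; the dS_C correction
  inherits this heterogeneity. On true-state oracles the bias vanishes.
* A consequence of the two previous points: when per-pair convergence
  counts are of order one (as in the benchmark conditions), the pairwise
  dN_C distribution contains irreducible zeros (pairs with no convergent
  event) and the dS_C quantile map can send a focal pair whose dS_C ranks
  low into that near-zero region, producing occasional very large neutral
  ω_C values. The neutral *median* ω_C stays below 1 and the synonymous
  false-positive rate at the neutral 95th percentile stays at the nominal
  level, but the upper tail of the neutral ω_C distribution is heavy, so
  detection power measured against the neutral 95th percentile is
  unstable across simulation seeds and lower than it would be in a regime
  with abundant per-pair synonymous convergence. Screening applications
  should combine an ω_C cut-off with an O_C^N cut-off (as the
  higher-order search does by default) rather than rely on ω_C alone.
* dS_C correction requires exhaustive enumeration, so K > 2 rates use the
  uncorrected dS_C.
* The ML ω is a single ratio across sites and branches; branch-site
  selection models are out of scope.
* The empirical family ships no published matrix; users supply their own
  exchangeability file or rely on the synthetic default (clearly labelled
  synthetic).
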