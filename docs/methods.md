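# Methods

## Model and fitting procedure

The object of study is a two-layer signed causal network: backbone nodes
(unmeasured biological activities) joined by signed directed causal edges,
and measured genes attached to backbone nodes by signed evidence edges. A
contrast supplies per-gene log2 fold changes β (treated minus control) with
estimated variances.

Differential backbone values are defined as the minimizer of the energy

    E(f) = Σ_{(x,y,s) ∈ E_bb} (f_x − s·f_y)² + Σ_{(b,g,s) ∈ E_ev} (β_g − s·f_b)²,

i.e., the smoothest signed-graph extension of the gene data onto the
backbone, with the gene values held fixed as a Dirichlet boundary
condition. All edge weights are 1, and each directed edge contributes one
symmetric residual; edge direction is retained in the data model for
provenance but does not weight the energy. Stationarity gives the linear
system L₃f = −L₂β, where L₃ = K + D (K the signed backbone Laplacian, D the
diagonal of per-node evidence-edge counts) and L₂ holds −s for each
evidence edge. L₃ is positive definite exactly when every backbone
connected component carries at least one measured evidence edge; this is
what `validate_network` checks, and what makes the "identifiable component"
diagnosis meaningful. The fit is the linear map f = Mβ, M = −L₃⁻¹L₂,
computed by a dense symmetric solve (networks of interest have tens to
hundreds of backbone nodes; sparsity brings nothing at that scale).

Genes present in the contrast but absent from the network are ignored (the
network defines the scope of the analysis). Network genes missing from the
contrast drop their evidence edges with a warning; if that leaves a
component without evidence, the fit refuses with an error naming the
component rather than silently pseudo-inverting.

## The NPA score

The whole-network amplitude is the edge-averaged signed Dirichlet energy of
the fitted values, optionally with a ridge term:

    NPA(f) = (1/|E_bb|) Σ_{(x,y,s)} (f_x − s·f_y)² + α·(1/|V_bb|) Σ_v f_v².

With the default α = 0 this is a semi-norm: it is zero precisely when the
fitted values are sign-consistent along every backbone edge, and it scales
quadratically with the signal (NPA(cβ) = c²·NPA(β)). The |E_bb|
normalization makes scores comparable across network sizes. The score is a
quadratic form f'Qf = β'Aβ with Q = K/|E_bb| + (α/|V_bb|)·I and A = M'QM.

Useful structural facts, all asserted as tests: non-negativity; degree-2
homogeneity; zero input → zero output; and gauge invariance — flipping the
sign of every edge incident to one backbone node negates that node's
fitted value and changes neither the energy nor the score (the score
depends on sign-consistency classes, not on an arbitrary orientation of
"activity up").

## Uncertainty

Treating β as Normal(β̂, Σ) with Σ = diag(var_log2fc), per-node variances
are diag(MΣM'), and the score variance uses the exact first two moments of
a Gaussian quadratic form,

    Var(NPA) ≈ 4·β̂'AΣAβ̂ + 2·tr((AΣ)²),

from which a central-limit-theorem interval score ± z·sd is built (exact
Normal quantile for the requested level, lower bound truncated at 0, since
the amplitude is non-negative). The linear term dominates for clear
signals; near the null the quadratic form is skewed and the symmetric
interval is approximate — the Monte-Carlo comparison in the test suite
bounds the discrepancy (endpoints within 15% of the resampled percentile
interval on the toy network), and empirical coverage of the noiseless-
boundary NPA is 92–96% at nominal 95% over 500 simulated triplicate
datasets. The score estimator carries a positive bias tr(AΣ); at the noise
levels of interest it is small relative to the CI width and is not
corrected for.

## Permutation tests

Both tests recompute fit + score per permutation and use the
(k+1)/(n+1) counting rule (one-sided on score magnitude; p never 0). Ties
are counted as "at least as extreme" up to a 1e−9 relative tolerance so
that energy-equivalent permutations compare equal despite differing solve
paths.

**\*O (evidence specificity).** The assignment of measured fold-change
values to gene labels is shuffled uniformly across the full contrast
vector; when the contrast covers exactly the network genes this reduces to
shuffling within the network. Since the fit map M is fixed under this
null, permuted scores are computed exactly through M. Degenerate inputs
(fewer than two distinct fold-change values) warn and return p = 1.

**K\* (backbone wiring contribution).** The backbone edge list is redrawn:
endpoints sampled uniformly among distinct ordered backbone pairs (no
self-loops, no duplicate source→target), and the original multiset of edge
signs permuted, preserving sign frequencies exactly; the evidence layer is
untouched. Rewirings that strand a component away from all evidence are
solved in the minimum-norm least-squares sense. Graphs with a single
energy-distinct configuration (e.g., two backbone nodes and one edge,
where both orientations give the same energy) warn and return p = 1.

A deliberate consequence of the synthetic-data design: the generator draws
true backbone activities independently of the backbone wiring, which makes
the observed wiring exchangeable with its rewirings — K\* is then a true
null even for strong signals, and its p-values are uniform-to-conservative
on generated data. K\* gains power exactly when the perturbation is
structured with respect to the wiring (demonstrated in the tests with a
perturbation along the top eigenvector of the signed Laplacian, where
p ≤ 0.05 throughout). Passing tests therefore show calibration and
wiring-sensitivity, not that K\* flags every simulated signal; on curated
networks, where evidence aggregation follows the biology of the wiring,
the test addresses a real question.

**Verdict.** Significant ⇔ CI lower bound > 0; specific ⇔ both p-values
< 0.05 (the α level is a parameter). The three-way verdict encodes both.

## Profile comparison and negative control

Two backbone profiles are compared on the intersection of their node sets
(≥ 3 nodes): Pearson r with t-based p, Spearman ρ on average ranks with the
t approximation, least-squares regression of the second profile on the
first (direction fixed and documented), and R² = r². The reported
correlation p-values carry a caveat: backbone values share the network
smoothing and are not independent draws. The honest null is the
**negative control**: gene labels are permuted independently for each
comparison group (decorrelating the two contrasts), profiles refitted
through the linear maps, and a two-sided p computed from
(#{|r_perm| ≥ |r_obs|} + 1)/(n_perm + 1). `compare_contrasts` additionally
reports the same statistics on the shared measured genes, so
functional-layer vs transcriptional-layer comparisons are available for
any pair of inputs; if the gene layers share nothing the gene-level result
degrades to None with a warning while the backbone result survives.

## Synthetic data

The generator emulates the target study design: a connected signed
backbone graph (directed Erdős–Rényi over unordered pairs at
`backbone_edge_prob`, patched to connectivity with spanning edges, signs
negative with probability `negative_sign_prob`), each gene attached to one
guaranteed regulator plus Poisson(`extra_parent_rate`) extras, each
backbone node anchored by at least one gene — so generated networks are
identifiable by construction. A gene's expected log2 fold change is the
*mean* of its regulators' signed activities, matching the least-squares
geometry of the fit so the noiseless contrast equals the signed truth
exactly. Expression is two-group with i.i.d. Gaussian log2 noise;
per-gene baselines ~ Normal(7, 1) (microarray-like levels) cancel in the
contrast. The all-zero truth vector is the null condition.

Reference parameters, used as defaults and throughout the tests: 10
backbone nodes, 200 genes (≈ 20 per backbone node), standard-normal true
activities, log2 noise sd 0.1, 3 replicates per group — a typical
triplicate exposed-vs-control design at microarray-like noise. Under these
conditions the fitted backbone values correlate with the truth at r > 0.99
(median r ≈ 0.93 even at noise sd 2.0), the *O test has type-I error
0.02–0.09 at nominal 0.05 and full power at noise sd 0.05, and the
negative control is calibrated under the null and reaches p ≤ 0.001 for
shared signals. Problem sizes in the test suite (200 replicates for
calibration, 500 datasets for coverage, 100 networks for the solver
oracle, permutation depths 200–1000) were chosen to make those Monte-Carlo
estimates stable at a few-percent resolution.

What the simulations do **not** emulate: probe-level artifacts,
normalization residue, batch/plate effects, variance heterogeneity across
genes, correlated noise, or dose-response kinetics. Passing tests
demonstrate correctness of the algorithms and calibration under the stated
generative model, not performance on raw microarray data — real inputs
should arrive as properly preprocessed contrasts.

A fixed 12-backbone / 150-gene "toy xenobiotic" network (a receptor-like
hub, a repressor node attached by negative edges, phase I/II/III activity
nodes) is generated deterministically in code and used for docs and golden
tests. It mimics the *shape* of a curated xenobiotic-response model, not
its content.

## Numerical and design choices

* Dense `scipy.linalg.solve(assume_a="pos")` for L₃; minimum-norm `lstsq`
  fallback only inside the K\* null, where rewiring may disconnect
  evidence.
* Solver verified against an independent residual-matrix QR/lstsq oracle
  (max |Δ| ~ 1e−15 over 100 random networks) and numeric minimization.
* Exact Normal quantiles everywhere (no hard-coded 1.96).
* Relation vocabulary is exactly the four BEL tokens; unknown tokens are
  errors, never guesses. Consistent duplicate edges collapse with a
  warning; sign contradictions are hard errors (they would make E
  ill-posed). Node identifiers are case-sensitive exact strings; any
  gene-symbol mapping is the caller's concern.
* The two-group contrast is a plain pooled-variance t with
  Benjamini-Hochberg adjustment; moderated (shrinkage) models are out of
  scope because the scoring layer consumes only (log2fc, variance).
  `var_log2fc` is a variance, not a standard error.
* Result JSON embeds the run configuration (paths, n_perm, seed, α, level,
  tool version) but no timestamps, so same-seed runs are byte-identical;
  timestamps go to the stderr log. Outputs are written atomically.

## Known limitations

* The CI is a two-moment Gaussian approximation; for near-null scores it
  is conservative at the truncated lower bound and its upper tail
  understates the quadratic-form skew.
* The α = 0 score is blind to perturbations that are perfectly
  sign-consistent along the backbone (the semi-norm's kernel); the ridge
  term α > 0 restores sensitivity at the cost of mixing in magnitude.
* Correlation p-values between profiles ignore the dependence induced by
  smoothing; use the negative control for inference.
* K\* power depends on the perturbation being structured relative to the
  wiring; it cannot be demonstrated with wiring-independent synthetic
  truths (see above).
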