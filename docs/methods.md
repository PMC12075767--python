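# Methods

## The model

The quantity modeled is per-orthogroup expression of one tissue on the
log₂(TPM + 1) scale. Along a rooted ultrametric species tree, expression
evolves by Gaussian Brownian motion whose instantaneous variance depends on
a per-branch *rate class*: over a branch `b` of length `t_b` in class `c`,
the trait accumulates variance `σ²_c · t_b`. For tips `i, j` the implied
covariance is the rate-weighted length of their shared root path,
`C[i,j] = Σ_{b ∈ path(i) ∩ path(j)} σ²_class(b) · t_b`.

The root state is a per-orthogroup nuisance parameter profiled at its
maximum-likelihood (equivalently GLS) value `μ̂ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)`. The
resulting profiled log-likelihood is evaluated by Felsenstein's post-order
pruning — contrasts between sibling messages plus a final
`−½ log(2π v_root)` root term — which is exact Gaussian elimination and
equals the dense multivariate-normal expression above (this equivalence is a
test invariant at |Δ| < 1e-8). Pruning is vectorized across orthogroups that
share a missingness pattern: branch variances do not depend on the data, so
one variance pass serves all orthogroups at once, making likelihood
evaluations on 2,000 orthogroups sub-millisecond.

One σ² per class is shared by all orthogroups of a tissue; the fitted model
reports the σ² vector and the summed −ln L. Candidate models are compared by
raw −ln L (lowest wins, ties broken toward fewer classes); AIC is reported
as supplementary output only, mirroring how such model tables are
conventionally printed for this analysis.

### Fitting

The single-rate MLE has a closed form: with all branch variances scaled by a
common `s`, the log-likelihood is `A − (M/2)·ln s − Q/(2s)` with `M` the
total number of Gaussian terms and `Q` the quadratic sum at `s = 1`, so
`ŝ = Q/M` (two likelihood evaluations identify `Q` exactly). Multi-class
fits run L-BFGS-B on log σ² (bounds `[ln 1e-9, ln 1e9]`, ftol 1e-8) from
five deterministic starts centered on the shared-rate solution with
alternating ± log-offsets. Orthogroups with fewer than three scored species
are excluded; missing species prune the tree per orthogroup, with merged
branches represented as per-class time vectors so a collapsed unifurcation
retains each segment's rate class.

### A known ML pathology, and how it is handled

Profiled-root ML is *unbounded* for some branch-class assignments: if a
subset `S` of classes covers **exactly one** tip's entire root path, sending
`σ²_S → 0` collapses that tip's marginal variance while the free per-OG root
absorbs its residual, so the density diverges. (If two or more tips collapse
they are forced to coincide, which distinct data penalize infinitely — that
direction is safe; clade-structured assignments are safe for this reason.)
Assignments with such a direction have no ML fit at all: `random_assignment`
redraws them (the check enumerates class subsets and counts fully covered
tips) and model construction refuses them with an explanatory error. Both
rejection rules are symmetric in class labels, so per-branch class
frequencies of the random model remain uniform. Without this guard the
"random rates" reference model intermittently reports absurdly good −ln L
driven purely by the divergence.

A related, milder effect of profiling the root: the one lost degree of
freedom lands mostly on the deep background branches, so on a 12-tip tree
the *background* class rate is biased low by roughly `1/n_effective`
(~10%), while clade rates estimated mostly from within-clade contrasts (the
venomous-clade rate in all recovery experiments) are recovered within ~1%
at 2,000 orthogroups. ML rather than REML is used deliberately — it is the
estimator whose closed forms (`σ̂² = Σ(xᵢ−μ̂)²/(n·tᵢ)` on two tips) anchor
the oracle tests.

### Ancestral states, node changes, ancestral specificity

Marginal reconstructions use two-pass Gaussian belief propagation with a
flat root prior: a post-order pass of below-messages, a pre-order pass of
above-messages, and a precision-weighted combination at each node. With the
flat prior this equals the GLS/BLUP estimator (universal-kriging mean),
verified against dense linear algebra on small trees; tip reconstructions
equal the observations with variance 0, and the reported node variance
includes the root-mean uncertainty term.

Node-level change counts compare each internal node's reconstruction with
its parent's along the connecting branch (root excluded); the change
threshold ε defaults to 0 (any sign change counts) because no magnitude
convention is imposed, and is exposed as a parameter. Ancestral tissue
specificity back-transforms reconstructions to TPM (`2^x − 1`, clipped at 0)
and applies the same top-tissue/fold-change rule as for extant species;
nodes with fewer than two reconstructed tissues are skipped with a log
entry.

### The bounded variant

The bounded model discretizes expression onto a uniform grid over
`[lo, hi]` with reflecting (Neumann) boundaries. The diffusion generator's
eigenbasis on such a grid is the DCT cosine basis, so each branch transition
`exp(σ²t/2 · Δ)` is formed by one eigendecomposition reused across
branches. Tip observations become two-cell linearly interpolated masses
(keeping discretization error O(dx²)); the root is profiled by maximizing
over grid cells; cell masses are converted to densities (one `dx` per tip)
so the value is directly comparable to the Gaussian log-likelihood, to which
it converges as the bounds widen (|Δ| ≈ 4e-5 at ±10 SD with dx = 0.02 on the
4-tip reference example; a property test asserts |Δ| < 0.01 and improvement
over narrow bounds). The Gaussian core is the contract used everywhere else;
the bounded variant documents and tests the limit relationship.

## Tissue specificity and cross-species sets

Per species, tissue profiles are arithmetic means of replicate TPM (median
selectable); tissues without samples are absent, never zero-filled. A gene
is specific to its top tissue when top mean ≥ `tpm_min` (default 2) and
FC = top/second ≥ `fc_min` (default 2); a zero second mean with an expressed
top gives FC = +∞ (specific); an exact tie gives FC = 1 (unassigned) since
the rule requires strict dominance. Group comparisons of set sizes use
one-sided two-sample t-tests, Welch by default with the pooled variant
selectable — published df values for such comparisons are consistent with
either flavor depending on the comparison, so both are exposed. The
"expressed" threshold for secretome counts is mean TPM ≥ 1, exposed as a
parameter.

Gene-level calls lift to orthogroups by species votes (a species votes for
a tissue when any member gene is specific there; intra-species conflicts
are logged and each vote kept), and an OG joins a tissue's cross-species
set with ≥ `min_species` (default 2) supporting species. The random
representative for the OG matrix is drawn from the lexicographically sorted
member list by a generator keyed on (seed, og, species) via SHA-256, so the
choice is reproducible and independent of input file order.

## Similarity

Correlations between (species, tissue) columns of the complete-OG matrix
use log₂(TPM + 1) for Pearson (raw selectable; ranks are unaffected for
Spearman); zero-variance columns yield missing correlations, never 0.
Distances are `1 − ρ`. The expression tree is classic Saitou–Nei neighbor
joining with deterministic tie-breaking by the joined subtrees' smallest
leaf labels; a negative branch length is clamped to 0 with the deficit
moved to its sibling so path distances are preserved. On exactly additive
matrices NJ provably recovers every split (tested on random trees, and
cross-checked against an independent NJ implementation).

## The synthetic generator

The generator is the exact statistical inverse of the analysis. Per
orthogroup, one baseline BM realization (root ~ N(root_mean, root_sd²),
branch-class rates) is shared by all tissues; tissue structure enters only
through planted offsets: tissue-specific orthogroups gain
`specific_effect` (default +3 log₂) in their target tissue, and
lineage-restricted `Shift`s add a signed delta to a clade's nodes in one
tissue (emulating ancestral gain/loss at the node joining the venomous
clade and the glandless lineage). Replicates add N(0, replicate_noise_sd²)
on the log scale (multiplicative on TPM, matching how replicate spread
behaves); TPM = 2^x − 1 clipped at 0. A configurable fraction of
orthogroups carries a second, correlated paralog per species.

One design point was genuinely open: fully independent per-tissue BM
realizations would make every between-tissue profile diverge, so the
fold-change rule would fire on a large fraction of unplanted genes and
planted sets could never be recovered with precision 1. The shared-baseline
design makes the planted sets the *only* specificity signal, which is what
lets recovery be measured exactly; the cost is that the generator does not
emulate incidental between-tissue divergence (nor species batch effects,
library-size artifacts, count noise at low TPM, or paralog tree structure).
Passing recovery tests therefore certify the inference machinery against
its own generative assumptions, not robustness to those real-data features.

Default study shape: 12 species on the fixed topology (four-species
venomous clade sister to the glandless lineage; five gland-of-Leiblein
species; two outgroups), unit depth with equal node-level spacing (the
source phylogeny's branch lengths are not published), three tissues, three
replicates, 2,588 orthogroups, root mean 5 and SD 2 on the log₂ scale
(median background TPM ≈ 30), replicate noise SD 0.25, 4% of orthogroups
specific per tissue, half of orthogroups multi-member, 15% of genes flagged
secreted. Recovery experiments in the tests and the acceptance script use
2,000 orthogroups — large enough that Monte-Carlo error on a recovered rate
is ~1–2%, small enough that the whole suite runs in well under a minute of
fitting time.

## Numerical choices and degenerate inputs

* Ultrametricity is enforced at relative tolerance 1e-6, reporting the
  worst tip pair; trees with all-zero branch lengths are rejected.
* Specificity with a single tissue raises (FC undefined); empty call sets
  count to an empty mapping; secretome summaries with no secreted genes
  report 0 with a warning flag.
* Orthogroups missing a member in any included species are excluded from
  the matrix with a log entry; singleton orthogroups reproduce the
  gene-level profiles exactly under either representative method.
* NJ requires ≥ 4 finite-distance labels; equal all-pairs distances resolve
  arbitrarily with zero internal branches.
* Optimizer convergence |Δ −lnL| < 1e-8; rates bounded in [1e-9, 1e9];
  degenerate (unbounded-likelihood) class assignments rejected as above.

## Limitations

Rates are shared across orthogroups within a tissue (no per-OG rates), the
tree is fixed and single (no phylogenetic uncertainty), the random-model
row is a single seeded draw by default, and Ornstein–Uhlenbeck or trend
models are out of scope. σ² estimates are scale-dependent (log₂(TPM+1) by
default; raw selectable) and are comparable only across fits on the same
scale. Cross-species batch correction is assumed done upstream; the
generator produces batch-free data and the matrix builder accepts an
externally corrected matrix.
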