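# Methods

This note records the models, parameter choices and numerical decisions
behind `foldprobe`, and what the synthetic validation does and does not
demonstrate.

## Problem setting and assumptions

The planner receives a set *M* of candidate 3-D models of one target
protein.  Models may be redundant (several can share a fold) and
incomplete (no model may have the correct fold).  The working
representation of "fold" is deliberately coarse: the binary contact
pattern over pairs of secondary-structure elements (SSEs) common to the
ensemble.  Coarseness is the point — SSE-level contacts are robust to
the threading misalignments and backbone flexibility that corrupt
residue-level comparisons, and the space of fold values is small enough
to enumerate, which is what makes an explicit none-of-the-above test
possible.

Two assumptions are inherited from that representation.  First, the
models must agree roughly on the SSE complement; SSEs are matched across
models by kind and residue-interval overlap (Jaccard ≥ 0.5 against the
growing cluster consensus, greedy, at most one annotation per model per
cluster), and only clusters present in ≥ 50 % of models enter the common
set.  Second, SSE contact states are treated as conditionally
independent given the model, which is what lets fold likelihoods factor
over fingerprint pairs.

## Geometry

All distances are Cβ–Cβ.  Glycine (and any residue lacking a Cβ record)
gets a virtual Cβ constructed from N/Cα/C with ideal tetrahedral
geometry (bond 1.53 Å, both bond angles 109.5°, L-chirality); this keeps
every distance criterion uniform across residue types.  The construction
is rotation/translation-equivariant and agrees with the common
fixed-coefficient reconstruction to within ~2°.

SSE annotations come, in order of preference, from a user-supplied
sidecar file, from HELIX/SHEET records, or from a built-in Cα-geometry
assigner using distance windows on |Cα_i − Cα_{i+k}| for k = 2, 3, 4
(helix: 5.5 ± 0.5, 5.3 ± 0.5, 6.4 ± 0.6 Å; strand: 6.7 ± 0.6, 9.9 ± 0.9,
12.4 ± 1.1 Å).  At least two consecutive qualifying positions are
required (a lone hit is treated as noise) and segments shorter than 4
(helix) / 3 (strand) residues are discarded.  The user-supplied route is
preferred because predicted secondary structure is the natural input for
this problem; the internal assigner exists so that bare coordinate files
remain usable.

## Stage 1: fingerprint selection

An SSE pair is in contact in a model when at least `min_contacts` = 5
residue pairs sit strictly closer than `contact_distance` = 9 Å and at
least `min_residue_fraction` = 20 % of *each* SSE's residues have a
partner in the other (the two-sided reading is the conservative
resolution of an ambiguous rule).  A model lacking its own matched
annotation for a common SSE uses the consensus interval, so every model
exposes a state for every pair — the frequency counts require a shared
universe.

Contact probabilities are softened by the agreement weight *q*:
Pr(*c* = x) = (1/|M|) Σ_i Q(x, y_i) with Q(x, y) = q if x = y else
1 − q, and joints carry the product Q(x, y_i) Q(x′, y′_i).  The default
q = 0.8 sits mid-range of the values under which plan rankings were
observed to be insensitive (0.7–0.9); it encodes the expectation —
borne out by the stage-2 Bayes errors — that a planned cross-link set
decides an SSE contact with well under 10 % error.  One consequence
worth noting: with q < 1 two *distinct* pairs are never fully redundant
even when their states coincide in every model, because their
experimental readouts are independent; the self-information I(c, c) is
nevertheless H(c) exactly.

Entropies and mutual informations are in bits; the greedy mRMR step adds
the pair maximizing H(c) − mean I(c, selected) (pure entropy first,
lexicographic tie-break) and stops below `stop_threshold` = 0.01 bits,
interpreted on the raw incremental difference.

### Plan assessment

ε, τ and ν are computed by exhaustive enumeration over the 2^|F|
outcome vectors (refused above |F| = 20).  Decisions are
maximum-likelihood with uniform model priors.  Per assumed-true model
and dataset: if two or more models attain the maximum likelihood the
dataset is a tie (τ); otherwise a unique winner whose fold signature
differs from the assumed model's is an error (ε).  Ties carry zero
error, which is why ε can *rise* while τ collapses as the fingerprint
grows — errors only become possible once decisions do.  Tie counting is
model-level (two same-fold models tying is still a tie): this matches
the interpretation rule, which returns the tied-for-optimal model set,
and makes τ flat-line at the mass of duplicated folds.  ν enumerates
datasets with no prior on X and uniform treatment of uncovered folds;
with strict-inequality comparisons it equals the uncovered fraction of
fold space, zero exactly while the models' signatures span all 2^|F|
values.

Two empirical caveats found while validating the trends: τ is not
monotone along arbitrary greedy trajectories (Hamming-parity effects can
raise it even after all signatures are distinct); it decreases
monotonically in the regime the trend describes, where each added pair
separates previously tied folds.  Similarly the stage-2 Bayes error is
not monotone in plan size with a fixed decision midpoint: past ~2·k₀
links the background false-positive channel P(Binomial(n, p_far) > k₀)
grows slowly, giving a shallow U-shape with its floor near the default
plan size.

## Stage 2: cross-link planning

Candidates for an SSE pair are residue pairs drawn from residues lying
in the matched interval in ≥ half the models possessing the SSE, with
Cβ–Cβ ≤ 19 Å (the cross-linkable window) in at least one model.  Link
formation probability is tiered: 0.95 (≤ 9 Å), 0.5 (9–19 Å), 0.05
(> 19 Å); boundaries are inclusive downward.

**Misalignment.** Each SSE of the pair carries an independent register
offset δ with Pr(0) = 0.5 and exponentially decaying tails (decay 1.0)
up to `delta_max` = 2; probing residue r under offset δ reads the
geometry of r + δ, and probes shifted out of the structure fall to the
far tier.

**Flexibility.** Alternative backbones are sampled along the lowest
non-rigid eigenmode of a Cα anisotropic elastic network (unit springs,
10 Å cutoff, mass-free Hessian).  The mode is scaled to 1 Å maximum
per-residue displacement and sampled at 5 amplitudes spanning ±3 Å, each
residue's Cβ displaced rigidly with its Cα.  Weights follow the Hookean
energy, Pr(b) ∝ exp(−λa²/2kT), with kT set so the extreme sample has
5 % of the centre's weight.  Networks without exactly six near-zero
modes (tiny or disconnected chains) fall back to the unperturbed
structure with a warning.

Links are conditionally independent given (model, δ_a, δ_b, backbone),
so all joints marginalize products of per-link conditionals over those
shared latent variables, models in the contact class weighted uniformly.
Relevance I(ℓ, c) uses the stage-1 Pr(c) (uniform on request); under
c = 0 every link forms at the background rate p_far = 0.05, and an
empty contact class falls back to the near tier for c = 1.  Selection
is greedy mRMR to a fixed `plan_size` = 10.

Interpretation is a logistic likelihood in the detected count k,
Pr(Y | c = 1) = 1/(1 + e^{−s(k − k₀)}) with k₀ = 3 and s = ln(19)/k₀,
which pins 0.05 / 0.5 / 0.95 at k = 0 / 3 / 6; Pr(Y | c = 0) is the
mirrored curve, so the decision reduces to k > k₀, with the tie at
k = k₀ resolved conservatively to "not in contact" and flagged.  The
plan's Bayes error enumerates all 2^|L| outcome vectors with uniform
Pr(c): the c = 1 generative law is the noise-marginalized mixture, the
c = 0 law the independent background rate.

## Synthetic fixtures

The generator emulates what matters about fold-recognition ensembles
for this method and nothing more: a shared SSE complement (ideal
helices, 1.5 Å rise / 100° per residue / 2.3 Å radius, or ideal 3.3 Å
strands with alternating Cβ pleat) placed on a linear slot layout 10 Å
apart, so that adjacent SSEs are unambiguously in contact and
non-adjacent ones are not; alternative packing topologies as
permutations of SSEs over slots with pairwise-distinct adjacency sets;
per-model boundary jitter (clamped at residue 1), whole-SSE register
offsets, and Gaussian coordinate noise.  SSE intervals are separated by
4-residue numbering gaps with no loop residues modeled.  The ground
truth is an unperturbed build of a chosen variant, optionally excluded
from the ensemble to exercise none-of-the-above.

What passing tests on these fixtures shows: the estimators, the greedy
searches, the enumeration formulas and the end-to-end decision logic
are correct, and the method behaves as designed under controlled
misalignment and flexibility.  What they do not show: performance on
real fold-recognition ensembles, whose SSE annotation errors, partial
models, loop mediated contacts and correlated threading errors are
outside the generator's vocabulary.

Simulated outcomes use the strict disulfide criterion Cβ–Cβ < 9 Å in
the truth — deliberately tighter than the 19 Å planning window, so
mid-range planned links legitimately come back negative.  Fold labels
compare full-universe signatures at a sweep of residue-fraction
thresholds r (default 0.05–0.2); models are ranked by fold likelihood
for the ROC, positives being same-fold-as-truth models, and degenerate
label sets report AUC as undefined rather than 0 or 1.

## Problem sizes and determinism

Validation workloads are sized for interactive use: enumeration-based
metrics are exercised at |F| ≤ 6 and |L| ≤ 10 (the enumeration cap is
20), Monte-Carlo cross-checks use 10⁵ draws at three standard errors,
and the end-to-end recovery study runs 200 seeded replicates of
20-model, 2–3-variant noiseless fixtures with degenerate interpretation
noise (δmax = 0, single backbone) — the full noise model is exercised
separately on single-pair plans.  Every stochastic path draws from a
`numpy` generator seeded explicitly; identical seeds give bit-identical
ensembles, plans and reports.

## Known limitations

* Contact universes, not residue maps: no GDT/TM-score style
  comparisons, by design.
* The sigmoid likelihood ignores where detected links sit within the
  SSEs; a sufficient count is used as a proxy for spatial spread.
* Misalignment is per-SSE and uncorrelated; threading errors that shift
  several SSEs together are not modeled.
* Flexibility is a single global mode; local unfolding, which can trap
  cross-links transiently, is absent.
* Disulfide formability is distance-tiered only; no dihedral or burial
  term.
* Model priors are uniform; fold-recognition scores could be plugged in
  as priors but are not.
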