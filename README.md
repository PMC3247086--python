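# foldprobe

Planning disulfide cross-linking experiments to determine a protein's
fold from a pool of candidate structural models.

Fold-recognition pipelines routinely produce a pool of plausible 3-D
models for a target sequence, and the native-like model is often in the
pool without being the top-ranked one.  `foldprobe` plans a small set of
disulfide cross-linking ("trapping") experiments — pairs of cysteine
substitutions whose S–S bond formation reports spatial proximity — that
discriminates the candidate folds, and then interprets the outcomes
probabilistically, including the case where *none* of the candidates has
the correct fold.  It is a library for structural bioinformaticians,
with a thin `foldprobe` command-line wrapper.

## Method

Planning proceeds in two stages of minimum-redundancy maximum-relevance
(mRMR) feature selection.

**Stage 1 — topological fingerprint.** Each model *m<sub>i</sub>* is
reduced to an SSE contact graph *G<sub>i</sub>* = (*S*, *C<sub>i</sub>*)
over the secondary-structure elements *S* common to the ensemble: an SSE
pair is in contact when ≥ 5 residue pairs sit closer than 9 Å (Cβ–Cβ)
and ≥ 20 % of each SSE's residues have a partner in the other SSE.
Treating each pair *c* as a Bernoulli variable, occurrence frequencies
softened by an agreement weight *q* ∈ (0.5, 1] (default 0.8) give
Pr(*c*) and pairwise joints; the fingerprint *F* ⊂ *S* × *S* is grown
greedily, at each step adding the pair maximizing

&nbsp;&nbsp;&nbsp;&nbsp;H(*c*) − (1/|F|) Σ<sub>c′∈F</sub> I(*c*, *c′*)

until the incremental score drops below 0.01 bits.  A plan is assessed
by enumerating all 2<sup>|F|</sup> outcome vectors: the Bayes error ε
(probability of uniquely selecting a wrong-fold model), the expected tie
ratio τ (mass of datasets with several tied-for-best models), and the
none-of-the-above ratio ν (fraction of datasets an unrepresented fold
would win outright).

**Stage 2 — cross-link plans.** For each fingerprint pair, candidate
links are residue pairs (one per SSE, from residues common to ≥ half the
models) cross-linkable (≤ 19 Å) in at least one model.  Link formation
probability is tiered on distance (0.95 / 0.5 / 0.05 for ≤ 9 Å / 9–19 Å
/ > 19 Å) and marginalized over two noise sources that make links
dependent: per-SSE threading misalignment δ (half the mass at δ = 0,
exponential tails to ±2) and backbone flexibility sampled along the
lowest non-rigid mode of a Cα elastic network.  mRMR selects 10 links
(relevance = mutual information with the contact variable, redundancy =
mean MI between links under the shared noise).  Outcomes are interpreted
through a sigmoidal likelihood in the detected-link count *k*, centred
at *k*₀ = 3 of 10 (likelihood ≈ 0.05 / 0.5 / 0.95 at *k* = 0 / 3 / 6),
and each plan carries its own Bayes error from exact enumeration of the
2<sup>|L|</sup> outcome vectors.

A simulation harness generates CASP-like synthetic ensembles (a common
SSE complement packed in alternative topologies, with boundary jitter,
register shifts and coordinate noise), reads simulated outcomes off a
ground-truth structure (disulfide iff Cβ–Cβ < 9 Å), and scores fold
recovery by ROC/AUC across contact-fraction thresholds *r*.

## Worked example

```bash
python examples/plan_crosslinks.py
```

```
link   residues   score    Pr(link | contact)
   1     7-24    0.3202   0.823
   2     5-23    0.1785   0.751
   3     7-23    0.1840   0.807
   ...
  10     5-20    0.1654   0.769

plan Bayes error: 0.2576%
```

Ten residue pairs probe a helix pair 8 Å apart across a 10-model
ensemble.  Each marginal probability is the chance the disulfide forms
given the SSEs really touch, averaged over misalignment offsets and
elastic-mode backbones; 0.82 rather than 0.95 is the price of that
noise.  The plan's Bayes error — the probability that the 10 outcomes,
fed through the sigmoidal decision rule, mis-call the contact — is
0.26 %, far below the 10 % working tolerance that motivates the uniform
*q* weight in stage 1.

`examples/plan_fingerprint.py` prints the per-step ε/τ/ν table for a
two-topology ensemble, `examples/simulate_end_to_end.py` runs the full
pipeline with the truth variant present (exact recovery, AUC 1.0) and
absent (none-of-the-above flagged), and
`examples/misalignment_robustness.py` shows register-shifted models
being recovered once the offset distribution is marginalized.

The same workflow is scriptable from a shell:

```bash
foldprobe plan-fingerprint models_dir/          # per-step ε/τ/ν table
foldprobe plan-xlinks models_dir/ --out plan.tsv
foldprobe interpret models_dir/ plan.tsv data.tsv
foldprobe simulate --seed 3 --n-models 20
```

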