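# Methods

This note documents the models, conventions and numerical choices behind
`structqa`, and what the synthetic experiments do and do not demonstrate.

## Confidence bands and coverage statistics

Per-residue confidence (pLDDT) lives on [0, 100] and is partitioned at
90/70/50. Band assignment uses strict inequalities at the upper boundaries
(90.0 → *confident*, 70.0 → *low*): the headline definitions of the bands
are phrased with strict ">", and one convention has to win at the exact
boundary values. The `confident_fraction` statistic likewise counts
pLDDT > 70 strictly. Region finding exposes the comparator (`gt`/`ge`/
`lt`/`le`) because "a region with pLDDT ≥ 70" and "a long region with
pLDDT < 50" are both legitimate queries; the default minimum length for
"long" low-confidence regions is 30 residues, a conventional
disorder-region scale, since no canonical value exists.

The multi-domain screen applies its two confident-residue conditions
conjunctively (count ≥ 600 **and** count > L/2) and excludes any entry
with a template hit covering more than half its sequence, encoded as
"best >50 %-coverage identity = 0". Entries lacking template information
are skipped with a warning rather than silently kept.

## Structure metrics

**Kabsch.** SVD-based with the usual determinant sign correction;
rank-deficient (collinear) point sets are rejected because they do not
determine a rotation. Tests cross-check against Horn's closed-form
quaternion method.

**lDDT-Cα.** Inclusion radius 15 Å and thresholds {0.5, 1, 2, 4} Å, the
standard parameters of the metric; Cα only, no stereochemistry penalty,
same-residue pairs excluded. The reference defines the scored residue set
and the pair inclusion, so the metric is deliberately directional:
swapping model and reference changes the scored set (tested on a
partially resolved reference). Pairs whose model side is missing count as
violated; residues with no scorable pair are excluded from the global
mean and reported as NaN.

**TM-score.** d₀(L) = 1.24 (L − 15)^⅓ − 1.8, floored at 0.5 Å where the
closed form is undefined or negative (L ≤ 21). The search superposes on
every contiguous seed fragment of lengths L, L/2, L/4 (minimum 4),
then iteratively re-superposes on the pairs closer than the inclusion
cutoff max(d₀, 2 Å) until the included set is stable (cap 20 iterations),
scoring each seed's **converged** superposition and keeping the best.
Scoring at convergence — rather than at every intermediate iterate —
makes the result independent of which seed found a given stable set.
Consequence, verified empirically: for 20-residue chains perturbed with
isotropic Gaussian noise up to σ ≈ 0.6 Å, every seed converges to the
same stable set and the search equals an exhaustive-seed oracle to
machine precision; by σ ≈ 0.8 Å distinct stable subsets appear and a
heuristic seed set can miss the best one (differences ~0.02). The
oracle-agreement experiments therefore use σ ∈ {0.3, 0.45, 0.6}, the
regime in which the documented search is exact. Residue correspondence is
by identical sequence index (prediction vs. experiment of one sequence);
sequence-independent alignment is out of scope.

**Weighted aggregation.** Σ wᵢsᵢ / Σ wᵢ over per-residue scores with
weights in [0, 1]; with binary resolved flags it reduces to the
unweighted mean over resolved residues. Only this downstream weighting
contract is implemented; producing the per-residue resolvability
probabilities themselves is a predictor-internal matter.

## Contacts

Representative atom: Cβ, or Cα for glycine. Non-glycine residues without
a Cβ fall back to Cα with a logged warning by default (a hard-error mode
exists), because Cα-trace data would otherwise be unusable. "Separated by
at least three other residues" is encoded as |i − j| ≥ 4 in sequence
positions and applies only within a chain; cross-chain pairs have no
separation requirement. Detection uses a k-d tree; correctness is checked
exactly against an all-pairs double loop. A contact pair is counted once
(unordered); chain-level ratios count contacts involving at least one
residue of the chain. The accuracy-vs-ratio table uses right-open bins
with a closed last bin.

## Disorder benchmarking and calibration

AUC uses the Mann–Whitney rank statistic with midranks, i.e. the
probability a random disordered residue outscores a random ordered one
plus half the tie probability; this makes the score invariant under any
strictly monotone transform, so ranking by 1 − 0.01 × pLDDT or by −pLDDT
is equivalent (tested). Evaluation is restricted to labelled residues via
an optional mask, matching benchmark references that leave residues
unlabelled.

Sequence preprocessing for disorder benchmarks remaps X and U to glycine
and splits sequences longer than 2,000 residues into 1–2,000 and
2,001–end, so per-segment score arrays concatenate to exactly the full
length; the second segment starts at 2,001 to make the concatenation
well defined.

Calibration is ordinary least squares of observed accuracy on predicted
confidence, with percentile-bootstrap confidence intervals from 1,000
seeded resamples of individual residues (the resampling unit matches
per-residue scatter). The bootstrap is implemented with multiplicity
weights (`bincount`) for O(n) per replicate. The pair generator draws
predicted values uniformly on (20, 85) and adds Gaussian noise on the
observed side only, untruncated, so the regression of observed on
predicted recovers the generating slope and intercept without attenuation
or edge bias; empirically the CI machinery is calibrated (true-slope
coverage ≈ 95 % over 2,000 replicates, widths matching the theoretical
sampling sd to < 1 %).

## Dataset rules

The evaluation-set filter applies its nine rules strictly in the listed
order, and the order matters: collapsing duplicate sequences by
resolved-residue count *before* per-cluster resolution selection can keep
a different chain than the reverse order (a designed two-record fixture
pins this down). Date comparisons are strict ("after 2018-04-30" excludes
the cutoff day); "best non-zero resolution" means the smallest positive
value, records without one lose ties, and a cluster with no positive
resolution contributes no representative. Duplicate comparison happens
after the ambiguity filter, per the listed order. Search-tool execution is
replaced by a documented TSV hit-table contract so the rule logic is
testable in isolation.

## Ontology

Propagation is the transitive closure over is_a and part_of edges, with
alternative ids resolved to primary ids and obsolete terms excluded from
the graph; a configured edge list can be removed first (curated fixes),
and the result must be acyclic. Display-term selection reads "child" as
*direct* child via the propagation relations (the natural reading; a
descendant-based variant would only shrink the selection) and uses a
strict > threshold. Annotation counts are per protein by default; the
molecular-function and cellular-component namespaces are the default
report, both configurable. A protein annotated to several selected terms
is counted in each term's row — deliberate double-counting, as a
coverage-per-term display requires.

## Synthetic data: what it emulates, and what it does not

Chains are Cα traces with exactly 3.8 Å consecutive spacing — an ideal
helix (2.3 Å radius, 100°/turn, rise solved to preserve the spacing), an
ideal strand zigzag, or a self-avoiding random walk (clash distance
3.4 Å, bounded retries) — with a pseudo-Cβ placed 1.53 Å from the Cα
along a tetrahedral-ish local-frame direction and omitted for glycines.
Complexes place helical chains on a line, close enough for cross-chain
contacts or > 20 Å apart; chains of one entity share a sequence, and the
realised contact counts are recomputed by an independent brute-force loop
and stored as ground truth. The generators are deterministic given a
seed, with per-item streams derived by keyed seeding so enlarging a
cohort does not shift earlier entries.

Disorder proteomes assign each protein round(0.4 × L) disordered residues
in 1–3 contiguous segments (0.4 reflecting the 37–50 % estimated
disordered fraction of the human proteome); disordered residues draw
pLDDT from Uniform(20, 50) and ordered ones from Uniform(70, 98), chosen
to straddle the 50 and 70 cut-offs. Because these distributions do not
overlap, the confidence-derived predictor separates them essentially
perfectly (AUC ≈ 1): the experiment validates the scoring/evaluation
pipeline, not the hardness of real disorder prediction, where ordered and
disordered confidence distributions overlap substantially. Similarly, the
banded proteome apportions band counts exactly (largest remainder) before
shuffling, so recovering the designed fractions tests bookkeeping
end-to-end rather than statistical estimation.

None of the generators attempt realistic energetics, rotamers, sequence
composition or MSA structure; passing tests demonstrate the correctness
of the analysis layer on inputs with known truth, not predictor accuracy
on real proteins. Published proteome-scale figures (coverage percentages,
benchmark AUCs, correlation coefficients, dataset sizes) depend on
external prediction sets and are expressly not reproduced.

## Problem sizes

The default experiment sizes — 200-protein proteomes, 100 random
complexes (≤ ~140 residues each), 50 perturbed 30-residue chains for the
lDDT oracle, 20-residue TM toys, 100 calibration replicates at n = 50,000
with 1,000 bootstrap resamples — are chosen so every exact check runs on
a single CPU in seconds to a couple of minutes while keeping the
statistics (coverage counts, AUC, realized fractions) well resolved.
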