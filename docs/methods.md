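# Methods

## Editor model

An editor is (class, target→product base, PAM pattern, activity window,
spacer length). Window positions are 1-based, counted 5′→3′ from the
PAM-distal end of the protospacer, inclusive at both ends. Shipped
defaults are the values standard for these enzymes in the base-editing
literature — BE3: C→T, PAM NGG, spacer 20 nt, window 4–8; ABE7.10: A→G,
PAM NGG, spacer 20 nt, window 4–7 (deliberately narrower than BE3's) —
and every number is overridable through the YAML registry, so the
config, not the code, is authoritative. Unknown config keys are rejected
outright: a typo in an editor definition should fail fast, not silently
fall back to a default.

## Site screening

The five checks run strictly in order (base match → PAM → window →
homopolymer → GC) and the first failing stage labels the site; the five
labels are fixed output strings. Design-strand logic: a CBE edits C on
the plus strand or G on the plus strand via the minus-strand C;
likewise A/T for an ABE. All coordinates at interfaces are 1-based
inclusive (VCF convention); minus-strand protospacers are reported as
their plus-strand genomic span with `strand=-`.

**Searchable range.** "A PAM downstream within a certain length" is made
precise as: every placement that puts the target base at protospacer
position p ∈ [1, spacer_length], with the PAM immediately 3′ of the
protospacer on the design strand. This makes `no_PAM` and
`activity_window_error` mutually exclusive and well defined — no PAM at
*any* placement versus PAM(s) only at placements that leave the target
outside the window.

**Sequence filters.** Homopolymer and GC are computed over the
protospacer only (the spacer is what hybridizes), never the PAM. Bounds
are inclusive and evaluated in integer arithmetic
(`30·len ≤ 100·GC ≤ 75·len`), so a 20-mer with exactly 6 or 15 G/C
bases sits on the boundary and passes; float rounding can never flip a
boundary case. Placements that would run past a chromosome end, or that
contain an ambiguous base (N) in the protospacer or PAM, are skipped —
a conservative choice: we refuse to design against uncertain sequence.

## Off-target scan and CFD scoring

The scanner is a vectorized sliding-window comparison (numpy) over both
strands of every chromosome, returning all loci within the mismatch
budget whose adjacent PAM satisfies the policy. The default budget is 4
mismatches, the Cas-OFFinder-typical setting; the PAM policy is
`strict` (the editor's own pattern), `relaxed` (adds NAG for NGG
editors), or `any` (no constraint — with budget 0 this doubles as the
exact-repeat counter). Genomic N never matches any query base. The
on-target locus itself is excluded from the hit list (scoring it would
reward nothing); exact duplicates elsewhere are genuine off-targets and
are included.

CFD-style scoring is the multiplicative model: score = Π (per-mismatch
position/base-pair multiplier) × PAM-variant multiplier, defined over
the PAM-proximal 20 nt; a perfect match with a canonical PAM scores
1.0. The per-site off-target feature is the arithmetic mean of hit
scores, with 0.0 (best possible) when there are no hits. Guides shorter
than 20 nt fall back to 0.5^mismatches with a logged warning. The
penalty table is data, not code (TSV, `--cfd-table`); the packaged
default (`cfd_synthetic_default.tsv`) is **synthetic**: a smooth
position gradient (PAM-proximal mismatches most damaging),
transition/transversion asymmetry, canonical-PAM multiplier 1, strongly
down-weighted non-canonical PAMs. It reproduces the qualitative shape
of published mismatch-activity data but is not a refit of any published
coefficient set; users with a preferred published table should load it
as a file. All correctness tests use a uniform table so that scanner
and scoring logic are validated independently of table contents.

## Candidate evaluation and RRA

The five features (bystander count in window, GC fraction, exact
repeats, overlapping SNPs, mean CFD) are each smaller-is-better. The
bystander count includes the target base itself — a constant +1 that
can never change an ordering, kept because it makes the count a direct
property of the window content. Ranks are computed per feature within a
site, ascending with ties averaged, and normalized by the site's
candidate count m (each feature list is site-local, so a rank is
meaningful relative to the actual alternatives).

The RRA score is min over k of BetaCDF(r(k); k, 5−k+1) on the sorted
normalized ranks: the probability that the k-th order statistic of five
independent uniform ranks would be at most r(k), minimized over k. No
multiplicity correction is applied to the minimum — the scores are used
purely ordinally to pick a winner, and a monotone transform of all
scores cannot change the winner. Exact ties break deterministically:
lower off-target score, then smaller genomic start, then plus strand.

Properties maintained (and tested): permutation invariance of winner
and scores; a candidate weakly dominated on all five features never
outranks its dominator; a single-candidate site scores exactly 1 and
wins trivially.

## Pleiotropy model

Case-control GWAS on a linear observed scale report β_obs whose scale
depends on the case fraction Φ. The conversion to the allelic
substitution effect is the rational form

    β = β_obs / D
    D = Φ(1−Φ) + 0.5(1−2Φ)(1−2θ)β_obs
        − (0.084 + 0.9Φ(1−2Φ))·θ(1−θ)·Φ(1−Φ)·β_obs²

chosen because it reproduces the standard small-effect limit
β → β_obs/(Φ(1−Φ)). The grouping of the correction terms admits
alternative readings; the parse is isolated in one function
(`convert_beta`, `parse=` switch) with the alternative grouping
(`linear`: β = β_obs·D − 1) retained for comparison only. D ≤ 0 raises
a dedicated error carrying the inputs; such records are counted,
logged, and excluded from profiles rather than silently dropped.

Classification uses α = 0.05 with a strict inequality (P < α) and no
multiple-testing correction, matching the stated thresholds of the
screening convention this implements; both α and the weak-pleiotropy
criterion (n_significant ≤ 1 by default) are configurable and echoed in
output headers. Strength bins are [0,10), [10,20], (20,∞) — "fewer than
10", "10–20" (inclusive at both ends), "more than 20". β = 0 is never
classified as promotion or inhibition regardless of P.

QQ diagnostics pair sorted observed P values with expected quantiles
(i−0.5)/n, both on the −log10 scale; zero P values are clamped to the
smallest positive float with a warning.

**Rounding.** Reported percentages use exact decimal arithmetic with
half-up rounding — 1 decimal for pleiotropy bins and failure shares, 2
decimals for the feasible-gRNA categories — so boundary ties (e.g.
0.575%) round predictably upward rather than by float banker's
rounding.

## Synthetic fixtures

The generator plants constructs inside segments wide enough to contain
every base that can influence a placement (protospacer + PAM on both
sides of the target), flanked by 3 nt of fixed padding, so the random
background cannot alter a planted outcome. Editable sites get a
contiguous block of planted NGG PAMs realizing exactly the requested
multiplicity; failure sites get exactly the defect their label names.
Every construct is verified against a literal brute-force screen before
emission, and planted off-target decoys are verified to be the *only*
hits of their source guide within the 4-mismatch budget (the trailing
background is redrawn on the rare collision). PAM planting supports
NGG-family editors — the shipped BE3 and ABE7.10 — which is where the
multiplicity-engineering logic is well defined.

One integer seed drives independent `numpy.default_rng` child streams
for genome, SNP, and GWAS draws, so all outputs are byte-identical for
a given spec. GWAS defaults emulate a PheWAS-style panel: 131
phenotypes, case fractions Φ ∈ (0.1, 0.5), allele frequencies
θ ∈ (0.1, 0.9), effect magnitude 0.05 for planted associations
(P < α/10) and zero-centred noise with P > α for nulls — so planted
promotion/inhibition counts are recovered exactly by construction.

What the fixtures deliberately do **not** emulate: real genome
composition (GC structure, repeats, low-complexity regions), linkage
between SNPs, correlated phenotypes, or effect-size distributions.
Passing tests therefore demonstrate algorithmic correctness against
engineered truth, not performance on real genomes.

## Problem sizes and runtime choices

Test and acceptance runs use sizes chosen to make brute-force oracle
comparison exhaustive and fast: oracle-equivalence suites run 20 seeded
genomes of 10–50 kb at mismatch budgets 0–4 against literal
all-positions scans; RRA calibration uses 10⁵ Monte-Carlo draws against
50 random rank configurations (agreement within 3 standard errors);
effect-conversion contracts are checked on a 9×9 (Φ, θ) grid at
β_obs = 10⁻⁸. The whole suite completes in well under a minute on one
CPU.

## Known limitations

- Off-target search is substitution-only: no DNA/RNA bulges, no
  chromatin or accessibility weighting, no RNA-level off-targets.
- The default CFD table is synthetic (see above); absolute CFD values
  should not be compared across tables, only within a run.
- Editing-efficiency prediction (machine-learning models) is out of
  scope; screening is rule-based by design so every decision is
  explainable by a named criterion.
- Multi-allelic input sites use the first ALT allele.
- GWAS Φ and θ must be supplied as columns; the package does not
  compute them from genotype data.
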