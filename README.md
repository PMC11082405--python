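# bexplore

In-silico design and ranking of base-editing guide RNAs, with pleiotropy
profiling of candidate editing loci.

## The problem

Base editors (cytosine base editors, C→T; adenine base editors, A→G) can
correct pathogenic point mutations without double-strand breaks, but a
target is only editable if its sequence context cooperates: the editor's
Cas module needs a PAM at the right distance, the target base must fall
inside the deaminase's activity window, and the spacer must be a workable
gRNA (no long homopolymers, moderate GC). When several protospacer
placements are possible, they differ in bystander risk, off-target
burden, and polymorphism overlap — so the choice of gRNA matters. And
even a perfectly edited locus can be a poor therapeutic target if the
SNP is pleiotropic: significantly associated with many other phenotypes.

`bexplore` addresses all three steps for configurable editors (BE3 and
ABE7.10 ship as defaults; any NGG/IUPAC-PAM editor can be defined in
YAML):

1. **Screening** — five sequential checks per site, each with a bit-exact
   failure label: target-base match (`base_match_error`), PAM presence
   (`no_PAM`), activity window (`activity_window_error`), homopolymer
   run < 7 (`continuous_identical_base_error`), and 30% ≤ GC ≤ 75%
   (`GC_ratio_error`).
2. **Evaluation and ranking** — five features per surviving candidate,
   all smaller-is-better: bystander bases in the window, spacer GC,
   genome-wide exact repeats, overlapping background SNPs, and mean CFD
   off-target score from a genome-wide mismatch scan (budget ≤ 4 by
   default). Per-feature ranks `r_f` are normalized by the site's
   candidate count *m* and aggregated with robust rank aggregation:

   for the sorted normalized ranks r(1) ≤ … ≤ r(5),

       RRA = min_k BetaCDF(r(k); k, 5 − k + 1)

   — the smallest probability that the k-th order statistic of five
   independent uniforms would lie at or below r(k). The candidate with
   the minimal RRA score is the recommended gRNA.
3. **Pleiotropy** — observed-scale GWAS effects β_obs are converted to
   allelic substitution effects β = β_obs / D(β_obs, Φ, θ), where Φ is
   the sample case fraction and θ the effect-allele frequency; each
   (SNP, phenotype) pair is classified as promotion (β > 0, P < 0.05),
   inhibition (β < 0, P < 0.05), or non-significant; SNPs are binned by
   pleiotropy strength and screened for weak pleiotropy (≤ 1 significant
   phenotype by default).

A deterministic synthetic-fixture generator (`bexplore.simulate`) plants
editable sites, each failure mode, off-target decoys at chosen mismatch
distances, SNP tracks, and GWAS tables with known promotion/inhibition
structure — and verifies its own truth tables before emitting. It is the
test bed for the whole pipeline.

## Worked example

Generate a small fixture and run the design pipeline:

```sh
bexplore simulate --spec demo_spec.yaml --out demo_fx
bexplore design --genome demo_fx/genome.fa --sites demo_fx/sites.tsv \
    --snps demo_fx/snps.vcf --editor BE3 --out demo_run
```

with `demo_spec.yaml`:

```yaml
seed: 42
genome_length: 6000
planted_sites:
  - {editor: BE3, outcome: editable, multiplicity: 2}
  - {editor: BE3, outcome: editable}
  - {editor: BE3, outcome: no_PAM}
  - {editor: BE3, outcome: GC_ratio_error}
snp_density: 0.002
gwas:
  n_snps: 3
  n_phenotypes: 20
  planted: [[4, 1], [0, 1], [0, 0]]
```

The design run prints

```
screened 4 site(s): 2 editable, 2 failed, 0 skipped on load
```

and `demo_run/report.tsv` holds one row per (site × candidate) — the
two-candidate site at chr1:39 shows both placements, their features, and
the RRA tie-break picking the earlier-starting spacer:

```
site_id   status    fail_reason     strand protospacer           pam  start end  ... rra_score  is_best
chr1:39   editable                  +      TATCGCGAGTCGACCTACCT  GGG  36    55   ... 0.2373     False
chr1:39   editable                  +      ATATCGCGAGTCGACCTACC  TGG  35    54   ... 0.2373     True
chr1:104  editable                  +      GAGCCGCCTAGCCTCTCGCT  CGG  101   120  ... 1.0        True
chr1:169  failed    no_PAM
chr1:234  failed    GC_ratio_error
```

`demo_run/summary.tsv` tabulates editable sites by feasible-gRNA count
(here one site with 1 gRNA and one with 2, i.e. 50.00% each; 3 guides
over 2 sites) and failures by label. The pleiotropy subcommand recovers
the planted GWAS structure:

```sh
bexplore pleiotropy --gwas demo_fx/gwas --out demo_prof.tsv
# pleiotropy strength <10: 3 (100.0%)
# weak-pleiotropy SNPs: 2
```

`snp1` (4 promotion + 1 inhibition associations) is excluded from the
weak set; `snp2` (0/1) and `snp3` (0/0) pass.

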