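# Methods

## Problem setting and model

Two long-diverged diploid species meet in sympatry; putative hybrids are
diagnosed from a few low-copy nuclear loci plus one organellar locus. The
statistical leverage comes from *fixed interspecific differences*: alignment
characters at which every sampled haplotype of species A carries one state
and every haplotype of species B a different state. A true F1 then shows
*additivity* — both parental states superimposed — at every diagnostic
character of every nuclear locus, carries exactly one haplotype from each
parental panel per locus, and carries the maternal species' chloroplast.

### Character model

Alignments are over `{A, C, G, T, -, N}`; direct-sequencing consensus rows
may additionally carry the six two-base IUPAC codes (a diploid superimposes
at most two bases; 3/4-fold codes are rejected at input). Columns are
0-based, intervals half-open.

Indels are recoded before any counting: a maximal run of gap-containing
columns over which the per-sample presence pattern is constant is one
*indel event* and becomes a single binary character (present/absent). This
matches the convention of scoring a multi-bp indel as one mutational step
in haplotype networks and one fixed difference in divergence counts.
Adjacent gapped columns with different presence patterns are distinct
events; an all-gap column is rejected as uninformative.

A heterozygous indel cannot be represented as a consensus state: the two
superimposed frame-shifted traces are unreadable in practice. The model for
this is the `readable_prefix`: the consensus is faithful up to the first
column where exactly one allele is gapped, and `N` from there on. The
pipeline therefore scores additivity only over readable diagnostic
characters and the index denominator shrinks accordingly (an individual
with nothing readable reports NA).

### Diagnostic sites

A character is diagnostic iff the non-missing states within each species
group are each a single state and the two differ. Missing states (`N`) are
ignored rather than disqualifying, and such characters are flagged
`missing_data` in the output — a permissive rule chosen because missing
data at this scale is sparse terminal trimming, not systematic; the flag
lets a user apply the strict rule downstream. Only haplotype-role rows
define species alleles; consensus rows (which include the hybrids) never
leak into allele definitions. Indel characters participate exactly like
substitutions.

### Phasing

Haplotype inference is Excoffier–Slatkin EM plus panel-constrained
maximum-posterior resolution, replacing a Bayesian coalescent phaser. The
rationale: with ≤6 haplotypes per species and strong fixed differences,
resolutions are nearly forced, and the EM maximum-likelihood frequencies
are the textbook estimator for unphased diploid data.

* E-step weights each compatible unordered haplotype pair (h, k) by
  f_h·f_k (×2 when h ≠ k); the M-step re-estimates frequencies from
  expected counts. Convergence when max |Δf| < 1e-8 or 10,000 iterations;
  the log-likelihood is non-decreasing (asserted in tests). On
  phase-unambiguous data (≤1 heterozygous character per genotype) the
  estimate equals direct gene counting exactly.
* Resolution enumeration is panel-first: all pairs from the named parental
  panels compatible with the genotype (missing characters constrain
  nothing). Only a genotype the panel cannot explain falls back to
  heterozygous-site expansion (2^(k−1) orientations; a configurable bound,
  default 20 het characters, guards the combinatorics), with `N` characters
  imputed from the nearest panel haplotype — the parsimony assumption that
  an unsampled variant matches its closest named relative where it cannot
  be read. Without any panel, `N` expands over the alleles observed at that
  character.
* Ties between resolutions: prefer two panel-named haplotypes over any
  novel vector, then the higher frequency product, then lexicographic state
  order; ties are reported. Confidence is the chosen resolution's share of
  the summed posterior.

Cloning-based phasing of problematic individuals is modelled as directly
supplying haplotype-role rows for those samples, not as simulated colony
picking.

### Median-joining networks

Per species and locus: (1) the minimum spanning network — a pair (u, v) is
linked iff d(u, v) ≤ minimax(u, v) + ε, where minimax is the largest edge on
the MST path (ε = 0 keeps the MST plus all weight-tied alternatives);
(2) quasi-medians of connected triplets (per character the majority state,
or all three on a three-way split) are added while they reduce the network
cost; (3) peripheral median vectors (degree ≤ 1) are deleted and the
network rebuilt to a fixpoint. All characters have weight 1, including
multi-bp indel events; counts only annotate node size. Determinism:
haplotypes in name order, candidate medians in lexicographic state order,
best-improvement acceptance.

The *cost* of a network is defined as the minimum-spanning-tree weight over
its node set — the quantity the median-insertion step minimizes, and the
quantity tested against an exhaustive Steiner-tree oracle on small
instances. The drawn network retains all ε-tied links, whose summed weight
can legitimately exceed the tree weight (e.g. three mutually-adjacent
haplotypes), so "total drawn edge weight" is not the minimized quantity.
For the same reason the ε-monotonicity property (ε = 0 links ⊆ ε = 1 links)
holds at the fixed-node-set minimum-spanning-network stage and is tested
there; after median insertion the node sets differ.

### Generation classification

Per-locus cluster patterns — AA (both haplotypes cluster with species A),
AS, SS — feed independent-Mendelian likelihoods:

| class  | AA  | AS  | SS  |
|--------|-----|-----|-----|
| pure_A | 1   | 0   | 0   |
| pure_B | 0   | 0   | 1   |
| F1     | 0   | 1   | 0   |
| F2     | 1/4 | 1/2 | 1/4 |
| BC_A   | 1/2 | 1/2 | 0   |
| BC_B   | 0   | 1/2 | 1/2 |

Posterior ∝ prior × product over loci (uniform prior by default).
A novel (`UN`) haplotype inherits its nearest cluster for pattern purposes
(a vector one step from a species-A haplotype still witnesses species-A
ancestry); a distance tie leaves that haplotype unassigned, giving AN/SN
patterns that are marginalized over the patterns they are consistent with
(AN → AA + AS). Fully uninformative loci are dropped. `f1_consistent`
requires AS at *every* locus. This classifier formalizes a verbal F1
argument; it deliberately ignores fern-specific complications such as
intragametophytic selfing, and is labelled an extension in reports.

Worked closed forms (frozen as test oracles): three AS loci under uniform
priors give posterior(F1) = 1/(1 + 3·(1/2)³) = 1/1.375 ≈ 0.7273; three AA
loci give posterior(pure_A) = 1/(1 + (1/4)³ + (1/2)³) ≈ 0.8767 (the
backcross term dominates the alternative mass).

### Maternal assignment and added statistics

The chloroplast locus is recoded like nuclear loci; each hybrid's plastid
haplotype is assigned to the species whose haplotype set is strictly nearer
in mutational steps (ties → ambiguous). Directionality is summarized with
an exact two-sided binomial test against 0.5 (ambiguous excluded);
germination rates get Wilson 95% intervals and Holm-corrected pairwise
Fisher exact tests. These tests are additions of this package — the
descriptive counts are the primary output — and are flagged as such in the
report text.

## Synthetic generator

`fernhybrid.simulate` draws, per locus: a uniform-random ancestral
sequence; fixed substitution positions and indel intervals; per-haplotype
private mutation positions — all mutually disjoint, so within-species
variation never blurs the species boundary and networks are star-like
(panels radiate off a core haplotype). Species B carries the deletion
allele at fixed indels. Parental diploids draw two haplotypes per locus
from their population's frequency vector (Hardy–Weinberg within
population); F1 = one haplotype from each species; an F2 gamete picks the
A- or B-side haplotype of an F1 independently per locus (free recombination
between loci, none within); backcrosses pair one F1 gamete with one
parental draw. Consensus rows are produced by the same superposition +
truncation rule the analysis assumes; a per-base miscall rate replaces a
readable consensus character with a uniform random base (so an F1
diagnostic site fails additivity with probability exactly the error rate —
the property the error-model test checks). Chloroplast sequences copy the
maternal species per the configured rule; germination counts are binomial
draws. Everything descends from one `numpy` Generator seed; same seed,
byte-identical outputs.

The packaged default configuration encodes the study design this package
was built around: locus lengths 453/601/490/975 bp; fixed differences
9 / 11 + one 5-bp indel / 7 / 11 + three indels (chloroplast indel lengths
4/6/3 bp — counts are design values, lengths a choice); haplotype counts
2&2 / 6&2 / 6&3; parental sample sizes 157 (8 populations) and 70 (3
populations); 22 hybrids, all F1, all B-maternal; germination rates
0.798/0.654/0.203 with 240/230/250 spores; sequencing error 0 (clean Sanger
reads). Per-population haplotype frequencies are plausible values chosen
once (dominant haplotype 0.55–1.0; one A-population carries the rare cam
variant; one population is gapCp1-monomorphic; the rarer B haplotype of
gapCp1 is private to one location), since the source design reports them
only graphically. The gapCp1 indel sits at fractional position 0.72 so that
most diagnostic substitutions stay readable in heterozygous-indel
individuals.

What the generator does **not** emulate: alignment error, recombination
within a locus, base-composition or rate heterogeneity, PCR chimeras,
shared ancestral polymorphism across the species boundary, and
intragametophytic selfing. Tests passing on this generator therefore
demonstrate correctness of the inference machinery under the stated model,
not robustness to those real-data pathologies.

## Numerical and engineering choices

* EM: tolerance 1e-8 on frequencies, 10,000-iteration cap, uniform
  initialization; frequencies sum to 1 within 1e-9.
* Phasing enumeration caps: 20 heterozygous characters, 65,536 resolutions
  (errors are explicit `ComplexityError`s).
* Posteriors: normalized exactly; all-zero likelihood raises rather than
  returning NaNs.
* Networks: Prim's algorithm with lowest-index tie-breaks on dense integer
  distance matrices (panels here are tiny); quasi-median expansion capped
  at 81 vectors per triplet; at most 64 medians.
* TSV output is byte-stable (fixed column order, `%.6g` floats, LF).
* Test problem sizes: the oracle suites use 200 random diagnostic matrices,
  100 random ≤5-haplotype/≤4-character network instances against the
  exhaustive Steiner oracle, and a 2000-individual F2 cohort on three
  compact 60-bp loci for the Mendelian fraction (the Mendelian statistics
  depend on pattern draws, not locus length, so short loci are used there).

## Known limitations

* The EM phaser has no recombination model and no multi-locus joint
  phasing (loci are treated independently, as the study design assumes).
* Median-joining is a heuristic; its cost equals the exhaustive Steiner
  optimum on all tested small instances, but no optimality guarantee exists
  for larger panels.
* The generation classifier's pattern likelihoods assume exactly two
  source species, autosomal diploid inheritance, and independent loci;
  with few loci its power to separate F1 from later classes is limited
  (three AS loci leave ~27% posterior on F2/backcross classes combined).
* Published divergence counts can be recomputed from deposited haplotype
  sequences when staged under `data/deposited/` (see the acceptance test);
  germination rates are wet-lab observations and enter only as simulator
  parameters.
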