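# Methods

## Model and assumptions

`pedimpute` treats a pedigree as a closed system of chromosome flow: every
haplotype carried by a non-founder is a mosaic of copies of founder
chromosomes, with breakpoints at the crossovers of the intervening meioses.
The method is purely rules-based — no population linkage disequilibrium, no
genotype likelihoods, no sampling. Its contract:

- the pedigree structure is correct;
- every member of a (sub-)pedigree has framework ("set 1") genotypes;
- markers are diallelic; genotypes are alternate-allele dosages {0,1,2};
- dense ("set 2") genotypes exist for a subset of members and are to be
  completed in the rest.

Pedigrees containing members without set 1 data are split into maximal
connected sub-pedigrees of fully genotyped trios. Parent links are severed
in pairs (a child never keeps exactly one in-pedigree parent, because the
trio machinery requires both); severed children become founders of their
sub-pedigree, and their chromosomes become founding chromosomes. The same
rule handles half-sib/single-known-parent records at parse time. Loops and
inbreeding are permitted in the data model; the segment tracer records all
paths.

## Stage conventions

**Trio phasing.** Each (father, mother, child) dosage triple is resolved by
enumerating the transmissible-allele pairs consistent with all three
genotypes. One compatible pair forces the child's ordered phase
(paternal|maternal) and both transmissions; the all-heterozygote triple is
ambiguous; an empty set is a Mendelian error, which is recorded and excluded
from informativeness but never removed from the data. A missing parent is
treated as able to transmit either allele, so the child is still phased when
the other parent plus the child force it. Resolution depends only on the
three dosages, so the trio sweep converges in a single pass; the fixed-point
loop is retained as a guard. Slot semantics: slot 0/1 = paternal/maternal
for non-founders, proxy homolog A/B for founders (founder proxies are written
into the same phase matrix).

**Crossovers, multi-meiosis chromosomes.** For a parent that is itself a
phased trio offspring, a marker is informative for the meiosis parent→child
when the parent is heterozygous with known phase, the child's inherited
allele is known, and neither locus is a Mendelian error. The inherited
allele then names the parental homolog; runs of constant homolog become
local segments with 3-generation paths (grandparent → parent → child), and
each switch is a crossover placed in the open interval between the flanking
informative markers.

**Crossovers, founder chromosomes.** A founder's offspring are dichotomized
at founder-heterozygous markers by inherited allele. The orientation (which
allele sits on proxy homolog A) is chosen per marker so that the total
number of offspring group flips — one crossover each — is minimal. The
minimum is computed *exactly* by dynamic programming over the vector of
current offspring groups (state space ≤ 2^sibship; sibships are small). A
greedy left-to-right scan was evaluated first and rejected: with ragged
per-offspring informativeness a locally tied orientation can resolve against
the truth, inflating the event count above the true number and
mis-attributing segments. The exact minimum is provably a lower bound on
the true count, because the truth is always one feasible explanation.

Two sub-rules matter:

- *Anchoring.* Only markers informative for ≥2 offspring can localize a
  crossover. Where a single offspring is informative, the founder's phase is
  constrained by that offspring alone, so its group there is a free gauge
  and asserting a boundary would be arbitrary (and was observed to produce
  wrong attributions before this rule was adopted). Events are therefore
  placed between consecutive *anchored* markers, segments span anchored
  runs, and single-informative markers are attributed only when strictly
  inside a run.
- *Ties.* When the flip count is equal under either orientation (always the
  case in a two-offspring family), the event is assigned to the
  lexicographically smallest offspring and flagged `arbitrarily_assigned`.
  Either choice yields a proxy representation with consistent genotype
  flow; the flag marks that the offspring attribution (not the count) is
  conventional.

A single-offspring founder gets the transmitted haplotype itself as proxy
homolog A (complemented against the founder's dosages for homolog B). The
proxy may be a recombinant of the true homologs; imputation is unaffected
because all attribution is expressed in the same representation.

**Uncertainty regions are never imputed through.** Crossover uncertainty
intervals, and the chromosome-terminal regions beyond the outermost
informative (or anchored) marker of each meiosis, are excluded from
segments: a crossover there is undetectable, so no origin is asserted. This
conservatism is what makes the error-free pipeline exact rather than merely
accurate; its price is reduced yield near chromosome ends and around
crossovers.

**Nonfounder matrix.** From each founder homolog a depth-first traversal
(explicit work stack, no recursion-depth limit) intersects the intervals
known to descend along the current path with the child's local segments
attributed to the transmitting parent's current homolog; surviving
intervals extend the path. Intervals are half-open in bp; a segment's bp
bounds are [position of first marker, position of last marker + 1], so dense
markers strictly between two framework markers of the same segment are
covered and positions in gaps are not. Adjacent same-path intervals are
merged; same-origin overlaps (inbreeding paths) are merged for querying,
and any residual overlap of different origins is conservatively treated as
unknown.

**Imputation.** Known set 2 haploid alleles (trio-phased or homozygote
splits) are projected onto the origin of their covering segment. Agreeing
observations merge; disagreement marks the founder allele *conflicted*.
For sequenced founders with exactly one homolog resolved, the other is the
dosage complement (iterated to a fixed point; an out-of-range complement
conflicts both homologs). A diploid genotype is imputed only when both
slots' origins are known and both founder alleles are resolved; observations
are preserved verbatim and never overwritten. The conflict policy is
`abstain` by default (`majority` is available); abstention reflects that
disagreements arise from genotyping error or structural variation, where a
vote would manufacture confidence. Unphased heterozygotes in non-founders
contribute nothing directly (complement inference is defined for founders
only); haploid-only knowledge yields no diploid call.

**Evaluation.** IQS on the 3×3 imputed-vs-held-out dosage table is the
kappa construction: `P_o` the diagonal fraction, `P_c` the product of the
table's own marginals, `IQS = (P_o − P_c)/(1 − P_c)`, excluded when
`P_c = 1` (e.g. monomorphic agreement) or no cells compare. Comparison is
restricted to cells that were masked *and* imputed; unrecovered cells are
yield, not errors. MAF bins (0,0.01], (0.01,0.05], (0.05,0.1], (0.1,0.2],
(0.2,0.3], (0.3,0.4], (0.4,0.5] with the first bin closed at 0;
availability bins [0,0.1], (0.1,0.25], (0.25,0.75], (0.75,0.9], (0.9,1].
Empty bins are reported empty, not zero. Availability is the per-marker
fraction of set-2-carrying individuals with an unmasked genotype; MAF is
computed over a designated unrelated set (the founders, in simulations).

## Simulator

The gene-dropping simulator provides the study conditions and the oracle for
every stage. Defaults (the packaged demo fixture): one chromosome of
100 Mb and 1 Morgan with a uniform genetic map, 500 framework markers on a
uniform grid, 2,000 dense markers uniform-random at distinct positions,
error and missingness 0. Acceptance-scale runs use 2,000 + 5,000 markers.
Founder allele frequencies mix a rare-skewed Beta(0.6, 6)/2 component
(weight 0.5) with Uniform(0.01, 0.5), so all seven MAF bins are populated.
Crossovers are Haldane: count ~ Poisson(map length in Morgans), positions
uniform, no interference. Genotyping error resamples a cell uniformly from
the two other dosages. Everything is deterministic from one seed.

The demonstration pedigree has 37 members over 4 generations, with founder
sibships of size 4, 2 and 1 in every generation band, so multi-offspring
dichotomization, the two-offspring arbitrary assignment, single-offspring
proxy phasing, and both chromosome subtypes are all exercised by one
fixture. `random_pedigree` generates arbitrary-shape pedigrees for property
tests.

What the simulator does *not* emulate: linkage disequilibrium among founder
haplotypes (sites are independent), crossover interference, sex-specific
maps, de novo mutation, and copy-number variation. Passing tests therefore
demonstrate the correctness of the inheritance logic, not robustness to
structural variation — on real data, CNV regions are a documented source of
imputation error for this family of methods, and the abstain policy plus
Mendelian-error flags are the only mitigations here.

## Numerical and degenerate-input choices

- Coordinates: VCF is 1-based inclusive; internal intervals and BED output
  are half-open (0-based for BED). Conversion at the I/O boundary only.
- Chromosome-spanning segments (founder self-segments, single-offspring
  proxies) use an open-ended bp bound rather than a chromosome length, which
  the inputs do not declare.
- Deterministic ordering everywhere (sorted individual ids, topological trio
  order): two runs on identical inputs produce byte-identical artifacts.
- A meiosis with no informative markers, or a founder family with no
  anchored markers, contributes no segments (logged); downstream cells
  resolve as not-imputable rather than guessed.
- Markers present in both set 1 and set 2 are deduplicated in favor of
  set 2; multi-allelic and non-SNP VCF records are skipped with a logged
  count.
- Conflicted founder alleles are data, not exceptions; `ImputedMatrix`
  distinguishes observed / imputed / not-imputable / conflicted per cell.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run on a 37-member pedigree with
2,000 + 5,000 markers (seconds per run), 200 founder-offspring meioses for
the crossover bound, 1,000 random tables for the IQS oracle, and a 0.5%
error run for robustness. These sizes exercise every code path while
keeping the full suite fast; the algorithms are linear in markers and near
linear in pedigree size, so larger cohorts scale accordingly.

## Known limitations

- Crossover resolution is bounded by informative-marker (for founders:
  anchored-marker) spacing. Two crossovers of the same family falling in
  one uncertainty window are undetectable and can silently mis-attribute
  the enclosed interval; at sparse framework densities this is the dominant
  residual error source on otherwise clean data, and projection conflicts
  are its observable symptom. Denser frameworks shrink the windows
  quadratically.
- Minimal-explanation ambiguity can survive anchoring when two crossovers
  in adjacent windows share an anchor; the dynamic program then picks one
  minimal explanation deterministically.
- Founders with all offspring uninformative (e.g. homozygous founders
  everywhere) cannot be phased and impute nothing through their gametes.
- No genotype uncertainty: inputs are hard calls, outputs are hard calls.
- Between-pedigree IBD, population reference panels, and multi-allelic
  markers are out of scope.
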