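# Methods

This note records the models and procedures shalemeta implements, the
defaults that matter, what the synthetic benchmark does and does not
emulate, and the numerical choices made where the design was open.

## Read quality control

Reads pass a fixed rule chain: 3' quality trim, minimum length,
low-complexity filter, exact-duplicate removal. Each removed read is
counted under the first rule that fired, so the report always sums to the
input count, and the chain is idempotent (re-filtering its own output
removes nothing).

**Trimming.** The trimmer removes terminal bases while either the terminal
base quality or the mean quality of the terminal window (default 5 bases,
threshold Q15) falls below the threshold. The trailing-base condition is
deliberate: a pure window mean can stop while the read still ends in a
hard-zero base (a window of [40,40,40,40,2] averages 32), leaving exactly
the artifact the trim exists to remove.

**Low complexity.** Shannon entropy of the empirical k-mer distribution
(default k=3), with `N` as a fifth symbol so N-runs cannot score as
complex. Reads below 1.5 bits are removed. The threshold sits between the
two canonical low-complexity archetypes and real sequence: homopolymers
score 0 bits, perfect dinucleotide repeats exactly 1.0 bit, while random
100-200 nt reads score about 6 bits, so any cut in (1.0, 6) separates them;
1.5 keeps dinucleotide repeats strictly inside the removed class rather
than on the boundary. Entropy is a stand-in for whatever dust-style metric
a given QC tool uses; the threshold, k, and all trim parameters are
exposed as flags.

**Duplicates** are defined as identical post-trim base strings (not
prefix-duplicates), first occurrence kept.

## LCA taxonomic profiling

Per read, hits are retained when the bitscore is at least 60 and within
the top 10% of the read's best bitscore (the retained-hit window default
of the standard LCA binning tools). Retained hits map to species through
the reference catalog and the read is assigned the lowest common ancestor
of those species.

**Min-support (default 207 reads).** A taxon is reported only when its
subtree gathers at least the support threshold; reads at unsupported taxa
move to the nearest supported ancestor. Because subtree totals are
invariant under these upward moves, a single pass over the original
subtree totals suffices and the result is order-independent. Reads whose
entire root path lacks support are counted unassigned — push-up rather
than discard was chosen because it conserves reads, matching the
documented behavior of the reference LCA implementations. Reported-taxon
counts are monotonically non-increasing in both the bitscore and support
thresholds.

**Rarefaction.** Assigned reads are subsampled without replacement at each
depth (default 3+ replicates). The support threshold scales proportionally
with depth (`ceil(207 * depth/total)`, minimum 1) so shallow depths do not
trivially report zero taxa; a fixed-support mode (`--fixed-support`) is
available for sensitivity analysis. Depth 0 reports 0 taxa and full depth
with one replicate reproduces the full profile exactly.

## Coverage assignment (multi-mapping redistribution)

The pipeline's core statistic is a fractional read count per protein
reference. "Coverage" is read counts, not per-base depth: only hit tables
are available, and the downstream unit of reporting is unique reads (URs).

1. **Best hits.** Per read, hits under 60 bits are dropped; the maximal
   bitscore tier is kept and successively filtered by minimal e-value,
   maximal percent identity, maximal alignment length (the canonical
   informativeness order of the tabular alignment columns; configurable).
   A read with one surviving reference is *unique* and contributes exactly
   1.0 to it.
2. **Tier 1 (weighted).** A multi-mapping read whose best set intersects
   the uniquely-covered set U splits its unit mass over that intersection
   with weights proportional to unique coverage. Mass is restricted
   strictly to the intersection; best-tier references outside U receive
   nothing. Weights use raw unique read counts by default; a
   length-normalized mode (counts / protein length) is a flag, since
   nothing in the rule's statement involves lengths.
3. **Tier 2 (species fallback).** Otherwise, if any best-set reference
   belongs to a species with positive species-summed unique coverage, mass
   is split over those species proportionally to species coverage and
   uniformly within each species' best-set references (the within-species
   split is a design choice; the rule only prescribes the between-species
   proportionality).
4. **Tier 3 (dropped).** Otherwise the read contributes nothing.

The pass is single-shot: weights are frozen from the unique-coverage
stage. An optional EM mode re-derives tier-1 weights from updated total
coverage until the L1 change falls below 1e-6 (max 100 iterations); it is
not the default because the procedure being reproduced is one pass.

Numerical determinism: per-read weight vectors are accumulated into
reference totals in sorted read-id order, so the ledger is bitwise
identical under any permutation of the input. Conservation (total coverage
= unique + weighted + fallback read counts) holds to 1e-9 and is tested
against an independently coded brute-force transcription of the three
tiers on 1,000 random instances.

## Functional aggregation

The manual curation step of description-based enzyme grouping is replaced
by a declarative rule table: ordered categories with case-insensitive
include/exclude patterns (substring by default, regex via a `re:` prefix).
A reference matching k categories contributes to all k cells — enzyme
names like "cytochrome P450 monooxygenase" legitimately belong to two
reported groups — so category margins may exceed the read total; the
matrix records the multi-counted reference count, and a first-match mode
exists. The shipped rule file covers the oxidative hydrocarbon metabolism
groups (mono-/dioxygenases, alcohol and aldehyde dehydrogenases,
cytochrome P450, laccase) and the inorganic sulfur oxidation systems
(sulfide:quinone oxidoreductase, flavocytochrome c sulfide dehydrogenase,
the Sox components, adenylylsulfate reductase, sulfate
adenylyltransferase, sulfite oxidase, dissimilatory sulfite reductase,
sulfur relay proteins) plus a few hydrolases; it is user-extensible and
makes no claim of completeness.

## Geochemistry

**Rock-Eval.** HI = 100 S2/TOC (mg HC/g TOC), OI = 100 S3CO2/TOC (mg
CO2/g TOC), hydrocarbon potential S1+S2, and pyrolyzable carbon
PC = 0.083 (S1+S2) + (12/440) S3CO2 + (12/280) S3CO with RC = TOC − PC.
The conversion constants are the standard programmed-pyrolysis carbon
fractions (0.083 for hydrocarbons, 12/440 and 12/280 the carbon mass
fractions of the CO2 and CO signals). PC + RC = TOC closes to 1e-9 by
construction, and PC > TOC raises a consistency error. Kerogen typing
uses HI bands — I above 600, II above 300, III above 50, IV at or below
50 mg HC/g TOC, boundaries assigned downward — a declared, configurable
convention for the pseudo-Van-Krevelen classification; OI is carried but
does not enter the default banding.

**Sulfur.** Organic sulfur is total minus sulfate, pyritic and sulfidic
(acid-volatile) sulfur, as exact arithmetic; a negative remainder sets a
flag and is never clamped, because silently repaired mass balances hide
measurement problems. Pyritic sulfur from pyrite-bound iron uses FeS2
stoichiometry, S = Fe × 2·32.065/55.845 ≈ 1.1484 Fe. The sulfidic fraction
is named for the acid-volatile sulfide determination (methylene-blue
colorimetry); sources that print "sulfite" for this fraction are treated
as meaning sulfide.

**GC-MS classing.** Ions under 3% of the base peak are discarded. Spectra
with a library match of at least 80% keep the library identity regardless
of ions; 50-79% matches are assigned to the class (aromatic, aliphatic,
alcohol, aldehyde, carboxylic acid) with the most characteristic ions
among the top 8 dominant retained ions, requiring at least 2 matches, ties
broken by the summed intensity of the matching ions and then
alphabetically. The counting rule (top-8, ≥2) is a design choice: "the
presence of characteristic and dominating ions" needs an operational
definition. The ion lists overlap — the alcohol list is a strict subset of
the carboxylic-acid list, and aliphatic shares 4 of 5 ions with it — so
exact ties are real; the alphabetical order happens to resolve the
subset-induced ties toward the more specific class (alcohol, aliphatic),
and the shared ions {43, 57} alone can never separate aliphatic from
carboxylic acid (the decision then falls entirely to the deterministic
tie-break, not to those ions).

## Synthetic benchmark

The generator replaces the study's deposited reads so that every stage is
testable at desk scale with known truth. Defaults are the package's
standard conditions: 20 species (full eight-rank lineages, roughly 3
species per genus), 10 references per species with lognormal abundance,
50,000 aligned reads, a 0.40 multi-mapping rate, true-hit bitscores
N(90, 15) truncated at zero (about 2% of reads fall below the 60-bit
floor and surface as unaligned), and 30% "hypothetical protein"
descriptions. The 0.40 multi-mapping rate is a free parameter chosen as a
demanding desk-scale setting, not an estimate of any particular dataset.

Homologous cross-hits are restricted to the true reference's genus, which
makes genus-level LCA behavior directly testable. The first planted
homolog always ties the true hit exactly (so the realized multi-mapping
fraction equals the configured rate); additional homologs tie with
probability 0.5 or score lower by an Exponential(rate 0.2, mean 5 bits)
decrement. Read sequences are random ACGT — hits are generated directly
from the score model rather than by running an aligner, because the
aligner is outside the pipeline boundary.

Contaminants are planted in exact configured counts after the clean
reads: sub-34 nt reads, exact duplicates of distinct clean reads,
homopolymer/dinucleotide repeats, and all-low-quality reads (the
low-quality "tail" spans the whole read, so they trim to empty and are
counted under `empty_after_trim`). Geochemistry records are built so the
sulfur fractions sum exactly to the total (the stored organic truth is
the exact floating-point remainder of the same subtraction chain the
speciation performs, making recovery bitwise). Spectra plant each class's
most class-specific ion (aromatic 77, aliphatic 99, alcohol 45, aldehyde
44, carboxylic acid 60) among the dominant ions over a disjoint
background; without a diagnostic ion a class whose ion list is contained
in another's would be unrecoverable by any counting rule.

What the generator does **not** emulate: sequence evolution or realistic
read error profiles, protein sequences, cross-genus spurious alignments,
database incompleteness, or chimeric reads. Passing the recovery
benchmarks therefore demonstrates the algorithms' correctness under their
own stated assumptions, not performance on real sequencing data.

## Problem sizes

The shipped test suite and acceptance script run the redistribution
oracle on 1,000 random instances (≤10 reads, ≤6 references, ≤3 species),
conservation on 100 instances (≤200 reads), the recovery benchmark at
50,000 reads over 200 references, LCA against the oracle on all 2- and
3-subsets of a 50-node random tree, QC on 2,200 reads with 200 planted
contaminants, and the spectrum classifier on 25 planted spectra. These
sizes give stable statistics (recovery correlations ≥ 0.999 in practice)
while the whole suite completes in well under a minute.

## Known limitations

* Per-base depth is not computed; coverage is read-count mass.
* The LCA tool-chain's "meganized" intermediate format is not parsed;
  alignments enter as standard 12-column tables.
* The entropy low-complexity filter is a declared stand-in for
  tool-specific dust-style metrics.
* Kerogen band thresholds and the Rock-Eval conversion constants follow
  the standard convention; instruments that report differently need the
  configurable thresholds adjusted.
* The shipped functional rule file covers the reported enzyme groups
  only; real nr descriptions will need additional rules and excludes.
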