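# shalemeta

Metagenomic read profiling and geochemistry for rock-hosted microbial
communities — built around the analysis chain used to characterize the
lithobiontic community of a weathered, organic-rich black shale: who is
there (taxonomic profiling), what they can do (protein-level functional
profiling), and what they have done to the rock (kerogen and sulfur
geochemistry).

It is aimed at researchers who have protein-alignment hit tables from a
shotgun metagenome (reads aligned against a non-redundant protein
database) plus Rock-Eval / sulfur / GC-MS measurements of the host rock,
and who want a reproducible, scriptable version of the usual
desk-analysis steps.

## What it computes

**Read QC.** 3' quality trimming, minimum length 34 nt, k-mer-entropy
low-complexity removal, exact-duplicate removal — with an audit report in
which every input read is accounted for exactly once.

**LCA taxonomic profiles.** Reads are assigned to the lowest common
ancestor (LCA) of the species their retained hits point to (bitscore ≥ 60
and within 10% of the read's best hit), and a taxon is reported only with
min-support ≥ 207 reads in its subtree; unsupported reads are pushed up to
the nearest supported ancestor. Rarefaction curves (mean ± sd of reported
taxa over subsampling depths) support cutoff choice. Output is a profile
TSV or Krona-importable text.

**Coverage with multi-mapping redistribution.** The per-reference
statistic is a fractional read count. Reads with a single best-scoring
hit (unique reads, URs) count 1.0 toward their reference; a multi-mapping
read with best set B splits its unit mass over B ∩ U (U = references with
unique coverage) with weights

    w(p) = u(p) / Σ_{q ∈ B ∩ U} u(q),

where u(p) is p's unique-read count; failing that, mass falls back to the
species represented in B proportionally to species-summed unique
coverage; failing that, the read is dropped. Conservation (Σ coverage =
unique + weighted + fallback reads) holds to 1e-9. An optional EM mode
iterates the tier-1 weights to convergence.

**Functional aggregation.** A declarative rule table maps free-text
protein descriptions (e.g. "catechol 2,3-dioxygenase") to enzyme
categories; unique reads and coverage aggregate into a category × taxon
matrix at any rank. A curated default rule set for hydrocarbon- and
sulfur-oxidation enzymes ships with the package.

**Geochemistry.** Rock-Eval indices HI = 100·S2/TOC, OI = 100·S3CO2/TOC,
PC = 0.083(S1+S2) + (12/440)·S3CO2 + (12/280)·S3CO, RC = TOC − PC, and HI-band
kerogen typing (I/II/III/IV); sulfur speciation with organic S by
difference and pyritic S from iron via FeS2 stoichiometry
(S = 2·32.065/55.845 × Fe); and a GC-MS classifier that keeps library
identities at ≥ 80% match and otherwise assigns major compound classes
from characteristic fragment ions (aromatic 65/77/78/79, aliphatic
43/57/71/85/99, alcohols 45/59/73/87, aldehydes 44/58/72, carboxylic
acids 43/45/57/59/60/71/73/85/87).

**Synthetic data.** Every input — taxonomy, catalog, reads, hit tables
with a controlled multi-mapping rate, QC contaminants in exact counts,
geochemistry records, spectra with planted ions — can be generated with
known ground truth, so the whole pipeline is testable without external
data. See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a small benchmark, QC the reads, compute coverage and a profile:

```
$ shalemeta simulate --seed 11 --n-species 8 --refs-per-species 5 \
    --n-reads 3000 --contaminants short=12,duplicate=6 --outdir demo
3018 reads, 5353 hits written to demo

$ shalemeta qc --in demo/reads.fastq --out demo/kept.fastq --report demo/qc.tsv
kept 3000/3018 reads (removed: {'empty_after_trim': 0, 'short': 12,
'low_complexity': 0, 'duplicate': 6})

$ shalemeta assign --aln demo/hits.tsv --catalog demo/catalog.tsv \
    --out demo/coverage.tsv --ledger demo/fates.tsv
coverage 2927.0 over 40 references (unique 1778, weighted 1149,
fallback 0, dropped 0, unaligned 73)

$ shalemeta profile --aln demo/hits.tsv --catalog demo/catalog.tsv \
    --tax demo/nodes.dmp,demo/names.dmp --min-support 207 --out demo/profile.tsv
7 taxa reported, 73 reads unassigned
```

The QC line says all 18 planted contaminants (12 short reads, 6
duplicates) were removed and nothing else. The coverage line accounts for
every aligned read: 1778 were unique best hits (each contributing 1.0),
1149 multi-mapped and were redistributed by unique-coverage weights, and
73 reads had no hit reaching the 60-bit floor — total coverage 2927.0 =
1778 + 1149. The profile holds only taxa with ≥ 207 supporting reads;
reads at thinner taxa were pushed up to supported ancestors:

```
$ head -4 demo/profile.tsv
#taxon_id  rank     name        count  lineage
#unassigned  73
8   genus    Genus_001    671  root;Superkingdom_001;...;Genus_001
12  species  Species_002  570  root;...;Genus_002;Species_002
```

Aggregating coverage by protein description at genus rank
(`shalemeta aggregate ... --rank genus`) then yields the category × taxon
matrix, e.g. `adenylylsulfate_reductase  Genus_003  13  22.24` — 13
unique reads and 22.24 total coverage of that enzyme group in that genus.

Geochemistry works the same way from TSV records:
`shalemeta geochem rock-eval`, `shalemeta geochem sulfur`, and
`shalemeta geochem classify-spectra`.

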