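# Methods

## The model

The package analyzes a single-exon coding gene segregating as two deeply
divergent allele classes within and across lineages. The working model
is: an ancestral allele (Clade I) and a derived allele (Clade II)
separated by a small set of fixed nucleotide differences (~1% of CDS
columns, most of them nonsynonymous), maintained as standing variation;
diploid genotypes form by pairing; rare crossovers between the two
alleles create mosaic haplotypes that carry ancestral states at some
diagnostic sites and derived states at others. Everything downstream —
diagnostic-site discovery, painting, proportion summaries, divergence
statistics, enrichment at ligand-binding residues — operates on this
two-clade abstraction.

Coordinates are 1-based alignment columns; the codon frame starts at
column 1 (codon of column *c* is `(c−1)//3 + 1`). `N` and `-` are
missing data, excluded per-sample from every count; each reported
proportion carries its effective denominator.

## Diagnostic sites

A column is diagnostic when each clade's major allele (among non-missing
haplotypes) reaches frequency ≥ `fixation_threshold` and the two major
alleles differ. The default threshold 1.0 demands strict fixed
differences; relaxing it (e.g. 0.9) admits near-fixed sites and makes
that choice explicit rather than baked in. Columns entirely missing in a
clade are skipped with a log line. Synonymous/nonsynonymous status is
judged against the Clade-I consensus codon; if two diagnostic sites fall
in one codon, both are labeled from the joint codon change and a warning
is emitted. Swapping the clade arguments swaps the state labels but
selects the same columns.

## Painting and classification

A haplotype's painting is its state vector over the diagnostic columns:
A = ancestral state, D = derived state, M = missing; a third allele also
paints M but increments a warning counter. Categories: `ancestral`
(no D), `derived` (no A), `mixture` (both), `unclassifiable` (no
informative site). The minimal crossover count of a vector is the number
of adjacent A–D transitions after deleting M entries; this equals the
minimum over all completions of the M sites (missing data is completed
optimistically, in the parsimony spirit of interpreting mosaics).

Diploid classification: two pure-A haplotypes → homozygote-I; two pure-D
→ homozygote-II; one of each → heterozygote; any mixture haplotype →
recombinant. For unphased samples (IUPAC-coded), a sample is called
recombinant only when no assignment of its per-site allele pairs into
two haplotypes yields two pure ones. That criterion has a closed form —
the non-missing site genotypes must be all hom-ancestral, all
hom-derived, or all heterozygous to avoid the recombinant call — which
the tests verify against the literal search over all 2^h phase
assignments. This is deliberately conservative: without phase, only
configurations that *force* a mosaic are reported as recombinant.

Lineage summaries count categories per lineage; proportions are over
classified samples (unclassifiable counted, excluded from the
denominator). The headline TSV rounds percentages to whole numbers
(round-half-even); the JSON sidecar keeps full precision.

## Divergence and dN/dS

Pairwise divergence is variant sites / compared sites × 100. Two
denominator modes exist because the phrase "variant sites / CDS length"
is ambiguous for incomplete data: `pairwise` (default) excludes columns
missing in either sequence from numerator and denominator; `full_cds`
divides by the alignment length. Reports always name the mode and both
numerator and denominator, so the convention is auditable. Percentages
print at 2 d.p., round-half-even.

NG86 counting: per sense codon, each of the 9 single-base changes is
synonymous or nonsynonymous by translation; changes producing a stop
count as nonsynonymous, so expected sites satisfy N + S = 3 × codons
exactly. Site counts are averaged between the two sequences. Observed
differences in codons differing at 2–3 positions are averaged over all
minimal mutational pathways that avoid stop-codon intermediates; when
every pathway is blocked, all pathways are used (logged in the stats
notes only through the totals — the fallback is deterministic). dN and
dS use the Jukes–Cantor correction d = −3/4·ln(1 − 4p/3); p ≥ 3/4 flags
the correction undefined, and dS = 0 flags ω undefined — the documented
behavior for all-nonsynonymous clade differences, not an error.

Branch statistics replace codon-model maximum likelihood deliberately:
Fitch parsimony reconstruction plus per-branch counting is desk-scale,
deterministic and testable against exhaustive oracles, and on
near-identical sequences its reconstructions coincide with model-based
ones at the diagnostic sites. Per-branch (nonsyn, syn) counts are
contrasted against the pooled remaining branches by a two-sided Fisher
exact test; the output makes no claim of equivalence to a
likelihood-ratio test, and published ω values from branch models are not
targets of this screen.

## Fitch reconstruction

Standard small-parsimony downpass (intersection where possible,
otherwise union with one change) on a rooted binary tree, per column;
missing leaf states are fully ambiguous {A,C,G,T}. Resolution is
top-down: the root takes the state of the designated outgroup leaf when
it lies in the root set, else the alphabetically first member; each
child inherits its parent's resolved state when possible, else applies
the same rule. Every resolution that had to fall back to the blind
alphabetical choice among >1 states is recorded as *tied*; in branch
counting, a differing column with a tied endpoint is reported as
ambiguous, counted separately, never silently assigned. Supplying an
outgroup is therefore what licenses polarizing the clade-divergence
branch.

## Ligand-related residues and enrichment

Receptor residues and docked ligand poses come from PDB-style coordinate
files (structure prediction and docking are upstream inputs, never
performed here). A residue is ligand-related when its minimum atom–atom
distance (all atoms, not Cα-only — pocket definitions in docking
practice are atom-level) to a pose is ≤ the cutoff (default 5.0 Å).
"Within the cutoff of all poses" is read literally as an intersection
over poses, but the union reading is exposed and both sets are reported,
because plain-language intent is ambiguous; likewise both two-sided and
one-sided Fisher p are reported (two-sided default). The Fisher test is
computed by direct hypergeometric enumeration in exact rational
arithmetic — the two-sided p sums probabilities ≤ the observed table's
probability with no floating-point tie tolerance — over the 2×2 table of
substitution × binding membership across all residues.

## Synthetic data

The generator emulates the study conditions, not generic sequence
evolution. Defaults: 314 codons (942 nt, the V1R2 CDS span), 11
diagnostic sites, nonsynonymous fraction 1.0, six lineages with
derived-allele frequencies {1.0, 1.0, 0.65, 0.5, 0.5, 0.0} mirroring
lake tribes fixed for one clade, polymorphic haplochromines, and
riverine lineages carrying only the ancestral allele; recombinant
fraction 0 (mosaics are a V1R6-like setting, e.g. 13 sites and
recombinant fraction ~0.1); missing rate 0.

The ancestral CDS is drawn codon-wise uniformly from the 61 sense codons
(the genes are intact single-exon CDSs, so neither allele may contain a
premature stop). Diagnostic sites are planted requirement-first: each
site is assigned synonymous or nonsynonymous up front (count =
round(fraction × n)), then a codon position capable of that change is
drawn, which makes the planted fraction exact whenever the sense-codon
pool allows it; labels are evaluated single-site against the ancestral
codon context. Crossover breakpoints are placed in distinct gaps between
consecutive diagnostic sites (only inter-diagnostic intervals are
observable in a painting), so a mosaic with *b* breakpoints paints with
exactly *b* minimal crossovers. Haplotype clade labels are i.i.d. per
lineage frequency and pairs form by random union — Hardy–Weinberg by
construction.

What the generator does **not** model: within-clade polymorphism,
coalescent/demographic structure, linkage beyond the two planted
alleles, sequencing error beyond uniform missingness, indels, or
mutation-rate calibration. Exact-recovery results on these panels
(sensitivity = specificity = 1 for site discovery, 100% classification
recovery at missing rate 0) therefore certify the algorithms, not
robustness to real-data noise; the threshold and missing-data machinery
exist precisely because real panels are messier.

## Problem sizes and numerics

The test suite and the acceptance script run desk-scale versions of each
analysis: panels of 50–900 haplotypes, CDSs of 100–322 codons, 1000
random 50-codon pairs for the NG86 oracle, exhaustive checks over all
3^L painting vectors to length 12 and all 4^4 leaf labelings of 4-leaf
trees (seeded samples on 6-leaf trees), and full hypergeometric
enumerations for table margins up to 400. Oracle comparisons use
absolute tolerance 1e-12 for NG86 (pure counting arithmetic) and 1e-7
against scipy's Fisher implementation (which applies a relative tie
tolerance ours does not). Determinism: every stochastic component takes
a numpy `default_rng` seed; the pipeline itself is seed-free apart from
recording it, and identical configs reproduce byte-identical outputs.

## Known limitations

* Diagnostic-site discovery assumes the two clades are given by
  reference haplotype lists; it does not infer clade membership de novo
  (tree inference is upstream).
* The recombinant call for unphased data cannot see mosaics whose
  genotypes are consistent with two pure haplotypes (e.g. a mosaic
  paired with its mirror image) — a fundamental identifiability limit,
  not an implementation one.
* Fitch parsimony underestimates changes on long branches and leaves
  root-adjacent polarization ambiguous without an outgroup; ambiguous
  columns are surfaced rather than resolved.
* The enrichment test treats residues as exchangeable; it ignores
  spatial autocorrelation of both substitutions and pocket residues.
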