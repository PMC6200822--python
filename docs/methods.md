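# Methods

This note documents the models and procedures implemented in `npclkit`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic-data generators do and do not emulate.

## Coordinates and sequence normalisation

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted exactly once, at the I/O boundary, and the two
conversions are inverse bijections (property-tested). Sequences are
uppercased on read and any character outside `{A,C,G,T,N,-}` becomes `N`
with a logged count, so parsed + warned always accounts for the input.
Minus-strand exons are stored 5′→3′ after reverse complement, because primer
design and alignment operate on the sense sequence.

## Local alignment (exon screening)

The aligner is a deliberate re-implementation of BLASTN's heuristic
architecture rather than a binding to an external binary, so the screening
rules are reproducible and parameter-complete:

* exact k-mer seeds (default k=11) against an index of the subject, merged
  into maximal exact diagonal runs;
* banded, affine-gap, X-drop extension from each run in both directions.
  Scoring defaults: match +1, mismatch −2, gap open −5, gap extend −2,
  X-drop 20; a gap of length *g* costs `open + g·extend` (BLAST convention).
  The band half-width is derived from `xdrop/|gap_extend|` because the
  X-drop bound also bounds how far the optimal path can drift off the seed
  diagonal;
* both subject strands are scanned; hits record identity
  (= matching columns / aligned columns), template coverage (= aligned
  template span / template length) and the full column map, from which the
  primer-conservation score is later computed.

Being banded and seeded, the heuristic score can never exceed the exact
Smith–Waterman optimum under the same scoring; the test suite asserts this,
plus identity agreement within ±0.03 on 10%-divergent pairs, against an
exact dynamic-programming oracle.

Screening thresholds follow the published protocol and are strict
inequalities: exons must be longer than 600 bp; an exon is single-copy iff
its only within-genome hit above identity 0.80 and coverage 0.50 is its own
locus (the same homology rule reused, self-hit excluded by coordinate
overlap); an ortholog is retained iff its best query-genome hit (highest
score, ties to the lower query coordinate) exceeds both thresholds. The
published protocol does not fix the aligner's word size or E-value; the
defaults above are this package's own, and all are configurable.

## Primer design

Primers are substrings of the sense template, 18–25 nt, GC fraction within
[0.20, 0.80]. Complementarity is scored in the ungapped antiparallel
ALIGN style: the maximum over relative offsets of (+1 per Watson–Crick
pair, −1 otherwise), floored at 0, with the 3′-anchored variant restricted
to offsets whose overlap includes the oligo's 3′ terminus. Thresholds are
strict: self score <6.00, self 3′ score <3.00, and mutual 3′ score of a
pair <3.00. The reverse primer is validated on its actual oligo (the
reverse complement of its template window) because the 3′-anchored score is
not strand-symmetric. Melting temperature uses the closed-form
`Tm = 64.9 + 41·(nGC − 16.4)/L`; it is reported, not filtered on, since the
protocol filters only length, GC and complementarity. Primer-pair weights
(+1/−1) put the printed thresholds on the ALIGN scale; exact Primer3
thermodynamic parity is out of scope.

Pairs must amplify 700–1200 bp. The selection score is the fraction of
identical aligned columns over the union of the two primer-binding windows
in the template↔query alignment — the simplest score that captures
"cross-genome conservation of the priming sites"; a pair whose windows are
not fully covered by the alignment is demoted below every scored pair.
Ranking is total: conservation descending, then |product − 950| ascending,
then leftmost forward start, then (forward length, reverse start, reverse
length). By default primers are searched in 200-bp windows at the two ends
of the locus and the ranked list is capped (`max_pairs=50`); exhaustive
forward×reverse enumeration over kilobase loci is combinatorially explosive
and never changes the top of the ranking. `max_pairs=None` with an explicit
window restores full enumeration (used by the brute-force oracle tests).

## Distances and rate calibration

Per-locus divergence is the overall mean pairwise distance: the mean over
all unordered sequence pairs, with sites containing `N`/`-` pairwise-deleted
per pair. The default model is the uncorrected p-distance, with JC69
(`d = −(3/4)ln(1 − 4p/3)`) and K2P (`d = −(1/2)ln((1−2P−Q)√(1−2Q))`)
selectable; the published analysis does not name its model, so transparency
was preferred over guessing. The standard error is a site bootstrap:
columns resampled with replacement (default 1000 replicates, one seed
governing all replicate draws), SE = SD of replicate means. Saturated pairs
(p ≥ 0.75 under JC69, non-positive log arguments under K2P) raise an error
by default or are dropped with a warning in `drop` mode.

The absolute rate of a locus is calibrated against cytochrome *b*:
`μ = (d_locus / d_cytb) × μ_cytb` with `μ_cytb = 0.01035`
substitutions/site/My. The calibration is linear in the numerator and
invariant under joint rescaling of both distances; its SE propagates both
bootstrap SEs through the ratio to first order. All rates are reported in
substitutions/site/My. (Note that published per-locus rates quoted as
"×10⁻⁸ per site per million years" sit numerically closer to per-year
values given this calibrator — 0.01035/site/My ≡ 1.035×10⁻⁸/site/year; the
package does not force agreement and reports /site/My throughout.)

## Supermatrix and trees

Concatenation takes per-locus alignments, uses the union of taxa in order
of first appearance, pads missing locus×taxon blocks with `-`, and emits a
RAxML-style partition table; `split_by_partition` inverts it exactly. Both
raw and gap-stripped column counts are reported, since a published
concatenation length may refer to either. Maximum-likelihood inference is
delegated by design: the module writes the RAxML-ready relaxed PHYLIP and
partition files instead of running an external binary; the in-repo tree
method is Saitou–Nei neighbor joining. NJ is deterministic (lowest-index
pair joined on equal Q), does not clamp negative branch lengths, and is
exact on additive matrices — the test suite asserts topology and branch
lengths to 1e-9 on random additive instances and cross-checks topology
against dendropy's NJ. Bootstrap support resamples supermatrix columns,
rebuilds the NJ tree, and reports the percentage of replicates containing
each split of the full-data tree; ≥70% is flagged "strong" as metadata, not
as a filter.

PCR validation matrices (success / failure / not attempted) are summarised
as success rates over attempted reactions only, overall, per marker and per
order; the universal panel keeps markers with PSR ≥ 0.80. Markers with no
attempted reactions have undefined PSR and are excluded with a warning.

## Polymorphism statistics

Inputs are phased haplotype alignments (two haplotypes per diploid
individual for nuclear loci, one for mtDNA); chromatogram assembly and
phasing are upstream of this package's contract. Per locus and population:
*S* counts columns with ≥2 distinct non-missing bases; *H* counts distinct
haplotype strings; `Hd = n(1 − Σp²)/(n−1)`; `k̂` is the mean pairwise
difference count under pairwise deletion; `π = k̂ / L_used` with `L_used`
the columns free of gaps and Ns in every haplotype (complete deletion for
the per-site normalisation — the common default of standard polymorphism
software; configurable by subsetting input columns). π is additionally
reported ×10³ for comparability with the usual display convention.

Tajima's `D = (k̂ − S/a₁)/√(e₁S + e₂S(S−1))` uses the standard constants
for sample size n and is undefined (reported NA) for monomorphic loci.

The HKA test is implemented in the one-population + single-outgroup form:
per locus *i* with per-site θᵢ, sample size nᵢ and scaled divergence time T
shared across loci,

```
E[Sᵢ]  = θᵢ Lᵢ a₁(nᵢ)            Var[Sᵢ] = E[Sᵢ] + (θᵢ Lᵢ)² a₂(nᵢ)
E[Dᵢ]  = θᵢ Lᵢ (T + (nᵢ+1)/2nᵢ)  Var[Dᵢ] = E[Dᵢ] + (θᵢ Lᵢ (nᵢ+1)/2nᵢ)²
```

The (θᵢ…, T) vector is fitted by numerical minimisation of the X² sum
(L-BFGS-B multistart polished by Nelder–Mead, moment-based initial values);
the p-value refers X² to χ² with 2L−(L+1) = L−1 degrees of freedom, so at
least two loci are required. Correctness is defined against these equations
and a coarse-to-fine grid-search oracle (agreement to 3 decimals on toy
tables), not against any particular desktop program's output. One subtlety:
joint doubling of S, D and lengths is an exactly neutral transformation
only on self-consistent tables (X² = 0); on general data the quadratic
variance terms shift the optimum slightly, so the scaling property is
asserted at a self-consistent instance.

## Synthetic data

The genome-pair simulator emulates a template/query comparison between two
distantly related genomes: ancestral exons uniform over {A,C,G,T} separated
by independent random introns; the query genome carries each surviving exon
substituted per site with probability d under a Jukes–Cantor kernel (default
d = 0.08, i.e. ortholog identity ≈ 0.92, comfortably inside the 0.80
screening threshold), with freshly drawn introns so only exons align.
Defaults are the pipeline's evaluation conditions: 50 loci of 800–1500 bp,
5 paralog duplications (copies at 5% divergence placed on a second
chromosome), and 5 loci deleted from the query genome — deletions are an
exact count by default (a per-locus probability mode exists) so the planted
truth table is deterministic. About 30% of exons are annotated on the minus
strand to exercise strand handling. A single master seed spawns per-locus
child streams, making locus subsets reproducible in isolation.

What the simulator does **not** emulate: indels inside exons, codon
structure and selection, base-composition bias, repeats and low-complexity
sequence, split exons, and assembly artefacts. Passing the truth-recovery
tests therefore demonstrates the correctness of the screening logic under
the stated divergence model, not the aligner's robustness to every feature
of real genomes.

The coalescent sampler is Hudson's neutral algorithm without recombination:
with k lineages, exponential waiting times at rate k(k−1)/2 (time in units
of 2N generations), random pair joins, and Poisson mutations at rate θ/2
per lineage per unit time, placed at distinct columns of an L-site locus
(infinite-sites; exceeding L raises an error rather than silently
recycling sites). Expectations E[S] = θ·a₁(n) and E[k̂] = θ are verified to
within 3 standard errors at 5000 and 800 replicates respectively, and the
neutral mean of Tajima's D at n=20, θ=5 falls in (−0.2, 0.2) over 2000
replicates. No recombination, migration, demography or indel evolution.

## Problem sizes used in the test and acceptance runs

Chosen as representative desk-scale settings: truth-table recovery at the
default 50-locus configuration (~85 kb per genome); aligner oracle
comparisons on ≤1 kb pairs; rate-recovery over 100 replicates of
1000-site pairwise alignments with 1000 bootstrap replicates each;
coalescent calibration at 5000/2000 replicates as above. The reference
calibration quantity (ratio calibration of identical alignments → 0.01035
substitutions/site/My) is exact by construction and independent of these
sizes.

## Known limitations

* The aligner is substitution-oriented: long indels (beyond the X-drop
  band) truncate extensions rather than bridging them; no translated
  search, chaining or repeat masking.
* Primer scoring is sequence-only (no secondary-structure thermodynamics,
  multiplexing or degenerate bases).
* The HKA implementation is the one-population + outgroup form; the
  two-species 1987 form is not implemented.
* ML tree inference is exported, not executed; NJ is a desk-scale stand-in
  for topology-level checks.
* Population statistics assume phased haplotypes; the IUPAC-expansion mode
  for unphased input assigns alleles randomly under a fixed seed and is
  explicitly approximate.
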