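# Methods

## The inference problem

A stop-codon polymorphism (SCP) is within-species variation in the position
of a gene's translation-terminating stop codon. Relative to the ancestral
state, a derived allele either *adds* coding sequence (the stop moved
downstream, converting 3′-UTR into C-terminal coding sequence) or
*subtracts* it (a premature stop). Because each gene is observed only at
the present, polarity is inferred by outgroup parsimony: the stop position
of the orthologous gene in a monomorphic sister species is taken as the
ancestral state. This is valid only when the sister gene is informative,
hence the hard exclusions: sister polymorphic in stop position, sister data
missing, or sister stop shared by no focal allele.

Three mutation classes produce additions:

- **point**: the stop triplet is substituted to a sense codon; translation
  continues in the same frame to the next in-frame UTR stop;
- **frameshift**: an indel of length ≢ 0 (mod 3) upstream of the stop
  shifts the frame so the annotated stop is bypassed;
- **deletion_fusion**: a deletion removes the stop codon and the entire
  3′ flank and lands in (or upstream of) the downstream gene in frame with
  its start codon. Fusion calls are always annotated as requiring
  transcript-level evidence: a replicated assembly error can produce
  exactly this genomic signature.

Two lengths summarize each addition. `added` is the gain in protein length
(derived − ancestral, stop codons excluded). `new` counts every residue
whose codon composition the causal mutation altered: for point events
`new = added`; for frameshifts it also includes the frameshifted residues
upstream of the old stop, counted from the codon containing the indel (an
indel inside a codon attributes that codon to `new`). Ancestral protein
length ("outgroup allele length") excludes the stop codon.

Note a selection artifact inherent to the design: frameshifts whose shifted
frame hits a stop *before* the ancestral stop are observed as subtractions
or not at all, so the observed distribution of `new` among additions is
biased upward. This is a property of the ascertainment, not of the code.

## Scan procedure

Alignment columns are used only to transfer the reference's start/stop
anchors onto each strain; all codon arithmetic happens in each strain's own
ungapped coordinates, because indels make column-triplets ill-defined.

- *Aligned-stop check*: a strain has an aligned stop iff it carries
  residues at the three reference-stop columns, those residues spell
  TAA/TAG/TGA, and they are contiguous in the strain's own sequence (an
  insertion inside the codon disrupts it). N-containing triplets never
  count as stops.
- *Walkback*: from the aligned stop, step back one ungapped triplet at a
  time to the start anchor, recording premature stops; a nonzero
  (stop − start) mod 3 implies a frameshift between the anchors.
- *Effective stop* (the allele key): the first stop in the frame
  established from the annotated start. When the walked frame equals the
  start frame this is the upstream-most walked stop (or the aligned stop);
  otherwise the scan resumes forward from the start frame. Equivalence
  with naive start-anchored translation is property-tested over ≥10,000
  random mutated sequences.
- *Allele partition*: strains group by the alignment column of their
  effective stop's first base; a gene is SCP-flagged when ≥2 distinct
  positions exist or any strain lacks an aligned stop. Strains whose start
  anchor was masked away (poly-N rule) cannot have their frame established
  and are excluded from the partition with a reason, rather than taking
  the whole gene down.
- *Singleton exclusion*: single-strain alleles are likely sequencing
  errors or strongly deleterious variants and are removed. A mutation
  fingerprint — the exact internal indel ops plus substitutions at the
  reference and allele stop triplets, relative to the reference row —
  identifies *double singletons*: strains sharing a stop position through
  independent mutations. An allele survives only if ≥2 strains share an
  identical fingerprint; minority fingerprints inside a supported allele
  are excluded individually.

## Built-in aligner

The default aligner is a reference-anchored star alignment: every strain is
globally aligned to its species' reference with affine gap scoring (match
+1, mismatch −1, gap open −4, gap extend −1; Bio.Align.PairwiseAligner),
and the pairwise alignments are merged over reference coordinates with
insertion columns sized to the longest insertion observed at each position.
This is deterministic, dependency-free, and effectively exact for the
near-identical within-species families this pipeline consumes; for deeply
diverged inputs an external aligner should be plugged in through the
`AlignerContract` (FASTA in, FASTA out).

Edge cleanup iterates (default max 10 rounds): rows with trailing gaps or
no reachable in-frame stop are extended 3′-wards in 150-nt granules via a
caller-supplied flank source and the family realigned; when no flank
remains, edges are pruned to the outermost residue-only columns. A row
still lacking an in-frame stop excludes the gene ("no in-frame stop"). The
150-nt granule mirrors the initial 3′-UTR window; the prune rule
(trim-to-common-support) is our reading of an under-specified step.

The quality filter counts internal gap characters (gaps not in a run
touching a row edge) plus N characters; the gene is excluded when the count
exceeds 25% of total cells (rows × columns). The denominator is
configurable (`cells` | `columns`) because the prose rule is ambiguous;
`cells` is the default since gap/N counts are summed over all rows. The
threshold is a strict ">": exactly 25% passes.

## Translation evidence

Footprint density = (mean per-nucleotide hits over the ORF) ÷ mRNA
abundance, normalized per replicate and then averaged (the alternative
order is not distinguishable from published descriptions; this one is
fixed here). Tier boundaries: strong > 0.03; moderate (0.015, 0.03]; low
(0.005, 0.015]; none ≤ 0.005 — the outer bounds are strict as printed, and
interior boundary values are assigned to the lower tier. Literature
evidence enters as a curated TSV and combines with the ribosome call as a
join (max) on the ordered scale none < low < moderate < strong.

The readthrough null for a gene counts codons from its stop to the next
in-frame stop within the annotated 3′-UTR boundary, both stops excluded;
genes with no in-frame UTR stop before the boundary are excluded from the
null distribution rather than assigned a censored value.

## Statistics

- G-test of independence: G = 2·Σ O·ln(O/E) with margin-derived
  expectations (0·ln 0 = 0), chi-square tail with (r−1)(c−1) df. No
  Williams or continuity correction by default — this reproduces the
  printed p = 0.0009 for the 9:45 vs 19:20 class-ratio table — but a
  Williams toggle is provided.
- Geometric mean and 95% CI: computed on natural logs and
  back-transformed; CI uses the t quantile with n−1 df. Extension lengths
  are approximately lognormal, which motivates the log scale.
- Two-sample t-test on log lengths: pooled-variance Student form by
  default (Welch by flag); the choice matters little at the sample sizes
  involved and the published flavor is unstated.
- Monophyly: a strain set is monophyletic iff it is one side of some edge
  bipartition of the unrooted strain tree; trivial splits count. Checked
  against exhaustive bipartition enumeration in tests.

## Synthetic cohorts

The simulator emulates the survey's input geometry: two species (defaults
38 and 35 strains plus a reference each), one locus per gene consisting of
an ORF (default 120 codons, ATG start, single in-frame stop, no internal
in-frame stop) and a 150-nt 3′-UTR guaranteed to contain an in-frame stop
(so readthrough lengths are finite), with GC content 0.40 and per-site
neutral substitution probability 0.002 per strain — of the order of the
polymorphism density in the real strain panels.

Two deliberate idealizations keep planted events exactly recoverable and
the truth table exact:

1. Neutral substitutions are rejection-sampled so they never create or
   destroy a stop codon in *any* reading frame anywhere in the locus. Every
   carrier of a planted event therefore realizes the identical derived
   protein, and clean loci can never drift into SCP status.
2. Indels are planted only at positions where gap placement is
   unambiguous (the inserted/deleted base differs from both neighbours),
   and the locus is shielded from substitutions for indel-event genes, so
   the aligner recovers the exact planted columns.

Realized `added`/`new` values are measured from the constructed sequences
by brute-force translation and recorded in the truth table; truth invariants
(`new ≥ added`, point ⇒ equality, singleton events have one carrier) are
property-tested. Per-gene RNG substreams are derived from (seed, gene
index, attempt), so cohorts are reproducible and individual loci can be
regenerated in isolation.

What passing simulator-based tests does **not** show: robustness to real
indel evolution, alignment ambiguity in repeats, demography/linkage
(strains are exchangeable here), introns (input must be intronless; the
real survey removed two intron artifacts manually), base-calling error
models beyond the planted kinds, or diverged orthology. The negative
control (zero planted events ⇒ zero SCP flags) and the 100%-recovery
round-trip are statements about this idealized generative model.

## Catalog-row pair synthesis

The classifier round-trip (and the acceptance script) constructs, per
catalog row, an ancestral/derived pair realizing the recorded
(outgroup length L, added a, new n, class) exactly. Outside the causal
mutation the sequence is drawn from {A, C, G} — with no T no stop codon can
arise in any frame — and the required stops are then placed: the ancestral
in-frame stop at codon L, and for frameshift rows a shifted-frame stop
positioned so a 1-nt deletion at codon boundary k = L + a − n yields a
derived protein of L + a codons with n new residues. A 1-nt deletion (not
insertion) is used because an insertion cannot realize a = 1: the derived
codon straddling the old stop would have to begin with the stop's final
base. Fusion rows delete from codon k through the whole flank into a
downstream ORF constructed to supply the remaining length in frame.

## Defaults and knobs

| Parameter | Default | Meaning |
| --- | --- | --- |
| `quality_threshold` | 0.25 | max internal gap+N fraction (strict >) |
| `quality_denominator` | cells | denominator of that fraction |
| `utr_window` / `flank_granule` | 150 nt | initial 3′-UTR window, extension step |
| density tiers | 0.03 / 0.015 / 0.005 | evidence boundaries (hits/nt per unit mRNA) |
| aligner scores | +1 / −1 / −4 / −1 | match / mismatch / open / extend |
| `max_iter` (edge cleanup) | 10 | extend-and-prune rounds |
| `sub_rate` (simulator) | 0.002/site | neutral substitution probability |

## Known limitations

- The star alignment assumes one sensible reference per family; families
  without a reference fall back to the first sequence.
- Multi-allele genes yield one catalog row (longest well-supported
  addition); the events TSV lists every polarized allele individually.
  Ambiguous second events of three-or-more-allele genes are reported with
  certainty "ambiguous" and kept out of headline counts.
- Fusion detection requires a downstream-ORF annotation; without it a
  fusion-like deletion fails classification loudly rather than being
  silently mislabeled.
- Genome-wide funnel counts from the published survey depend on external
  genome, resequencing and footprint data and are not recomputed here; the
  funnel machinery itself is exercised on synthetic cohorts.
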