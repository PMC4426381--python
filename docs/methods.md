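# Methods

## Scope and model of the data

The package analyses variant calls made for two inbred parental lines
(and optionally a third cultivar) against one reference assembly.  Its
units of work are: a variant call with GATK-style site annotations, a
stranded gene model with exon/CDS intervals, a fixed window grid over
the genome, and an RNA-seq coverage track.  Assumptions baked into the
pipeline:

* **Inbred lines are effectively homozygous.**  Heterozygous calls are
  therefore treated as sequencing/mapping artifact candidates: they are
  kept in the record stream and counted in density scans (where they
  are harmless), but excluded from the frameshift audit and from marker
  selection.
* **Coordinates.**  Internally everything is 0-based half-open; VCF and
  GFF3 positions are converted at the file boundary.  A variant belongs
  to the window containing its (normalised) start position.
* **One edit at a time.**  The frameshift audit evaluates each InDel in
  isolation against the reference gene model; genes with several
  candidates are flagged, not haplotype-combined.

## InDel normalisation

VCF permits many representations of the same edit inside repetitive
context.  `normalize_indel` right-trims the allele pair, left-extends
through the repeat while the edit stays sequence-equivalent, then
trims the shared prefix (the standard left-align/parsimony algorithm).
The invariants that matter — applying the raw and the normalised record
yields identical chromosomes, and normalisation is idempotent — are
property-tested, and every downstream stage consumes normalised
records, so verdicts are invariant under representation change.

## Hard filtering

Thresholds (defaults): site depth DP > 100 fails (`max_depth`);
QD < 2 (`min_qd`); FS > 60 (`max_fisher_strand`); MQ < 40 (`min_mq`);
ReadPosRankSum < −8; MQRankSum < −12.5.  Bounds are strict, so a value
exactly at a threshold passes.  An absent annotation passes its filter
— the rank-sum statistics are undefined for sites without both allele
classes, and failing them by absence would discard most hom-alt sites.
Depth is interpreted at site level.  Filtering precedes the genotype
screen in the cascade.

## Density scans and window annotation

Windows are fixed and anchored at 0 (not sliding), which keeps count
conservation exact: window counts sum to input counts at every grid
size, and a 1-Mb count equals the sum of its two 0.5-Mb halves.
Gene-rich windows require *strictly more than* `min_genes` (default 50)
gene starts per 0.5 Mb; using starts avoids double counting.  Each
window also carries its N-base fraction; windows above 0.5 are flagged
as assembly gaps so that zero-polymorphism windows over gaps are not
mistaken for conserved sequence.  Per-chromosome linear densities are
reported relative to the maximum-density chromosome.

## Introgression segments

Per line, windows at or above a density threshold seed segments; seed
runs separated by at most `merge_gap` (default 1) intervening windows
merge; gap-flagged windows never seed and longer gap runs break
segments.  Classification works on the union of both lines' segment
footprints using per-line genome-wide medians:

| class                | low-divergence line A  | high-divergence line B         |
|----------------------|------------------------|--------------------------------|
| `reference_from_wild`| ≥ 5,000 SNPs/Mb        | ≤ 0.1 × median (its floor)     |
| `reference_divergent`| ≥ 5,000 SNPs/Mb        | ≥ 2 × median                   |
| `lineA_specific`     | ≥ 5,000 SNPs/Mb        | near its background            |
| `lineB_divergent`    | below threshold        | ≥ 2 × median                   |

The absolute 5,000 SNPs/Mb anchor for line A and the relative (2×
median, 0.1× median) rules for line B reflect that the wild parent's
background is itself high and variable, while the cultivated parent's
peaks sit near a reproducible absolute level.  The both-high class is
reported with a note that an introgression arising in one line and
transferred to the other is an equally consistent reading.  A third
line is "concordant" when elevated over at least half of the segment's
windows; it is recorded, never used to change the class.  An optional
Jaccard overlap of variant positions between lines is reported as a
descriptive statistic only — allele-identity sharing is not part of the
classification rule.

## The frameshift audit

Candidates are InDel×gene pairs from two routes, union taken: the
frame rule (normalised footprint intersects a CDS interval and the
length change is not a multiple of 3) and an upstream
effect-prediction "frameshift" tag when the VCF is annotated.  The
cascade then applies, in order: homozygosity; expression (maximum exon
coverage ≥ 200 — the value 200 itself passes, per the
"< 200 → nondetectable" rule); the pseudo-frameshift screen; impact
classification.  Stage counts are non-increasing and terminal buckets
partition the candidates.

**Pseudo-frameshift detection** is decided by one fact: after applying
the edit to the chromosome, projecting the exon boundaries through the
edit, re-splicing and translating (strand-aware, to the first stop),
does the mutant protein differ from the reference protein?  Context
labels explain pseudo calls and are assigned by priority:
`outside_cds_after_normalization` (the left-aligned edit no longer
touches the CDS — the classic neighbour-identical base at an exon
border), `inframe_after_normalization` (net CDS length change ≡ 0 mod
3), `border_artifact` (at a start/stop codon or exon–intron border),
and `protein_unchanged` as the catch-all — reached in practice by
edits downstream of an internal stop codon in partial or mis-predicted
gene models.  Verdicts are withheld for incomplete models (no start
codon, no terminal stop, or CDS length not a multiple of 3).  An edit
that changes a splice donor/acceptor dinucleotide is flagged
`splice_disrupted` but still audited on the naively projected CDS; no
re-splicing model is attempted.

**Impact classes** for genuine frameshifts, with `d` the first
differing residue, `L` and `M` reference and mutant lengths, and a
terminus fraction of 0.25: `truncated_major` if M < 0.5·L ("missing
most of the protein" — 0.5 chosen to separate "most" from the ~25 %
terminus categories); `extended_C_terminal` if M > L and d in the last
quarter; `altered_C_terminal` if d is in the last quarter;
`altered_N_terminal` if a common suffix covers at least three quarters
with differences confined to the first quarter; otherwise
`truncated_major`.  Note a single frameshift cannot re-synchronise the
reading frame, so `altered_N_terminal` arises only from annotation
artifacts or curation, not from the edit model itself; homology-based
rescue of such cases is represented only as a free-text curation
column.

**Cross-accession sharing** is identity matching: an accession carries
the audited variant iff it has a normalised InDel with the same
(chrom, pos, ref, alt).  A different InDel in the same gene does not
count.

## Marker design

Homozygous InDels of 10–350 bp qualify (10 bp mirrors the smallest
size-marker practical on a 3 % agarose gel; 350 bp keeps products
small).  An amplicon of ~150 bp (at least 30 bp flanks) is centred on
the InDel; allele sizes differ by exactly the signed InDel length.
Flanks that are > 80 % one nucleotide are flagged `low_complexity`,
flanks containing N `near_gap`.  `gel_resolvable` requires ≥ 10 bp
size difference and products ≤ 500 bp; only resolvable candidates are
emitted.  No melting-temperature or dimer modelling is done — flank
sequences are exported verbatim for external primer tools.

## The synthetic study

Defaults are the study conditions, not tuning knobs:

* 3 chromosomes × 5 Mb (keeps the full pipeline under a minute while
  leaving ≥ 10 windows per chromosome and ~2,000 genes); euchromatic
  arms are the outer 1.5 Mb per side, at 120 genes per 0.5-Mb tile
  versus 5 in the pericentromere.
* background change rates 1/1,100 bp (line A) and 1/111 bp (line B);
  InDels are 1/6 of changes (the observed SNP:InDel ratio of a
  low-divergence cultivar comparison is ≈ 5:1), enriched 3× in
  gene-rich tiles with the per-chromosome background mass renormalised
  so realized densities match the nominal rates; heterozygous artifact
  fraction 2 %.
* InDel lengths geometric (p = 0.35) truncated at 326 bp — the cap
  mirrors the largest insertion such short-read studies detect, as a
  bound, not a target.
* four planted segments, one per pattern class, window-aligned at the
  default scale (line A peaks at 6,000–12,000 SNPs/Mb; line B peak at
  25,000 vs its ≈ 7,500 background; the wild-introgression segment
  drops line B to ≈ 300 SNPs/Mb); gap runs of 0.4, 0.2 and 1.6 Mb.
* the frameshift plan plants, per line: 5 genuine frameshifts with
  target impact classes, one pseudo of each reason, 6 heterozygous and
  5 silent-gene candidates (cascade truth 20 → 14 → 9 → 5).  Genuine
  edits are verified at plant time by transcript-level simulation
  (independent of the audit's genomic projection path) and re-drawn
  until the realized impact class matches the target.  The
  `protein_unchanged` category is hosted by genes deliberately given an
  internal stop codon, emulating partial/mis-predicted annotations.
  Stop-codon-anchored constructions (border and in-frame pseudo
  categories) are hosted on plus-strand genes; all other categories use
  both strands.
* background InDels are excluded from CDS footprints (raw *and*
  left-aligned) and from the reserved marker region, so the audit and
  marker truths are exact by construction; background SNPs are
  unrestricted.  Expression maxima force one silent host to exactly
  199 and one expressed host to exactly 200 so the threshold edge is
  always represented.

What the generator does **not** emulate: read-level errors and mapping
artifacts (hets are planted directly, not arising from misalignment),
repeat structure and real codon usage, transcript isoforms, segmental
duplications, and LD between variants.  Passing tests therefore show
the *logic* of filtering, windowing, classification, translation and
design is correct under the stated statistical structure — not that the
thresholds are optimal for any particular real dataset.

## Numerical and degenerate-input choices

* Ties in relative chromosome density are broken by chromosome order.
* The last window of a chromosome may be short; densities are per-Mb
  normalised by actual window length.
* Empty variant streams: window counts are all zero; relative density
  requires at least one variant (error otherwise); an empty VCF yields
  an all-zero cascade table.
* Normalisation at the chromosome start stops extending at position 0.
* Amplicons too close to a contig end are an error; such InDels are
  silently skipped by the bulk designer.
* Acceptance-style checks run at these problem sizes: the default
  3 × 5 Mb study; a 2 × 2 Mb study for the 10-seed cascade-closure
  loop; gene-free 3 × 5 Mb studies for the 20-seed introgression loop;
  a 200-candidate frameshift panel for the oracle-equivalence check.

## Known limitations

* The pseudo/genuine verdict ignores splice-site semantics beyond the
  disruption flag; a frameshift that also destroys a donor site is
  audited on the naive projection.
* Terminal codons are located from the ends of the terminal CDS
  segments; a start or stop codon split across a splice junction would
  be approximated (flagged via the usual border padding).
* The accession matrix requires calls against the same reference and
  contig names; no liftover is attempted.
* Segment boundaries inherit the window grid: sub-window precision of
  real breakpoints is not recovered.
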