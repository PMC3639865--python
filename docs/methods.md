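# Methods

## Scope and model

`gstyper` implements the computational spine of a two-pool, 17-amplicon
fusion-primer HLA typing assay at desk scale. Reads are assumed to be
instrument-delivered FASTA beginning at the 10-bp multiplex identifier
(adapter already removed) and long enough to cover a whole amplicon, so a
reverse-orientation read is simply the reverse complement of the amplicon
with its own MID prefixed. Quality values do not exist in this format and
are not modelled.

Genotype calling follows the layer model of amplicon typing software. The
core assumption is *clonality*: each read derives from one template
molecule, so phase is exact within a read, and a diploid locus yields at
most two distinct true sequences per amplicon. Calling reduces to: partition
reads into usable vs artefactual, collapse usable reads into ≤ 2 haplotype
consensus sequences per amplicon, and enumerate all allele pairs that match
every consensus with zero mismatches. Phase *between* amplicons is not
observable (the amplicons do not overlap), so allele pairs related by
exon shuffling are deliberately both reported; the MM3/MM4 phase-layer
counts make that residual ambiguity visible rather than hiding it.

## Reference database and panel

The reference is a deterministic synthetic construction (`gstyper.mockdb`,
fixed internal seed), not a copy of any public database: two random gene
backbones (class I: 17 features, exon 2 = 270 bp; class II: 9 features)
carry planted variants that realise the scenarios the caller must handle —
intron-only null/low alleles, a 6-bp exon-deletion null, a null variant
under a primer footprint, intra-exon and inter-exon cis/trans quartets, a
5-bp C homopolymer at an exon 4 start, DRB paralogues with locus-signature
variants, and a DRB pseudo-locus ≥ 8 differences from every functional
allele. Generating the reference in code keeps it byte-reproducible and
lets tests derive expected sequences from the same coordinates; the
annotated-FASTA dialect (reader and writer, byte-stable round trip) is the
interchange format for user-supplied databases. Feature *absence* is an
explicit state: a missing intron behaves as a wildcard in matching, never
as an empty string. The main class I loci carry 8–11 alleles; accessory
loci (DRB3/4/5, pseudo-locus, DQB1, DPB1) carry 2–5, enough to exercise
co-amplification, sub-binning and wildcard behaviour without inflating
pair-enumeration cost.

The panel mirrors the published assay's structure (same locus/exon rows,
pool membership and pooling factors: 0.5 / 1 / 6; short pool = the 5
shortest amplicons) with primer footprints re-positioned onto the synthetic
gene models; primer lengths match the original position spans. Primer
overhangs into coding sequence (DQB1 exon 2: 9 bp / 3 bp; DQB1 exon 3:
20 bp; DRB exon 2 reverse: 21 bp) are modelled as *masked* exon bases:
primer-derived, always showing the reference base, excluded from mismatch
counting. Consequence, stated rather than hidden: a variant under the
generic DRB reverse primer (the DRB1\*03:68N-style null) is undetectable
and the allele is retained in the ambiguity string with a warning. 24 MIDs
(pairwise Hamming ≥ 3) are packaged so a 20-sample validation run fits in
one simulated run.

## Library-prep computations

Signals are fit against the 8-point 0–100 ng/µl standard series by ordinary
least squares; QC passes iff r² > 0.98 (a flat signal scores r² = 0: it
carries no calibration information). Concentration converts to molarity
with the standard 660 g·mol⁻¹·bp⁻¹ average double-stranded base-pair mass
(configurable). Pool volumes are `factor × base_molecules / (molecules/µl)`
with base 1×10⁹ molecules and are never rescaled; a volume above
`max_volume` (default 20 µl) flags the amplicon for re-amplification, and a
zero-concentration amplicon is carried as `failed`, not dropped. The final
dilution target (5×10⁵ molecules) is plan metadata.

## Synthetic run generator

The generator defines the study conditions; its defaults are fixed and the
acceptance run uses them unchanged.

* **Genotypes** — per sample and locus, one allele uniform from the locus,
  homozygous with probability 0.103 (the validation-panel composition),
  otherwise a distinct second allele.
* **Depth** — reads per (sample, amplicon) ~ negative binomial with mean
  `mean_depth × pooling_factor` (×1.4 emulsion-PCR efficiency boost for
  short-pool amplicons) and dispersion 10; occasional low draws below the
  20-read threshold are the intended no-result pathway, not a defect.
* **Errors** — substitutions at 0.1%/bp; homopolymer ±1 indels per run of
  length L ≥ 3 with probability 0.005·(L−1), boosted 3× in reverse reads
  for runs near the exon 5' start so the direction-aware consensus rule is
  actually exercised. The platform's published error rates are not
  quantitative enough to pin these; both are config, chosen as
  field-typical, and stated here rather than tuned.
* **Artefacts** — 5% of DRB exon 2 reads come from the pseudo-locus; 2% of
  DRB1-derived DRB exon 2 reads are single-crossover chimeras with a
  DRB3/4/5 haplotype (uniform break point inside the exon).
* **Fidelity limits** — MID and primer bases are emitted error-free
  (demultiplexing loss is not a quantity under study here), reads always
  span the full amplicon, and no flowgram/quality simulation is attempted.
  Passing tests therefore demonstrate correct *algorithmic* behaviour under
  a realistic error structure, not performance on real 454 data; in
  particular real runs lose ~35% of raw reads to filters this format
  cannot express.

Templates carry the primer (reference) sequence over both primer
footprints, because PCR products do: template variation under a primer is
erased by amplification.

## Numerical and algorithmic choices

* **Alignment** — mismatch counts are unit-cost edit distances with free
  end gaps on the query's flanks (reference overhang free), computed by
  edlib; a brute-force DP oracle in the test suite pins the semantics.
  Equal-length comparisons use a capped Hamming fast path.
* **Layering** — a read is master iff its best core alignment over the
  locus's alleles (the whole co-amplified group for DRB) is ≤ 4 mismatches
  (default): large enough to keep ~3-substitution reads, small enough to
  reject the ≥ 8-difference pseudogenes. Chimera deactivation splits the
  covered exon at its midpoint and deactivates reads whose halves
  best-match different DRB loci (each half within 2 mismatches of its
  best).
* **Clustering** — exact-sequence grouping; variants differing from a
  larger cluster only in homopolymer run lengths merge into it. At a
  disputed run, a direction with unanimous reads wins; if both directions
  are unanimous but disagree, forward wins (documented tie-break); else
  read-count majority. Clusters under 10% of master reads drop as noise;
  a surviving third cluster sets the review flag. Lane order is read-count
  descending with lexicographic tie-break for determinism.
* **Calling** — pairs are enumerated exhaustively (loci here hold ≤ 11
  alleles); compatibility requires a zero-mismatch perfect matching of
  clusters to the two alleles at every amplicon, a single cluster matching
  both. `min_reads` (default 20) per amplicon gates a result; below it the
  locus is `no_result`. With no zero-mismatch pair, the best pair is
  reported with its mismatch count under `review` (novel-variant path) —
  a wrong silent call is never produced.
* **Phase layers** — for a candidate pair, clusters are relabelled so the
  zero-mismatch assignment is lane-consistent; MM is the total under the
  better global lane mapping, MM3/MM4 re-score with the exon-3/exon-4
  amplicon's mapping swapped while exon 2 stays fixed. Fewer than two
  amplicons: not applicable.
* **Null exclusion** — in `exon_plus_flank` mode (default retained flank:
  10 bp, capped by primer geometry) candidates must also match the intron
  flanks; removed alleles are recorded with the discriminating feature
  (e.g. `intron2`). An ABSENT intron is a wildcard, so alleles with
  unannotated introns are never excluded on missing evidence; suffixed
  alleles that survive get an explicit retention warning. In `exon_only`
  mode no exclusion happens.
* **Unphased comparison** — the Sanger-style count superposes the two
  haplotypes into IUPAC codes over the exons a generic SBT kit covers
  (A/B: 2–4, C/DQB1: 2–3, DRB/DPB1: 2), on the same informative spans the
  clonal assay sees (Sanger runs on the same PCR products, so primer-masked
  bases are invisible to both). This guarantees unphased ≥ phased on every
  input. Length-discordant haplotypes (exonic indel) compare structurally.
  Ambiguity counts are counts of distinct 4-digit genotype *pairs*.

## Validation harness and problem sizes

The end-to-end check types 20 simulated samples at the three class I loci,
mean depth 200 reads/amplicon (~45k reads), default error model, fixed
seed, in `exon_plus_flank` mode — a desk-scale analogue of a multi-run
clinical validation, sized to finish in seconds on one CPU. Expected
outcome, asserted by the acceptance test and recomputed by
`scripts/acceptance.py`: zero mistypings and 100% concordance over loci
with a result, where *correct* means the true 4-digit pair is contained in
the reported ambiguity string. DRB co-amplification, chimera deactivation
and pseudogene routing are validated separately at smaller scale because
accessory-locus depth, not correctness, dominates there.

## Known limitations

* Phase between amplicons is unmodelled and unmodellable with non-
  overlapping amplicons; inter-exon shuffled pairs stay in the string.
* The homozygous-by-dropout failure mode is real: an allele missing a
  required feature yields no reads and the locus looks homozygous for the
  partner (demonstrated with the DPB1 allele lacking intron 2 annotation).
* Copy-number of DRB3/4/5 is not modelled; accessory loci are called only
  on cluster evidence.
* Thresholds (fail threshold 4, cluster fraction 0.10, min reads 20, flank
  10 bp) are defaults with stated rationale, not fitted quantities; the
  original software's internal criteria are not public.
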