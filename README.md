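# gstyper

Desk-scale re-implementation of an automated amplicon-NGS HLA class I/II
genotyping workflow, for people who want to study, test or teach the
*computational* side of sequence-based HLA typing without a sequencer:
library-prep normalisation math, MID/primer demultiplexing, exon-boundary
trimming, layered read-to-allele genotype calling with 4-digit ambiguity
strings, intron-based null-allele exclusion, and the phased-vs-unphased
ambiguity-reduction metric — exercised end to end on simulator-generated
reads against a packaged synthetic allele reference.

## The problem and the method

High-resolution HLA typing must name, for each locus (HLA-A, -B, -C, -DRB1,
-DRB3/4/5, -DQB1, -DPB1), the pair of alleles a sample carries, at 2-field
("4-digit", protein-level) resolution. Unphased Sanger sequencing reads both
chromosomes at once, so heterozygous positions appear as IUPAC mixtures and
many allele pairs are equally consistent with the trace (cis/trans
ambiguity). Clonal amplicon sequencing reads single molecules: phase within
each read is known, which collapses most of that ambiguity and lets intron
flanks separate non-expressed (suffix N) alleles from their expressed
twins.

The pipeline mirrors a 17-amplicon fusion-primer assay on a pyrosequencing
platform:

1. **libprep** — signals from an 8-point standard series (0–100 ng/µl) are
   fit by OLS (QC: r² > 0.98), translated to ng/µl, converted to
   molecules/µl via `c·10⁻⁹/(L·660)·N_A`, and drawn into two pools
   (short/long) with per-amplicon pooling factors (0.5 for the five shortest
   amplicons, 6 for generic DRB exon 2, 1 otherwise) at 1×10⁹ molecules per
   factor-1 amplicon.
2. **preprocess** — reads of structure `MID + primer + template` are
   assigned by *exact* 10-bp MID and primer match (reverse reads are
   recognised by the reverse-complemented reverse primer and re-oriented),
   then trimmed at the exon/intron boundary: the 3' cut point is
   `MID + primer + distance-to-exon + exon + offset`, keeping the complete
   exon and, optionally, a retained intron flank.
3. **genotyper** — per amplicon, reads are partitioned into *master*
   (≤ 4 mismatches to some allele of the locus), *failed* (pseudogene or
   error-laden) and *deactivated* (DRB1×DRB3/4/5 crossover chimeras) layers;
   master reads form ≤ 2 haplotype clusters, merging homopolymer-length
   variants with a direction-aware consensus (an error-free forward
   direction corrects reverse-direction homopolymer miscalls, the classic
   C₅ trouble spot at an exon start). Every allele pair with a
   zero-mismatch cluster assignment at every amplicon enters the candidate
   list; the deduplicated 4-digit pair list is the **ambiguity string**.
   Phase-layer counts MM3/MM4 show the mismatches the swapped exon-3/exon-4
   assignment would incur; in `exon_plus_flank` mode candidates whose intron
   flank conflicts with the observed flank consensus (e.g. an intron-2 null
   variant) are excluded and recorded.
4. **metrics** — the unphased (Sanger-style) ambiguity count superposes the
   two haplotypes into IUPAC codes per covered exon and counts all
   consistent pairs; `100·(unphased − phased)/unphased` is the ambiguity
   reduction.

The reference database, the Table-like panel and the GS-style reads are all
synthetic (deterministically generated; see `gstyper.mockdb` and
`docs/methods.md`), engineered to contain the clinically interesting cases:
intron-only null/low-expression alleles, a 6-bp exon-deletion null, a null
hidden under a primer, cis/trans quartets, co-amplified DRB paralogues and
pseudogenes.

## Worked example

```python
from gstyper import (load_packaged_database, load_packaged_panel,
                     simulate_genotypes, type_run, concordance)
from gstyper.simulate import ErrorModel, simulate_reads

db = load_packaged_database()
panel = load_packaged_panel(db)
truth = simulate_genotypes(db, n_samples=4, homozygote_rate=0.103, seed=11,
                           loci=["A", "B", "C"], mids=sorted(panel.mids))
run = simulate_reads(truth, panel, db, mean_depth=200,
                     error_model=ErrorModel(), seed=11)
report = type_run(run.reads, panel, db, run.association, loci=["A", "B", "C"])

call = report["samples"]["S01"]["loci"]["A"]
print("truth   :", truth.genotypes["S01"]["A"])
print("status  :", call["status"])
print("called  :", call["ambiguity_string_4digit"])
print("excluded:", call["excluded_null_alleles"])
print("phased/unphased ambiguities:", call["n_phased_4digit"], "/",
      call.get("n_unphased_4digit"))
print("overall :", concordance(report, truth).overall)
```

prints

```
truth   : ('A*01:01:01:02N', 'A*01:02')
status  : called
called  : ['A*01:01N+A*01:02']
excluded: [['A*01:01:01:01', 'intron2']]
phased/unphased ambiguities: 1 / 2
overall : {'total': 12, 'no_result': 0, 'correct': 12, 'mistyping': 0, 'concordance_pct': 100.0}
```

Sample S01 truly carries the *non-expressed* A\*01:01:01:02N: exon sequence
alone cannot separate it from the expressed A\*01:01:01:01, but the observed
intron-2 flank matches the null variant, so the expressed allele is the one
excluded (`intron2`) and the call is the single correct 4-digit pair —
Sanger superposition would have left 2 possibilities. Across the 4 samples
and 3 loci, every true genotype is contained in the reported ambiguity
string (100% concordance, 0 mistypings).

A CLI wraps the same stages (`gstyper simulate | libprep | preprocess |
type | concordance | run-all`); try
`gstyper run-all --help`.

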