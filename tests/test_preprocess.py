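import pytest

from gstyper.panel import revcomp
from gstyper.preprocess import (
    Read,
    TooShortError,
    build_run_report,
    demultiplex,
    read_association_file,
    read_fasta,
    trim_read,
    write_association_file,
)
from gstyper.simulate import write_fasta


@pytest.fixture()
def assoc(panel):
    return {"S01": "MID01", "S02": "MID02"}


def _synthetic_read(panel, db, mid_id, amp_id, direction="F"):
    amp = panel.by_id(amp_id)
    template = amp.template(db.get(amp.reference))
    mid = panel.mids[mid_id]
    body = template if direction == "F" else revcomp(template)
    return Read(f"read-{amp_id}-{direction}", mid + body)


def test_exact_match_assignment(db, panel, assoc):
    read = _synthetic_read(panel, db, "MID01", "A-ex2")
    result = demultiplex([read], panel, assoc)
    assert list(result.bins) == [("S01", "A-ex2", "F")]


def test_reverse_reads_detected_and_binned(db, panel, assoc):
    read = _synthetic_read(panel, db, "MID02", "C-ex3", "R")
    result = demultiplex([read], panel, assoc)
    assert list(result.bins) == [("S02", "C-ex3", "R")]


def test_single_mid_mismatch_rejected(db, panel, assoc):
    read = _synthetic_read(panel, db, "MID01", "A-ex2")
    flipped = ("A" if read.seq[0] != "A" else "C") + read.seq[1:]
    result = demultiplex([Read(read.id, flipped)], panel, assoc)
    assert not result.bins
    assert result.unassigned[0][1] == "no-MID"
    # the fuzzy opt-in mode recovers it
    fuzzy = demultiplex([Read(read.id, flipped)], panel, assoc, max_mismatches=1)
    assert list(fuzzy.bins) == [("S01", "A-ex2", "F")]


def test_primer_mismatch_rejected(db, panel, assoc):
    read = _synthetic_read(panel, db, "MID01", "A-ex2")
    seq = read.seq[:10] + "TTTTTTTT" + read.seq[18:]
    result = demultiplex([Read(read.id, seq)], panel, assoc)
    assert result.unassigned[0][1] == "no-primer"


def test_read_conservation(db, panel, clean_run):
    run = clean_run["run"]
    demux = demultiplex(run.reads, panel, run.association)
    assert demux.assigned_count + len(demux.unassigned) == len(run.reads)
    assert len(demux.unassigned) == 0  # zero error rate -> nothing rejected
    # empty input conserves trivially
    empty = demultiplex([], panel, run.association)
    assert empty.assigned_count == 0 and not empty.unassigned


def test_duplicate_mid_in_association_rejected(db, panel):
    with pytest.raises(ValueError, match="duplicate"):
        demultiplex([], panel, {"S01": "MID01", "S02": "MID01"})


def test_trim_modes(db, panel):
    amp = panel.by_id("A-ex2")
    read = _synthetic_read(panel, db, "MID01", "A-ex2")
    allele = db.get(amp.reference)
    exon = allele.feature("exon2")
    assert trim_read(read, amp, "F", "exon_only") == exon
    flanked = trim_read(read, amp, "F", "exon_plus_flank", 10)
    assert flanked == allele.feature("intron1")[-10:] + exon + allele.feature("intron2")[:10]
    # reverse orientation trims to the same forward-oriented sequence
    rev = _synthetic_read(panel, db, "MID01", "A-ex2", "R")
    assert trim_read(rev, amp, "R", "exon_plus_flank", 10) == flanked


def test_trimming_never_removes_exon_bases(db, panel, clean_run):
    run = clean_run["run"]
    truth_by_id = run.truth_by_id()
    demux = demultiplex(run.reads, panel, run.association)
    for (sample, amp_id, direction), reads in demux.bins.items():
        amp = panel.by_id(amp_id)
        for read in reads[:3]:
            allele = db.get(truth_by_id[read.id]["allele"])
            covered = allele.feature(amp.exon_feature)[
                amp.cov_lo - 1 + amp.masked_prefix : amp.cov_hi
            ]
            assert covered in trim_read(read, amp, direction, "exon_plus_flank")


def test_too_short_read_rejected(db, panel):
    amp = panel.by_id("A-ex2")
    with pytest.raises(TooShortError):
        trim_read(Read("tiny", "ACGTACGTACGTACG"), amp, "F")


def test_run_report_fields(db, panel, clean_run):
    run = clean_run["run"]
    demux = demultiplex(run.reads, panel, run.association)
    report = build_run_report(demux, run.reads)
    assert report.assigned_reads + report.unassigned_reads == report.total_reads
    lengths = sorted(len(r.seq) for r in run.reads)
    assert report.median_read_length == pytest.approx(
        (lengths[len(lengths) // 2] + lengths[(len(lengths) - 1) // 2]) / 2
    )
    d = report.to_dict()
    assert d["passed filter reads"] == len(run.reads)
    assert d["mixed"] is None and d["dot"] is None  # sequencer-only metrics
    # empty input -> all-zero report
    empty = build_run_report(demultiplex([], panel, run.association), [])
    assert empty.total_reads == 0 and empty.median_read_length == 0.0


def test_drb_pooling_factor_dominates_read_counts(db, panel):
    from gstyper.simulate import ErrorModel, simulate_genotypes, simulate_reads

    truth = simulate_genotypes(db, 4, 0.1, seed=8, loci=["A", "DRB1"],
                               mids=sorted(panel.mids))
    run = simulate_reads(truth, panel, db, 80, ErrorModel.noise_free(), seed=8)
    demux = demultiplex(run.reads, panel, run.association)
    counts = demux.per_amplicon_counts()
    assert max(counts, key=counts.get) == "DRB-ex2"  # factor 6 amplicon


def test_association_file_roundtrip(tmp_path):
    assoc = {"S01": "MID01", "S02": "MID02"}
    path = tmp_path / "assoc.tsv"
    write_association_file(assoc, "RUN7", path)
    loaded, run_id, warnings = read_association_file(path, "RUN7")
    assert loaded == assoc and run_id == "RUN7" and not warnings
    _, _, warnings = read_association_file(path, "RUN8")
    assert warnings and "RUN8" in warnings[0]
    with pytest.raises(ValueError, match="duplicate"):
        write_association_file({"S01": "MID01", "S02": "MID01"}, "X", path)


def test_fasta_roundtrip(tmp_path, clean_run):
    run = clean_run["run"]
    path = tmp_path / "reads.fna"
    write_fasta(run.reads[:50], path)
    assert read_fasta(path) == run.reads[:50]
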