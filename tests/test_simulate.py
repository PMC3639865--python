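import itertools

import numpy as np
import pytest

from gstyper.libprep import fit_standard_curve
from gstyper.panel import revcomp
from gstyper.preprocess import demultiplex, trim_read
from gstyper.simulate import (
    ErrorModel,
    simulate_genotypes,
    simulate_quant_plate,
    simulate_reads,
)


def test_homozygote_rate_extremes(db, panel):
    mids = sorted(panel.mids)
    t0 = simulate_genotypes(db, 10, 0.0, seed=1, loci=["A", "B"], mids=mids)
    assert t0.homozygote_fraction() == 0.0
    t1 = simulate_genotypes(db, 10, 1.0, seed=1, loci=["A", "B"], mids=mids)
    assert t1.homozygote_fraction() == 1.0


def test_homozygote_fraction_within_binomial_bounds(db):
    mids = [f"X{i:03d}" for i in range(200)]
    truth = simulate_genotypes(db, 200, 0.103, seed=2, loci=["A", "B", "C"], mids=mids)
    # 600 locus draws at p=0.103: the 95% binomial interval is well inside
    assert 0.06 <= truth.homozygote_fraction() <= 0.15


def test_sample_capacity_error(db, panel):
    with pytest.raises(ValueError, match="exceed"):
        simulate_genotypes(db, 25, 0.1, seed=1, mids=sorted(panel.mids))


def test_same_seed_byte_identical(db, panel, clean_run):
    truth = clean_run["truth"]
    r1 = simulate_reads(truth, panel, db, 30, ErrorModel(), seed=5)
    r2 = simulate_reads(truth, panel, db, 30, ErrorModel(), seed=5)
    assert r1.reads == r2.reads
    assert r1.read_truth == r2.read_truth


def test_empty_truth_rejected(db, panel):
    from gstyper.simulate import SimTruth

    with pytest.raises(ValueError, match="empty"):
        simulate_reads(SimTruth({}, {}, 0), panel, db, 10, ErrorModel(), seed=1)


def test_mid_closure(db, panel, clean_run):
    run = clean_run["run"]
    allowed = {panel.mids[mid] for mid in run.association.values()}
    for read in run.reads:
        assert read.seq[:10] in allowed


def test_noise_free_reads_roundtrip_to_source_exons(db, panel, clean_run):
    """With a zero error model, demultiplexed + trimmed reads reproduce the
    source allele's exon sequence exactly (exon_only mode)."""
    run = clean_run["run"]
    truth_by_id = run.truth_by_id()
    demux = demultiplex(run.reads, panel, run.association)
    assert not demux.unassigned
    checked = 0
    for (sample, amp_id, direction), reads in demux.bins.items():
        amp = panel.by_id(amp_id)
        for read in reads[:5]:
            rec = truth_by_id[read.id]
            allele = db.get(rec["allele"])
            exon = allele.feature(amp.exon_feature)
            trimmed = trim_read(read, amp, direction, "exon_only")
            expected = exon[amp.cov_lo - 1 + amp.masked_prefix : amp.cov_hi]
            assert trimmed.startswith(expected) or trimmed == expected
            checked += 1
    assert checked > 100


def test_homopolymer_errors_only_change_run_lengths(db, panel):
    """Homopolymer indels must alter run lengths of existing runs, never the
    base composition of the run structure."""
    mids = sorted(panel.mids)
    truth = simulate_genotypes(db, 3, 0.0, seed=4, loci=["C"], mids=mids)
    em = ErrorModel(substitution_rate=0.0, homopolymer_indel_base_rate=0.2,
                    chimera_rate=0.0, pseudogene_fraction=0.0)
    run = simulate_reads(truth, panel, db, 40, em, seed=4)
    hp_reads = [t for t in run.read_truth if t["n_hp_indel"] > 0]
    assert hp_reads, "expected some homopolymer errors at rate 0.2"
    reads_by_id = {r.id: r.seq for r in run.reads}
    amp_by_id = {a.id: a for a in panel.amplicons}
    for rec in hp_reads[:50]:
        amp = amp_by_id[rec["amplicon"]]
        template = amp.template(db.get(rec["allele"]))
        template = (
            amp.fwd_primer
            + template[amp.fwd.length : len(template) - amp.rev.length]
            + amp.rev_primer
        )
        seq = reads_by_id[rec["read"]][10:]
        if rec["direction"] == "R":
            seq = revcomp(seq)
        rle = lambda s: "".join(k for k, _ in itertools.groupby(s))
        assert rle(seq) == rle(template)
        assert len(seq) != len(template) or seq != template


def test_chimera_fraction_close_to_rate(db, panel):
    mids = sorted(panel.mids)
    truth = simulate_genotypes(db, 8, 0.0, seed=6, loci=["DRB1", "DRB5"], mids=mids)
    em = ErrorModel(substitution_rate=0.0, homopolymer_indel_base_rate=0.0,
                    chimera_rate=0.05, pseudogene_fraction=0.0)
    run = simulate_reads(truth, panel, db, 150, em, seed=6)
    eligible = [
        t for t in run.read_truth
        if t["amplicon"] == "DRB-ex2" and not t["pseudogene"]
        and (t["locus"] == "DRB1" or t["chimera"])
    ]
    n_chim = sum(t["chimera"] for t in eligible)
    frac = n_chim / len(eligible)
    # binomial 99.9% interval around 0.05 at n ~ 2000
    assert 0.03 <= frac <= 0.075
    # each chimera carries a single crossover: 5' half DRB1, 3' half DRB3/4/5
    chim = next(t for t in run.read_truth if t["chimera"])
    assert chim["chimera_partner"].startswith("DRB5")
    assert chim["crossover"] > 0


def test_missing_feature_skipped_with_warning(db, panel):
    mids = sorted(panel.mids)
    truth = simulate_genotypes(db, 1, 0.0, seed=1, loci=["DPB1"], mids=mids)
    truth.genotypes["S01"]["DPB1"] = ("DPB1*04:01:01", "DPB1*01:01:01")
    run = simulate_reads(truth, panel, db, 50, ErrorModel.noise_free(), seed=1)
    assert any("DPB1*04:01:01" in w for w in run.warnings)
    assert all(t["allele"] != "DPB1*04:01:01" for t in run.read_truth)


def test_quant_plate_contract(panel):
    plate = simulate_quant_plate(panel, noise_sd=0.0, seed=1)
    assert len(plate.standards) == 8
    concs = [c for c, _ in plate.standards]
    assert concs[0] == 0.0 and concs[-1] == 100.0
    assert fit_standard_curve(plate.standards).r_squared == pytest.approx(1.0, abs=1e-12)
    noisy = simulate_quant_plate(panel, noise_sd=800.0, seed=1)
    curve = fit_standard_curve(noisy.standards)
    # recompute r^2 with the textbook formula as oracle
    x = np.array([s[0] for s in noisy.standards])
    y = np.array([s[1] for s in noisy.standards])
    b, a = np.polyfit(x, y, 1)
    r2 = 1 - np.sum((y - (b * x + a)) ** 2) / np.sum((y - y.mean()) ** 2)
    assert curve.r_squared == pytest.approx(r2, abs=1e-12)
    assert not curve.passed
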