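import numpy as np
import pytest
from oracle_align import dp_mismatches

from gstyper.allele_db import Allele, parse_allele_name
from gstyper.genotyper import (
    AlleleMatcher,
    HaplotypeCluster,
    align_to_reference,
    ambiguity_reduction,
    build_haplotype_clusters,
    call_genotype,
    exclude_null_alleles,
    pair_to_4digit_string,
    partition_layers,
    phase_layer_mismatches,
    sanger_ambiguity_count,
)
from gstyper.mockdb import build_mock_database
from gstyper.panel import load_packaged_panel


# ---------------------------------------------------------------------------
# helpers: construct error-free trimmed reads / clusters from the reference
# ---------------------------------------------------------------------------


def expected_trimmed(matcher, amp_id, allele_name):
    """The trimmed sequence an error-free read of *allele_name* yields."""
    ctx = matcher.context(amp_id)
    core = matcher.core(amp_id, allele_name)
    f5 = matcher.flank5(amp_id, allele_name)
    assert core is not None and f5 is not None
    tail_len = ctx["window_len"] - len(f5) - len(core)
    tail = ""
    if tail_len > 0:
        src = matcher.tail_source(amp_id, allele_name)
        assert src is not None
        tail = src[:tail_len]
    return f5 + core + tail


def make_clusters(matcher, locus, pair, count=50):
    """Lane-ordered error-free clusters for an allele pair (lane k = allele k)."""
    out = {}
    for amp in matcher.panel.for_locus(locus):
        seqs = [expected_trimmed(matcher, amp.id, name) for name in pair]
        if seqs[0] == seqs[1]:
            out[amp.id] = [
                HaplotypeCluster(amp.id, seqs[0], 2 * count, count, count)
            ]
        else:
            out[amp.id] = [
                HaplotypeCluster(amp.id, s, count, count // 2, count - count // 2)
                for s in seqs
            ]
    return out


def reads_from(matcher, amp_id, allele_name, n, direction="F", prefix="r"):
    seq = expected_trimmed(matcher, amp_id, allele_name)
    return [(f"{prefix}{i}", seq, direction) for i in range(n)]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def test_alignment_examples(db):
    exon = db.get("A*01:01:01:01").feature("exon2")
    assert align_to_reference(exon, exon).mismatches == 0
    sub = "T" + exon[1:] if exon[0] != "T" else "A" + exon[1:]
    assert align_to_reference(sub, exon).mismatches == 1
    # 6 bp exonic deletion (null-allele style) costs exactly 6 gap bases
    ref = db.get("A*74:01:01:01").feature("exon3")
    deleted = db.get("A*74:12N").feature("exon3")
    assert len(ref) - len(deleted) == 6
    assert align_to_reference(deleted, ref).mismatches == 6


def test_alignment_rejects_empty():
    with pytest.raises(ValueError):
        align_to_reference("", "ACGT")


def test_alignment_equals_dp_oracle_on_random_instances():
    rng = np.random.default_rng(1234)
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        q = "".join(rng.choice(bases, size=rng.integers(1, 51)))
        r = "".join(rng.choice(bases, size=rng.integers(1, 51)))
        assert align_to_reference(q, r).mismatches == dp_mismatches(q, r)


# ---------------------------------------------------------------------------
# layer partition
# ---------------------------------------------------------------------------


def test_error_free_read_goes_to_master(matcher, panel):
    amp = panel.by_id("A-ex2")
    part = partition_layers(
        reads_from(matcher, "A-ex2", "A*02:01:01:01", 5), matcher, amp, "A"
    )
    assert part.counts == (5, 0, 0)


def test_pseudogene_reads_fail(matcher, panel):
    amp = panel.by_id("DRB-ex2")
    pseudo = expected_trimmed(matcher, "DRB-ex2", "DRBP*01:01:01")
    # the pseudo-locus is engineered >= 8 differences from every functional allele
    dists = [
        matcher.core_mismatches("DRB-ex2", pseudo, n)
        for n in matcher.allele_names("DRB")
    ]
    assert min(dists) >= 8
    part = partition_layers([("p1", pseudo, "F")], matcher, amp, "DRB")
    assert part.counts == (0, 1, 0)


def test_drb_crossover_read_deactivated(matcher, panel):
    amp = panel.by_id("DRB-ex2")
    t1 = expected_trimmed(matcher, "DRB-ex2", "DRB1*01:01:01")
    t2 = expected_trimmed(matcher, "DRB-ex2", "DRB5*01:01:01")
    mid = len(t1) // 2
    chimera = t1[:mid] + t2[mid:]
    part = partition_layers([("c1", chimera, "F")], matcher, amp, "DRB")
    assert part.counts == (0, 0, 1)


def test_layer_override_moves_reads(matcher, panel):
    amp = panel.by_id("DRB-ex2")
    pseudo = expected_trimmed(matcher, "DRB-ex2", "DRBP*01:01:01")
    part = partition_layers(
        [("p1", pseudo, "F")], matcher, amp, "DRB", move_to_master={"p1"}
    )
    assert part.counts == (1, 0, 0)
    good = expected_trimmed(matcher, "DRB-ex2", "DRB1*01:01:01")
    part = partition_layers(
        [("g1", good, "F")], matcher, amp, "DRB", move_to_failed={"g1"}
    )
    assert part.counts == (0, 1, 0)


# ---------------------------------------------------------------------------
# haplotype clustering
# ---------------------------------------------------------------------------


def test_two_allele_mix_gives_two_clusters(matcher):
    reads = reads_from(matcher, "A-ex2", "A*02:01:01:01", 25, prefix="a") + \
        reads_from(matcher, "A-ex2", "A*03:01:01:01", 25, prefix="b")
    clusters, review = build_haplotype_clusters(reads, "A-ex2")
    assert len(clusters) == 2 and not review
    assert {c.consensus for c in clusters} == {
        expected_trimmed(matcher, "A-ex2", "A*02:01:01:01"),
        expected_trimmed(matcher, "A-ex2", "A*03:01:01:01"),
    }


def test_homozygote_gives_one_cluster(matcher):
    reads = reads_from(matcher, "B-ex2", "B*08:01:01:01", 30)
    clusters, _ = build_haplotype_clusters(reads, "B-ex2")
    assert len(clusters) == 1
    assert clusters[0].read_count == 30


def test_reverse_homopolymer_undercall_corrected_by_forward_reads(matcher):
    """A 5 bp C run at the exon 4 start, undercalled to 4 bp only in reverse
    reads: the merged cluster's consensus keeps C5 because the forward
    direction is unanimous at that run."""
    clean = expected_trimmed(matcher, "C-ex4", "C*07:01:01:01")
    f5 = matcher.context("C-ex4")["f5"]
    assert clean[f5 : f5 + 6] == "CCCCC" + clean[f5 + 5]
    undercalled = clean[:f5] + clean[f5 + 1 :]  # C5 -> C4
    reads = [(f"f{i}", clean, "F") for i in range(30)] + [
        (f"r{i}", undercalled, "R") for i in range(20)
    ]
    clusters, review = build_haplotype_clusters(reads, "C-ex4")
    assert len(clusters) == 1 and not review
    assert clusters[0].consensus == clean
    assert clusters[0].read_count == 50
    assert (clusters[0].fwd_count, clusters[0].rev_count) == (30, 20)


def test_substitution_variants_are_not_merged(matcher):
    clean = expected_trimmed(matcher, "A-ex2", "A*02:01:01:01")
    other = expected_trimmed(matcher, "A-ex2", "A*03:01:01:01")
    reads = [(f"f{i}", clean, "F") for i in range(30)] + [
        (f"g{i}", other, "F") for i in range(30)
    ]
    clusters, _ = build_haplotype_clusters(reads, "A-ex2")
    assert len(clusters) == 2


def test_noise_clusters_dropped_and_third_cluster_flags_review(matcher):
    a = expected_trimmed(matcher, "A-ex2", "A*02:01:01:01")
    b = expected_trimmed(matcher, "A-ex2", "A*03:01:01:01")
    c = expected_trimmed(matcher, "A-ex2", "A*24:02:01:01")
    reads = [(f"a{i}", a, "F") for i in range(50)] + [
        (f"b{i}", b, "F") for i in range(40)
    ] + [(f"c{i}", c, "F") for i in range(5)]
    clusters, review = build_haplotype_clusters(reads, "A-ex2", 0.10)
    assert len(clusters) == 2 and not review  # 5/95 < 10%: dropped as noise
    reads += [(f"d{i}", c, "F") for i in range(10)]
    clusters, review = build_haplotype_clusters(reads, "A-ex2", 0.10)
    assert len(clusters) == 2 and review  # 15/105 > 10%: review flag


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------


def test_heterozygote_called_uniquely(matcher):
    pair = ("A*02:01:01:01", "A*03:01:01:01")
    clusters = make_clusters(matcher, "A", pair)
    call = call_genotype(clusters, "A", matcher, min_reads=20)
    assert call.status == "called"
    assert call.ambiguity_string_4digit == [pair_to_4digit_string(*pair)]
    assert all(c.mm == 0 for c in call.candidates)


def test_homozygote_pair_present(matcher):
    pair = ("B*08:01:01:01", "B*08:01:01:01")
    clusters = make_clusters(matcher, "B", pair)
    call = call_genotype(clusters, "B", matcher, min_reads=20)
    assert pair in [c.names for c in call.candidates]


def test_insufficient_reads_is_no_result(matcher):
    pair = ("A*02:01:01:01", "A*03:01:01:01")
    clusters = make_clusters(matcher, "A", pair, count=5)
    call = call_genotype(clusters, "A", matcher, min_reads=20)
    assert call.status == "no_result"
    assert not call.candidates


def test_novel_variant_reported_for_review_with_nonzero_mm(matcher):
    pair = ("A*02:01:01:01", "A*03:01:01:01")
    clusters = make_clusters(matcher, "A", pair)
    seq = clusters["A-ex2"][0].consensus
    pos = len(seq) // 2
    novel = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
    clusters["A-ex2"][0] = HaplotypeCluster("A-ex2", novel, 50, 25, 25)
    call = call_genotype(clusters, "A", matcher, min_reads=20)
    assert call.status == "review"
    assert call.candidates and call.candidates[0].mm > 0


def test_adding_alleles_never_removes_true_pair(db, panel):
    """Database growth monotonicity: a richer reference can only widen the
    ambiguity string, never drop the true pair."""
    pair = ("A*02:01:01:01", "A*03:01:01:01")
    db2 = build_mock_database()
    donor = db2.get("A*02:01:01:01")
    feats = dict(donor.features)
    exon2 = feats["exon2"]
    feats["exon2"] = exon2[:7] + ("A" if exon2[7] != "A" else "C") + exon2[8:]
    db2.add(Allele(parse_allele_name("A*98:01"), feats))
    panel2 = load_packaged_panel(db2)
    m1 = AlleleMatcher(db, panel, "exon_plus_flank", 10)
    m2 = AlleleMatcher(db2, panel2, "exon_plus_flank", 10)
    c1 = call_genotype(make_clusters(m1, "A", pair), "A", m1, 20)
    c2 = call_genotype(make_clusters(m2, "A", pair), "A", m2, 20)
    want = pair_to_4digit_string(*pair)
    assert want in c1.ambiguity_string_4digit
    assert want in c2.ambiguity_string_4digit
    assert set(c1.ambiguity_string_4digit) <= set(c2.ambiguity_string_4digit)


# ---------------------------------------------------------------------------
# null-allele exclusion
# ---------------------------------------------------------------------------


def test_intron_null_excluded_in_flank_mode(matcher):
    pair = ("A*01:01:01:01", "A*24:02:01:01")
    clusters = make_clusters(matcher, "A", pair)
    call = call_genotype(clusters, "A", matcher, min_reads=20)
    # exon-identical intron variants make four 4-digit pairs before exclusion
    assert len(call.ambiguity_string_4digit) == 4
    call = exclude_null_alleles(call, clusters, matcher, "exon_plus_flank")
    assert call.ambiguity_string_4digit == [pair_to_4digit_string(*pair)]
    excluded = dict(call.excluded_null_alleles)
    assert excluded["A*01:01:01:02N"] == "intron2"
    assert excluded["A*24:02:01:02L"] == "intron2"


def test_exon_only_mode_retains_suffixed_alleles(matcher_exon_only):
    pair = ("A*01:01:01:01", "A*24:02:01:01")
    clusters = make_clusters(matcher_exon_only, "A", pair)
    call = call_genotype(clusters, "A", matcher_exon_only, min_reads=20)
    call = exclude_null_alleles(call, clusters, matcher_exon_only, "exon_only")
    assert not call.excluded_null_alleles
    assert "A*01:01N+A*24:02" in call.ambiguity_string_4digit


def test_uncovered_null_retained_with_warning(matcher):
    # A*68:11N differs from A*68:01 only in exon 1, which no A amplicon covers
    pair = ("A*68:01:01:01", "A*02:01:01:01")
    clusters = make_clusters(matcher, "A", pair)
    call = call_genotype(clusters, "A", matcher, min_reads=20)
    call = exclude_null_alleles(call, clusters, matcher, "exon_plus_flank")
    assert "A*02:01+A*68:11N" in call.ambiguity_string_4digit
    assert any("A*68:11N" in w for w in call.warnings)


# ---------------------------------------------------------------------------
# phase layers
# ---------------------------------------------------------------------------


def test_phase_layers_true_pair(matcher):
    pair = ("B*40:01:01:01", "B*40:02:01:01")  # differ in exon 2 and exon 3
    clusters = make_clusters(matcher, "B", pair)
    mm, mm3, mm4 = phase_layer_mismatches(pair, clusters, matcher)
    assert mm == 0
    assert mm3 == 2  # swapping the exon 3 clusters breaks both haplotypes
    assert mm4 == 0  # exon 4 identical between the two alleles


def test_phase_layers_shuffled_decoy(matcher):
    """The exon-shuffled decoy pair shows MM > 0 but MM3 = 0 against the
    true pair's lane-ordered clusters: the inter-exon cis/trans ambiguity
    becomes visible in the phase layer."""
    truth = ("B*40:01:01:01", "B*40:02:01:01")
    decoy = ("B*40:03:01:01", "B*40:04:01:01")
    clusters = make_clusters(matcher, "B", truth)
    mm, mm3, mm4 = phase_layer_mismatches(decoy, clusters, matcher)
    assert mm > 0
    assert mm3 == 0


def test_phase_layers_single_amplicon_not_applicable(matcher):
    pair = ("DPB1*01:01:01", "DPB1*02:01:01")
    clusters = make_clusters(matcher, "DPB1", pair)
    assert phase_layer_mismatches(pair, clusters, matcher) == (None, None, None)


# ---------------------------------------------------------------------------
# ambiguity metrics
# ---------------------------------------------------------------------------


def test_sanger_count_homozygote_unique(matcher):
    assert sanger_ambiguity_count(
        ("C*01:02:01:01", "C*01:02:01:01"), "C", matcher
    ) == 1


def test_cis_trans_pair_two_unphased_one_phased(matcher):
    pair = ("B*15:01:01:01", "B*15:02:01:01")
    assert sanger_ambiguity_count(pair, "B", matcher) == 2
    clusters = make_clusters(matcher, "B", pair)
    call = call_genotype(clusters, "B", matcher, min_reads=20)
    assert call.ambiguity_string_4digit == [pair_to_4digit_string(*pair)]


def test_sanger_never_below_phased(matcher, validation_run):
    report = validation_run["report"]
    checked = 0
    for sample in report["samples"].values():
        for doc in sample["loci"].values():
            if "n_unphased_4digit" in doc:
                assert doc["n_unphased_4digit"] >= doc["n_phased_4digit"]
                checked += 1
    assert checked >= 50


@pytest.mark.parametrize("u,p,expected", [(20, 2, 90.0), (7, 7, 0.0), (4, 1, 75.0)])
def test_ambiguity_reduction_formula(u, p, expected):
    assert ambiguity_reduction(u, p) == pytest.approx(expected)


def test_ambiguity_reduction_rejects_inverted_counts():
    with pytest.raises(ValueError):
        ambiguity_reduction(2, 5)
    with pytest.raises(ValueError):
        ambiguity_reduction(3, 0)
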