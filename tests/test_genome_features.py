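"""Gene-structure operations: intron chains, model-set comparison and
merging, junction support bins, lncRNA filtering, GFF3 round trips."""
import warnings

import numpy as np
import pytest

from regudyn.genome_features import (
    ComparisonClass,
    classify_junction_support,
    compare_model_sets,
    filter_lncrna,
    merge_model_sets,
)
from regudyn.gff3 import Gff3ParseError, read_gff3, write_gff3
from regudyn.models import Junction, TranscriptModel

from conftest import make_set, make_transcript


# ---------------------------------------------------------------------------
# intron chains

def brute_force_chain(exons):
    out = []
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        out.append((e0, s1))
    return out


def test_intron_chain_examples():
    t1 = make_transcript("t1", "g1", "chr1", "+", [(0, 100)])
    assert t1.intron_chain() == ()
    t2 = make_transcript("t2", "g1", "chr1", "+", [(0, 100), (200, 300)])
    assert [(j.donor, j.acceptor) for j in t2.intron_chain()] == [(100, 200)]


def test_intron_chain_matches_brute_force_gap_scan():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 9))
        pos = 0
        exons = []
        for _ in range(n):
            length = int(rng.integers(10, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(30, 500))
        t = make_transcript("t", "g", "chr1", "+", exons)
        got = [(j.donor, j.acceptor) for j in t.intron_chain()]
        assert got == brute_force_chain(exons)
        assert len(got) == n - 1
        assert all(a < b for a, b in got)


def test_junction_requires_acceptor_after_donor():
    with pytest.raises(ValueError):
        Junction("chr1", "+", 100, 100)


# ---------------------------------------------------------------------------
# model-set comparison

def brute_force_compare(query, reference, min_recip=0.8):
    """All-pairs comparator re-deriving the classification rules."""
    def exon_overlap(a, b):
        if a.chrom != b.chrom:
            return 0
        return sum(
            max(0, min(e1, e2) - max(s1, s2))
            for s1, e1 in a.exons
            for s2, e2 in b.exons
        )

    def chain(t):
        return tuple((j.donor, j.acceptor) for j in t.intron_chain())

    out = {}
    for q in query:
        same = [r for r in reference if r.strand == q.strand and exon_overlap(q, r) > 0]
        anti = [r for r in reference if r.strand != q.strand and exon_overlap(q, r) > 0]
        exact = False
        if len(q.exons) > 1:
            exact = any(
                chain(r) == chain(q) and r.chrom == q.chrom and r.strand == q.strand
                for r in reference
                if len(r.exons) > 1
            )
        else:
            for r in same:
                if len(r.exons) != 1:
                    continue
                ov = exon_overlap(q, r)
                if min(ov / q.spliced_length, ov / r.spliced_length) >= min_recip:
                    exact = True
        if exact:
            out[q.transcript_id] = ComparisonClass.EXACT_MATCH
        elif same:
            out[q.transcript_id] = ComparisonClass.NOVEL_ISOFORM
        elif anti:
            out[q.transcript_id] = ComparisonClass.OTHER
        else:
            out[q.transcript_id] = ComparisonClass.NOVEL_LOCUS
    return out


def random_model_set(rng, n, prefix, chroms=("chr1", "chr2")):
    ts = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 6))
        pos = int(rng.integers(0, 50_000))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 800))
        ts.append(
            make_transcript(f"{prefix}{i}", f"{prefix}g{i}", chrom, strand, exons)
        )
    return make_set(ts)


def test_exact_match_ignores_transcript_end_shifts():
    ref = make_set([make_transcript("r1", "rg1", "chr1", "+",
                                    [(100, 200), (300, 400), (500, 600)])])
    # same intron chain, ends extended by 50 bp either way
    q = make_set([make_transcript("q1", "qg1", "chr1", "+",
                                  [(50, 200), (300, 400), (500, 650)])])
    classes, counts = compare_model_sets(q, ref)
    assert classes["q1"] is ComparisonClass.EXACT_MATCH
    assert counts[ComparisonClass.EXACT_MATCH] == 1


def test_exon_skipping_is_novel_isoform():
    ref = make_set([make_transcript("r1", "rg1", "chr1", "+",
                                    [(100, 200), (300, 400), (500, 600)])])
    q = make_set([make_transcript("q1", "qg1", "chr1", "+",
                                  [(100, 200), (500, 600)])])
    classes, _ = compare_model_sets(q, ref)
    assert classes["q1"] is ComparisonClass.NOVEL_ISOFORM


def test_opposite_strand_overlap_is_other_and_disjoint_is_novel_locus():
    ref = make_set([make_transcript("r1", "rg1", "chr1", "+", [(100, 400)])])
    q = make_set(
        [
            make_transcript("q1", "qg1", "chr1", "-", [(200, 300)]),
            make_transcript("q2", "qg2", "chr1", "+", [(10_000, 10_200)]),
        ]
    )
    classes, _ = compare_model_sets(q, ref)
    assert classes["q1"] is ComparisonClass.OTHER
    assert classes["q2"] is ComparisonClass.NOVEL_LOCUS


def test_compare_matches_quadratic_oracle_on_random_fixtures():
    rng = np.random.default_rng(42)
    for trial in range(5):
        q = random_model_set(rng, 60, f"q{trial}_")
        r = random_model_set(rng, 60, f"r{trial}_")
        classes, _ = compare_model_sets(q, r)
        assert classes == brute_force_compare(list(q), list(r))


def test_self_comparison_is_all_exact_match():
    rng = np.random.default_rng(7)
    s = random_model_set(rng, 40, "s_")
    classes, counts = compare_model_sets(s, s)
    assert set(classes.values()) == {ComparisonClass.EXACT_MATCH}
    assert counts[ComparisonClass.EXACT_MATCH] == len(s)


def test_class_counts_invariant_under_input_order():
    rng = np.random.default_rng(3)
    q = random_model_set(rng, 50, "q_")
    r = random_model_set(rng, 50, "r_")
    _, counts = compare_model_sets(q, r)
    shuffled = make_set(sorted(q, key=lambda t: t.transcript_id, reverse=True))
    _, counts2 = compare_model_sets(shuffled, r)
    assert counts == counts2


def test_disjoint_assemblies_raise():
    q = make_set([make_transcript("q", "g", "scaffold_9", "+", [(0, 100)])])
    r = make_set([make_transcript("r", "g", "chr1", "+", [(0, 100)])])
    with pytest.raises(ValueError, match="assembly"):
        compare_model_sets(q, r)


# ---------------------------------------------------------------------------
# junction support bins

def test_junction_bin_boundaries_and_tally_oracle():
    js = [Junction("chr1", "+", i * 1000, i * 1000 + 100) for i in range(1000)]
    rng = np.random.default_rng(0)
    counts = {}
    for j in js:
        counts[(j.chrom, j.donor, j.acceptor)] = int(rng.integers(0, 2000))
    bins, props = classify_junction_support(js, counts)
    # direct tally
    expected = {"0": 0, "1-500": 0, ">500": 0}
    for j in js:
        n = counts[(j.chrom, j.donor, j.acceptor)]
        expected["0" if n == 0 else "1-500" if n <= 500 else ">500"] += 1
    for b, n in expected.items():
        assert props[b] == pytest.approx(n / len(js))
    assert sum(props.values()) == pytest.approx(1.0)
    # strict boundary: 500 supported reads is not "over 500"
    j = js[0]
    key = (j.chrom, j.donor, j.acceptor)
    assert classify_junction_support([j], {key: 500})[0][j] == "1-500"
    assert classify_junction_support([j], {key: 600})[0][j] == ">500"
    assert classify_junction_support([j], {})[0][j] == "0"


def test_negative_support_count_rejected():
    j = Junction("chr1", "+", 0, 10)
    with pytest.raises(ValueError):
        classify_junction_support([j], {("chr1", 0, 10): -1})


# ---------------------------------------------------------------------------
# merging

def test_overlapping_supplement_gene_excluded():
    primary = make_set([make_transcript("p1", "pg1", "chr1", "+", [(100, 400)])])
    supp = make_set(
        [
            make_transcript("s1", "sg1", "chr1", "+", [(200, 300)]),
            make_transcript("s2", "sg2", "chr1", "+", [(5000, 5200)]),
        ]
    )
    res = merge_model_sets(primary, supp)
    assert "s1" not in res.merged
    assert "s2" in res.merged
    assert res.gene_provenance == {"pg1": "primary", "sg2": "supplement"}


def test_disjoint_sets_merge_to_sum_and_merge_is_idempotent():
    rng = np.random.default_rng(5)
    a = random_model_set(rng, 20, "a_", chroms=("chr1",))
    b = random_model_set(rng, 20, "b_", chroms=("chr2",))
    merged = merge_model_sets(a, b).merged
    assert len(merged) == len(a) + len(b)
    again = merge_model_sets(merged, b).merged
    assert set(t.transcript_id for t in again) == set(t.transcript_id for t in merged)


def test_merge_provenance_matches_brute_force_overlap_scan():
    rng = np.random.default_rng(9)
    primary = random_model_set(rng, 40, "p_")
    supp = random_model_set(rng, 40, "s_")
    res = merge_model_sets(primary, supp)

    def overlaps_primary(ts):
        for t in ts:
            for p in primary:
                if p.chrom == t.chrom and p.strand == t.strand:
                    for s1, e1 in t.exons:
                        for s2, e2 in p.exons:
                            if min(e1, e2) > max(s1, s2):
                                return True
        return False

    for gid, ts in supp.genes().items():
        expected = "supplement" if not overlaps_primary(ts) else None
        assert res.gene_provenance.get(gid) == expected


# ---------------------------------------------------------------------------
# lncRNA filter

def test_lncrna_filter_rules_and_set_algebra_oracle():
    ts = []
    scores, flags = {}, {}
    rng = np.random.default_rng(1)
    for i in range(60):
        length = int(rng.integers(50, 1500))
        ts.append(make_transcript(f"t{i}", f"g{i}", "chr1", "+",
                                  [(i * 3000, i * 3000 + length)]))
        scores[f"t{i}"] = float(rng.random())
        flags[f"t{i}"] = bool(rng.random() < 0.3)
    tset = make_set(ts)
    kept = filter_lncrna(tset, scores, flags, min_length=200, coding_cutoff=0.5)
    oracle = {
        t.transcript_id
        for t in ts
        if t.spliced_length >= 200
        and not flags[t.transcript_id]
        and scores[t.transcript_id] < 0.5
    }
    assert kept == oracle


def test_lncrna_short_and_high_potential_excluded_missing_score_warned():
    ts = make_set(
        [
            make_transcript("short", "g1", "chr1", "+", [(0, 150)]),
            make_transcript("coding", "g2", "chr1", "+", [(1000, 1500)]),
            make_transcript("noscore", "g3", "chr1", "+", [(3000, 3500)]),
        ]
    )
    with pytest.warns(UserWarning, match="noscore"):
        kept = filter_lncrna(
            ts, {"short": 0.1, "coding": 0.95}, {}, min_length=200, coding_cutoff=0.5
        )
    assert kept == set()


# ---------------------------------------------------------------------------
# GFF3

def test_gff3_coordinate_convention(tmp_path):
    p = tmp_path / "one.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        "chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1\n"
        "chr1\t.\texon\t101\t200\t.\t+\t.\tID=t1.e1;Parent=t1\n"
    )
    models = read_gff3(p)
    assert models.transcripts["t1"].exons == [(100, 200)]


def test_gff3_round_trip_is_identity(tmp_path):
    rng = np.random.default_rng(8)
    from test_genome_features import random_model_set  # self-import safe under pytest

    s = random_model_set(rng, 50, "rt_")
    p = tmp_path / "rt.gff3"
    write_gff3(s, p)
    back = read_gff3(p)
    assert {t.transcript_id for t in back} == {t.transcript_id for t in s}
    for t in s:
        assert back.transcripts[t.transcript_id].exons == t.exons
        assert back.transcripts[t.transcript_id].gene_id == t.gene_id


def test_gff3_orphan_exon_reports_line_number(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text(
        "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        "chr1\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=ghost\n"
    )
    with pytest.raises(Gff3ParseError, match="line 2"):
        read_gff3(p)


def test_generator_annotation_round_trips_without_warnings(noise_free_dataset):
    _, ds = noise_free_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        models = read_gff3(ds / "annotation.gff3")
    assert len(models) > 0
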