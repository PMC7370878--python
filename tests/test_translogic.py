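"""PWM normalization, motif scanning, deviation scores, opening index,
footprints and pioneer calling."""
import numpy as np
import pandas as pd
import pytest

from regudyn.pwm import PWM, normalize_pwm, read_pwm_file, write_pwm_file
from regudyn.translogic import (
    call_pioneer_tfs,
    footprint_profile,
    log_odds_matrix,
    motif_deviation,
    opening_index,
    scan_motifs,
    tf_activity_summary,
    track_background_density,
    _raw_deviation,
)


# ---------------------------------------------------------------------------
# PWM normalization and I/O

def test_uniform_position_stays_uniform():
    pwm = normalize_pwm("m", "tf", np.full((3, 4), 0.25))
    assert np.allclose(pwm.matrix, 0.25)


def test_pseudocount_arithmetic_on_degenerate_position():
    pwm = normalize_pwm("m", "tf", np.array([[1.0, 0.0, 0.0, 0.0]]))
    expected = np.array([1.008, 0.008, 0.008, 0.008])
    expected = expected / expected.sum()
    # tolerance clamping perturbs the dominant entry by ~1e-6 only
    assert np.allclose(pwm.matrix[0], expected, atol=1e-5)
    assert pwm.matrix[0, 0] == pytest.approx(0.9767, abs=1e-3)


def test_rows_sum_to_one_and_entries_positive():
    rng = np.random.default_rng(0)
    raw = rng.random((12, 4))
    pwm = normalize_pwm("m", "tf", raw)
    assert np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)
    assert (pwm.matrix > 0).all()


def test_all_zero_position_rejected_with_position():
    raw = np.array([[0.25, 0.25, 0.25, 0.25], [0.0, 0.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="position 1"):
        normalize_pwm("m", "tf", raw)


def test_pwm_file_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    raw = rng.random((8, 4))
    pwm = normalize_pwm("M7", "Sox", raw)
    path = tmp_path / "M7.txt"
    write_pwm_file(pwm, path, raw=raw)
    back = read_pwm_file(path)
    assert back.motif_id == "M7" and back.tf_name == "Sox"
    assert np.allclose(back.matrix.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(back.matrix, pwm.matrix, atol=1e-6)


# ---------------------------------------------------------------------------
# motif scanning

def _pwm_from_consensus(cons):
    raw = np.full((len(cons), 4), 0.02)
    for i, b in enumerate(cons):
        raw[i, "ACGT".index(b)] = 0.94
    return normalize_pwm("m", "tf", raw)


def _revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


def test_consensus_hits_with_maximal_score_on_both_strands():
    cons = "ACGTACGTACGT"
    pwm = _pwm_from_consensus(cons)
    max_score = log_odds_matrix(pwm).max(axis=1).sum()
    hits = scan_motifs({"s": "TT" + cons + "GG"}, pwm)
    fwd = [h for h in hits if h.strand == "+"]
    assert any(h.start == 2 and h.score == pytest.approx(max_score) for h in fwd)
    hits_rc = scan_motifs({"s": "TT" + _revcomp(cons) + "GG"}, pwm)
    rev = [h for h in hits_rc if h.strand == "-"]
    assert any(h.start == 2 and h.score == pytest.approx(max_score) for h in rev)


def test_short_sequences_and_n_windows_are_skipped():
    pwm = _pwm_from_consensus("ACGTACGTACGT")
    assert scan_motifs({"s": "ACGT"}, pwm) == []
    seq = "ACGTACGNACGT"  # N inside the only window
    assert scan_motifs({"s": seq}, pwm) == []


def brute_force_scan(sequences, pwm, score_fraction=0.8):
    lom = {"+": log_odds_matrix(pwm),
           "-": log_odds_matrix(pwm.reverse_complement())}
    threshold = score_fraction * lom["+"].max(axis=1).sum()
    hits = set()
    for sid, seq in sequences.items():
        seq = seq.upper()
        for strand, m in lom.items():
            for start in range(len(seq) - len(pwm) + 1):
                window = seq[start: start + len(pwm)]
                if any(b not in "ACGT" for b in window):
                    continue
                score = sum(m[i, "ACGT".index(b)] for i, b in enumerate(window))
                if score >= threshold:
                    hits.add((sid, start, strand, round(score, 9)))
    return hits


def test_scanner_agrees_with_exhaustive_window_scorer():
    rng = np.random.default_rng(2)
    cons = "GATTACAGGT"
    pwm = _pwm_from_consensus(cons)
    seqs = {}
    for i in range(30):
        s = "".join("ACGT"[j] for j in rng.integers(0, 4, size=120))
        if i % 3 == 0:  # plant instances
            pos = int(rng.integers(0, 100))
            s = s[:pos] + cons + s[pos + len(cons):]
        if i % 7 == 0:
            s = s[:50] + "N" + s[51:]
        seqs[f"s{i}"] = s
    hits = {
        (h.seq_id, h.start, h.strand, round(h.score, 9))
        for h in scan_motifs(seqs, pwm)
    }
    assert hits == brute_force_scan(seqs, pwm)


def test_planted_instances_recalled(noise_free_dataset):
    _, ds = noise_free_dataset
    from regudyn.synth import TruthLabels
    from regudyn.pipeline import _read_fasta

    truth = TruthLabels.load(ds / "truth.json")
    seqs = _read_fasta(ds / "elements.fa")
    for mid, eids in truth.motif_elements.items():
        pwm = read_pwm_file(ds / "motifs" / f"{mid}.txt")
        hit_ids = {h.seq_id for h in scan_motifs(seqs, pwm)}
        assert set(eids) <= hit_ids  # recall 1.0 on planted instances


# ---------------------------------------------------------------------------
# deviation scores

def test_counts_equal_to_expectation_give_raw_deviation_zero():
    # every element has identical stage profile: observed == expected exactly
    X = np.tile(np.array([1.0, 2.0, 3.0]), (10, 1)) * np.arange(1, 11)[:, None]
    member = np.zeros(10, dtype=bool)
    member[[2, 5]] = True
    y = _raw_deviation(X, member, X.mean(axis=1))
    assert np.allclose(y, 0.0, atol=1e-12)


def test_planted_enrichment_has_largest_z_at_its_stage():
    rng = np.random.default_rng(3)
    n, stages = 200, 6
    X = rng.exponential(10.0, (n, stages))
    boosted = np.arange(20)
    X[boosted, 2] *= 3.0
    counts = pd.DataFrame(X, index=[f"e{i}" for i in range(n)],
                          columns=[f"S{j}" for j in range(stages)])
    ind = pd.DataFrame(False, index=counts.index, columns=["hot", "cold"])
    ind.iloc[boosted, 0] = True
    ind.iloc[rng.choice(n, 20, replace=False), 1] = True
    res = motif_deviation(counts, ind, n_background=50, seed=0)
    assert res.z.loc["hot"].idxmax() == "S2"
    assert res.z.loc["hot", "S2"] > res.z.loc["cold"].abs().max()


def test_deviation_deterministic_under_seed():
    rng = np.random.default_rng(4)
    counts = pd.DataFrame(rng.exponential(1.0, (50, 4)),
                          index=[f"e{i}" for i in range(50)], columns=list("abcd"))
    ind = pd.DataFrame(rng.random((50, 2)) < 0.2,
                       index=counts.index, columns=["m1", "m2"])
    a = motif_deviation(counts, ind, seed=11)
    b = motif_deviation(counts, ind, seed=11)
    assert a.z.equals(b.z)


def test_random_motif_deviation_centered_near_zero():
    """A motif hitting random elements is its own background: its z is
    near zero in expectation (self-consistency over seeds)."""
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(rng.exponential(1.0, (300, 5)),
                          index=[f"e{i}" for i in range(300)],
                          columns=[f"S{j}" for j in range(5)])
    zs = []
    for seed in range(10):
        pick = np.random.default_rng(seed).random(300) < 0.1
        ind = pd.DataFrame({"m": pick}, index=counts.index)
        res = motif_deviation(counts, ind, n_background=50, seed=seed)
        zs.append(res.z.loc["m"].to_numpy())
    zs = np.concatenate(zs)
    assert abs(np.nanmean(zs)) < 0.5


# ---------------------------------------------------------------------------
# opening index and footprints

def test_uniform_cut_density_scores_zero():
    track = {"chr1": np.full(10_000, 3.0)}
    bg = track_background_density(track)
    hits = [("chr1", 1000 + 500 * i) for i in range(12)]
    score = opening_index(track, hits, motif_length=12, background_density=bg)
    assert score == pytest.approx(0.0, abs=1e-12)


def test_eightfold_flank_density_scores_three():
    track = {"chr1": np.full(20_000, 1.0)}
    hits = [("chr1", 2000 + 1000 * i) for i in range(12)]
    for _, start in hits:
        track["chr1"][start - 200: start] = 8.0
        track["chr1"][start + 12: start + 212] = 8.0
    score = opening_index(track, hits, motif_length=12, background_density=1.0)
    assert score == pytest.approx(3.0)


def test_opening_index_needs_minimum_hits():
    track = {"chr1": np.ones(1000)}
    assert opening_index(track, [("chr1", 100)], 12, 1.0, min_hits=10) is None


def test_footprint_profile_additivity_and_orientation():
    track = {"chr1": np.arange(400, dtype=float)}
    one = footprint_profile(track, [("chr1", 200, "+")], motif_length=10, flank=50)
    assert np.array_equal(one, np.arange(150, 260, dtype=float))
    two = footprint_profile(track, [("chr1", 200, "+")] * 2, motif_length=10, flank=50)
    assert np.array_equal(two, 2 * one)
    minus = footprint_profile(track, [("chr1", 200, "-")], motif_length=10, flank=50)
    assert np.array_equal(minus, one[::-1])


def test_planted_footprint_minimum_falls_in_core(noise_free_dataset):
    _, ds = noise_free_dataset
    from regudyn.bedio import read_bedgraph
    from regudyn.synth import TruthLabels
    from regudyn.elements import filter_and_merge_peaks
    from regudyn.bedio import read_bed
    import json

    truth = TruthLabels.load(ds / "truth.json")
    manifest = json.loads((ds / "manifest.json").read_text())
    (pioneer,) = [m for m, f in truth.motif_pioneer.items() if f]
    stage = truth.pioneer_stage[pioneer]
    track = read_bedgraph(ds / f"cutsites_{stage}.bedGraph")
    peaks = {st: read_bed(ds / f"peaks_{st}.bed") for st in manifest["atac_stages"]}
    elements = {e.element_id: e for e in filter_and_merge_peaks(peaks)}
    # genomic hit positions from the recorded planted offsets
    from regudyn.pipeline import _read_fasta
    from regudyn.translogic import scan_motifs
    seqs = _read_fasta(ds / "elements.fa")
    pwm = read_pwm_file(ds / "motifs" / f"{pioneer}.txt")
    hits = [
        (elements[h.seq_id].chrom, elements[h.seq_id].start + h.start, h.strand)
        for h in scan_motifs(seqs, pwm)
        if h.seq_id in truth.motif_elements[pioneer]
    ]
    flank = 100
    profile = footprint_profile(track, hits, motif_length=len(pwm), flank=flank)
    core = profile[flank: flank + len(pwm)]
    assert profile.argmin() >= flank and profile.argmin() < flank + len(pwm)
    assert core.mean() < 0.25 * profile[:flank].mean()


# ---------------------------------------------------------------------------
# pioneer calling and activity summary

def _score_row(opening, z, tpm):
    return pd.DataFrame(
        [{"tf": "T", "stage": "S1", "opening": opening, "deviation_z": z, "tpm": tpm}]
    )


@pytest.mark.parametrize(
    "opening,z,tpm,expected",
    [
        (3.0, 12.0, 10.0, True),
        (3.0, 12.0, 1.0, False),   # expression fails
        (2.0, 12.0, 10.0, False),  # opening fails
        (3.0, 10.0, 10.0, False),  # strict inequality on deviation
        (np.nan, 12.0, 10.0, False),  # undefined score is never a pioneer
    ],
)
def test_pioneer_threshold_rule(opening, z, tpm, expected):
    out = call_pioneer_tfs(_score_row(opening, z, tpm))
    assert bool(out["pioneer"].iloc[0]) is expected


def test_pioneer_calls_monotone_in_each_score():
    rng = np.random.default_rng(6)
    base = pd.DataFrame(
        {
            "tf": [f"t{i}" for i in range(50)],
            "stage": "S1",
            "opening": rng.uniform(0, 5, 50),
            "deviation_z": rng.uniform(0, 20, 50),
            "tpm": rng.uniform(0, 10, 50),
        }
    )
    called = set(call_pioneer_tfs(base).query("pioneer")["tf"])
    for col in ("opening", "deviation_z", "tpm"):
        raised = base.copy()
        raised[col] = raised[col] + 1.0
        called_up = set(call_pioneer_tfs(raised).query("pioneer")["tf"])
        assert called <= called_up


def test_activity_summary_join_and_flags():
    z = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
                     index=["a", "b"], columns=["S1", "S2", "S3"])
    expr = pd.DataFrame([[10.0, 20.0, 30.0]], index=["a"], columns=["S1", "S2", "S3"])
    out = tf_activity_summary(z, expr)
    assert len(out) == 6
    assert out[out.tf == "a"]["complete"].all()
    assert not out[out.tf == "b"]["complete"].any()
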