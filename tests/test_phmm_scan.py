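"""Profile-HMM construction, Viterbi scoring, scanning and calibration."""

import itertools

import numpy as np
import pytest

import riboregulon as rb
from riboregulon.phmm_scan import (ModelDegeneracyError, batch_glocal_scores,
                                   encode_seq, revcomp)


def tiny_model(rows, pseudocount=1.0, gap_threshold=0.5):
    return rb.build_phmm([(f"r{i}", s) for i, s in enumerate(rows)],
                         pseudocount=pseudocount, gap_threshold=gap_threshold)


# ---------------------------------------------------------------------------
# construction


def test_match_emission_smoothing_formula():
    """(count + pc) / (total + 4 pc): column of three A's gives P(A) = 4/7."""
    m = tiny_model(["ACGT", "A-GT", "ACGA"], pseudocount=1.0)
    assert m.length == 4
    assert m.match_emissions[0, 0] == pytest.approx(4 / 7)
    # column 2 has C, gap, C: P(C) = (2+1)/(2+4)
    assert m.match_emissions[1, 1] == pytest.approx(3 / 6)


def test_emissions_and_transitions_normalised():
    m = tiny_model(["ACGT", "A-GT", "ACGA", "AC-T", "TCGT"])
    assert np.allclose(m.match_emissions.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(m.insert_emissions.sum(axis=1), 1.0, atol=1e-9)
    for k in range(m.length + 1):
        for t in ((m.t_mm, m.t_mi, m.t_md), (m.t_im, m.t_ii, m.t_id)):
            probs = [2.0 ** t_[k] for t_ in t if np.isfinite(t_[k])]
            assert sum(probs) == pytest.approx(1.0, abs=1e-9)


def test_transition_counts_match_manual_tally():
    """Transitions equal a brute-force tally over per-row M/I/D state paths."""
    rows = ["AC-GTA", "A-CG-A", "ACAGTA", "-CCGTA", "AC-GT-"]
    pc = 0.5
    m = tiny_model(rows, pseudocount=pc, gap_threshold=0.4)
    # columns with gap fraction <= 0.4 are match states; tally by the same
    # published rule, implemented independently here
    ncol = len(rows[0])
    nrow = len(rows)
    gapf = [sum(r[c] == "-" for r in rows) / nrow for c in range(ncol)]
    match_cols = [c for c in range(ncol) if gapf[c] <= 0.4]
    assert m.match_columns == match_cols
    counts = {}
    for r in rows:
        prev = ("M", 0)
        for c in range(ncol):
            if c in match_cols:
                k = match_cols.index(c) + 1
                kind = "D" if r[c] == "-" else "M"
                counts[prev + (kind,)] = counts.get(prev + (kind,), 0) + 1
                prev = (kind, k)
            elif r[c] != "-":
                counts[prev + ("I",)] = counts.get(prev + ("I",), 0) + 1
                prev = ("I", prev[1])
        counts[prev + ("M",)] = counts.get(prev + ("M",), 0) + 1
    L = m.length
    arr = {"M": {"M": m.t_mm, "I": m.t_mi, "D": m.t_md},
           "I": {"M": m.t_im, "I": m.t_ii, "D": m.t_id},
           "D": {"M": m.t_dm, "I": m.t_di, "D": m.t_dd}}
    for (kind, k) in [("M", k) for k in range(L + 1)] + \
                     [("I", k) for k in range(L + 1)] + \
                     [("D", k) for k in range(1, L + 1)]:
        n_out = 2 if k == L else 3
        total = sum(counts.get((kind, k, d), 0) for d in "MID")
        for d, pcount in (("M", pc), ("I", pc), ("D", pc if k < L else 0.0)):
            got = 2.0 ** arr[kind][d][k]
            if d == "D" and k == L:
                continue
            want = (counts.get((kind, k, d), 0) + pc) / (total + n_out * pc)
            assert got == pytest.approx(want, abs=1e-12), (kind, k, d)


def test_zero_match_columns_raises():
    with pytest.raises(ModelDegeneracyError):
        tiny_model(["A---", "-C--", "--G-"], gap_threshold=0.1)


def test_degenerate_nucleotides_map_to_n():
    assert list(encode_seq("ACGTRYN")) == [0, 1, 2, 3, 4, 4, 4]


# ---------------------------------------------------------------------------
# Viterbi


def uniform_two_state_model():
    """Two match states, uniform emissions, deterministic M->M transitions."""
    L = 2
    ninf = -np.inf
    return rb.ProfileHMM(
        length=L,
        match_emissions=np.full((L, 4), 0.25),
        insert_emissions=np.full((L + 1, 4), 0.25),
        background=np.full(4, 0.25), pseudocount=0.0,
        t_mm=np.zeros(L + 1), t_mi=np.full(L + 1, ninf),
        t_md=np.full(L + 1, ninf), t_im=np.full(L + 1, ninf),
        t_ii=np.full(L + 1, ninf), t_id=np.full(L + 1, ninf),
        t_dm=np.full(L + 1, ninf), t_di=np.full(L + 1, ninf),
        t_dd=np.full(L + 1, ninf))


def test_uniform_model_scores_zero_bits():
    m = uniform_two_state_model()
    for s in ("AA", "CG", "TA", "GT"):
        score, path = rb.viterbi_score(m, s)
        assert score == pytest.approx(0.0, abs=1e-12)
        assert [k for k, _, _ in path] == ["M", "M"]


def _enumerate_paths(model, seq):
    """Exhaustive global path enumeration oracle for tiny models.

    States are generated recursively following the M/I/D topology; returns
    the best total log-odds score over all legal paths."""
    L = len(seq)
    x = encode_seq(seq)
    em, ei = model.match_logodds, model.insert_logodds
    trans = {("M", "M"): model.t_mm, ("M", "I"): model.t_mi, ("M", "D"): model.t_md,
             ("I", "M"): model.t_im, ("I", "I"): model.t_ii, ("I", "D"): model.t_id,
             ("D", "M"): model.t_dm, ("D", "I"): model.t_di, ("D", "D"): model.t_dd}
    best = [-np.inf]

    def step(kind, k, i, score):
        if k == model.length and kind in "MID":
            # may only proceed to end (after optional inserts at I_L)
            pass
        if i == L and k == model.length:
            end = score + trans[(kind, "M")][k]
            if end > best[0]:
                best[0] = end
        for nxt in "MID":
            t = trans[(kind, nxt)][k]
            if not np.isfinite(t):
                continue
            if nxt == "M" and k < model.length and i < L:
                step("M", k + 1, i + 1, score + t + em[k, x[i]])
            elif nxt == "I" and i < L:
                step("I", k, i + 1, score + t + ei[k, x[i]])
            elif nxt == "D" and k < model.length:
                step("D", k + 1, i, score + t)

    step("M", 0, 0, 0.0)
    return best[0]


def test_viterbi_equals_exhaustive_enumeration_all_3mers():
    """DP score matches brute-force path enumeration on a 3-state toy model."""
    m = tiny_model(["ACG", "A-G", "ACG", "ATG", "AC-"], pseudocount=0.7)
    assert m.length == 3
    for combo in itertools.product("ACGT", repeat=3):
        seq = "".join(combo)
        dp, _ = rb.viterbi_score(m, seq)
        assert dp == pytest.approx(_enumerate_paths(m, seq), abs=1e-9), seq


@pytest.mark.parametrize("seq", ["A", "AC", "ACGTC", "NNNN"])
def test_viterbi_equals_enumeration_varied_lengths(seq):
    m = tiny_model(["ACG", "A-G", "ACG", "ATG", "AC-"], pseudocount=0.7)
    dp, _ = rb.viterbi_score(m, seq)
    assert dp == pytest.approx(_enumerate_paths(m, seq), abs=1e-9)


def test_consensus_path_closed_form(aptamer_model):
    """For a sharply peaked model the consensus attains the all-match path sum."""
    rows = ["ACGTACGT"] * 8
    m = tiny_model(rows, pseudocount=1e-9)
    score, path = rb.viterbi_score(m, "ACGTACGT")
    closed = m.t_mm.sum() + sum(m.match_logodds[k, :4].max() for k in range(m.length))
    assert score == pytest.approx(closed, abs=1e-9)
    assert all(k == "M" for k, _, _ in path)


def test_identical_rows_consensus_is_viterbi_optimum():
    """Zero-entropy limit: no other 8-mer outscores the consensus."""
    m = tiny_model(["GATTACCA"] * 6, pseudocount=1e-9)
    best, _ = rb.viterbi_score(m, "GATTACCA")
    rng = np.random.default_rng(0)
    for _ in range(50):
        other = "".join(rng.choice(list("ACGT"), size=8))
        assert rb.viterbi_score(m, other)[0] <= best + 1e-12


def test_empty_sequence_raises(aptamer_model):
    with pytest.raises(ValueError):
        rb.viterbi_score(aptamer_model, "")


def test_batch_glocal_agrees_with_single(aptamer_model):
    rng = np.random.default_rng(1)
    wins = rng.integers(0, 4, size=(8, 2 * aptamer_model.length)).astype(np.int8)
    batch = batch_glocal_scores(aptamer_model, wins)
    for i in range(len(wins)):
        seq = "".join("ACGT"[c] for c in wins[i])
        single, _ = rb.viterbi_score(aptamer_model, seq, mode="glocal")
        assert batch[i] == pytest.approx(single, abs=1e-9)


# ---------------------------------------------------------------------------
# scanning


@pytest.fixture(scope="module")
def calibrated(aptamer_model):
    thr = rb.calibrate_threshold(aptamer_model, rb.iid_background(0.5),
                                 target_fpr=1e-4, n_windows=10000, seed=11)
    return aptamer_model, thr


def test_scan_recovers_planted_motif(calibrated):
    model, thr = calibrated
    cfg = rb.SimConfig(seed=17, n_genomes=1, genome_length=4000,
                       motif_identity=0.95)
    genomes, _, _, truth = rb.simulate_genomes(cfg)
    hits = rb.scan_genome(model, "g000", genomes[0].seq, thr)
    assert len(hits) == 1
    gid, s, e, strand = truth.planted_hits[0]
    h = hits[0]
    overlap = max(0, min(e, h.end) - max(s, h.start))
    assert h.strand == strand
    assert overlap >= 0.9 * (e - s)


def test_minus_strand_hit_reported_on_forward_coordinates(calibrated):
    model, thr = calibrated
    for seed in range(4, 12):
        cfg = rb.SimConfig(seed=seed, n_genomes=1, genome_length=4000,
                           motif_identity=1.0)
        genomes, _, _, truth = rb.simulate_genomes(cfg)
        gid, s, e, strand = truth.planted_hits[0]
        if strand != "-":
            continue
        hits = rb.scan_genome(model, gid, genomes[0].seq, thr)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (s, e)
        return
    pytest.fail("no minus-strand plant among seeds")


def test_all_n_genome_yields_no_hits(calibrated):
    model, thr = calibrated
    assert rb.scan_genome(model, "gN", "N" * 1000, thr) == []


def test_strand_symmetry_of_scan(calibrated):
    """Scanning the reverse complement swaps strands and reflects coordinates."""
    model, thr = calibrated
    cfg = rb.SimConfig(seed=23, n_genomes=1, genome_length=4000, motif_identity=0.95)
    genomes, _, _, _ = rb.simulate_genomes(cfg)
    seq = genomes[0].seq
    fwd = rb.scan_genome(model, "g", seq, thr)
    rev = rb.scan_genome(model, "g", revcomp(seq), thr)
    n = len(seq)
    flipped = sorted((n - h.end, n - h.start, "+" if h.strand == "-" else "-",
                      round(h.score, 6)) for h in rev)
    assert flipped == sorted((h.start, h.end, h.strand, round(h.score, 6))
                             for h in fwd)


def test_merging_idempotence_step_one_vs_half_window(calibrated):
    model, thr = calibrated
    cfg = rb.SimConfig(seed=29, n_genomes=1, genome_length=4000, motif_identity=1.0)
    genomes, _, _, _ = rb.simulate_genomes(cfg)
    seq = genomes[0].seq
    w = 2 * model.length
    dense = rb.scan_genome(model, "g", seq, thr, window=w, step=1)
    sparse = rb.scan_genome(model, "g", seq, thr, window=w, step=w // 2)
    assert [(h.start, h.end, h.strand) for h in dense] == \
           [(h.start, h.end, h.strand) for h in sparse]


def test_window_smaller_than_model_raises(aptamer_model):
    with pytest.raises(ValueError):
        rb.scan_genome(aptamer_model, "g", "ACGT" * 100, 0.0,
                       window=aptamer_model.length - 1)


# ---------------------------------------------------------------------------
# calibration


def test_calibration_median_at_fpr_half(aptamer_model):
    thr = rb.calibrate_threshold(aptamer_model, rb.iid_background(0.5),
                                 target_fpr=0.5, n_windows=501, seed=5)
    rng = np.random.default_rng(5)
    wins = rb.iid_background(0.5)(rng, 501, 2 * aptamer_model.length)
    scores = batch_glocal_scores(aptamer_model, wins)
    assert thr == pytest.approx(float(np.median(scores)), abs=1e-9)


def test_calibration_matches_independent_quantile(aptamer_model):
    fpr = 1e-2
    thr = rb.calibrate_threshold(aptamer_model, rb.iid_background(0.4),
                                 target_fpr=fpr, n_windows=2000, seed=7)
    rng = np.random.default_rng(7)
    wins = rb.iid_background(0.4)(rng, 2000, 2 * aptamer_model.length)
    scores = np.sort(batch_glocal_scores(aptamer_model, wins))
    # linear-interpolation quantile recomputed by its textbook formula
    h = (len(scores) - 1) * (1 - fpr)
    lo = int(np.floor(h))
    want = scores[lo] + (h - lo) * (scores[min(lo + 1, len(scores) - 1)] - scores[lo])
    assert thr == pytest.approx(float(want), abs=1e-9)


def test_calibration_threshold_monotone_in_fpr(aptamer_model):
    t_loose = rb.calibrate_threshold(aptamer_model, rb.iid_background(0.5),
                                     1e-1, 4000, seed=3)
    t_strict = rb.calibrate_threshold(aptamer_model, rb.iid_background(0.5),
                                      1e-3, 4000, seed=3)
    assert t_strict >= t_loose


def test_calibration_resolution_error(aptamer_model):
    with pytest.raises(ValueError):
        rb.calibrate_threshold(aptamer_model, rb.iid_background(0.5),
                               1e-4, 100, seed=1)


# ---------------------------------------------------------------------------
# structure compatibility


def test_structure_compat_consensus_scores_one(aptamer_model, consensus_structure):
    frac, ok = rb.structure_compat(aptamer_model.consensus, aptamer_model,
                                   consensus_structure)
    assert frac == pytest.approx(1.0)
    assert ok


def test_structure_compat_counts_disrupted_helix(aptamer_model, consensus_structure):
    """Breaking 4 of 24 pairs with complement-breaking substitutions: 20/24."""
    seq = list(aptamer_model.consensus)
    broken = 0
    comp_break = {"A": "C", "C": "A", "G": "G", "T": "C"}
    for a, b in consensus_structure.pairs[:4]:
        seq[b] = {"A": "A", "C": "C", "G": "A", "T": "T"}.get(seq[a], "A")
        # force a non-canonical pairing at column b
        partner = seq[a]
        for cand in "ACGT":
            if (partner, cand) not in {("A", "T"), ("T", "A"), ("G", "C"),
                                       ("C", "G"), ("G", "T"), ("T", "G")}:
                seq[b] = cand
                break
        broken += 1
    frac, ok = rb.structure_compat("".join(seq), aptamer_model, consensus_structure)
    n = len(consensus_structure.pairs)
    assert frac == pytest.approx((n - broken) / n)


def test_structure_compat_indeterminate_when_no_pair_matched(aptamer_model):
    """A structure over columns absent from the path flags indeterminate."""
    cs = rb.ConsensusStructure(structure="", pairs=[])
    frac, ok = rb.structure_compat(aptamer_model.consensus, aptamer_model, cs)
    assert frac is None and ok is None


def test_consensus_structure_balanced_brackets():
    cs = rb.ConsensusStructure.from_dotbracket("((..))..<>")
    assert cs.pairs == [(0, 5), (1, 4), (8, 9)]
    with pytest.raises(ValueError):
        rb.ConsensusStructure.from_dotbracket("((..)")
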