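"""Transmission inference, greedy phasing vs exhaustive oracle, breakpoints."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_population, flip_map_vs_truth, informative_bp, make_tm
from crosshap import markers as mk
from crosshap import phasing, popsim
from crosshap.markers import GenotypeMatrix
from crosshap.phasing import UNKNOWN


def gm_from_rows(mother, father, progeny_rows):
    """Multi-marker matrix; each arg row is a list of (a, b) call tuples."""
    n_prog = len(progeny_rows[0])
    inds = ["mo", "fa"] + [f"k{j}" for j in range(n_prog)]
    m = len(mother)
    calls = np.full((m, len(inds), 2), mk.MISSING, dtype="<U1")
    for i in range(m):
        calls[i, 0] = list(mother[i])
        calls[i, 1] = list(father[i])
        for j in range(n_prog):
            calls[i, 2 + j] = list(progeny_rows[i][j])
    markers = pd.DataFrame(
        {"lg": ["LG1"] * m, "bp": [(i + 1) * 100 for i in range(m)]},
        index=pd.Index([f"LG1_{(i + 1) * 100}" for i in range(m)], name="marker"),
    )
    return GenotypeMatrix(markers, inds, calls, "mo", "fa")


@pytest.mark.parametrize(
    "child, expected, is_err",
    [
        (("A", "G"), "A", False),   # obligate paternal G removed -> maternal A
        (("G", "G"), "G", False),   # both G: maternal allele must be G
        (("A", "A"), ".", True),    # no paternal G present: Mendelian error
    ],
)
def test_obligate_allele_subtraction(child, expected, is_err):
    gm = gm_from_rows([("A", "G")], [("G", "G")], [[child]])
    classes = mk.classify_markers(gm)
    at = phasing.raw_transmission(gm, classes, "maternal")
    assert at.alleles[0, 0] == expected
    assert bool(at.mendel_error[0, 0]) is is_err


def test_subtraction_when_hom_parent_shares_no_allele():
    # mother A/G, father C/C is not a biallelic SNP -> unusable, no transmissions
    gm = gm_from_rows([("A", "G")], [("C", "C")], [[("A", "C")]])
    with pytest.warns(UserWarning):
        classes = mk.classify_markers(gm)
    at = phasing.raw_transmission(gm, classes, "maternal")
    assert at.alleles.shape[0] == 0


def test_perfect_cosegregation_phases_with_zero_recombination():
    # 2 markers x 8 progeny, alleles perfectly co-segregating
    mom = [("A", "G"), ("C", "T")]
    dad = [("G", "G"), ("T", "T")]
    kids_m1 = [("A", "G")] * 4 + [("G", "G")] * 4
    kids_m2 = [("C", "T")] * 4 + [("T", "T")] * 4
    gm = gm_from_rows(mom, dad, [kids_m1, kids_m2])
    classes = mk.classify_markers(gm)
    tm = phasing.phase_parent(phasing.raw_transmission(gm, classes, "maternal"))
    assert phasing.count_recombinations(tm.labels) == 0


def exhaustive_min_recombinations(t):
    """Oracle: minimum total recombinations over all 2^(m-1) orientations.

    ``t`` is (m, n) with entries 0/1 (complete data).  Recombinations are
    counted per progeny between consecutive markers after orientation.
    """
    m = t.shape[0]
    best = None
    for bits in product([0, 1], repeat=m - 1):
        o = np.array((0,) + bits)
        lab = t ^ o[:, None]
        c = int(np.sum(lab[1:] != lab[:-1]))
        best = c if best is None else min(best, c)
    return best


@pytest.mark.parametrize("seed", range(30))
def test_greedy_phasing_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    t = rng.integers(0, 2, size=(4, 6)).astype(np.int8)
    tm = make_tm("maternal", np.zeros_like(t))  # shape/metadata only
    at = phasing.AlleleTransmission(
        "maternal", tm.markers, tm.progeny,
        alleles=np.where(t == 0, "A", "G").astype("<U1"),
        het_pair=np.array([["A", "G"]] * 4),
        mendel_error=np.zeros_like(t, dtype=bool),
    )
    phased = phasing.phase_parent(at)
    assert phasing.count_recombinations(phased.labels) == exhaustive_min_recombinations(t)


def test_label_flip_leaves_breakpoints_and_partition_invariant():
    labels = np.array([
        [1, 1, 2, 2],
        [1, 1, 2, 2],
        [1, 2, 2, 2],
        [1, 2, 2, 2],
        [1, 2, 2, 2],
    ])
    tm = make_tm("maternal", labels)
    flipped = tm.flipped()
    bp1 = phasing.detect_breakpoints(tm, min_run=1)
    bp2 = phasing.detect_breakpoints(flipped, min_run=1)
    pd.testing.assert_frame_equal(bp1, bp2)
    assert np.array_equal(np.where(tm.labels == 0, 0, 3 - tm.labels), flipped.labels)


@pytest.mark.parametrize(
    "seq, min_run, expected_intervals",
    [
        ("1111122222", 1, [(5000, 6000)]),
        ("1111111111", 1, []),
        ("1112111111", 3, []),                  # isolated 2 smoothed away
        ("1111221111", 3, []),                  # short double-flip masked, flanks merge
        ("1112222222", 3, [(3000, 4000)]),      # genuine switch, both runs long enough
    ],
)
def test_breakpoint_detection_rules(seq, min_run, expected_intervals):
    labels = np.array([[int(c)] for c in seq])
    tm = make_tm("maternal", labels)
    got = phasing.detect_breakpoints(tm, min_run=min_run)
    assert [(r.start_bp, r.end_bp) for r in got.itertuples()] == expected_intervals


def test_smoothing_masks_short_runs_only():
    seq = np.array([1, 1, 1, 2, 1, 1, 2, 2, 2], dtype=np.int8)
    out = phasing.smooth_labels(seq, min_run=3)
    # every run shorter than min_run is masked, including the length-2 [1,1]
    assert list(out) == [1, 1, 1, 0, 0, 0, 2, 2, 2]
    assert list(phasing.smooth_labels(seq, min_run=1)) == list(seq)
    assert list(phasing.smooth_labels(seq, min_run=2)) == [1, 1, 1, 0, 1, 1, 2, 2, 2]


def test_transmissions_recovered_exactly_without_error(clean_pop):
    """Zero error/missing: inferred transmissions equal truth up to per-LG
    label switching, with no unknowns."""
    truth = clean_pop["truth"]
    for parent, tm in clean_pop["tms"].items():
        assert (tm.labels != UNKNOWN).all()
        flip_map_vs_truth(tm, truth, parent)  # raises if not flip-equal


def test_breakpoints_contain_true_crossovers_without_error(clean_pop):
    truth, tms = clean_pop["truth"], clean_pop["tms"]
    bps = pd.concat([phasing.detect_breakpoints(tm, min_run=1)
                     for tm in tms.values()], ignore_index=True)
    score = popsim.score_breakpoint_recovery(truth, bps, informative_bp(tms))
    assert score["n_recovered"] == score["n_detectable"]
    assert score["n_unmatched_inferred"] == 0


def test_breakpoint_recovery_with_skim_error():
    """1% genotype error, min_run=3: >=95% of detectable crossovers recovered
    within one flanking-marker interval when each parent sees ~200 informative
    markers per linkage group.  (A switch needs min_run markers on each side,
    so crossovers within min_run-1 markers of a group end are lost — the rate
    is therefore reported against the informative-marker sequence length.)"""
    rec, det = 0, 0
    for seed in (21, 22, 23):
        pop = build_population(n_lg=2, markers_per_lg=500, n_progeny=60,
                               missing_rate=0.0, genotype_error_rate=0.01, seed=seed)
        bps = pd.concat([phasing.detect_breakpoints(tm, min_run=3)
                         for tm in pop["tms"].values()], ignore_index=True)
        score = popsim.score_breakpoint_recovery(
            pop["truth"], bps, informative_bp(pop["tms"]), slack_markers=1)
        rec += score["n_recovered"]
        det += score["n_detectable"]
    assert det > 300
    assert rec / det >= 0.95


@given(
    seq=st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=40),
    min_run=st.integers(min_value=1, max_value=5),
)
@settings(max_examples=80, deadline=None, derandomize=True)
def test_smoothing_invariants(seq, min_run):
    """Smoothing never invents labels, leaves only runs >= min_run, and is
    idempotent."""
    arr = np.array(seq, dtype=np.int8)
    out = phasing.smooth_labels(arr, min_run)
    assert np.all((out == arr) | (out == UNKNOWN))
    known = out[out != UNKNOWN]
    if len(known):
        run_lengths = []
        start = 0
        for k in range(1, len(known) + 1):
            if k == len(known) or known[k] != known[start]:
                run_lengths.append(k - start)
                start = k
        assert min(run_lengths) >= min_run
    assert np.array_equal(phasing.smooth_labels(out, min_run), out)


def test_transmissions_tsv_round_trip(tmp_path, clean_pop):
    tm = clean_pop["tms"]["maternal"]
    path = tmp_path / "tm.tsv"
    phasing.write_transmissions_tsv(tm, path)
    back = phasing.read_transmissions_tsv(path, "maternal")
    assert np.array_equal(back.labels, tm.labels)
    assert back.progeny == tm.progeny
    assert back.markers["bp"].tolist() == tm.markers["bp"].tolist()
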