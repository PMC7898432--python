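"""Region diplotype calls, recombinant exclusion, ANOVA/Tukey, SNP panels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import build_population, flip_map_vs_truth, make_tm
from crosshap import diplotypes as dip
from crosshap.association import QTLRegion
from crosshap.phasing import UNKNOWN


def region(start=1000, end=9000, lg="LG1"):
    return QTLRegion(f"{lg}:{start}-{end}", lg, start, end, [], float("nan"))


def tms_pair(mat_rows, pat_rows, **kw):
    return {"maternal": make_tm("maternal", mat_rows, **kw),
            "paternal": make_tm("paternal", pat_rows, **kw)}


def test_exactly_four_diplotype_classes():
    classes = dip.enumerate_diplotypes()
    assert sorted(classes) == ["M1P1", "M1P2", "M2P1", "M2P2"]
    assert len(set(classes)) == 4


def test_uniform_labels_give_clean_call_with_prefixes():
    tms = tms_pair(np.full((5, 1), 2), np.full((5, 1), 2))
    calls = dip.call_region_diplotypes(tms, region(), min_run=1)
    assert calls["call"].iloc[0] == "M2P2"
    assert dip.render_call(calls["call"].iloc[0], ("TA", "KP")) == "TA2KP2"


def test_both_labels_from_one_parent_is_recombinant():
    mat = np.array([[1], [1], [2], [2], [2]])
    tms = tms_pair(mat, np.full((5, 1), 1))
    calls = dip.call_region_diplotypes(tms, region(), min_run=1)
    assert calls["call"].iloc[0] == dip.RECOMBINANT


def test_all_unknown_labels_give_unknown():
    tms = tms_pair(np.full((5, 1), UNKNOWN), np.full((5, 1), UNKNOWN))
    calls = dip.call_region_diplotypes(tms, region(), min_run=1)
    assert calls["call"].iloc[0] == dip.UNKNOWN_CALL


def test_low_information_fraction_gives_unknown():
    mat = np.array([[2], [UNKNOWN], [UNKNOWN], [UNKNOWN], [UNKNOWN]])
    tms = tms_pair(mat, np.full((5, 1), 1))
    calls = dip.call_region_diplotypes(tms, region(), min_info_frac=0.5, min_run=1)
    assert calls["call"].iloc[0] == dip.UNKNOWN_CALL


def test_isolated_flip_smoothed_not_recombinant():
    mat = np.array([[2], [2], [1], [2], [2], [2]])
    tms = tms_pair(mat, np.full((6, 1), 1))
    calls = dip.call_region_diplotypes(tms, region(), min_run=3)
    assert calls["call"].iloc[0] == "M2P1"


TOY_GROUPS = {
    "M1P1": [388.0, 402.0, 371.0, 419.0, 395.0],
    "M2P1": [329.0, 301.0, 344.0, 362.0],
    "M2P2": [499.0, 530.0, 477.0, 481.0, 512.0, 468.0],
}


def toy_calls_pheno():
    rows, ph = [], []
    k = 0
    for call, vals in TOY_GROUPS.items():
        for v in vals:
            rows.append((f"i{k}", "LG1:1-2", call, 1.0, 1.0))
            ph.append((f"i{k}", v))
            k += 1
    calls = pd.DataFrame(rows, columns=["individual", "region_id", "call",
                                        "frac_maternal", "frac_paternal"])
    pheno = pd.DataFrame(ph, columns=["individual", "trait"])
    return calls, pheno


def test_anova_f_matches_scipy_oracle():
    calls, pheno = toy_calls_pheno()
    rep = dip.diplotype_effect_test(calls, pheno)
    f, p = stats.f_oneway(*[np.array(v) for v in TOY_GROUPS.values()])
    assert rep.f_stat == pytest.approx(f, abs=1e-10)
    assert rep.p_value == pytest.approx(p, abs=1e-12)
    assert rep.df_between == 2 and rep.df_within == 12
    assert len(rep.tukey) == 3  # C(3,2) pairs


def test_tukey_matches_statsmodels_oracle():
    calls, pheno = toy_calls_pheno()
    rep = dip.diplotype_effect_test(calls, pheno)
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    merged = calls.merge(pheno, on="individual")
    sm = pairwise_tukeyhsd(merged["trait"], merged["call"])
    pairs = list(combinations(sm.groupsunique, 2))
    sm_p = {frozenset(pair): p for pair, p in zip(pairs, sm.pvalues)}
    for row in rep.tukey.itertuples():
        assert row.p_adj == pytest.approx(sm_p[frozenset((row.group1, row.group2))],
                                          abs=1e-8)


def test_identical_groups_give_f_zero_p_one():
    calls, pheno = toy_calls_pheno()
    pheno["trait"] = 400.0
    rep = dip.diplotype_effect_test(calls, pheno)
    assert rep.f_stat == 0.0 and rep.p_value == 1.0


def test_two_group_tukey_p_equals_anova_p():
    calls, pheno = toy_calls_pheno()
    keep = calls["call"] != "M1P1"
    rep = dip.diplotype_effect_test(calls[keep], pheno)
    assert len(rep.tukey) == 1
    assert rep.tukey["p_adj"].iloc[0] == pytest.approx(rep.p_value, abs=1e-9)


def test_recombinants_excluded_but_counted():
    calls, pheno = toy_calls_pheno()
    calls.loc[calls.index[:2], "call"] = dip.RECOMBINANT
    calls.loc[calls.index[2], "call"] = dip.UNKNOWN_CALL
    rep = dip.diplotype_effect_test(calls, pheno)
    assert rep.n_recombinant == 2 and rep.n_unknown == 1
    assert rep.n_called == len(calls) - 3
    assert int(rep.groups["n"].sum()) == rep.n_called


def test_single_usable_group_yields_null_report():
    calls, pheno = toy_calls_pheno()
    calls.loc[calls["call"] != "M2P2", "call"] = dip.RECOMBINANT
    rep = dip.diplotype_effect_test(calls, pheno)
    assert rep.f_stat is None and rep.reason is not None


def test_welch_variant_behaves():
    calls, pheno = toy_calls_pheno()
    rep = dip.diplotype_effect_test(calls, pheno, welch=True)
    assert 0 < rep.p_value < 0.05


def test_zero_error_diplotypes_match_truth(clean_pop):
    """At zero error the region calls equal the simulator's diplotypes (up to
    the per-LG label flip), and RECOMBINANT calls are exactly the individuals
    whose true transmissions switch within the region's informative markers."""
    truth, tms = clean_pop["truth"], clean_pop["tms"]
    reg = region(start=4_000_000, end=10_000_000, lg="LG1")
    calls = dip.call_region_diplotypes(tms, reg, min_run=1)
    flips = {p: flip_map_vs_truth(tms[p], truth, p)["LG1"] for p in tms}
    for row in calls.itertuples():
        true_sets = {}
        for p in ("maternal", "paternal"):
            tm = tms[p]
            sel = ((tm.markers["lg"] == "LG1") & (tm.markers["bp"] >= reg.start_bp)
                   & (tm.markers["bp"] <= reg.end_bp)).to_numpy()
            rows = truth.markers.index.get_indexer(tm.markers.index[sel])
            j = truth.individuals.index(row.individual)
            true_sets[p] = set(truth.transmissions[p][rows, j])
        if any(len(s) > 1 for s in true_sets.values()):
            assert row.call == dip.RECOMBINANT
        else:
            m = true_sets["maternal"].pop()
            p_ = true_sets["paternal"].pop()
            if flips["maternal"]:
                m = 3 - m
            if flips["paternal"]:
                p_ = 3 - p_
            assert row.call == f"M{m}P{p_}"


def test_full_panel_agreement_is_one(clean_pop):
    tms = clean_pop["tms"]
    reg = region(start=4_000_000, end=10_000_000, lg="LG1")
    full_markers = []
    for tm in tms.values():
        sel = ((tm.markers["lg"] == "LG1") & (tm.markers["bp"] >= reg.start_bp)
               & (tm.markers["bp"] <= reg.end_bp))
        full_markers += list(tm.markers.index[sel])
    out = dip.predict_diplotype_from_snp_panel(tms, reg, full_markers)
    assert out["agreement"] == 1.0


def test_empty_panel_rejected(clean_pop):
    with pytest.raises(ValueError, match="at least one"):
        dip.predict_diplotype_from_snp_panel(clean_pop["tms"], region(), [])


def test_24_snp_panel_predicts_diplotypes():
    """~24 evenly spaced region SNPs with skim-like noise call the region
    diplotype in >=95% of individuals; a single SNP does markedly worse."""
    pop = build_population(n_lg=1, markers_per_lg=200, n_progeny=80,
                           missing_rate=0.1, genotype_error_rate=0.01, seed=31)
    tms = pop["tms"]
    reg = region(start=4_000_000, end=12_000_000, lg="LG1")
    union = []
    for tm in tms.values():
        sel = ((tm.markers["lg"] == "LG1") & (tm.markers["bp"] >= reg.start_bp)
               & (tm.markers["bp"] <= reg.end_bp))
        union += [(bp, m) for m, bp in tm.markers.loc[sel, "bp"].items()]
    union = [m for _, m in sorted(union)]
    panel24 = [union[i] for i in np.linspace(0, len(union) - 1, 24).astype(int)]
    out24 = dip.predict_diplotype_from_snp_panel(tms, reg, panel24)
    out1 = dip.predict_diplotype_from_snp_panel(tms, reg, [union[len(union) // 2]])
    assert out24["agreement"] >= 0.95
    assert out1["agreement"] < out24["agreement"]
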