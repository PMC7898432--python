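"""Region-level diplotype calling and diplotype-effect testing.

Within a QTL region each individual carries one haplotype from each parent, so
with two phased haplotypes per parent exactly four diplotype classes exist:
M1P1, M1P2, M2P1, M2P2 (rendered e.g. TA1KP1 ... TA2KP2 with user-supplied
parent prefixes).  A parent's haplotype over the region is assigned only when
a single label is observed across the region's informative markers — seeing
both labels from one parent is evidence of a recombination event inside the
region, and such individuals are reported as RECOMBINANT and excluded from the
effect test.  Isolated single-marker label flips are masked first with the
same run-length smoothing used for breakpoint calling, so that genotyping
noise is not mistaken for recombination.

Diplotype effects on the trait are tested by one-way fixed-effects ANOVA with
post hoc Tukey HSD (studentized-range) pairwise comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import QTLRegion
from .phasing import UNKNOWN, TransmissionMatrix, smooth_labels

RECOMBINANT = "RECOMBINANT"
UNKNOWN_CALL = "UNKNOWN"

DIPLOTYPE_CLASSES = ("M1P1", "M1P2", "M2P1", "M2P2")

__all__ = [
    "RECOMBINANT",
    "UNKNOWN_CALL",
    "DIPLOTYPE_CLASSES",
    "enumerate_diplotypes",
    "call_region_diplotypes",
    "DiplotypeEffectReport",
    "diplotype_effect_test",
    "predict_diplotype_from_snp_panel",
    "render_call",
]


def enumerate_diplotypes() -> tuple[str, ...]:
    """All non-degenerate diplotype classes for two haplotypes per parent."""
    return tuple(f"M{m}P{p}" for m in (1, 2) for p in (1, 2))


def render_call(call: str, prefixes: tuple[str, str] = ("M", "P")) -> str:
    """Rewrite M2P1 as e.g. TA2KP1 given parent prefixes ('TA', 'KP')."""
    if call in (RECOMBINANT, UNKNOWN_CALL):
        return call
    m, p = call[1], call[3]
    return f"{prefixes[0]}{m}{prefixes[1]}{p}"


def _parent_haplotype(labels: np.ndarray, min_info_frac: float) -> tuple[str | int, float]:
    """Reduce one parent's smoothed region labels for one individual.

    Returns (haplotype 1/2, RECOMBINANT or UNKNOWN_CALL, info fraction).
    """
    n = len(labels)
    known = labels[labels != UNKNOWN]
    frac = len(known) / n if n else 0.0
    if n == 0:
        return UNKNOWN_CALL, 0.0
    uniq = np.unique(known)
    if len(uniq) > 1:
        return RECOMBINANT, frac
    if frac < min_info_frac or len(uniq) == 0:
        return UNKNOWN_CALL, frac
    return int(uniq[0]), frac


def call_region_diplotypes(
    tms: dict[str, TransmissionMatrix],
    region: QTLRegion,
    min_info_frac: float = 0.5,
    min_run: int = 3,
    marker_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-individual diplotype over a QTL region.

    ``tms`` maps 'maternal'/'paternal' to the corresponding phased
    transmission matrices.  Per parent, region labels are smoothed
    (``min_run``) and reduced: both haplotype labels observed -> RECOMBINANT;
    fewer than ``min_info_frac`` of that parent's region markers called ->
    UNKNOWN; otherwise the unique observed label.  ``marker_subset`` restricts
    the calculation to a marker panel (see
    :func:`predict_diplotype_from_snp_panel`).

    Returns a DataFrame (individual, region_id, call, frac_maternal,
    frac_paternal).
    """
    per_parent: dict[str, tuple[list, np.ndarray]] = {}
    progeny = None
    for parent in ("maternal", "paternal"):
        tm = tms[parent]
        in_region = (
            (tm.markers["lg"] == region.lg)
            & (tm.markers["bp"] >= region.start_bp)
            & (tm.markers["bp"] <= region.end_bp)
        )
        if marker_subset is not None:
            in_region &= tm.markers.index.isin(marker_subset)
        idx = in_region.to_numpy().nonzero()[0]
        if len(idx) == 0:
            warnings.warn(f"region {region.region_id} has no {parent} informative markers")
        per_parent[parent] = (idx, tm.labels)
        if progeny is None:
            progeny = tm.progeny
        elif tm.progeny != progeny:
            raise ValueError("transmission matrices disagree on progeny")

    rows = []
    for j, ind in enumerate(progeny):
        hap = {}
        frac = {}
        for parent in ("maternal", "paternal"):
            idx, labels = per_parent[parent]
            seq = smooth_labels(labels[idx, j], min_run) if len(idx) else np.array([], np.int8)
            hap[parent], frac[parent] = _parent_haplotype(seq, min_info_frac)
        if RECOMBINANT in hap.values():
            call = RECOMBINANT
        elif UNKNOWN_CALL in hap.values():
            call = UNKNOWN_CALL
        else:
            call = f"M{hap['maternal']}P{hap['paternal']}"
        rows.append((ind, region.region_id, call, frac["maternal"], frac["paternal"]))
    return pd.DataFrame(rows, columns=["individual", "region_id", "call",
                                       "frac_maternal", "frac_paternal"])


@dataclass
class DiplotypeEffectReport:
    """Group summaries plus ANOVA and Tukey HSD results for one region."""

    region_id: str
    groups: pd.DataFrame            # call, n, mean, sd
    n_called: int
    n_recombinant: int
    n_unknown: int
    f_stat: float | None = None
    df_between: int | None = None
    df_within: int | None = None
    p_value: float | None = None
    tukey: pd.DataFrame | None = None
    reason: str | None = None

    def to_json(self) -> str:
        d = {
            "region_id": self.region_id,
            "groups": self.groups.to_dict(orient="records"),
            "n_called": self.n_called,
            "n_recombinant": self.n_recombinant,
            "n_unknown": self.n_unknown,
            "anova": {
                "F": self.f_stat, "df_between": self.df_between,
                "df_within": self.df_within, "p": self.p_value,
            },
            "tukey": None if self.tukey is None else self.tukey.to_dict(orient="records"),
            "reason": self.reason,
        }
        return json.dumps(d, indent=2)


def _anova_oneway(samples: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA with explicit degenerate-case handling."""
    k = len(samples)
    n = sum(len(s) for s in samples)
    grand = np.concatenate(samples).mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n - k
    if ssb <= 0.0:
        return 0.0, df_b, df_w, 1.0
    if ssw <= 0.0:
        return float("inf"), df_b, df_w, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def _welch_anova(samples: list[np.ndarray]):
    """Welch's heteroscedastic one-way ANOVA (F*, df1, df2, p).

    ``df2`` is rounded for the integer-typed report field; the p-value uses
    the unrounded value.
    """
    k = len(samples)
    n = np.array([len(s) for s in samples], dtype=float)
    m = np.array([s.mean() for s in samples])
    v = np.array([s.var(ddof=1) for s in samples])
    if np.any(v <= 0):
        return _anova_oneway(samples)
    w = n / v
    mw = (w * m).sum() / w.sum()
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(f, k - 1, df2))
    return float(f), k - 1, int(round(df2)), p


def diplotype_effect_test(
    calls: pd.DataFrame,
    pheno: pd.DataFrame,
    prefixes: tuple[str, str] = ("M", "P"),
    welch: bool = False,
) -> DiplotypeEffectReport:
    """ANOVA + Tukey HSD of the trait across diplotype groups of one region.

    RECOMBINANT and UNKNOWN individuals are excluded (but counted).  With
    fewer than two groups of size >= 2 the report carries null test fields and
    a ``reason``.  ``welch=True`` substitutes Welch's heteroscedastic ANOVA
    for the classical equal-variance F test (Tukey is still the classical
    studentized-range procedure).
    """
    region_id = calls["region_id"].iloc[0] if len(calls) else ""
    trait = pheno.set_index("individual")["trait"]
    merged = calls.merge(
        trait.rename("trait"), left_on="individual", right_index=True, how="inner"
    )
    n_rec = int((merged["call"] == RECOMBINANT).sum())
    n_unk = int((merged["call"] == UNKNOWN_CALL).sum())
    usable = merged[~merged["call"].isin([RECOMBINANT, UNKNOWN_CALL])]

    grp_stats = (
        usable.groupby("call")["trait"]
        .agg(n="size", mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan)
        .reset_index()
        .sort_values("call")
        .reset_index(drop=True)
    )
    grp_stats["call"] = [render_call(c, prefixes) for c in grp_stats["call"]]
    report = DiplotypeEffectReport(
        region_id=region_id,
        groups=grp_stats,
        n_called=int(len(usable)),
        n_recombinant=n_rec,
        n_unknown=n_unk,
    )
    big = [g for _, g in usable.groupby("call") if len(g) >= 2]
    if len(big) < 2:
        report.reason = "fewer than two diplotype groups with >= 2 members"
        return report

    samples = [g["trait"].to_numpy(dtype=float) for g in big]
    names = [render_call(g["call"].iloc[0], prefixes) for g in big]
    if welch:
        f, df_b, df_w, p = _welch_anova(samples)
    else:
        f, df_b, df_w, p = _anova_oneway(samples)
    report.f_stat, report.df_between, report.df_within, report.p_value = f, df_b, df_w, p

    if np.isfinite(f) and f > 0:
        hsd = stats.tukey_hsd(*samples)
        rows = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                rows.append((names[i], names[j],
                             float(np.mean(samples[i]) - np.mean(samples[j])),
                             float(hsd.pvalue[i, j])))
        report.tukey = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p_adj"])
    else:
        rows = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                rows.append((names[i], names[j],
                             float(np.mean(samples[i]) - np.mean(samples[j])), 1.0))
        report.tukey = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p_adj"])
    return report


def predict_diplotype_from_snp_panel(
    tms: dict[str, TransmissionMatrix],
    region: QTLRegion,
    panel: list[str],
    full_calls: pd.DataFrame | None = None,
    min_info_frac: float = 0.5,
    min_run: int = 2,
) -> dict:
    """Re-call region diplotypes from a marker panel and score agreement.

    Agreement is the fraction of individuals whose full-region call is one of
    the four diplotype classes and whose panel call equals it (panel calls of
    RECOMBINANT/UNKNOWN count as disagreement).  When ``full_calls`` is not
    supplied it is computed with the same ``min_info_frac``/``min_run``.  The
    panel default ``min_run=2`` masks isolated label flips, which on a small
    panel would otherwise masquerade as in-region recombination.  Supports
    choosing a reduced genotyping panel for marker-assisted selection.
    """
    if not panel:
        raise ValueError("panel must contain at least one marker")
    in_window: set[str] = set()
    for tm in tms.values():
        mask = ((tm.markers["lg"] == region.lg)
                & (tm.markers["bp"] >= region.start_bp)
                & (tm.markers["bp"] <= region.end_bp))
        in_window.update(tm.markers.index[mask])
    extra = set(panel) - in_window
    if extra:
        raise ValueError(f"panel markers outside region: {sorted(extra)[:5]}")
    if full_calls is None:
        full_calls = call_region_diplotypes(tms, region, min_info_frac=min_info_frac,
                                            min_run=min_run)
    panel_calls = call_region_diplotypes(
        tms, region, min_info_frac=min_info_frac, min_run=min_run, marker_subset=panel
    )
    merged = full_calls.merge(panel_calls, on=["individual", "region_id"],
                              suffixes=("_full", "_panel"))
    proper = merged[merged["call_full"].isin(DIPLOTYPE_CLASSES)]
    n = len(proper)
    agree = int((proper["call_full"] == proper["call_panel"]).sum())
    return {
        "n_compared": n,
        "n_agree": agree,
        "agreement": agree / n if n else float("nan"),
        "calls": merged,
    }
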