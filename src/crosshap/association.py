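"""Single-marker quantitative-trait association with permutation p-values.

Each marker is tested by ordinary least squares of the trait on a per-marker
predictor — either the transmitted-haplotype indicator from a phased parent
(0/1 for haplotype 1/2) or raw allele dosage — with the Wald t-test giving the
asymptotic p (t distribution, n-2 df).  The asymptotic p is validated by a
per-marker permutation test that shuffles predictor labels across individuals
and recomputes the statistic; the empirical p uses the add-one convention
p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1), so it can never be 0.

Markers whose permutation p passes a threshold (0.001 by default) are merged
into QTL regions while consecutive significant markers on the same linkage
group are within ``max_gap_bp`` of each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

from .phasing import UNKNOWN, TransmissionMatrix

__all__ = [
    "OLSResult",
    "QTLRegion",
    "qassoc",
    "permute_p",
    "permute_p_exact",
    "scan_association",
    "define_regions",
    "haplotype_predictor",
]


@dataclass
class OLSResult:
    slope: float
    t: float
    p: float
    n: int
    flagged: bool = False  # constant predictor (or trait): no test possible


@dataclass
class QTLRegion:
    region_id: str
    lg: str
    start_bp: int
    end_bp: int
    markers: list[str]
    min_p: float

    def contains(self, lg: str, bp: float) -> bool:
        return lg == self.lg and self.start_bp <= bp <= self.end_bp


def qassoc(y: np.ndarray, x: np.ndarray) -> OLSResult:
    """Simple linear regression of trait ``y`` on predictor ``x``.

    NaNs in either vector are dropped pairwise.  A constant predictor or
    constant trait yields slope 0, t 0, p 1 and the ``flagged`` bit.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 3:
        return OLSResult(0.0, 0.0, 1.0, n, flagged=True)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return OLSResult(0.0, 0.0, 1.0, n, flagged=True)
    res = stats.linregress(x, y)
    return OLSResult(float(res.slope), float(res.slope / res.stderr),
                     float(res.pvalue), n)


def _abs_corr_stat(yc: np.ndarray, xc: np.ndarray) -> float:
    """|dot(yc, xc)| — a monotone surrogate for |t| under label permutation.

    With both vectors centred, permuting y leaves its mean and variance
    unchanged, so |t| is a strictly increasing function of |sum(y_perm * xc)|.
    """
    return float(abs(yc @ xc))


def permute_p(
    y: np.ndarray,
    x: np.ndarray,
    n_perm: int,
    rng: np.random.Generator | int,
) -> float:
    """Empirical two-sided permutation p for the OLS slope (add-one corrected).

    Predictor labels are shuffled across individuals; because the |t| ordering
    is the |correlation| ordering, only the permuted cross-products need to be
    computed, which vectorises to a single matrix-vector product.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.PCG64(int(rng)))
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if len(y) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    yc = y - y.mean()
    xc = x - x.mean()
    obs = _abs_corr_stat(yc, xc)
    perms = np.tile(yc, (n_perm, 1))
    rng.permuted(perms, axis=1, out=perms)
    stats_perm = np.abs(perms @ xc)
    tol = 1e-9 * max(obs, 1.0)
    n_ge = int(np.sum(stats_perm >= obs - tol))
    return (1 + n_ge) / (n_perm + 1)


def permute_p_exact(y: np.ndarray, x: np.ndarray, max_n: int = 9) -> float:
    """Exact permutation p by full enumeration of all n! label orders.

    Includes the identity permutation, so the result is at least 1/n!.
    Feasible only for small n (guarded by ``max_n``).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = len(y)
    if n > max_n:
        raise ValueError(f"exact enumeration limited to n <= {max_n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    yc = y - y.mean()
    xc = x - x.mean()
    obs = _abs_corr_stat(yc, xc)
    tol = 1e-9 * max(obs, 1.0)
    n_ge = 0
    n_tot = 0
    for perm in _iter_permutations(range(n)):
        n_tot += 1
        if abs(yc[list(perm)] @ xc) >= obs - tol:
            n_ge += 1
    return n_ge / n_tot


def haplotype_predictor(tm: TransmissionMatrix) -> pd.DataFrame:
    """0/1 indicator of transmitted haplotype 2 per marker, NaN where unknown."""
    x = tm.labels.astype(float)
    x[tm.labels == UNKNOWN] = np.nan
    x = x - 1.0
    return pd.DataFrame(x, index=tm.markers.index, columns=tm.progeny)


def scan_association(
    tm: TransmissionMatrix,
    pheno: pd.DataFrame,
    n_perm: int = 9999,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-marker OLS + permutation scan of one parent's transmissions.

    ``pheno`` needs columns ``individual``/``trait``; individuals without a
    phenotype, and per marker those with unknown transmission, are dropped.
    Returns a DataFrame (marker, lg, bp, parent, n, slope, t, p_asym, p_perm).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.PCG64(0 if rng is None else int(rng)))
    trait = pheno.set_index("individual")["trait"]
    common = [p for p in tm.progeny if p in trait.index]
    y_all = trait.loc[common].to_numpy(dtype=float)
    cols = [tm.progeny.index(p) for p in common]
    pred = haplotype_predictor(tm).iloc[:, cols].to_numpy()

    rows = []
    for i, marker in enumerate(tm.markers.index):
        x = pred[i]
        res = qassoc(y_all, x)
        if res.flagged:
            p_perm = 1.0
        else:
            p_perm = permute_p(y_all, x, n_perm, rng)
        rows.append((marker, tm.markers["lg"].iloc[i], int(tm.markers["bp"].iloc[i]),
                     tm.parent, res.n, res.slope, res.t, res.p, p_perm, res.flagged))
    return pd.DataFrame(rows, columns=["marker", "lg", "bp", "parent", "n",
                                       "slope", "t", "p_asym", "p_perm", "flagged"])


def define_regions(
    assoc: pd.DataFrame,
    threshold: float = 0.001,
    max_gap_bp: int = 1_000_000,
    p_col: str = "p_perm",
) -> list[QTLRegion]:
    """Threshold-and-merge QTL regions from a (possibly multi-parent) scan table.

    Markers with ``p_col`` <= threshold are merged into one region while
    consecutive significant markers on the same linkage group are at most
    ``max_gap_bp`` apart; region bounds are the min/max bp of member markers.
    """
    sig = assoc[assoc[p_col] <= threshold].sort_values(["lg", "bp"])
    regions: list[QTLRegion] = []
    for lg, sub in sig.groupby("lg", sort=False):
        bps = sub["bp"].to_numpy()
        split = np.nonzero(np.diff(bps) > max_gap_bp)[0]
        starts = np.r_[0, split + 1]
        ends = np.r_[split, len(bps) - 1]
        for s, e in zip(starts, ends):
            members = sub.iloc[s:e + 1]
            regions.append(QTLRegion(
                region_id=f"{lg}:{int(members['bp'].min())}-{int(members['bp'].max())}",
                lg=str(lg),
                start_bp=int(members["bp"].min()),
                end_bp=int(members["bp"].max()),
                markers=list(dict.fromkeys(members["marker"])),
                min_p=float(members[p_col].min()),
            ))
    regions.sort(key=lambda r: (r.lg, r.start_bp))
    return regions


def regions_to_frame(regions: list[QTLRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.region_id, r.lg, r.start_bp, r.end_bp, len(r.markers), r.min_p)
         for r in regions],
        columns=["region_id", "lg", "start_bp", "end_bp", "n_snps", "min_p"],
    )
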