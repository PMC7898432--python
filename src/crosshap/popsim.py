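"""Synthetic pseudo-testcross F1 populations with full truth tracking.

Emulates the data structure of a biparental mapping population between two
highly heterozygous tree-crop parents genotyped by low-coverage (skim)
sequencing: a fraction of SNPs is heterozygous in the mother and homozygous in
the father (maternal-informative), a fraction the reverse, plus both-het and
uninformative sites; progeny are built from simulated meioses (Poisson
crossovers, no interference, i.e. the Haldane model) and then corrupted with
genotyping error and missingness.  A quantitative trait receives
diplotype-specific QTL effects, which readily produces transgressive
segregation — progeny far outside both parental means — as observed for fruit
weight in mango.

Every stochastic choice is recorded in a :class:`TruthSet` so downstream
phasing, breakpoint and diplotype inferences can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import MISSING, GenotypeMatrix, MarkerClass

BASES = np.array(["A", "C", "G", "T"])

__all__ = [
    "SimulationConfig",
    "ParentGenome",
    "Gamete",
    "QTLSpec",
    "TruthSet",
    "simulate_parents",
    "simulate_meiosis",
    "simulate_progeny",
    "simulate_trait",
    "simulate_population",
    "default_fruit_weight_qtl",
    "detectable_crossovers",
    "score_breakpoint_recovery",
    "write_truth_tsv",
]


@dataclass
class SimulationConfig:
    """Population and genotyping parameters for one simulated cross.

    Defaults mirror a mango-style mapping population: 104 F1 progeny from two
    heterozygous parents, 20 linkage groups, skim-sequencing-like missingness
    (10%) and genotype error (1%).  Marker density (200/LG) is a desk-scale
    stand-in for the millions of skim-called SNPs; linkage-group physical and
    map lengths approximate a mid-sized fruit-tree chromosome.
    """

    n_lg: int = 20
    markers_per_lg: int = 200
    lg_length_bp: int = 16_000_000
    lg_length_cm: float = 60.0
    n_progeny: int = 104
    frac_maternal_informative: float = 0.4
    frac_paternal_informative: float = 0.4
    frac_both_het: float = 0.1
    missing_rate: float = 0.1
    genotype_error_rate: float = 0.01
    seed: int = 0
    mother_id: str = "mother"
    father_id: str = "father"

    def validate(self) -> None:
        for name in ("n_lg", "markers_per_lg", "lg_length_bp", "n_progeny"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lg_length_cm < 0:
            raise ValueError("lg_length_cm must be >= 0")
        fracs = (
            self.frac_maternal_informative,
            self.frac_paternal_informative,
            self.frac_both_het,
        )
        for f in fracs + (self.missing_rate, self.genotype_error_rate):
            if not 0.0 <= f <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("informative/both-het fractions sum to more than 1")

    def lg_ids(self) -> list[str]:
        return [f"LG{i + 1}" for i in range(self.n_lg)]


@dataclass
class ParentGenome:
    """One parent's two phased haplotypes over the shared marker map.

    ``markers`` carries lg, bp and cm per marker; ``hap1``/``hap2`` are allele
    arrays (the ordered pair defines the true phase — a marker is heterozygous
    in this parent iff the two entries differ).
    """

    markers: pd.DataFrame
    hap1: np.ndarray
    hap2: np.ndarray

    def is_het(self) -> np.ndarray:
        return self.hap1 != self.hap2


@dataclass
class Gamete:
    """Product of one simulated meiosis on one linkage group."""

    lg: str
    start_label: int                  # haplotype (1/2) transmitted at position 0
    crossovers_bp: np.ndarray         # exact crossover positions, sorted
    labels: np.ndarray                # transmitted haplotype (1/2) at each marker
    alleles: np.ndarray               # transmitted allele at each marker

    def label_at(self, bp: float) -> int:
        n_before = int(np.searchsorted(self.crossovers_bp, bp))
        return 1 + ((self.start_label - 1 + n_before) % 2)


@dataclass
class QTLSpec:
    """A single QTL: its location and the trait effect of each diplotype.

    ``effects`` must have exactly the four keys M1P1, M1P2, M2P1, M2P2
    (maternal haplotype x paternal haplotype at the QTL position).
    """

    lg: str
    position_bp: int
    effects: dict[str, float]
    baseline: float = 400.0
    noise_sd: float = 80.0

    def __post_init__(self) -> None:
        if set(self.effects) != {"M1P1", "M1P2", "M2P1", "M2P2"}:
            raise ValueError("effects keys must be exactly {M1P1,M1P2,M2P1,M2P2}")


def default_fruit_weight_qtl(lg: str = "LG1", position_bp: int = 8_000_000) -> QTLSpec:
    """Fruit-weight-like QTL: ~400 g baseline, diplotype effects spanning 170 g.

    The effect table mirrors the structure seen for mango fruit weight: the
    paternal haplotype carries the major, near-additive effect, the lowest
    group sits 71 g below and the highest 99 g above baseline (group means
    ~329 g and ~499 g), and the paternal contrast is slightly attenuated
    (140 g vs 170 g) in the alternative maternal background.  Residual noise
    is 80 g.
    """
    return QTLSpec(
        lg=lg,
        position_bp=position_bp,
        effects={"M1P1": -56.0, "M1P2": 84.0, "M2P1": -71.0, "M2P2": 99.0},
        baseline=400.0,
        noise_sd=80.0,
    )


@dataclass
class TruthSet:
    """Everything the simulator knows: transmissions, crossovers, classes.

    ``transmissions[parent]`` is an (n_markers, n_progeny) int8 array of true
    transmitted haplotype labels (1/2) at every marker (defined for all
    markers, informative or not).  ``crossovers`` is a DataFrame with columns
    individual, parent, lg, bp (exact positions).  ``gametes`` keeps the full
    per-meiosis record for arbitrary-position queries.
    """

    markers: pd.DataFrame
    individuals: list[str]
    marker_classes: pd.Series
    transmissions: dict[str, np.ndarray]
    crossovers: pd.DataFrame
    gametes: dict[tuple[str, str, str], Gamete] = field(repr=False, default_factory=dict)

    def haplotype_at(self, individual: str, parent: str, lg: str, bp: float) -> int:
        return self.gametes[(individual, parent, lg)].label_at(bp)

    def diplotype_at(self, individual: str, lg: str, bp: float) -> str:
        m = self.haplotype_at(individual, "maternal", lg, bp)
        p = self.haplotype_at(individual, "paternal", lg, bp)
        return f"M{m}P{p}"


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_parents(config: SimulationConfig) -> tuple[ParentGenome, ParentGenome, pd.Series]:
    """Draw the shared marker map, marker classes, and both parents' phased haplotypes.

    Returns (mother, father, true_classes).  Class fractions follow the config;
    an informative marker is heterozygous in one parent while the other parent
    is homozygous for one of the same two alleles.
    """
    config.validate()
    rng = _child_rngs(config.seed, 4)[0]
    ids, lgs, bps, cms = [], [], [], []
    for lg in config.lg_ids():
        n = config.markers_per_lg
        bp = np.sort(rng.choice(np.arange(1, config.lg_length_bp + 1), size=n, replace=False))
        cm = bp / config.lg_length_bp * config.lg_length_cm
        lgs += [lg] * n
        bps += bp.tolist()
        cms += cm.tolist()
        ids += [f"{lg}_{p}" for p in bp]
    markers = pd.DataFrame(
        {"lg": lgs, "bp": bps, "cm": cms}, index=pd.Index(ids, name="marker")
    )
    m = len(markers)
    probs = [
        config.frac_maternal_informative,
        config.frac_paternal_informative,
        config.frac_both_het,
    ]
    probs.append(max(0.0, 1.0 - sum(probs)))
    class_codes = rng.choice(4, size=m, p=np.asarray(probs) / sum(probs))
    class_map = [
        MarkerClass.MATERNAL_INFORMATIVE,
        MarkerClass.PATERNAL_INFORMATIVE,
        MarkerClass.BOTH_HET,
        MarkerClass.UNINFORMATIVE,
    ]
    classes = pd.Series([class_map[c] for c in class_codes], index=markers.index,
                        name="marker_class")

    # two distinct alleles per site; hom parent shares one of the het parent's alleles
    pair_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    a, b = BASES[pair_idx[:, 0]], BASES[pair_idx[:, 1]]
    swap = rng.random(m) < 0.5          # true phase of the het parent
    shared = np.where(rng.random(m) < 0.5, a, b)

    mo1, mo2 = a.copy(), b.copy()
    mo1[swap], mo2[swap] = b[swap], a[swap]
    fa1, fa2 = mo1.copy(), mo2.copy()

    is_mat = class_codes == 0
    is_pat = class_codes == 1
    is_both = class_codes == 2
    is_unin = class_codes == 3
    fa1[is_mat] = shared[is_mat]
    fa2[is_mat] = shared[is_mat]
    mo1[is_pat] = shared[is_pat]
    mo2[is_pat] = shared[is_pat]
    # both-het: independent phase in the father
    fswap = rng.random(m) < 0.5
    fa1[is_both & fswap], fa2[is_both & fswap] = (
        fa2[is_both & fswap].copy(), fa1[is_both & fswap].copy())
    mo1[is_unin] = a[is_unin]
    mo2[is_unin] = a[is_unin]
    fa1[is_unin] = a[is_unin]
    fa2[is_unin] = a[is_unin]

    mother = ParentGenome(markers, mo1, mo2)
    father = ParentGenome(markers, fa1, fa2)
    return mother, father, classes


def simulate_meiosis(parent: ParentGenome, lg: str, rng: np.random.Generator,
                     lg_length_cm: float | None = None) -> Gamete:
    """One meiosis on one linkage group under the Haldane model.

    The crossover count is Poisson with mean (map length in cM)/100 and
    crossover positions are uniform on the cM axis; the transmitted haplotype
    alternates between the parent's hap1 and hap2 at each crossover.
    """
    sel = parent.markers["lg"] == lg
    if not sel.any():
        raise ValueError(f"unknown linkage group {lg!r}")
    cm = parent.markers.loc[sel, "cm"].to_numpy()
    bp = parent.markers.loc[sel, "bp"].to_numpy()
    if lg_length_cm is None:
        lg_length_cm = float(cm.max()) if len(cm) else 0.0
    n_xo = rng.poisson(lg_length_cm / 100.0)
    xo_cm = np.sort(rng.uniform(0.0, lg_length_cm, size=n_xo))
    start = int(rng.integers(1, 3))
    n_before = np.searchsorted(xo_cm, cm)
    labels = 1 + ((start - 1 + n_before) % 2)
    h1 = parent.hap1[sel.to_numpy()]
    h2 = parent.hap2[sel.to_numpy()]
    alleles = np.where(labels == 1, h1, h2)
    # exact bp positions via the linear cM<->bp map of this LG
    bp_per_cm = bp.max() / cm.max() if len(cm) and cm.max() > 0 else 0.0
    xo_bp = xo_cm * bp_per_cm
    return Gamete(lg=lg, start_label=start, crossovers_bp=xo_bp,
                  labels=labels.astype(np.int8), alleles=alleles)


def simulate_progeny(
    mother: ParentGenome,
    father: ParentGenome,
    config: SimulationConfig,
    classes: pd.Series | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Build the F1 genotype matrix and its truth record.

    Each progeny is the union of one maternal and one paternal gamete per
    linkage group.  Genotyping error then flips single alleles (to a random
    different base) at ``genotype_error_rate`` per call, and whole calls are
    masked at ``missing_rate``; parents are corrupted by the same process,
    as they are genotyped on the same platform as the progeny.
    """
    config.validate()
    rngs = _child_rngs(config.seed, 4)
    rng = rngs[1]
    markers = mother.markers
    m = len(markers)
    progeny = [f"F1_{i + 1:03d}" for i in range(config.n_progeny)]
    individuals = [config.mother_id, config.father_id] + progeny
    n_ind = len(individuals)

    calls = np.full((m, n_ind, 2), MISSING, dtype="<U1")
    calls[:, 0, 0], calls[:, 0, 1] = mother.hap1, mother.hap2
    calls[:, 1, 0], calls[:, 1, 1] = father.hap1, father.hap2

    lg_slices = {lg: (markers["lg"] == lg).to_numpy().nonzero()[0]
                 for lg in markers["lg"].unique()}
    trans = {p: np.zeros((m, config.n_progeny), dtype=np.int8) for p in ("maternal", "paternal")}
    gametes: dict[tuple[str, str, str], Gamete] = {}
    xo_rows = []
    for i, ind in enumerate(progeny):
        for parent_name, parent in (("maternal", mother), ("paternal", father)):
            for lg, idx in lg_slices.items():
                g = simulate_meiosis(parent, lg, rng, lg_length_cm=config.lg_length_cm)
                gametes[(ind, parent_name, lg)] = g
                trans[parent_name][idx, i] = g.labels
                col = 0 if parent_name == "maternal" else 1
                calls[idx, 2 + i, col] = g.alleles
                for x in g.crossovers_bp:
                    xo_rows.append((ind, parent_name, lg, float(x)))

    # genotyping error: flip one allele of a call to a random different base
    err_rng = rngs[2]
    err_mask = err_rng.random((m, n_ind)) < config.genotype_error_rate
    which = err_rng.integers(0, 2, size=(m, n_ind))
    repl = BASES[err_rng.integers(0, 4, size=(m, n_ind))]
    for mi, ii in zip(*err_mask.nonzero()):
        cur = calls[mi, ii, which[mi, ii]]
        new = repl[mi, ii]
        if new == cur:  # redraw deterministically: next base cyclically
            new = BASES[(np.searchsorted(BASES, cur) + 1) % 4]
        calls[mi, ii, which[mi, ii]] = new

    miss = err_rng.random((m, n_ind)) < config.missing_rate
    calls[miss, :] = MISSING

    gm = GenotypeMatrix(
        markers=markers[["lg", "bp"]].copy(),
        individuals=individuals,
        calls=calls,
        mother_id=config.mother_id,
        father_id=config.father_id,
    )
    crossovers = pd.DataFrame(xo_rows, columns=["individual", "parent", "lg", "bp"])
    if classes is None:
        classes = pd.Series(
            [MarkerClass.UNINFORMATIVE] * m, index=markers.index, name="marker_class"
        )
    truth = TruthSet(
        markers=markers.copy(),
        individuals=progeny,
        marker_classes=classes,
        transmissions=trans,
        crossovers=crossovers,
        gametes=gametes,
    )
    return gm, truth


def simulate_trait(
    truth: TruthSet,
    qtls: list[QTLSpec],
    rng: np.random.Generator | int,
    baseline: float | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Quantitative trait per progeny: baseline + per-QTL diplotype effects + noise.

    An individual recombinant across a QTL's surrounding region still has a
    well-defined haplotype pair at the QTL position itself, which is what
    receives the effect.  ``baseline``/``noise_sd`` default to the first QTL's
    values (they describe the trait, not an individual locus).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.PCG64(int(rng)))
    if not qtls:
        raise ValueError("at least one QTLSpec required (use effects of 0 for a null trait)")
    if baseline is None:
        baseline = qtls[0].baseline
    if noise_sd is None:
        noise_sd = qtls[0].noise_sd
    values = np.full(len(truth.individuals), float(baseline))
    for q in qtls:
        for i, ind in enumerate(truth.individuals):
            d = truth.diplotype_at(ind, q.lg, q.position_bp)
            values[i] += q.effects[d]
    values += rng.normal(0.0, noise_sd, size=len(values))
    return pd.DataFrame({"individual": truth.individuals, "trait": values})


def simulate_population(
    config: SimulationConfig, qtls: list[QTLSpec] | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthSet]:
    """Convenience wrapper: parents -> progeny -> trait, all from ``config.seed``."""
    mother, father, classes = simulate_parents(config)
    gm, truth = simulate_progeny(mother, father, config, classes)
    trait_rng = _child_rngs(config.seed, 4)[3]
    if qtls is None:
        qtls = [default_fruit_weight_qtl(lg=config.lg_ids()[0],
                                         position_bp=config.lg_length_bp // 2)]
    pheno = simulate_trait(truth, qtls, trait_rng)
    return gm, pheno, truth


# ---------------------------------------------------------------------------
# truth-based scoring
# ---------------------------------------------------------------------------

def detectable_crossovers(truth: TruthSet, informative_bp: dict[str, dict[str, np.ndarray]]
                          ) -> pd.DataFrame:
    """Classify true crossovers by detectability at marker resolution.

    ``informative_bp[parent][lg]`` gives the sorted bp positions of markers
    informative for that parent.  A crossover is *detectable* iff it falls
    strictly inside the informative-marker span and the total number of
    crossovers of that gamete in its inter-marker gap is odd (an even number
    cancels and produces no transmission switch).  Returns the crossovers
    table with added columns ``gap_left_bp``, ``gap_right_bp``, ``detectable``.
    """
    rows = []
    for (ind, parent, lg), g in truth.gametes.items():
        bps = informative_bp.get(parent, {}).get(lg)
        if bps is None or len(bps) < 2 or len(g.crossovers_bp) == 0:
            for x in g.crossovers_bp:
                rows.append((ind, parent, lg, float(x), np.nan, np.nan, False))
            continue
        gap_idx = np.searchsorted(bps, g.crossovers_bp)
        for k, x in enumerate(g.crossovers_bp):
            gi = gap_idx[k]
            inside = 0 < gi < len(bps)
            if inside:
                n_in_gap = int(np.sum(gap_idx == gi))
                det = n_in_gap % 2 == 1
                rows.append((ind, parent, lg, float(x), float(bps[gi - 1]),
                             float(bps[gi]), det))
            else:
                rows.append((ind, parent, lg, float(x), np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["individual", "parent", "lg", "bp",
                                       "gap_left_bp", "gap_right_bp", "detectable"])


def score_breakpoint_recovery(
    truth: TruthSet,
    breakpoints: pd.DataFrame,
    informative_bp: dict[str, dict[str, np.ndarray]],
    slack_markers: int = 0,
) -> dict:
    """Score inferred breakpoint intervals against true crossovers.

    A detectable true crossover counts as recovered when some inferred
    interval for the same gamete contains its position, allowing the interval
    to be widened by ``slack_markers`` informative markers on each side (0 =
    strict containment).  Returns recovery counts plus the number of inferred
    breakpoints not matching any detectable crossover gap.
    """
    det = detectable_crossovers(truth, informative_bp)
    det_sub = det[det["detectable"]]
    n_recovered = 0
    matched = set()
    bp_groups = {k: v for k, v in breakpoints.groupby(["individual", "parent", "lg"])}
    for row in det_sub.itertuples():
        key = (row.individual, row.parent, row.lg)
        found = False
        bps = informative_bp[row.parent][row.lg]
        for b in bp_groups.get(key, pd.DataFrame()).itertuples():
            lo, hi = b.start_bp, b.end_bp
            if slack_markers:
                i_lo = np.searchsorted(bps, lo)
                i_hi = np.searchsorted(bps, hi)
                lo = bps[max(0, i_lo - slack_markers)]
                hi = bps[min(len(bps) - 1, i_hi + slack_markers)]
            if lo <= row.bp <= hi:
                found = True
                matched.add((key, b.Index))
                break
        n_recovered += found
    n_spurious = len(breakpoints) - len(matched)
    return {
        "n_true": int(len(det)),
        "n_detectable": int(len(det_sub)),
        "n_recovered": int(n_recovered),
        "n_inferred": int(len(breakpoints)),
        "n_unmatched_inferred": int(n_spurious),
        "recovery_rate": float(n_recovered / len(det_sub)) if len(det_sub) else float("nan"),
    }


def write_truth_tsv(truth: TruthSet, outdir: str | Path) -> None:
    """Write transmissions (per parent) and crossovers as TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for parent, arr in truth.transmissions.items():
        df = pd.DataFrame(arr, index=truth.markers.index, columns=truth.individuals)
        df.insert(0, "lg", truth.markers["lg"].to_numpy())
        df.insert(1, "bp", truth.markers["bp"].to_numpy())
        df.to_csv(outdir / f"truth_transmissions_{parent}.tsv", sep="\t")
    truth.crossovers.to_csv(outdir / "truth_crossovers.tsv", sep="\t", index=False,
                            float_format="%.1f")
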