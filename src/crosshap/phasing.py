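"""Parental-haplotype phasing from progeny co-segregation and breakpoint calling.

At a marker heterozygous in one parent and homozygous in the other, the allele
each progeny received from the heterozygous parent is obtained by subtracting
the obligate allele contributed by the homozygous parent.  Those allele-level
transmissions are phased into consistent haplotype labels (1/2) per linkage
group by greedy adjacent-marker majority co-segregation: marker 1 is oriented
arbitrarily, and each subsequent marker is oriented to minimise apparent
recombinations against the previous oriented marker across progeny.  On a
chain, the total recombination count decomposes over adjacent marker pairs,
so with complete data this greedy choice attains the global minimum that an
exhaustive search over orientations would find.

Haplotype labels within a linkage group are only defined up to a global 1<->2
flip (label switching); every downstream quantity — breakpoints, association
statistics, diplotype partitions — is invariant under that flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MISSING, GenotypeMatrix, MarkerClass

UNKNOWN = 0  # transmission label for "cannot determine"

__all__ = [
    "UNKNOWN",
    "AlleleTransmission",
    "TransmissionMatrix",
    "raw_transmission",
    "phase_parent",
    "detect_breakpoints",
    "smooth_labels",
    "count_recombinations",
    "write_transmissions_tsv",
    "read_transmissions_tsv",
]


@dataclass
class AlleleTransmission:
    """Allele-level transmissions from one parent, before phasing.

    ``alleles`` (n_informative_markers, n_progeny) holds the transmitted
    allele of the heterozygous parent, ``"."`` where unknown; ``het_pair``
    gives the parent's two alleles per marker in lexicographic order;
    ``mendel_error`` flags calls incompatible with the parental genotypes.
    """

    parent: str
    markers: pd.DataFrame          # lg, bp of informative markers, sorted
    progeny: list[str]
    alleles: np.ndarray
    het_pair: np.ndarray           # (m, 2)
    mendel_error: np.ndarray       # bool (m, n)


@dataclass
class TransmissionMatrix:
    """Phased haplotype-label transmissions for one parent.

    ``labels`` (n_markers, n_progeny) with entries 1, 2 or 0 (unknown);
    ``orientation`` records the phase bit chosen per marker and
    ``low_confidence`` flags markers whose orientation vote was tied.
    """

    parent: str
    markers: pd.DataFrame
    progeny: list[str]
    labels: np.ndarray
    orientation: np.ndarray
    low_confidence: np.ndarray

    def lg_index(self, lg: str) -> np.ndarray:
        return (self.markers["lg"] == lg).to_numpy().nonzero()[0]

    def flipped(self, lgs=None) -> "TransmissionMatrix":
        """Copy with haplotype labels 1<->2 swapped on the given LGs (all by default)."""
        lab = self.labels.copy()
        sel = np.ones(len(self.markers), bool) if lgs is None else \
            self.markers["lg"].isin(lgs).to_numpy()
        lab[sel] = np.where(lab[sel] == 0, 0, 3 - lab[sel])
        return TransmissionMatrix(self.parent, self.markers, self.progeny, lab,
                                  ~self.orientation, self.low_confidence)


def raw_transmission(gm: GenotypeMatrix, classes: pd.Series, parent: str) -> AlleleTransmission:
    """Obligate-allele subtraction at markers informative for ``parent``.

    For a maternal-informative marker with mother a/b and father hom c/c, a
    progeny call {x, c} implies maternal allele x; {c, c} resolves to c (valid
    only when c is one of a/b).  Calls incompatible with the parents are
    flagged as Mendelian errors and left unknown.
    """
    if parent == "maternal":
        want = MarkerClass.MATERNAL_INFORMATIVE
        het_id, hom_id = gm.mother_id, gm.father_id
    elif parent == "paternal":
        want = MarkerClass.PATERNAL_INFORMATIVE
        het_id, hom_id = gm.father_id, gm.mother_id
    else:
        raise ValueError("parent must be 'maternal' or 'paternal'")
    sel = (classes == want).to_numpy()
    markers = gm.markers[sel].copy()
    het_calls = gm.column(het_id)[sel]
    hom_calls = gm.column(hom_id)[sel]
    progeny = gm.progeny
    prog_idx = [gm.individuals.index(p) for p in progeny]
    calls = gm.calls[np.ix_(sel.nonzero()[0], prog_idx)]

    m, n = len(markers), len(progeny)
    out = np.full((m, n), MISSING, dtype="<U1")
    err = np.zeros((m, n), dtype=bool)
    het_pair = np.sort(het_calls, axis=1)
    for i in range(m):
        a, b = het_pair[i]
        c = hom_calls[i, 0]
        for j in range(n):
            x, y = calls[i, j]
            if x == MISSING:
                continue
            got = None
            if c in (x, y):
                # remove one copy of the obligate allele
                rem = y if x == c else x
                if rem in (a, b):
                    got = rem
                elif rem == c and c in (a, b):
                    got = c
            if got is None:
                err[i, j] = True
            else:
                out[i, j] = got
    return AlleleTransmission(parent, markers, progeny, out, het_pair, err)


def phase_parent(at: AlleleTransmission, anchor_min_pairs: int = 25,
                 anchor_sigma: float = 3.0) -> TransmissionMatrix:
    """Greedy minimum-recombination phasing, independently per linkage group.

    Ties in the orientation vote (including markers with no informative
    neighbouring pair) keep the default orientation and are flagged
    low-confidence.

    A marker corrupted at the parent level (e.g. a both-het site misread as
    informative) transmits essentially random or constant labels; with enough
    progeny its orientation vote hovers near 50:50.  Such a marker must not
    anchor the comparison chain, or every downstream marker inherits a random
    orientation and the whole population appears to recombine at one point.
    A vote is therefore *indecisive* when it is based on at least
    ``anchor_min_pairs`` pairs yet its margin is within ``anchor_sigma``
    binomial standard deviations of an even split; indecisive markers are
    flagged low-confidence and skipped as anchors (after three consecutive
    skips the chain re-bases to avoid stalling on a corrupt leading marker).
    Below ``anchor_min_pairs`` pairs the test has no power and the behaviour
    is plain adjacent-marker greedy phasing.
    """
    m, n = at.alleles.shape
    # binary transmission: 0 = lexicographically smaller het allele, 1 = larger
    t = np.full((m, n), -1, dtype=np.int8)
    t[at.alleles == at.het_pair[:, [0]]] = 0
    t[at.alleles == at.het_pair[:, [1]]] = 1

    orientation = np.zeros(m, dtype=bool)
    low_conf = np.zeros(m, dtype=bool)
    labels = np.zeros((m, n), dtype=np.int8)
    for lg in at.markers["lg"].unique():
        idx = (at.markers["lg"] == lg).to_numpy().nonzero()[0]
        prev = None
        stall = 0
        for i in idx:
            ti = t[i]
            decisive = True
            if prev is None:
                o = False
            else:
                both = (ti >= 0) & (prev >= 0)
                agree = int(np.sum(ti[both] == prev[both]))
                total = int(both.sum())
                margin = abs(2 * agree - total)
                if margin == 0:
                    o = False
                    low_conf[i] = True
                    decisive = total == 0 or total < anchor_min_pairs
                else:
                    o = agree * 2 < total  # flip if majority disagrees
                    if total >= anchor_min_pairs and margin < anchor_sigma * np.sqrt(total):
                        low_conf[i] = True
                        decisive = False
            orientation[i] = o
            oriented = np.where(ti >= 0, ti ^ int(o), -1)
            labels[i] = np.where(oriented >= 0, oriented + 1, UNKNOWN)
            if np.any(oriented >= 0):
                if decisive:
                    prev = oriented
                    stall = 0
                else:
                    stall += 1
                    if stall >= 3:
                        prev = oriented
                        stall = 0
    return TransmissionMatrix(at.parent, at.markers, at.progeny, labels,
                              orientation, low_conf)


def smooth_labels(seq: np.ndarray, min_run: int) -> np.ndarray:
    """Mask runs of identical non-unknown labels shorter than ``min_run`` to unknown.

    Runs are measured on the subsequence of non-unknown entries; isolated
    miscalls (run length < min_run) are treated as genotyping noise rather
    than evidence of a double crossover.
    """
    out = seq.copy()
    known = (seq != UNKNOWN).nonzero()[0]
    if len(known) == 0 or min_run <= 1:
        return out
    vals = seq[known]
    start = 0
    for k in range(1, len(vals) + 1):
        if k == len(vals) or vals[k] != vals[start]:
            if k - start < min_run:
                out[known[start:k]] = UNKNOWN
            start = k
    return out


def count_recombinations(labels: np.ndarray) -> int:
    """Total label switches between consecutive non-unknown entries, all progeny."""
    total = 0
    for j in range(labels.shape[1]):
        seq = labels[:, j]
        seq = seq[seq != UNKNOWN]
        total += int(np.sum(seq[1:] != seq[:-1]))
    return total


def detect_breakpoints(tm: TransmissionMatrix, min_run: int = 3) -> pd.DataFrame:
    """Call recombination breakpoints per progeny from a phased transmission matrix.

    Runs shorter than ``min_run`` are masked to unknown first (error
    smoothing); a breakpoint is then reported at every remaining 1<->2 switch
    between consecutive non-unknown markers, as the bp interval from the last
    marker before the switch to the first marker after it.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    rows = []
    bp_arr = tm.markers["bp"].to_numpy()
    for lg in tm.markers["lg"].unique():
        idx = tm.lg_index(lg)
        for j, ind in enumerate(tm.progeny):
            seq = smooth_labels(tm.labels[idx, j], min_run)
            known = (seq != UNKNOWN).nonzero()[0]
            vals = seq[known]
            switch = (vals[1:] != vals[:-1]).nonzero()[0]
            for s in switch:
                left = idx[known[s]]
                right = idx[known[s + 1]]
                rows.append((ind, tm.parent, lg, int(bp_arr[left]), int(bp_arr[right])))
    return pd.DataFrame(rows, columns=["individual", "parent", "lg", "start_bp", "end_bp"])


def write_transmissions_tsv(tm: TransmissionMatrix, path) -> None:
    df = pd.DataFrame(tm.labels, index=tm.markers.index, columns=tm.progeny)
    df = df.replace(UNKNOWN, pd.NA)
    df.insert(0, "lg", tm.markers["lg"].to_numpy())
    df.insert(1, "bp", tm.markers["bp"].to_numpy())
    df.insert(2, "low_confidence", tm.low_confidence.astype(int))
    df.to_csv(path, sep="\t", na_rep="NA")


def read_transmissions_tsv(path, parent: str) -> TransmissionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"lg": str})
    meta = ["lg", "bp", "low_confidence"]
    progeny = [c for c in df.columns if c not in meta]
    labels = df[progeny].fillna(UNKNOWN).to_numpy(dtype=np.int8)
    markers = df[["lg", "bp"]].copy()
    markers.index.name = "marker"
    return TransmissionMatrix(
        parent, markers, progeny, labels,
        orientation=np.zeros(len(df), dtype=bool),
        low_confidence=df["low_confidence"].to_numpy(dtype=bool),
    )
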