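import numpy as np
import pandas as pd
import pytest

from crosshap import markers as mk
from crosshap import phasing, popsim


def build_population(**overrides):
    """Simulate a population and phase both parents; returns a dict of stages."""
    cfg = popsim.SimulationConfig(**overrides)
    gm, pheno, truth = popsim.simulate_population(cfg)
    classes = mk.classify_markers(gm)
    tms = {
        parent: phasing.phase_parent(phasing.raw_transmission(gm, classes, parent))
        for parent in ("maternal", "paternal")
    }
    return {"config": cfg, "gm": gm, "pheno": pheno, "truth": truth,
            "classes": classes, "tms": tms}


@pytest.fixture(scope="session")
def clean_pop():
    """Error-free, fully observed population for exact-recovery checks."""
    return build_population(n_lg=3, markers_per_lg=120, n_progeny=60,
                            missing_rate=0.0, genotype_error_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_pop():
    """Skim-like population: 1% genotype error, 10% missing calls."""
    return build_population(n_lg=2, markers_per_lg=150, n_progeny=80, seed=7)


def make_tm(parent, label_rows, bp=None, lg="LG1", progeny=None):
    """TransmissionMatrix literal: ``label_rows`` is (m, n) of 1/2/0."""
    labels = np.asarray(label_rows, dtype=np.int8)
    m, n = labels.shape
    if bp is None:
        bp = [(i + 1) * 1000 for i in range(m)]
    if progeny is None:
        progeny = [f"ind{j + 1}" for j in range(n)]
    markers = pd.DataFrame(
        {"lg": [lg] * m, "bp": bp},
        index=pd.Index([f"{lg}_{p}" for p in bp], name="marker"),
    )
    return phasing.TransmissionMatrix(
        parent, markers, list(progeny), labels,
        orientation=np.zeros(m, dtype=bool),
        low_confidence=np.zeros(m, dtype=bool),
    )


def informative_bp(tms):
    """Per parent / per LG sorted informative-marker bp arrays (for truth scoring)."""
    return {
        parent: {
            lg: tm.markers.loc[tm.markers["lg"] == lg, "bp"].to_numpy()
            for lg in tm.markers["lg"].unique()
        }
        for parent, tm in tms.items()
    }


def flip_map_vs_truth(tm, truth, parent):
    """Infer the per-LG label flip relating ``tm`` to the simulator's truth.

    Returns {lg: flip_bool} or raises AssertionError if neither orientation
    matches exactly (callers that allow mismatches should not use this).
    """
    flips = {}
    for lg in tm.markers["lg"].unique():
        idx = tm.lg_index(lg)
        rows = truth.markers.index.get_indexer(tm.markers.index[idx])
        t_true = truth.transmissions[parent][rows]
        inf = tm.labels[idx]
        known = inf != 0
        if np.array_equal(inf[known], t_true[known]):
            flips[lg] = False
        elif np.array_equal(inf[known], 3 - t_true[known]):
            flips[lg] = True
        else:
            raise AssertionError(f"{parent}/{lg}: transmissions differ beyond relabel")
    return flips
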