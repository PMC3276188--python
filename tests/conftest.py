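"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

import mhcrec as M


@pytest.fixture(scope="session")
def panel_founders():
    return M.load_mauritius_founders()


@pytest.fixture(scope="session")
def panel(panel_founders):
    return panel_founders[0]


@pytest.fixture(scope="session")
def founders(panel_founders):
    return panel_founders[1]


@pytest.fixture(scope="session")
def observed_spectrum():
    return M.load_mauritius_spectrum()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def brute_force_min_switches(compat: np.ndarray, max_h: int = 4) -> int:
    """Exhaustive mosaic enumeration: the independent oracle for the DP.

    Tries every number of switches h, every placement of h cut points, and
    every founder sequence with distinct consecutive founders, returning the
    smallest feasible h.  Exponential — only for tiny instances.
    """
    n_m, n_f = compat.shape
    # seg_ok[s][e][f]: founder f compatible with markers s..e-1
    seg_ok = np.zeros((n_m, n_m + 1, n_f), dtype=bool)
    for s in range(n_m):
        run = np.ones(n_f, dtype=bool)
        for e in range(s + 1, n_m + 1):
            run &= compat[e - 1]
            seg_ok[s, e] = run
    for h in range(0, max_h + 1):
        for cuts in combinations(range(1, n_m), h):
            bounds = [0, *cuts, n_m]
            seg_masks = [seg_ok[bounds[i], bounds[i + 1]] for i in range(h + 1)]
            if any(not mk.any() for mk in seg_masks):
                continue
            for seq in product(range(n_f), repeat=h + 1):
                if any(a == b for a, b in zip(seq, seq[1:])):
                    continue
                if all(seg_masks[i][f] for i, f in enumerate(seq)):
                    return h
    raise AssertionError(f"no mosaic with <= {max_h} switches")


def random_compat_instance(rng: np.random.Generator) -> np.ndarray:
    """Random small compatibility matrix with every marker explainable."""
    n_m = int(rng.integers(2, 9))
    n_f = int(rng.integers(2, 6))
    mat = rng.random((n_m, n_f)) < 0.45
    for i in range(n_m):
        if not mat[i].any():
            mat[i, rng.integers(0, n_f)] = True
    return mat


def compat_from_matrix(mat: np.ndarray) -> M.CompatibilityMatrix:
    n_m, n_f = mat.shape
    panel = M.MarkerPanel(tuple(f"m{i}" for i in range(n_m)))
    return M.CompatibilityMatrix(
        matrix=mat,
        orphan=~mat.any(axis=1),
        panel=panel,
        founders=tuple(f"F{j}" for j in range(n_f)),
    )
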