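"""Shared fixtures: small pedigrees and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dyadige.pedigree import Pedigree


def make_pedigree(rows):
    """Pedigree from (id, sire, dam, sex) tuples."""
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"]))


@pytest.fixture
def trio():
    """Sire, dam, one offspring."""
    return make_pedigree([
        ("S", "0", "0", "M"),
        ("D", "0", "0", "F"),
        ("X", "S", "D", "M"),
    ])


@pytest.fixture
def sib_quartet():
    """Two full sibs and one paternal half sib."""
    return make_pedigree([
        ("S", "0", "0", "M"),
        ("D1", "0", "0", "F"),
        ("D2", "0", "0", "F"),
        ("A", "S", "D1", "M"),
        ("B", "S", "D1", "F"),
        ("C", "S", "D2", "M"),
    ])


def random_pedigree(rng, n=60, n_generations=4, p_female=0.5):
    """Random multi-generation pedigree (possibly inbred) for oracle tests."""
    per_gen = n // n_generations
    rows = []
    prev_m, prev_f = [], []
    count = 0
    for g in range(n_generations):
        size = per_gen if g < n_generations - 1 else n - per_gen * (n_generations - 1)
        cur_m, cur_f = [], []
        for _ in range(size):
            ident = f"I{count:03d}"
            count += 1
            sex = "F" if rng.random() < p_female else "M"
            if g == 0 or not prev_m or not prev_f:
                sire = dam = "0"
            elif rng.random() < 0.15:  # occasional unknown parent
                sire, dam = rng.choice(prev_m), "0"
            else:
                sire, dam = rng.choice(prev_m), rng.choice(prev_f)
            rows.append((ident, sire, dam, sex))
            (cur_f if sex == "F" else cur_m).append(ident)
        prev_m = prev_m + cur_m
        prev_f = prev_f + cur_f
    return make_pedigree(rows)


def kinship_oracle(ped: Pedigree) -> np.ndarray:
    """Brute-force recursive kinship; A = 2f.

    Independent of the tabular method: plain double recursion
    f(i,i) = 0.5 (1 + f(s_i, d_i)), f(i,j) = 0.5 (f(s_i, j) + f(d_i, j))
    for i later in pedigree order, unknown parents contributing 0.
    """
    n = len(ped)
    cache: dict[tuple[int, int], float] = {}

    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        key = (min(i, j), max(i, j))
        if key in cache:
            return cache[key]
        a, b = key
        if a == b:
            val = 0.5 * (1.0 + f(ped.sire_idx[a], ped.dam_idx[a]))
        else:
            # b appears later in topological order: recurse through b's parents
            val = 0.5 * (f(ped.sire_idx[b], a) + f(ped.dam_idx[b], a))
        cache[key] = val
        return val

    return np.array([[2.0 * f(i, j) for j in range(n)] for i in range(n)])
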