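"""Pedigree algebra: tabular A, inbreeding reporting rule, depth, and
gene-dropping equivalence of simulated breeding values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoselect.pedigree import (
    Pedigree,
    PedigreeError,
    additive_relationship,
    inbreeding_coefficients,
    pedigree_depth,
    simulate_breeding_values,
)

from conftest import small_pedigree


def test_tabular_closed_forms():
    ped = small_pedigree()
    A = additive_relationship(ped)
    ix = ped.index_of
    assert A[ix("d"), ix("a")] == pytest.approx(0.5)  # parent-offspring
    assert A[ix("a"), ix("b")] == pytest.approx(0.5)  # full sibs
    assert A[ix("c"), ix("c")] == pytest.approx(1.25)  # full-sib mating, F = 0.25
    assert np.allclose(A, A.T)


def test_cycle_detection():
    with pytest.raises(PedigreeError, match="cycle"):
        Pedigree.from_triples([("a", "b", None), ("b", "a", None)])


def test_topological_sort_from_unordered_input():
    ped = Pedigree.from_triples([("c", "a", "b"), ("a", None, None), ("b", None, None)])
    assert ped.index_of("c") > max(ped.index_of("a"), ped.index_of("b"))


def test_inbreeding_reporting_rule():
    ped = small_pedigree()
    F = inbreeding_coefficients(ped)
    # founders and individuals with founder parents (unknown grandparents) -> missing
    assert np.isnan(F.loc["d"]) and np.isnan(F.loc["a"])
    # all four grandparents known -> reported
    assert F.loc["c"] == pytest.approx(0.25)
    # without the grandparent rule, non-inbred a is 0
    F2 = inbreeding_coefficients(ped, require_grandparents=False)
    assert F2.loc["a"] == pytest.approx(0.0)


def test_unrelated_parents_with_known_grandparents_give_zero():
    rows = [(g, None, None) for g in "ghij"]
    rows += [("p", "g", "h"), ("q", "i", "j"), ("kid", "p", "q")]
    F = inbreeding_coefficients(Pedigree.from_triples(rows))
    assert F.loc["kid"] == pytest.approx(0.0)


def test_pedigree_depth_conventions():
    ped = Pedigree.from_triples([("f", None, None), ("c", "f", None), ("g", "c", None)])
    depth, summary = pedigree_depth(ped)
    assert depth.loc["f"] == 0 and depth.loc["c"] == 1 and depth.loc["g"] == 2
    assert summary == {"max": 2, "mean": 1.0}
    _, alt = pedigree_depth(ped, founders_at_one=True)
    assert alt == {"max": 3, "mean": 2.0}


def test_breeding_value_founder_variance():
    ped = Pedigree.from_triples([(i, None, None) for i in range(2000)])
    bv = simulate_breeding_values(ped, 4.0, seed=0)
    # Monte-Carlo: Var ~ chi2, SE of variance ~ sigma2 * sqrt(2/n)
    assert np.var(bv) == pytest.approx(4.0, abs=3 * 4.0 * np.sqrt(2 / 2000))


def test_breeding_value_zero_variance_and_midparent():
    ped = small_pedigree()
    assert (simulate_breeding_values(ped, 0.0, seed=1) == 0).all()
    # non-inbred trio: Var(offspring - midparent) ~ sigma2/2
    trio = Pedigree.from_triples([("d", None, None), ("s", None, None), ("o", "d", "s")])
    rng = np.random.default_rng(3)
    devs = []
    for _ in range(4000):
        bv = simulate_breeding_values(trio, 1.0, seed=rng)
        devs.append(bv[trio.index_of("o")] - 0.5 * (bv[trio.index_of("d")] + bv[trio.index_of("s")]))
    assert np.var(devs) == pytest.approx(0.5, abs=3 * 0.5 * np.sqrt(2 / 4000))


def test_breeding_value_covariance_matches_A():
    """Replicate covariance of simulated BVs ~ sigma2_A * A on a 6-member pedigree."""
    ped = Pedigree.from_triples(
        [("d", None, None), ("s", None, None), ("a", "d", "s"), ("b", "d", "s"),
         ("c", "a", "b"), ("e", "c", None)]
    )
    A = additive_relationship(ped)
    rng = np.random.default_rng(7)
    sims = np.array([simulate_breeding_values(ped, 1.0, seed=rng) for _ in range(20000)])
    C = np.cov(sims.T)
    assert np.abs(C - A).max() < 0.06  # ~3 Monte-Carlo SE at 20k reps


def _gene_drop_A(ped: Pedigree, n_rep: int, seed: int) -> np.ndarray:
    """Independent oracle: allele-sharing probabilities from gene dropping."""
    rng = np.random.default_rng(seed)
    n = len(ped)
    counter = [0]
    pairs = np.zeros((n_rep, n, 2), dtype=np.int64)
    for i in range(n):
        d, s = ped.dam[i], ped.sire[i]
        for slot, parent in enumerate((d, s)):
            if parent < 0:
                counter[0] += 2
                pairs[:, i, slot] = np.arange(n_rep) * 10_000 + counter[0]  # unique founder alleles per rep
                counter[0] += 1
            else:
                pick = rng.integers(0, 2, n_rep)
                pairs[:, i, slot] = pairs[np.arange(n_rep), parent, pick]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            # P(random allele from i IBD to random allele from j), x2
            share = 0.0
            for ai in range(2):
                for aj in range(2):
                    share += np.mean(pairs[:, i, ai] == pairs[:, j, aj])
            A[i, j] = share / 2.0
    return A


def test_tabular_matches_gene_dropping_oracle():
    ped = Pedigree.from_triples(
        [("d", None, None), ("s", None, None), ("x", None, None),
         ("a", "d", "s"), ("b", "d", "s"), ("c", "a", "b"),
         ("e", "c", "x"), ("f", "e", "b")]
    )
    A = additive_relationship(ped)
    A_mc = _gene_drop_A(ped, n_rep=40000, seed=5)
    assert np.abs(A - A_mc).max() < 0.02


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 6), st.integers(0, 6)), min_size=1, max_size=14))
def test_A_positive_semidefinite_on_random_pedigrees(raw):
    """A from the tabular method is symmetric PSD on arbitrary pedigrees."""
    rows = [(f"f{k}", None, None) for k in range(7)]
    for i, (has_parents, d, s) in enumerate(raw):
        rows.append((f"i{i}", f"f{d}" if has_parents else None, f"f{s}" if has_parents else None))
    ped = Pedigree.from_triples(rows)
    A = additive_relationship(ped)
    assert np.allclose(A, A.T)
    assert np.linalg.eigvalsh(A).min() >= -1e-8


def test_csv_round_trip(tmp_path, tiny_study):
    from phenoselect.pedigree import read_pedigree_csv, write_pedigree_csv

    path = tmp_path / "ped.csv"
    write_pedigree_csv(tiny_study.pedigree, path)
    back = read_pedigree_csv(path)
    assert list(back.ids) == list(tiny_study.pedigree.ids)
    assert (back.dam == tiny_study.pedigree.dam).all()
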