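import numpy as np
import pandas as pd
import pytest

from hetmate import (
    GenotypeTable,
    RelatednessMatrix,
    allele_frequencies,
    assortment_permutation_test,
    gen_mating_table,
    gen_population,
    het_map,
    paternity_exclusion,
    paternity_exclusion_batch,
    relatedness_randomization_ci,
    wang_relatedness,
    SynthConfig,
)


def _pairs(n, year=True):
    df = pd.DataFrame({
        "female_id": [f"f{k}" for k in range(n)],
        "male_id": [f"m{k}" for k in range(n)],
    })
    if year:
        df["year"] = ["2014" if k % 2 == 0 else "2015" for k in range(n)]
    return df


def test_assortment_maximal_statistic():
    """Female het identical to male het in every pair: r = 1, tiny p."""
    pairs = _pairs(50)
    vals = np.linspace(0.1, 0.9, 50)
    trait = {f"f{k}": vals[k] for k in range(50)} | {f"m{k}": vals[k] for k in range(50)}
    res = assortment_permutation_test(pairs, trait, n_perm=10_000, seed=0)
    assert res.observed == pytest.approx(1.0)
    assert res.p_value <= 0.001


def test_assortment_default_n_perm_and_errors():
    import inspect

    assert inspect.signature(assortment_permutation_test).parameters["n_perm"].default == 10_000
    pairs = _pairs(5)
    flat = {f"f{k}": 0.5 for k in range(5)} | {f"m{k}": float(k) for k in range(5)}
    with pytest.raises(ValueError, match="variance"):
        assortment_permutation_test(pairs, flat, n_perm=10, seed=0)
    with pytest.raises(ValueError, match=">= 3 pairs"):
        assortment_permutation_test(_pairs(2), {"f0": 1, "f1": 2, "m0": 1, "m1": 2},
                                    n_perm=10, seed=0)


def test_assortment_reproducible_and_spearman():
    rng = np.random.default_rng(8)
    pairs = _pairs(30)
    trait = {i: float(v) for i, v in zip(
        list(pairs.female_id) + list(pairs.male_id), rng.random(60))}
    a = assortment_permutation_test(pairs, trait, n_perm=500, seed=4)
    b = assortment_permutation_test(pairs, trait, n_perm=500, seed=4)
    assert a.p_value == b.p_value and a.null_q025 == b.null_q025
    s = assortment_permutation_test(pairs, trait, n_perm=500, seed=4, method="spearman")
    assert -1.0 <= s.observed <= 1.0


def test_assortment_pvalues_near_uniform_under_null():
    """Permutation p-values should be (super-)uniform under random pairing."""
    reject_05 = 0
    reject_20 = 0
    n_rep = 300
    for i in range(n_rep):
        rng = np.random.default_rng(1000 + i)
        pairs = _pairs(40)
        trait = {i_: float(v) for i_, v in zip(
            list(pairs.female_id) + list(pairs.male_id), rng.random(80))}
        p = assortment_permutation_test(pairs, trait, n_perm=199, seed=i).p_value
        reject_05 += p <= 0.05
        reject_20 += p <= 0.20
    assert reject_05 / n_rep <= 0.05 + 0.03
    assert abs(reject_20 / n_rep - 0.20) <= 0.07


def test_relatedness_ci_degenerate_equal_r():
    pairs = _pairs(6)
    rows = []
    for f in pairs.female_id:
        for m in pairs.male_id:
            rows.append({"id1": f, "id2": m, "r": 0.1, "phi": 0.2, "delta": 0.0,
                         "n_loci": 10, "out_of_range": False})
    rmat = RelatednessMatrix(pd.DataFrame(rows))
    res = relatedness_randomization_ci(pairs, rmat, n_iter=200, seed=0)
    assert res.observed == pytest.approx(0.1)
    assert res.null_q025 == pytest.approx(0.1) and res.null_q975 == pytest.approx(0.1)
    assert res.observed_inside


def test_relatedness_ci_missing_dyads_listed():
    pairs = _pairs(3)
    rmat = RelatednessMatrix(pd.DataFrame(
        [{"id1": "f0", "id2": "m0", "r": 0.0, "phi": 0, "delta": 0,
          "n_loci": 5, "out_of_range": False}]
    ))
    with pytest.raises(ValueError, match="missing relatedness"):
        relatedness_randomization_ci(pairs, rmat, n_iter=10, seed=0)


def test_relatedness_ci_default_iterations():
    import inspect

    assert inspect.signature(relatedness_randomization_ci).parameters["n_iter"].default == 100_000


def test_relatedness_ci_within_year_only():
    """Null re-pairings never cross year boundaries: with year-specific r
    plateaus the null distribution stays degenerate per year."""
    pairs = _pairs(4)  # years alternate 2014/2015
    rows = []
    for f in pairs.female_id:
        for m in pairs.male_id:
            yr_f = int(f[1:]) % 2
            yr_m = int(m[1:]) % 2
            rows.append({"id1": f, "id2": m,
                         "r": 0.2 if yr_f == 0 and yr_m == 0 else 0.0,
                         "phi": 0, "delta": 0, "n_loci": 5, "out_of_range": False})
    rmat = RelatednessMatrix(pd.DataFrame(rows))
    res = relatedness_randomization_ci(pairs, rmat, n_iter=100, seed=1)
    # 2 of 4 pairs sit in the 2014 block where r = 0.2 for every combination
    assert res.observed == pytest.approx(0.1)
    assert res.null_q025 == pytest.approx(0.1) and res.null_q975 == pytest.approx(0.1)


# -- paternity exclusion -----------------------------------------------------


def test_paternity_constructed_match_and_mismatch():
    L = 6
    mother = np.tile([1, 2], (L, 1))
    father = np.tile([3, 4], (L, 1))
    # offspring: one maternal + one paternal allele at every locus
    off = np.tile([1, 3], (L, 1))
    rep = paternity_exclusion(off, mother, father)
    assert rep.mismatches == 0 and not rep.excluded
    # candidate lacking the non-maternal allele at exactly 3 loci
    cand = father.copy()
    cand[:3] = [5, 6]
    rep2 = paternity_exclusion(off, mother, cand)
    assert rep2.mismatches == 3 and rep2.excluded
    assert rep2.mismatch_loci == (0, 1, 2)


def test_paternity_ambiguous_maternal_sharing_keeps_both_alleles():
    # mother shares both offspring alleles: candidate carrying either passes
    mother = np.array([[1, 2]])
    off = np.array([[1, 2]])
    assert paternity_exclusion(off, mother, np.array([[2, 9]])).mismatches == 0
    assert paternity_exclusion(off, mother, np.array([[8, 9]])).mismatches == 1


def test_paternity_zero_comparable_loci_errors():
    g = np.array([[0, 0]])
    with pytest.raises(ValueError):
        paternity_exclusion(g, g, g)


def test_paternity_symmetric_under_allele_relabeling():
    rng = np.random.default_rng(10)
    off = rng.integers(1, 9, (12, 2))
    mother = rng.integers(1, 9, (12, 2))
    cand = rng.integers(1, 9, (12, 2))
    base = paternity_exclusion(np.sort(off, 1), np.sort(mother, 1), np.sort(cand, 1))
    relabel = np.vectorize({**{k: 20 - k for k in range(1, 10)}}.get)
    again = paternity_exclusion(
        np.sort(relabel(off), 1), np.sort(relabel(mother), 1), np.sort(relabel(cand), 1)
    )
    assert base.mismatches == again.mismatches


def test_paternity_batch_matches_single():
    rng = np.random.default_rng(11)
    off = np.sort(rng.integers(1, 9, (20, 10, 2)), axis=-1)
    mo = np.sort(rng.integers(1, 9, (20, 10, 2)), axis=-1)
    ca = np.sort(rng.integers(1, 9, (20, 10, 2)), axis=-1)
    batch = paternity_exclusion_batch(off, mo, ca)
    for k in range(20):
        single = paternity_exclusion(off[k], mo[k], ca[k])
        assert batch.loc[k, "mismatches"] == single.mismatches
        assert bool(batch.loc[k, "excluded"]) == single.excluded
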