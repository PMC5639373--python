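"""Resampling tests for non-random pairing and Mendelian paternity exclusion.

* ``assortment_permutation_test`` -- is the trait correlation between pair
  members larger than expected under random pairing?  The null distribution
  is built by permuting the females among pairs (within year when year
  labels exist) and recomputing the correlation; the two-sided add-one
  p-value ``(1 + #{|T_null| >= |T_obs|}) / (n_perm + 1)`` is strictly valid.

* ``relatedness_randomization_ci`` -- does the observed mean pair
  relatedness fall inside the 95% percentile interval of means obtained from
  randomly re-paired (within-year bijection) males and females?

* ``paternity_exclusion`` -- Mendelian mismatch counting for a
  mother/offspring/candidate-father trio: at each locus the candidate must
  carry one of the offspring's possible paternal alleles; enough mismatching
  loci (default 2, since single mismatches are commonly genotyping error)
  exclude the candidate as sire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING
from .genetic_stats import RelatednessMatrix


@dataclass(frozen=True)
class ResamplingResult:
    """Observed statistic plus a resampled null-distribution summary."""

    observed: float
    null_n: int
    null_q025: float
    null_q975: float
    p_value: float | None
    seed: int | None
    method: str
    observed_inside: bool | None = None

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "null_n": self.null_n,
            "null_q025": self.null_q025,
            "null_q975": self.null_q975,
            "p_value": self.p_value,
            "observed_inside": self.observed_inside,
            "method": self.method,
            "seed": self.seed,
        }


def _validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    for col in ("female_id", "male_id"):
        if col not in pairs.columns:
            raise ValueError(f"pair table needs a {col!r} column")
    if "year" in pairs.columns:
        for col in ("female_id", "male_id"):
            dup = pairs.duplicated(subset=[col, "year"])
            if dup.any():
                raise ValueError(f"individual appears in >1 pair within a year ({col})")
    return pairs


def _year_blocks(pairs: pd.DataFrame) -> list[np.ndarray]:
    if "year" in pairs.columns:
        return [np.flatnonzero((pairs["year"] == y).to_numpy()) for y in pairs["year"].unique()]
    return [np.arange(len(pairs))]


def assortment_permutation_test(
    pairs: pd.DataFrame,
    trait: Mapping[str, float],
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "pearson",
) -> ResamplingResult:
    """Permutation test for assortative pairing on a per-individual trait.

    The observed statistic is the correlation of (female trait, male trait)
    over pairs; female traits are permuted among pairs, within year when a
    ``year`` column is present.  Default 10 000 permutations.
    """
    pairs = _validate_pairs(pairs)
    x = np.array([trait.get(i, np.nan) for i in pairs["female_id"]], dtype=float)
    y = np.array([trait.get(i, np.nan) for i in pairs["male_id"]], dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    pairs, x, y = pairs[ok].reset_index(drop=True), x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 pairs with trait values for both members, got {n}")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero trait variance in one sex; correlation undefined")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    observed = float(np.mean(zx * zy))

    rng = np.random.default_rng(seed)
    blocks = _year_blocks(pairs)
    idx = np.tile(np.arange(n), (n_perm, 1))
    for block in blocks:
        perms = rng.permuted(np.tile(block, (n_perm, 1)), axis=1)
        idx[:, block] = perms
    # permuting within blocks leaves each sex's marginal trait multiset intact
    assert np.array_equal(np.sort(idx[0]), np.arange(n))
    null = (zx[idx] * zy[None, :]).mean(axis=1)
    p = float((1 + np.sum(np.abs(null) >= np.abs(observed) - 1e-12)) / (n_perm + 1))
    return ResamplingResult(
        observed=observed,
        null_n=n_perm,
        null_q025=float(np.quantile(null, 0.025)),
        null_q975=float(np.quantile(null, 0.975)),
        p_value=p,
        seed=seed,
        method=f"permutation-{method}",
    )


def relatedness_randomization_ci(
    pairs: pd.DataFrame,
    rmat: RelatednessMatrix,
    n_iter: int = 100_000,
    seed: int | None = None,
) -> ResamplingResult:
    """Randomization CI for the mean relatedness of breeding pairs.

    Each null replicate re-pairs the females and males of each year by a
    random bijection and records the mean relatedness of the resulting
    pairs; the 95% percentile interval of those means is compared with the
    observed mean.  Default 100 000 iterations.
    """
    pairs = _validate_pairs(pairs)
    missing = [
        (f, m)
        for f, m in zip(pairs["female_id"], pairs["male_id"])
        if not rmat.has(f, m)
    ]
    blocks = _year_blocks(pairs)
    females = pairs["female_id"].to_numpy()
    males = pairs["male_id"].to_numpy()
    for block in blocks:
        for f in females[block]:
            for m in males[block]:
                if not rmat.has(f, m):
                    missing.append((f, m))
    if missing:
        raise ValueError(
            f"missing relatedness for {len(missing)} dyad(s), e.g. {missing[:3]}"
        )
    observed = float(np.mean([rmat.r(f, m) for f, m in zip(females, males)]))

    rng = np.random.default_rng(seed)
    n = len(pairs)
    totals = np.zeros(n_iter)
    for block in blocks:
        bf, bm = females[block], males[block]
        sub = np.array([[rmat.r(f, m) for m in bm] for f in bf])  # (k, k)
        k = len(block)
        perms = rng.permuted(np.tile(np.arange(k), (n_iter, 1)), axis=1)
        totals += sub[np.arange(k)[None, :], perms].sum(axis=1)
    null = totals / n
    lo, hi = float(np.quantile(null, 0.025)), float(np.quantile(null, 0.975))
    return ResamplingResult(
        observed=observed,
        null_n=n_iter,
        null_q025=lo,
        null_q975=hi,
        p_value=None,
        seed=seed,
        method="randomization-ci",
        observed_inside=bool(lo - 1e-12 <= observed <= hi + 1e-12),
    )


# ---------------------------------------------------------------------------
# Paternity exclusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MismatchReport:
    """Mendelian mismatch counts for one mother/offspring/candidate trio."""

    mismatches: int
    loci_compared: int
    excluded: bool
    mismatch_loci: tuple[int, ...]
    threshold: int


def _mismatch_mask(
    offspring: np.ndarray, mother: np.ndarray, candidate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-locus mismatch and comparable masks, shapes (..., L)."""
    o1, o2 = offspring[..., 0], offspring[..., 1]
    m1, m2 = mother[..., 0], mother[..., 1]
    c1, c2 = candidate[..., 0], candidate[..., 1]
    comparable = (o1 != MISSING) & (m1 != MISSING) & (c1 != MISSING)
    in_m1 = (o1 == m1) | (o1 == m2)
    in_m2 = (o2 == m1) | (o2 == m2)
    carry1 = (o1 == c1) | (o1 == c2)
    carry2 = (o2 == c1) | (o2 == c2)
    # paternal candidate alleles: both offspring alleles when the mother shares
    # both (or neither -- indeterminate, conservative); otherwise the allele
    # the mother cannot have provided
    both = in_m1 & in_m2
    neither = ~in_m1 & ~in_m2
    mism = np.where(
        both | neither,
        ~carry1 & ~carry2,
        np.where(in_m1, ~carry2, ~carry1),
    )
    return mism & comparable, comparable


def paternity_exclusion(
    offspring: np.ndarray,
    mother: np.ndarray,
    candidate: np.ndarray,
    threshold: int = 2,
) -> MismatchReport:
    """Mendelian exclusion of a candidate sire for one trio.

    Per locus the offspring's possible paternal alleles are its alleles minus
    one attributable to the mother (both remain candidates when the mother
    shares both); a mismatch is scored when the candidate carries neither.
    ``excluded`` is True when mismatches reach ``threshold`` (default 2).
    """
    offspring = np.asarray(offspring, dtype=np.int64)
    mother = np.asarray(mother, dtype=np.int64)
    candidate = np.asarray(candidate, dtype=np.int64)
    mism, comparable = _mismatch_mask(offspring, mother, candidate)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("trio has zero loci typed in all three individuals")
    count = int(mism.sum())
    return MismatchReport(
        mismatches=count,
        loci_compared=n_comp,
        excluded=count >= threshold,
        mismatch_loci=tuple(int(j) for j in np.flatnonzero(mism)),
        threshold=threshold,
    )


def paternity_exclusion_batch(
    offspring: np.ndarray,
    mothers: np.ndarray,
    candidates: np.ndarray,
    threshold: int = 2,
) -> pd.DataFrame:
    """Vectorised exclusion over stacked trios, shapes (n, L, 2) each."""
    mism, comparable = _mismatch_mask(
        np.asarray(offspring, dtype=np.int64),
        np.asarray(mothers, dtype=np.int64),
        np.asarray(candidates, dtype=np.int64),
    )
    counts = mism.sum(axis=-1)
    return pd.DataFrame(
        {
            "mismatches": counts,
            "loci_compared": comparable.sum(axis=-1),
            "excluded": counts >= threshold,
        }
    )
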