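"""Monte-Carlo and exact expected offspring heterozygosity for a dyad.

Offspring are produced by free Mendelian transmission: per locus, one
uniformly chosen allele from each parent, independent across loci and
offspring, no mutation, no linkage.  Loci missing in either parent are
missing in the offspring (dropped, not imputed).

Because an offspring's HL has a denominator (the sum of E_l over its typed
polymorphic loci) that is the same for every offspring of a given dyad, the
exact expectation factorises per locus:

    E[HL] = sum_l E_l * h_l / sum_l E_l,    h_l = P(offspring homozygous at l)

with h_l = (number of equal (paternal, maternal) allele pairs) / 4 from the
two parental genotypes.  ``expected_offspring_hl_exact`` returns this exact
value; the Monte-Carlo routine mirrors the iterate-and-average protocol
(average HL of ``n_offspring`` simulated offspring, averaged over
``n_iterations`` iterations, defaults 100 x 1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, AlleleFrequencies
from .genetic_stats import expected_heterozygosity


@dataclass(frozen=True)
class DyadGeneticProfile:
    """Per-dyad offspring-heterozygosity summary."""

    focal_id: str
    partner_id: str
    r: float
    offspring_hl_mc: float
    offspring_hl_exact: float
    mc_se: float
    n_loci: int
    n_offspring: int
    n_iterations: int
    seed: int | None


def _as_geno(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.int64)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("genotype vector must have shape (n_loci, 2)")
    return v


def simulate_offspring(
    father: np.ndarray,
    mother: np.ndarray,
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate ``n`` offspring genotype vectors, shape (n, n_loci, 2).

    Each offspring receives one uniformly chosen allele from each parent per
    locus; a locus missing in either parent is missing in every offspring.
    """
    father = _as_geno(father)
    mother = _as_geno(mother)
    if father.shape != mother.shape:
        raise ValueError("parents must be typed on the same locus set")
    if n < 1:
        raise ValueError("n must be >= 1")
    L = father.shape[0]
    shared = (father[:, 0] != MISSING) & (mother[:, 0] != MISSING)
    if not shared.any():
        raise ValueError("parents share no typed loci")
    rng = np.random.default_rng(seed)
    pa = father[np.arange(L), rng.integers(0, 2, size=(n, L))]
    ma = mother[np.arange(L), rng.integers(0, 2, size=(n, L))]
    off = np.sort(np.stack([pa, ma], axis=-1), axis=-1)
    off[:, ~shared, :] = MISSING
    return off


def _locus_setup(
    father: np.ndarray,
    mother: np.ndarray,
    freqs: AlleleFrequencies,
    loci: Sequence[str] | None,
):
    father = _as_geno(father)
    mother = _as_geno(mother)
    loci = tuple(loci) if loci is not None else freqs.loci
    if father.shape[0] != len(loci) or mother.shape[0] != len(loci):
        raise ValueError("genotype vectors do not match the locus list")
    e = np.array([expected_heterozygosity(freqs, l) for l in loci])
    shared = (father[:, 0] != MISSING) & (mother[:, 0] != MISSING)
    if not shared.any():
        raise ValueError("parents share no typed loci")
    usable = shared & (e > 0.0)
    den = float(e[usable].sum())
    # P(homozygous offspring) per locus: matching (paternal, maternal) picks / 4
    match = (
        (father[:, :, None] == mother[:, None, :]).sum(axis=(1, 2)).astype(float) / 4.0
    )
    return father, mother, e, usable, den, match


def expected_offspring_hl_exact(
    father: np.ndarray,
    mother: np.ndarray,
    freqs: AlleleFrequencies,
    loci: Sequence[str] | None = None,
) -> float:
    """Exact expectation of offspring HL for one dyad (closed form).

    Equals the brute-force enumeration over all 4^L equiprobable offspring
    because HL's denominator is constant across a dyad's offspring.
    Undefined (NaN) when every shared typed locus is monomorphic.
    """
    _, _, e, usable, den, match = _locus_setup(father, mother, freqs, loci)
    if den == 0.0:
        return float("nan")
    return float((e[usable] * match[usable]).sum() / den)


def dyad_offspring_hl(
    father: np.ndarray,
    mother: np.ndarray,
    freqs: AlleleFrequencies,
    loci: Sequence[str] | None = None,
    n_offspring: int = 100,
    n_iterations: int = 1000,
    seed: int | None = None,
    focal_id: str = "focal",
    partner_id: str = "partner",
    r: float = float("nan"),
) -> DyadGeneticProfile:
    """Monte-Carlo mean offspring HL with its exact counterpart.

    Per iteration, ``n_offspring`` offspring are simulated and their mean HL
    taken; the reported value is the mean of the iteration means and
    ``mc_se`` the standard error of that mean (SD of iteration means over
    sqrt(n_iterations)).
    """
    father, mother, e, usable, den, _ = _locus_setup(father, mother, freqs, loci)
    exact = expected_offspring_hl_exact(father, mother, freqs, loci)
    if den == 0.0:
        raise ValueError("offspring HL undefined: all shared typed loci are monomorphic")
    rng = np.random.default_rng(seed)
    Lu = int(usable.sum())
    fa = father[usable]
    mo = mother[usable]
    ev = e[usable]
    iter_means = np.empty(n_iterations)
    ar = np.arange(Lu)
    for it in range(n_iterations):
        pa = fa[ar, rng.integers(0, 2, size=(n_offspring, Lu))]
        ma = mo[ar, rng.integers(0, 2, size=(n_offspring, Lu))]
        hom = pa == ma
        iter_means[it] = float((hom @ ev).mean() / den)
    mc = float(iter_means.mean())
    se = float(iter_means.std(ddof=1) / np.sqrt(n_iterations)) if n_iterations > 1 else float("nan")
    return DyadGeneticProfile(
        focal_id=focal_id,
        partner_id=partner_id,
        r=r,
        offspring_hl_mc=mc,
        offspring_hl_exact=exact,
        mc_se=se,
        n_loci=Lu,
        n_offspring=n_offspring,
        n_iterations=n_iterations,
        seed=seed,
    )
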