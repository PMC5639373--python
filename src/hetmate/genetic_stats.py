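"""Individual heterozygosity and pairwise relatedness from microsatellites.

Two marker-based quantities are computed here:

* **Homozygosity by locus (HL)** -- an individual homozygosity index that
  weights each locus by its expected heterozygosity ``E_l = 1 - sum_a p_a^2``:

      HL = sum(E_l over homozygous typed loci)
         / sum(E_l over all typed polymorphic loci)

  The complement ``het = 1 - HL`` is the heterozygosity measure used by the
  rest of the pipeline.  A split-half locus correlation (``hhc_split_half``)
  checks whether a marker panel is a consistent proxy for genome-wide
  heterozygosity: identity disequilibrium (variance in inbreeding) makes
  heterozygosity correlate across independent locus subsets.

* **Pairwise relatedness** -- a moment estimator of the two-gene and
  four-gene IBD coefficients (phi, Delta) from the identity-by-state
  configuration of a dyad's genotypes at each locus, with relatedness
  ``r = phi/2 + Delta``.  Estimates are method-of-moments values: they may
  fall outside [-1, 1] and are deliberately not clamped, so that averages
  over dyads remain unbiased; out-of-range values are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, AlleleFrequencies, GenotypeTable

PEDIGREE_R = {
    "clone": 1.0,
    "parent-offspring": 0.5,
    "full-sib": 0.5,
    "half-sib": 0.25,
    "unrelated": 0.0,
}

#: (phi, Delta) IBD coefficients of the standard outbred pedigree classes
PEDIGREE_PHI_DELTA = {
    "clone": (0.0, 1.0),
    "parent-offspring": (1.0, 0.0),
    "full-sib": (0.5, 0.25),
    "half-sib": (0.5, 0.0),
    "unrelated": (0.0, 0.0),
}


def pedigree_expected_r(relationship: str) -> float:
    """Expected relatedness of a named pedigree class (test oracle)."""
    try:
        return PEDIGREE_R[relationship]
    except KeyError:
        raise ValueError(
            f"unknown relationship {relationship!r}; expected one of {sorted(PEDIGREE_R)}"
        ) from None


# ---------------------------------------------------------------------------
# Expected heterozygosity and HL
# ---------------------------------------------------------------------------


def expected_heterozygosity(
    freqs: AlleleFrequencies, locus: str, corrected: bool = False
) -> float:
    """Plug-in expected heterozygosity ``E_l = 1 - sum_a p_a^2`` at one locus.

    ``corrected=True`` substitutes the unbiased estimate of ``sum p^2``
    (2n/(2n-1)-style correction); the plug-in form is the default because it
    is what the HL index conventionally uses.
    """
    a2, _, _ = freqs.moments(locus, corrected=corrected)
    return 1.0 - a2


def _expected_het_vector(
    freqs: AlleleFrequencies, loci: Sequence[str], corrected: bool
) -> np.ndarray:
    return np.array(
        [expected_heterozygosity(freqs, l, corrected=corrected) for l in loci]
    )


def hl_table(
    table: GenotypeTable,
    freqs: AlleleFrequencies,
    min_loci: int = 10,
    corrected: bool = False,
) -> pd.DataFrame:
    """HL, het = 1 - HL and loci-used counts for every individual.

    Loci missing for an individual are excluded from both sums; monomorphic
    loci (E_l = 0) carry no weight and are not counted in ``n_loci_used``.
    Individuals with fewer than ``min_loci`` usable loci, or with zero
    denominator, get ``NaN`` and ``flag`` set.

    Returns a DataFrame indexed like ``table.individuals`` with columns
    ``id, hl, het, n_loci_used, flag``.
    """
    e = _expected_het_vector(freqs, table.loci, corrected)  # (L,)
    typed = table.typed_mask()  # (n, L)
    hom = typed & (table.calls[:, :, 0] == table.calls[:, :, 1])
    usable = typed & (e > 0.0)
    num = (hom * e).sum(axis=1)
    den = (typed * e).sum(axis=1)
    n_used = usable.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hl = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), np.nan)
    flag = (n_used < min_loci) | (den <= 0.0)
    hl = np.where(flag, np.nan, hl)
    return pd.DataFrame(
        {
            "id": list(table.individuals),
            "hl": hl,
            "het": 1.0 - hl,
            "n_loci_used": n_used.astype(int),
            "flag": flag,
        }
    )


def hl_index(
    table: GenotypeTable,
    freqs: AlleleFrequencies,
    individual: str,
    min_loci: int = 10,
    corrected: bool = False,
) -> dict:
    """One individual's row of :func:`hl_table`, as a plain dict."""
    i = table.index_of(individual)
    row = hl_table(table, freqs, min_loci=min_loci, corrected=corrected).iloc[i]
    return {
        "id": individual,
        "hl": float(row["hl"]),
        "het": float(row["het"]),
        "n_loci_used": int(row["n_loci_used"]),
        "flag": bool(row["flag"]),
    }


def het_map(
    table: GenotypeTable,
    freqs: AlleleFrequencies,
    min_loci: int = 10,
) -> dict[str, float]:
    """id -> het (1 - HL) for all unflagged individuals; convenience wrapper."""
    df = hl_table(table, freqs, min_loci=min_loci)
    ok = df[~df["flag"]]
    return dict(zip(ok["id"], ok["het"]))


# ---------------------------------------------------------------------------
# Split-half heterozygosity-heterozygosity correlation (HHC)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HHCResult:
    """Summary of random split-half heterozygosity correlations."""

    n_splits: int
    correlations: np.ndarray  # NaN where a split was undefined
    mean_r: float
    q025: float
    q975: float
    n_undefined: int

    def __repr__(self) -> str:
        return (
            f"HHCResult(n_splits={self.n_splits}, mean_r={self.mean_r:.3f}, "
            f"95% [{self.q025:.3f}, {self.q975:.3f}], undefined={self.n_undefined})"
        )


def hhc_split_half(
    table: GenotypeTable,
    freqs: AlleleFrequencies,
    n_splits: int = 1000,
    seed: int | None = None,
    min_loci: int = 1,
) -> HHCResult:
    """Heterozygosity-heterozygosity correlation over random locus split-halves.

    For each split the loci are randomly partitioned into disjoint halves of
    sizes floor(L/2) and ceil(L/2); per-individual het (1 - HL) is computed on
    each half and the Pearson correlation across individuals recorded.  Splits
    where either half has zero het variance are recorded as NaN and excluded
    from the summary, with their count reported.
    """
    if table.n_loci < 4:
        raise ValueError("need at least 4 loci for a split-half correlation")
    rng = np.random.default_rng(seed)
    L = table.n_loci
    e = _expected_het_vector(freqs, table.loci, corrected=False)
    typed = table.typed_mask()
    hom = typed & (table.calls[:, :, 0] == table.calls[:, :, 1])
    het_w = (typed & ~hom) * e  # per-locus E_l contribution of het loci
    all_w = typed * e

    corrs = np.full(n_splits, np.nan)
    for s in range(n_splits):
        perm = rng.permutation(L)
        half_a, half_b = perm[: L // 2], perm[L // 2 :]
        vals = []
        for half in (half_a, half_b):
            den = all_w[:, half].sum(axis=1)
            num = het_w[:, half].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            vals.append(v)
        ok = ~np.isnan(vals[0]) & ~np.isnan(vals[1])
        if ok.sum() < 5:
            continue
        x, y = vals[0][ok], vals[1][ok]
        if x.std() == 0.0 or y.std() == 0.0:
            continue
        corrs[s] = np.corrcoef(x, y)[0, 1]
    defined = corrs[~np.isnan(corrs)]
    if defined.size == 0:
        raise ValueError("every split-half correlation was undefined")
    return HHCResult(
        n_splits=n_splits,
        correlations=corrs,
        mean_r=float(defined.mean()),
        q025=float(np.quantile(defined, 0.025)),
        q975=float(np.quantile(defined, 0.975)),
        n_undefined=int(np.isnan(corrs).sum()),
    )


# ---------------------------------------------------------------------------
# Pairwise relatedness (moment estimator, Wang-type)
# ---------------------------------------------------------------------------


@dataclass
class RelatednessMatrix:
    """Pairwise relatedness estimates for a set of unordered dyads.

    ``table`` is a long-format DataFrame with columns
    ``id1, id2, r, phi, delta, n_loci, out_of_range``; lookups via
    :meth:`r` are symmetric in the two ids.  Raw estimates are stored;
    values outside [-1, 1] are flagged, never clamped.
    """

    table: pd.DataFrame
    estimator: str = "wang"
    _lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._lookup = {
            frozenset((a, b)): r
            for a, b, r in zip(self.table["id1"], self.table["id2"], self.table["r"])
        }

    def r(self, id1: str, id2: str) -> float:
        key = frozenset((id1, id2))
        if key not in self._lookup:
            raise KeyError(f"no relatedness estimate for dyad ({id1!r}, {id2!r})")
        return self._lookup[key]

    def has(self, id1: str, id2: str) -> bool:
        return frozenset((id1, id2)) in self._lookup


def _ibs_category_probs(a2: np.ndarray, a3: np.ndarray, a4: np.ndarray):
    """Per-locus IBS-category probabilities under the (phi, Delta) model.

    Dyad genotypes fall into four identity-by-state categories:
    1 identical genotypes; 2 one homozygote vs a heterozygote carrying its
    allele; 3 two heterozygotes sharing exactly one allele; 4 no shared
    allele.  For outbred individuals the category probabilities are linear in
    (phi, Delta) with coefficients that depend only on the allele-frequency
    moments a2, a3, a4:

        P_k = Delta * [k == 1] + phi * c_k + (1 - phi - Delta) * b_k

    where b_k are the unrelated-dyad probabilities and c_k those for a dyad
    sharing exactly one gene IBD.  The expressions below follow from
    enumerating allele draws (and are Monte-Carlo-verified in the tests).
    """
    b1 = 2.0 * a2**2 - a4
    b2 = 4.0 * (a3 - a4)
    b3 = 4.0 * (a2 - 2.0 * a3 + 2.0 * a4 - a2**2)
    c1 = a2
    c2 = 2.0 * (a2 - a3)
    c3 = 1.0 - 3.0 * a2 + 2.0 * a3
    return (b1, b2, b3), (c1, c2, c3)


def _wang_locus_design(
    freqs: AlleleFrequencies, loci: Sequence[str], corrected: bool
) -> dict[str, np.ndarray]:
    """Per-locus moment coefficients, similarity weights and usability mask."""
    a2 = np.empty(len(loci))
    a3 = np.empty(len(loci))
    a4 = np.empty(len(loci))
    poly = np.zeros(len(loci), dtype=bool)
    for j, locus in enumerate(loci):
        a2[j], a3[j], a4[j] = freqs.moments(locus, corrected=corrected)
        poly[j] = len(freqs.frequencies(locus)) >= 2
    (b1, b2, b3), (c1, c2, c3) = _ibs_category_probs(a2, a3, a4)
    u = 2.0 * a2 - a4  # similarity of two random gene pairs; drives locus weights
    w = np.where(poly, 1.0 / u, 0.0)
    # centred design matrix rows per locus: E[P_k] - b_k = phi*(c_k - b_k) + Delta*(d_k - b_k)
    x_phi = np.stack([c1 - b1, c2 - b2, c3 - b3])  # (3, L)
    x_delta = np.stack([1.0 - b1, -b2, -b3])
    base = np.stack([b1, b2, b3])
    return {"w": w, "poly": poly, "x_phi": x_phi, "x_delta": x_delta, "base": base}


def _classify_ibs(ga: np.ndarray, gb: np.ndarray):
    """IBS categories for paired genotype arrays of shape (..., L, 2).

    Returns boolean arrays (cat1, cat2, cat3, valid): valid = both typed.
    Category 4 is the remainder.  Genotypes must be stored allele-ascending.
    """
    a1, a2_ = ga[..., 0], ga[..., 1]
    b1, b2_ = gb[..., 0], gb[..., 1]
    valid = (a1 != MISSING) & (b1 != MISSING)
    a_hom = a1 == a2_
    b_hom = b1 == b2_
    same = (a1 == b1) & (a2_ == b2_)
    share_a1 = (a1 == b1) | (a1 == b2_)
    share_a2 = (a2_ == b1) | (a2_ == b2_)
    any_share = share_a1 | share_a2
    cat1 = same & valid
    cat2 = valid & ~same & (
        (a_hom & ~b_hom & ((a1 == b1) | (a1 == b2_)))
        | (b_hom & ~a_hom & ((b1 == a1) | (b1 == a2_)))
    )
    cat3 = valid & any_share & ~cat1 & ~cat2
    return cat1, cat2, cat3, valid


def _wang_core(
    ga: np.ndarray,
    gb: np.ndarray,
    design: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised moment estimates (phi, Delta, n_loci) for dyad genotype arrays.

    ``ga``/``gb`` have shape (n_dyads, L, 2).  Per dyad the locus-wise category
    indicators and design coefficients are averaged with weights 1/(2*a2 - a4)
    over the loci usable for that dyad, and the resulting over-determined 3x2
    linear moment system is solved by least squares.
    """
    cat1, cat2, cat3, valid = _classify_ibs(ga, gb)
    usable = valid & design["poly"][None, :]
    w = design["w"][None, :] * usable  # (n, L)
    wsum = w.sum(axis=1)
    n_loci = usable.sum(axis=1)
    ok = wsum > 0

    def wavg(values: np.ndarray) -> np.ndarray:
        # values: (L,) or (n, L) -> weighted mean per dyad
        return (w * values).sum(axis=1) / np.where(ok, wsum, 1.0)

    p_obs = np.stack([wavg(cat1), wavg(cat2), wavg(cat3)])  # (3, n)
    base = np.stack([wavg(design["base"][k]) for k in range(3)])
    xp = np.stack([wavg(design["x_phi"][k]) for k in range(3)])
    xd = np.stack([wavg(design["x_delta"][k]) for k in range(3)])
    y = p_obs - base

    # closed-form 2x2 least squares per dyad
    app = (xp * xp).sum(axis=0)
    apd = (xp * xd).sum(axis=0)
    add = (xd * xd).sum(axis=0)
    byp = (xp * y).sum(axis=0)
    byd = (xd * y).sum(axis=0)
    det = app * add - apd**2
    bad = ~ok | (np.abs(det) < 1e-14)
    det_safe = np.where(bad, 1.0, det)
    phi = (add * byp - apd * byd) / det_safe
    delta = (app * byd - apd * byp) / det_safe
    phi = np.where(bad, np.nan, phi)
    delta = np.where(bad, np.nan, delta)
    return phi, delta, n_loci


def relatedness_arrays(
    ga: np.ndarray,
    gb: np.ndarray,
    freqs: AlleleFrequencies,
    loci: Sequence[str] | None = None,
    corrected: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-level API: (r, n_loci) for stacked dyad genotype arrays."""
    loci = tuple(loci) if loci is not None else freqs.loci
    design = _wang_locus_design(freqs, loci, corrected)
    phi, delta, n_loci = _wang_core(ga, gb, design)
    return phi / 2.0 + delta, n_loci


def wang_relatedness(
    table: GenotypeTable,
    freqs: AlleleFrequencies,
    dyads: Iterable[tuple[str, str]],
    corrected: bool = True,
) -> RelatednessMatrix:
    """Moment-estimator pairwise relatedness for the given dyads.

    ``r = 0`` means random allele sharing given the population allele
    frequencies; positive/negative values mean more/less sharing than random.
    Symmetric by construction (the category classification does not depend on
    dyad order).  Dyads with no usable shared locus get ``NaN`` and are
    flagged via ``n_loci == 0``.
    """
    dyads = list(dyads)
    ia = np.array([table.index_of(a) for a, _ in dyads], dtype=int)
    ib = np.array([table.index_of(b) for _, b in dyads], dtype=int)
    design = _wang_locus_design(freqs, table.loci, corrected)
    phi, delta, n_loci = _wang_core(table.calls[ia], table.calls[ib], design)
    r = phi / 2.0 + delta
    df = pd.DataFrame(
        {
            "id1": [a for a, _ in dyads],
            "id2": [b for _, b in dyads],
            "r": r,
            "phi": phi,
            "delta": delta,
            "n_loci": n_loci,
            "out_of_range": ~np.isnan(r) & ((r < -1.0) | (r > 1.0)),
        }
    )
    return RelatednessMatrix(df, estimator="wang")


def queller_goodnight_relatedness(
    table: GenotypeTable,
    freqs: AlleleFrequencies,
    dyads: Iterable[tuple[str, str]],
) -> RelatednessMatrix:
    """Queller & Goodnight (1989) regression relatedness, as a cross-check.

    Not the pipeline's default estimator; it provides an independent route to
    the same pedigree expectations for validation.  Numerators and
    denominators are summed across loci before dividing, and the two
    directional estimates are averaged.
    """
    dyads = list(dyads)
    loci = table.loci
    results = np.full(len(dyads), np.nan)
    n_used = np.zeros(len(dyads), dtype=int)
    pmap = [freqs.frequencies(l) for l in loci]
    for k, (ida, idb) in enumerate(dyads):
        ga = table.genotypes_of(ida)
        gb = table.genotypes_of(idb)
        num_x = num_y = den_x = den_y = 0.0
        count = 0
        for j in range(len(loci)):
            a, b = int(ga[j, 0]), int(ga[j, 1])
            c, d = int(gb[j, 0]), int(gb[j, 1])
            if MISSING in (a, c) or len(pmap[j]) < 2:
                continue
            pa, pb = pmap[j].get(a, 0.0), pmap[j].get(b, 0.0)
            pc, pd_ = pmap[j].get(c, 0.0), pmap[j].get(d, 0.0)
            sim = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
            num_x += sim - pa - pb
            den_x += 1.0 + (a == b) - pa - pb
            num_y += sim - pc - pd_
            den_y += 1.0 + (c == d) - pc - pd_
            count += 1
        if count and den_x != 0.0 and den_y != 0.0:
            results[k] = 0.5 * (num_x / den_x + num_y / den_y)
            n_used[k] = count
    df = pd.DataFrame(
        {
            "id1": [a for a, _ in dyads],
            "id2": [b for _, b in dyads],
            "r": results,
            "phi": np.nan,
            "delta": np.nan,
            "n_loci": n_used,
            "out_of_range": ~np.isnan(results) & (np.abs(results) > 1.0),
        }
    )
    return RelatednessMatrix(df, estimator="queller-goodnight")
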