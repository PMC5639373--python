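"""Synthetic microsatellite populations, pedigrees, matings and trials.

Every generator is a pure function of a :class:`SynthConfig` (seed
mandatory): re-running with the same config reproduces the output bitwise.
The defaults emulate the field study's scale -- 17 polymorphic loci, a few
hundred diploid birds, 45-minute six-choice trials with roughly 13% of
trials ending with no stimulus visited -- and the generators carry their
ground truth (pedigree class, extra-pair sire, assortment target) through to
the outputs so that every analysis stage can be validated by recovery tests.

Genotypes are drawn under Hardy-Weinberg equilibrium with optional
inbreeding: an individual with inbreeding coefficient F is autozygous at a
locus (one allele drawn and duplicated) with probability F, else receives
two independent draws.  Pedigreed dyads are built by explicit gamete
transmission from simulated parents, which makes their expected relatedness
exact rather than assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, AlleleFrequencies, GenotypeTable
from .genetic_stats import PEDIGREE_R, het_map
from .preference_analysis import PreferenceTrial

N_STIM = 6  # stimulus slots per six-choice trial

_STREAMS = {
    "population": 11,
    "pedigree": 23,
    "mating": 37,
    "trials": 47,
    "breeding": 59,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters for the synthetic generators.

    ``frequency_concentration`` is the symmetric Dirichlet parameter for the
    per-locus allele frequencies; ``None`` means exactly equifrequent
    alleles.  ``inbreeding_f`` is either a single coefficient for everyone
    or a sequence of candidate values sampled uniformly per individual
    (giving variance in inbreeding, i.e. identity disequilibrium).
    """

    seed: int
    n_individuals: int = 300
    n_loci: int = 17
    alleles_per_locus: int = 8
    frequency_concentration: float | None = 1.0
    inbreeding_f: float | Sequence[float] = 0.0
    assortment_rho: float = 0.0
    preference_strength: float = 0.0
    n_trials: int = 412
    p_zero: float = 0.13
    extra_pair_rate: float = 0.10
    total_time_range: tuple[float, float] = (600.0, 2400.0)
    trial_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1 or self.alleles_per_locus < 1:
            raise ValueError("counts must be positive")
        if self.frequency_concentration is not None and self.frequency_concentration <= 0:
            raise ValueError("frequency_concentration must be positive (or None)")
        if not -1.0 <= self.assortment_rho <= 1.0:
            raise ValueError("assortment_rho must lie in [-1, 1]")
        if self.preference_strength < 0:
            raise ValueError("preference_strength must be >= 0")
        if not 0.0 <= self.p_zero <= 1.0 or not 0.0 <= self.extra_pair_rate <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        fs = np.atleast_1d(np.asarray(self.inbreeding_f, dtype=float))
        if ((fs < 0) | (fs > 1)).any():
            raise ValueError("inbreeding coefficients must lie in [0, 1]")


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream]])


def _locus_names(n: int) -> list[str]:
    return [f"L{j + 1:02d}" for j in range(n)]


def _draw_locus_frequencies(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    k = cfg.alleles_per_locus
    if cfg.frequency_concentration is None:
        return np.full((cfg.n_loci, k), 1.0 / k)
    return rng.dirichlet(np.full(k, cfg.frequency_concentration), size=cfg.n_loci)


def _resolve_f(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    fs = np.atleast_1d(np.asarray(cfg.inbreeding_f, dtype=float))
    if fs.size == 1:
        return np.full(n, fs[0])
    if fs.size == n:
        return fs.copy()
    return fs[rng.integers(0, fs.size, size=n)]


def _sample_genotypes(
    rng: np.random.Generator, p: np.ndarray, n: int, f: np.ndarray
) -> np.ndarray:
    """HWE-with-inbreeding genotypes; p is (L, k), f per individual; (n, L, 2)."""
    L, k = p.shape
    cum = np.cumsum(p, axis=1)  # (L, k)
    u = rng.random((n, L, 2))
    draws = (u[..., :, None] > cum[None, :, None, :]).sum(axis=-1) + 1  # codes 1..k
    auto = rng.random((n, L)) < f[:, None]
    draws[..., 1] = np.where(auto, draws[..., 0], draws[..., 1])
    return np.sort(draws, axis=-1).astype(np.int32)


def _true_frequencies(cfg: SynthConfig, p: np.ndarray) -> AlleleFrequencies:
    loci = _locus_names(cfg.n_loci)
    freqs = [
        {a + 1: float(p[j, a]) for a in range(p.shape[1]) if p[j, a] > 0}
        for j in range(cfg.n_loci)
    ]
    return AlleleFrequencies.from_frequencies(loci, freqs, None)


def gen_population(cfg: SynthConfig) -> tuple[GenotypeTable, AlleleFrequencies]:
    """A diploid population plus its true generating allele frequencies."""
    rng = _rng(cfg, "population")
    p = _draw_locus_frequencies(cfg, rng)
    f = _resolve_f(cfg, rng, cfg.n_individuals)
    calls = _sample_genotypes(rng, p, cfg.n_individuals, f)
    ids = [f"ind{i + 1:04d}" for i in range(cfg.n_individuals)]
    return GenotypeTable(ids, _locus_names(cfg.n_loci), calls), _true_frequencies(cfg, p)


# ---------------------------------------------------------------------------
# Pedigreed dyads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DyadSet:
    """Paired genotype arrays with their true pedigree class."""

    genotypes_a: np.ndarray  # (n, L, 2)
    genotypes_b: np.ndarray
    relationship: str
    expected_r: float
    loci: tuple[str, ...]
    freqs: AlleleFrequencies  # true generating frequencies


def _gamete(rng: np.random.Generator, parents: np.ndarray) -> np.ndarray:
    """One allele per locus from each parent genotype array (n, L, 2) -> (n, L)."""
    n, L, _ = parents.shape
    pick = rng.integers(0, 2, size=(n, L))
    return np.take_along_axis(parents, pick[..., None], axis=2)[..., 0]


def _mate(rng: np.random.Generator, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    off = np.stack([_gamete(rng, pa), _gamete(rng, pb)], axis=-1)
    return np.sort(off, axis=-1)


def gen_pedigree_dyads(cfg: SynthConfig, relationship: str, n_dyads: int) -> DyadSet:
    """Dyads of a known relatedness class built by explicit gamete transmission."""
    if relationship not in PEDIGREE_R:
        raise ValueError(
            f"unknown relationship {relationship!r}; expected one of {sorted(PEDIGREE_R)}"
        )
    rng = _rng(cfg, "pedigree")
    p = _draw_locus_frequencies(cfg, rng)
    zero_f = np.zeros(n_dyads)

    def fresh() -> np.ndarray:
        return _sample_genotypes(rng, p, n_dyads, zero_f)

    if relationship == "unrelated":
        ga, gb = fresh(), fresh()
    elif relationship == "clone":
        ga = fresh()
        gb = ga.copy()
    elif relationship == "parent-offspring":
        ga = fresh()
        gb = _mate(rng, ga, fresh())
    elif relationship == "full-sib":
        p1, p2 = fresh(), fresh()
        ga = _mate(rng, p1, p2)
        gb = _mate(rng, p1, p2)
    else:  # half-sib
        shared = fresh()
        ga = _mate(rng, shared, fresh())
        gb = _mate(rng, shared, fresh())
    return DyadSet(
        genotypes_a=ga,
        genotypes_b=gb,
        relationship=relationship,
        expected_r=PEDIGREE_R[relationship],
        loci=tuple(_locus_names(cfg.n_loci)),
        freqs=_true_frequencies(cfg, p),
    )


def dyadset_table(dyads: DyadSet) -> tuple[GenotypeTable, list[tuple[str, str]]]:
    """Flatten a DyadSet into one GenotypeTable plus the dyad id pairs."""
    n = dyads.genotypes_a.shape[0]
    ids_a = [f"A{k:05d}" for k in range(n)]
    ids_b = [f"B{k:05d}" for k in range(n)]
    calls = np.concatenate([dyads.genotypes_a, dyads.genotypes_b], axis=0)
    table = GenotypeTable(ids_a + ids_b, dyads.loci, calls)
    return table, list(zip(ids_a, ids_b))


# ---------------------------------------------------------------------------
# Mating tables
# ---------------------------------------------------------------------------


def assign_sexes(table: GenotypeTable) -> dict[str, str]:
    """Deterministic alternating sexes: even index female, odd index male."""
    return {ind: ("F" if i % 2 == 0 else "M") for i, ind in enumerate(table.individuals)}


def gen_mating_table(
    cfg: SynthConfig,
    table: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
) -> pd.DataFrame:
    """Breeding pairs with a tunable female-male heterozygosity correlation.

    Pairing rank-matches each female's noisy het target against the males'
    het ranks, so the realised correlation approximates ``assortment_rho``
    (0 = random pairing, 1 = rank-identical).  Pairs are split over two year
    labels to exercise within-year resampling.
    """
    from .genotype_io import allele_frequencies

    rng = _rng(cfg, "mating")
    if freqs is None:
        freqs = allele_frequencies(table)
    het = het_map(table, freqs, min_loci=1)
    sexes = assign_sexes(table)
    females = [i for i in table.individuals if sexes[i] == "F" and i in het]
    males = [i for i in table.individuals if sexes[i] == "M" and i in het]
    n_pairs = min(len(females), len(males))
    if n_pairs < 2:
        raise ValueError("not enough individuals of each sex to form pairs")
    females, males = females[:n_pairs], males[:n_pairs]
    hf = np.array([het[i] for i in females])
    hm = np.array([het[i] for i in males])
    rho = cfg.assortment_rho
    zf = (hf - hf.mean()) / (hf.std() if hf.std() > 0 else 1.0)
    noise = rng.standard_normal(n_pairs)
    target = rho * zf + math.sqrt(max(0.0, 1.0 - rho * rho)) * noise
    # female with the k-th ranked target gets the male with the k-th ranked het
    f_order = np.argsort(target, kind="stable")
    m_order = np.argsort(hm, kind="stable")
    partner = np.empty(n_pairs, dtype=int)
    partner[f_order] = m_order
    years = ["2014" if k % 2 == 0 else "2015" for k in range(n_pairs)]
    return pd.DataFrame(
        {
            "female_id": females,
            "male_id": [males[j] for j in partner],
            "year": years,
        }
    )


# ---------------------------------------------------------------------------
# Preference trials
# ---------------------------------------------------------------------------


def gen_preference_trials(
    cfg: SynthConfig,
    table: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
) -> list[PreferenceTrial]:
    """Six-choice trials with a tunable preference for het similarity.

    Each focal bird runs the repeated-group design A, B, C, A (the number of
    focals is n_trials/4, rounded).  Slot durations are Dirichlet draws whose
    concentration loads on similarity via ``exp(-strength * |het_f - het_s|)``
    scaled to a random total time budget; with probability ``p_zero`` a trial
    is all-zero (focal never left the central platform).
    """
    from .genotype_io import allele_frequencies

    rng = _rng(cfg, "trials")
    if freqs is None:
        freqs = allele_frequencies(table)
    het = het_map(table, freqs, min_loci=1)
    sexes = assign_sexes(table)
    by_sex = {
        "F": [i for i in table.individuals if sexes[i] == "F" and i in het],
        "M": [i for i in table.individuals if sexes[i] == "M" and i in het],
    }
    if min(len(by_sex["F"]), len(by_sex["M"])) < 7:
        raise ValueError("need at least 7 genotyped individuals of each sex")
    n_focals = max(1, round(cfg.n_trials / 4))
    trials: list[PreferenceTrial] = []
    t = 0
    for k in range(n_focals):
        sex = "F" if k % 2 == 0 else "M"
        focal = by_sex[sex][k % len(by_sex[sex])]
        pool = [i for i in by_sex["M" if sex == "F" else "F"] if i != focal]
        groups = {}
        for gname in ("A", "B", "C"):
            groups[gname] = list(rng.choice(pool, size=N_STIM, replace=False))
        for gname in ("A", "B", "C", "A"):
            stims = groups[gname]
            t += 1
            if rng.random() < cfg.p_zero:
                durations = (0.0,) * N_STIM
            else:
                d_het = np.array([abs(het[focal] - het[s]) for s in stims])
                w = np.exp(-cfg.preference_strength * d_het)
                alpha = cfg.trial_concentration * N_STIM * w / w.sum()
                props = rng.dirichlet(alpha)
                total = rng.uniform(*cfg.total_time_range)
                durations = tuple(np.round(props * total, 1))
            trials.append(
                PreferenceTrial(
                    trial_id=f"T{t:04d}",
                    focal_id=focal,
                    focal_sex=sex,
                    group=gname,
                    stimulus_ids=tuple(stims),
                    durations=durations,
                )
            )
    return trials


# ---------------------------------------------------------------------------
# Breeding records with cross-fostering and extra-pair sires
# ---------------------------------------------------------------------------


def gen_breeding_records(
    cfg: SynthConfig,
    pairs: pd.DataFrame,
    table: GenotypeTable,
    mean_clutch: int = 7,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Broods with Mendelian offspring, extra-pair sires and cross-fostering.

    Each pair rears one brood; every chick is independently sired by a random
    other male with probability ``extra_pair_rate``.  Broods are grouped into
    same-hatch-day triplets and chicks rotated among the triplet so that no
    chick stays with its biological parents; incomplete cohorts (< 3 broods)
    are left unfostered with a warning.  Truth columns (genetic sire,
    extra-pair flag) are retained.
    """
    import logging

    logger = logging.getLogger(__name__)
    rng = _rng(cfg, "breeding")
    males = list(pairs["male_id"])
    n_broods = len(pairs)
    rows = []
    geno_rows = []
    ids = []
    for b, row in enumerate(pairs.itertuples(index=False)):
        clutch = int(rng.integers(mean_clutch - 2, mean_clutch + 3))
        mother = table.genotypes_of(row.female_id)
        social = table.genotypes_of(row.male_id)
        hatch_day = b // 3  # consecutive triplets share a hatch day
        for c in range(clutch):
            ep = bool(rng.random() < cfg.extra_pair_rate) and len(males) > 1
            if ep:
                others = [m for m in males if m != row.male_id]
                sire_id = others[int(rng.integers(0, len(others)))]
            else:
                sire_id = row.male_id
            sire = table.genotypes_of(sire_id)
            off = _mate(rng, mother[None, ...], sire[None, ...])[0]
            oid = f"chick{b + 1:03d}_{c + 1}"
            ids.append(oid)
            geno_rows.append(off)
            rows.append(
                {
                    "offspring_id": oid,
                    "brood_id": f"brood{b + 1:03d}",
                    "hatch_day": hatch_day,
                    "mother_id": row.female_id,
                    "social_father_id": row.male_id,
                    "genetic_father_id": sire_id,
                    "extra_pair": ep,
                }
            )
    records = pd.DataFrame(rows)
    # cross-foster: rotate broods within complete same-day triplets
    records["foster_brood_id"] = records["brood_id"]
    fostered = np.zeros(len(records), dtype=bool)
    brood_day = records.drop_duplicates("brood_id").set_index("brood_id")["hatch_day"]
    for day in brood_day.unique():
        cohort = list(brood_day.index[brood_day == day])
        if len(cohort) < 3:
            logger.warning("hatch-day cohort with %d brood(s) skipped for fostering", len(cohort))
            continue
        rotated = cohort[1:] + cohort[:1]
        for src, dst in zip(cohort, rotated):
            mask = (records["brood_id"] == src).to_numpy()
            records.loc[mask, "foster_brood_id"] = dst
            fostered |= mask
    records["fostered"] = fostered
    offspring_table = GenotypeTable(ids, table.loci, np.stack(geno_rows))
    return offspring_table, records
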