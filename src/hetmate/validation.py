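"""Replicated validation experiments over the synthetic study conditions.

Each function runs a self-contained simulation experiment -- generate data
with known ground truth, run the corresponding pipeline stage, measure the
recovery/calibration -- and returns plain numbers.  They are the shared
backbone of the test suite, the acceptance report and the analysis drivers,
so that all three quote the same computations.

All experiments are deterministic functions of their ``seed``; replicate
seeds are derived by offsetting it.
"""

from __future__ import annotations

import numpy as np

from .genotype_io import allele_frequencies
from .genetic_stats import (
    PEDIGREE_R,
    het_map,
    wang_relatedness,
)
from .offspring_sim import dyad_offspring_hl
from .mating_analysis import (
    assortment_permutation_test,
    paternity_exclusion_batch,
    relatedness_randomization_ci,
)
from .preference_analysis import (
    association_proportions,
    attach_heterozygosity,
    similarity_preference_test,
)
from .synthetic_data import (
    SynthConfig,
    dyadset_table,
    gen_breeding_records,
    gen_mating_table,
    gen_pedigree_dyads,
    gen_population,
    gen_preference_trials,
)


def pedigree_recovery(
    seed: int,
    n_dyads: int = 500,
    n_loci: int = 20,
    alleles_per_locus: int = 8,
) -> dict[str, float]:
    """Mean relatedness estimate per pedigree class (equifrequent alleles).

    Allele frequencies are estimated from the dyad sample itself, as a field
    study would.  Returns class -> mean estimate.
    """
    out: dict[str, float] = {}
    for k, rel in enumerate(sorted(PEDIGREE_R)):
        cfg = SynthConfig(
            seed=seed + k, n_loci=n_loci, alleles_per_locus=alleles_per_locus,
            frequency_concentration=None,
        )
        ds = gen_pedigree_dyads(cfg, rel, n_dyads)
        table, dyads = dyadset_table(ds)
        rmat = wang_relatedness(table, allele_frequencies(table), dyads)
        out[rel] = float(rmat.table["r"].mean())
    return out


def offspring_mc_agreement(
    seed: int,
    n_dyads: int = 200,
    n_loci: int = 5,
    n_offspring: int = 100,
    n_iterations: int = 200,
) -> float:
    """Fraction of dyads whose Monte-Carlo offspring HL falls within three
    Monte-Carlo standard errors of the exact expectation."""
    cfg = SynthConfig(seed=seed, n_individuals=2 * n_dyads, n_loci=n_loci)
    table, _ = gen_population(cfg)
    freqs = allele_frequencies(table)
    ids = table.individuals
    hits = 0
    used = 0
    for k in range(n_dyads):
        fa = table.genotypes_of(ids[2 * k])
        mo = table.genotypes_of(ids[2 * k + 1])
        prof = dyad_offspring_hl(
            fa, mo, freqs, table.loci,
            n_offspring=n_offspring, n_iterations=n_iterations, seed=seed + 7 + k,
        )
        if np.isnan(prof.offspring_hl_exact) or prof.mc_se == 0.0:
            continue
        used += 1
        hits += abs(prof.offspring_hl_mc - prof.offspring_hl_exact) <= 3 * prof.mc_se
    return hits / used if used else float("nan")


def assortment_rejection_rate(
    seed: int,
    n_datasets: int = 1000,
    n_pairs: int = 70,
    n_perm: int = 999,
    rho: float = 0.0,
    alpha: float = 0.05,
) -> float:
    """Share of synthetic datasets where the het-assortment permutation test
    rejects at ``alpha``; rho=0 measures type-I error, rho>0 power."""
    rej = 0
    for i in range(n_datasets):
        cfg = SynthConfig(seed=seed + i, n_individuals=2 * n_pairs, assortment_rho=rho)
        table, _ = gen_population(cfg)
        freqs = allele_frequencies(table)
        pairs = gen_mating_table(cfg, table, freqs)
        het = het_map(table, freqs)
        res = assortment_permutation_test(pairs, het, n_perm=n_perm, seed=cfg.seed)
        rej += res.p_value <= alpha
    return rej / n_datasets


def relatedness_ci_coverage(
    seed: int,
    n_reps: int = 500,
    n_pairs: int = 70,
    n_iter: int = 2000,
) -> float:
    """Share of random-mating replicates whose observed mean pair relatedness
    lies inside the 95% randomization interval."""
    inside = 0
    for i in range(n_reps):
        cfg = SynthConfig(seed=seed + i, n_individuals=2 * n_pairs)
        table, _ = gen_population(cfg)
        freqs = allele_frequencies(table)
        pairs = gen_mating_table(cfg, table, freqs)
        dyads = set()
        for y in pairs["year"].unique():
            sub = pairs[pairs["year"] == y]
            dyads |= {(f, m) for f in sub["female_id"] for m in sub["male_id"]}
        rmat = wang_relatedness(table, freqs, sorted(dyads))
        res = relatedness_randomization_ci(pairs, rmat, n_iter=n_iter, seed=cfg.seed)
        inside += res.observed_inside
    return inside / n_reps


def similarity_rejection_rate(
    seed: int,
    n_datasets: int = 1000,
    n_trials: int = 60,
    n_perm: int = 199,
    strength: float = 0.0,
    alpha: float = 0.05,
) -> float:
    """Share of synthetic trial sets where the similarity-preference test
    rejects at ``alpha``; strength=0 measures type-I error."""
    rej = 0
    for i in range(n_datasets):
        cfg = SynthConfig(
            seed=seed + i, n_individuals=140, n_trials=n_trials,
            preference_strength=strength,
        )
        table, _ = gen_population(cfg)
        freqs = allele_frequencies(table)
        trials = gen_preference_trials(cfg, table, freqs)
        obs, _ = association_proportions(trials)
        obs = attach_heterozygosity(obs, het_map(table, freqs, min_loci=1))
        res = similarity_preference_test(obs, n_perm=n_perm, seed=cfg.seed)
        rej += res.p_value <= alpha
    return rej / n_datasets


def paternity_recovery(
    seed: int,
    n_trios: int = 2000,
    extra_pair_rate: float = 0.10,
    threshold: int = 2,
) -> dict[str, float]:
    """Detection and false-exclusion rates of Mendelian paternity exclusion
    on broods with a known share of extra-pair sires (equifrequent alleles)."""
    detected = []
    false_flags = []
    total = 0
    block = 0
    while total < n_trios:
        cfg = SynthConfig(
            seed=seed + block, n_individuals=600,
            frequency_concentration=None, extra_pair_rate=extra_pair_rate,
        )
        table, _ = gen_population(cfg)
        pairs = gen_mating_table(cfg, table)
        offspring, records = gen_breeding_records(cfg, pairs, table)
        om = np.stack([offspring.genotypes_of(o) for o in records["offspring_id"]])
        mm = np.stack([table.genotypes_of(m) for m in records["mother_id"]])
        cm = np.stack([table.genotypes_of(s) for s in records["social_father_id"]])
        rep = paternity_exclusion_batch(om, mm, cm, threshold=threshold)
        ep = records["extra_pair"].to_numpy()
        detected.append(rep["excluded"].to_numpy()[ep])
        false_flags.append(rep["excluded"].to_numpy()[~ep])
        total += len(records)
        block += 1
    det = np.concatenate(detected)
    fal = np.concatenate(false_flags)
    return {
        "extra_pair_detection_rate": float(det.mean()) if det.size else float("nan"),
        "false_exclusion_rate": float(fal.mean()),
        "n_extra_pair": int(det.size),
        "n_within_pair": int(fal.size),
    }
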