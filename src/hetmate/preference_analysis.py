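"""Six-choice mate-preference trials: proportions, repeatability, similarity test.

A trial puts one focal bird on a central platform surrounded by six
opposite-sex stimulus birds for 45 minutes; the time spent in each choice
zone is the association duration.  The preference measure is the proportion
of a trial's total association time spent with each stimulus, which
separates directional preference from overall choosiness.  Trials in which
the focal bird never visited any stimulus (total duration zero) are
excluded and logged.

Repeatability of focal-stimulus association is the one-way intraclass
correlation computed from ANOVA mean squares with focal-stimulus
combination as the grouping factor:

    r = (MS_among - MS_within) / (MS_among + (n0 - 1) * MS_within),
    n0 = (N - sum(k_i^2)/N) / (g - 1)

The similarity-preference test asks whether association proportions track
heterozygosity similarity s = -|het_focal - het_stimulus|; its null
distribution permutes the six proportions within each trial, the design's
only exchangeability (trial totals are constrained to one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mating_analysis import ResamplingResult

logger = logging.getLogger(__name__)

N_STIMULI = 6

TRIALS_CSV_COLUMNS = (
    ["trial_id", "focal_id", "focal_sex", "group"]
    + [f"stim{k}" for k in range(1, 7)]
    + [f"dur{k}" for k in range(1, 7)]
)


@dataclass(frozen=True)
class PreferenceTrial:
    """One focal bird's association durations in a six-choice test."""

    trial_id: str
    focal_id: str
    focal_sex: str
    group: str
    stimulus_ids: tuple[str, ...]
    durations: tuple[float, ...]
    session: str | None = None

    def __post_init__(self) -> None:
        if len(self.stimulus_ids) != N_STIMULI or len(self.durations) != N_STIMULI:
            raise ValueError(f"a trial has exactly {N_STIMULI} stimulus slots")
        d = np.asarray(self.durations, dtype=float)
        if not np.all(np.isfinite(d)) or (d < 0).any():
            raise ValueError(
                f"trial {self.trial_id!r}: durations must be finite and non-negative"
            )

    @property
    def total_duration(self) -> float:
        return float(sum(self.durations))


def read_trials_csv(path: str | Path) -> list[PreferenceTrial]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRIALS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trial columns {missing}")
    trials = []
    for row in df.itertuples(index=False):
        trials.append(
            PreferenceTrial(
                trial_id=row.trial_id,
                focal_id=row.focal_id,
                focal_sex=row.focal_sex,
                group=row.group,
                stimulus_ids=tuple(getattr(row, f"stim{k}") for k in range(1, 7)),
                durations=tuple(float(getattr(row, f"dur{k}")) for k in range(1, 7)),
            )
        )
    return trials


def write_trials_csv(trials: Iterable[PreferenceTrial], path: str | Path) -> None:
    rows = []
    for t in trials:
        row = {"trial_id": t.trial_id, "focal_id": t.focal_id,
               "focal_sex": t.focal_sex, "group": t.group}
        row.update({f"stim{k + 1}": s for k, s in enumerate(t.stimulus_ids)})
        row.update({f"dur{k + 1}": d for k, d in enumerate(t.durations)})
        rows.append(row)
    pd.DataFrame(rows, columns=TRIALS_CSV_COLUMNS).to_csv(path, index=False)


def association_proportions(
    trials: Sequence[PreferenceTrial],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stimulus association proportions plus an exclusion log.

    Returns ``(observations, exclusions)``: observations has one row per
    (trial, stimulus) with the proportion of that trial's total association
    time; trials with zero total time are excluded and logged.
    """
    obs_rows = []
    excl_rows = []
    for t in trials:
        total = t.total_duration
        if total == 0.0:
            excl_rows.append({"trial_id": t.trial_id, "focal_id": t.focal_id,
                              "reason": "no stimulus visited"})
            continue
        for slot, (stim, dur) in enumerate(zip(t.stimulus_ids, t.durations), start=1):
            obs_rows.append(
                {
                    "trial_id": t.trial_id,
                    "focal_id": t.focal_id,
                    "focal_sex": t.focal_sex,
                    "group": t.group,
                    "slot": slot,
                    "stimulus_id": stim,
                    "duration": dur,
                    "total_duration": total,
                    "proportion": dur / total,
                }
            )
    obs = pd.DataFrame(
        obs_rows,
        columns=["trial_id", "focal_id", "focal_sex", "group", "slot",
                 "stimulus_id", "duration", "total_duration", "proportion"],
    )
    excl = pd.DataFrame(excl_rows, columns=["trial_id", "focal_id", "reason"])
    if len(excl):
        logger.info("excluded %d trial(s) with zero total association time", len(excl))
    return obs, excl


def attach_heterozygosity(
    obs: pd.DataFrame, het: Mapping[str, float]
) -> pd.DataFrame:
    """Join per-individual het values onto observations as covariates."""
    out = obs.copy()
    out["het_focal"] = out["focal_id"].map(het)
    out["het_stimulus"] = out["stimulus_id"].map(het)
    return out


# ---------------------------------------------------------------------------
# Repeatability (one-way ANOVA ICC)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatabilityResult:
    r: float
    ms_among: float
    ms_within: float
    n0: float
    groups: int
    n_total: int
    negative: bool
    se_boot: float | None = None


def repeatability_anova(values: Mapping[object, Sequence[float]]) -> RepeatabilityResult:
    """Intraclass correlation from one-way ANOVA mean squares.

    ``values`` maps each group (e.g. a focal-stimulus combination) to its
    repeated measurements.  Unbalanced designs use the effective group size
    ``n0 = (N - sum(k_i^2)/N) / (g - 1)``.  A negative estimate (MS_among
    below MS_within) is reported as-is with ``negative=True``.
    """
    groups = [np.asarray(v, dtype=float) for v in values.values() if len(v) > 0]
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([len(v) for v in groups], dtype=float)
    N = float(sizes.sum())
    if N == g:
        raise ValueError("all groups are singleton; within-group MS undefined")
    grand = float(np.concatenate(groups).mean())
    means = np.array([v.mean() for v in groups])
    ss_among = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(sum(((v - m) ** 2).sum() for v, m in zip(groups, means)))
    ms_among = ss_among / (g - 1)
    ms_within = ss_within / (N - g)
    n0 = (N - float((sizes**2).sum()) / N) / (g - 1)
    r = (ms_among - ms_within) / (ms_among + (n0 - 1.0) * ms_within)
    return RepeatabilityResult(
        r=float(r),
        ms_among=ms_among,
        ms_within=ms_within,
        n0=float(n0),
        groups=g,
        n_total=int(N),
        negative=bool(ms_among < ms_within),
    )


def repeatability_bootstrap_se(
    values: Mapping[object, Sequence[float]],
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap SE of the ICC, resampling groups with replacement.

    The printed '+/-' of the field estimate has no stated formula; this SE is
    labelled as a group-level bootstrap and is not a parametric match.
    """
    keys = list(values.keys())
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        pick = rng.integers(0, len(keys), size=len(keys))
        sample = {k: values[keys[j]] for k, j in enumerate(pick)}
        try:
            reps.append(repeatability_anova(sample).r)
        except ValueError:
            continue  # degenerate resample (all singleton groups)
    if len(reps) < 2:
        raise ValueError("bootstrap produced too few defined replicates")
    return float(np.std(reps, ddof=1))


# ---------------------------------------------------------------------------
# Similarity-preference permutation test
# ---------------------------------------------------------------------------


def similarity_preference_test(
    obs: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> ResamplingResult:
    """Do focal birds spend more time with stimuli of similar heterozygosity?

    The statistic is the Pearson correlation, across all (trial, stimulus)
    observations, between the association proportion and the similarity
    score ``s = -|het_focal - het_stimulus|`` (invariant to shifting all het
    values).  The null permutes the six proportions within each trial.
    """
    required = {"trial_id", "proportion", "het_focal", "het_stimulus"}
    if not required.issubset(obs.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    trials = obs["trial_id"].unique()
    if len(trials) < 10:
        raise ValueError(f"need >= 10 trials after exclusions, got {len(trials)}")
    # build (T, 6) matrices in a stable trial order
    P = []
    S = []
    for tid, sub in obs.groupby("trial_id", sort=False):
        P.append(sub["proportion"].to_numpy())
        S.append(-np.abs(sub["het_focal"].to_numpy() - sub["het_stimulus"].to_numpy()))
    if len({len(p) for p in P}) != 1:
        raise ValueError("every trial must contribute the same number of observations")
    P = np.asarray(P, dtype=float)
    S = np.asarray(S, dtype=float)
    s_flat = S.ravel()
    if s_flat.std() == 0.0:
        raise ValueError("zero variance in the similarity score")
    p_flat = P.ravel()
    n = p_flat.size
    zs = (s_flat - s_flat.mean()) / s_flat.std()
    zp = (p_flat - p_flat.mean()) / p_flat.std()
    observed = float(np.mean(zs * zp))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    # within-trial permutation keeps the proportion multiset per trial, hence
    # the flattened mean/std of P are constant across permutations
    p_mean, p_std = p_flat.mean(), p_flat.std()
    chunk = max(1, min(n_perm, int(2e7 / max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(P, (m,) + P.shape).copy(), axis=2)
        flat = perm.reshape(m, n)
        null[done : done + m] = ((flat - p_mean) / p_std @ zs) / n
        done += m
    p = float((1 + np.sum(np.abs(null) >= np.abs(observed) - 1e-12)) / (n_perm + 1))
    return ResamplingResult(
        observed=observed,
        null_n=n_perm,
        null_q025=float(np.quantile(null, 0.025)),
        null_q975=float(np.quantile(null, 0.975)),
        p_value=p,
        seed=seed,
        method="within-trial-permutation",
    )
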