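"""Individual-based stochastic simulation of the cage invasion protocol.

One replicate emulates the experimental cycle: adults mate (each female fails
to mate with a fixed probability, otherwise mates once with a male drawn from
the fitness-weighted male pool), mated females lay clutches sampled with
replacement from an empirical clutch-size table scaled by their genotype's
fecundity multiplier, eggs hatch with the hatch probability of the maternal
genotype, a fixed number of larvae (the cage carrying capacity, 600 in the
experiment) is drawn at random without replacement to seed the next
generation, and each larva survives to adulthood independently. Every random
event is drawn from the appropriate binomial / multinomial / multivariate
hypergeometric distribution over *classes* of individuals, so the cost per
generation depends on the number of distinct genotype classes rather than the
census size — replicates at N = 20,000 for law-of-large-numbers checks cost
the same as N = 600.

Replicate seeds derive from the master seed through ``numpy``'s
``SeedSequence`` spawning, so ensembles are reproducible and replicate-order
independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    AlleleClass,
    Exposure,
    IndividualState,
    ModelParams,
    embryo_transform,
    gamete_distribution_with_carriage,
)
from .trajectory import PopulationTrajectory

__all__ = ["simulate_cage", "summarize_ensemble"]


class _OffspringCache:
    """Cache of offspring-class distributions per (mother, father) class."""

    def __init__(self, params: ModelParams):
        self.params = params
        self._gametes: dict[tuple[IndividualState, str], list] = {}
        self._pairs: dict[tuple, tuple[list, np.ndarray]] = {}

    def _gamete_joint(self, ind: IndividualState, sex: str) -> list:
        key = (ind, sex)
        if key not in self._gametes:
            joint = gamete_distribution_with_carriage(ind, sex, self.params)
            self._gametes[key] = [(a, k, p) for (a, k), p in joint.items() if p > 0]
        return self._gametes[key]

    def offspring(self, mother: IndividualState, father: IndividualState
                  ) -> tuple[list[IndividualState], np.ndarray]:
        key = (mother, father)
        if key not in self._pairs:
            dist: dict[IndividualState, float] = {}
            for ma, mk, pf in self._gamete_joint(mother, "female"):
                for pa, pk, pm in self._gamete_joint(father, "male"):
                    for child, p in embryo_transform(
                            (ma, pa), mk, pk, self.params).items():
                        dist[child] = dist.get(child, 0.0) + pf * pm * p
            classes = list(dist)
            probs = np.array([dist[c] for c in classes])
            self._pairs[key] = (classes, probs / probs.sum())
        return self._pairs[key]


def _summaries(classes: list[IndividualState], counts: np.ndarray) -> dict:
    total = counts.sum()
    if total == 0:
        return {"carrier_freq": math.nan, "drive_allele_freq": math.nan,
                "W_freq": math.nan, "R1_freq": math.nan, "R2_freq": math.nan}
    alleles = {a: 0.0 for a in AlleleClass}
    carriers = 0
    for ind, n in zip(classes, counts):
        alleles[ind.maternal_allele] += 0.5 * n
        alleles[ind.paternal_allele] += 0.5 * n
        if ind.carries_drive:
            carriers += n
    return {
        "carrier_freq": carriers / total,
        "drive_allele_freq": alleles[AlleleClass.D] / total,
        "W_freq": alleles[AlleleClass.W] / total,
        "R1_freq": alleles[AlleleClass.R1] / total,
        "R2_freq": alleles[AlleleClass.R2] / total,
    }


def _simulate_one(params: ModelParams, release_freq: float, generations: int,
                  rng: np.random.Generator, capacity: int,
                  release_exposure: Exposure) -> PopulationTrajectory:
    cage = params.cage
    cache = _OffspringCache(params)
    clutch = np.asarray(cage.clutch_sizes, dtype=float)
    mean_clutch = clutch.mean()
    # expected egg output of an all-wild-type cage, for the egg-output index
    egg_norm = (capacity / 2.0) * (1.0 - cage.mating_failure_prob) * mean_clutch

    if release_exposure is Exposure.MATERNAL:
        het = IndividualState(AlleleClass.D, AlleleClass.W, Exposure.MATERNAL)
    else:
        het = IndividualState(AlleleClass.W, AlleleClass.D, Exposure.PATERNAL)
    wt = IndividualState(AlleleClass.W, AlleleClass.W, Exposure.NONE)
    n_het = int(round(release_freq * capacity))
    classes = [het, wt]
    counts = np.array([n_het, capacity - n_het])

    # sex split of the founding adults
    females = rng.binomial(counts, 0.5)
    males = counts - females

    traj = PopulationTrajectory()
    traj.append({"generation": 0, **_summaries(classes, counts),
                 "egg_index": math.nan, "eggs_total": math.nan,
                 "larvae_seeded": int(counts.sum()),
                 "adults": int(counts.sum()), "extinct": False})

    for gen in range(1, generations + 1):
        male_fit = np.array([params.fitness.male_fitness(c.genotype, c.exposure)
                             for c in classes], dtype=float)
        male_weights = males * male_fit
        if females.sum() == 0 or male_weights.sum() <= 0:
            traj.extinct = True
            break
        male_probs = male_weights / male_weights.sum()

        # hatched offspring pooled over all matings
        pooled: dict[IndividualState, int] = {}
        eggs_total = 0
        for i, ind in enumerate(classes):
            if females[i] == 0:
                continue
            mated = rng.binomial(females[i], 1.0 - cage.mating_failure_prob)
            if mated == 0:
                continue
            fec = params.fitness.female_fecundity(ind.genotype, ind.exposure)
            hatch = cage.hatch_for(ind.genotype)
            partners = rng.multinomial(mated, male_probs)
            for j in np.nonzero(partners)[0]:
                k = int(partners[j])
                laid = rng.choice(clutch, size=k)
                eggs = int(np.round(laid * fec).sum())
                eggs_total += eggs
                if eggs == 0:
                    continue
                hatched = rng.binomial(eggs, hatch)
                if hatched == 0:
                    continue
                kids, probs = cache.offspring(ind, classes[j])
                for child, n in zip(kids, rng.multinomial(hatched, probs)):
                    if n:
                        pooled[child] = pooled.get(child, 0) + int(n)

        hatched_total = sum(pooled.values())
        if hatched_total == 0:
            traj.append({"generation": gen, **_summaries([], np.array([])),
                         "egg_index": eggs_total / egg_norm,
                         "eggs_total": eggs_total, "larvae_seeded": 0,
                         "adults": 0, "extinct": True})
            traj.extinct = True
            break

        kid_classes = list(pooled)
        kid_counts = np.array([pooled[c] for c in kid_classes])
        # 600-larva draw without replacement (all, if fewer hatched)
        if hatched_total > capacity:
            seeded = rng.multivariate_hypergeometric(kid_counts, capacity)
        else:
            seeded = kid_counts
        assert seeded.sum() <= hatched_total <= eggs_total

        summaries = _summaries(kid_classes, seeded)
        survivors = rng.binomial(seeded, cage.larva_survival_prob)
        females = rng.binomial(survivors, 0.5)
        males = survivors - females
        keep = survivors > 0
        classes = [c for c, k in zip(kid_classes, keep) if k]
        females, males = females[keep], males[keep]

        traj.append({"generation": gen, **summaries,
                     "egg_index": eggs_total / egg_norm,
                     "eggs_total": eggs_total,
                     "larvae_seeded": int(seeded.sum()),
                     "adults": int(survivors.sum()), "extinct": False})
        if survivors.sum() == 0:
            traj.extinct = True
            break
    return traj


def simulate_cage(params: ModelParams, release_freq: float, generations: int,
                  replicates: int, seed: int,
                  capacity: int | None = None,
                  release_exposure: Exposure = Exposure.MATERNAL
                  ) -> list[PopulationTrajectory]:
    """Simulate replicate cage invasions.

    ``capacity`` overrides the carrying capacity in ``params.cage`` (used for
    large-N convergence checks). Identical arguments and seed give bit-
    identical trajectories.
    """
    if seed is None:
        raise ValueError("a master seed is required")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if not (0.0 < release_freq < 1.0):
        raise ValueError("release_freq must be in (0, 1)")
    cap = capacity if capacity is not None else params.cage.capacity
    streams = np.random.SeedSequence(seed).spawn(replicates)
    return [
        _simulate_one(params, release_freq, generations,
                      np.random.Generator(np.random.PCG64(s)), cap,
                      release_exposure)
        for s in streams
    ]


def summarize_ensemble(trajectories: list[PopulationTrajectory],
                       quantiles: tuple[float, float] = (0.025, 0.975)
                       ) -> pd.DataFrame:
    """Per-generation mean, quantile band and extinction fraction.

    Trajectories truncated by extinction contribute missing values beyond
    their last recorded generation (explicit NaN padding).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    frames = [t.to_frame().set_index("generation") for t in trajectories]
    horizon = max(f.index.max() for f in frames)
    index = pd.RangeIndex(0, horizon + 1, name="generation")
    value_cols = ["carrier_freq", "drive_allele_freq", "W_freq", "R1_freq",
                  "R2_freq", "egg_index"]
    stacked = np.stack([f.reindex(index)[value_cols].to_numpy()
                        for f in frames])  # (rep, gen, col)
    out = pd.DataFrame(index=index)
    lo, hi = quantiles
    import warnings as _warnings
    for k, col in enumerate(value_cols):
        vals = stacked[:, :, k]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            out[f"{col}_mean"] = np.nanmean(vals, axis=0)
            out[f"{col}_lo"] = np.nanquantile(vals, lo, axis=0)
            out[f"{col}_hi"] = np.nanquantile(vals, hi, axis=0)
    alive = np.stack([(~f.reindex(index)["extinct"].isna() &
                       ~f.reindex(index)["extinct"].astype("boolean").fillna(True))
                      .to_numpy() for f in frames])
    out["extinct_fraction"] = 1.0 - alive.mean(axis=0)
    out["n_replicates"] = len(frames)
    return out.reset_index()
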