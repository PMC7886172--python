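"""Deterministic discrete-generation recursion of drive/resistance dynamics.

The state is an infinite-population frequency distribution over individual
classes (zygotic genotype x deposition exposure x germline mosaic mixture),
identical in the two sexes under a fair sex ratio. One generation is:

1. weight each female class by its fecundity multiplier and each male class by
   its fitness multiplier (mate-choice weighting);
2. form the two gamete pools, jointly with the flag "gamete's source germline
   cell carried a drive allele" (which determines deposition into the zygote);
3. unite gametes at random and pass every zygote through the embryonic
   deposition transform;
4. renormalise.

With all rates zero and fitness flat the drive is a neutral Mendelian marker;
with end-joining and deposition off and fitness flat the drive allele
frequency follows the classic cost-free homing recursion
``q' = q + h*q*(1-q)`` with ``h = c*hdr``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

from .model_core import (
    AlleleClass,
    Exposure,
    IndividualState,
    ModelParams,
    embryo_transform,
    gamete_distribution_with_carriage,
    genotype_key,
    parse_genotype,
)
from .trajectory import PopulationTrajectory

__all__ = ["PopulationState", "step", "run", "egg_output_index", "sweep",
           "perturb"]

_PRUNE = 1e-15  # drop classes below this frequency to keep the state small


@dataclass
class PopulationState:
    """Frequency distribution over individual classes at one generation.

    The same distribution applies to both sexes (fair sex ratio, sex-
    independent inheritance); sex-specific fitness enters at reproduction.
    """

    generation: int
    freqs: dict[IndividualState, float]
    extinct: bool = False

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")

    # -- derived summaries -------------------------------------------------

    def carrier_freq(self) -> float:
        return sum(f for ind, f in self.freqs.items() if ind.carries_drive)

    def allele_freqs(self) -> dict[AlleleClass, float]:
        out = {a: 0.0 for a in AlleleClass}
        for ind, f in self.freqs.items():
            out[ind.maternal_allele] += 0.5 * f
            out[ind.paternal_allele] += 0.5 * f
        return out

    def drive_allele_freq(self) -> float:
        return self.allele_freqs()[AlleleClass.D]

    def nondrive_composition(self) -> dict[AlleleClass, float]:
        """W/R1/R2 frequencies among non-drive alleles (empty if drive fixed)."""
        freqs = self.allele_freqs()
        total = sum(v for a, v in freqs.items() if a is not AlleleClass.D)
        if total <= 0.0:
            return {}
        return {a: freqs[a] / total for a in
                (AlleleClass.W, AlleleClass.R1, AlleleClass.R2)}


def egg_output_index(state: PopulationState, params: ModelParams,
                     normalization: float = 1.0) -> float:
    """Fecundity-weighted mean egg production of the female pool.

    Fecundity multipliers are relative to wild type, so with the default
    ``normalization=1`` an all-wild-type population scores exactly 1 and a
    population of sterile females scores 0.
    """
    if normalization <= 0:
        raise ValueError("normalization must be positive")
    raw = sum(f * params.fitness.female_fecundity(ind.genotype, ind.exposure)
              for ind, f in state.freqs.items())
    return raw / normalization


def _reproductive_weights(state: PopulationState, params: ModelParams):
    female = {}
    male = {}
    for ind, f in state.freqs.items():
        wf = f * params.fitness.female_fecundity(ind.genotype, ind.exposure)
        wm = f * params.fitness.male_fitness(ind.genotype, ind.exposure)
        if wf > 0.0:
            female[ind] = wf
        if wm > 0.0:
            male[ind] = wm
    return female, male


def step(state: PopulationState, params: ModelParams) -> PopulationState:
    """Advance the recursion one generation.

    A total reproductive output of zero in either sex flags extinction and
    freezes the frequencies rather than dividing by zero.
    """
    if state.extinct:
        return replace(state, generation=state.generation + 1)
    female_w, male_w = _reproductive_weights(state, params)
    tot_f = sum(female_w.values())
    tot_m = sum(male_w.values())
    if tot_f <= 0.0 or tot_m <= 0.0:
        return PopulationState(state.generation + 1, dict(state.freqs),
                               extinct=True)

    def gamete_pool(weights: dict, sex: str) -> dict:
        pool: dict[tuple[AlleleClass, bool], float] = {}
        total = sum(weights.values())
        for ind, w in weights.items():
            joint = gamete_distribution_with_carriage(ind, sex, params)
            for key, p in joint.items():
                pool[key] = pool.get(key, 0.0) + (w / total) * p
        return pool

    eggs = gamete_pool(female_w, "female")
    sperm = gamete_pool(male_w, "male")

    offspring: dict[IndividualState, float] = {}
    for ((ma, mk), pf), ((pa, pk), pm) in itertools.product(
            eggs.items(), sperm.items()):
        weight = pf * pm
        if weight < _PRUNE:
            continue
        for child, p in embryo_transform((ma, pa), mk, pk, params).items():
            offspring[child] = offspring.get(child, 0.0) + weight * p

    total = sum(offspring.values())
    freqs = {ind: f / total for ind, f in offspring.items() if f / total > _PRUNE}
    norm = sum(freqs.values())
    freqs = {ind: f / norm for ind, f in freqs.items()}
    return PopulationState(state.generation + 1, freqs)


def initial_state(release_freq: float,
                  release_exposure: Exposure = Exposure.MATERNAL
                  ) -> PopulationState:
    """Release of drive heterozygotes into a wild-type population.

    Released carriers inherited the drive from a female parent by default, so
    their maternal allele is D and their exposure tag is maternal.
    """
    if not (0.0 < release_freq < 1.0):
        raise ValueError("release_freq must be in (0, 1)")
    if release_exposure is Exposure.MATERNAL:
        het = IndividualState(AlleleClass.D, AlleleClass.W, Exposure.MATERNAL)
    elif release_exposure is Exposure.PATERNAL:
        het = IndividualState(AlleleClass.W, AlleleClass.D, Exposure.PATERNAL)
    else:
        het = IndividualState(AlleleClass.D, AlleleClass.W, Exposure.NONE)
    wt = IndividualState(AlleleClass.W, AlleleClass.W, Exposure.NONE)
    return PopulationState(0, {het: release_freq, wt: 1.0 - release_freq})


def _record(state: PopulationState, params: ModelParams,
            normalization: float) -> dict:
    alleles = state.allele_freqs()
    return {
        "generation": state.generation,
        "carrier_freq": state.carrier_freq(),
        "drive_allele_freq": alleles[AlleleClass.D],
        "W_freq": alleles[AlleleClass.W],
        "R1_freq": alleles[AlleleClass.R1],
        "R2_freq": alleles[AlleleClass.R2],
        "egg_index": egg_output_index(state, params, normalization),
        "extinct": state.extinct,
    }


def run(params: ModelParams, release_freq: float, generations: int,
        release_exposure: Exposure = Exposure.MATERNAL,
        egg_normalization: float = 1.0) -> PopulationTrajectory:
    """Run the recursion for ``generations`` steps after a release at g=0.

    Returns a trajectory of length ``generations + 1`` including the release
    generation. Extinction freezes the remaining generations and sets the
    trajectory flag.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    state = initial_state(release_freq, release_exposure)
    traj = PopulationTrajectory()
    traj.append(_record(state, params, egg_normalization))
    for _ in range(generations):
        state = step(state, params)
        traj.append(_record(state, params, egg_normalization))
    traj.extinct = state.extinct
    return traj


# ---------------------------------------------------------------------------
# Parameter sweeps


def perturb(params: ModelParams, path: str, rel_change: float) -> ModelParams:
    """Return params with the field at ``path`` scaled by ``1 + rel_change``.

    Paths address numeric fields with dots, e.g. ``germline_male.hdr_frac`` or
    ``deposition.cut_maternal``. ``fitness.female_fecundity.W/D`` scales every
    override whose genotype part is W/D (exposure variants included), so
    maternal/paternal parental-effect entries are varied together and keep
    their ratio constant. Perturbed probabilities are clipped to [0, 1] with a
    warning.
    """
    parts = path.split(".")

    def clipped(value: float) -> float:
        new = value * (1.0 + rel_change)
        if new < 0.0 or new > 1.0:
            warnings.warn(f"perturbed value {new:.4g} for {path} clipped to [0, 1]")
            new = min(1.0, max(0.0, new))
        return new

    if parts[0] == "fitness":
        if len(parts) != 3 or parts[1] not in ("female_fecundity", "male_fitness"):
            raise KeyError(f"unknown parameter path {path!r}")
        attr = "female_overrides" if parts[1] == "female_fecundity" else "male_overrides"
        table = dict(getattr(params.fitness, attr))
        hits = [k for k in table if k.split("|")[0] == parts[2]]
        if not hits:
            # no explicit override: seed one from the default rule
            pair = parse_genotype(parts[2])
            if parts[1] == "female_fecundity":
                base = params.fitness.female_fecundity(pair)
            else:
                base = params.fitness.male_fitness(pair)
            table[parts[2]] = base
            hits = [parts[2]]
        for k in hits:
            table[k] = clipped(table[k])
        return replace(params, fitness=replace(params.fitness, **{attr: table}))

    if len(parts) != 2:
        raise KeyError(f"unknown parameter path {path!r}")
    group, name = parts
    if group not in ("germline_female", "germline_male", "deposition", "cage"):
        raise KeyError(f"unknown parameter path {path!r}")
    obj = getattr(params, group)
    if not hasattr(obj, name) or not isinstance(getattr(obj, name), (int, float)):
        raise KeyError(f"unknown parameter path {path!r}")
    return replace(params, **{group: replace(obj, **{name: clipped(getattr(obj, name))})})


def sweep(params: ModelParams, path: str, rel_changes: list[float],
          release_freq: float, generations: int) -> list[PopulationTrajectory]:
    """One deterministic trajectory per relative perturbation of one field."""
    return [run(perturb(params, path, delta), release_freq, generations)
            for delta in rel_changes]
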