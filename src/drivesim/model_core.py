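"""Core domain types and the two elementary transmission transforms.

The model tracks four allele classes at a haplosufficient female-fertility
locus targeted by a homing CRISPR drive:

* ``W``  — wild type: cleavable by the nuclease, functional gene copy.
* ``D``  — the drive cassette: cleavage-resistant (it replaces its own target
  site) and disrupts the target gene.
* ``R1`` — end-joining product that restores a cleavage-resistant *functional*
  target gene.
* ``R2`` — end-joining product that is cleavage-resistant but *non-functional*.

Two transforms generate all the dynamics:

1. :func:`gamete_distribution` — germline nuclease activity in a drive
   heterozygote cuts the W homologue with probability ``c``; cuts resolve by
   homology-directed repair (fraction ``hdr_frac``, producing another D copy:
   "homing") or by end-joining (producing R1 with fraction ``r1_frac``, else
   R2). Any germline cell pair without both a D and a W allele segregates
   Mendelianly.
2. :func:`embryo_transform` — nuclease deposited into the egg by a drive-
   carrying mother (rate ``cut_maternal``) or father (``cut_paternal``) cuts
   each zygotic W allele; embryonic cuts resolve by HDR from the homologous
   chromosome or by end-joining. The modified allele pair enters a fraction
   ``germline_mosaic_frac`` of the germline stem cells, the untouched zygotic
   pair the remainder — this mosaicism is what couples parental deposition to
   reduced homing and somatic fitness costs one generation later.
"""

from __future__ import annotations

import enum
import importlib.resources
import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "AlleleClass",
    "Exposure",
    "GermlineParams",
    "DepositionParams",
    "FitnessTable",
    "CageParams",
    "ModelParams",
    "IndividualState",
    "genotype_key",
    "gamete_distribution",
    "gamete_distribution_with_carriage",
    "embryo_transform",
    "load_params",
    "available_strains",
]


class AlleleClass(enum.Enum):
    """The four allele classes at the drive target locus."""

    W = "W"
    D = "D"
    R1 = "R1"
    R2 = "R2"

    def __repr__(self) -> str:  # compact in dict dumps
        return self.value

    @property
    def cleavable(self) -> bool:
        return self is AlleleClass.W

    @property
    def functional(self) -> bool:
        """Does the allele encode a working copy of the fertility gene?"""
        return self in (AlleleClass.W, AlleleClass.R1)


_ALLELE_ORDER = {a: i for i, a in enumerate(AlleleClass)}


class Exposure(enum.Enum):
    """Which parents carried a drive allele (hence possible deposition)."""

    NONE = "none"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BOTH = "both"

    @staticmethod
    def from_flags(mother_carries: bool, father_carries: bool) -> "Exposure":
        if mother_carries and father_carries:
            return Exposure.BOTH
        if mother_carries:
            return Exposure.MATERNAL
        if father_carries:
            return Exposure.PATERNAL
        return Exposure.NONE


Pair = tuple[AlleleClass, AlleleClass]


def genotype_key(a: AlleleClass, b: AlleleClass) -> Pair:
    """Unordered genotype as a canonically ordered pair (W < D < R1 < R2)."""
    return (a, b) if _ALLELE_ORDER[a] <= _ALLELE_ORDER[b] else (b, a)


def genotype_str(pair: Pair) -> str:
    return f"{pair[0].value}/{pair[1].value}"


def parse_genotype(text: str) -> Pair:
    parts = text.split("/")
    if len(parts) != 2:
        raise ValueError(f"malformed genotype {text!r}")
    return genotype_key(AlleleClass(parts[0]), AlleleClass(parts[1]))


def _check_prob(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class GermlineParams:
    """Germline cleavage/repair rates for one sex.

    ``cut_prob`` (c): probability that the W allele in a D/W germline cell is
    cleaved during gametogenesis. ``hdr_frac``: fraction of cleaved alleles
    repaired by HDR (becoming D). ``r1_frac``: fraction of end-joined alleles
    that remain functional (R1). The implied drive transmission is
    ``p = (1 + c*hdr_frac) / 2``.
    """

    cut_prob: float
    hdr_frac: float
    r1_frac: float

    def __post_init__(self) -> None:
        _check_prob(self.cut_prob, "cut_prob")
        _check_prob(self.hdr_frac, "hdr_frac")
        _check_prob(self.r1_frac, "r1_frac")

    @property
    def homing_rate(self) -> float:
        """Fraction of non-drive chromosomes converted to drive (c * hdr)."""
        return self.cut_prob * self.hdr_frac

    @property
    def transmission(self) -> float:
        return (1.0 + self.homing_rate) / 2.0


@dataclass(frozen=True)
class DepositionParams:
    """Embryonic (deposited-nuclease) cleavage/repair rates.

    ``cut_maternal`` / ``cut_paternal``: probability that a zygotic W allele is
    cleaved by nuclease deposited by a drive-carrying mother / father. Cuts
    resolve by HDR from the homologous chromosome with ``hdr_frac``, otherwise
    by end-joining (R1 with ``r1_frac``, else R2). ``germline_mosaic_frac``
    (m): fraction of germline stem cells that carry the embryo-modified pair.
    """

    cut_maternal: float = 0.0
    cut_paternal: float = 0.0
    hdr_frac: float = 0.0
    r1_frac: float = 1.0 / 3.0
    germline_mosaic_frac: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cut_maternal", "cut_paternal", "hdr_frac", "r1_frac",
                     "germline_mosaic_frac"):
            _check_prob(getattr(self, name), name)


def _default_female_fecundity(pair: Pair) -> float:
    # haplosufficient fertility locus: any functional copy -> fertile
    return 1.0 if any(a.functional for a in pair) else 0.0


@dataclass(frozen=True)
class FitnessTable:
    """Fitness multipliers keyed by (unordered genotype, exposure).

    Lookup order: exposure-specific override, genotype override, default rule.
    The default female rule encodes haplosufficiency at the target locus:
    multiplier 1 with at least one functional allele (W or R1), 0 otherwise
    (D/D, D/R2, R2/R2 females are sterile). Males default to 1. Overrides use
    string keys ``"W/D"`` or ``"W/D|maternal"``.
    """

    female_overrides: Mapping[str, float] = field(default_factory=dict)
    male_overrides: Mapping[str, float] = field(default_factory=dict)
    #: enforce sterility of females lacking a functional allele. Disable only
    #: for abstract limits (e.g. treating the drive as a neutral marker).
    strict: bool = True

    def __post_init__(self) -> None:
        for table in (self.female_overrides, self.male_overrides):
            for key, value in table.items():
                _check_prob(value, f"fitness[{key}]")
                geno = key.split("|")[0]
                parse_genotype(geno)
        if self.strict:
            for pair_text, value in self.female_overrides.items():
                pair = parse_genotype(pair_text.split("|")[0])
                if not any(a.functional for a in pair) and value > 0:
                    raise ValueError(
                        f"females with no functional allele must be sterile: {pair_text}"
                    )

    @classmethod
    def flat(cls) -> "FitnessTable":
        """All multipliers 1 (target-gene disruption ignored); for neutral
        and cost-free model limits."""
        ones = {genotype_str(genotype_key(a, b)): 1.0
                for a in AlleleClass for b in AlleleClass}
        return cls(female_overrides=ones, male_overrides=ones, strict=False)

    def _lookup(self, table: Mapping[str, float], pair: Pair,
                exposure: Exposure, default: float) -> float:
        canonical = genotype_str(pair)
        specific = f"{canonical}|{exposure.value}"
        if specific in table:
            return table[specific]
        if canonical in table:
            return table[canonical]
        return default

    def female_fecundity(self, pair: Pair, exposure: Exposure = Exposure.NONE) -> float:
        return self._lookup(self.female_overrides, genotype_key(*pair), exposure,
                            _default_female_fecundity(genotype_key(*pair)))

    def male_fitness(self, pair: Pair, exposure: Exposure = Exposure.NONE) -> float:
        return self._lookup(self.male_overrides, genotype_key(*pair), exposure, 1.0)


@dataclass(frozen=True)
class CageParams:
    """Cage-protocol parameters for the individual-based simulation."""

    capacity: int = 600
    mating_failure_prob: float = 0.1
    larva_survival_prob: float = 0.9
    hatch_prob: float = 0.9
    clutch_sizes: tuple[int, ...] = ()
    #: per-maternal-genotype hatch overrides, e.g. {"W/D": 0.5}; genotypes
    #: not listed use ``hatch_prob``
    hatch_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        _check_prob(self.mating_failure_prob, "mating_failure_prob")
        _check_prob(self.larva_survival_prob, "larva_survival_prob")
        _check_prob(self.hatch_prob, "hatch_prob")
        for key, value in self.hatch_overrides.items():
            parse_genotype(key)
            _check_prob(value, f"hatch_overrides[{key}]")
        if not self.clutch_sizes:
            raise ValueError("clutch-size table must be non-empty")
        if any((not float(c).is_integer()) or c < 0 for c in self.clutch_sizes):
            raise ValueError("clutch sizes must be non-negative integers")

    def hatch_for(self, pair: Pair) -> float:
        return self.hatch_overrides.get(genotype_str(genotype_key(*pair)),
                                        self.hatch_prob)


@dataclass(frozen=True)
class ModelParams:
    """All rates of the dynamic model for one strain."""

    germline_female: GermlineParams
    germline_male: GermlineParams
    deposition: DepositionParams
    fitness: FitnessTable
    cage: CageParams
    strain: str = "unnamed"

    def germline(self, sex: str) -> GermlineParams:
        if sex == "female":
            return self.germline_female
        if sex == "male":
            return self.germline_male
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IndividualState:
    """Zygotic genotype plus deposition exposure and germline mosaic mixture.

    ``germline_mixture`` is a distribution over unordered allele pairs in the
    germline stem cells, stored as a sorted tuple of (pair, weight) so states
    are hashable and usable as frequency-map keys.
    """

    maternal_allele: AlleleClass
    paternal_allele: AlleleClass
    exposure: Exposure = Exposure.NONE
    germline_mixture: tuple[tuple[Pair, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.germline_mixture:
            object.__setattr__(
                self, "germline_mixture", ((self.genotype, 1.0),))
        total = sum(w for _, w in self.germline_mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"germline_mixture weights sum to {total}, not 1")
        if any(w < -1e-15 for _, w in self.germline_mixture):
            raise ValueError("negative germline_mixture weight")

    @property
    def genotype(self) -> Pair:
        return genotype_key(self.maternal_allele, self.paternal_allele)

    @property
    def carries_drive(self) -> bool:
        return AlleleClass.D in (self.maternal_allele, self.paternal_allele)


def _pair_gametes(pair: Pair, g: GermlineParams) -> dict[AlleleClass, float]:
    """Gamete distribution from a single germline stem-cell pair."""
    a, b = pair
    if AlleleClass.D in pair and AlleleClass.W in pair:
        c, hdr, rho = g.cut_prob, g.hdr_frac, g.r1_frac
        ej = c * (1.0 - hdr)
        return {
            AlleleClass.D: (1.0 + c * hdr) / 2.0,
            AlleleClass.W: (1.0 - c) / 2.0,
            AlleleClass.R1: ej * rho / 2.0,
            AlleleClass.R2: ej * (1.0 - rho) / 2.0,
        }
    # no drive + cleavable target together: Mendelian segregation
    out: dict[AlleleClass, float] = {}
    out[a] = out.get(a, 0.0) + 0.5
    out[b] = out.get(b, 0.0) + 0.5
    return out


def gamete_distribution(individual: IndividualState, sex: str,
                        params: ModelParams) -> dict[AlleleClass, float]:
    """Distribution of gamete allele classes produced by an individual.

    The germline is a mosaic: the total distribution is the mixture over
    ``germline_mixture`` of per-cell-pair distributions, with drive homing
    (and end-joining) applying only in cells pairing a D with a W allele.
    """
    g = params.germline(sex)
    out: dict[AlleleClass, float] = {}
    for pair, weight in individual.germline_mixture:
        if weight == 0.0:
            continue
        for allele, p in _pair_gametes(pair, g).items():
            out[allele] = out.get(allele, 0.0) + weight * p
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"gamete probabilities sum to {total}")
    return out


def gamete_distribution_with_carriage(
        individual: IndividualState, sex: str,
        params: ModelParams) -> dict[tuple[AlleleClass, bool], float]:
    """Joint distribution over (gamete allele, gamete-source cell carries D).

    Deposition into an egg happens when the oocyte's germline cell carried a
    drive allele (the nuclease is expressed there regardless of which allele
    the gamete inherits), so the carriage flag is per germline component, not
    per transmitted allele.
    """
    g = params.germline(sex)
    out: dict[tuple[AlleleClass, bool], float] = {}
    for pair, weight in individual.germline_mixture:
        if weight == 0.0:
            continue
        carries = AlleleClass.D in pair
        for allele, p in _pair_gametes(pair, g).items():
            key = (allele, carries)
            out[key] = out.get(key, 0.0) + weight * p
    return out


def _allele_fate(allele: AlleleClass, homologue: AlleleClass, cut_prob: float,
                 dep: DepositionParams) -> list[tuple[AlleleClass, float]]:
    """Fate of one zygotic allele under deposited-nuclease exposure."""
    if not allele.cleavable or cut_prob == 0.0:
        return [(allele, 1.0)]
    fates: dict[AlleleClass, float] = {allele: 1.0 - cut_prob}
    hdr = cut_prob * dep.hdr_frac
    ej = cut_prob * (1.0 - dep.hdr_frac)
    # HDR repairs from the homologous chromosome, copying whatever is there
    fates[homologue] = fates.get(homologue, 0.0) + hdr
    fates[AlleleClass.R1] = fates.get(AlleleClass.R1, 0.0) + ej * dep.r1_frac
    fates[AlleleClass.R2] = fates.get(AlleleClass.R2, 0.0) + ej * (1.0 - dep.r1_frac)
    return [(a, p) for a, p in fates.items() if p > 0.0]


def embryo_transform(
        zygote: Pair,
        mother_carries_drive: bool,
        father_carries_drive: bool,
        params: ModelParams,
        *,
        maternal_cut: float | None = None,
        paternal_cut: float | None = None,
) -> dict[IndividualState, float]:
    """Distribution over individual states after embryonic deposition.

    Each zygotic W allele is cut independently with probability
    ``1 - (1 - d_m[mother carries])(1 - d_p[father carries])`` (independent
    maternal and paternal exposures). A cut resolves by HDR from the zygotic
    homologue or by end-joining (R1/R2). The modified pair seeds a fraction
    ``m`` of the germline stem cells; the zygotic pair the remaining ``1 - m``.
    With both deposition rates zero this is the identity apart from recording
    exposure.

    ``maternal_cut`` / ``paternal_cut`` override the per-side cut rates;
    requesting a nonzero rate for a parent that carries no drive is a contract
    violation and raises ``ValueError``.
    """
    dep = params.deposition
    d_m = dep.cut_maternal if maternal_cut is None else _check_prob(maternal_cut, "maternal_cut")
    d_p = dep.cut_paternal if paternal_cut is None else _check_prob(paternal_cut, "paternal_cut")
    if maternal_cut is not None and maternal_cut > 0 and not mother_carries_drive:
        raise ValueError("nonzero maternal deposition requested but mother carries no drive")
    if paternal_cut is not None and paternal_cut > 0 and not father_carries_drive:
        raise ValueError("nonzero paternal deposition requested but father carries no drive")

    exposure = Exposure.from_flags(mother_carries_drive, father_carries_drive)
    cut = 1.0 - (1.0 - d_m * mother_carries_drive) * (1.0 - d_p * father_carries_drive)
    mat, pat = zygote
    m = dep.germline_mosaic_frac

    out: dict[IndividualState, float] = {}
    for (a, pa), (b, pb) in itertools.product(
            _allele_fate(mat, pat, cut, dep), _allele_fate(pat, mat, cut, dep)):
        prob = pa * pb
        modified = genotype_key(a, b)
        zyg = genotype_key(mat, pat)
        if modified == zyg or m == 0.0:
            mixture: tuple[tuple[Pair, float], ...] = ((zyg, 1.0),)
        elif m == 1.0:
            mixture = ((modified, 1.0),)
        else:
            mixture = tuple(sorted(
                [(modified, m), (zyg, 1.0 - m)],
                key=lambda item: tuple(_ALLELE_ORDER[x] for x in item[0])))
        state = IndividualState(mat, pat, exposure, mixture)
        out[state] = out.get(state, 0.0) + prob
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"embryo outcome probabilities sum to {total}")
    return out


# ---------------------------------------------------------------------------
# Parameter files


def _params_from_dict(doc: Mapping, strain: str = "unnamed") -> ModelParams:
    germ = doc["germline"]
    fit = doc.get("fitness", {})
    cage = doc.get("cage", {})
    return ModelParams(
        germline_female=GermlineParams(**germ["female"]),
        germline_male=GermlineParams(**germ["male"]),
        deposition=DepositionParams(**doc.get("deposition", {})),
        fitness=FitnessTable(
            female_overrides=dict(fit.get("female_fecundity", {}) or {}),
            male_overrides=dict(fit.get("male_fitness", {}) or {}),
        ),
        cage=CageParams(
            capacity=int(cage.get("capacity", 600)),
            mating_failure_prob=float(cage.get("mating_failure_prob", 0.1)),
            larva_survival_prob=float(cage.get("larva_survival_prob", 0.9)),
            hatch_prob=float(cage.get("hatch_prob", 0.9)),
            hatch_overrides=dict(cage.get("hatch_overrides", {}) or {}),
            clutch_sizes=tuple(int(c) for c in cage.get("clutch_sizes", ())),
        ),
        strain=str(doc.get("strain", strain)),
    )


def load_params(source: str | Path) -> ModelParams:
    """Load a strain parameter file (YAML), or a bundled strain by name.

    ``load_params("zpg")`` loads the packaged baseline; any other string or
    path is treated as a file path.
    """
    name = str(source)
    if name in available_strains():
        ref = importlib.resources.files("drivesim") / "params" / f"{name}.yaml"
        doc = yaml.safe_load(ref.read_text())
        return _params_from_dict(doc, strain=name)
    path = Path(source)
    doc = yaml.safe_load(path.read_text())
    return _params_from_dict(doc, strain=path.stem)


def available_strains() -> list[str]:
    ref = importlib.resources.files("drivesim") / "params"
    return sorted(p.name[:-5] for p in ref.iterdir() if p.name.endswith(".yaml"))
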