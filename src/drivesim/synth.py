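"""Synthetic generators for every input the analysis chain consumes.

The generators emulate the statistical structure of the experiments:

* transmission screens — per-clutch larval counts from a zero-inflated
  negative binomial (clutch data are over-dispersed with failed layers), and
  binomial marker inheritance at ``p = (1 + c*hdr)/2`` from the true
  parameters, stratified by parent sex and parental drive origin;
* the r1-balancer deposition pedigree — F2 pools in which deposited nuclease
  converted W alleles to novel resistant alleles at the true embryonic rate,
  and F3 outcross pools carrying the expected 4-fold-diluted signal, both
  sampled at finite amplicon depth (multinomial);
* pooled amplicon allele tables along a simulated cage trajectory, with the
  abstract R1/R2 class frequencies decomposed into concrete indel identities
  drawn from a configurable spectrum (a few in-frame identities for R1, mostly
  frameshifts for R2), so which r1 identity dominates a cage varies by seed.

Everything is deterministic under a fixed master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import AlleleRecord, AlleleTable
from .estimators import DepositionCounts, ScreenCounts
from .model_core import ModelParams, load_params
from .trajectory import PopulationTrajectory

__all__ = ["SynthConfig", "make_screen", "make_deposition_pools",
           "make_allele_tables"]


@dataclass
class SynthConfig:
    """True parameters and sampling sizes for the synthetic experiments."""

    seed: int = 0
    params: ModelParams = field(default_factory=lambda: load_params("zpg"))
    # screen sizes
    n_clutches: int = 40
    clutch_mean: float = 110.0
    clutch_dispersion: float = 4.0     # negative binomial shape k
    zero_inflation: float = 0.05       # extra failed-layer mass
    # amplicon sequencing
    depth: int = 5000
    # indel spectrum
    n_r1_identities: int = 2
    n_r2_identities: int = 6
    deletion_size_p: float = 0.25      # geometric-like deletion sizes
    insertion_prob: float = 0.2
    identity_concentration: float = 0.3   # Dirichlet alpha; small -> one winner
    amplicon_length: int = 332
    cut_site: int = 209

    def __post_init__(self) -> None:
        if min(self.n_clutches, self.depth, self.n_r1_identities,
               self.n_r2_identities) <= 0:
            raise ValueError("all sizes must be positive")
        for name in ("zero_inflation", "insertion_prob", "deletion_size_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed)
        return np.random.Generator(np.random.PCG64(ss.spawn(stream + 1)[stream]))


def _clutch_sizes(config: SynthConfig, rng: np.random.Generator, n: int
                  ) -> np.ndarray:
    k = config.clutch_dispersion
    p = k / (k + config.clutch_mean)
    sizes = rng.negative_binomial(k, p, size=n)
    failed = rng.random(n) < config.zero_inflation
    sizes[failed] = 0
    return sizes


def make_screen(config: SynthConfig) -> pd.DataFrame:
    """Synthetic transmission-screen count tables.

    One row per clutch with columns matching :class:`ScreenCounts`; reciprocal
    crosses (parent sex) and both parental drive origins are emitted. Clutches
    with zero larvae are kept in the table (they inform fecundity, not
    transmission).
    """
    rng = config.rng(0)
    rows = []
    for sex in ("female", "male"):
        p = config.params.germline(sex).transmission
        for origin in ("maternal", "paternal"):
            sizes = _clutch_sizes(config, rng, config.n_clutches)
            positives = rng.binomial(sizes, p)
            for i, (total, pos) in enumerate(zip(sizes, positives)):
                rows.append({
                    "strain": config.params.strain, "parent_sex": sex,
                    "drive_origin": origin, "clutch_id": f"{sex[0]}{origin[0]}{i}",
                    "total": int(total), "positive": int(pos),
                })
    return pd.DataFrame(rows)


def screen_counts(frame: pd.DataFrame) -> list[ScreenCounts]:
    """Convert a screen table to :class:`ScreenCounts` (skips empty clutches)."""
    return [ScreenCounts(int(r.positive), int(r.total), r.clutch_id,
                         r.parent_sex, r.drive_origin, r.strain)
            for r in frame.itertuples() if r.total > 0]


def make_deposition_pools(config: SynthConfig, deposition_rate: float | None = None,
                          n_f2_individuals: int = 150
                          ) -> dict[str, DepositionCounts]:
    """Simulate the drive/r1-balancer deposition pedigree.

    F1 drive/r1 heterozygotes are outcrossed to wild type; their non-drive F2
    progeny are r1/W, and deposited nuclease converts the W allele to a novel
    resistant allele with probability ``e`` (the true embryonic end-joining
    rate, defaulting to the maternal deposition rate of the configured
    strain). F2 individuals are pooled and sequenced at finite depth; the F3
    generation outcrosses the pool to wild type, halving inherited mutation
    frequencies and adding fresh W alleles.
    """
    rng = config.rng(1)
    e = (config.params.deposition.cut_maternal
         if deposition_rate is None else float(deposition_rate))
    if not (0.0 <= e <= 1.0):
        raise ValueError("deposition rate must be in [0, 1]")

    # F2 chromosomes: one r1 balancer + one (possibly converted) W per individual
    converted = rng.binomial(n_f2_individuals, e)
    f2_chroms = {"inherited_r1": n_f2_individuals,
                 "wt": n_f2_individuals - converted,
                 "novel_r": converted}
    total = sum(f2_chroms.values())
    f2_probs = np.array([f2_chroms["wt"], f2_chroms["inherited_r1"],
                         f2_chroms["novel_r"]]) / total
    wt, r1, novel = rng.multinomial(config.depth, f2_probs)
    f2 = DepositionCounts(int(wt), int(r1), int(novel), "F2")

    # F3: each F2 transmits a random allele; the wild-type mate contributes W
    f3_probs = np.concatenate([f2_probs / 2.0, [0.0]])
    f3_probs[0] += 0.5
    wt, r1, novel, _ = rng.multinomial(config.depth, f3_probs)
    f3 = DepositionCounts(int(wt), int(r1), int(novel), "F3")
    return {"F2": f2, "F3": f3}


def _indel_identities(config: SynthConfig, rng: np.random.Generator):
    """Concrete indel descriptors for the resistant classes.

    R1 identities are in-frame deletions near the cut; R2 identities are
    mostly frameshifts. Relative abundances come from a Dirichlet draw with
    small concentration, so a single identity typically dominates.
    """
    def records(n, in_frame):
        out = []
        attempts = 0
        while len(out) < n and attempts < 1000:
            attempts += 1
            if rng.random() < config.insertion_prob:
                ins = int(rng.geometric(config.deletion_size_p))
                dele = 0
                pos = config.cut_site
            else:
                dele = int(rng.geometric(config.deletion_size_p))
                ins = 0
                pos = config.cut_site - rng.integers(0, max(1, dele))
            net = ins - dele
            if in_frame != (net % 3 == 0) or net == 0:
                continue
            rec = (int(pos), dele, ins)
            if rec not in [r[:3] for r in out]:
                out.append(rec)
        return out

    r1 = records(config.n_r1_identities, in_frame=True)
    r2 = records(config.n_r2_identities, in_frame=False)
    w_r1 = rng.dirichlet([config.identity_concentration] * len(r1))
    w_r2 = rng.dirichlet([config.identity_concentration] * len(r2))
    return (r1, w_r1), (r2, w_r2)


def make_allele_tables(config: SynthConfig, trajectory: PopulationTrajectory,
                       sample_generations: list[int] | None = None,
                       sample: str = "cage") -> list[AlleleTable]:
    """Pooled amplicon allele tables along a simulated trajectory.

    Per sampled generation the non-drive allele-class frequencies (W, R1, R2)
    are expanded into concrete indel identities and sampled at the configured
    depth (multinomial). The first R1 identity is entered into the registry as
    a confirmed r1 allele, the first R2 identity as confirmed r2 (emulating
    phenotypically validated alleles).
    """
    rng = config.rng(2)
    frame = trajectory.to_frame().set_index("generation")
    if sample_generations is None:
        sample_generations = list(frame.index)
    (r1_ids, w_r1), (r2_ids, w_r2) = _indel_identities(config, rng)

    registry = {}
    for (pos, dele, ins), klass in [(r1_ids[0], "confirmed_r1"),
                                    (r2_ids[0], "confirmed_r2")]:
        registry[f"{pos}:{dele}D{ins}I"] = klass

    tables = []
    for gen in sample_generations:
        row = frame.loc[gen]
        nondrive = np.array([row["W_freq"], row["R1_freq"], row["R2_freq"]])
        total = nondrive.sum()
        if total <= 0:
            continue
        w, r1, r2 = nondrive / total
        probs = np.concatenate([[w], r1 * w_r1, r2 * w_r2])
        counts = rng.multinomial(config.depth, probs)
        records = []
        if counts[0]:
            records.append(AlleleRecord(0, 0, 0, int(counts[0])))
        for (pos, dele, ins), n in zip(r1_ids + r2_ids, counts[1:]):
            if n:
                records.append(AlleleRecord(pos, dele, ins, int(n)))
        tables.append(AlleleTable(sample, int(gen), records, config.cut_site,
                                  config.amplicon_length, registry))
    if not tables:
        raise ValueError("trajectory has no generations with non-drive alleles")
    return tables
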