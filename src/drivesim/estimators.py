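"""Screen arithmetic: the estimators applied to genetic-cross count data.

These implement the bookkeeping used to turn raw screen counts into rates:

* drive transmission from marker-screen counts, with Wilson intervals and
  per-clutch standard errors;
* the transmission-to-homing conversion ``h = 2p - 1`` (a transmission of
  60.2% corresponds to homing of 20.4% of non-drive chromosomes);
* relative fecundity of a strain's females against contemporaneous wild type;
* embryonic end-joining rates from the r1-balancer deposition screen, where
  the F2 rate is the frequency of novel resistant alleles among
  nuclease-sensitive (WT + novel R) alleles and the F3 rate multiplies the
  overall novel-R frequency by the Mendelian dilution factor of 4;
* the 2-fold F2-to-F3 Mendelian-dilution check and the 1:1 WT:r1
  depletion test for the no-deposition control;
* summaries of meiotic end-joining among captured non-homed chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenCounts",
    "DepositionCounts",
    "ProportionEstimate",
    "transmission_rate",
    "transmission_table",
    "homing_from_inheritance",
    "relative_fecundity",
    "embryonic_ej_rate_f2",
    "embryonic_ej_rate_f3",
    "mendelian_dilution_check",
    "wt_depletion_test",
    "meiotic_ej_summary",
]


@dataclass(frozen=True)
class ScreenCounts:
    """Marker counts for one clutch of a transmission screen."""

    positive: int
    total: int
    clutch_id: str = ""
    parent_sex: str = ""
    drive_origin: str = ""   # maternal / paternal
    strain: str = ""

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total progeny scored must be positive")
        if not (0 <= self.positive <= self.total):
            raise ValueError("positive count outside [0, total]")


@dataclass(frozen=True)
class DepositionCounts:
    """Amplicon allele-class counts for one deposition-screen pool."""

    wt: int
    inherited_r1: int
    novel_r: int
    generation: str = "F2"

    def __post_init__(self) -> None:
        if min(self.wt, self.inherited_r1, self.novel_r) < 0:
            raise ValueError("counts must be non-negative")
        if self.wt + self.inherited_r1 + self.novel_r == 0:
            raise ValueError("at least one count must be nonzero")


@dataclass(frozen=True)
class ProportionEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n: int

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _wilson(positive: int, total: int, level: float = 0.95) -> ProportionEstimate:
    ci = stats.binomtest(positive, total).proportion_ci(
        confidence_level=level, method="wilson")
    return ProportionEstimate(positive / total, ci.low, ci.high, total)


def transmission_rate(counts: ScreenCounts | Iterable[ScreenCounts],
                      level: float = 0.95) -> ProportionEstimate:
    """Pooled drive-transmission estimate with a two-sided Wilson interval."""
    if isinstance(counts, ScreenCounts):
        counts = [counts]
    counts = list(counts)
    if not counts:
        raise ValueError("no screen counts supplied")
    positive = sum(c.positive for c in counts)
    total = sum(c.total for c in counts)
    return _wilson(positive, total, level)


def transmission_table(counts: Iterable[ScreenCounts]) -> pd.DataFrame:
    """Per-stratum transmission: pooled Wilson CI and clutch-level s.e.m.

    Strata follow the screen design: (strain, parent sex, parental drive
    origin). The clutch-level mean/s.e.m. mirrors how such screens are
    usually reported; the pooled Wilson interval weights clutches by size.
    """
    rows = []
    frame = pd.DataFrame([c.__dict__ for c in counts])
    for (strain, sex, origin), grp in frame.groupby(
            ["strain", "parent_sex", "drive_origin"], sort=False):
        est = _wilson(int(grp.positive.sum()), int(grp.total.sum()))
        per_clutch = grp.positive / grp.total
        rows.append({
            "strain": strain, "parent_sex": sex, "drive_origin": origin,
            "n_clutches": len(grp), "n_progeny": int(grp.total.sum()),
            "transmission": est.estimate,
            "wilson_low": est.ci_low, "wilson_high": est.ci_high,
            "clutch_mean": per_clutch.mean(),
            "clutch_sem": per_clutch.sem() if len(grp) > 1 else math.nan,
        })
    return pd.DataFrame(rows)


def homing_from_inheritance(p: float) -> tuple[float, bool]:
    """Convert a transmission fraction to homed fraction of non-drive
    chromosomes, ``h = 2p - 1``.

    Sub-Mendelian transmission (p < 0.5) cannot be explained by homing;
    the estimate is reported as 0 with the flag set.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("transmission fraction must be in [0, 1]")
    h = 2.0 * p - 1.0
    if h < 0.0:
        return 0.0, True
    return h, False


def relative_fecundity(strain_counts: Sequence[float],
                       wt_counts: Sequence[float],
                       strain_sperm_absent: Sequence[bool] | None = None,
                       wt_sperm_absent: Sequence[bool] | None = None,
                       use_median: bool = False,
                       ci: bool = False,
                       n_boot: int = 2000,
                       rng: np.random.Generator | None = None):
    """Mean larval output of strain females over contemporaneous wild type.

    Zero-progeny females count unless flagged sperm-absent (females with no
    evidence of insemination are excluded as unmated rather than infertile).
    With ``ci=True`` returns (ratio, low, high) from a seeded bootstrap.
    """
    def clean(values, flags):
        values = np.asarray(values, dtype=float)
        if flags is not None:
            values = values[~np.asarray(flags, dtype=bool)]
        return values

    strain = clean(strain_counts, strain_sperm_absent)
    wt = clean(wt_counts, wt_sperm_absent)
    if strain.size == 0 or wt.size == 0:
        raise ValueError("empty clutch-count input")
    center = np.median if use_median else np.mean
    if center(wt) <= 0:
        raise ValueError("wild-type mean larval output must be positive")
    ratio = float(center(strain) / center(wt))
    if not ci:
        return ratio
    rng = np.random.default_rng(0) if rng is None else rng
    boots = []
    for _ in range(n_boot):
        s = rng.choice(strain, strain.size)
        w = rng.choice(wt, wt.size)
        if center(w) > 0:
            boots.append(center(s) / center(w))
    low, high = np.percentile(boots, [2.5, 97.5])
    return ratio, float(low), float(high)


def embryonic_ej_rate_f2(counts: DepositionCounts) -> float:
    """Embryonic end-joining rate from an F2 deposition pool.

    Frequency of novel resistant alleles among nuclease-sensitive alleles,
    ``novel_R / (novel_R + WT)``; the inherited r1 balancer is cleavage-
    resistant and drops out of the denominator.
    """
    denom = counts.novel_r + counts.wt
    if denom == 0:
        raise ValueError("no nuclease-sensitive (WT or novel R) alleles in pool")
    return counts.novel_r / denom


def embryonic_ej_rate_f3(novel_r_frequency: float) -> tuple[float, bool]:
    """Embryonic end-joining rate from the F3 novel-R allele frequency.

    The outcross to wild type contributes fresh W alleles, diluting embryo-
    derived mutations 4-fold, so the rate is ``4 x frequency``. Frequencies
    above 0.25 imply a rate above 1 and are flagged.
    """
    if not (0.0 <= novel_r_frequency <= 1.0):
        raise ValueError("frequency must be in [0, 1]")
    flagged = novel_r_frequency > 0.25
    return 4.0 * novel_r_frequency, flagged


@dataclass(frozen=True)
class DilutionCheck:
    fold_reduction: float | None
    consistent_with_mendelian: bool
    p_value: float | None
    flagged: bool


def mendelian_dilution_check(f2_freq: float, f3_count: int, f3_total: int
                             ) -> DilutionCheck:
    """Check the expected 2-fold F2-to-F3 reduction of a mutation frequency.

    Under Mendelian inheritance a mutation at frequency f in the sampled F2
    appears at f/2 in the F3 outcross progeny. The F3 count is tested
    against binomial(total, f2/2); a ratio near 1 instead of 2 suggests
    post-zygotic amplification (e.g. homing by deposited nuclease).
    """
    if f3_total <= 0:
        raise ValueError("F3 total must be positive")
    f3_freq = f3_count / f3_total
    if f3_freq == 0.0:
        consistent = stats.binomtest(0, f3_total, f2_freq / 2.0).pvalue > 0.05
        return DilutionCheck(None, consistent, None, flagged=True)
    test = stats.binomtest(f3_count, f3_total, min(1.0, f2_freq / 2.0))
    return DilutionCheck(f2_freq / f3_freq, test.pvalue > 0.05, test.pvalue,
                         flagged=False)


@dataclass(frozen=True)
class DepletionTest:
    wt_fraction: float
    p_value: float
    depleted: bool


def wt_depletion_test(counts: DepositionCounts, alpha: float = 0.05
                      ) -> DepletionTest:
    """Departure of the WT allele from the 1:1 WT:r1 control expectation.

    Without deposited nuclease the F2 pool carries only the inherited r1
    balancer and WT at 1:1. Deposition converts WT to novel R, so novel R
    counts against WT: the exact binomial test compares WT successes out of
    WT + r1 + novel R against 0.5 (one-sided: depletion).
    """
    total = counts.wt + counts.inherited_r1 + counts.novel_r
    test = stats.binomtest(counts.wt, total, 0.5, alternative="less")
    return DepletionTest(counts.wt / total, test.pvalue, test.pvalue < alpha)


def meiotic_ej_summary(records: pd.DataFrame | Iterable[tuple[str, str]]
                       ) -> dict:
    """Summarise sequenced non-homed chromosomes from the meiotic screen.

    ``records`` holds one row per sequenced chromosome with columns
    ``allele`` (identity, e.g. an indel descriptor; WT rows may repeat) and
    ``klass`` in {WT, confirmed_r1, confirmed_r2, in_frame, out_of_frame}.
    Returns the mutated fraction, the number of distinct mutant identities
    and the class composition of mutated chromosomes.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["allele", "klass"])
    if records.empty:
        raise ValueError("no records supplied")
    mutated = records[records["klass"] != "WT"]
    composition = (mutated["klass"].value_counts(normalize=True).to_dict()
                   if len(mutated) else {})
    return {
        "n": len(records),
        "n_mutated": len(mutated),
        "fraction_mutated": len(mutated) / len(records),
        "distinct_alleles": mutated["allele"].nunique(),
        "class_composition": composition,
    }
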