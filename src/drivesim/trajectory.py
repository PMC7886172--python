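"""Per-generation trajectory container shared by both simulators."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: column order of the trajectory table
COLUMNS = ["generation", "carrier_freq", "drive_allele_freq",
           "W_freq", "R1_freq", "R2_freq", "egg_index"]


@dataclass
class PopulationTrajectory:
    """Sequence of per-generation population summaries.

    ``records`` hold one dict per generation with at least the keys in
    :data:`COLUMNS`; simulators may add extra bookkeeping columns (egg and
    larva counts, extinction flags). Allele frequencies are among all zygotic
    alleles, so ``drive_allele_freq + W_freq + R1_freq + R2_freq == 1``.
    """

    records: list[dict] = field(default_factory=list)
    extinct: bool = False

    def append(self, record: dict) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.records)
        ordered = [c for c in COLUMNS if c in frame.columns]
        extra = [c for c in frame.columns if c not in ordered]
        return frame[ordered + extra]

    def series(self, column: str) -> pd.Series:
        return self.to_frame().set_index("generation")[column]

    def r1_among_nondrive(self) -> pd.Series:
        """R1 frequency among non-drive alleles (NaN where none remain)."""
        frame = self.to_frame().set_index("generation")
        nondrive = frame[["W_freq", "R1_freq", "R2_freq"]].sum(axis=1)
        return frame["R1_freq"] / nondrive
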