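"""Classification of amplicon indel alleles and resistance-profile building.

Pooled amplicon sequencing across the drive target site yields allele-count
tables (one row per distinct indel haplotype, CRISPResso-style). Alleles are
classified against a registry of phenotypically confirmed resistance alleles
(e.g. the 6-bp in-frame deletion used as an r1 balancer) and otherwise by two
rules: an indel must alter a 20-bp window centred on the cleavage site to
count as a target-site mutation (a large insertion outside the window is the
incomplete-homing drive signature), and unregistered in-window indels are
called in-frame or out-of-frame by their net length change modulo 3. The
"confirmed" classes come only from the registry because frame alone cannot
prove a functional (r1) or null (r2) phenotype.

Per-generation compositions pool alleles that never exceed a threshold
frequency (1% by default) in *any* sampled generation into their frame class,
mirroring how resistance profiles are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["AlleleRecord", "AlleleTable", "classify", "composition",
           "read_allele_tables", "read_registry"]

CLASSES = ("WT", "drive", "confirmed_r1", "confirmed_r2", "in_frame",
           "out_of_frame", "outside_window")

#: insertions at least this long, outside the cut window, are treated as the
#: incomplete-homing signature of the drive cassette
LARGE_INSERTION_MIN = 30


@dataclass(frozen=True)
class AlleleRecord:
    """One amplicon indel haplotype.

    Coordinates are 0-based within the amplicon; ``position`` is where the
    deletion starts, or the inter-base insertion point for pure insertions.
    """

    position: int
    del_len: int
    ins_len: int
    count: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.del_len < 0 or self.ins_len < 0:
            raise ValueError("indel lengths must be non-negative")
        if self.position < 0:
            raise ValueError("position must be non-negative")

    @property
    def net_change(self) -> int:
        return self.ins_len - self.del_len

    @property
    def is_wt(self) -> bool:
        return self.del_len == 0 and self.ins_len == 0

    @property
    def descriptor(self) -> str:
        return f"{self.position}:{self.del_len}D{self.ins_len}I"


@dataclass
class AlleleTable:
    """Allele records for one pooled sample.

    ``registry`` maps indel descriptors (``"pos:DELdINSi"`` form) to confirmed
    classes (``confirmed_r1`` / ``confirmed_r2``).
    """

    sample: str
    generation: int
    records: list[AlleleRecord]
    cut_site: int
    amplicon_length: int = 332
    registry: Mapping[str, str] = field(default_factory=dict)
    window: int = 20

    def __post_init__(self) -> None:
        if not (0 <= self.cut_site <= self.amplicon_length):
            raise ValueError("cut site outside amplicon")
        for klass in self.registry.values():
            if klass not in ("confirmed_r1", "confirmed_r2"):
                raise ValueError(f"registry class must be confirmed r1/r2, got {klass}")


def _alters_window(record: AlleleRecord, cut_site: int, window: int) -> bool:
    half = window // 2
    lo, hi = cut_site - half, cut_site + half  # [lo, hi) bases around the cut
    if record.del_len > 0:
        if record.position < hi and record.position + record.del_len > lo:
            return True
    if record.ins_len > 0 and lo <= record.position <= hi:
        return True
    return False


def classify(record: AlleleRecord, table: AlleleTable) -> str:
    """Assign one of the allele classes to a record (total function).

    Registry matches win; indels that do not alter the cut window are
    ``outside_window`` (counted with WT) unless they carry the large-insertion
    drive signature; remaining in-window indels are called by frame.
    """
    if record.is_wt:
        return "WT"
    if record.descriptor in table.registry:
        return table.registry[record.descriptor]
    if not _alters_window(record, table.cut_site, table.window):
        if record.ins_len >= LARGE_INSERTION_MIN:
            return "drive"
        return "outside_window"
    if record.net_change % 3 == 0:
        return "in_frame"
    return "out_of_frame"


def composition(tables: Iterable[AlleleTable], threshold: float = 0.01,
                include_drive: bool = False) -> pd.DataFrame:
    """Per-generation stacked frequencies of non-drive allele classes.

    An allele is tracked individually (labelled by its descriptor and class)
    if its frequency exceeds ``threshold`` in any sampled generation;
    otherwise it is pooled into its frame class. Frequencies are among
    non-drive alleles (WT + resistant), the denominator used for resistance
    profiles; ``include_drive=True`` switches to all alleles.

    Returns a long-format frame (generation, label, klass, frequency), with
    frequencies summing to 1 within each generation.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no allele tables supplied")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")

    rows = []
    for table in tables:
        for record in table.records:
            if record.count == 0:
                continue
            klass = classify(record, table)
            rows.append({"generation": table.generation,
                         "descriptor": record.descriptor,
                         "klass": klass, "count": record.count})
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("allele tables contain no reads")
    if not include_drive:
        frame = frame[frame["klass"] != "drive"]
    # outside-window indels do not alter the target: count them as WT
    frame.loc[frame["klass"] == "outside_window", "klass"] = "WT"
    frame.loc[frame["klass"] == "WT", "descriptor"] = "WT"

    per_gen = frame.groupby("generation")["count"].sum().rename("gen_total")
    frame = frame.merge(per_gen, on="generation")
    frame["freq"] = frame["count"] / frame["gen_total"]

    # any-generation rule: individually tracked if above threshold anywhere
    peak = frame.groupby("descriptor")["freq"].max()
    tracked = set(peak[peak > threshold].index) | {"WT"}

    def label(row) -> str:
        if row["descriptor"] in tracked:
            return row["descriptor"]
        return {"in_frame": "in_frame", "out_of_frame": "out_of_frame",
                "confirmed_r1": "in_frame", "confirmed_r2": "out_of_frame"
                }.get(row["klass"], row["klass"])

    frame["label"] = frame.apply(label, axis=1)
    out = (frame.groupby(["generation", "label", "klass"], as_index=False)
           ["freq"].sum())
    # a tracked allele keeps its class; pooled groups take the frame class
    pooled_mask = out["label"].isin(("in_frame", "out_of_frame"))
    out.loc[pooled_mask, "klass"] = out.loc[pooled_mask, "label"]
    out = (out.groupby(["generation", "label", "klass"], as_index=False)
           ["freq"].sum().rename(columns={"freq": "frequency"}))
    return out.sort_values(["generation", "frequency"],
                           ascending=[True, False]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Delimited-text I/O (CRISPResso-exportable shape)


def read_registry(path: str | Path) -> dict[str, str]:
    """Registry TSV with columns name, descriptor, class."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame["descriptor"], frame["class"]))


def read_allele_tables(path: str | Path, cut_site: int,
                       amplicon_length: int = 332,
                       registry: Mapping[str, str] | None = None
                       ) -> list[AlleleTable]:
    """Read a TSV with columns sample, generation, position, del_len,
    ins_len, count into one table per (sample, generation)."""
    frame = pd.read_csv(path, sep="\t")
    tables = []
    for (sample, gen), grp in frame.groupby(["sample", "generation"]):
        records = [AlleleRecord(int(r.position), int(r.del_len),
                                int(r.ins_len), int(r.count))
                   for r in grp.itertuples()]
        tables.append(AlleleTable(str(sample), int(gen), records, cut_site,
                                  amplicon_length, dict(registry or {})))
    return tables
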