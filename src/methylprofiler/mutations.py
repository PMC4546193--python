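"""KRAS/BRAF mutation accounting and PCR-RFLP interpretation.

KRAS codon 12 and 13 status comes from a mutagenic PCR-RFLP assay: the
codon-12 amplicon (162 bp, BstNI) releases a 113 bp fragment from the
wild-type allele or 142 bp from the mutant; the codon-13 amplicon (174 bp,
BglI) releases 165 bp (wild type) or 125 bp (mutant).  BRAF V600E status is
imported directly (pyrosequencing readout).  Frequencies are tabulated per
histological group and pooled over the non-metastatic tumor groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._tables import RFLP_ASSAYS

__all__ = [
    "ASSAYS",
    "MutationRecord",
    "RflpObservation",
    "interpret_rflp",
    "mutation_frequencies",
    "read_mutation_table",
]

ASSAYS = ("KRAS_c12", "KRAS_c13", "BRAF_V600E")

#: Electrophoresis sizing tolerance in bp for matching diagnostic fragments.
SIZE_TOLERANCE_BP = 3

#: Reporting groups of the mutation frequency table: all normal-histology
#: samples pooled, the three tumor groups, and their pooled total.
REPORT_GROUPS: dict[str, tuple[str, ...]] = {
    "N": ("Y", "N", "CN", "F"),
    "LGD": ("LGD",),
    "HGD": ("HGD",),
    "CRC": ("CRC",),
}
TOTAL_GROUPS = ("LGD", "HGD", "CRC")


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    assay: str
    status: str  # WT | MUT | NA

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.status not in ("WT", "MUT", "NA"):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class RflpObservation:
    """Fragment sizes (bp) observed after restriction digestion of one assay."""

    assay: str
    fragment_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.assay not in RFLP_ASSAYS:
            raise ValueError(f"no RFLP fragment map for assay {self.assay!r}")
        if any(s <= 0 for s in self.fragment_sizes):
            raise ValueError("fragment sizes must be positive")


def interpret_rflp(obs: RflpObservation) -> str:
    """Genotype call from observed restriction fragment sizes.

    A size matches a diagnostic fragment within +/-3 bp (chip
    electrophoresis sizing error; the wild-type and mutant diagnostics are
    >6 bp apart in both assays, so the windows cannot overlap).  Presence of
    the mutant diagnostic dominates — a heterozygous or heterogeneous sample
    showing both fragments is called MUT.  Neither diagnostic present
    returns NA.  A fragment longer than the amplicon is a hard error.
    """
    spec = RFLP_ASSAYS[obs.assay]
    for size in obs.fragment_sizes:
        if size > spec["amplicon"]:
            raise ValueError(
                f"{obs.assay}: observed fragment {size} bp exceeds the "
                f"{spec['amplicon']} bp amplicon"
            )
    def seen(target: int) -> bool:
        return any(abs(s - target) <= SIZE_TOLERANCE_BP for s in obs.fragment_sizes)

    if seen(spec["mut_fragment"]):
        return "MUT"
    if seen(spec["wt_fragment"]):
        return "WT"
    return "NA"


def mutation_frequencies(
    records: Iterable[MutationRecord],
    meta: pd.DataFrame,
    report_groups: dict[str, tuple[str, ...]] | None = None,
    total_groups: Sequence[str] = TOTAL_GROUPS,
) -> pd.DataFrame:
    """Mutation counts and percentages per reporting group plus pooled total.

    ``meta`` is indexed by sample_id with a ``group`` column; every record's
    sample must be present.  Returns a tidy frame with columns ``group,
    assay, n, count, percent`` where the "Total" row pools the samples of
    ``total_groups``.  Percentages are NaN for empty groups.
    """
    report_groups = report_groups or REPORT_GROUPS
    recs = pd.DataFrame([vars(r) for r in records])
    missing = set(recs["sample_id"]) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
    recs["group"] = recs["sample_id"].map(meta["group"])

    blocks = dict(report_groups)
    blocks["Total"] = tuple(total_groups)
    rows = []
    for label, members in blocks.items():
        sub = recs[recs["group"].isin(members)]
        for assay in ASSAYS:
            a = sub[(sub["assay"] == assay) & (sub["status"] != "NA")]
            n = a["sample_id"].nunique()
            count = int((a["status"] == "MUT").sum())
            pct = round(100.0 * count / n, 1) if n else float("nan")
            rows.append({"group": label, "assay": assay, "n": n,
                         "count": count, "percent": pct})
    return pd.DataFrame(rows)


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a mutation CSV with either direct status or raw fragment sizes.

    Columns: ``sample_id, assay`` and one of ``status`` or
    ``fragment_sizes`` (semicolon-separated bp integers, interpreted through
    :func:`interpret_rflp`).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "assay" not in df.columns:
        raise ValueError(f"{path}: need sample_id and assay columns")
    out = []
    for r in df.itertuples():
        status = getattr(r, "status", "") or ""
        if not status:
            sizes = tuple(int(s) for s in getattr(r, "fragment_sizes", "").split(";") if s)
            status = interpret_rflp(RflpObservation(r.assay, sizes))
        out.append(MutationRecord(r.sample_id, r.assay, status))
    return out
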