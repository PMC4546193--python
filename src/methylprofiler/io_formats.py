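"""Tabular I/O for the methylation pipeline.

Reads tidy long-format Ct exports and sample metadata, writes the
samples x genes fraction matrix (percent scale, 2 decimals) and summary
tables.  All formats are plain CSV/TSV; parsing is total over the declared
dialect — every row either yields a record or a located hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fraction_model import DIGESTS

__all__ = [
    "GROUPS",
    "CtDialect",
    "SampleMeta",
    "read_ct_table",
    "read_sample_meta",
    "write_fraction_matrix",
    "read_fraction_matrix",
    "write_summary",
]

#: The ten histological groups of the cohort design.
GROUPS = ("Y", "N", "CN", "F", "LGD", "HGD", "CRC", "MCRC", "UCi", "UCa")

_DIGEST_CANON = {d.lower(): d for d in DIGESTS}


@dataclass(frozen=True)
class CtDialect:
    """Accepted spellings of the no-amplification sentinel and the separator.

    Instrument exports differ in how a reaction that never crossed threshold
    is written; any cell matching (case-insensitively) an entry of
    ``no_amplification`` becomes NaN.
    """

    no_amplification: tuple[str, ...] = ("Undetermined", "", "NaN", "N/A")
    sep: str | None = None  # None: sniff from extension (.tsv -> tab)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biopsy sample."""

    sample_id: str
    patient_id: str
    group: str
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"expected one of {GROUPS}"
            )


def _sep_for(path: Path, dialect: CtDialect) -> str:
    if dialect.sep is not None:
        return dialect.sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_ct_table(path: str | Path, dialect: CtDialect = CtDialect()) -> pd.DataFrame:
    """Read a tidy Ct export into a record table.

    Requires columns ``sample_id, gene, digest, ct``.  Digest labels are
    case-normalized to Mo/Ms/Md/Msd; unknown labels are a hard error naming
    the offending row.  Duplicate (sample, gene, digest) rows are averaged
    (arithmetic mean of numeric Cts) and flagged in the ``duplicate`` column.

    Returns a DataFrame with columns ``sample_id, gene, digest, ct,
    duplicate``; ``ct`` is NaN for no-amplification rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    required = ["sample_id", "gene", "digest", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    digests = df["digest"].str.strip()
    canon = digests.str.lower().map(_DIGEST_CANON)
    if canon.isna().any():
        row = int(canon.isna().idxmax())
        raise ValueError(
            f"{path}: unknown digest label {digests.iloc[row]!r} at data row {row + 1}"
        )
    df = df.assign(digest=canon)

    no_amp = {s.lower() for s in dialect.no_amplification}
    raw_ct = df["ct"].str.strip()
    is_na = raw_ct.str.lower().isin(no_amp)
    ct = pd.to_numeric(raw_ct.where(~is_na, other=None), errors="coerce")
    unparsed = ct.isna() & ~is_na
    if unparsed.any():
        row = int(unparsed.idxmax())
        raise ValueError(
            f"{path}: unparseable ct value {raw_ct.iloc[row]!r} at data row {row + 1}"
        )
    if (ct.dropna() <= 0).any():
        row = int((ct <= 0).idxmax())
        raise ValueError(f"{path}: non-positive ct at data row {row + 1}")
    df = df.assign(ct=ct)

    grouped = df.groupby(["sample_id", "gene", "digest"], sort=False, as_index=False).agg(
        ct=("ct", "mean"), duplicate=("ct", lambda s: len(s) > 1)
    )
    return grouped


def read_sample_meta(path: str | Path, sep: str | None = None) -> list[SampleMeta]:
    """Read and validate the sample metadata table.

    Checks every group label against the ten-group enumeration and enforces
    the pairing invariant: a ``pair_id`` must occur on exactly two samples of
    the same patient, one LGD and one CRC.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path, CtDialect()), dtype=str,
                     keep_default_na=False)
    required = ["sample_id", "patient_id", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "pair_id" not in df.columns:
        df["pair_id"] = ""

    metas = [
        SampleMeta(
            sample_id=r.sample_id.strip(),
            patient_id=r.patient_id.strip(),
            group=r.group.strip(),
            pair_id=r.pair_id.strip() or None,
        )
        for r in df.itertuples()
    ]
    validate_pairs(metas)
    return metas


def validate_pairs(metas: Sequence[SampleMeta]) -> None:
    """Enforce the synchronous-pair invariant on a metadata collection."""
    by_pair: dict[str, list[SampleMeta]] = {}
    for m in metas:
        if m.pair_id is not None:
            by_pair.setdefault(m.pair_id, []).append(m)
    broken = []
    for pid, members in by_pair.items():
        groups = sorted(m.group for m in members)
        patients = {m.patient_id for m in members}
        if len(members) != 2 or groups != ["CRC", "LGD"] or len(patients) != 1:
            broken.append(pid)
    if broken:
        raise ValueError(
            "broken synchronous pair(s) "
            f"{sorted(broken)}: each pair_id must mark exactly one LGD and one "
            "CRC sample of the same patient"
        )


def meta_frame(metas: Iterable[SampleMeta]) -> pd.DataFrame:
    """Metadata collection as a DataFrame indexed by sample_id."""
    df = pd.DataFrame([vars(m) for m in metas])
    return df.set_index("sample_id", drop=False)


def write_fraction_matrix(
    matrix: pd.DataFrame, path: str | Path, genes: Sequence[str] | None = None
) -> None:
    """Write a samples x genes fraction matrix as TSV percentages.

    ``matrix`` holds fractions on [0, 1] (samples as index, genes as
    columns); cells are written as percentages with two decimals, missing
    values as ``NA``.  Column order follows ``genes`` (the panel order) when
    given, else the matrix's own column order.
    """
    out = matrix.copy()
    if genes is not None:
        out = out.reindex(columns=list(genes))
    out = (out * 100.0).round(2)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.2f")


def read_fraction_matrix(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_fraction_matrix`; returns fractions on [0, 1]."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    return df / 100.0


def write_summary(tables: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write named summary tables into one TSV file, blocks separated by '#' headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, table in tables.items():
            fh.write(f"# {name}\n")
            table.to_csv(fh, sep="\t", na_rep="NA", index=False)
            fh.write("\n")


def pivot_fractions(fracs: pd.DataFrame, value: str = "f_hm") -> pd.DataFrame:
    """Tidy per-assay fractions -> samples x genes matrix of one fraction kind."""
    return fracs.pivot(index="sample_id", columns="gene", values=value)
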