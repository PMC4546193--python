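"""Methylation fraction arithmetic for the four-digest MSRE qPCR assay.

Each sample x gene assay consists of four parallel reactions: a mock digest
(Mo, no enzyme), a methylation-sensitive digest (Ms, cuts unmethylated DNA),
a methylation-dependent digest (Md, cuts methylated DNA), and a double digest
(Msd, both enzymes).  Relative input DNA per reaction is ``2**-Ct``; the
digestible denominator is the mock amount minus the double-digest amount
(DNA refractory to digestion).  The hypermethylated and unmethylated
fractions are

    F_HM = C_Ms / (C_Mo - C_Msd)
    F_UM = C_Md / (C_Mo - C_Msd)

with the intermediately methylated fraction defined as the complement
``1 - F_HM - F_UM`` after clipping/normalization.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NO_AMPLIFICATION",
    "QCFlag",
    "CtQuadruple",
    "DigestFractions",
    "amount_from_ct",
    "compute_fractions",
    "fraction_matrix",
]

#: Sentinel for a reaction that never crossed the fluorescence threshold
#: (treated as zero input DNA, the Ct -> infinity limit).
NO_AMPLIFICATION = float("nan")

DIGESTS = ("Mo", "Ms", "Md", "Msd")


class QCFlag(enum.Flag):
    """Quality flags attached to a computed fraction set."""

    OK = 0
    #: digestible denominator (C_Mo - C_Msd) was not positive; no fractions.
    NEG_DENOM = enum.auto()
    #: raw F_HM + F_UM exceeded 1 and both were rescaled by their sum.
    SUM_GT_ONE_RESCALED = enum.auto()
    #: a raw fraction fell outside [0, 1] and was clipped.
    CLIPPED = enum.auto()
    #: mock digest missing; assay not computable.
    NO_MOCK = enum.auto()


def _is_no_amp(ct: float | None) -> bool:
    return ct is None or (isinstance(ct, float) and math.isnan(ct))


@dataclass(frozen=True)
class CtQuadruple:
    """The four digest Ct readings for one sample x gene assay.

    Any reading may be :data:`NO_AMPLIFICATION` (NaN); at least the mock
    digest must be present for the assay to be computable.
    """

    ct_mo: float
    ct_ms: float
    ct_md: float
    ct_msd: float

    def __post_init__(self) -> None:
        for name in ("ct_mo", "ct_ms", "ct_md", "ct_msd"):
            ct = getattr(self, name)
            if not _is_no_amp(ct) and ct <= 0:
                raise ValueError(f"{name} must be a positive cycle count, got {ct}")


@dataclass(frozen=True)
class DigestFractions:
    """Normalized methylation fractions with QC provenance.

    ``f_hm + f_um + f_im == 1`` exactly whenever the QC flags allow a result;
    the raw (pre-clipping) values are retained in ``raw_f_hm``/``raw_f_um``.
    """

    f_hm: float
    f_um: float
    f_im: float
    f_refractory: float
    qc: QCFlag = field(default=QCFlag.OK)
    raw_f_hm: float = float("nan")
    raw_f_um: float = float("nan")

    @property
    def ok(self) -> bool:
        """True when fractions are usable (possibly clipped/rescaled)."""
        return not (self.qc & (QCFlag.NEG_DENOM | QCFlag.NO_MOCK))


def amount_from_ct(ct: float) -> float:
    """Relative initial DNA amount ``2**-ct`` for one reaction.

    :data:`NO_AMPLIFICATION` maps to 0 (the Ct -> infinity limit).  A
    non-positive Ct is a domain error: threshold cycles are strictly positive.
    """
    if _is_no_amp(ct):
        return 0.0
    if ct <= 0:
        raise ValueError(f"Ct must be positive, got {ct}")
    return 2.0 ** (-ct)


def compute_fractions(q: CtQuadruple) -> DigestFractions:
    """Compute hypermethylated/unmethylated/intermediate fractions for one assay.

    Raw fractions are clipped to [0, 1] (``CLIPPED``); if their sum still
    exceeds 1 they are rescaled by the sum (``SUM_GT_ONE_RESCALED``), so the
    reported triple always satisfies ``f_hm + f_um + f_im == 1``.  A
    non-positive digestible denominator yields ``NEG_DENOM`` and NaN
    fractions; a missing mock digest yields ``NO_MOCK``.
    """
    nan = float("nan")
    if _is_no_amp(q.ct_mo):
        return DigestFractions(nan, nan, nan, nan, QCFlag.NO_MOCK)

    c_mo = amount_from_ct(q.ct_mo)
    c_ms = amount_from_ct(q.ct_ms)
    c_md = amount_from_ct(q.ct_md)
    c_msd = amount_from_ct(q.ct_msd)

    f_refractory = c_msd / c_mo
    denom = c_mo - c_msd
    if denom <= 0:
        return DigestFractions(nan, nan, nan, f_refractory, QCFlag.NEG_DENOM)

    raw_hm = c_ms / denom
    raw_um = c_md / denom

    qc = QCFlag.OK
    f_hm = min(max(raw_hm, 0.0), 1.0)
    f_um = min(max(raw_um, 0.0), 1.0)
    if f_hm != raw_hm or f_um != raw_um:
        qc |= QCFlag.CLIPPED
    total = f_hm + f_um
    if total > 1.0:
        f_hm /= total
        f_um /= total
        qc |= QCFlag.SUM_GT_ONE_RESCALED
    f_im = 1.0 - f_hm - f_um
    return DigestFractions(f_hm, f_um, f_im, f_refractory, qc, raw_hm, raw_um)


def fraction_matrix(ct_records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized fraction computation over a tidy Ct table.

    Parameters
    ----------
    ct_records
        Tidy frame with columns ``sample_id, gene, digest, ct`` (one row per
        reaction; ``ct`` NaN for no amplification), as produced by
        :func:`methylprofiler.io_formats.read_ct_table` or the simulator.

    Returns
    -------
    pandas.DataFrame
        One row per (sample_id, gene) with columns ``f_hm, f_um, f_im,
        f_refractory, qc`` (flag names joined by ``|``, ``OK`` when clean).
        Fractions are on the [0, 1] scale; uncomputable assays carry NaN.
    """
    wide = ct_records.pivot_table(
        index=["sample_id", "gene"], columns="digest", values="ct", aggfunc="mean"
    )
    for d in DIGESTS:
        if d not in wide.columns:
            wide[d] = np.nan
    amt = {d: np.where(np.isnan(wide[d].to_numpy()), 0.0, 2.0 ** -wide[d].to_numpy())
           for d in DIGESTS}
    no_mock = np.isnan(wide["Mo"].to_numpy())

    with np.errstate(divide="ignore", invalid="ignore"):
        f_ref = amt["Msd"] / amt["Mo"]
        denom = amt["Mo"] - amt["Msd"]
        raw_hm = amt["Ms"] / denom
        raw_um = amt["Md"] / denom
    neg_denom = (denom <= 0) & ~no_mock

    f_hm = np.clip(raw_hm, 0.0, 1.0)
    f_um = np.clip(raw_um, 0.0, 1.0)
    clipped = (f_hm != raw_hm) | (f_um != raw_um)
    total = f_hm + f_um
    rescaled = total > 1.0
    scale = np.where(rescaled, total, 1.0)
    f_hm = f_hm / scale
    f_um = f_um / scale
    f_im = 1.0 - f_hm - f_um

    bad = no_mock | neg_denom
    for arr in (f_hm, f_um, f_im):
        arr[bad] = np.nan
    f_ref[no_mock] = np.nan

    qc = np.empty(len(wide), dtype=object)
    for i in range(len(wide)):
        flags = []
        if no_mock[i]:
            flags.append("NO_MOCK")
        elif neg_denom[i]:
            flags.append("NEG_DENOM")
        else:
            if clipped[i]:
                flags.append("CLIPPED")
            if rescaled[i]:
                flags.append("SUM_GT_ONE_RESCALED")
        qc[i] = "|".join(flags) if flags else "OK"

    out = pd.DataFrame(
        {
            "f_hm": f_hm,
            "f_um": f_um,
            "f_im": f_im,
            "f_refractory": f_ref,
            "qc": qc,
        },
        index=wide.index,
    ).reset_index()
    return out
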