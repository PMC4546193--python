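"""Hypermethylation calls, prevalence, penetrance signature, and gene classes.

Methylation is reduced to a qualitative trait: a gene is called
hypermethylated in a sample when its hypermethylated DNA fraction exceeds a
threshold (15% in the study design).  Per-group prevalences, a pooled
tumor penetrance (LGD + HGD + CRC, metastatic CRC excluded), a
minimum-penetrance gene signature, and the A-D gene classes all derive from
the resulting binary call matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GROUPS

__all__ = [
    "CallConfig",
    "call_hypermethylated",
    "call_matrix",
    "group_prevalence",
    "combined_penetrance",
    "derive_signature",
    "classify_gene",
    "classify_genes",
    "choose_threshold",
    "reconstruct_counts",
    "signature_analysis",
]

NON_TUMOR_GROUPS = ("Y", "N", "CN", "F", "UCi", "UCa")


@dataclass(frozen=True)
class CallConfig:
    """Thresholds governing calls, the signature, and gene classes.

    threshold_tau
        Hypermethylation call threshold on the fraction scale (default 0.15).
        Calls use strict inequality: ``f_hm > tau``.
    tumor_groups
        Groups pooled for penetrance (default LGD, HGD, CRC; metastatic CRC
        excluded).
    signature_min_penetrance
        Minimum pooled tumor penetrance for signature membership (>=,
        default 0.85).
    group_prevalence_cut
        "More than half of the samples" cut for per-group methylated status
        in class assignment (strict >, default 0.50).
    common_cut
        Pooled all-sample prevalence above which a gene counts as commonly
        methylated (class A; strict >, default 0.95).
    """

    threshold_tau: float = 0.15
    tumor_groups: tuple[str, ...] = ("LGD", "HGD", "CRC")
    signature_min_penetrance: float = 0.85
    group_prevalence_cut: float = 0.50
    common_cut: float = 0.95

    def __post_init__(self) -> None:
        for name in ("threshold_tau", "signature_min_penetrance",
                     "group_prevalence_cut", "common_cut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def call_hypermethylated(f_hm: float, tau: float = 0.15):
    """Binary hypermethylation call: True iff ``f_hm > tau``; NaN stays missing."""
    if f_hm is None or (isinstance(f_hm, float) and np.isnan(f_hm)):
        return np.nan
    return bool(f_hm > tau)


def call_matrix(fractions: pd.DataFrame, tau: float = 0.15) -> pd.DataFrame:
    """Samples x genes fraction matrix -> call matrix (1.0/0.0/NaN)."""
    return (fractions > tau).astype(float).where(fractions.notna())


def group_prevalence(calls: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per gene x group methylated counts, denominators, and fractions.

    ``calls`` is a samples x genes 0/1/NaN matrix; ``meta`` must carry a
    ``group`` column indexed by sample.  Missing calls are excluded from the
    denominator.  Returns a tidy frame with columns ``gene, group, count, n,
    fraction, percent`` (``percent`` rounded to the integer as printed in
    prevalence tables; fraction NaN when n == 0).
    """
    groups = meta.loc[calls.index, "group"]
    rows = []
    for grp, sub in calls.groupby(groups, sort=False):
        n = sub.notna().sum(axis=0)
        count = (sub == 1.0).sum(axis=0)
        frac = count / n.where(n > 0)
        for gene in calls.columns:
            rows.append(
                {
                    "gene": gene,
                    "group": grp,
                    "count": int(count[gene]),
                    "n": int(n[gene]),
                    "fraction": float(frac[gene]) if n[gene] > 0 else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out["percent"] = (out["fraction"] * 100).round(0)
    return out


def combined_penetrance(
    prevalence: pd.DataFrame, tumor_groups: tuple[str, ...] = ("LGD", "HGD", "CRC")
) -> pd.DataFrame:
    """Pooled penetrance per gene over the tumor groups.

    Pools counts and denominators (not an average of fractions): penetrance
    = sum(count) / sum(n) over ``tumor_groups``.  Returns ``gene, count, n,
    penetrance`` with NaN penetrance when the pooled denominator is zero.
    """
    sub = prevalence[prevalence["group"].isin(tumor_groups)]
    pooled = sub.groupby("gene", sort=False)[["count", "n"]].sum().reset_index()
    pooled["penetrance"] = pooled["count"] / pooled["n"].where(pooled["n"] > 0)
    return pooled


def derive_signature(penetrance: pd.DataFrame, min_penetrance: float = 0.85) -> list[str]:
    """Genes whose pooled tumor penetrance is >= ``min_penetrance``.

    Sorted by penetrance descending, ties broken alphabetically.
    """
    hits = penetrance[penetrance["penetrance"] >= min_penetrance]
    hits = hits.sort_values(["penetrance", "gene"], ascending=[False, True])
    return list(hits["gene"])


def classify_gene(per_group: dict[str, float], config: CallConfig = CallConfig(),
                  group_sizes: dict[str, int] | None = None) -> str:
    """Assign one gene to class A, B, C, D, or NONE from per-group prevalence.

    ``per_group`` maps each of the ten groups to its prevalence fraction.
    Classes, applied in order:

    * A — pooled prevalence over all samples exceeds ``common_cut``
      (commonly methylated, normals included);
    * B — prevalent (> ``group_prevalence_cut``) in every tumor group
      including MCRC and in no non-tumor group;
    * C — prevalent in LGD, HGD and CRC but not MCRC, and in no non-tumor
      group;
    * D — prevalent in at least one group;
    * NONE — prevalent nowhere.

    Pooling uses ``group_sizes`` (defaults to the study's cohort sizes).
    Missing groups make the classification indeterminate ("NA").
    """
    from ._tables import GROUP_SIZES

    sizes = group_sizes or GROUP_SIZES
    if any(g not in per_group or per_group[g] is None or np.isnan(per_group[g])
           for g in GROUPS):
        return "NA"
    cut = config.group_prevalence_cut
    pooled = sum(per_group[g] * sizes[g] for g in GROUPS) / sum(sizes[g] for g in GROUPS)
    prevalent = {g for g in GROUPS if per_group[g] > cut}
    tumor_all = {"LGD", "HGD", "CRC", "MCRC"}
    non_tumor = set(NON_TUMOR_GROUPS)
    if pooled > config.common_cut:
        return "A"
    if tumor_all <= prevalent and not (prevalent & non_tumor):
        return "B"
    if {"LGD", "HGD", "CRC"} <= prevalent and "MCRC" not in prevalent \
            and not (prevalent & non_tumor):
        return "C"
    if prevalent:
        return "D"
    return "NONE"


def classify_genes(prevalence: pd.DataFrame, config: CallConfig = CallConfig()) -> pd.Series:
    """Class labels for every gene in a tidy prevalence table."""
    sizes = prevalence.groupby("group")["n"].first().to_dict()
    out = {}
    for gene, sub in prevalence.groupby("gene", sort=False):
        per_group = dict(zip(sub["group"], sub["fraction"]))
        out[gene] = classify_gene(per_group, config, group_sizes=sizes)
    return pd.Series(out, name="gene_class")


def choose_threshold(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    grid: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    tumor_groups: tuple[str, ...] = ("LGD", "HGD", "CRC"),
    normal_groups: tuple[str, ...] = ("Y", "N"),
) -> tuple[float, pd.DataFrame]:
    """Select the call threshold separating normal from tumorous samples.

    For each candidate tau the per-gene Youden's J = sensitivity (tumor
    samples called) + specificity (normal samples not called) - 1 is
    averaged over genes; the tau maximizing mean J wins, ties broken toward
    the smallest tau.  Returns (tau, grid table with mean J per candidate).
    """
    groups = meta.loc[fractions.index, "group"]
    tumor = fractions[groups.isin(tumor_groups)]
    normal = fractions[groups.isin(normal_groups)]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need at least 2 samples per side, got {len(tumor)} tumor / "
            f"{len(normal)} normal"
        )
    rows = []
    for tau in grid:
        sens = (tumor > tau).sum(axis=0) / tumor.notna().sum(axis=0)
        spec = (normal <= tau).sum(axis=0) / normal.notna().sum(axis=0)
        j = (sens + spec - 1.0).mean()
        rows.append({"tau": tau, "mean_youden_j": float(j)})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_youden_j"].idxmax(), "mean_youden_j"]
    tau = float(table.loc[np.isclose(table["mean_youden_j"], best), "tau"].min())
    return tau, table


def reconstruct_counts(printed_percent: float, n: int) -> int:
    """Invert a rounded printed percentage to the underlying integer count.

    Returns the k in [0, n] minimizing ``|100 k / n - printed_percent|``.
    An exact tie between two candidate counts is ambiguous and raises.
    """
    if not 0 <= printed_percent <= 100:
        raise ValueError(f"printed percentage out of range: {printed_percent}")
    if n < 1:
        raise ValueError("n must be >= 1")
    errs = [abs(100.0 * k / n - printed_percent) for k in range(n + 1)]
    best = min(errs)
    hits = [k for k, e in enumerate(errs) if e == best]
    if len(hits) > 1:
        raise ValueError(
            f"ambiguous count for {printed_percent}% of n={n}: candidates {hits}"
        )
    return hits[0]


@dataclass
class SignatureResult:
    """Full per-gene summary: prevalence, penetrance, membership, class."""

    prevalence: pd.DataFrame
    penetrance: pd.DataFrame
    signature: list[str]
    gene_classes: pd.Series
    table: pd.DataFrame = field(repr=False, default=None)


def signature_analysis(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    config: CallConfig = CallConfig(),
    exclude_common: bool = True,
) -> SignatureResult:
    """End-to-end call -> prevalence -> penetrance -> signature -> classes.

    ``exclude_common`` drops commonly-methylated genes (class A: prevalent
    across normals and tumors alike) from signature membership — such genes
    carry no tumor-specific information even at 100% tumor penetrance.
    """
    calls = call_matrix(fractions, config.threshold_tau)
    prev = group_prevalence(calls, meta)
    pen = combined_penetrance(prev, config.tumor_groups)
    classes = classify_genes(prev, config)
    candidates = pen
    if exclude_common:
        common = set(classes[classes == "A"].index)
        candidates = pen[~pen["gene"].isin(common)]
    sig = derive_signature(candidates, config.signature_min_penetrance)

    wide = prev.pivot(index="gene", columns="group", values="fraction")
    table = wide.reindex(columns=[g for g in GROUPS if g in wide.columns])
    table = table.join(pen.set_index("gene")["penetrance"])
    table["in_signature"] = table.index.isin(sig)
    table["gene_class"] = classes
    return SignatureResult(prev, pen, sig, classes, table.reset_index())
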