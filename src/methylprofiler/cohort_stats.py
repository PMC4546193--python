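"""Group summaries, synchronous-pair comparison, and penetrance contrasts.

Implements the cohort-level statistics: per-group mean +/- SD methylation,
the paired comparison of synchronous low-grade-dysplasia/carcinoma lesions
from the same patient, and the contrast between gene hypermethylation
penetrance and driver-mutation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_groups",
    "PairComparison",
    "paired_comparison",
    "compare_penetrance",
]


def summarize_groups(fractions: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of methylation percent per gene x group.

    ``fractions`` is a samples x genes matrix on [0, 1]; output is on the
    percent scale with columns ``gene, group, mean_pct, sd_pct, n``.  The SD
    uses the n-1 denominator; missing cells are excluded with reduced n, a
    single observation yields SD NaN, an empty group yields all-NaN.
    """
    groups = meta.loc[fractions.index, "group"]
    pct = fractions * 100.0
    rows = []
    for grp, sub in pct.groupby(groups, sort=False):
        n = sub.notna().sum(axis=0)
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        for gene in pct.columns:
            rows.append({"gene": gene, "group": grp,
                         "mean_pct": float(mean[gene]), "sd_pct": float(sd[gene]),
                         "n": int(n[gene])})
    return pd.DataFrame(rows)


@dataclass
class PairComparison:
    """Per-pair descriptives and the cohort-level one-sided paired test."""

    per_pair: pd.DataFrame
    n_pairs: int
    mean_diff_level: float
    mean_diff_count: float
    p_level: float | None
    p_count: float | None
    test: str


def paired_comparison(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    tau: float = 0.15,
    test: str = "t",
    union_genes: bool = False,
) -> PairComparison:
    """Compare synchronous LGD-CRC lesion pairs from the same patients.

    For each pair the number of genes called hypermethylated (> ``tau``) and
    the mean methylation percent over the genes methylated in that lesion
    are computed per lesion; ``union_genes`` averages instead over the union
    of genes methylated in either lesion of the pair.  At >= 2 complete
    pairs a one-sided paired test (``"t"`` or ``"wilcoxon"``) of
    LGD > CRC is run on both measures; with fewer pairs only descriptives
    are returned (p-values None).
    """
    paired = meta[meta["pair_id"].notna() & (meta["pair_id"] != "")]
    rows = []
    for pid, sub in paired.groupby("pair_id"):
        lesions = {}
        for r in sub.itertuples():
            if r.sample_id not in fractions.index:
                continue
            lesions[r.group] = fractions.loc[r.sample_id] * 100.0
        if set(lesions) != {"LGD", "CRC"}:
            continue
        called = {g: lesions[g] > tau * 100.0 for g in lesions}
        if union_genes:
            sel = called["LGD"] | called["CRC"]
            called = {"LGD": sel, "CRC": sel}
        row = {"pair_id": pid}
        for g in ("LGD", "CRC"):
            vals = lesions[g][called[g]]
            row[f"count_{g}"] = int(called[g].sum())
            row[f"mean_{g}"] = float(vals.mean()) if len(vals) else np.nan
        row["diff_count"] = row["count_LGD"] - row["count_CRC"]
        row["diff_mean"] = row["mean_LGD"] - row["mean_CRC"]
        rows.append(row)
    per_pair = pd.DataFrame(rows)
    n = len(per_pair)
    if n == 0:
        return PairComparison(per_pair, 0, np.nan, np.nan, None, None, test)
    d_level = per_pair["diff_mean"].to_numpy(dtype=float)
    d_count = per_pair["diff_count"].to_numpy(dtype=float)
    def _paired_t(d: np.ndarray) -> float:
        d = d[~np.isnan(d)]
        if np.std(d, ddof=1) == 0.0:
            # degenerate: identical differences carry no evidence either way
            return 0.0 if d.mean() > 0 else 1.0
        return float(stats.ttest_1samp(d, 0.0, alternative="greater").pvalue)

    p_level = p_count = None
    if n >= 2:
        if test == "t":
            p_level = _paired_t(d_level)
            p_count = _paired_t(d_count)
        elif test == "wilcoxon":
            p_level = float(stats.wilcoxon(d_level[~np.isnan(d_level)],
                                           alternative="greater").pvalue)
            # zero differences are dropped by the signed-rank procedure
            nz = d_count[d_count != 0]
            p_count = float(stats.wilcoxon(nz, alternative="greater").pvalue) if len(nz) \
                else 1.0
        else:
            raise ValueError(f"unknown test {test!r}")
    return PairComparison(
        per_pair, n, float(np.nanmean(d_level)), float(np.mean(d_count)),
        p_level, p_count, test,
    )


def compare_penetrance(
    gene_penetrance: pd.DataFrame,
    mutation_freqs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Contrast gene hypermethylation penetrance with mutation frequency.

    ``gene_penetrance`` has columns ``gene, count, n``; ``mutation_freqs``
    has ``assay, count, n`` (one pooled row per assay).  Both must refer to
    the same tumor sample set (equal n), otherwise the proportions are not
    comparable and an error is raised.  Every (gene, assay) pair is tested
    with Fisher's exact test (two-sided), Bonferroni-corrected over pairs;
    the exact test remains valid for zero-count mutations.
    """
    rows = []
    n_tests = len(gene_penetrance) * len(mutation_freqs)
    for g in gene_penetrance.itertuples():
        for m in mutation_freqs.itertuples():
            if g.n != m.n:
                raise ValueError(
                    f"mismatched sample sets: {g.gene} n={g.n} vs {m.assay} n={m.n}"
                )
            table = [[g.count, g.n - g.count], [m.count, m.n - m.count]]
            p = float(stats.fisher_exact(table).pvalue)
            p_adj = min(1.0, p * n_tests)
            rows.append({
                "gene": g.gene, "assay": m.assay,
                "gene_penetrance": g.count / g.n, "mutation_frequency": m.count / m.n,
                "p_value": p, "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            })
    return pd.DataFrame(rows)
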