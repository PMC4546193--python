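"""Calls, prevalence, penetrance signature, gene classes, threshold choice."""

import math

import numpy as np
import pandas as pd
import pytest

from methylprofiler._tables import GROUP_SIZES, GROUPS
from methylprofiler.calls_signature import (
    CallConfig,
    call_hypermethylated,
    call_matrix,
    choose_threshold,
    classify_gene,
    combined_penetrance,
    derive_signature,
    group_prevalence,
    reconstruct_counts,
    signature_analysis,
)


def test_call_is_strictly_greater_than_threshold():
    assert call_hypermethylated(0.6066, 0.15) is True
    assert call_hypermethylated(0.15, 0.15) is False
    assert math.isnan(call_hypermethylated(float("nan"), 0.15))


def _tiny_cohort():
    # 2 LGD + 2 N samples, 2 genes; geneB missing in one normal
    fractions = pd.DataFrame(
        {"geneA": [0.6, 0.3, 0.02, 0.05], "geneB": [0.2, 0.10, 0.01, np.nan]},
        index=["L1", "L2", "N1", "N2"],
    )
    meta = pd.DataFrame(
        {"sample_id": ["L1", "L2", "N1", "N2"],
         "group": ["LGD", "LGD", "N", "N"]}
    ).set_index("sample_id", drop=False)
    return fractions, meta


def test_group_prevalence_counts_and_missing_handling():
    fractions, meta = _tiny_cohort()
    prev = group_prevalence(call_matrix(fractions, 0.15), meta)
    prev = prev.set_index(["gene", "group"])
    assert prev.loc[("geneA", "LGD"), "count"] == 2
    assert prev.loc[("geneA", "LGD"), "fraction"] == 1.0
    assert prev.loc[("geneB", "LGD"), "count"] == 1
    # the NaN cell leaves the denominator
    assert prev.loc[("geneB", "N"), "n"] == 1


def test_combined_penetrance_pools_counts():
    prev = pd.DataFrame(
        [{"gene": "g", "group": grp, "count": c, "n": n, "fraction": c / n}
         for grp, c, n in (("LGD", 17, 17), ("HGD", 6, 6), ("CRC", 16, 17))]
    )
    pen = combined_penetrance(prev)
    assert pen.loc[0, "penetrance"] == pytest.approx(39 / 40)
    # equals the count-weighted mean of per-group prevalences
    weighted = (17 * 1.0 + 6 * 1.0 + 17 * (16 / 17)) / 40
    assert pen.loc[0, "penetrance"] == pytest.approx(weighted)


def test_derive_signature_sorting_and_bounds():
    pen = pd.DataFrame({"gene": ["b", "a", "c"], "count": [34, 34, 33],
                        "n": [40, 40, 40], "penetrance": [0.85, 0.85, 0.825]})
    assert derive_signature(pen, 0.85) == ["a", "b"]  # >= and alphabetical tie
    assert derive_signature(pen, 1.01) == []
    pen_all = pen.assign(penetrance=1.0)
    assert derive_signature(pen_all, 0.85) == ["a", "b", "c"]


@pytest.mark.parametrize(
    "prevalent, expected",
    [
        (set(GROUPS), "A"),  # everywhere -> commonly methylated
        ({"LGD", "HGD", "CRC", "MCRC"}, "B"),
        ({"LGD", "HGD", "CRC"}, "C"),
        ({"HGD"}, "D"),
        (set(), "NONE"),
    ],
)
def test_classify_gene(prevalent, expected):
    per_group = {g: (0.99 if g in prevalent else 0.1) for g in GROUPS}
    assert classify_gene(per_group, CallConfig(), GROUP_SIZES) == expected


def test_classify_gene_missing_group_is_na():
    per_group = {g: 0.9 for g in GROUPS}
    per_group["UCa"] = float("nan")
    assert classify_gene(per_group, CallConfig(), GROUP_SIZES) == "NA"


def test_tumor_only_prevalence_with_normal_contamination_is_d():
    # prevalent in tumors but also in one normal group -> not B/C
    per_group = {g: 0.1 for g in GROUPS}
    for g in ("LGD", "HGD", "CRC", "N"):
        per_group[g] = 0.8
    assert classify_gene(per_group, CallConfig(), GROUP_SIZES) == "D"


class TestChooseThreshold:
    def _meta(self, n_tumor, n_normal):
        ids = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
        grp = ["LGD"] * n_tumor + ["N"] * n_normal
        return pd.DataFrame({"sample_id": ids, "group": grp}).set_index(
            "sample_id", drop=False)

    def test_perfect_separation_returns_smallest_tau(self):
        meta = self._meta(3, 3)
        fr = pd.DataFrame({"g1": [0.5, 0.55, 0.45, 0.02, 0.01, 0.03]},
                          index=meta.index)
        tau, table = choose_threshold(fr, meta)
        assert tau == 0.05
        assert table["mean_youden_j"].max() == pytest.approx(1.0)

    def test_flat_profile_tie_breaks_to_smallest(self):
        meta = self._meta(3, 3)
        fr = pd.DataFrame({"g1": [0.1] * 6}, index=meta.index)
        tau, _ = choose_threshold(fr, meta)
        assert tau == 0.05

    def test_too_few_samples(self):
        meta = self._meta(1, 3)
        fr = pd.DataFrame({"g1": [0.5, 0.0, 0.0, 0.0]}, index=meta.index)
        with pytest.raises(ValueError, match="at least 2"):
            choose_threshold(fr, meta)

    def test_simulated_cohort_selects_near_fifteen_percent(self, default_cohort,
                                                           default_fractions):
        tau, _ = choose_threshold(default_fractions, default_cohort.meta)
        assert abs(tau - 0.15) <= 0.05 + 1e-12  # within one grid step


class TestReconstructCounts:
    @pytest.mark.parametrize("pct,n,k", [(94, 17, 16), (100, 6, 6), (76, 17, 13),
                                         (83, 6, 5), (57, 7, 4), (92.5, 40, 37)])
    def test_enumerated_examples(self, pct, n, k):
        assert reconstruct_counts(pct, n) == k

    def test_ambiguous_is_error(self):
        with pytest.raises(ValueError, match="ambiguous"):
            reconstruct_counts(25, 2)  # 0/2 and 1/2 equally close

    def test_domain_guards(self):
        with pytest.raises(ValueError):
            reconstruct_counts(101, 10)
        with pytest.raises(ValueError):
            reconstruct_counts(50, 0)


class TestPipelineInvariants:
    def test_permutation_invariance(self, default_cohort, default_fractions):
        meta = default_cohort.meta
        res = signature_analysis(default_fractions, meta)
        rng = np.random.default_rng(0)
        perm = rng.permutation(default_fractions.index)
        res2 = signature_analysis(default_fractions.loc[perm], meta)
        assert res.signature == res2.signature
        assert res.gene_classes.sort_index().equals(res2.gene_classes.sort_index())

    def test_raising_tau_never_increases_prevalence(self, default_cohort,
                                                    default_fractions):
        meta = default_cohort.meta
        lo = group_prevalence(call_matrix(default_fractions, 0.10), meta)
        hi = group_prevalence(call_matrix(default_fractions, 0.20), meta)
        merged = lo.merge(hi, on=["gene", "group"], suffixes=("_lo", "_hi"))
        assert (merged["count_hi"] <= merged["count_lo"]).all()

    def test_raising_min_penetrance_never_grows_signature(self, default_cohort,
                                                          default_fractions):
        meta = default_cohort.meta
        res85 = signature_analysis(default_fractions, meta,
                                   CallConfig(signature_min_penetrance=0.85))
        res95 = signature_analysis(default_fractions, meta,
                                   CallConfig(signature_min_penetrance=0.95))
        assert set(res95.signature) <= set(res85.signature)


def test_call_config_validation():
    with pytest.raises(ValueError):
        CallConfig(threshold_tau=0.0)
    with pytest.raises(ValueError):
        CallConfig(signature_min_penetrance=1.5)
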