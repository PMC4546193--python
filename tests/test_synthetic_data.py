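"""Forward simulator: moment matching, determinism, inversion, structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from methylprofiler._tables import (
    GROUP_MOMENTS,
    GROUP_SIZES,
    GROUPS,
    SIGNATURE_GENES,
    TOP10_PREVALENCE,
)
from methylprofiler.calls_signature import reconstruct_counts
from methylprofiler.fraction_model import fraction_matrix
from methylprofiler.io_formats import pivot_fractions, validate_pairs, SampleMeta
from methylprofiler.synthetic_data import (
    SimulationConfig,
    beta_from_moments,
    default_anchor_fractions,
    simulate_cohort,
    simulate_pairs,
)


class TestBetaFromMoments:
    def test_uniform_closed_form(self):
        a, b = beta_from_moments(50.0, 100.0 / np.sqrt(12.0))
        assert a == pytest.approx(1.0) and b == pytest.approx(1.0)

    def test_moment_equations_solved(self):
        a, b = beta_from_moments(60.66, 25.27)
        assert a == pytest.approx(1.660, abs=5e-3)
        assert b == pytest.approx(1.077, abs=5e-3)
        mean, var = stats.beta.stats(a, b, moments="mv")
        assert 100 * mean == pytest.approx(60.66, abs=1e-9)
        assert 100 * np.sqrt(var) == pytest.approx(25.27, abs=1e-9)

    def test_infeasible_sd_shrunk(self, caplog):
        a, b = beta_from_moments(50.0, 80.0)  # above the 50% Bernoulli bound
        mean, var = stats.beta.stats(a, b, moments="mv")
        assert 100 * mean == pytest.approx(50.0)
        assert np.sqrt(var) == pytest.approx(0.95 * 0.5)

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            beta_from_moments(0.0, 1.0)
        with pytest.raises(ValueError):
            beta_from_moments(100.0, 1.0)


class TestCohortStructure:
    def test_determinism(self):
        a = simulate_cohort(seed=11)
        b = simulate_cohort(seed=11)
        pd.testing.assert_frame_equal(a.ct, b.ct)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.mutations, b.mutations)
        c = simulate_cohort(seed=12)
        assert not a.ct["ct"].equals(c.ct["ct"])

    def test_group_sizes_and_pairs(self, default_cohort):
        meta = default_cohort.meta
        assert meta["group"].value_counts().to_dict() == GROUP_SIZES
        validate_pairs([SampleMeta(**r) for r in
                        meta.to_dict("records")])
        assert meta["pair_id"].notna().sum() == 14  # 7 pairs x 2 lesions

    def test_truth_aligned_with_emitted_assays(self, default_cohort):
        ct_keys = set(map(tuple, default_cohort.ct[["sample_id", "gene"]]
                          .drop_duplicates().itertuples(index=False)))
        truth_keys = list(map(tuple, default_cohort.truth[["sample_id", "gene"]]
                              .itertuples(index=False)))
        assert len(truth_keys) == len(set(truth_keys))
        assert set(truth_keys) == ct_keys

    def test_double_digest_reflects_refractory_floor(self, default_cohort):
        msd = default_cohort.ct.query("digest == 'Msd'")["ct"]
        # 1% refractory DNA -> double digest amplifies, ~log2(100) cycles late
        assert msd.notna().mean() > 0.95
        assert msd.mean() > default_cohort.ct.query("digest == 'Mo'")["ct"].mean()


class TestZeroNoise:
    def test_inversion_recovers_truth_exactly(self):
        cohort = simulate_cohort(SimulationConfig().zero_noise(), seed=5)
        measured = pivot_fractions(fraction_matrix(cohort.ct))
        truth = cohort.truth.pivot(index="sample_id", columns="gene",
                                   values="true_m")
        truth = truth.loc[measured.index, measured.columns]
        err = (measured - truth).abs().to_numpy()
        assert np.nanmax(err) < 1e-9

    def test_no_refractory_means_silent_double_digest(self):
        cohort = simulate_cohort(SimulationConfig().zero_noise(), seed=5)
        assert cohort.ct.query("digest == 'Msd'")["ct"].isna().all()


def _model_mean_pct(gene, grp_idx, anchor):
    """Analytic mean of the (possibly prevalence-anchored) cell distribution."""
    mean, sd = GROUP_MOMENTS[gene][grp_idx]
    if anchor is None or sd <= 0 or mean <= 0 or mean >= 100:
        return mean
    a, b = beta_from_moments(mean, sd)
    tau = 0.15
    c = stats.beta.cdf(tau, a, b)
    mu = a / (a + b)
    part_above = mu * (1.0 - special.betainc(a + 1, b, tau))  # E[X; X > tau]
    e_above = part_above / (1.0 - c) if c < 1 else tau
    e_below = (mu - part_above) / c if c > 0 else tau
    return 100.0 * (anchor * e_above + (1 - anchor) * e_below)


class TestMomentRecovery:
    def test_cell_means_within_three_se_of_model(self, default_cohort):
        """Sample means track the generator's analytic cell means.

        Checked cell-by-cell at 3 SE; with ~550 cells a few exceedances of a
        3-sigma band are expected under the null, so up to 1% are tolerated.
        """
        truth = default_cohort.truth.pivot(index="sample_id", columns="gene",
                                           values="true_m") * 100
        groups = default_cohort.meta["group"]
        anchors = default_anchor_fractions()
        n_checked = n_bad = 0
        for gene in truth.columns:
            for gi, grp in enumerate(GROUPS):
                mean, sd = GROUP_MOMENTS[gene][gi]
                if sd <= 0:
                    continue
                vals = truth.loc[groups == grp, gene]
                model = _model_mean_pct(gene, gi, anchors.get((gene, grp)))
                se = sd / np.sqrt(len(vals))
                n_checked += 1
                if abs(vals.mean() - model) > 3 * se:
                    n_bad += 1
        assert n_checked > 500
        assert n_bad <= 0.01 * n_checked

    def test_anchored_cells_reproduce_printed_counts(self, default_cohort):
        """Exact-count anchoring: true fractions realize the printed
        per-group methylated-case counts for the signature genes."""
        truth = default_cohort.truth.pivot(index="sample_id", columns="gene",
                                           values="true_m")
        groups = default_cohort.meta["group"]
        for gene, row in TOP10_PREVALENCE.items():
            for grp in ("LGD", "HGD", "CRC", "MCRC"):
                k = reconstruct_counts(row[grp], GROUP_SIZES[grp])
                called = (truth.loc[groups == grp, gene] > 0.15).sum()
                assert called == k, (gene, grp)

    def test_bernoulli_anchoring_mode(self):
        config = SimulationConfig(anchor_exact_counts=False)
        cohort = simulate_cohort(config, seed=9)
        truth = cohort.truth.pivot(index="sample_id", columns="gene",
                                   values="true_m")
        groups = cohort.meta["group"]
        # SFRP1 in LGD is anchored at 100%: every Bernoulli draw methylated
        # would be rare; just require a plausible binomial outcome
        called = (truth.loc[groups == "LGD", "SFRP1"] > 0.15).sum()
        assert called >= 13


class TestMutations:
    def test_rates_respected_at_extremes(self):
        rates = {a: {g: 0.0 for g in GROUPS} for a in
                 ("KRAS_c12", "KRAS_c13", "BRAF_V600E")}
        rates["KRAS_c12"]["LGD"] = 1.0
        cohort = simulate_cohort(SimulationConfig(mutation_rates=rates), seed=2)
        muts = cohort.mutations.assign(
            group=cohort.mutations["sample_id"].map(cohort.meta["group"]))
        lgd = muts[(muts.group == "LGD") & (muts.assay == "KRAS_c12")]
        assert (lgd["status"] == "MUT").all()
        rest = muts[~((muts.group == "LGD") & (muts.assay == "KRAS_c12"))]
        assert (rest["status"] == "WT").all()

    def test_normals_never_mutated_by_default(self, default_cohort):
        muts = default_cohort.mutations.assign(
            group=default_cohort.mutations["sample_id"].map(
                default_cohort.meta["group"]))
        normals = muts[muts.group.isin(("Y", "N", "CN", "F", "UCi", "UCa"))]
        assert (normals["status"] == "WT").all()


class TestSimulatePairs:
    def test_structure_and_shift(self):
        fractions, meta = simulate_pairs(n_pairs=7, shift_pct=15.0, seed=0)
        assert len(meta) == 14
        validate_pairs([SampleMeta(**r) for r in meta.to_dict("records")])
        lgd = fractions.loc[meta[meta.group == "LGD"].index]
        crc = fractions.loc[meta[meta.group == "CRC"].index]
        assert lgd.to_numpy().mean() > crc.to_numpy().mean()

    def test_pair_correlation_positive(self):
        rng_means = []
        for seed in range(30):
            fr, meta = simulate_pairs(n_pairs=7, shift_pct=0.0, seed=seed,
                                      genes=("SFRP1",))
            lgd = fr.loc[[f"LGD{i + 1:02d}" for i in range(7)], "SFRP1"].to_numpy()
            crc = fr.loc[[f"CRC{i + 1:02d}" for i in range(7)], "SFRP1"].to_numpy()
            rng_means.append(np.corrcoef(lgd, crc)[0, 1])
        assert np.mean(rng_means) > 0.3
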