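"""Mixture simulation: fractions, effect layout, profiles, mixing."""

import numpy as np
import pytest
from scipy import stats

from ctsdm import (
    EffectMap,
    ReferencePanel,
    SimulationDesign,
    assign_effects,
    draw_fractions,
    effect_size,
    mix,
    preset_design,
    simulate_cell_profiles,
    simulate_dataset,
)


class TestDrawFractions:
    def test_single_cell_type_degenerate_bounds(self):
        d = SimulationDesign(
            cell_types=("A",), fraction_bounds={"A": (1.0, 1.0)}, n=5, snr=1.0
        )
        f = draw_fractions(d, 5, 0)
        assert np.all(f == 1.0)

    def test_five_cell_design_rows_sum_to_one(self):
        d = preset_design("450k")
        f = draw_fractions(d, 500, 1)
        assert f.shape == (500, 5)
        assert np.allclose(f.sum(axis=1), 1.0)
        assert np.all(f >= 0)

    def test_epithelial_mean_fraction_near_interval_midpoint(self):
        """The interval means of the five-cell design sum to 1, so after row
        renormalisation the epithelial mean stays near 0.35."""
        d = preset_design("450k")
        f = draw_fractions(d, 10_000, 2)
        j = d.cell_types.index("Epithelial")
        assert f[:, j].mean() == pytest.approx(0.35, abs=0.01)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(
                cell_types=("A",), fraction_bounds={"A": (0.5, 1.2)}, n=5, snr=1.0
            )


class TestAssignEffects:
    def test_450k_layout_counts_and_disjointness(self):
        d = preset_design("450k")
        em = assign_effects(d, 10_000, 0)
        counts = dict(zip(d.cell_types, em.column_counts))
        assert counts == {
            "Epithelial": 500,
            "Fibroblast": 0,
            "CD4T": 500,
            "Monocyte": 500,
            "B-cell": 0,
        }
        # non-overlapping: at most one affected cell type per CpG
        assert em.truth.sum(axis=1).max() == 1
        assert em.any_effect.sum() == 1500

    @pytest.mark.parametrize(
        "name,total,unique",
        [
            ("epic-1a", 4000, 4000),
            ("epic-1b", 4000, 3500),
            ("epic-2a", 3000, 3000),
            ("epic-2b", 3000, 2500),
        ],
    )
    def test_epic_settings_totals(self, name, total, unique):
        d = preset_design(name)
        em = assign_effects(d, 20_000, 3)
        assert em.column_counts.sum() == total
        assert em.any_effect.sum() == unique
        if name.endswith("b"):
            i, j = d.cell_types.index("CD4T"), d.cell_types.index("CD8T")
            assert np.sum(em.truth[:, i] & em.truth[:, j]) == 500

    def test_zero_counts_give_empty_truth(self):
        d = preset_design("450k")
        d = SimulationDesign(
            cell_types=d.cell_types,
            fraction_bounds=d.fraction_bounds,
            n=10,
            snr=1.0,
        )
        assert not assign_effects(d, 100, 0).truth.any()

    def test_counts_exceeding_p_rejected(self):
        d = preset_design("450k")
        with pytest.raises(ValueError):
            assign_effects(d, 1000, 0)

    def test_counts_are_seed_independent(self):
        d = preset_design("450k", scale=0.2)
        c1 = assign_effects(d, 2000, 1).column_counts
        c2 = assign_effects(d, 2000, 99).column_counts
        assert np.array_equal(c1, c2)


class TestEffectSize:
    def test_is_elementwise_product(self):
        assert effect_size(10, np.array([0.02]))[0] == pytest.approx(0.2)
        assert effect_size(7, np.array([0.05]))[0] == pytest.approx(0.35)
        assert np.all(effect_size(0, np.array([0.01, 0.04])) == 0.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            effect_size(-1, np.array([0.02]))
        with pytest.raises(ValueError):
            effect_size(1, np.array([0.0]))


def _tiny_panel(p=4, k=2, var=1e-24):
    mu = np.full((p, k), 0.5)
    mu[:, 1] = 0.3
    return ReferencePanel(
        cpg_ids=[f"c{i}" for i in range(p)],
        cell_types=[f"t{j}" for j in range(k)],
        mu=mu,
        var=np.full((p, k), var),
        pooled_var=np.full(p, var),
    )


class TestSimulateCellProfiles:
    def test_vanishing_variance_recovers_shifted_means(self):
        panel = _tiny_panel()
        truth = np.zeros((4, 2), dtype=bool)
        truth[1, 0] = True
        em = EffectMap(truth=truth, effect_size=np.full(4, 0.2))
        y = np.array([1, 0])
        prof = simulate_cell_profiles(panel, em, y, 0)
        assert prof[1, 0, 0] == pytest.approx(0.5 + 0.2, abs=1e-9)  # case, planted
        assert prof[1, 0, 1] == pytest.approx(0.5, abs=1e-9)  # control
        assert prof[0, 0, 0] == pytest.approx(0.5, abs=1e-9)  # null CpG

    def test_control_means_recover_panel_means(self):
        panel = _tiny_panel(var=0.0004)
        em = EffectMap(
            truth=np.zeros((4, 2), dtype=bool), effect_size=np.zeros(4)
        )
        y = np.zeros(10_000, dtype=int)
        prof = simulate_cell_profiles(panel, em, y, 1)
        assert np.allclose(prof.mean(axis=2), panel.mu, atol=0.002)

    def test_same_seed_identical(self):
        panel = _tiny_panel(var=0.01)
        em = EffectMap(truth=np.zeros((4, 2), dtype=bool), effect_size=np.zeros(4))
        y = np.array([1, 0, 1])
        assert np.array_equal(
            simulate_cell_profiles(panel, em, y, 7),
            simulate_cell_profiles(panel, em, y, 7),
        )


class TestMix:
    def test_single_cell_type_is_identity(self, rng):
        prof = rng.uniform(0.2, 0.8, (5, 1, 3))
        f = np.ones((3, 1))
        assert np.allclose(mix(prof, f), prof[:, 0, :])

    def test_constant_profiles_convexity(self):
        prof = np.full((2, 3, 4), 0.42)
        f = np.random.default_rng(0).dirichlet(np.ones(3), size=4)
        assert np.allclose(mix(prof, f), 0.42)

    def test_two_component_arithmetic(self):
        prof = np.zeros((1, 2, 1))
        prof[0, 0, 0], prof[0, 1, 0] = 0.2, 0.8
        f = np.array([[0.25, 0.75]])
        assert mix(prof, f)[0, 0] == pytest.approx(0.65)

    def test_unnormalised_fractions_rejected(self):
        prof = np.full((1, 2, 1), 0.5)
        with pytest.raises(ValueError):
            mix(prof, np.array([[0.5, 0.6]]))


class TestSimulateDataset:
    def test_case_control_balance(self, small_design, small_panel):
        ds = simulate_dataset(small_design, small_panel, 0)
        assert ds.phenotype.sum() == 40
        assert ds.n_samples == 80

    def test_bitwise_reproducible(self, small_design, small_panel):
        a = simulate_dataset(small_design, small_panel, 12)
        b = simulate_dataset(small_design, small_panel, 12)
        assert np.array_equal(a.bulk, b.bulk)
        assert np.array_equal(a.fractions, b.fractions)
        assert np.array_equal(a.truth.truth, b.truth.truth)

    def test_clipped_bulk_stays_in_beta_band(self, small_design, small_panel):
        ds = simulate_dataset(small_design, small_panel, 1)
        eps = small_design.epsilon
        assert ds.bulk.min() >= eps and ds.bulk.max() <= 1 - eps

    def test_snr_zero_is_null_calibrated(self, small_panel):
        """With no signal, two-sample t tests at planted CpGs are uniform."""
        design = SimulationDesign(
            cell_types=("CD4T", "Monocyte", "B-cell"),
            fraction_bounds={
                "CD4T": (0.4, 0.6),
                "Monocyte": (0.2, 0.4),
                "B-cell": (0.0, 0.2),
            },
            n=60,
            snr=0.0,
            effects={"CD4T": 100},
            p=400,
        )
        pvals = []
        for r in range(5):
            ds = simulate_dataset(design, small_panel, 100 + r)
            planted = ds.truth.truth[:, 0]
            cases = ds.bulk[np.ix_(planted, ds.phenotype == 1)]
            ctrls = ds.bulk[np.ix_(planted, ds.phenotype == 0)]
            pvals.append(stats.ttest_ind(cases, ctrls, axis=1).pvalue)
        ks = stats.kstest(np.concatenate(pvals), "uniform")
        assert ks.pvalue > 1e-3

    def test_planted_mixture_gap_matches_analytic_expectation(self, small_panel):
        """Case-minus-control bulk mean at a planted (c,k) approaches
        s_c * E[f_k] for large n."""
        design = SimulationDesign(
            cell_types=("CD4T", "Monocyte", "B-cell"),
            fraction_bounds={
                "CD4T": (0.4, 0.6),
                "Monocyte": (0.2, 0.4),
                "B-cell": (0.0, 0.2),
            },
            n=4000,
            snr=11.0,
            effects={"CD4T": 50},
            p=400,
        )
        ds = simulate_dataset(design, small_panel, 2)
        j = 0
        planted = ds.truth.truth[:, j]
        gap = (
            ds.bulk[np.ix_(planted, ds.phenotype == 1)].mean(axis=1)
            - ds.bulk[np.ix_(planted, ds.phenotype == 0)].mean(axis=1)
        )
        expected = ds.truth.effect_size[planted] * ds.fractions[:, j].mean()
        assert np.corrcoef(gap, expected)[0, 1] > 0.9
        assert gap.mean() == pytest.approx(expected.mean(), rel=0.1)

    def test_mean_gap_monotone_in_snr(self, small_panel, small_design):
        """Average planted case-control gap grows with SNR."""
        gaps = []
        for snr in (7.0, 11.0, 15.0):
            d = SimulationDesign(
                cell_types=small_design.cell_types,
                fraction_bounds=small_design.fraction_bounds,
                n=200,
                snr=snr,
                effects=dict(small_design.effects),
                p=400,
            )
            vals = []
            for r in range(3):
                ds = simulate_dataset(d, small_panel, 50 + r)
                planted = ds.truth.any_effect
                vals.append(
                    np.abs(
                        ds.bulk[np.ix_(planted, ds.phenotype == 1)].mean()
                        - ds.bulk[np.ix_(planted, ds.phenotype == 0)].mean()
                    )
                )
            gaps.append(np.mean(vals))
        assert gaps[0] < gaps[1] < gaps[2]

    def test_cell_type_mismatch_rejected(self, small_design):
        from ctsdm import synthesize_reference

        other = synthesize_reference(400, ["X", "Y", "Z"], seed=0)
        with pytest.raises(ValueError):
            simulate_dataset(small_design, other, 0)
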