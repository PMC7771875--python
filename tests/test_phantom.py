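"""Synthetic generators: pool calibration, spectra, phantoms, cohorts."""

import numpy as np
import pytest

from aptwq import (
    CohortSimParams,
    LesionSpec,
    LorentzianPool,
    PhantomSpec,
    TissuePoolSet,
    build_lesion_phantom,
    correct_b0,
    make_pool_set,
    mann_whitney,
    mtr_asym_integral,
    normalize_zspectrum,
    roc_curve,
    simulate_cohort_table,
    simulate_zspectrum,
)
from aptwq.errors import PhantomSpecError
from aptwq.phantom import CLASS_TARGET_PERCENT


def engine_aptw(pools, protocol, asym, **kwargs):
    raw, s0 = simulate_zspectrum(pools, protocol, **kwargs)
    z = normalize_zspectrum(raw, s0, protocol, warn=False)
    return 100.0 * mtr_asym_integral(correct_b0(z, asym), asym)


class TestPoolSets:
    @pytest.mark.parametrize("label", sorted(CLASS_TARGET_PERCENT))
    def test_generator_engine_closure(self, protocol, asym, label):
        # the engine recovers each class's calibrated APTw (closure)
        got = engine_aptw(make_pool_set(label), protocol, asym)
        assert got == pytest.approx(CLASS_TARGET_PERCENT[label], abs=0.2)

    def test_tumour_classes_hit_cohort_averages(self, protocol, asym):
        assert engine_aptw(make_pool_set("HGG"), protocol, asym) == pytest.approx(2.6, abs=0.2)
        assert engine_aptw(make_pool_set("LGG"), protocol, asym) == pytest.approx(1.5, abs=0.2)

    def test_amide_amplitude_ordering(self):
        amps = {lab: make_pool_set(lab).amide_amplitude for lab in ("NAWM", "LGG", "HGG")}
        assert amps["NAWM"] < amps["LGG"] < amps["HGG"]

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown tissue class"):
            make_pool_set("GM")

    def test_zero_amide_symmetric_pools_give_zero(self, protocol, asym):
        pools = TissuePoolSet("toy", (LorentzianPool(0.0, 0.8, 2.0),))
        assert engine_aptw(pools, protocol, asym) == pytest.approx(0.0, abs=1e-9)


class TestSimulateZspectrum:
    def test_seeded_determinism(self, protocol):
        pools = make_pool_set("HGG")
        a, _ = simulate_zspectrum(pools, protocol, noise_sd=0.01, rng=7)
        b, _ = simulate_zspectrum(pools, protocol, noise_sd=0.01, rng=7)
        c, _ = simulate_zspectrum(pools, protocol, noise_sd=0.01, rng=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_noise_mc_mean_matches_noiseless(self, protocol, asym):
        pools = make_pool_set("HGG")
        truth = engine_aptw(pools, protocol, asym)
        rng = np.random.default_rng(123)
        vals = np.array(
            [
                engine_aptw(pools, protocol, asym, noise_sd=0.005, rng=rng)
                for _ in range(200)
            ]
        )
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - truth) <= 2 * se

    def test_rician_noise_supported(self, protocol):
        raw, _ = simulate_zspectrum(
            make_pool_set("LGG"), protocol, noise_sd=0.01, rng=1, noise_model="rician"
        )
        assert (raw >= 0).all()

    def test_oversaturated_pools_rejected(self, protocol):
        pools = TissuePoolSet(
            "bad", (LorentzianPool(0.0, 0.95, 2.0), LorentzianPool(0.0, 0.1, 2.0))
        )
        with pytest.raises(PhantomSpecError, match="saturates"):
            simulate_zspectrum(pools, protocol)

    def test_presaturated_reference_smaller_than_ideal(self, protocol):
        pools = make_pool_set("NAWM")
        _, s0_ideal = simulate_zspectrum(pools, protocol, s0_mode="ideal")
        _, s0_pre = simulate_zspectrum(pools, protocol, s0_mode="presaturated")
        assert s0_pre < s0_ideal


class TestLesionPhantom:
    def test_empty_lesion_list_is_uniform_background(self):
        bundle = build_lesion_phantom(PhantomSpec(grid_shape=(6, 6, 2), noise_sd=0.0))
        assert not bundle.lesion_mask.any()
        assert not bundle.exclusion_mask.any()
        assert np.ptp(bundle.offset_stack, axis=(0, 1, 2)).max() < 1e-9

    def test_necrotic_core_marked_and_disjoint_from_viable(self):
        spec = PhantomSpec(
            grid_shape=(20, 20, 2),
            lesions=(LesionSpec((10, 10, 0), 10.0, "HGG", 4.0),),
            noise_sd=0.0,
        )
        bundle = build_lesion_phantom(spec)
        viable = bundle.lesion_mask & ~bundle.exclusion_mask
        assert bundle.exclusion_mask.any()
        assert not (viable & bundle.exclusion_mask).any()
        assert bundle.truth.loc[0, "tissue"] == "HGG"

    def test_overlapping_lesions_rejected(self):
        spec = PhantomSpec(
            grid_shape=(24, 24, 2),
            lesions=(
                LesionSpec((8, 8, 0), 8.0, "HGG"),
                LesionSpec((12, 12, 0), 8.0, "LGG"),
            ),
        )
        with pytest.raises(PhantomSpecError, match="overlap"):
            build_lesion_phantom(spec)

    def test_lesion_outside_grid_rejected(self):
        spec = PhantomSpec(
            grid_shape=(10, 10, 2), lesions=(LesionSpec((1, 5, 0), 8.0, "HGG"),)
        )
        with pytest.raises(PhantomSpecError, match="outside"):
            build_lesion_phantom(spec)

    def test_seeded_determinism(self):
        spec = PhantomSpec(grid_shape=(8, 8, 2), noise_sd=0.01, seed=5)
        a = build_lesion_phantom(spec)
        b = build_lesion_phantom(spec)
        assert np.array_equal(a.offset_stack, b.offset_stack)


class TestCohortSimulator:
    def test_order_constraint_over_seeds(self):
        for seed in (0, 1, 2):
            tab = simulate_cohort_table(CohortSimParams(seed=seed))
            df = tab.df
            assert (df["aptw_min"] <= df["aptw_mean"]).all()
            assert (df["aptw_mean"] <= df["aptw_max"]).all()

    def test_seeded_determinism(self):
        a = simulate_cohort_table(CohortSimParams(seed=3)).df
        b = simulate_cohort_table(CohortSimParams(seed=3)).df
        assert a.equals(b)

    def test_single_group_table(self):
        tab = simulate_cohort_table(
            CohortSimParams(group_sizes={"HGG": 0, "LGG": 6, "MET": 0})
        )
        assert len(tab) == 6
        assert set(tab.df["group"]) == {"LGG"}

    def test_zero_sd_separated_groups_give_perfect_auc(self):
        params = CohortSimParams(
            group_sizes={"HGG": 5, "LGG": 5, "MET": 0},
            group_params={
                "HGG": {"mean": (3.0, 0.0), "max": (4.0, 0.0), "min": (2.0, 0.0)},
                "LGG": {"mean": (1.0, 0.0), "max": (1.5, 0.0), "min": (0.5, 0.0)},
            },
        )
        tab = simulate_cohort_table(params).df
        r = roc_curve(tab["aptw_mean"], tab["group"], positive="HGG")
        assert r.auc == 1.0

    def test_infeasible_degenerate_means_rejected(self):
        params = CohortSimParams(
            group_sizes={"HGG": 2, "LGG": 0, "MET": 0},
            group_params={"HGG": {"mean": (5.0, 0.0), "max": (4.0, 0.0), "min": (2.0, 0.0)}},
        )
        with pytest.raises(PhantomSpecError, match="infeasible|ordered"):
            simulate_cohort_table(params)

    def test_power_at_reference_effect_sizes(self):
        # at the default HGG/LGG separation, the two-group comparison of the
        # APTw mean should reject at alpha=.05 in well over 80% of cohorts
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            tab = simulate_cohort_table(
                CohortSimParams(group_sizes={"HGG": 16, "LGG": 6, "MET": 0}, seed=seed)
            ).df
            r = mann_whitney(
                tab.loc[tab["group"] == "HGG", "aptw_mean"],
                tab.loc[tab["group"] == "LGG", "aptw_mean"],
            )
            rejections += r.p_value <= 0.05
        assert rejections / n_rep > 0.8


class TestTable1Fixture:
    def test_row_count(self, fixture_cohort):
        assert len(fixture_cohort) == 26

    def test_known_subject_values(self, fixture_cohort):
        df = fixture_cohort.df.set_index("subject_id")
        assert df.loc[8, ["aptw_mean", "aptw_max", "aptw_min"]].tolist() == [5.08, 5.83, 3.93]
        assert df.loc[7, "aptw_mean"] == 0.92
        assert df.loc[7, "group"] == "HGG"

    def test_exclusion_annotations(self, fixture_cohort):
        df = fixture_cohort.df.set_index("subject_id")
        assert set(df.index[df["excluded"]]) == {12, 16, 25, 26}
        assert "progression" in df.loc[12, "exclusion_reason"]
        assert "metastasis" in df.loc[25, "exclusion_reason"]

    def test_range_is_derived_not_stored(self, fixture_cohort):
        df = fixture_cohort.df
        assert np.allclose(df["aptw_range"], df["aptw_max"] - df["aptw_min"])
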