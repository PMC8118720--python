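"""Trait derivation: assay reduction arithmetic, scaling, MAI, table build."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mycotraits.config import AssayGeometry, MicroscopyScaling
from mycotraits.traits import (AssayQCWarning, InvalidStandardError,
                               build_trait_table, emission_coefficient,
                               enzyme_activity, growth_yield,
                               hyphal_length_per_gram,
                               moisture_association_index,
                               quench_coefficient,
                               standardize_per_microcosm)


class TestEmissionCoefficient:
    @pytest.mark.parametrize("std,blank,amount,expected", [
        (2000.0, 0.0, 0.5, 4000.0),
        (1500.0, 500.0, 0.25, 4000.0),
    ])
    def test_arithmetic(self, std, blank, amount, expected):
        assert emission_coefficient(std, blank, amount) == expected

    def test_zero_net_signal_invalid(self):
        with pytest.raises(InvalidStandardError):
            emission_coefficient(1000.0, 1000.0, 0.5)

    def test_nonpositive_amount_rejected(self):
        with pytest.raises(ValueError):
            emission_coefficient(2000.0, 0.0, 0.0)


class TestQuenchCoefficient:
    def test_no_quench_is_one(self):
        assert quench_coefficient(1100.0, 100.0, 1000.0, 0.0) == 1.0

    def test_arithmetic(self):
        assert quench_coefficient(900.0, 100.0, 2000.0, 0.0) == \
            pytest.approx(0.4)

    def test_total_quench_clamped_to_zero(self):
        with pytest.warns(AssayQCWarning):
            assert quench_coefficient(100.0, 100.0, 2000.0, 0.0) == 0.0

    def test_above_range_clamped(self):
        with pytest.warns(AssayQCWarning):
            assert quench_coefficient(4000.0, 0.0, 2000.0, 0.0) == 1.5

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(InvalidStandardError):
            quench_coefficient(900.0, 100.0, 0.0, 0.0)


class TestEnzymeActivity:
    assay = AssayGeometry()  # 75 ml, 0.2 ml/well, 1 h, 0.2 g

    def test_null_signal(self):
        assert enzyme_activity(0.0, 0.0, 0.0, 0.0, 1.0, 4000.0,
                               self.assay) == 0.0

    def test_hand_arithmetic(self):
        # 1000 * 75 / (4000 * 0.2 * 1 * 0.2) = 468.75
        assert enzyme_activity(1000.0, 0.0, 0.0, 0.0, 1.0, 4000.0,
                               self.assay) == pytest.approx(468.75)

    def test_incubation_time_proportionality(self):
        import dataclasses
        doubled = dataclasses.replace(self.assay, incubation_time_h=2.0)
        a1 = enzyme_activity(1000.0, 10.0, 5.0, 1.0, 0.9, 4000.0, self.assay)
        a2 = enzyme_activity(1000.0, 10.0, 5.0, 1.0, 0.9, 4000.0, doubled)
        assert a2 == pytest.approx(a1 / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            enzyme_activity(1.0, 0.0, 0.0, 0.0, 0.0, 4000.0, self.assay)
        with pytest.raises(ValueError):
            enzyme_activity(np.nan, 0.0, 0.0, 0.0, 1.0, 4000.0, self.assay)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_fluorescence_scale_invariance(self, scale):
        """Multiplying every reading (samples, controls, standards) by a
        constant leaves the derived activity unchanged."""
        s, h, c, b, std = 1200.0, 110.0, 90.0, 40.0, 2100.0
        def derive(k):
            f_e = emission_coefficient(k * std, k * b, 0.5)
            q = quench_coefficient(k * s * 0.8, k * h, k * std, k * b)
            return enzyme_activity(k * s, k * h, k * c, k * b, q, f_e,
                                   self.assay)
        assert derive(scale) == pytest.approx(derive(1.0), rel=1e-9)


class TestHyphalLength:
    def test_hand_arithmetic(self):
        scaling = MicroscopyScaling(filter_area_mm2=200.0, field_area_mm2=0.2,
                                    extract_volume_ml=50.0,
                                    filtered_volume_per_filter_ml=5.0,
                                    litter_mass_extracted_g=0.5)
        # 0.002 * 1000 * 10 / 0.5 = 40
        assert hyphal_length_per_gram([0.002], scaling) == pytest.approx(40.0)

    def test_all_zero_fields(self):
        assert hyphal_length_per_gram([0.0, 0.0], MicroscopyScaling()) == 0.0

    def test_mass_proportionality(self):
        import dataclasses
        s1 = MicroscopyScaling()
        s2 = dataclasses.replace(s1, litter_mass_extracted_g=1.0)
        assert hyphal_length_per_gram([0.003], s2) == \
            pytest.approx(hyphal_length_per_gram([0.003], s1) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hyphal_length_per_gram([], MicroscopyScaling())


class TestGrowthYield:
    def test_ratio(self):
        assert growth_yield(10.0, 2.0) == 5.0

    def test_no_growth(self):
        assert growth_yield(0.0, 1.0) == 0.0

    def test_zero_mass_loss_is_undefined(self):
        assert np.isnan(growth_yield(10.0, 0.0))


class TestMAI:
    def test_growth_only_at_4_percent(self):
        assert moisture_association_index(
            {0.04: 3.7, 0.27: 0.0, 0.50: 0.0}) == pytest.approx(4.0)

    def test_growth_only_at_50_percent(self):
        assert moisture_association_index(
            {0.04: 0.0, 0.27: 0.0, 0.50: 12.0}) == pytest.approx(50.0)

    def test_equal_growth_gives_27(self):
        assert moisture_association_index(
            {0.04: 5.0, 0.27: 5.0, 0.50: 5.0}) == pytest.approx(27.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            moisture_association_index({0.04: 0.0, 0.50: 0.0})

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            moisture_association_index({0.27: 5.0})

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=3,
                    max_size=3).filter(lambda h: sum(h) > 0))
    @settings(max_examples=200, deadline=None)
    def test_bounds_hold_for_any_lengths(self, lengths):
        """MAI is a convex combination of the moisture weights x 100."""
        mai = moisture_association_index(dict(zip((0.04, 0.27, 0.50),
                                                  lengths)))
        assert 4.0 - 1e-9 <= mai <= 50.0 + 1e-9


def test_standardize_per_microcosm():
    assert standardize_per_microcosm(468.75, 4.0) == pytest.approx(1875.0)
    assert standardize_per_microcosm(123.0, 0.0) == 0.0
    assert standardize_per_microcosm(0.0, 3.0) == 0.0
    with pytest.raises(ValueError):
        standardize_per_microcosm(1.0, -0.1)


class TestBuildTraitTable:
    def test_default_design_row_counts(self, default_experiment,
                                       default_derived):
        assert len(default_derived.traits) == 90   # 15 isolates x 3 x 2
        assert len(default_derived.mai) == 15
        assert default_derived.log["n_controls_excluded"] == 6

    def test_missing_microscopy_isolate(self, default_experiment):
        tab = default_experiment
        drop = tab.microcosms.loc[tab.microcosms["isolate_id"] == "ISO03",
                                  "microcosm_id"]
        mic = tab.microscopy[~tab.microscopy["microcosm_id"].isin(drop)]
        res = build_trait_table(tab.microcosms, mic, tab.enzyme_plates,
                                tab.config.assay, tab.config.microscopy)
        iso3 = res.traits[res.traits["isolate_id"] == "ISO03"]
        assert iso3["growth_yield_m_per_g"].isna().all()
        assert iso3["activity_BG"].notna().all()
        mai3 = res.mai[res.mai["isolate_id"] == "ISO03"]
        assert mai3.empty or mai3["mai_percent"].isna().all()

    def test_row_order_invariance(self, default_experiment):
        tab = default_experiment
        rng = np.random.default_rng(0)
        def shuffle(df):
            return df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res1 = build_trait_table(tab.microcosms, tab.microscopy,
                                 tab.enzyme_plates, tab.config.assay,
                                 tab.config.microscopy)
        res2 = build_trait_table(shuffle(tab.microcosms),
                                 shuffle(tab.microscopy),
                                 shuffle(tab.enzyme_plates),
                                 tab.config.assay, tab.config.microscopy)
        a = res1.traits.sort_values("microcosm_id").reset_index(drop=True)
        b = res2.traits.sort_values("microcosm_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_orphan_microcosm_rejected(self, default_experiment):
        tab = default_experiment
        bad = tab.microscopy.copy()
        bad.loc[0, "microcosm_id"] = "M999"
        with pytest.raises(ValueError, match="M999"):
            build_trait_table(tab.microcosms, bad, tab.enzyme_plates,
                              tab.config.assay, tab.config.microscopy)

    def test_mass_basis_bookkeeping_cancels_in_yield(self,
                                                     noiseless_experiment):
        """Growth yield is the same whether total length is booked per
        remaining or per initial mass, up to the mass factor itself."""
        tab = noiseless_experiment
        r_rem = build_trait_table(tab.microcosms, tab.microscopy,
                                  tab.enzyme_plates, tab.config.assay,
                                  tab.config.microscopy,
                                  mass_basis="remaining")
        r_ini = build_trait_table(tab.microcosms, tab.microscopy,
                                  tab.enzyme_plates, tab.config.assay,
                                  tab.config.microscopy, mass_basis="initial")
        m = r_rem.traits.merge(r_ini.traits, on="microcosm_id",
                               suffixes=("_rem", "_ini"))
        ratio = (m["total_hyphal_length_m_ini"]
                 / m["total_hyphal_length_m_rem"])
        expected = m["initial_mass_g_rem"] / m["final_mass_g_rem"]
        assert np.allclose(ratio, expected, rtol=1e-9)
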