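"""Intensity-ratio mapping, chemical shift index and region calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rad51quant import (PeakTable, RandomCoilModel, call_interaction_region,
                        disorder_flag, intensity_ratio, secondary_shift,
                        simulate_nmr_titration)
from rad51quant.nmr import RegionCall
from rad51quant.synthetic import synthetic_rad52_cterm_sequence


def table(residues, aas, intensities, ca=None):
    data = {"residue": residues, "aa": list(aas), "intensity": intensities}
    if ca is not None:
        data["ca_shift"] = ca
    return PeakTable(pd.DataFrame(data))


def region_oracle(profile, threshold, min_run, max_gap):
    """Brute-force run enumeration over the observed residues."""
    observed = profile.dropna()
    sub = sorted(observed[observed < threshold].index)
    runs, current = [], []
    for res in sub:
        if current and res - current[-1] - 1 > max_gap:
            runs.append(current)
            current = []
        current.append(res)
    if current:
        runs.append(current)
    return [(r[0], r[-1]) for r in runs if len(r) >= min_run]


class TestPeakTable:
    def test_proline_rows_rejected(self):
        with pytest.raises(ValueError, match="proline"):
            table([1, 2], "AP", [1.0, 1.0])

    def test_non_increasing_residues_rejected(self):
        with pytest.raises(ValueError):
            table([2, 1], "AC", [1.0, 1.0])

    def test_tsv_round_trip(self, tmp_path):
        t = table([1, 3, 4], "ACD", [1.0, 2.0, 0.5], ca=[52.5, 58.2, 54.2])
        path = tmp_path / "peaks.tsv"
        t.to_tsv(path)
        back = PeakTable.from_tsv(path)
        pd.testing.assert_frame_equal(t.data, back.data)


class TestIntensityRatio:
    def test_identical_tables_give_unity(self):
        t = table([1, 2, 3], "ACD", [2.0, 3.0, 4.0])
        np.testing.assert_allclose(intensity_ratio(t, t), 1.0)

    def test_residue_missing_from_bound_is_nan(self):
        free = table([1, 2, 3], "ACD", [1.0, 1.0, 1.0])
        bound = table([1, 3], "AD", [0.5, 0.8])
        ratio = intensity_ratio(bound, free)
        assert np.isnan(ratio.loc[2])
        assert ratio.loc[1] == pytest.approx(0.5)

    def test_zero_free_intensity_names_residue(self):
        free = table([1, 2], "AC", [1.0, 0.0])
        bound = table([1, 2], "AC", [1.0, 1.0])
        with pytest.raises(ValueError, match="2"):
            intensity_ratio(bound, free)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        seq = synthetic_rad52_cterm_sequence()
        free, bound = simulate_nmr_titration(seq, region=(310, 395), attenuation=0.2,
                                             noise_cv=0.05, seed=9, start_residue=206)
        r1 = intensity_ratio(bound, free)
        free2 = PeakTable(free.data.assign(intensity=free.data["intensity"] * c))
        bound2 = PeakTable(bound.data.assign(intensity=bound.data["intensity"] * c))
        r2 = intensity_ratio(bound2, free2)
        np.testing.assert_allclose(r1, r2, rtol=1e-9)
        c1 = call_interaction_region(r1)
        c2 = call_interaction_region(r2)
        assert [(x.start_residue, x.end_residue) for x in c1] == \
               [(x.start_residue, x.end_residue) for x in c2]


class TestSecondaryShift:
    def test_random_coil_input_gives_zero(self):
        rc = RandomCoilModel()
        seq = "ACDEFG"
        coil = rc.predict(seq)
        t = table(list(coil.index), seq, [1.0] * 6, ca=list(coil.values))
        np.testing.assert_allclose(secondary_shift(t, seq, rc), 0.0, atol=1e-12)

    def test_planted_deviation_recovered_exactly(self):
        seq = synthetic_rad52_cterm_sequence()
        planted = {r: 2.0 for r in range(320, 330)}
        free, _ = simulate_nmr_titration(seq, region=(310, 395), attenuation=0.2,
                                         noise_cv=0.0, seed=1, start_residue=206,
                                         ca_deviations=planted)
        delta = secondary_shift(free, seq, start_residue=206)
        for res, value in planted.items():
            if res in delta.index:
                assert delta.loc[res] == pytest.approx(value, abs=1e-9)
        untouched = delta.drop([r for r in planted if r in delta.index])
        np.testing.assert_allclose(untouched, 0.0, atol=1e-9)

    def test_pre_proline_correction_is_table_value(self):
        rc = RandomCoilModel()
        before_p = rc.predict("KPA")  # K followed by P
        before_a = rc.predict("KAA")  # K followed by A
        diff = before_p.iloc[0] - before_a.iloc[0]
        assert diff == pytest.approx(rc.next_residue_corrections["P"])

    def test_sequence_mismatch_rejected(self):
        t = table([1], "A", [1.0], ca=[52.5])
        with pytest.raises(ValueError, match="sequence says"):
            secondary_shift(t, "C")


class TestDisorderFlag:
    def test_all_zero_profile_fully_disordered(self):
        flags, frac = disorder_flag(pd.Series(0.0, index=range(1, 11)))
        assert frac == 1.0 and flags.all()

    def test_structured_stretch_fraction(self):
        profile = pd.Series(0.0, index=range(1, 101))
        profile.loc[41:50] = 3.0
        _, frac = disorder_flag(profile, cutoff=0.5)
        assert frac == pytest.approx(0.9)

    def test_zero_cutoff_counts_exact_zeros(self):
        profile = pd.Series([0.0, 0.1, 0.0, -0.2], index=[1, 2, 3, 4])
        _, frac = disorder_flag(profile, cutoff=0.0)
        assert frac == pytest.approx(0.5)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            disorder_flag(pd.Series(dtype=float))


class TestCallInteractionRegion:
    def test_planted_region_called_exactly_at_zero_noise(self):
        seq = synthetic_rad52_cterm_sequence()
        free, bound = simulate_nmr_titration(seq, region=(310, 395), attenuation=0.2,
                                             noise_cv=0.0, seed=4, start_residue=206)
        calls = call_interaction_region(intensity_ratio(bound, free), threshold=0.5)
        assert len(calls) == 1
        assert (calls[0].start_residue, calls[0].end_residue) == (310, 395)
        assert calls[0].mean_ratio == pytest.approx(0.2)

    def test_flat_profile_gives_no_calls(self):
        profile = pd.Series(1.0, index=range(1, 200))
        assert call_interaction_region(profile) == []

    def test_two_separated_segments(self):
        profile = pd.Series(1.0, index=range(1, 101))
        profile.loc[10:25] = 0.1
        profile.loc[60:80] = 0.2
        calls = call_interaction_region(profile, threshold=0.5, min_run=5, max_gap=3)
        assert [(c.start_residue, c.end_residue) for c in calls] == [(10, 25), (60, 80)]

    def test_matches_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = 80
            observed = rng.random(n) > 0.15
            values = np.where(rng.random(n) < 0.3, 0.2, 1.0)
            profile = pd.Series(np.where(observed, values, np.nan), index=range(1, n + 1))
            calls = call_interaction_region(profile, threshold=0.5, min_run=3, max_gap=2)
            expected = region_oracle(profile, 0.5, 3, 2)
            assert [(c.start_residue, c.end_residue) for c in calls] == expected

    def test_invalid_parameters_rejected(self):
        profile = pd.Series(1.0, index=range(1, 10))
        with pytest.raises(ValueError):
            call_interaction_region(profile, threshold=1.5)
        with pytest.raises(ValueError):
            call_interaction_region(profile, min_run=0)

    def test_region_call_interval_validated(self):
        with pytest.raises(ValueError):
            RegionCall(start_residue=10, end_residue=5, mean_ratio=0.2, n_observed=3)
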