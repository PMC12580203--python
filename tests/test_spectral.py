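"""Frequency-domain statistics against closed forms and brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fpvs.spectral import (
    AmplitudeSpectrum,
    HarmonicSet,
    NoiseWindow,
    amplitude_spectrum,
    average_spectra,
    baseline_correct,
    enumerate_harmonics,
    rank_electrodes,
    roi_mean,
    roi_mean_values,
    select_roi,
    significant_harmonics,
    snr,
    summed_baseline_amplitude,
    zscore,
)


def brute_force_neighbor_stats(amps, window):
    """Independent loop implementation of the local noise statistics."""
    n_ch, n_bins = amps.shape
    mean = np.full_like(amps, np.nan, dtype=float)
    sd = np.full_like(amps, np.nan, dtype=float)
    for c in range(n_ch):
        for b in range(n_bins):
            neigh = []
            ok = True
            for side in (-1, 1):
                for step in range(
                    window.exclude_adjacent + 1,
                    window.exclude_adjacent + window.bins_per_side + 1,
                ):
                    j = b + side * step
                    if not 0 <= j < n_bins:
                        ok = False
                        break
                    neigh.append(amps[c, j])
            if not ok:
                continue
            neigh = sorted(neigh)
            k = window.exclude_extremes
            if k:
                neigh = neigh[k:-k]
            mean[c, b] = np.mean(neigh)
            sd[c, b] = np.std(neigh, ddof=1)
    return mean, sd


def make_spectrum(amps, resolution=1.0, kind="raw"):
    amps = np.atleast_2d(np.asarray(amps, dtype=float))
    freqs = np.arange(amps.shape[1]) * resolution
    labels = [f"E{i}" for i in range(amps.shape[0])]
    return AmplitudeSpectrum(freqs, amps, labels, kind=kind)


# --- amplitude_spectrum -----------------------------------------------------


def test_sixty_second_resolution():
    data = np.zeros((1, 60 * 512))
    spec = amplitude_spectrum(data, 512.0)
    assert spec.resolution == pytest.approx(1 / 60)
    # 2 Hz and all analysis harmonics are exactly bin-aligned (2 Hz = bin 120)
    assert spec.bin_index(2.0) == 120
    for h in (4, 6, 8, 10, 12, 14):
        spec.bin_index(float(h))


def test_cosine_amplitude_is_half_at_its_bin():
    fs, dur, amp, freq = 256.0, 4.0, 0.8, 3.0
    t = np.arange(int(fs * dur)) / fs
    spec = amplitude_spectrum(amp * np.cos(2 * np.pi * freq * t), fs)
    assert spec.value_at(freq, "CH00") == pytest.approx(amp / 2, rel=1e-9)
    others = np.delete(spec.amplitudes[0], spec.bin_index(freq))
    assert np.abs(others).max() < 1e-9


def test_zero_input_zero_spectrum():
    spec = amplitude_spectrum(np.zeros((2, 512)), 256.0)
    assert np.all(spec.amplitudes == 0)


def test_non_integer_second_duration_rejected():
    with pytest.raises(ValueError):
        amplitude_spectrum(np.zeros((1, 300)), 256.0)


# --- local statistics vs brute force ---------------------------------------


@pytest.mark.parametrize(
    "window",
    [NoiseWindow(), NoiseWindow(5), NoiseWindow(8, exclude_adjacent=1),
     NoiseWindow(10, exclude_extremes=2)],
)
def test_local_stats_match_brute_force(window):
    rng = np.random.default_rng(0)
    for _ in range(25):
        amps = rng.random((2, 64)) + 0.1
        spec = make_spectrum(amps)
        mean, sd = brute_force_neighbor_stats(amps, window)
        bl = baseline_correct(spec, window).amplitudes
        sn = snr(spec, window).amplitudes
        zz = zscore(spec, window).amplitudes
        np.testing.assert_allclose(bl, amps - mean, atol=1e-12)
        np.testing.assert_allclose(sn, amps / mean, atol=1e-12)
        np.testing.assert_allclose(zz, (amps - mean) / sd, atol=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_local_stats_match_brute_force_property(seed):
    rng = np.random.default_rng(seed)
    window = NoiseWindow(int(rng.integers(2, 12)))
    amps = rng.lognormal(0, 1, size=(1, 50))
    spec = make_spectrum(amps)
    mean, sd = brute_force_neighbor_stats(amps, window)
    np.testing.assert_allclose(
        baseline_correct(spec, window).amplitudes, amps - mean, atol=1e-10
    )
    np.testing.assert_allclose(
        zscore(spec, window).amplitudes, (amps - mean) / sd, atol=1e-10
    )


def test_flat_spectrum_statistics():
    spec = make_spectrum(np.full((1, 40), 2.5))
    assert np.allclose(baseline_correct(spec).amplitudes[0, 10:-10], 0.0)
    assert np.allclose(snr(spec).amplitudes[0, 10:-10], 1.0)
    # SD of identical neighbors is 0 -> Z undefined, flagged as NaN
    assert np.all(np.isnan(zscore(spec).amplitudes[0, 10:-10]))


def test_linear_ramp_baseline_is_zero():
    spec = make_spectrum(np.arange(40.0))
    bl = baseline_correct(spec).amplitudes[0]
    assert np.allclose(bl[10:-10], 0.0, atol=1e-9)


def test_edge_bins_flagged_undefined():
    spec = make_spectrum(np.random.default_rng(1).random((1, 30)))
    for out in (baseline_correct(spec), snr(spec), zscore(spec)):
        assert np.all(np.isnan(out.amplitudes[0, :10]))
        assert np.all(np.isnan(out.amplitudes[0, -10:]))
        assert np.all(np.isfinite(out.amplitudes[0, 10:20]) | np.isnan(out.amplitudes[0, 10:20]))


def test_isolated_peak_recovered_by_baseline_and_snr():
    floor = 0.2
    amps = np.full((1, 41), floor)
    amps[0, 20] = 2.0  # 10x the floor
    spec = make_spectrum(amps)
    assert baseline_correct(spec).amplitudes[0, 20] == pytest.approx(1.8)
    assert snr(spec).amplitudes[0, 20] == pytest.approx(10.0)


def test_snr_zero_at_zero_bin():
    amps = np.full((1, 41), 0.5)
    amps[0, 20] = 0.0
    assert snr(make_spectrum(amps)).amplitudes[0, 20] == 0.0


def test_zscore_requires_raw_kind():
    spec = make_spectrum(np.ones((1, 40)))
    bl = baseline_correct(spec)
    with pytest.raises(ValueError):
        zscore(bl)


# --- harmonics --------------------------------------------------------------


def test_enumerate_harmonics_paradigm_defaults():
    hset = enumerate_harmonics(2.0, 10.0, 14.0)
    assert hset.harmonics == (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)
    assert len(hset.harmonics) == 7
    assert hset.collisions == frozenset({10.0})
    assert hset.summable == (2.0, 4.0, 6.0, 8.0, 12.0, 14.0)


def test_enumerate_harmonics_edge_cases():
    assert enumerate_harmonics(2.0, 10.0, 1.9).harmonics == ()
    hset = enumerate_harmonics(1.0, 4.0, 8.0)
    assert len(hset.harmonics) == 8
    assert hset.collisions == frozenset({4.0, 8.0})


def z_spectrum(values_by_freq, resolution=1.0, n_bins=20):
    amps = np.zeros((1, n_bins))
    freqs = np.arange(n_bins) * resolution
    for f, v in values_by_freq.items():
        amps[0, int(round(f / resolution))] = v
    return AmplitudeSpectrum(freqs, amps, ["ROI"], kind="zscore")


def test_significant_run_counts():
    hset = enumerate_harmonics(2.0, 10.0, 14.0)
    zs = z_spectrum({2: 5, 4: 4, 6: 3, 8: 2.5, 10: 9, 12: 1, 14: 1})
    assert significant_harmonics(zs, hset)[0] == 4
    assert significant_harmonics(z_spectrum({}), hset)[0] == 0
    # gap at 4 Hz ends the run even though 6 Hz is significant
    zs = z_spectrum({2: 5, 4: 1, 6: 5})
    assert significant_harmonics(zs, hset)[0] == 1


def test_collision_skipped_without_breaking_run():
    hset = enumerate_harmonics(2.0, 10.0, 14.0)
    zs = z_spectrum({2: 5, 4: 5, 6: 5, 8: 5, 10: 0, 12: 5, 14: 5})
    assert significant_harmonics(zs, hset)[0] == 6


def test_unaligned_harmonic_rejected():
    hset = enumerate_harmonics(2.5, 10.0, 5.0)
    zs = z_spectrum({})
    with pytest.raises(ValueError):
        significant_harmonics(zs, hset)


def test_sbl_additivity_and_linearity():
    hset = enumerate_harmonics(2.0, 10.0, 14.0)
    amps = np.zeros((1, 20))
    spec = AmplitudeSpectrum(np.arange(20.0), amps, ["A"], kind="baseline_corrected")
    assert summed_baseline_amplitude(spec, hset)[0] == 0.0
    for f in hset.summable:
        amps[0, int(f)] = 0.1
    assert summed_baseline_amplitude(spec, hset)[0] == pytest.approx(0.6)
    doubled = AmplitudeSpectrum(
        np.arange(20.0), 2 * amps, ["A"], kind="baseline_corrected"
    )
    assert summed_baseline_amplitude(doubled, hset)[0] == pytest.approx(1.2)


def test_sbl_empty_summable_rejected():
    hset = HarmonicSet(2.0, (2.0,), frozenset({2.0}), 2.0)
    spec = AmplitudeSpectrum(
        np.arange(20.0), np.zeros((1, 20)), ["A"], kind="baseline_corrected"
    )
    with pytest.raises(ValueError):
        summed_baseline_amplitude(spec, hset)


# --- ranking / ROI ----------------------------------------------------------


def sbl_table(values):
    rows = []
    for (ch, cond, ses), v in values.items():
        rows.append({"electrode": ch, "condition": cond, "session": ses, "sbl": v})
    return pd.DataFrame(rows)


def test_rank_by_max_over_cells():
    tab = sbl_table(
        {
            ("A", "c1", "s1"): 0.1, ("A", "c1", "s2"): 0.9,
            ("B", "c1", "s1"): 0.5, ("B", "c1", "s2"): 0.4,
            ("C", "c1", "s1"): 0.2, ("C", "c1", "s2"): 0.2,
        }
    )
    assert rank_electrodes(tab) == ["A", "B", "C"]
    assert select_roi(rank_electrodes(tab), 2) == ("A", "B")
    assert select_roi(rank_electrodes(tab), 3) == ("A", "B", "C")


def test_rank_ties_break_by_label():
    tab = sbl_table({(ch, "c", "s"): 1.0 for ch in "DBCA"})
    assert rank_electrodes(tab) == ["A", "B", "C", "D"]


def test_select_roi_k_too_large():
    with pytest.raises(ValueError):
        select_roi(["A", "B"], 3)


def test_roi_mean_examples():
    spec = make_spectrum(np.arange(10.0)[None, :].repeat(3, axis=0) * [[1], [2], [3]])
    single = roi_mean(spec, ["E1"])
    np.testing.assert_allclose(single.amplitudes[0], spec.amplitudes[1])
    values = [1.0, 2.0, 3.0, 4.0, 5.0]
    labels = ["A", "B", "C", "D", "E"]
    assert roi_mean_values(values, labels, labels) == pytest.approx(3.0)
    # permutation invariance
    perm = [3, 1, 4, 0, 2]
    assert roi_mean_values(
        [values[i] for i in perm], [labels[i] for i in perm], labels
    ) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        roi_mean(spec, [])


def test_average_spectra_group_mean():
    a = make_spectrum(np.ones((1, 12)))
    b = make_spectrum(3 * np.ones((1, 12)))
    g = average_spectra([a, b])
    assert np.allclose(g.amplitudes, 2.0)
    with pytest.raises(ValueError):
        average_spectra([a, make_spectrum(np.ones((1, 13)))])
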