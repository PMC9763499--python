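"""The eight-step spectrogram pipeline: unit checks, oracles and invariants."""

import numpy as np
import pytest

from callfinder.audio import Waveform
from callfinder.config import PreprocessingConfig
from callfinder.preprocessing import (
    DB_FLOOR,
    NormalizedClip,
    PowerSpectrogram,
    add_noise,
    compress_frequency,
    fit_to_length,
    normalize,
    preprocess_clip,
    random_augment,
    stft_power,
    to_db,
)


def _spec(values, freqs=None, times=None):
    values = np.asarray(values, dtype=float)
    f, t = values.shape
    freqs = np.arange(f, dtype=float) * 100 if freqs is None else np.asarray(freqs, float)
    times = np.arange(t, dtype=float) * 0.01 if times is None else np.asarray(times, float)
    return PowerSpectrogram(values=values, freq_axis=freqs, time_axis=times)


# ---------------------------------------------------------------- stft_power

def test_stft_zero_signal_gives_zero_spectrogram():
    cfg = PreprocessingConfig()
    spec = stft_power(Waveform(np.zeros(4000), 8000), cfg)
    assert spec.shape[0] == cfg.fft_window_length // 2 + 1
    assert np.all(spec.values == 0)


def test_stft_peak_bin_matches_analytic_frequency():
    # 1 kHz sine, 1024-point window at 16 kHz -> analytic bin f*N/sr = 64
    sr = 16000
    cfg = PreprocessingConfig(target_sample_rate=sr, fft_window_length=1024,
                              fft_hop=256, f_min=50, f_max=8000)
    sine = np.sin(2 * np.pi * 1000 * np.arange(sr) / sr)
    spec = stft_power(Waveform(sine, sr), cfg)
    assert np.argmax(spec.values.mean(axis=1)) == 64


def test_stft_parseval_energy_per_frame(rng):
    sr, win, hop = 8000, 256, 128
    cfg = PreprocessingConfig(fft_window_length=win, fft_hop=hop)
    x = rng.standard_normal(2000)
    spec = stft_power(Waveform(x, sr), cfg)
    from scipy.signal import get_window

    window = get_window("hann", win, fftbins=True)
    for frame_idx in [0, 3, spec.shape[1] - 1]:
        start = frame_idx * hop
        frame = x[start : start + win] * window
        # one-sided power: double every bin except DC and Nyquist
        p = spec.values[:, frame_idx].copy()
        full = p[0] + p[-1] + 2 * p[1:-1].sum()
        np.testing.assert_allclose(full / win, np.sum(frame ** 2), rtol=1e-9)


def test_stft_rejects_window_longer_than_signal():
    cfg = PreprocessingConfig(fft_window_length=512, fft_hop=128)
    with pytest.raises(ValueError):
        stft_power(Waveform(np.zeros(100), 8000), cfg)


# ------------------------------------------------------------ random_augment

def test_identity_intervals_leave_spectrogram_unchanged(rng):
    cfg = PreprocessingConfig(intensity_interval=(0, 0), pitch_interval=(1, 1),
                              time_interval=(1, 1))
    s = _spec(rng.random((20, 30)))
    out = random_augment(s, cfg, rng)
    np.testing.assert_array_equal(out.values, s.values)


def test_fixed_intensity_scales_power(rng):
    cfg = PreprocessingConfig(intensity_interval=(6, 6), pitch_interval=(1, 1),
                              time_interval=(1, 1))
    s = _spec(rng.random((10, 10)))
    out = random_augment(s, cfg, rng)
    np.testing.assert_allclose(out.values, s.values * 10 ** 0.6, rtol=1e-12)


def test_time_stretch_column_source_map(rng):
    cfg = PreprocessingConfig(intensity_interval=(0, 0), pitch_interval=(1, 1),
                              time_interval=(2, 2))
    s = _spec(rng.random((5, 100)))
    out = random_augment(s, cfg, rng)
    assert out.values.shape[1] == 200
    for j in range(200):  # brute-force index map
        np.testing.assert_array_equal(out.values[:, j], s.values[:, j // 2])


def test_augmentation_is_deterministic_under_seed(rng):
    cfg = PreprocessingConfig(augment=True)
    s = _spec(rng.random((30, 40)))
    a = random_augment(s, cfg, np.random.default_rng(7))
    b = random_augment(s, cfg, np.random.default_rng(7))
    np.testing.assert_array_equal(a.values, b.values)


# -------------------------------------------------------- compress_frequency

def test_compression_identity_when_rows_already_match():
    cfg = PreprocessingConfig(f_min=500, f_max=4000, n_freq_bins=256)
    freqs = np.linspace(500, 4000, 256)
    values = np.random.default_rng(0).random((256, 8))
    out = compress_frequency(_spec(values, freqs=freqs), cfg)
    np.testing.assert_array_equal(out.values, values)


def test_compression_two_bin_example():
    cfg = PreprocessingConfig(target_sample_rate=8000, f_min=0.0, f_max=300,
                              n_freq_bins=2)
    values = np.arange(4, dtype=float)[:, None] * np.ones((1, 3))
    out = compress_frequency(_spec(values, freqs=[0, 100, 200, 300]), cfg)
    np.testing.assert_array_equal(out.values[0], values[0])
    np.testing.assert_array_equal(out.values[1], values[3])


def test_out_of_band_rows_never_contribute():
    cfg = PreprocessingConfig(target_sample_rate=24000, f_min=100, f_max=2000,
                              n_freq_bins=8)
    freqs = np.array([150.0, 1000.0, 1900.0, 10000.0])
    values = np.zeros((4, 5))
    values[3] = 99.0  # the 10 kHz row
    out = compress_frequency(_spec(values, freqs=freqs), cfg)
    assert np.all(out.values < 99.0)


def test_compression_matches_bruteforce_nearest_neighbor(rng):
    for _ in range(100):
        f = int(rng.integers(3, 40))
        t = int(rng.integers(1, 8))
        freqs = np.sort(rng.uniform(0, 4000, size=f))
        freqs += np.arange(f) * 1e-6  # enforce strictly increasing
        values = rng.random((f, t))
        f_min = float(rng.uniform(0, 1500))
        f_max = float(rng.uniform(f_min + 200, 4000))
        in_band = [i for i in range(f) if f_min <= freqs[i] <= f_max]
        if not in_band:
            continue
        n_bins = int(rng.integers(1, 16))
        cfg = PreprocessingConfig(target_sample_rate=8000, f_min=f_min, f_max=f_max,
                                  n_freq_bins=n_bins)
        out = compress_frequency(_spec(values, freqs=freqs), cfg)
        targets = [(f_min + f_max) / 2] if n_bins == 1 else np.linspace(f_min, f_max, n_bins)
        for row, target in enumerate(targets):
            best = min(in_band, key=lambda i: abs(freqs[i] - target))
            np.testing.assert_array_equal(out.values[row], values[best])


def test_compression_errors_without_band_overlap():
    cfg = PreprocessingConfig(target_sample_rate=16000, f_min=5000, f_max=6000)
    with pytest.raises(ValueError):
        compress_frequency(_spec(np.ones((4, 4)), freqs=[0, 100, 200, 300]), cfg)


# ------------------------------------------------------------------ add_noise

def test_snr_zero_db_equal_powers_gives_unit_alpha(rng):
    cfg = PreprocessingConfig(snr_interval=(0, 0), pitch_interval=(1, 1),
                              time_interval=(1, 1))
    s = _spec(np.full((4, 6), 2.0))
    noise = _spec(np.full((4, 6), 2.0))
    out = add_noise(s, noise, cfg, rng)
    np.testing.assert_allclose(out.values, 4.0, rtol=1e-12)


def test_snr_ten_db_equal_powers_gives_tenth_alpha(rng):
    cfg = PreprocessingConfig(snr_interval=(10, 10), pitch_interval=(1, 1),
                              time_interval=(1, 1))
    s = _spec(np.full((4, 6), 2.0))
    noise = _spec(np.full((4, 6), 2.0))
    out = add_noise(s, noise, cfg, rng)
    np.testing.assert_allclose(out.values - s.values, 0.2, rtol=1e-12)


@pytest.mark.parametrize("snr_db", [-7.5, 0.0, 3.3, 12.0])
def test_realized_snr_matches_drawn_value(snr_db, rng):
    # recompute the mean-power ratio of the two added components post-hoc
    cfg = PreprocessingConfig(snr_interval=(snr_db, snr_db))
    s = _spec(rng.random((16, 24)) + 0.1)
    noise = _spec(rng.random((16, 40)) + 0.1)
    out = add_noise(s, noise, cfg, np.random.default_rng(3))
    added = out.values - s.values
    realized = 10 * np.log10(s.values.mean() / added.mean())
    assert abs(realized - snr_db) < 1e-9


def test_zero_noise_spectrogram_is_rejected(rng):
    cfg = PreprocessingConfig()
    with pytest.raises(ValueError):
        add_noise(_spec(np.ones((4, 4))), _spec(np.zeros((4, 4))), cfg, rng)


# ------------------------------------------------------- to_db and normalize

def test_db_conversion_values():
    s = _spec([[1.0, 100.0, 0.0]])
    out = to_db(s)
    np.testing.assert_allclose(out[0], [0.0, 20.0, 10 * np.log10(DB_FLOOR)])


def test_minmax_normalization_endpoints():
    cfg = PreprocessingConfig(normalization_mode="minmax")
    np.testing.assert_allclose(
        normalize(np.array([[-10.0, 0.0, 10.0]]), cfg), [[0.0, 0.5, 1.0]]
    )


def test_minmax_constant_matrix_maps_to_zeros():
    cfg = PreprocessingConfig(normalization_mode="minmax")
    assert np.all(normalize(np.full((3, 3), 5.0), cfg) == 0)


def test_db_normalization_endpoints_and_clipping():
    cfg = PreprocessingConfig(normalization_mode="db", min_db=-100, ref_db=20)
    out = normalize(np.array([[-100.0, 20.0, -160.0, 50.0]]), cfg)
    np.testing.assert_allclose(out, [[0.0, 1.0, 0.0, 1.0]])


# --------------------------------------------------------------- fit_to_length

def test_fit_identity_when_width_matches():
    cfg = PreprocessingConfig(sequence_length=2.048, target_sample_rate=8000, fft_hop=128)
    assert cfg.t_net == 128
    x = np.random.default_rng(0).random((4, 128))
    out = fit_to_length(x, cfg, mode="center")
    np.testing.assert_array_equal(out.values, x)


def test_fit_center_pads_symmetrically():
    cfg = PreprocessingConfig(sequence_length=2.048, target_sample_rate=8000, fft_hop=128)
    x = np.ones((4, 100))
    out = fit_to_length(x, cfg, mode="center")
    assert out.values.shape == (4, 128)
    assert np.all(out.values[:, :14] == 0) and np.all(out.values[:, -14:] == 0)
    assert np.all(out.values[:, 14:114] == 1)


def test_fit_center_crop_offset():
    cfg = PreprocessingConfig(sequence_length=2.048, target_sample_rate=8000, fft_hop=128)
    x = (np.arange(150)[None, :] / 149.0) * np.ones((2, 1))
    out = fit_to_length(x, cfg, mode="center")
    np.testing.assert_array_equal(out.values[0], np.arange(11, 139) / 149.0)


def test_fit_random_requires_rng():
    cfg = PreprocessingConfig()
    with pytest.raises(ValueError):
        fit_to_length(np.ones((2, 10)), cfg, mode="random")


# ------------------------------------------------------------- full pipeline

@pytest.mark.parametrize("mode", ["minmax", "db"])
def test_pipeline_shape_and_range_contract(mode, rng):
    cfg = PreprocessingConfig(n_freq_bins=64, normalization_mode=mode, augment=True)
    w = Waveform(rng.standard_normal(8000) * 0.3, 8000)
    noise_pool = [Waveform(rng.standard_normal(4000) * 0.3, 8000)]
    clip = preprocess_clip(w, cfg, noise_pool=noise_pool, rng=np.random.default_rng(5))
    assert clip.values.shape == (64, cfg.t_net)
    assert clip.values.min() >= 0 and clip.values.max() <= 1


def test_pipeline_deterministic_without_augmentation(rng):
    cfg = PreprocessingConfig(n_freq_bins=32)
    w = Waveform(rng.standard_normal(6000) * 0.2, 8000)
    a = preprocess_clip(w, cfg)
    b = preprocess_clip(w, cfg)
    np.testing.assert_array_equal(a.values, b.values)


def test_pipeline_deterministic_under_seed_with_augmentation(rng):
    cfg = PreprocessingConfig(n_freq_bins=32, augment=True)
    w = Waveform(rng.standard_normal(6000) * 0.2, 8000)
    a = preprocess_clip(w, cfg, rng=np.random.default_rng(11))
    b = preprocess_clip(w, cfg, rng=np.random.default_rng(11))
    np.testing.assert_array_equal(a.values, b.values)


def test_tone_concentrates_energy_at_center_row(rng):
    cfg = PreprocessingConfig(n_freq_bins=64, normalization_mode="minmax")
    f_center = (cfg.f_min + cfg.f_max) / 2
    t = np.arange(8000) / 8000
    tone = preprocess_clip(Waveform(np.sin(2 * np.pi * f_center * t), 8000), cfg)
    white = preprocess_clip(Waveform(rng.standard_normal(8000) * 0.5, 8000), cfg)

    def center_concentration(clip):
        row_max = clip.values.max(axis=1)
        return row_max[31:33].max() / row_max.sum()

    assert center_concentration(tone) > center_concentration(white)


@pytest.mark.parametrize("seq_len,hop", [(0.5, 128), (1.0, 64), (0.25, 256)])
def test_t_net_follows_sequence_length(seq_len, hop):
    cfg = PreprocessingConfig(sequence_length=seq_len, fft_hop=hop)
    assert cfg.t_net == int(round(seq_len * 8000 / hop))
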