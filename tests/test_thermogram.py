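"""Synthetic thermogram sequences, matrix I/O and ROI series extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thyrotherm import fem
from thyrotherm.thermogram import (
    CAMERA_RANGE,
    Thermogram,
    ThermogramSequence,
    ThermogramValidationError,
    patient_series,
    read_sequence,
    read_thermogram_matrix,
    synthesize_thermogram_sequence,
    window_mean,
    write_sequence,
    write_thermogram_matrix,
)


@pytest.fixture(scope="module")
def small_sequence(protocol_default):
    return synthesize_thermogram_sequence(
        protocol_default, frame_shape=(64, 96), noise_sd=0.0, seed=0
    )


def test_default_sequence_shape_and_count(protocol_default):
    seq = synthesize_thermogram_sequence(protocol_default, noise_sd=0.0, seed=0)
    assert len(seq) == 20
    assert seq.frames[0].shape == (480, 640)
    assert np.all(np.diff([f.timestamp for f in seq.frames]) == 15.0)


def test_noiseless_marked_pixel_equals_simulated_front_temperature(
    protocol_default, small_sequence
):
    res = protocol_default
    for frame, field in zip(small_sequence.frames, res.reheating_fields[1:]):
        expected = fem.evaluate_field(field, res.probes.front_of_nodule)
        r, c = frame.marked_point
        assert frame.values[r, c] == expected


def test_noiseless_patient_series_tracks_simulation(protocol_default):
    seq = synthesize_thermogram_sequence(protocol_default, noise_sd=0.0, seed=0)
    ps = patient_series(seq)
    truth = np.array(
        [
            fem.evaluate_field(f, protocol_default.probes.front_of_nodule)
            for f in protocol_default.reheating_fields[1:]
        ]
    )
    assert np.abs(ps.values - truth).max() < 0.05


def test_background_noise_sd_recovered(protocol_default):
    seq = synthesize_thermogram_sequence(
        protocol_default, frame_shape=(480, 640), noise_sd=0.04, seed=7
    )
    # rows far above the rendered band are pure background + noise
    bg = seq.frames[0].values[:200, :]
    assert bg.size > 1e5
    assert 0.039 <= bg.std() <= 0.041


def test_fixed_seed_sequences_are_bit_identical(protocol_default):
    a = synthesize_thermogram_sequence(
        protocol_default, frame_shape=(64, 96), noise_sd=0.04, seed=11
    )
    b = synthesize_thermogram_sequence(
        protocol_default, frame_shape=(64, 96), noise_sd=0.04, seed=11
    )
    assert all(
        np.array_equal(x.values, y.values) for x, y in zip(a.frames, b.frames)
    )
    c = synthesize_thermogram_sequence(
        protocol_default, frame_shape=(64, 96), noise_sd=0.04, seed=12
    )
    assert not np.array_equal(a.frames[0].values, c.frames[0].values)


def test_window_averaging_suppresses_noise_by_window_size(protocol_default):
    """sd of (noisy ROI - noiseless ROI) ~ noise_sd / 11 for an 11x11 mean."""
    clean = synthesize_thermogram_sequence(
        protocol_default, frame_shape=(48, 64), noise_sd=0.0, seed=0
    )
    base = patient_series(clean).values
    diffs = []
    for seed in range(50):
        noisy = synthesize_thermogram_sequence(
            protocol_default, frame_shape=(48, 64), noise_sd=0.04, seed=seed
        )
        diffs.extend(patient_series(noisy).values - base)
    diffs = np.asarray(diffs)
    expected_sd = 0.04 / 11
    se = expected_sd / np.sqrt(2 * len(diffs))
    assert abs(diffs.std() - expected_sd) < 3 * se


def test_window_mean_constant_and_gradient_frames():
    const = Thermogram(values=np.full((32, 32), 30.0))
    assert window_mean(const, (16, 16)) == 30.0
    # linear column gradient: the symmetric mean equals the centre pixel
    grad = Thermogram(values=np.tile(np.arange(32.0), (32, 1)))
    assert window_mean(grad, (16, 16)) == grad.values[16, 16]


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_window_mean_matches_brute_force_loop(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(20.0, 40.0, size=(24, 30))
    frame = Thermogram(values=values)
    r, c = int(rng.integers(5, 19)), int(rng.integers(5, 25))
    total = 0.0
    for i in range(r - 5, r + 6):
        for j in range(c - 5, c + 6):
            total += values[i, j]
    assert window_mean(frame, (r, c)) == pytest.approx(total / 121, abs=1e-12)


def test_window_mean_border_and_size_validation():
    frame = Thermogram(values=np.full((20, 20), 30.0))
    with pytest.raises(ValueError, match="border"):
        window_mean(frame, (3, 10))
    with pytest.raises(ValueError, match="border"):
        window_mean(frame, (10, 17))
    with pytest.raises(ValueError, match="odd"):
        window_mean(frame, (10, 10), size=10)


def test_patient_series_equals_framewise_window_means(small_sequence):
    ps = patient_series(small_sequence)
    assert len(ps) == 20
    assert ps.spacing == 15.0
    mark = small_sequence.frames[0].marked_point
    for i, frame in enumerate(small_sequence.frames):
        assert ps.values[i] == window_mean(frame, mark)


def test_patient_series_propagates_window_errors(small_sequence):
    frames = [
        Thermogram(values=f.values, timestamp=f.timestamp, marked_point=(1, 1))
        for f in small_sequence.frames
    ]
    seq = ThermogramSequence(frames=frames)
    with pytest.raises(ValueError, match="frame 0"):
        patient_series(seq)


def test_matrix_roundtrip_is_exact(tmp_path, rng):
    values = rng.uniform(20.0, 40.0, size=(17, 23))
    frame = Thermogram(values=values)
    path = tmp_path / "frame.csv"
    write_thermogram_matrix(frame, path)
    again = read_thermogram_matrix(path)
    assert np.array_equal(again.values, values)
    assert again.shape == (17, 23)


def test_matrix_parser_accepts_semicolon_decimal_comma(tmp_path):
    path = tmp_path / "euro.csv"
    path.write_text("30,5;31,0;29,25\n30,0;30,1;30,2\n")
    frame = read_thermogram_matrix(path)
    assert frame.shape == (2, 3)
    assert frame.values[0, 2] == 29.25


def test_matrix_parser_rejects_ragged_rows(tmp_path):
    path = tmp_path / "ragged.csv"
    path.write_text("30.0,31.0\n30.0,30.1,30.2\n")
    with pytest.raises(ThermogramValidationError, match="ragged"):
        read_thermogram_matrix(path)


def test_out_of_camera_range_values_rejected(tmp_path):
    path = tmp_path / "hot.csv"
    path.write_text("30.0,2500.0\n30.0,30.1\n")
    with pytest.raises(ThermogramValidationError, match=r"-40.*2000"):
        read_thermogram_matrix(path)
    with pytest.raises(ThermogramValidationError):
        Thermogram(values=np.array([[25.0, -100.0]]))
    assert CAMERA_RANGE == (-40.0, 2000.0)


def test_sequence_directory_roundtrip(tmp_path, protocol_default):
    seq = synthesize_thermogram_sequence(
        protocol_default, frame_shape=(32, 48), noise_sd=0.04, seed=5
    )
    write_sequence(seq, tmp_path / "seq")
    again = read_sequence(tmp_path / "seq")
    assert len(again) == len(seq)
    assert again.frames[0].marked_point == seq.frames[0].marked_point
    assert all(
        np.array_equal(a.values, b.values)
        for a, b in zip(seq.frames, again.frames)
    )
    ps_a, ps_b = patient_series(seq), patient_series(again)
    assert np.array_equal(ps_a.values, ps_b.values)


def test_sequence_validation():
    f1 = Thermogram(values=np.full((8, 8), 30.0), timestamp=0.0, marked_point=(4, 4))
    f2 = Thermogram(values=np.full((8, 9), 30.0), timestamp=15.0, marked_point=(4, 4))
    with pytest.raises(ThermogramValidationError):
        ThermogramSequence(frames=[f1, f2])
    with pytest.raises(ThermogramValidationError):
        ThermogramSequence(frames=[])
    with pytest.raises(ThermogramValidationError):
        Thermogram(values=np.full((8, 8), 30.0), marked_point=(8, 0))
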