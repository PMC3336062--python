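import numpy as np
import pandas as pd
import pytest

from hmfuse.preprocess import (
    BinTable,
    Scaler,
    SpectraBlock,
    Spectrum,
    ai_bin,
    als_baseline,
    apply_scaler,
    autoscale,
    preprocess_block,
    ptw_align,
    total_area_normalize,
)


def _peaky(n=600, centers=(150, 300, 430), width=4.0):
    """Compact Gaussian peaks: exactly zero (to machine precision) off-peak."""
    x = np.zeros(n)
    i = np.arange(n)
    for c in centers:
        x += 8.0 * np.exp(-0.5 * ((i - c) / width) ** 2)
    return x


# ---------------------------------------------------------------- ALS
def test_als_recovers_constant_baseline():
    x = _peaky() + 3.7
    z, corrected = als_baseline(x, lam=1e9, p=1e-6)
    assert np.max(np.abs(z - 3.7)) < 1e-6
    # away from peaks, the corrected signal must be ~0
    quiet = np.r_[0:100, 500:600]
    assert np.max(np.abs(corrected[quiet])) < 1e-6


def test_als_recovers_affine_baseline():
    n = 600
    t = np.arange(n)
    base = 1.5 + 0.004 * t
    x = _peaky(n) + base
    z, corrected = als_baseline(x, lam=1e9, p=1e-6)
    assert np.max(np.abs(z - base)) < 1e-6


def test_als_cubic_baseline_under_peak():
    n = 600
    t = np.arange(n) / n
    base = 2.0 + 1.0 * t - 3.0 * t**2 + 2.0 * t**3
    x = _peaky(n) + base
    z, _ = als_baseline(x, lam=1e3, p=1e-4)
    assert np.max(np.abs(z - base)) <= 0.05


def test_als_input_validation():
    with pytest.raises(ValueError):
        als_baseline([1.0, 2.0])
    with pytest.raises(ValueError):
        als_baseline(np.ones(10), lam=-1)
    with pytest.raises(ValueError):
        als_baseline(np.ones(10), p=1.5)


# ---------------------------------------------------------------- PTW
def test_ptw_recovers_integer_shift():
    n = 400
    i = np.arange(n)
    ref = np.exp(-0.5 * ((i - 200) / 6.0) ** 2) + 0.5 * np.exp(
        -0.5 * ((i - 120) / 5.0) ** 2
    )
    shifted = np.roll(ref, 5)  # features moved 5 points to higher indices
    coeffs, aligned = ptw_align(shifted, ref)
    assert abs(coeffs[0] - 5.0) < 0.1
    mid = slice(30, n - 30)
    assert np.corrcoef(aligned[mid], ref[mid])[0, 1] > 0.999


def test_ptw_identity_and_errors():
    x = np.sin(np.linspace(0, 6, 200)) + 2
    coeffs, aligned = ptw_align(x, x)
    assert np.allclose(aligned, x)
    assert np.allclose(coeffs, [0.0, 1.0, 0.0])
    with pytest.raises(ValueError):
        ptw_align(x, np.ones(200))
    with pytest.raises(ValueError):
        ptw_align(x, x[:-1])
    with pytest.raises(ValueError):
        ptw_align(x, x, degree=5)


# ---------------------------------------------------------------- normalization
def test_total_area_normalize_rows_sum_to_one():
    rng = np.random.default_rng(0)
    M = rng.uniform(0.1, 3.0, size=(12, 40))
    N = total_area_normalize(M)
    assert np.max(np.abs(N.sum(axis=1) - 1.0)) < 1e-12


def test_total_area_normalize_names_offending_sample():
    M = np.ones((3, 4))
    M[1] = -1.0
    with pytest.raises(ValueError, match="s2"):
        total_area_normalize(M, sample_ids=["s1", "s2", "s3"])


# ---------------------------------------------------------------- autoscale
def test_autoscale_mean_and_sd():
    rng = np.random.default_rng(1)
    M = rng.normal(3, 5, size=(30, 8))
    Z, scaler = autoscale(M)
    assert np.max(np.abs(Z.mean(axis=0))) < 1e-10
    assert np.max(np.abs(Z.std(axis=0, ddof=1) - 1.0)) < 1e-10
    # training-set parameters applied to new data reproduce the transform
    assert np.allclose(apply_scaler(M, scaler), Z)
    back = scaler.inverse_transform(Z)
    assert np.allclose(back, M)


def test_autoscale_zero_variance_rejected():
    M = np.ones((5, 3))
    M[:, 0] = np.arange(5)
    with pytest.raises(ValueError, match="zero-variance"):
        autoscale(M)


def test_scaler_dimension_mismatch():
    s = Scaler(mean_=np.zeros(3), sd_=np.ones(3))
    with pytest.raises(ValueError):
        s.transform(np.ones((2, 4)))


# ---------------------------------------------------------------- AI binning
def _toy_block(rows):
    ppm = np.linspace(1.0, 1.11, 12)
    M = np.array(rows, dtype=float)
    md = pd.DataFrame(
        {"group": ["g"] * M.shape[0]},
        index=pd.Index([f"s{i}" for i in range(M.shape[0])], name="sample_id"),
    )
    return SpectraBlock(ppm=ppm, intensities=M, metadata=md, block_id="toy")


def test_ai_bin_splits_printed_toy_in_the_valley():
    v = [0, 0, 5, 9, 5, 0, 0, 4, 8, 4, 0, 0]
    block = _toy_block([v, v])
    table = ai_bin(block, noise_region=(1.0, 1.005), min_bin_width=0.02)
    signal = table.signal()
    assert signal.values.shape[1] == 2
    # the split boundary must fall inside the zero valley (indices 5-6)
    ppm = block.ppm
    inner = signal.boundaries[0][1]
    assert ppm[5] <= inner <= ppm[6] + 1e-12
    assert signal.boundaries[1][0] == inner


def test_ai_bin_flags_noise_bins():
    rng = np.random.default_rng(3)
    n = 256
    ppm = np.linspace(0.5, 9.0, n)
    M = rng.normal(0, 0.01, size=(6, n))
    M[:, 100:110] += 5.0 / (1.0 + ((np.arange(10) - 5) / 2.0) ** 2)
    md = pd.DataFrame({"group": ["g"] * 6}, index=[f"s{i}" for i in range(6)])
    block = SpectraBlock(ppm=ppm, intensities=M, metadata=md)
    table = ai_bin(block, noise_region=(8.0, 9.0), min_bin_width=0.1)
    assert table.noise_flags.any()
    sig = table.signal()
    assert 0 < sig.values.shape[1] < table.values.shape[1]
    # the peak bin survives
    peak_ppm = ppm[105]
    assert any(lo <= peak_ppm < hi for lo, hi in sig.boundaries)


def test_ai_bin_errors():
    block = _toy_block([[0, 0, 5, 9, 5, 0, 0, 4, 8, 4, 0, 0]])
    with pytest.raises(ValueError):
        ai_bin(block, noise_region=(5.0, 6.0), min_bin_width=0.02)
    with pytest.raises(ValueError):
        ai_bin(block, noise_region=(1.0, 1.005), min_bin_width=10.0)


def test_bintable_invariants():
    md = pd.DataFrame({"group": ["g", "g"]}, index=["a", "b"])
    vals = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"], columns=["x", "y"])
    with pytest.raises(ValueError):
        BinTable(
            boundaries=[(0.0, 1.0), (0.5, 2.0)],
            values=vals,
            noise_flags=np.zeros(2, bool),
            metadata=md,
        )


# ---------------------------------------------------------------- containers
def test_spectrum_grid_validation():
    with pytest.raises(ValueError):
        Spectrum(ppm=[1.0, 1.0, 2.0], intensity=[0, 0, 0])
    with pytest.raises(ValueError):
        Spectrum(ppm=[1.0, 2.0], intensity=[0, 0, 0])


def test_spectra_block_csv_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    ppm = np.linspace(0.5, 9.0, 64)
    M = rng.normal(size=(4, 64))
    md = pd.DataFrame(
        {"group": ["C10", "C10", "N14", "N14"]},
        index=pd.Index([f"s{i}" for i in range(4)], name="sample_id"),
    )
    block = SpectraBlock(ppm=ppm, intensities=M, metadata=md, block_id="blockA")
    spath, mpath = tmp_path / "spec.csv", tmp_path / "meta.csv"
    block.write_csv(spath, mpath)
    back = SpectraBlock.read_csv(spath, mpath, block_id="blockA")
    assert np.allclose(back.intensities, M)
    assert list(back.groups) == list(block.groups)


# ---------------------------------------------------------------- pipeline
def test_preprocess_block_end_to_end(tiny_study):
    _, block_a, _, _ = tiny_study
    table = preprocess_block(block_a)
    vals = table.values.to_numpy()
    assert vals.shape[0] == block_a.intensities.shape[0]
    assert vals.shape[1] >= 3
    assert np.all(np.isfinite(vals))
    # bin integrals of a unit-area spectrum stay bounded by ~1
    assert vals.sum(axis=1).max() < 1.5
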