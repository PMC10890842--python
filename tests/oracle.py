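"""Independent brute-force oracles for the Fourier scoring pipeline.

Everything here is built from the DFT definition (explicit complex
exponential sums) and plain Python loops, deliberately avoiding the FFT code
paths under test.
"""

import numpy as np


def dft_matrix(n: int) -> np.ndarray:
    """Forward DFT matrix W[k, j] = exp(-2πi k j / n) from the definition."""
    k = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    return np.exp(-2j * np.pi * k * j / n)


def enumerate_band_bins(n: int, pixel_size: float, r_inner: float, r_outer: float):
    """Exhaustive loop over all n×n frequency pairs inside the annulus.

    Frequency of bin k is k/(n·Δx) folded to the negative half above n//2.
    Returns the set of (ky, kx) index pairs passed by the band.
    """
    passed = set()
    for ky in range(n):
        for kx in range(n):
            fy = (ky if ky <= n // 2 else ky - n) / (n * pixel_size)
            fx = (kx if kx <= n // 2 else kx - n) / (n * pixel_size)
            f = (fx * fx + fy * fy) ** 0.5
            if r_inner <= f <= r_outer:
                passed.add((ky, kx))
    return passed


def brute_force_bandpass(patch: np.ndarray, pixel_size: float,
                         r_inner: float, r_outer: float) -> np.ndarray:
    """Direct DFT → annular mask → inverse DFT (1/n² normalized)."""
    patch = np.asarray(patch, dtype=float)
    n = patch.shape[0]
    W = dft_matrix(n)
    spectrum = W @ patch @ W.T
    keep = enumerate_band_bins(n, pixel_size, r_inner, r_outer)
    masked = np.zeros_like(spectrum)
    for ky, kx in keep:
        masked[ky, kx] = spectrum[ky, kx]
    Winv = np.conj(W)
    back = (Winv @ masked @ Winv.T) / (n * n)
    assert np.abs(back.imag).max() < 1e-8 * max(np.linalg.norm(patch), 1e-300)
    return back.real


def brute_force_pixel_score(patch: np.ndarray, pixel_size: float,
                            r_inner: float, r_outer: float, sigma: float,
                            magnitude_mode: str = "abs") -> float:
    """Gaussian-weighted sum of the brute-force band-passed patch."""
    filtered = brute_force_bandpass(patch, pixel_size, r_inner, r_outer)
    n = filtered.shape[0]
    c = (n - 1) / 2.0
    d = np.arange(n) - c
    weight = np.exp(-(d[:, None] ** 2 + d[None, :] ** 2) / (2 * sigma**2))
    vals = np.abs(filtered) if magnitude_mode == "abs" else filtered
    return float(np.sum(weight * vals))
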