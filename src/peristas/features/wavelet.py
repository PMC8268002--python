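"""Single-level 3D wavelet decomposition into 8 full-resolution bands.

Each of the 2^3 low/high-pass axis combinations (LLL ... HHH) is isolated
in coefficient space and reconstructed back to the original grid, so VOI
masks apply to the bands unchanged.  Default basis Coiflet-1 with
periodization padding (orthogonal, so coefficient energy is conserved);
the basis is configurable.
"""

from __future__ import annotations

import numpy as np
import pywt

#: Band order: L/H per axis, low-pass first.
WAVELET_BAND_NAMES: tuple[str, ...] = (
    "LLL",
    "LLH",
    "LHL",
    "LHH",
    "HLL",
    "HLH",
    "HHL",
    "HHH",
)

_KEY_FOR_BAND = {name: name.lower().replace("l", "a").replace("h", "d") for name in WAVELET_BAND_NAMES}


def wavelet_bands(data: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """The 8 single-level wavelet bands, each at the input resolution."""
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
    w = pywt.Wavelet(wavelet)
    for ax, n in enumerate(data.shape):
        if n < w.dec_len:
            raise ValueError(
                f"axis {ax} has length {n} < filter length {w.dec_len} of {wavelet!r}"
            )
    coeffs = pywt.dwtn(data, w, mode="periodization")
    bands: dict[str, np.ndarray] = {}
    for name in WAVELET_BAND_NAMES:
        key = _KEY_FOR_BAND[name]
        solo = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(solo, w, mode="periodization")
        bands[name] = rec[tuple(slice(0, n) for n in data.shape)]
    return bands
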