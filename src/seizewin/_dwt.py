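"""Single-level discrete wavelet transform with symmetric boundary extension.

Implements the analysis (decomposition) half of the DWT for the Daubechies
family, producing ``floor((n + L - 1) / 2)`` approximation and detail
coefficients for a length-``n`` input and filter length ``L`` — the
"full-length convolution" convention. Output is numerically identical to
``pywt.dwt(x, wavelet, mode="symmetric")``.
"""

from __future__ import annotations

import numpy as np

# Daubechies scaling (lowpass reconstruction) filters, natural order,
# normalized so the coefficients sum to sqrt(2).
_DB_REC_LO: dict[str, tuple[float, ...]] = {
    "db1": (
        0.7071067811865476,
        0.7071067811865476,
    ),
    "db2": (
        0.48296291314469025,
        0.8365163037378079,
        0.22414386804185735,
        -0.12940952255092145,
    ),
    "db4": (
        0.23037781330885523,
        0.7148465705525415,
        0.6308807679295904,
        -0.02798376941698385,
        -0.18703481171888114,
        0.030841381835986965,
        0.032883011666982945,
        -0.010597401784997278,
    ),
}


def analysis_filters(wavelet_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (dec_lo, dec_hi) analysis filters for a supported wavelet."""
    try:
        rec_lo = np.asarray(_DB_REC_LO[wavelet_name.lower()], dtype=np.float64)
    except KeyError:
        raise ValueError(
            f"unsupported wavelet {wavelet_name!r}; "
            f"available: {sorted(_DB_REC_LO)}"
        ) from None
    dec_lo = rec_lo[::-1].copy()
    # quadrature mirror: g[k] = (-1)^(k+1) h[k] on the natural-order lowpass
    signs = np.where(np.arange(rec_lo.size) % 2 == 0, -1.0, 1.0)
    dec_hi = signs * rec_lo
    return dec_lo, dec_hi


def _symmetric_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-point symmetric extension: ... x1 x0 | x0 x1 ... xn-1 | xn-1 ..."""
    if pad > x.size:
        reps = int(np.ceil(pad / (2 * x.size))) + 1
        left = np.concatenate([x, x[::-1]] * reps)[-pad:]
        right = np.concatenate([x[::-1], x] * reps)[:pad]
        return np.concatenate([left, x, right])
    left = x[pad - 1 :: -1]
    right = x[: -pad - 1 : -1]
    return np.concatenate([left, x, right])


def dwt_single(x: np.ndarray, wavelet_name: str = "db4") -> tuple[np.ndarray, np.ndarray]:
    """One analysis level: returns (approx, detail) coefficient arrays.

    Lengths are both ``floor((len(x) + L - 1) / 2)`` where ``L`` is the
    filter length (e.g. 67 for a 128-sample input with db4).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("dwt_single expects a 1-D signal")
    if x.size < 2:
        raise ValueError("signal too short for a wavelet decomposition")
    dec_lo, dec_hi = analysis_filters(wavelet_name)
    L = dec_lo.size
    ext = _symmetric_extend(x, L - 1)
    # correlation with the analysis filter == convolution with its reverse
    approx = np.convolve(ext, dec_lo, mode="valid")[1::2]
    detail = np.convolve(ext, dec_hi, mode="valid")[1::2]
    return approx, detail


def dwt_output_len(n: int, wavelet_name: str = "db4") -> int:
    L = len(_DB_REC_LO[wavelet_name.lower()])
    return (n + L - 1) // 2
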