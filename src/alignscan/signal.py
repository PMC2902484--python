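"""Robust cutoffs and FFT smoothing of score tracks.

Significant peaks in a raw score track are extracted with cutoffs at
``median(X) +/- 1.4826 * MAD``, where MAD is the median absolute
deviation — 1.4826 is the factor making the MAD a consistent estimator
of one standard deviation under normality (1/Phi^-1(3/4)).  For closely
related sequences most columns score identically, the MAD collapses to
zero, and the spread falls back to the mean absolute deviation about the
mean; in that regime only the low (divergent) cutoff is meaningful, so
no conserved regions are callable.

Region-scale structure is read off a low-pass-filtered twin of the raw
track: a discrete Fourier transform with all coefficients above a cutoff
frequency zeroed, which turns contiguous sharp per-column peaks into
wide ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .profile import SliceBounds
from .scoring import ScoreTrack

#: MAD-to-standard-deviation consistency factor under normality.
MAD_SCALE = 1.4826


class SignalError(ValueError):
    pass


@dataclass(frozen=True)
class CutoffPair:
    """Low/high thresholds around the track median.

    ``high`` is ``None`` in the MAD_MEAN fallback regime, where only
    divergent regions can be revealed.
    """

    low: float
    high: Optional[float]
    basis: str              # "MAD" | "MAD_MEAN"
    center: float           # median of X


def _values(x: Union[ScoreTrack, np.ndarray]) -> np.ndarray:
    arr = x.values if isinstance(x, ScoreTrack) else np.asarray(x, float)
    if arr.size == 0:
        raise SignalError("empty score track")
    return arr


def compute_cutoffs(x: Union[ScoreTrack, np.ndarray],
                    k: float = MAD_SCALE,
                    tol: float = 1e-12) -> CutoffPair:
    """Robust cutoff pair for a score track.

    With ``med = median(X)`` and ``MAD = median(|X - med|)``:

    * ``MAD > tol``: low/high = ``med -/+ k*MAD``.
    * otherwise (degenerate spread): ``MAD_mean = mean(|X - mean(X)|)``,
      low = ``med - k*MAD_mean``, high disabled.

    The same factor ``k`` margins both branches for a single consistent
    definition; the fallback stays centred on the median for continuity.
    """
    arr = _values(x)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    if mad > tol:
        return CutoffPair(low=med - k * mad, high=med + k * mad,
                          basis="MAD", center=med)
    mad_mean = float(np.mean(np.abs(arr - np.mean(arr))))
    return CutoffPair(low=med - k * mad_mean, high=None,
                      basis="MAD_MEAN", center=med)


@dataclass(frozen=True)
class SmoothedTrack:
    """Low-pass-filtered twin of a raw score track."""

    values: np.ndarray
    bounds: SliceBounds
    method: str
    window: int


def smooth_fft(x: ScoreTrack, window: int = 10) -> SmoothedTrack:
    """Hard low-pass filter in the Fourier domain.

    Frequencies with index above ``ceil(L / (2*window))`` are zeroed
    (together with their conjugates), then the inverse transform's real
    part is returned.  The DC component is always retained, so the track
    mean is preserved exactly.  ``window`` is the approximate width in
    columns of the narrowest surviving feature; the default of 10 is on
    the scale of a short primer-sized region.
    """
    if window < 1:
        raise SignalError(f"smoothing window must be >= 1, got {window}")
    arr = _values(x)
    L = arr.size
    if L < 4:
        raise SignalError("track too short to smooth (need length >= 4)")
    kmax = math.ceil(L / (2 * window))
    spectrum = np.fft.rfft(arr)
    spectrum[kmax + 1:] = 0.0
    smoothed = np.fft.irfft(spectrum, n=L)
    return SmoothedTrack(values=smoothed, bounds=x.bounds,
                         method=x.method, window=window)
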