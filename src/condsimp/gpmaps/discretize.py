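"""Up-down discretization of a real-valued time series into a bit string.

Used to turn continuous dynamical phenotypes (e.g. a circadian
concentration profile) into a finite pattern: across consecutive windows
of W samples the sign of the slope is recorded, '1' for a positive slope
and '0' for a negative or flat one.  A series of T points yields
floor((T-1)/W) bits, one per complete window after the first sample; a
499,999-point series at W = 25,000 gives the 19-bit phenotype used for
circadian profiles.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..complexity import EncodedPattern

__all__ = ["updown_discretize"]


def updown_discretize(series: Sequence[float], window: int) -> EncodedPattern:
    x = np.asarray(series, dtype=float)
    T = x.size
    if window < 1:
        raise ValueError("window must be at least 1")
    if T <= window:
        raise ValueError(f"series of {T} points is too short for window {window}")
    n_bits = (T - 1) // window
    edges = x[: (n_bits + 1) * window : window]
    bits = (np.diff(edges) > 0).astype(int)
    return EncodedPattern("".join("01"[b] for b in bits), alphabet_size=2)
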