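"""Schematic pattern grammar for slope vectors.

A slope vector is translated day-by-day into ``rise`` / ``constant`` /
``fall`` symbols (positive / near-zero / negative slope), consecutive
repeats are collapsed, and the result is hyphen-joined.  This is the
vocabulary used to describe trajectory-cluster centroids.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

__all__ = ["label_pattern", "auto_epsilon"]

_SYMBOLS = {1: "rise", 0: "constant", -1: "fall"}


def label_pattern(slopes: Sequence[float], epsilon: float = 0.0) -> str:
    """Translate a slope vector into a schematic pattern string.

    Parameters
    ----------
    slopes : sequence of float
        Finite-difference slopes, one per time point.
    epsilon : float
        Tolerance band: a slope in ``[-epsilon, epsilon]`` is labelled
        ``constant``.  Must be nonnegative.

    Returns
    -------
    str
        Run-length-collapsed, hyphen-joined pattern, e.g.
        ``"rise-constant-fall"``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    arr = np.asarray(slopes, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("slopes must be a nonempty 1-D vector")
    signs = np.where(arr > epsilon, 1, np.where(arr < -epsilon, -1, 0))
    symbols: list[str] = []
    for s in signs:
        name = _SYMBOLS[int(s)]
        if not symbols or symbols[-1] != name:
            symbols.append(name)
    return "-".join(symbols)


def auto_epsilon(slopes: np.ndarray, scale: float = 0.1, quantile: float = 0.95) -> float:
    """Data-driven tolerance for the ``constant`` symbol.

    Defined as ``scale`` times the ``quantile``-th percentile of absolute
    slopes across the dataset; a strict zero rule would be measure-zero on
    real data.
    """
    arr = np.abs(np.asarray(slopes, dtype=float)).ravel()
    if arr.size == 0:
        raise ValueError("cannot derive epsilon from an empty slope set")
    return float(scale * np.quantile(arr, quantile))
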