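"""Windowed physicochemical features of phosphosite neighborhoods.

Computes, for a local sequence segment (by default 31 residues centered on a
site), mean Kyte-Doolittle hydropathy, charge statistics (f+, f-, FCR, NCPR),
the charge-patterning parameter kappa, aromatic/proline content, and a
charge-hydropathy (Uversky-style) disorder classification.  Phosphorylated
positions can be folded into the charge bookkeeping: each phosphosite counts
as one charged residue for FCR and contributes a configurable charge
(default -2) to the net charge sum.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KYTE_DOOLITTLE",
    "WindowProperties",
    "extract_window",
    "window_properties",
    "kappa",
    "delta",
    "delta_max",
    "uversky_classify",
    "ncpr_profile",
]

#: Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

POSITIVE = frozenset("KR")   # H treated as uncharged (configurable below)
NEGATIVE = frozenset("DE")
AROMATIC = frozenset("YFW")

_HW_DEFAULT = 15


def _check_sequence(seq: str) -> None:
    for ch in seq:
        if ch not in KYTE_DOOLITTLE:
            raise ValueError(f"unknown residue letter {ch!r}")


def residue_charges(seq: str, histidine_charge: float = 0.0) -> np.ndarray:
    """Per-residue formal charge (+1 K/R, -1 D/E, else 0)."""
    _check_sequence(seq)
    out = np.zeros(len(seq))
    for i, ch in enumerate(seq):
        if ch in POSITIVE:
            out[i] = 1.0
        elif ch in NEGATIVE:
            out[i] = -1.0
        elif ch == "H":
            out[i] = histidine_charge
    return out


def extract_window(
    sequence: str,
    position: int,
    half_width: int = _HW_DEFAULT,
    terminal_anchored: bool = False,
) -> tuple[str, int, int]:
    """Extract the local segment around a 1-based site position.

    Returns ``(window, start, end)`` with ``start``/``end`` 1-based inclusive
    coordinates on the parent sequence.  By default the window is
    ``[position - half_width, position + half_width]`` clipped to the
    sequence; with ``terminal_anchored=True`` a window that would be clipped
    is instead slid inward so that the full ``2 * half_width + 1`` residues
    are used whenever the sequence is long enough (reproducing e.g. a
    "last 31 residues" segment for a C-terminal site).
    """
    n = len(sequence)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} out of range 1..{n}")
    full = 2 * half_width + 1
    if terminal_anchored and n >= full:
        start = min(max(1, position - half_width), n - full + 1)
        end = start + full - 1
    else:
        start = max(1, position - half_width)
        end = min(n, position + half_width)
    return sequence[start - 1:end], start, end


@dataclass
class WindowProperties:
    """Physicochemical summary of one local segment."""

    window: str
    length: int
    mean_hydropathy: float
    normalized_mean_hydropathy: float
    f_plus: float
    f_minus: float
    fcr: float
    ncpr: float
    kappa: float | None
    aromatic_fraction: float
    proline_fraction: float
    disordered: bool
    n_phospho: int = 0
    protein_id: str | None = None
    site: str | None = None


def window_properties(
    window: str,
    phospho_positions: Iterable[int] = (),
    phospho_charge: float = -2.0,
    histidine_charge: float = 0.0,
) -> WindowProperties:
    """Charge/hydropathy characterization of a segment.

    ``phospho_positions`` are 1-based indices *within the window*.  A
    phosphorylated position counts as a charged residue for FCR (grouped
    with the negative fraction when its base residue is uncharged) and adds
    ``phospho_charge`` to the net-charge sum used for NCPR.
    """
    if not window:
        raise ValueError("empty window")
    _check_sequence(window)
    L = len(window)
    phospho = sorted(set(int(p) for p in phospho_positions))
    if phospho and (phospho[0] < 1 or phospho[-1] > L):
        raise ValueError("phospho position outside window")

    charges = residue_charges(window, histidine_charge)
    n_plus = int(np.sum(charges > 0))
    base_minus = int(np.sum(charges < 0))
    # phospho on an already-charged residue is not double counted for FCR
    phospho_on_neutral = sum(1 for p in phospho if charges[p - 1] == 0)
    f_plus = n_plus / L
    f_minus = (base_minus + phospho_on_neutral) / L
    fcr = f_plus + f_minus
    net = float(np.sum(charges)) + phospho_charge * len(phospho)
    ncpr = net / L

    kd = np.array([KYTE_DOOLITTLE[c] for c in window])
    mean_h = float(kd.mean())
    norm_h = float(((kd + 4.5) / 9.0).mean())

    return WindowProperties(
        window=window,
        length=L,
        mean_hydropathy=mean_h,
        normalized_mean_hydropathy=norm_h,
        f_plus=f_plus,
        f_minus=f_minus,
        fcr=fcr,
        ncpr=ncpr,
        kappa=kappa(window, histidine_charge=histidine_charge),
        aromatic_fraction=sum(1 for c in window if c in AROMATIC) / L,
        proline_fraction=window.count("P") / L,
        disordered=uversky_classify(window, histidine_charge=histidine_charge),
        n_phospho=len(phospho),
    )


# ---------------------------------------------------------------------------
# kappa


def _sigma(charges: np.ndarray) -> float:
    fp = np.mean(charges > 0)
    fm = np.mean(charges < 0)
    fcr = fp + fm
    if fcr == 0:
        return 0.0
    return (fp - fm) ** 2 / fcr


def delta(charges: np.ndarray, blob: int) -> float:
    """Mean squared deviation of blob-wise sigma from global sigma."""
    charges = np.asarray(charges, dtype=float)
    n = len(charges)
    if n < blob:
        raise ValueError("sequence shorter than blob size")
    sig_all = _sigma(charges)
    cp = np.concatenate(([0.0], np.cumsum(charges > 0)))
    cn = np.concatenate(([0.0], np.cumsum(charges < 0)))
    fp = (cp[blob:] - cp[:-blob]) / blob
    fm = (cn[blob:] - cn[:-blob]) / blob
    fcr = fp + fm
    sig = np.zeros_like(fcr)
    nz = fcr > 0
    sig[nz] = (fp[nz] - fm[nz]) ** 2 / fcr[nz]
    return float(np.mean((sig - sig_all) ** 2))


def _segregated_candidates(n_plus: int, n_minus: int, n_zero: int):
    """Arrangements with contiguous charge blocks, neutrals split around them.

    delta is invariant under sign swap and reversal, so one block order
    suffices.  Yields ternary charge arrays.
    """
    plus = [1.0] * n_plus
    minus = [-1.0] * n_minus
    for a in range(n_zero + 1):
        for b in range(n_zero - a + 1):
            c = n_zero - a - b
            yield np.array([0.0] * a + plus + [0.0] * b + minus + [0.0] * c)


def _n_arrangements(n_plus: int, n_minus: int, n_zero: int) -> int:
    from math import comb

    n = n_plus + n_minus + n_zero
    return comb(n, n_plus) * comb(n - n_plus, n_minus)


def _all_arrangements(n_plus: int, n_minus: int, n_zero: int):
    n = n_plus + n_minus + n_zero
    idx = range(n)
    for pos_p in itertools.combinations(idx, n_plus):
        rest = [i for i in idx if i not in pos_p]
        for pos_m in itertools.combinations(rest, n_minus):
            arr = np.zeros(n)
            arr[list(pos_p)] = 1.0
            arr[list(pos_m)] = -1.0
            yield arr


#: arrangement-count cap below which delta_max is found by enumeration
_ENUMERATION_CAP = 20_000


@functools.lru_cache(maxsize=4096)
def delta_max(
    n_plus: int, n_minus: int, n_zero: int, blob: int
) -> float:
    """Maximal delta over rearrangements of the given charge composition.

    Small compositions (at most ``_ENUMERATION_CAP`` distinct arrangements)
    are solved exactly by exhaustive enumeration.  Larger ones use the
    maximally segregated construction: each charge species in a single
    contiguous block, scanning all neutral-gap placements around the blocks.
    The construction coincides with the enumerated maximum whenever both
    charge species are present and the sequence comfortably exceeds the blob
    size, which covers the intended 31-residue windows.
    """
    best = 0.0
    if _n_arrangements(n_plus, n_minus, n_zero) <= _ENUMERATION_CAP:
        candidates = _all_arrangements(n_plus, n_minus, n_zero)
    else:
        candidates = _segregated_candidates(n_plus, n_minus, n_zero)
    for arr in candidates:
        best = max(best, delta(arr, blob))
    return best


def kappa(
    sequence: str | np.ndarray,
    blob_sizes: Sequence[int] = (5, 6),
    histidine_charge: float = 0.0,
) -> float | None:
    """Charge-patterning parameter in [0, 1]; ``None`` when undefined.

    kappa_g = delta_g / delta_max_g per blob size g, averaged over
    ``blob_sizes``.  Undefined (None) unless both positively and negatively
    charged residues are present (charged-vs-neutral patterning is a
    different quantity), the segment is at least as long as the largest
    blob, and the composition admits patterning variation (delta_max > 0).
    """
    if isinstance(sequence, str):
        charges = residue_charges(sequence, histidine_charge)
    else:
        charges = np.asarray(sequence, dtype=float)
    n = len(charges)
    if n < max(blob_sizes):
        return None
    n_plus = int(np.sum(charges > 0))
    n_minus = int(np.sum(charges < 0))
    n_zero = n - n_plus - n_minus
    if n_plus == 0 or n_minus == 0:
        return None
    vals = []
    for g in blob_sizes:
        dmax = delta_max(n_plus, n_minus, n_zero, g)
        if dmax == 0:
            return None
        vals.append(delta(charges, g) / dmax)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# charge-hydropathy disorder boundary


def uversky_classify(
    window: str,
    histidine_charge: float = 0.0,
    smooth: int = 5,
) -> bool:
    """Charge-hydropathy disorder call for a segment.

    Disordered iff the mean absolute net charge <R> exceeds the boundary
    ``2.785 * <H> - 1.151``, where <H> is the Kyte-Doolittle hydropathy
    rescaled to [0, 1] and smoothed with a ``smooth``-residue sliding window
    (edges clipped).  Points exactly on the boundary are classified ordered.
    """
    if not window:
        raise ValueError("empty window")
    _check_sequence(window)
    charges = residue_charges(window, histidine_charge)
    mean_r = abs(float(charges.mean()))
    kd = np.array([(KYTE_DOOLITTLE[c] + 4.5) / 9.0 for c in window])
    mean_h = float(_sliding_mean(kd, smooth).mean())
    return mean_r > 2.785 * mean_h - 1.151


def _sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean with clipped (shortened) edge windows."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def ncpr_profile(
    sequence: str, window: int = 5, histidine_charge: float = 0.0
) -> np.ndarray:
    """Per-residue net charge, smoothed over a centered sliding window."""
    if len(sequence) < window:
        raise ValueError("sequence shorter than smoothing window")
    charges = residue_charges(sequence, histidine_charge)
    return _sliding_mean(charges, window)
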