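"""Distortion metrics for comparing generated and real ECG sequences.

Three criteria are implemented: percent root mean square difference (PRD),
root mean square error (RMSE), and the discrete Frechet distance (FD)
between the two sequences viewed as ordered planar curves.  A brute-force
Frechet implementation that enumerates every monotone coupling is included
as an independent oracle for the dynamic-programming version.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .ecg_io import minmax_normalize
from .errors import DegenerateInputError, ShapeError, ValidationError

__all__ = [
    "CurvePoint",
    "MetricReport",
    "prd",
    "rmse",
    "to_curve",
    "discrete_frechet",
    "discrete_frechet_bruteforce",
    "evaluate_generated",
]


@dataclass(frozen=True)
class CurvePoint:
    """A point on an ordered curve: normalized time t, amplitude v."""

    t: float
    v: float


@dataclass
class MetricReport:
    """Mean PRD/RMSE/FD over a set of (reference, generated) pairs."""

    prd: float
    rmse: float
    fd: float
    n_pairs: int
    pairing: str

    def to_dict(self) -> dict:
        return {
            "prd": self.prd,
            "rmse": self.rmse,
            "fd": self.fd,
            "n_pairs": self.n_pairs,
            "pairing": self.pairing,
        }


def _check_pair(reference, generated) -> Tuple[np.ndarray, np.ndarray]:
    reference = np.asarray(reference, dtype=np.float64)
    generated = np.asarray(generated, dtype=np.float64)
    if reference.shape != generated.shape:
        raise ShapeError(
            f"sequence lengths differ: {reference.shape} vs {generated.shape}"
        )
    if reference.size == 0:
        raise ValidationError("sequences must be non-empty")
    return reference, generated


def prd(
    reference,
    generated,
    mode: str = "standard",
    normalize: bool = False,
) -> float:
    """Percent root mean square difference.

    mode="standard" (default): 100 * sqrt(sum((x - xhat)^2) / sum(x^2)).
    mode="as_printed": sqrt(100 * sum((x - xhat)^2) / sum(x^2)), i.e. the
    factor of 100 inside the radical as the formula is usually typeset.
    With normalize=True both sequences are min-max rescaled to [0, 1]
    before comparison.
    """
    x, xhat = _check_pair(reference, generated)
    if normalize:
        x = minmax_normalize(x)
        xhat = minmax_normalize(xhat)
    energy = float(np.sum(x ** 2))
    if energy == 0.0:
        raise DegenerateInputError("PRD undefined for an all-zero reference")
    ratio = float(np.sum((x - xhat) ** 2)) / energy
    if mode == "standard":
        return 100.0 * float(np.sqrt(ratio))
    if mode == "as_printed":
        return float(np.sqrt(100.0 * ratio))
    raise ValidationError(f"unknown PRD mode {mode!r}")


def rmse(reference, generated, normalize: bool = False) -> float:
    """Root mean square error: sqrt(mean((x - xhat)^2))."""
    x, xhat = _check_pair(reference, generated)
    if normalize:
        x = minmax_normalize(x)
        xhat = minmax_normalize(xhat)
    return float(np.sqrt(np.mean((x - xhat) ** 2)))


def to_curve(values, normalize_time: bool = True) -> np.ndarray:
    """Lift a 1-D sequence to an (N, 2) curve of (time, amplitude) points.

    Time is index/(N-1) so curves of different lengths share the [0, 1]
    axis; a single point gets t = 0.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ShapeError(f"expected a 1-D sequence, got shape {values.shape}")
    n = len(values)
    if n == 0:
        raise ValidationError("cannot build a curve from an empty sequence")
    if normalize_time and n > 1:
        t = np.arange(n) / (n - 1)
    else:
        t = np.arange(n, dtype=np.float64)
        if normalize_time:
            t = np.zeros(n)
    return np.column_stack([t, values])


def _as_points(curve) -> np.ndarray:
    if isinstance(curve, (list, tuple)) and curve and isinstance(curve[0], CurvePoint):
        curve = [(p.t, p.v) for p in curve]
    pts = np.asarray(curve, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[:, None]  # value-only 1-D mode
    if pts.size == 0:
        raise ValidationError("curves must be non-empty")
    return pts


def discrete_frechet(P, Q) -> float:
    """Discrete Frechet distance between ordered point sequences.

    Dynamic program over the coupling lattice: the frontier may advance in
    P, in Q, or in both at each step, and the distance is the minimum over
    couplings of the maximum pointwise Euclidean distance.  Accepts (N, d)
    arrays, lists of CurvePoint, or bare 1-D value sequences.
    """
    p = _as_points(P)
    q = _as_points(Q)
    if p.shape[1] != q.shape[1]:
        raise ShapeError("curves must have the same point dimension")
    # Pairwise Euclidean distances.
    diff = p[:, None, :] - q[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        row_prev = ca[i - 1]
        row = ca[i]
        for j in range(1, m):
            row[j] = max(
                min(row_prev[j], row_prev[j - 1], row[j - 1]), d[i, j]
            )
    return float(ca[-1, -1])


def discrete_frechet_bruteforce(P, Q) -> float:
    """Exhaustive enumeration of all monotone couplings (oracle).

    Walks every path from (0, 0) to (n-1, m-1) with unit steps in either
    or both indices and returns the minimum over paths of the maximum
    pointwise distance.  Exponential; intended for curves of a few points.
    """
    p = _as_points(P)
    q = _as_points(Q)
    if p.shape[1] != q.shape[1]:
        raise ShapeError("curves must have the same point dimension")
    n, m = len(p), len(q)

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(p[i] - q[j]))

    best = [np.inf]

    def walk(i: int, j: int, current_max: float) -> None:
        current_max = max(current_max, dist(i, j))
        if current_max >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = current_max
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                walk(ni, nj, current_max)

    walk(0, 0, 0.0)
    return best[0]


def evaluate_generated(
    real_windows: Sequence,
    generated: Sequence,
    pairing: str = "best",
    normalize: bool = True,
    prd_mode: str = "standard",
) -> MetricReport:
    """Score generated sequences against a pool of real windows.

    Sequences are truncated to the shortest length present, then (by
    default) min-max normalized.  pairing="best" matches each generated
    sequence with the real window minimizing RMSE against it;
    pairing="fixed" pairs by index (generated i with real i mod n_real).
    FD is computed on (normalized index, amplitude) planar curves.
    """
    real_list = [np.asarray(w, dtype=np.float64) for w in real_windows]
    gen_list = [np.asarray(g, dtype=np.float64) for g in generated]
    if not real_list or not gen_list:
        raise ValidationError("need at least one real and one generated sequence")
    if pairing not in ("best", "fixed"):
        raise ValidationError(f"unknown pairing strategy {pairing!r}")
    min_len = min(min(len(x) for x in real_list), min(len(x) for x in gen_list))
    if min_len == 0:
        raise ValidationError("sequences must be non-empty")
    real_arr = [x[:min_len] for x in real_list]
    gen_arr = [x[:min_len] for x in gen_list]
    if normalize:
        real_arr = [minmax_normalize(x) for x in real_arr]
        gen_arr = [minmax_normalize(x) for x in gen_arr]

    prds: List[float] = []
    rmses: List[float] = []
    fds: List[float] = []
    for i, g in enumerate(gen_arr):
        if pairing == "fixed":
            ref = real_arr[i % len(real_arr)]
        else:
            errors = [float(np.sqrt(np.mean((r - g) ** 2))) for r in real_arr]
            ref = real_arr[int(np.argmin(errors))]
        prds.append(prd(ref, g, mode=prd_mode))
        rmses.append(rmse(ref, g))
        fds.append(discrete_frechet(to_curve(ref), to_curve(g)))
    return MetricReport(
        prd=float(np.mean(prds)),
        rmse=float(np.mean(rmses)),
        fd=float(np.mean(fds)),
        n_pairs=len(gen_arr),
        pairing=pairing,
    )
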