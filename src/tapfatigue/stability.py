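"""Local dynamic stability: PCA state space and largest Lyapunov exponent.

The nine acceleration channels of the time-normalized cycles are
concatenated in time, centered, and projected onto their three dominant
principal axes.  Movement stability is then quantified Rosenstein-style:
for every reference point, find its nearest neighbor at least a Theiler
window away, track the mean log distance between the paired trajectories
over a horizon of k samples, and report the least-squares slope of that
divergence curve as the largest Lyapunov exponent (LLE).  Slopes are
fitted over 5%, 10%, quarter- and half-cycle horizons (lambda5,
lambda10, lambdaQ, lambdaH); with 100 phase points per cycle one sample
equals 1% of a cycle, so per-cycle exponents are the per-sample slopes
times 100.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kinematics import NormalizedCycleSet

log = logging.getLogger(__name__)

__all__ = ["StateSpace", "DivergenceCurve", "build_state_space",
           "divergence_curve", "estimate_lle"]


@dataclass
class StateSpace:
    """3-D principal-component score trajectory of the cyclic movement."""

    scores: np.ndarray  # (T, 3)
    variance_fractions: np.ndarray  # (3,) of total variance, descending
    cycle_index: np.ndarray  # (T,) cycle number of each sample
    phase_index: np.ndarray  # (T,) 0..n_phase-1 within-cycle position

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]


@dataclass
class DivergenceCurve:
    """Mean log divergence y(k) between nearest-neighbor trajectory pairs."""

    k: np.ndarray  # horizons, samples
    y: np.ndarray  # mean ln distance
    n_pairs: np.ndarray  # pairs contributing at each k
    n_zero_excluded: int = 0


def build_state_space(ncycles: NormalizedCycleSet, n_components: int = 3) -> StateSpace:
    """Project the concatenated 9-channel cycles onto their top-3 PCA axes.

    Columns are centered but not variance-scaled; the reported variance
    fractions are of the total variance, so their sum is at most 1.
    """
    tensor = ncycles.tensor
    n_cyc, n_phase, n_ch = tensor.shape
    if n_cyc < 2:
        raise ValueError("need at least 2 cycles to build a state space")
    X = tensor.reshape(n_cyc * n_phase, n_ch)
    Xc = X - X.mean(axis=0)
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    if svals[n_components - 1] <= svals[0] * 1e-12:
        raise ValueError(
            f"channel matrix has rank below {n_components}; inspect the recording "
            "(constant or duplicated channels?)"
        )
    scores = Xc @ vt[:n_components].T
    fractions = (svals[:n_components] ** 2) / np.sum(svals ** 2)
    cycle_index = np.repeat(np.arange(n_cyc), n_phase)
    phase_index = np.tile(np.arange(n_phase), n_cyc)
    return StateSpace(scores, fractions, cycle_index, phase_index)


def _nearest_neighbors(scores: np.ndarray, cand: np.ndarray, refs: np.ndarray,
                       theiler: int, chunk: int = 512) -> np.ndarray:
    """Index (into scores) of the nearest candidate to each reference,
    subject to the Theiler exclusion |i - j| >= theiler."""
    sc_c = scores[cand]
    nn = np.empty(refs.size, dtype=int)
    cc2 = np.einsum("ij,ij->i", sc_c, sc_c)
    for s in range(0, refs.size, chunk):
        r = refs[s:s + chunk]
        sr = scores[r]
        d2 = cc2[None, :] - 2.0 * sr @ sc_c.T + np.einsum("ij,ij->i", sr, sr)[:, None]
        d2[np.abs(r[:, None] - cand[None, :]) < theiler] = np.inf
        nn[s:s + chunk] = cand[np.argmin(d2, axis=1)]
    return nn


def divergence_curve(space: StateSpace | np.ndarray, theiler: int = 100,
                     K: int = 50, segment_len: int | None = None) -> DivergenceCurve:
    """Rosenstein divergence curve y(k), k = 0..K.

    For each reference point i the nearest neighbor j (Euclidean, with
    |i - j| >= theiler) is found once, and y(k) is the mean over pairs of
    ln||x(i+k) - x(j+k)||.  Zero initial distances (duplicate states) are
    excluded from the log mean and counted.

    Without ``segment_len`` every point is a reference and pairs running
    past the record end are excluded from that k's mean.  With
    ``segment_len`` (the phase length of one cycle) both reference and
    candidate points are restricted to those that can be propagated K
    samples without crossing a cycle boundary, and the reference set is
    held fixed across k -- appropriate for cyclic data whose
    cycle-to-cycle perturbations re-initialize at each cycle start.
    """
    scores = space.scores if isinstance(space, StateSpace) else np.asarray(space, dtype=float)
    T = scores.shape[0]
    if T <= theiler + K:
        raise ValueError(f"need more than theiler + K = {theiler + K} samples, got {T}")
    idx = np.arange(T)
    if segment_len is not None:
        pos = idx % segment_len
        mask = (pos <= segment_len - 1 - K) & (idx + K < T)
        refs = cand = idx[mask]
        if refs.size == 0:
            raise ValueError("segment_len too short for horizon K; no valid reference points")
    else:
        refs = cand = idx
    nn = _nearest_neighbors(scores, cand, refs, theiler)
    ks = np.arange(K + 1)
    y = np.full(K + 1, np.nan)
    n_pairs = np.zeros(K + 1, dtype=int)
    n_zero = 0
    for k in ks:
        ok = (refs + k < T) & (nn + k < T)
        d = np.linalg.norm(scores[refs[ok] + k] - scores[nn[ok] + k], axis=1)
        pos_d = d > 0
        n_zero += int(np.sum(~pos_d))
        if np.any(pos_d):
            y[k] = float(np.mean(np.log(d[pos_d])))
            n_pairs[k] = int(np.sum(pos_d))
    if n_zero:
        log.info("divergence_curve: excluded %d zero-distance pair evaluations", n_zero)
    if not np.isfinite(y[0]):
        raise ValueError("no finite initial distances; state space degenerate")
    return DivergenceCurve(ks, y, n_pairs, n_zero)


def estimate_lle(curve: DivergenceCurve,
                 horizons: tuple[int, ...] = (5, 10, 25, 50)) -> dict[int, float]:
    """Least-squares slope of y(k) over k in [0, h] for each horizon h.

    Returns NaN for a horizon with fewer than 3 finite points.  Units:
    ln-divergence per normalized sample (1 sample = 1% of a cycle).
    """
    if curve.k.max() < max(horizons):
        raise ValueError("divergence curve does not cover the largest horizon")
    out: dict[int, float] = {}
    for h in horizons:
        sel = curve.k <= h
        k, yv = curve.k[sel], curve.y[sel]
        fin = np.isfinite(yv)
        if np.sum(fin) < 3:
            log.warning("horizon %d has under 3 finite points; LLE undefined", h)
            out[h] = float("nan")
            continue
        out[h] = float(np.polyfit(k[fin], yv[fin], 1)[0])
    return out
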