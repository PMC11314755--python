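"""Chromatogram preprocessing: baseline correction, normalisation, alignment.

The processing order is fixed — baseline correction, then within-sample
max-normalisation (each trace divided by its highest resistance), then
cross-sample alignment against a pooled reference.  Training and
validation batches are processed together (the alignment reference is
computed from the pool) and the validation set is held back afterwards,
so that batch-level baseline differences are handled jointly while model
fitting only ever sees the training partition.

Baseline correction uses asymmetric least squares (AsLS): a Whittaker
smoother whose weights are iteratively reweighted so the fitted baseline
hugs the lower envelope of the trace.  Alignment applies a per-sample
integer-tick shift chosen by cross-correlation against the pooled median
trace; an optional piecewise mode aligns fixed-length segments
independently for non-rigid retention drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solveh_banded

logger = logging.getLogger(__name__)


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was applied out of order."""


class DegenerateSampleError(ValueError):
    """A trace is unusable (e.g. all zero after baseline correction)."""


@dataclass
class Chromatogram:
    """One sample's sensor-resistance time series plus processing state."""

    sample_id: str
    tick_s: float
    values: np.ndarray
    batch: str = ""
    baseline_corrected: bool = False
    normalised: bool = False
    aligned: bool = False
    applied_shift_ticks: int = 0
    max_raw_resistance: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("chromatogram values must be non-empty")
        if self.tick_s <= 0:
            raise ValueError("tick_s must be positive")

    def copy_with(self, **kw) -> "Chromatogram":
        kw.setdefault("values", self.values.copy())
        return replace(self, **kw)


def asls_baseline(y: np.ndarray, lam: float = 1e8, p: float = 0.01, niter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate (Whittaker smoother).

    lam controls smoothness (larger = stiffer baseline); p is the asymmetry
    weight given to points above the baseline, so peaks barely pull it up.
    """
    n = len(y)
    if n < 10:
        raise DegenerateSampleError(f"series of length {n} is shorter than the smoother window")
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = (lam * (d2.T @ d2)).tocsc()
    # W + lam*D'D is symmetric pentadiagonal positive definite: use a banded solver
    ab0 = np.zeros((3, n))
    ab0[0, 2:] = penalty.diagonal(2)
    ab0[1, 1:] = penalty.diagonal(1)
    ab0[2, :] = penalty.diagonal(0)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        ab = ab0.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(c: Chromatogram, lam: float = 1e8, p: float = 0.01, niter: int = 10) -> Chromatogram:
    """Subtract the AsLS-estimated baseline, flooring the result at zero."""
    if c.baseline_corrected:
        raise PipelineOrderError(f"{c.sample_id}: already baseline-corrected")
    z = asls_baseline(c.values, lam=lam, p=p, niter=niter)
    out = np.maximum(c.values - z, 0.0)
    return c.copy_with(
        values=out, baseline_corrected=True, max_raw_resistance=float(c.values.max())
    )


def normalize(c: Chromatogram) -> Chromatogram:
    """Divide by the within-sample maximum so the highest resistance is 1."""
    if not c.baseline_corrected:
        raise PipelineOrderError(f"{c.sample_id}: normalise requires baseline correction first")
    if c.normalised:
        return c.copy_with()
    m = float(c.values.max())
    if m <= 0:
        raise DegenerateSampleError(f"{c.sample_id}: all-zero trace cannot be normalised")
    return c.copy_with(values=c.values / m, normalised=True)


def _xcorr_shift(x: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Integer lag (in ticks) maximising correlation of x against ref."""
    lags = np.arange(-max_shift, max_shift + 1)
    best_lag, best_val = 0, -np.inf
    for lag in lags:
        if lag >= 0:
            a, b = x[lag:], ref[: len(ref) - lag]
        else:
            a, b = x[:lag], ref[-lag:]
        v = float(np.dot(a, b))
        if v > best_val + 1e-12 or (abs(v - best_val) <= 1e-12 and abs(lag) < abs(best_lag)):
            best_val, best_lag = v, lag
    return int(best_lag)


def _shift_series(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift left by `lag` ticks (positive lag = trace was late), zero-filling edges."""
    out = np.zeros_like(x)
    if lag == 0:
        out[:] = x
    elif lag > 0:
        out[: len(x) - lag] = x[lag:]
    else:
        out[-lag:] = x[: len(x) + lag]
    return out


def align(
    samples: list[Chromatogram],
    max_shift_s: float = 30.0,
    reference: np.ndarray | None = None,
    piecewise: bool = False,
    segment_s: float = 300.0,
) -> list[Chromatogram]:
    """Shift each trace toward the pooled median reference.

    By default a single global shift per sample (handles the dominant
    batch retention offset); with ``piecewise=True`` each fixed-length
    segment is shifted independently.  Edges are zero-filled; output
    lengths equal input lengths.
    """
    if not samples:
        return []
    lengths = {len(c.values) for c in samples}
    if len(lengths) != 1:
        raise ValueError(
            f"mixed trace lengths {sorted(lengths)}: truncate all traces to a common length before aligning"
        )
    for c in samples:
        if not c.normalised:
            raise PipelineOrderError(f"{c.sample_id}: align requires normalised traces")
    tick = samples[0].tick_s
    ref = np.median(np.stack([c.values for c in samples]), axis=0) if reference is None else reference
    max_shift = max(1, int(round(max_shift_s / tick)))
    out = []
    for c in samples:
        if piecewise:
            seg = max(2 * max_shift + 1, int(round(segment_s / tick)))
            shifted = np.zeros_like(c.values)
            for start in range(0, len(c.values), seg):
                sl = slice(start, min(start + seg, len(c.values)))
                lag = _xcorr_shift(c.values[sl], ref[sl], min(max_shift, (sl.stop - sl.start) // 2))
                shifted[sl] = _shift_series(c.values[sl], lag)
            lag_global = 0
            out.append(c.copy_with(values=shifted, aligned=True, applied_shift_ticks=lag_global))
        else:
            lag = _xcorr_shift(c.values, ref, max_shift)
            out.append(
                c.copy_with(values=_shift_series(c.values, lag), aligned=True, applied_shift_ticks=lag)
            )
    return out


@dataclass(frozen=True)
class PreprocessConfig:
    asls_lam: float = 1e8
    asls_p: float = 0.01
    asls_niter: int = 10
    max_shift_s: float = 30.0
    piecewise: bool = False
    segment_s: float = 300.0


def _correct_and_normalise(samples: list[Chromatogram], cfg: PreprocessConfig) -> list[Chromatogram]:
    kept = []
    for c in samples:
        bc = baseline_correct(c, lam=cfg.asls_lam, p=cfg.asls_p, niter=cfg.asls_niter)
        try:
            kept.append(normalize(bc))
        except DegenerateSampleError:
            logger.warning("excluding degenerate (all-zero) sample %s", c.sample_id)
    return kept


def co_process(
    training: list[Chromatogram],
    validation: list[Chromatogram],
    cfg: PreprocessConfig = PreprocessConfig(),
) -> tuple[list[Chromatogram], list[Chromatogram]]:
    """Process both batches together, then hold the validation set back.

    Baseline correction and normalisation are per-sample; the alignment
    reference (pooled median trace) is computed from the combined set so
    the batches land on a common retention grid.  Returns the two
    partitions separately — downstream model fitting must receive only the
    training partition.
    """
    ids_t = {c.sample_id for c in training}
    ids_v = {c.sample_id for c in validation}
    overlap = ids_t & ids_v
    if overlap:
        raise ValueError(f"overlapping sample_ids between partitions: {sorted(overlap)}")
    proc_t = _correct_and_normalise(training, cfg)
    proc_v = _correct_and_normalise(validation, cfg)
    pooled = align(
        proc_t + proc_v, max_shift_s=cfg.max_shift_s, piecewise=cfg.piecewise, segment_s=cfg.segment_s
    )
    keep_t = {c.sample_id for c in proc_t}
    return [c for c in pooled if c.sample_id in keep_t], [c for c in pooled if c.sample_id not in keep_t]


def processing_log(samples: list[Chromatogram]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in samples],
            "applied_shift_ticks": [c.applied_shift_ticks for c in samples],
            "max_raw_resistance": [c.max_raw_resistance for c in samples],
            "baseline_corrected": [c.baseline_corrected for c in samples],
            "normalised": [c.normalised for c in samples],
            "aligned": [c.aligned for c in samples],
        }
    )
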