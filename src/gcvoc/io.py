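"""Reading and writing the sensor's two-column text chromatogram format.

Each file holds one sample: whitespace/comma-separated rows of
``time_s  resistance``, one row per 0.5 s sampling tick by default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from gcvoc.preprocess import Chromatogram


class MalformedChromatogramError(ValueError):
    """Raised when a chromatogram text file violates the format contract."""


def write_chromatogram(path: str | Path, values: np.ndarray, tick_s: float = 0.5) -> None:
    t = np.arange(len(values)) * tick_s
    np.savetxt(path, np.column_stack([t, values]), fmt=["%.6g", "%.10g"], delimiter="\t")


def read_chromatogram(path: str | Path, sample_id: str | None = None, batch: str = "") -> Chromatogram:
    """Parse a two-column (time_s, resistance) text file into a Chromatogram.

    The time column must be uniformly and strictly increasing; resistances
    must be finite and positive.
    """
    path = Path(path)
    try:
        arr = np.loadtxt(path, delimiter=None, ndmin=2)
    except ValueError as exc:
        raise MalformedChromatogramError(f"{path}: cannot parse numeric columns ({exc})") from exc
    if arr.shape[1] != 2:
        raise MalformedChromatogramError(f"{path}: expected 2 columns, found {arr.shape[1]}")
    t, v = arr[:, 0], arr[:, 1]
    if len(t) < 2:
        raise MalformedChromatogramError(f"{path}: need at least 2 rows")
    dt = np.diff(t)
    tick = dt[0]
    if tick <= 0:
        raise MalformedChromatogramError(f"{path}: non-increasing time at row 2")
    bad = np.nonzero(np.abs(dt - tick) > 1e-6 * max(tick, 1.0))[0]
    if bad.size:
        row = int(bad[0]) + 2  # 1-based row of the offending tick
        raise MalformedChromatogramError(
            f"{path}: non-uniform tick spacing at row {row} (expected {tick}, got {dt[bad[0]]})"
        )
    if not np.all(np.isfinite(v)):
        raise MalformedChromatogramError(f"{path}: non-finite resistance value")
    if np.any(v <= 0):
        row = int(np.nonzero(v <= 0)[0][0]) + 1
        raise MalformedChromatogramError(f"{path}: non-positive resistance at row {row}")
    return Chromatogram(sample_id=sample_id or path.stem, tick_s=float(tick), values=v, batch=batch)


def read_manifest(cohort_dir: str | Path) -> tuple[dict[str, Chromatogram], pd.DataFrame]:
    """Load a cohort written by :func:`gcvoc.simulate.write_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    records = pd.read_csv(cohort_dir / "metadata.csv")
    batch_of = dict(zip(records["sample_id"], records["batch"]))
    missing = [
        sid for sid, rel in zip(manifest["sample_id"], manifest["path"])
        if not (cohort_dir / rel).exists()
    ]
    if missing:
        raise FileNotFoundError(f"manifest names missing chromatogram files: {missing}")
    chroms = {
        sid: read_chromatogram(cohort_dir / rel, sample_id=sid, batch=batch_of.get(sid, ""))
        for sid, rel in zip(manifest["sample_id"], manifest["path"])
    }
    return chroms, records
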