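"""Tidy CSV and TIFF interchange.

Trace interchange uses two CSVs: a per-flash table (sample_id, cycle, phase,
t_abs_s, t_local_s, Fs, Fm_prime) and a per-sample companion (sample_id, Fo,
Fm).  Plate stacks are multi-page grayscale TIFF, dark-adapted Fo/Fm frames
first, then one page per flash.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .npq import FluorescenceTrace, NPQSeries, TraceDataError
from .protocol import FlashSchedule

FLASH_COLUMNS = ["sample_id", "flash", "cycle", "phase", "t_abs_s", "t_local_s", "Fs", "Fm_prime"]
SAMPLE_COLUMNS = ["sample_id", "Fo", "Fm"]


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    buf = _io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_traces(
    traces: list[FluorescenceTrace],
    flashes_path,
    samples_path,
    header_comment: str | None = None,
) -> None:
    flash_df = pd.concat([t.to_frame() for t in traces], ignore_index=True)
    sample_df = pd.DataFrame(
        [{"sample_id": t.sample_id, "Fo": t.fo, "Fm": t.fm} for t in traces]
    )
    _write_csv(flash_df[FLASH_COLUMNS], flashes_path, header_comment)
    _write_csv(sample_df, samples_path, header_comment)


def read_traces(
    flashes_path, samples_path, schedule: FlashSchedule
) -> tuple[list[FluorescenceTrace], list[str]]:
    """Load traces; returns (traces, per-sample error messages).

    A malformed sample is reported and skipped so the rest of the run can
    proceed.
    """
    flash_df = pd.read_csv(flashes_path, comment="#")
    sample_df = pd.read_csv(samples_path, comment="#").set_index("sample_id")
    traces: list[FluorescenceTrace] = []
    errors: list[str] = []
    for sid, grp in flash_df.groupby("sample_id", sort=False):
        try:
            if sid not in sample_df.index:
                raise TraceDataError(f"{sid}: missing Fo/Fm row")
            grp = grp.sort_values("flash")
            traces.append(
                FluorescenceTrace(
                    sample_id=str(sid),
                    fo=float(sample_df.loc[sid, "Fo"]),
                    fm=float(sample_df.loc[sid, "Fm"]),
                    fm_prime=grp["Fm_prime"].to_numpy(dtype=float),
                    schedule=schedule,
                    fs=grp["Fs"].to_numpy(dtype=float) if "Fs" in grp else None,
                )
            )
        except (TraceDataError, ValueError, KeyError) as exc:
            errors.append(f"{sid}: {exc}")
    return traces, errors


def write_npq_series(series_list: list[NPQSeries], path, header_comment: str | None = None) -> None:
    df = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    _write_csv(df, path, header_comment)


def write_stack(stack: np.ndarray, path) -> None:
    """Multi-page grayscale TIFF, one page per frame (Fo, Fm, flashes...)."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
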