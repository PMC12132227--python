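"""Per-well and ROI mean-fluorescence extraction from plate image stacks.

The leaf-disc approach images a 96-well plate of leaf discs with a
fluorescence imager; each measurement (dark-adapted Fo, Fm, then one frame
per saturating flash) is one grayscale frame.  Extraction reduces each frame
to the mean pixel intensity inside a fixed circular mask per well — mirroring
manual ROI quantification over discs of roughly 320 pixels.  Masks come from
the plate-layout config; there is no automated disc detection.

Frame convention: frame 0 = Fo, frame 1 = Fm, frames 2.. = flashes in
schedule order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .npq import FluorescenceTrace
from .protocol import FlashSchedule


class LayoutError(ValueError):
    """Raised for invalid plate layouts or stack/layout mismatches."""


ROW_LETTERS = "ABCDEFGH"


def well_name(row: int, col: int) -> str:
    return f"{ROW_LETTERS[row]}{col + 1}"


@dataclass
class PlateLayout:
    """Geometry of a 96-well plate image.

    Well centers are laid out row-major (A1..H12) on a regular grid unless
    explicit ``centers`` are given.  ``disc_radius_px`` ~ 10 px gives a disc
    area of ~320 px, matching typical leaf-disc ROIs.
    """

    n_rows: int = 8
    n_cols: int = 12
    image_shape: tuple[int, int] = (360, 520)
    disc_radius_px: float = 10.0
    background: float = 0.0
    margin_px: float = 40.0
    centers: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.centers is None:
            h, w = self.image_shape
            ys = np.linspace(self.margin_px, h - self.margin_px, self.n_rows)
            xs = np.linspace(self.margin_px, w - self.margin_px, self.n_cols)
            cy, cx = np.meshgrid(ys, xs, indexing="ij")
            self.centers = np.column_stack([cy.ravel(), cx.ravel()])
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape != (self.n_rows * self.n_cols, 2):
            raise LayoutError(
                f"centers must be ({self.n_rows * self.n_cols}, 2), "
                f"got {self.centers.shape}"
            )
        h, w = self.image_shape
        r = self.disc_radius_px
        if (
            (self.centers[:, 0] - r < 0).any()
            or (self.centers[:, 0] + r > h).any()
            or (self.centers[:, 1] - r < 0).any()
            or (self.centers[:, 1] + r > w).any()
        ):
            raise LayoutError("a disc mask extends outside the image")
        # pairwise center distance must exceed 2r (no overlapping masks)
        d = np.linalg.norm(self.centers[:, None, :] - self.centers[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if (d <= 2 * r).any():
            raise LayoutError("disc masks overlap")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def well_names(self) -> list[str]:
        return [well_name(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def disc_mask(self, well_index: int) -> np.ndarray:
        """Boolean mask of the circular disc for one well."""
        cy, cx = self.centers[well_index]
        h, w = self.image_shape
        yy, xx = np.ogrid[:h, :w]
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.disc_radius_px**2


def extract_well_series(
    stack: np.ndarray,
    layout: PlateLayout,
    empty_margin: float = 0.3,
) -> pd.DataFrame:
    """Mean disc intensity per well per frame.

    Returns a tidy frame with columns ``well``, ``frame``, ``value`` and an
    ``empty`` flag per well; a well is empty when its mean never rises above
    ``background + empty_margin`` in any frame.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise LayoutError(f"expected a (frames, H, W) stack, got ndim={stack.ndim}")
    if stack.shape[1:] != layout.image_shape:
        raise LayoutError(
            f"frame shape {stack.shape[1:]} does not match layout {layout.image_shape}"
        )
    records = []
    for i, name in enumerate(layout.well_names):
        mask = layout.disc_mask(i)
        means = stack[:, mask].mean(axis=1)
        empty = bool((means <= layout.background + empty_margin).all())
        for frame, v in enumerate(means):
            records.append((name, frame, float(v), empty))
    return pd.DataFrame(records, columns=["well", "frame", "value", "empty"])


def extract_roi_series(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean intensity inside an arbitrary ROI mask, one value per frame.

    Used for the whole-plant approach, where the ROI is a manually chosen
    leaf region rather than a plate well.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.ndim != 3:
        raise LayoutError(f"expected a (frames, H, W) stack, got ndim={stack.ndim}")
    if mask.shape != stack.shape[1:]:
        raise LayoutError(f"mask shape {mask.shape} does not match frames {stack.shape[1:]}")
    if not mask.any():
        raise LayoutError("empty ROI mask")
    return stack[:, mask].mean(axis=1)


def traces_from_stack(
    stack: np.ndarray,
    layout: PlateLayout,
    schedule: FlashSchedule,
    empty_margin: float = 0.3,
) -> list[FluorescenceTrace]:
    """Build per-well fluorescence traces from a plate stack.

    Frames 0 and 1 map to Fo and Fm; the remaining frames to the schedule's
    flashes.  Empty wells are skipped.
    """
    if stack.shape[0] != schedule.n_flashes + 2:
        raise LayoutError(
            f"stack has {stack.shape[0]} frames; schedule needs "
            f"{schedule.n_flashes + 2} (Fo, Fm, flashes)"
        )
    table = extract_well_series(stack, layout, empty_margin=empty_margin)
    traces = []
    for well, grp in table.groupby("well", sort=False):
        if grp["empty"].iloc[0]:
            continue
        vals = grp.sort_values("frame")["value"].to_numpy()
        traces.append(
            FluorescenceTrace(
                sample_id=well,
                fo=float(vals[0]),
                fm=float(vals[1]),
                fm_prime=vals[2:],
                schedule=schedule,
                meta={"source": "plate_stack", "well": well},
            )
        )
    return traces
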