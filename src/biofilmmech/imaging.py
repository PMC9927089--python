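"""COMSTAT-style quantification of two-channel confocal stacks.

For each channel (bacterial cells, EPS matrix) the stack is binarized (Otsu
over the whole 3-D histogram by default, or a fixed cutoff), and two
summary statistics are computed:

* **biomass** — thresholded biovolume per substratum area, µm³/µm²;
* **roughness coefficient** Ra — normalized mean absolute deviation of the
  per-(y, x) column heights, Ra = Σ|h_i − h̄| / (N·h̄); 0 for a perfectly
  uniform layer, larger for punctate, heterogeneous structure.  Column
  height uses the top-most occupied voxel (empty columns count as height 0
  and are included in N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .datatypes import ImageStack
from .errors import DegenerateHistogramError, DomainError, UndefinedRoughnessError

__all__ = [
    "QuantResult",
    "binarize_channel",
    "biomass",
    "column_heights",
    "roughness_coefficient",
    "quantify_stack",
]


@dataclass(frozen=True)
class QuantResult:
    """Per-channel quantification summary."""

    channel: str
    biomass: float              # µm³/µm²
    roughness: float | None     # dimensionless; None if channel is empty
    mean_column_height: float   # µm
    threshold: float | None     # intensity cutoff used; None for boolean input


def binarize_channel(
    stack: ImageStack, channel: str, method: str = "otsu"
) -> tuple[np.ndarray, float | None]:
    """Binarize one channel; returns (boolean stack, threshold used).

    ``method`` is ``"otsu"`` or ``"fixed:<value>"`` (voxels strictly greater
    than the cutoff become True).  Boolean input passes through unchanged.
    """
    arr = np.asarray(stack.channels[channel])
    if arr.dtype == bool:
        return arr, None
    if method == "otsu":
        if np.ptp(arr) == 0:
            raise DegenerateHistogramError(
                f"channel {channel!r} has constant intensity; Otsu is undefined "
                f"— use method='fixed:<value>'")
        thr = float(threshold_otsu(arr))
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    else:
        raise DomainError(f"unknown binarization method {method!r}")
    return arr > thr, thr


def biomass(boolstack: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Biovolume per substratum area, µm³/µm².

    (true-voxel count × dz·dy·dx) / (ny·dy × nx·dx); equals the physical
    slab height for a completely filled stack.
    """
    boolstack = np.asarray(boolstack, dtype=bool)
    dz, dy, dx = voxel_size
    _, ny, nx = boolstack.shape
    return float(boolstack.sum() * dz * dy * dx / (ny * dy * nx * dx))


def column_heights(boolstack: np.ndarray, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Per-(y, x) column height in µm: (1 + top-most occupied z index)·dz.

    Gaps below the top-most voxel do not reduce the height (COMSTAT
    convention); empty columns have height 0.
    """
    boolstack = np.asarray(boolstack, dtype=bool)
    nz = boolstack.shape[0]
    dz = voxel_size[0]
    any_col = boolstack.any(axis=0)
    # highest occupied index per column: nz-1 − argmax over reversed z
    top = nz - 1 - np.argmax(boolstack[::-1], axis=0)
    heights = np.where(any_col, (top + 1) * dz, 0.0)
    return heights


def roughness_coefficient(heights: np.ndarray) -> float:
    """Ra = mean(|h − h̄|) / h̄ over all columns (zeros included)."""
    heights = np.asarray(heights, dtype=float).ravel()
    if heights.size == 0:
        raise DomainError("need at least one column")
    hbar = heights.mean()
    if hbar <= 0:
        raise UndefinedRoughnessError("all column heights are zero; Ra is undefined")
    return float(np.mean(np.abs(heights - hbar)) / hbar)


def quantify_stack(
    stack: ImageStack, method: str = "otsu"
) -> dict[str, QuantResult]:
    """Biomass, roughness, and mean column height for every channel."""
    out: dict[str, QuantResult] = {}
    for channel in stack.channels:
        boolstack, thr = binarize_channel(stack, channel, method=method)
        heights = column_heights(boolstack, stack.voxel_size)
        try:
            ra = roughness_coefficient(heights)
        except UndefinedRoughnessError:
            ra = None
        out[channel] = QuantResult(
            channel=channel,
            biomass=biomass(boolstack, stack.voxel_size),
            roughness=ra,
            mean_column_height=float(heights.mean()),
            threshold=thr,
        )
    return out
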