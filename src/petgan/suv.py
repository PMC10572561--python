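"""Organ-wise SUV_mean readout and error tables.

SUV readout must happen on denormalized stacks (values in SUV units); the
functions here operate on :class:`~petgan.io.ImageStack` voxels directly and
assume the caller has already inverted any [−1,1] normalization.  ROIs are
boolean masks aligned to the stack, typically derived from the phantom label
map (or a user-supplied integer-label NIfTI for real data).  Membership is
by voxel center; no fractional partial-volume weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["OrganROI", "suv_mean", "suv_error_table", "rois_from_label_map"]


@dataclass
class OrganROI:
    """A named voxel mask aligned to an image stack."""

    name: str
    mask: np.ndarray    # boolean, same shape as the stack

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ConfigError(f"ROI {self.name!r} is empty")


def rois_from_label_map(label_map: np.ndarray, names: dict | list) -> list:
    """Build ROIs from an integer label map.

    ``names`` maps label value → organ name, or is a list whose i-th entry
    names label i+1 (the phantom convention, 0 = background).
    """
    if isinstance(names, (list, tuple)):
        names = {i + 1: n for i, n in enumerate(names)}
    merged: dict = {}
    for label, name in names.items():
        mask = label_map == label
        if mask.any():
            # several labels may share one tissue name; merge their masks
            merged[name] = mask | merged.get(name, False)
    return [OrganROI(name=n, mask=m) for n, m in merged.items()]


def suv_mean(stack, roi: OrganROI) -> float:
    """Arithmetic mean of voxel values (SUV) inside the ROI mask."""
    vox = np.asarray(stack.voxels if hasattr(stack, "voxels") else stack,
                     dtype=float)
    if roi.mask.shape != vox.shape:
        raise ConfigError(
            f"ROI {roi.name!r} shape {roi.mask.shape} does not match stack "
            f"{vox.shape}")
    return float(vox[roi.mask].mean())


def suv_error_table(gen_stack, gt_stack, rois) -> pd.DataFrame:
    """Per-organ SUV_mean of generated and ground-truth stacks and the
    absolute error |SUV_gen − SUV_gt|."""
    rows = []
    for roi in rois:
        sg = suv_mean(gen_stack, roi)
        st = suv_mean(gt_stack, roi)
        rows.append({"organ": roi.name, "suv_mean_generated": sg,
                     "suv_mean_ground_truth": st,
                     "absolute_error": abs(sg - st)})
    return pd.DataFrame(rows)
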