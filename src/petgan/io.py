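"""Image-stack I/O, [−1,1] normalization, subject-level splits and batching.

Axis order is (slice, row, col), 0-based, slice 0 at the top of the head.
Files hold SUV-valued voxels (NIfTI-1); normalization to [−1,1] happens in
memory at training time so that SUV readout stays exact.  Normalization is
computed per subject over the union of that subject's early and delayed
stacks, so both time points share one affine map and the uptake change
between them survives normalization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

from .errors import ConfigError, DataError

__all__ = ["ImageStack", "NormParams", "PairedSample", "normalize",
           "denormalize", "split_subjects", "make_batches", "read_nifti",
           "write_nifti", "pair_slices"]


@dataclass
class ImageStack:
    """A 3-D activity volume in SUV with acquisition metadata."""

    voxels: np.ndarray              # (slice, row, col)
    spacing: tuple = (4.0, 4.0, 4.0)  # mm per axis, same order
    subject_id: str = ""
    time_post_injection: float = 0.0  # minutes

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DataError(f"expected 3-D voxels, got {self.voxels.ndim}-D")
        if len(self.spacing) != 3:
            raise DataError("spacing must have three entries")
        if not np.all(np.isfinite(self.voxels)):
            raise DataError("voxels contain non-finite values")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class NormParams:
    """The affine map sending SUV range [lo, hi] onto [−1, 1]."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ConfigError(f"need hi > lo, got [{self.lo}, {self.hi}]")


@dataclass
class PairedSample:
    """One training unit: an aligned early/delayed axial slice pair in [−1,1]."""

    early_slice: np.ndarray
    late_slice: np.ndarray
    subject_id: str
    slice_index: int
    t_early: float
    t_late: float
    norm: NormParams | None = None


def normalize(stack: ImageStack, params: NormParams | None = None):
    """Map voxel values affinely so [lo, hi] → [−1, 1].

    With ``params=None`` the range is taken from the stack's extremes.
    Returns (normalized stack, params); the params invert the map exactly.
    """
    if params is None:
        lo, hi = float(stack.voxels.min()), float(stack.voxels.max())
        if hi <= lo:
            raise ConfigError(
                "constant stack: cannot derive a normalization range")
        params = NormParams(lo, hi)
    x = stack.voxels
    y = 2.0 * (x - params.lo) / (params.hi - params.lo) - 1.0
    return replace(stack, voxels=y), params


def denormalize(stack: ImageStack, params: NormParams) -> ImageStack:
    """Inverse of :func:`normalize`: [−1, 1] back to SUV."""
    y = stack.voxels
    x = (y + 1.0) * 0.5 * (params.hi - params.lo) + params.lo
    return replace(stack, voxels=x)


def norm_params_for_pair(early: ImageStack, late: ImageStack) -> NormParams:
    """Shared normalization over the union of the two time points."""
    lo = float(min(early.voxels.min(), late.voxels.min()))
    hi = float(max(early.voxels.max(), late.voxels.max()))
    if hi <= lo:
        raise ConfigError("constant subject pair: degenerate range")
    return NormParams(lo, hi)


def pair_slices(early: ImageStack, late: ImageStack,
                params: NormParams | None = None) -> list:
    """Slice two aligned stacks into normalized :class:`PairedSample`s."""
    if early.voxels.shape != late.voxels.shape:
        raise DataError("early/late stacks have different shapes")
    if params is None:
        params = norm_params_for_pair(early, late)
    e, _ = normalize(early, params)
    l, _ = normalize(late, params)
    return [PairedSample(e.voxels[i], l.voxels[i], early.subject_id, i,
                         early.time_post_injection, late.time_post_injection,
                         norm=params)
            for i in range(early.n_slices)]


def split_subjects(subject_ids, counts=(12, 4, 2), seed: int = 0) -> dict:
    """Subject-level train/val/test assignment.

    Every slice of a subject inherits the subject's split, so no subject can
    leak across splits.  Deterministic for a given seed.
    """
    subject_ids = list(subject_ids)
    if sum(counts) != len(subject_ids):
        raise ConfigError(
            f"counts {tuple(counts)} sum to {sum(counts)} but there are "
            f"{len(subject_ids)} subjects")
    order = list(np.random.default_rng(seed).permutation(len(subject_ids)))
    names = ("train", "val", "test")
    out = {}
    pos = 0
    for name, cnt in zip(names, counts):
        for i in order[pos:pos + cnt]:
            out[subject_ids[i]] = name
        pos += cnt
    return out


def make_batches(samples, batch_size: int = 4, shuffle: bool = False,
                 seed: int = 0):
    """Yield lists of samples; every sample appears exactly once per epoch.

    The final batch may be short.  Shuffle order is seed-deterministic.
    """
    if batch_size < 1:
        raise ConfigError(f"batch_size must be >= 1, got {batch_size}")
    samples = list(samples)
    idx = np.arange(len(samples))
    if shuffle:
        idx = np.random.default_rng(seed).permutation(idx)
    for start in range(0, len(samples), batch_size):
        yield [samples[i] for i in idx[start:start + batch_size]]


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def write_nifti(stack: ImageStack, path: str) -> None:
    """Write a stack as NIfTI-1, spacing in the header zooms and metadata in
    the description field."""
    affine = np.diag([*stack.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(stack.voxels, dtype=np.float64), affine)
    img.header.set_zooms(stack.spacing)
    desc = f"subject={stack.subject_id};t={stack.time_post_injection}"
    img.header["descrip"] = desc.encode()[:79]
    nib.save(img, path)


def read_nifti(path: str) -> ImageStack:
    """Read a NIfTI file written by :func:`write_nifti` (or any 3-D NIfTI)."""
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    try:
        img = nib.load(path)
        vox = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise DataError(f"cannot read NIfTI file {path}: {exc}") from exc
    if vox.ndim != 3:
        raise DataError(f"{path}: expected a 3-D volume, got {vox.ndim}-D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    subject_id, t = "", 0.0
    desc = img.header["descrip"].tobytes().split(b"\x00")[0].decode(
        "ascii", "ignore")
    for part in desc.split(";"):
        if part.startswith("subject="):
            subject_id = part[len("subject="):]
        elif part.startswith("t="):
            try:
                t = float(part[2:])
            except ValueError:
                pass
    return ImageStack(voxels=vox, spacing=zooms, subject_id=subject_id,
                      time_post_injection=t)
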