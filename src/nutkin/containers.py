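"""Shared data containers of the pipeline.

A :class:`Kymograph` is a scalar field on a (time × position) grid — the
workhorse display of growth kinematics.  Axis conventions are explicit:
``axis_origin`` records whether positions are measured from the clamped
base or from the apex, because growth profiles are only steady in the
apex-attached frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Kymograph", "NodeTracks", "ProfilePair", "FrameSequence"]


@dataclass
class Kymograph:
    """Scalar field on a rectangular (time × position) grid.

    Attributes
    ----------
    field_name : what the values are (e.g. ``"curvature"``).
    times : (n_times,) strictly increasing instants (h).
    positions : (n_pos,) strictly increasing positions (mm).
    axis_origin : ``"from_base"`` or ``"from_apex"``.
    values : (n_times, n_pos) field values.
    mask : (n_times, n_pos) bool, ``True`` marks missing cells.
    units : units of the values.
    positions_t : optional (n_times, n_pos) time-varying positions for
        fields attached to material points (e.g. interfoliolar segments);
        ``positions`` then holds the time-mean.
    """

    field_name: str
    times: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    axis_origin: str = "from_base"
    units: str = ""
    mask: Optional[np.ndarray] = None
    positions_t: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.times), len(self.positions)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n_times={len(self.times)}, n_pos={len(self.positions)})"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.axis_origin not in ("from_base", "from_apex"):
            raise ValueError(f"unknown axis_origin {self.axis_origin!r}")

    @property
    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.mask)

    def cell_positions(self) -> np.ndarray:
        """(n_times, n_pos) position of every cell (uses positions_t if set)."""
        if self.positions_t is not None:
            return self.positions_t
        return np.broadcast_to(self.positions, self.values.shape)


@dataclass
class NodeTracks:
    """Linked positions of node markers over time.

    positions are image-plane coordinates (mm); ``visible`` flags frames
    where a node was actually detected (markers fade, split, or get
    occluded in real footage).
    """

    node_ids: np.ndarray
    times: np.ndarray
    positions: np.ndarray  # (n_times, n_nodes, 2) mm
    visible: np.ndarray  # (n_times, n_nodes) bool
    plane_label: str = "top"
    flags: list = field(default_factory=list)  # (frame, node) pairs needing manual review

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        n_t, n_n = len(self.times), len(self.node_ids)
        if self.positions.shape != (n_t, n_n, 2):
            raise ValueError(f"positions shape {self.positions.shape} != ({n_t}, {n_n}, 2)")
        if self.visible.shape != (n_t, n_n):
            raise ValueError("visible shape mismatch")
        if n_t > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class ProfilePair:
    """Time-averaged spatial profiles in the apex frame.

    ``mean_rate`` is the average elongation rate per apex-distance bin and
    ``diff_rate_envelope`` the averaged envelope of the differential
    elongation rate, on a common grid of bin centres.
    """

    apex_dist: np.ndarray
    mean_rate: np.ndarray
    diff_rate_envelope: np.ndarray
    counts_mean: np.ndarray
    counts_diff: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.apex_dist)
        for name in ("mean_rate", "diff_rate_envelope", "counts_mean", "counts_diff"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} shape {arr.shape} != ({n},)")


@dataclass
class FrameSequence:
    """A stack of grayscale frames at constant interval."""

    times: np.ndarray
    images: np.ndarray  # (n_frames, height, width), intensities in [0, 1]
    mm_per_px: float
    plane_label: str = "top"
    origin_mm: tuple = (0.0, 0.0)  # world coords of pixel (row 0, col 0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != len(self.times):
            raise ValueError("images must be (n_frames, H, W) matching times")
        if len(self.times) > 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("frame interval must be constant")
        if self.images.min() < -1e-9 or self.images.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.times)
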