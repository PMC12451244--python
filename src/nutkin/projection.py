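"""Orthogonal camera projection and apparent elongation rates.

Nutation bends the rachis within a (here horizontal) plane.  A top-view
camera looks along the normal of that plane and sees the true midline; a
side-view camera looks within the plane, so the bending motion carries
material segments towards and away from it and their *projected* lengths
oscillate even when the tissue elongates steadily.  The apparent elongation
rate measured on a side view is therefore the sum of

* a material term — the true elongation rate of the observed lateral face,
  which carries the differential-growth oscillation at the nutation period
  ``T``; and
* a geometric term — ``d/dt ln|cos θ|`` for a segment at angle θ to the
  image plane, an even function of θ that oscillates at ``T/2`` and can
  drive the apparent rate negative.

Disentangling the two (frequency ratio 2:1) is what the wavelet analysis
downstream is for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Kymograph
from .model import RachisTrajectory

__all__ = ["ProjectionSetup", "apparent_elongation", "mode_origin_decomposition"]

_FACE_OFFSET = {"outer": -1.0, "inner": +1.0, "midline": 0.0}


@dataclass
class ProjectionSetup:
    """Observation geometry.

    ``plane_label='top'`` is the true (bending-plane) view.  For
    ``'side'`` the camera lies in the bending plane; ``azimuth`` rotates
    its line of sight within that plane (0 = looking along +y, image axis
    = x).
    """

    plane_label: str = "side"
    azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.plane_label not in ("top", "side"):
            raise ValueError(f"unknown plane_label {self.plane_label!r}")

    @property
    def view_axis(self) -> np.ndarray:
        """Unit line-of-sight direction (3D, bending plane = xy)."""
        if self.plane_label == "top":
            return np.array([0.0, 0.0, 1.0])
        return np.array([np.sin(self.azimuth), np.cos(self.azimuth), 0.0])


def _face_polyline(traj: RachisTrajectory, face: str) -> np.ndarray:
    """(n_times, n_markers, 2) positions of the requested lateral face.

    The outer face is offset by ``-W/2`` along the left normal
    ``(-sinθ, cosθ)``: its arclength element carries the factor
    ``(1 + C·W/2)``, so it is the face whose rate is ``Ė + δĖ/2``.
    """
    if face not in _FACE_OFFSET:
        raise ValueError(f"face must be one of {sorted(_FACE_OFFSET)}")
    off = _FACE_OFFSET[face]
    if off == 0.0:
        return traj.xy
    if traj.params is None:
        raise ValueError("face-resolved projection needs traj.params for the beam width")
    w = off * traj.params.W / 2.0
    normal = np.stack([-np.sin(traj.theta), np.cos(traj.theta)], axis=-1)
    return traj.xy + w * normal


def _segment_lengths(traj, setup: ProjectionSetup, face: str):
    """True and projected lengths of material segments of the face polyline."""
    poly = _face_polyline(traj, face)
    seg = np.diff(poly, axis=1)  # (n_t, n-1, 2)
    true_len = np.hypot(seg[..., 0], seg[..., 1])
    if setup.plane_label == "top":
        proj_len = true_len.copy()
    else:
        u = poly[..., 0] * np.cos(setup.azimuth) - poly[..., 1] * np.sin(setup.azimuth)
        proj_len = np.abs(np.diff(u, axis=1))
    return true_len, proj_len


def _segment_apex_dist(traj) -> np.ndarray:
    """(n_times, n_segments) apex distance of segment midpoints."""
    s_mid = 0.5 * (traj.s[:, 1:] + traj.s[:, :-1])
    return traj.apex_s[:, None] - s_mid


def _default_grid(traj, n_pos: int = 80) -> np.ndarray:
    sp = _segment_apex_dist(traj)
    lo = max(float(sp.min(axis=1).max()), 0.0) + 1e-9
    hi = float(sp.max(axis=1).min()) - 1e-9
    return np.linspace(lo, hi, n_pos)


def _resample(rate, sp, grid):
    """Interpolate per-frame segment rates onto a fixed apex-distance grid."""
    n_t = rate.shape[0]
    out = np.full((n_t, len(grid)), np.nan)
    for k in range(n_t):
        x, y = sp[k], rate[k]
        good = np.isfinite(y)
        if good.sum() < 2:
            continue
        order = np.argsort(x[good])
        xv, yv = x[good][order], y[good][order]
        out[k] = np.interp(grid, xv, yv, left=np.nan, right=np.nan)
    return out


def apparent_elongation(
    traj: RachisTrajectory,
    setup: ProjectionSetup | None = None,
    face: str = "outer",
    positions=None,
    min_cos: float = 1e-6,
) -> Kymograph:
    """Apparent elongation-rate kymograph as seen by the camera.

    For each material segment of the observed face the apparent rate is
    ``d/dt ln(projected length)``.  In a side view of planar bending this
    equals the face's true rate plus ``d/dt ln|cos θ|``; at ``θ ≡ 0`` it
    reduces to the true rate.  Segments nearly perpendicular to the image
    plane (``|cos θ| < min_cos``) are masked, not errors.

    Returns a :class:`Kymograph` on a fixed apex-distance grid
    (``axis_origin='from_apex'``).
    """
    setup = setup or ProjectionSetup()
    true_len, proj_len = _segment_lengths(traj, setup, face)
    perp = proj_len < min_cos * true_len
    logp = np.where(perp, np.nan, np.log(np.where(perp, 1.0, proj_len)))
    rate = np.gradient(logp, traj.times, axis=0)
    sp = _segment_apex_dist(traj)
    grid = _default_grid(traj) if positions is None else np.asarray(positions, float)
    values = _resample(rate, sp, grid)
    return Kymograph(
        field_name=f"apparent_elongation[{setup.plane_label},{face}]",
        times=traj.times,
        positions=grid,
        values=values,
        axis_origin="from_apex",
        units="1/h",
    )


def mode_origin_decomposition(
    traj: RachisTrajectory,
    setup: ProjectionSetup | None = None,
    face: str = "outer",
    positions=None,
    min_cos: float = 1e-6,
):
    """Split the apparent rate into geometric and material terms.

    * geometric: ``d/dt ln(projected length / true length)`` — zero for a
      straight organ, frequency ``2/T`` for a symmetric θ oscillation;
    * material: ``d/dt ln(true face length)`` — the tissue's own rate,
      carrying the δĖ oscillation at frequency ``1/T``.

    Their sum reconstructs :func:`apparent_elongation` exactly (both are
    computed from the same discrete segment lengths and resampled with the
    same operator).

    Returns ``(geometric, material)`` kymographs.
    """
    setup = setup or ProjectionSetup()
    true_len, proj_len = _segment_lengths(traj, setup, face)
    perp = proj_len < min_cos * true_len
    ratio = np.where(perp, np.nan, proj_len / true_len)
    geo = np.gradient(np.log(ratio), traj.times, axis=0)
    mat = np.gradient(np.log(true_len), traj.times, axis=0)
    sp = _segment_apex_dist(traj)
    grid = _default_grid(traj) if positions is None else np.asarray(positions, float)
    kw = dict(times=traj.times, positions=grid, axis_origin="from_apex", units="1/h")
    geo_k = Kymograph(
        field_name=f"apparent_elongation_geometric[{setup.plane_label},{face}]",
        values=_resample(geo, sp, grid),
        **kw,
    )
    mat_k = Kymograph(
        field_name=f"apparent_elongation_material[{setup.plane_label},{face}]",
        values=_resample(mat, sp, grid),
        **kw,
    )
    return geo_k, mat_k
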