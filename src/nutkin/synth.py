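"""Synthetic time-lapse data with known ground truth.

Emulates everything the measurement chain consumes, in place of real
footage of a nutating rachis: fluorescent node markers advected by growth
(with jitter and dropout, mimicking dots that fade, split or get occluded),
speckle-textured organ images for image-correlation tests (pigment patterns
painted on the organ, advected and diluted by growth), and noisy curvature /
elongation kymographs sampled from the simulated trajectory.

Default frame intervals mirror typical acquisitions: 2.5 min for top views
(curvature and coarse elongation) and 1 min for side views (fine
image-correlation measurements).

A single integer seed fans out to independent per-product substreams, so
every product is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .containers import FrameSequence, Kymograph, NodeTracks
from .model import GrowthLawParams, RachisTrajectory, simulate
from .projection import ProjectionSetup, apparent_elongation

__all__ = [
    "SyntheticDataset",
    "make_node_tracks",
    "render_frames",
    "make_kymograph_dataset",
    "TOP_VIEW_INTERVAL_H",
    "SIDE_VIEW_INTERVAL_H",
]

TOP_VIEW_INTERVAL_H = 2.5 / 60.0
SIDE_VIEW_INTERVAL_H = 1.0 / 60.0


@dataclass
class SyntheticDataset:
    """Bundle of synthetic products with the generating truth attached."""

    params: GrowthLawParams
    truth: RachisTrajectory
    curvature_kymo: Kymograph
    elong_kymo: Kymograph
    node_tracks: NodeTracks
    frames: Optional[FrameSequence]
    seed: int


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _material_interp(traj: RachisTrajectory, material_s0, t_idx):
    """Arclength at time index ``t_idx`` of material points labelled by
    their initial arclength ``material_s0`` (linear in material label)."""
    return np.interp(material_s0, traj.material_ids, traj.s[t_idx])


def _positions_at(traj: RachisTrajectory, s_query, t_idx):
    """Planar position and angle at arclengths ``s_query`` (time t_idx)."""
    x = np.interp(s_query, traj.s[t_idx], traj.xy[t_idx, :, 0])
    y = np.interp(s_query, traj.s[t_idx], traj.xy[t_idx, :, 1])
    th = np.interp(s_query, traj.s[t_idx], traj.theta[t_idx])
    return x, y, th


def make_node_tracks(
    traj: RachisTrajectory,
    n_nodes: int = 11,
    noise_sd: float = 0.0,
    dropout_p: float = 0.0,
    seed: int = 0,
    stride: int = 1,
    plane_label: str = "top",
) -> NodeTracks:
    """Ground-truth node tracks: markers at fixed material coordinates.

    Nodes sit at ``n_nodes`` evenly spaced material arclengths (base and
    apex included) and are advected by growth.  Gaussian jitter of
    ``noise_sd`` mm is added independently per frame and coordinate;
    frames are flagged invisible with probability ``dropout_p``.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_nodes > traj.n_markers:
        raise ValueError(f"n_nodes={n_nodes} exceeds marker count {traj.n_markers}")
    rng_noise, rng_drop = _streams(seed, 2)
    t_idx = np.arange(0, traj.n_times, stride)
    times = traj.times[t_idx]
    mat = np.linspace(traj.material_ids[0], traj.material_ids[-1], n_nodes)
    pos = np.empty((len(t_idx), n_nodes, 2))
    for k, ti in enumerate(t_idx):
        s_q = _material_interp(traj, mat, ti)
        x, y, _ = _positions_at(traj, s_q, ti)
        pos[k, :, 0], pos[k, :, 1] = x, y
    if plane_label == "side":
        pos[..., 1] = 0.0  # lateral coordinate collapses in the side view
    if noise_sd > 0:
        pos = pos + rng_noise.normal(0.0, noise_sd, pos.shape)
    visible = rng_drop.random((len(t_idx), n_nodes)) >= dropout_p
    return NodeTracks(
        node_ids=np.arange(n_nodes),
        times=times,
        positions=pos,
        visible=visible,
        plane_label=plane_label,
    )


def render_frames(
    traj: RachisTrajectory,
    texture_corr_len: float = 1.0,
    mm_per_px: float = 0.25,
    noise_sd: float = 0.01,
    seed: int = 0,
    stride: int = 1,
    plane_label: str = "side",
    pad_mm: float = 4.0,
) -> FrameSequence:
    """Render speckle-textured frames of the organ.

    The texture lives in *material* coordinates (along-organ label ``u``,
    transverse offset ``w``), so speckle features move with material points
    and stretch dilutes them — summed pigment intensity per pixel drops as
    the tissue expands, as for real painted pigments.

    Side views show the outer lateral face (texture advected with that
    face, horizontal image coordinate = projected x); top views show the
    bending plane itself.
    """
    if texture_corr_len < 2.0 * mm_per_px:
        raise ValueError(
            f"texture_corr_len={texture_corr_len} mm unresolvable at {mm_per_px} mm/px"
        )
    params = traj.params or GrowthLawParams()
    rng_tex, rng_sensor = _streams(seed, 2)
    t_idx = np.arange(0, traj.n_times, stride)
    times = traj.times[t_idx]

    # material particle grid: ~3 particles per final pixel along u
    L_mat = traj.material_ids[-1]
    growth_factor = traj.apex_s[-1] / traj.apex_s[0]
    du = mm_per_px / (3.0 * growth_factor)
    u = np.arange(0.0, L_mat, du)
    w = np.arange(-params.W / 2, params.W / 2 + 1e-9, mm_per_px / 3.0)
    # correlation length applied anisotropically (grid spacings differ)
    corr_px_u = texture_corr_len / du
    corr_px_w = texture_corr_len / (mm_per_px / 3.0)
    tex = ndimage.gaussian_filter(rng_tex.random((len(u), len(w))), (corr_px_u, corr_px_w), mode="nearest")
    tex -= tex.min()
    tex /= max(tex.max(), 1e-12)
    tex = 0.3 + 0.7 * tex  # keep pigment everywhere, modulate contrast

    # image extent (fixed over the sequence)
    x_min, x_max = -pad_mm, float(traj.apex_s[-1]) + pad_mm
    if plane_label == "top":
        y_all = traj.xy[..., 1]
        y_min, y_max = float(y_all.min()) - pad_mm, float(y_all.max()) + pad_mm
    else:
        y_min, y_max = -params.W / 2 - pad_mm, params.W / 2 + pad_mm
    n_cols = int(np.ceil((x_max - x_min) / mm_per_px))
    n_rows = int(np.ceil((y_max - y_min) / mm_per_px))

    uu, ww = np.meshgrid(u, w, indexing="ij")
    uu, ww, tv = uu.ravel(), ww.ravel(), tex.ravel()
    # normalization: particle weight such that unstretched tissue ~ 0.9
    w_particle = 0.9 * (du * (mm_per_px / 3.0)) / mm_per_px**2

    images = np.empty((len(t_idx), n_rows, n_cols))
    for k, ti in enumerate(t_idx):
        s_q = _material_interp(traj, uu, ti)
        x, y, th = _positions_at(traj, s_q, ti)
        if plane_label == "side":
            # camera sees the outer lateral face; texture rides that face
            px = x - (params.W / 2) * (-np.sin(th))  # outer-face x (offset -W/2 along normal)
            py = ww  # vertical coordinate across the face
        else:
            px = x + ww * (-np.sin(th))
            py = y + ww * np.cos(th)
        col = (px - x_min) / mm_per_px
        row = (py - y_min) / mm_per_px
        img = np.zeros((n_rows, n_cols))
        c0, r0 = np.floor(col).astype(int), np.floor(row).astype(int)
        fc, fr = col - c0, row - r0
        ok = (c0 >= 0) & (c0 < n_cols - 1) & (r0 >= 0) & (r0 < n_rows - 1)
        c0, r0, fc, fr = c0[ok], r0[ok], fc[ok], fr[ok]
        val = tv[ok] * w_particle
        np.add.at(img, (r0, c0), val * (1 - fr) * (1 - fc))
        np.add.at(img, (r0, c0 + 1), val * (1 - fr) * fc)
        np.add.at(img, (r0 + 1, c0), val * fr * (1 - fc))
        np.add.at(img, (r0 + 1, c0 + 1), val * fr * fc)
        img = ndimage.gaussian_filter(img, 0.6)
        if noise_sd > 0:
            img = img + rng_sensor.normal(0.0, noise_sd, img.shape)
        images[k] = img
    np.clip(images, 0.0, 1.0, out=images)
    return FrameSequence(
        times=times,
        images=images,
        mm_per_px=mm_per_px,
        plane_label=plane_label,
        origin_mm=(x_min, y_min),
    )


def _resample_field(traj, field, times_out, positions, axis_origin):
    """Sample a per-marker field onto a regular (time × position) grid."""
    out = np.full((len(times_out), len(positions)), np.nan)
    for k, t in enumerate(times_out):
        ti = int(np.argmin(np.abs(traj.times - t)))
        coord = traj.s[ti] if axis_origin == "from_base" else traj.apex_s[ti] - traj.s[ti]
        order = np.argsort(coord)
        out[k] = np.interp(positions, coord[order], field[ti][order], left=np.nan, right=np.nan)
    return out


def make_kymograph_dataset(
    params: GrowthLawParams | None = None,
    t_end: float | None = None,
    noise_sd_curv: float = 0.0,
    noise_sd_elong: float = 0.0,
    node_noise_sd: float = 0.0,
    dropout_p: float = 0.0,
    n_nodes: int = 11,
    seed: int = 0,
    with_frames: bool = False,
    n_positions: int = 120,
) -> SyntheticDataset:
    """Simulate and bundle every synthetic product with its ground truth.

    The curvature kymograph is sampled on a base-anchored grid (as a
    top-view measurement would be); the elongation kymograph is the
    side-view apparent rate of the outer face.  Independent Gaussian noise
    is added per product; identical seeds give byte-identical bundles.
    """
    params = params or GrowthLawParams()
    rng_c, rng_e, seed_nodes, seed_frames = np.random.SeedSequence(seed).spawn(4)
    rng_c, rng_e = np.random.default_rng(rng_c), np.random.default_rng(rng_e)
    traj = simulate(params, t_end=t_end)
    stride = max(1, int(round(TOP_VIEW_INTERVAL_H / (traj.times[1] - traj.times[0]))))
    times_out = traj.times[::stride]

    positions = np.linspace(0.0, params.L0 * 0.98, n_positions)
    curv = _resample_field(traj, traj.C, times_out, positions, "from_base")
    if noise_sd_curv > 0:
        curv = curv + rng_c.normal(0.0, noise_sd_curv, curv.shape)
    curvature_kymo = Kymograph(
        field_name="curvature",
        times=times_out,
        positions=positions,
        values=curv,
        axis_origin="from_base",
        units="1/mm",
    )

    elong = apparent_elongation(traj, ProjectionSetup("side"), face="outer")
    vals = elong.values[::stride]
    if noise_sd_elong > 0:
        vals = vals + rng_e.normal(0.0, noise_sd_elong, vals.shape)
    elong_kymo = Kymograph(
        field_name=elong.field_name,
        times=times_out,
        positions=elong.positions,
        values=vals,
        axis_origin="from_apex",
        units="1/h",
    )

    tracks = make_node_tracks(
        traj,
        n_nodes=n_nodes,
        noise_sd=node_noise_sd,
        dropout_p=dropout_p,
        seed=seed_nodes.generate_state(1)[0] % (2**31),
        stride=stride,
    )
    frames = None
    if with_frames:
        frames = render_frames(
            traj,
            seed=seed_frames.generate_state(1)[0] % (2**31),
            stride=max(1, stride // 2),
        )
    return SyntheticDataset(
        params=params,
        truth=traj,
        curvature_kymo=curvature_kymo,
        elong_kymo=elong_kymo,
        node_tracks=tracks,
        frames=frames,
        seed=seed,
    )
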