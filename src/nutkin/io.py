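"""Tabular text formats tying the pipeline together.

Every artifact is diff-able plain text: a JSON header block (lines
prefixed ``#``) carrying units and axis conventions, followed by a CSV
body.  Floats are written with 17 significant digits so a read/write round
trip is lossless.  Frames go to multi-page TIFF (binary, inspection only).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FrameSequence, Kymograph, NodeTracks, ProfilePair
from .model import GrowthLawParams, RachisTrajectory

__all__ = [
    "write_kymograph", "read_kymograph",
    "write_tracks", "read_tracks",
    "write_profiles", "read_profiles",
    "write_trajectory", "read_trajectory",
    "write_params", "read_params",
    "write_energy_map", "read_energy_map",
    "write_frames",
]

_FMT = "%.17g"


def _f(x) -> str:
    return _FMT % x


def _write_with_header(path, header: dict, df: pd.DataFrame) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in json.dumps(header, indent=1).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=_FMT, lineterminator="\n")


def _read_with_header(path):
    path = Path(path)
    header_lines = []
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip("\n").lstrip())
                n_skip += 1
            else:
                break
    header = json.loads("\n".join(header_lines)) if header_lines else {}
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    return header, df


def write_kymograph(path, kymo: Kymograph) -> None:
    header = {
        "kind": "kymograph",
        "field_name": kymo.field_name,
        "units": kymo.units,
        "axis_origin": kymo.axis_origin,
        "position_units": "mm",
        "time_units": "h",
        "positions": [float(_f(p)) for p in kymo.positions],
        "has_positions_t": kymo.positions_t is not None,
    }
    data = {"time": kymo.times}
    for j, p in enumerate(kymo.positions):
        data[f"v{j}"] = np.where(kymo.mask[:, j], np.nan, kymo.values[:, j])
    if kymo.positions_t is not None:
        for j in range(len(kymo.positions)):
            data[f"p{j}"] = kymo.positions_t[:, j]
    _write_with_header(path, header, pd.DataFrame(data))


def read_kymograph(path) -> Kymograph:
    header, df = _read_with_header(path)
    if header.get("kind") != "kymograph":
        raise ValueError(f"{path} is not a kymograph file")
    positions = np.asarray(header["positions"], dtype=float)
    n = len(positions)
    values = df[[f"v{j}" for j in range(n)]].to_numpy()
    positions_t = None
    if header.get("has_positions_t"):
        positions_t = df[[f"p{j}" for j in range(n)]].to_numpy()
    return Kymograph(
        field_name=header["field_name"],
        times=df["time"].to_numpy(),
        positions=positions,
        values=values,
        axis_origin=header["axis_origin"],
        units=header["units"],
        positions_t=positions_t,
    )


def write_tracks(path, tracks: NodeTracks) -> None:
    header = {
        "kind": "node_tracks",
        "plane_label": tracks.plane_label,
        "position_units": "mm",
        "time_units": "h",
        "node_ids": [int(i) for i in tracks.node_ids],
        "flags": [[int(a), int(b)] for a, b in tracks.flags],
    }
    rows = []
    for k, t in enumerate(tracks.times):
        for j, nid in enumerate(tracks.node_ids):
            rows.append(
                (t, int(nid), tracks.positions[k, j, 0], tracks.positions[k, j, 1],
                 int(tracks.visible[k, j]))
            )
    df = pd.DataFrame(rows, columns=["time", "node_id", "x", "y", "visible"])
    _write_with_header(path, header, df)


def read_tracks(path) -> NodeTracks:
    header, df = _read_with_header(path)
    if header.get("kind") != "node_tracks":
        raise ValueError(f"{path} is not a node-tracks file")
    node_ids = np.asarray(header["node_ids"])
    times = np.unique(df["time"].to_numpy())
    n_t, n_n = len(times), len(node_ids)
    pos = np.full((n_t, n_n, 2), np.nan)
    vis = np.zeros((n_t, n_n), dtype=bool)
    t_index = {t: k for k, t in enumerate(times)}
    id_index = {int(i): j for j, i in enumerate(node_ids)}
    for t, nid, x, y, v in df.itertuples(index=False):
        k, j = t_index[t], id_index[int(nid)]
        pos[k, j] = (x, y)
        vis[k, j] = bool(v)
    return NodeTracks(
        node_ids=node_ids,
        times=times,
        positions=pos,
        visible=vis,
        plane_label=header["plane_label"],
        flags=[tuple(x) for x in header.get("flags", [])],
    )


def write_profiles(path, profile: ProfilePair) -> None:
    header = {
        "kind": "profile_pair",
        "axis": "distance from apex (mm)",
        "mean_rate_units": "1/h",
        "diff_rate_envelope_units": "1/h",
    }
    df = pd.DataFrame(
        {
            "apex_dist": profile.apex_dist,
            "mean_rate": profile.mean_rate,
            "diff_rate_envelope": profile.diff_rate_envelope,
            "counts_mean": profile.counts_mean,
            "counts_diff": profile.counts_diff,
        }
    )
    _write_with_header(path, header, df)


def read_profiles(path) -> ProfilePair:
    header, df = _read_with_header(path)
    if header.get("kind") != "profile_pair":
        raise ValueError(f"{path} is not a profile file")
    return ProfilePair(
        apex_dist=df["apex_dist"].to_numpy(),
        mean_rate=df["mean_rate"].to_numpy(),
        diff_rate_envelope=df["diff_rate_envelope"].to_numpy(),
        counts_mean=df["counts_mean"].to_numpy(),
        counts_diff=df["counts_diff"].to_numpy(),
    )


def write_params(path, params: GrowthLawParams) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_params(path) -> GrowthLawParams:
    return GrowthLawParams.from_dict(json.loads(Path(path).read_text()))


def write_trajectory(path, traj: RachisTrajectory, params_path=None) -> None:
    """Long-format CSV (one row per marker per time) + JSON parameter sidecar."""
    header = {
        "kind": "trajectory",
        "columns": "id=material label (mm), t (h), s (mm), C (1/mm), theta (rad), x/y (mm)",
        "n_times": int(traj.n_times),
        "n_markers": int(traj.n_markers),
    }
    n_t, n_m = traj.n_times, traj.n_markers
    df = pd.DataFrame(
        {
            "id": np.tile(traj.material_ids, n_t),
            "t": np.repeat(traj.times, n_m),
            "s": traj.s.ravel(),
            "C": traj.C.ravel(),
            "theta": traj.theta.ravel(),
            "x": traj.xy[..., 0].ravel(),
            "y": traj.xy[..., 1].ravel(),
        }
    )
    _write_with_header(path, header, df)
    if params_path is None:
        params_path = Path(path).with_suffix(".params.json")
    if traj.params is not None:
        write_params(params_path, traj.params)


def read_trajectory(path, params_path=None) -> RachisTrajectory:
    header, df = _read_with_header(path)
    if header.get("kind") != "trajectory":
        raise ValueError(f"{path} is not a trajectory file")
    n_t, n_m = header["n_times"], header["n_markers"]
    times = df["t"].to_numpy()[::n_m]
    material_ids = df["id"].to_numpy()[:n_m]
    shape = (n_t, n_m)
    params = None
    if params_path is None:
        params_path = Path(path).with_suffix(".params.json")
    if Path(params_path).exists():
        params = read_params(params_path)
    s = df["s"].to_numpy().reshape(shape)
    return RachisTrajectory(
        times=times,
        material_ids=material_ids,
        s=s,
        C=df["C"].to_numpy().reshape(shape),
        theta=df["theta"].to_numpy().reshape(shape),
        xy=np.stack([df["x"].to_numpy().reshape(shape), df["y"].to_numpy().reshape(shape)], axis=-1),
        apex_s=s[:, -1].copy(),
        params=params,
    )


def write_energy_map(path, emap) -> None:
    header = {
        "kind": "wavelet_energy_map",
        "normalization": emap.normalization,
        "n_modes": int(emap.n_modes),
        "period_units": "h",
        "position_units": "mm (from apex)",
        "periods": [float(_f(p)) for p in emap.periods],
    }
    data = {"position": emap.positions, "dominant_period": emap.dominant_period}
    for j in range(len(emap.periods)):
        data[f"e{j}"] = emap.energy[:, j]
    _write_with_header(path, header, pd.DataFrame(data))


def read_energy_map(path):
    from .spectral import WaveletEnergyMap

    header, df = _read_with_header(path)
    if header.get("kind") != "wavelet_energy_map":
        raise ValueError(f"{path} is not an energy-map file")
    periods = np.asarray(header["periods"], dtype=float)
    energy = df[[f"e{j}" for j in range(len(periods))]].to_numpy()
    return WaveletEnergyMap(
        positions=df["position"].to_numpy(),
        periods=periods,
        energy=energy,
        dominant_period=df["dominant_period"].to_numpy(),
        n_modes=int(header["n_modes"]),
        normalization=header["normalization"],
    )


def write_frames(path, frames: FrameSequence) -> None:
    """Multi-page TIFF for visual inspection (binary; keep out of the repo)."""
    import tifffile

    tifffile.imwrite(
        path,
        (np.clip(frames.images, 0, 1) * 65535).astype(np.uint16),
        metadata={
            "mm_per_px": frames.mm_per_px,
            "plane_label": frames.plane_label,
            "times_h": [float(t) for t in frames.times],
        },
    )
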