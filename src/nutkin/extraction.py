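"""Measurement chain for growth kinematics from time-lapse footage.

Mirrors how nutation kinematics are measured in practice: threshold the
organ, reduce it to a smooth midline with a moving median, fit circles
locally for signed curvature, track node markers with conservation /
ordering / displacement rules, differentiate inter-node distances for
segment elongation rates, correlate speckle texture between frames for the
fine (apparent) elongation field, take Hilbert-transform envelopes of the
oscillatory signals, and average everything in the apex-attached frame
where the growth profile is steady.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .containers import FrameSequence, Kymograph, NodeTracks, ProfilePair

__all__ = [
    "DetectionError",
    "EnvelopeError",
    "extract_midline",
    "local_curvature",
    "track_nodes",
    "segment_elongation",
    "dic_elongation",
    "envelope",
    "time_average_profiles",
    "differential_from_curvature",
]


class DetectionError(RuntimeError):
    """No organ found in the image."""


class EnvelopeError(ValueError):
    """Record too short for a meaningful envelope."""


# ---------------------------------------------------------------------------
# midline and curvature


def extract_midline(
    image: np.ndarray,
    mm_per_px: float,
    origin_mm=(0.0, 0.0),
    threshold: float | None = None,
    window_mm: float = 2.0,
) -> np.ndarray:
    """Extract the organ midline from a single top-view frame.

    The organ is assumed to run roughly along the image x axis, base on
    the left.  Pixels above ``threshold`` (Otsu if ``None``) form a point
    cloud; per column the intensity-weighted row centroid gives a raw
    midline, which a moving median filter of ``window_mm`` then smooths.

    Returns an ordered base-to-apex polyline, shape (n, 2), in mm.
    """
    image = np.asarray(image, dtype=float)
    if threshold is None:
        if image.max() <= image.min():
            raise DetectionError("blank image")
        threshold = threshold_otsu(image)
    mask = image > threshold
    if not mask.any():
        raise DetectionError("empty threshold mask: no organ detected")
    cols = np.where(mask.any(axis=0))[0]
    rows_c = np.empty(len(cols))
    # unweighted centroid of the masked band: immune to the (asymmetric)
    # pigment texture, limited only by edge quantization
    for i, c in enumerate(cols):
        rows_c[i] = np.where(mask[:, c])[0].mean()
    win = max(3, int(round(window_mm / mm_per_px)) | 1)
    rows_s = ndimage.median_filter(rows_c, size=win, mode="nearest")
    x = origin_mm[0] + cols * mm_per_px
    y = origin_mm[1] + rows_s * mm_per_px
    return np.column_stack([x, y])


def _taubin_circle(x: np.ndarray, y: np.ndarray):
    """Algebraic (Taubin) circle fit; returns (cx, cy, R) or None if collinear."""
    mx, my = x.mean(), y.mean()
    X, Y = x - mx, y - my
    Z = X * X + Y * Y
    Zm = Z.mean()
    if Zm <= 0:
        return None
    Z0 = (Z - Zm) / (2.0 * np.sqrt(Zm))
    A = np.column_stack([Z0, X, Y])
    try:
        _, sv, Vt = np.linalg.svd(A, full_matrices=False)
    except np.linalg.LinAlgError:
        return None
    v = Vt[2]
    a1 = v[0] / (2.0 * np.sqrt(Zm))
    a4 = -Zm * a1
    if abs(a1) < 1e-12:
        return None  # collinear: infinite radius
    cx = -v[1] / (2.0 * a1) + mx
    cy = -v[2] / (2.0 * a1) + my
    R2 = v[1] ** 2 + v[2] ** 2 - 4.0 * a1 * a4
    if R2 <= 0:
        return None
    return cx, cy, np.sqrt(R2) / (2.0 * abs(a1))


def local_curvature(midline: np.ndarray, window: float = 10.0) -> np.ndarray:
    """Signed curvature along a polyline by sliding-window circle fits.

    An algebraic (Taubin-style) fit, robust at small arcs, on all points
    within ``window/2`` arclength of each point.  Sign convention:
    bending to the left of the base-to-apex direction is positive.
    Collinear windows give curvature 0.
    """
    midline = np.asarray(midline, dtype=float)
    n = len(midline)
    # arclength measured on a lightly smoothed copy: point jitter inflates
    # the raw polyline length and would shrink the effective window
    ref = ndimage.uniform_filter1d(midline, size=min(5, n), axis=0, mode="nearest")
    seg = np.linalg.norm(np.diff(ref, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    C = np.zeros(n)
    for i in range(n):
        sel = np.abs(s - s[i]) <= window / 2.0
        if sel.sum() < 5:
            raise ValueError("curvature window spans fewer than 5 points")
        fit = _taubin_circle(midline[sel, 0], midline[sel, 1])
        if fit is None:
            continue
        cx, cy, R = fit
        j0, j1 = np.where(sel)[0][[0, -1]]
        tangent = midline[j1] - midline[j0]
        to_center = np.array([cx, cy]) - midline[i]
        sign = np.sign(tangent[0] * to_center[1] - tangent[1] * to_center[0])
        C[i] = sign / R
    return C


# ---------------------------------------------------------------------------
# node tracking and segment elongation


def _ordered_matching(track_pos, det_pos, max_disp):
    """Order-preserving min-cost matching of sorted tracks to sorted detections.

    DP over (tracks × detections) with a skip penalty of ``max_disp`` per
    unmatched item; matches farther than ``max_disp`` are forbidden.  Both
    inputs must be sorted along the organ; the matching can then never
    swap two markers.
    """
    n, m = len(track_pos), len(det_pos)
    skip = max_disp
    INF = 1e18
    cost = np.full((n + 1, m + 1), INF)
    cost[0, :] = np.arange(m + 1) * skip
    cost[:, 0] = np.arange(n + 1) * skip
    choice = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1=match, 2=skip track, 3=skip det
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = np.linalg.norm(track_pos[i - 1] - det_pos[j - 1])
            best, ch = cost[i - 1, j] + skip, 2
            if cost[i, j - 1] + skip < best:
                best, ch = cost[i, j - 1] + skip, 3
            if d <= max_disp and cost[i - 1, j - 1] + d < best:
                best, ch = cost[i - 1, j - 1] + d, 1
            cost[i, j], choice[i, j] = best, ch
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        ch = choice[i, j]
        if ch == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif ch == 2:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def track_nodes(
    detections: list,
    times: np.ndarray,
    max_disp: float,
    max_gap: int = 3,
    plane_label: str = "top",
) -> NodeTracks:
    """Link per-frame node detections into tracks.

    Rules, in the spirit of conservative marker tracking: the number of
    nodes is set by the first frame; per frame an order-preserving
    minimum-displacement matching links detections to tracks (two dots can
    never swap, which would violate the along-organ ordering); gaps of up
    to ``max_gap`` frames are closed by keeping the last position; longer
    gaps are flagged for manual correction rather than guessed.
    """
    times = np.asarray(times, dtype=float)
    first = np.asarray(detections[0], dtype=float)
    order = np.argsort(first[:, 0])
    n_nodes = len(first)
    pos = np.full((len(times), n_nodes, 2), np.nan)
    visible = np.zeros((len(times), n_nodes), dtype=bool)
    flags = []
    pos[0] = first[order]
    visible[0] = True
    last = pos[0].copy()
    gap = np.zeros(n_nodes, dtype=int)
    for k in range(1, len(times)):
        det = np.asarray(detections[k], dtype=float).reshape(-1, 2)
        if len(det) == 0:
            gap += 1
            continue
        det = det[np.argsort(det[:, 0])]
        pairs = _ordered_matching(last, det, max_disp)
        matched = np.zeros(n_nodes, dtype=bool)
        for ti, dj in pairs:
            pos[k, ti] = det[dj]
            visible[k, ti] = True
            last[ti] = det[dj]
            gap[ti] = 0
            matched[ti] = True
        gap[~matched] += 1
        for ti in np.where(gap > max_gap)[0]:
            flags.append((k, int(ti)))
    return NodeTracks(
        node_ids=np.arange(n_nodes),
        times=times,
        positions=pos,
        visible=visible,
        plane_label=plane_label,
        flags=flags,
    )


def _nan_filter(values, func, size):
    """Apply a 2D filter ignoring NaNs (small arrays only)."""
    def f(buf):
        b = buf[np.isfinite(buf)]
        return func(b) if len(b) else np.nan
    return ndimage.generic_filter(values, f, size=size, mode="nearest")


def segment_elongation(tracks: NodeTracks, smooth: bool = True, filter_size: int = 3) -> Kymograph:
    """Elongation rate of each interfoliolar segment from node tracks.

    Per consecutive-node pair, rate = d ln(inter-node distance)/dt by
    centred finite differences (one-sided at the record edges).  Cells
    with an invisible node are masked and propagate as masked rates.  With
    ``smooth=True`` the field is cleaned with a mean then a median filter
    (``filter_size``² each).  Values sit at segment midpoints; the
    midpoints advect with growth, so the kymograph carries time-varying
    positions (``positions_t``).
    """
    p = np.where(tracks.visible[..., None], tracks.positions, np.nan)
    d = np.linalg.norm(np.diff(p, axis=1), axis=2)  # (n_t, n_seg)
    with np.errstate(invalid="ignore", divide="ignore"):
        logd = np.log(d)
        rate = np.gradient(logd, tracks.times, axis=0)
    if smooth:
        rate = _nan_filter(rate, np.nanmean, filter_size)
        rate = _nan_filter(rate, np.nanmedian, filter_size)
    # along-organ coordinate: cumulative chordal arclength from the base
    seg_len = np.where(np.isfinite(d), d, 0.0)
    s_nodes = np.concatenate([np.zeros((len(tracks.times), 1)), np.cumsum(seg_len, axis=1)], axis=1)
    mid = 0.5 * (s_nodes[:, 1:] + s_nodes[:, :-1])
    mid_mean = np.nanmean(np.where(np.isfinite(d), mid, np.nan), axis=0)
    fallback = np.nanmean(mid, axis=0)
    mid_mean = np.where(np.isfinite(mid_mean), mid_mean, fallback)
    return Kymograph(
        field_name="segment_elongation",
        times=tracks.times,
        positions=mid_mean,
        values=rate,
        axis_origin="from_base",
        units="1/h",
        positions_t=mid,
    )


# ---------------------------------------------------------------------------
# image-correlation (apparent) elongation


def _band_profile(image: np.ndarray) -> np.ndarray:
    """Mean intensity per column over the organ band rows."""
    row_mean = image.mean(axis=1)
    th = 0.25 * row_mean.max()
    rows = np.where(row_mean > th)[0]
    if len(rows) == 0:
        raise DetectionError("no organ band in frame")
    return image[rows.min(): rows.max() + 1].mean(axis=0)


def _ncc_displacement(ref, cur, centers, half, search):
    """Sub-pixel displacement per window centre by 1D normalized cross-correlation."""
    disp = np.full(len(centers), np.nan)
    peak = np.full(len(centers), np.nan)
    for i, c in enumerate(centers):
        a = ref[c - half: c + half]
        a = a - a.mean()
        na = np.linalg.norm(a)
        if na < 1e-12:
            continue
        scores = np.full(2 * search + 1, -np.inf)
        for k, dpx in enumerate(range(-search, search + 1)):
            b = cur[c + dpx - half: c + dpx + half]
            b = b - b.mean()
            nb = np.linalg.norm(b)
            if nb < 1e-12:
                continue
            scores[k] = float(a @ b) / (na * nb)
        kbest = int(np.argmax(scores))
        if not np.isfinite(scores[kbest]):
            continue
        d = kbest - search
        # parabolic sub-pixel refinement (skipped on an exact match, where
        # the vertex of a parabola through asymmetric neighbours would
        # drift off the true zero shift)
        if scores[kbest] > 1.0 - 1e-12:
            disp[i] = d
            peak[i] = scores[kbest]
            continue
        if 0 < kbest < 2 * search and np.isfinite(scores[kbest - 1]) and np.isfinite(scores[kbest + 1]):
            y0, y1, y2 = scores[kbest - 1], scores[kbest], scores[kbest + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                d = d + 0.5 * (y0 - y2) / denom
        disp[i] = d
        peak[i] = scores[kbest]
    return disp, peak


def dic_elongation(
    frames: FrameSequence,
    window_px: int = 48,
    step_px: int = 8,
    search_px: int = 16,
    pair_lag: int | None = None,
    min_corr: float = 0.5,
    strain_fit_px: int = 128,
    smooth_time_h: float = 0.2,
) -> Kymograph:
    """Apparent elongation-rate field by image-to-image correlation.

    Intensity profiles sampled along the organ band are correlated between
    frames ``pair_lag`` apart (default ≈ 9 min); the sub-pixel (parabolic)
    displacement field is differentiated along the organ by local linear
    regression over ``strain_fit_px`` and divided by the lag to give the
    apparent elongation rate, then lightly smoothed in time.  The default
    lag and smoothing windows stay well below a quarter of the fastest
    (T/2) oscillation so the oscillatory signal is not attenuated, while
    the strain regression spans several correlation windows to average
    their sub-pixel errors.  Projection artifacts survive by construction
    — negative apparent rates are perfectly legal output.  Windows whose
    correlation peak falls below ``min_corr`` are masked.
    """
    dt = frames.times[1] - frames.times[0]
    if pair_lag is None:
        pair_lag = max(1, int(round(0.15 / dt)))
    profiles = np.array([_band_profile(im) for im in frames.images])
    n_cols = profiles.shape[1]
    half = window_px // 2
    margin = half + search_px + 1
    centers = np.arange(margin, n_cols - margin, step_px)
    if len(centers) < 4:
        raise ValueError("frames too narrow for the correlation window")
    n_pairs = frames.n_frames - pair_lag
    disp = np.full((n_pairs, len(centers)), np.nan)
    for k in range(n_pairs):
        d, pk = _ncc_displacement(profiles[k], profiles[k + pair_lag], centers, half, search_px)
        d[~(pk >= min_corr)] = np.nan
        disp[k] = d
    # strain by local linear regression of displacement vs column
    half_fit = max(1, strain_fit_px // (2 * step_px))
    strain = np.full_like(disp, np.nan)
    for j in range(len(centers)):
        lo, hi = max(0, j - half_fit), min(len(centers), j + half_fit + 1)
        xw = centers[lo:hi].astype(float)
        yw = disp[:, lo:hi]
        good = np.isfinite(yw)
        xm = xw - xw.mean()
        denom = (xm**2).sum()
        ok = good.sum(axis=1) == len(xw)
        if denom > 0 and ok.any():
            strain[ok, j] = (yw[ok] * xm).sum(axis=1) / denom
    rate = strain / (pair_lag * dt)
    if smooth_time_h > 0:
        w = max(1, int(round(smooth_time_h / dt)))
        filled = np.where(np.isfinite(rate), rate, 0.0)
        norm = ndimage.uniform_filter1d(np.isfinite(rate).astype(float), w, axis=0, mode="nearest")
        rate_s = ndimage.uniform_filter1d(filled, w, axis=0, mode="nearest")
        with np.errstate(invalid="ignore"):
            rate = np.where(norm > 0.5, rate_s / np.maximum(norm, 1e-12), np.nan)
    t_mid = 0.5 * (frames.times[:n_pairs] + frames.times[pair_lag:])
    positions = frames.origin_mm[0] + centers * frames.mm_per_px
    return Kymograph(
        field_name="dic_apparent_elongation",
        times=t_mid,
        positions=positions,
        values=rate,
        axis_origin="from_base",
        units="1/h",
    )


# ---------------------------------------------------------------------------
# envelopes and time-averaged profiles


def _dominant_period(series: np.ndarray, dt: float) -> float:
    v = series - series.mean()
    spec = np.abs(np.fft.rfft(v)) ** 2
    freqs = np.fft.rfftfreq(len(v), dt)
    if len(spec) < 2 or spec[1:].max() <= 1e-30 * max(np.abs(series).max() ** 2, 1e-300):
        return np.nan  # no oscillatory content (zero or constant signal)
    k = 1 + int(np.argmax(spec[1:]))
    return np.inf if freqs[k] == 0 else 1.0 / freqs[k]


def envelope(kymo: Kymograph, min_cycles: float = 3.0, smooth: bool = True) -> Kymograph:
    """Per-position amplitude envelope via the analytic signal.

    Each position's time series is detrended (mean removed), Hilbert
    transformed, and the analytic-signal magnitude lightly smoothed over a
    quarter of the dominant period.  For a pure sine of amplitude A the
    result is A away from the record edges.  Records shorter than
    ``min_cycles`` dominant periods raise :class:`EnvelopeError`.
    """
    dt = kymo.times[1] - kymo.times[0]
    record = kymo.times[-1] - kymo.times[0]
    vals = np.where(kymo.mask, np.nan, kymo.values)
    out = np.full_like(vals, np.nan)
    periods = []
    for j in range(vals.shape[1]):
        v = vals[:, j]
        good = np.isfinite(v)
        if good.mean() < 0.8:
            continue
        v = np.where(good, v, np.interp(kymo.times, kymo.times[good], v[good]))
        P = _dominant_period(v, dt)
        if np.isfinite(P):
            periods.append(P)
        env = np.abs(signal.hilbert(v - v.mean()))
        if smooth and np.isfinite(P):
            w = max(1, int(round(P / 4.0 / dt)))
            env = ndimage.uniform_filter1d(env, w, mode="nearest")
        out[:, j] = env
    if periods and record < min_cycles * np.median(periods):
        raise EnvelopeError(
            f"record of {record:.2f} h covers fewer than {min_cycles} oscillation "
            f"periods (~{np.median(periods):.2f} h)"
        )
    return Kymograph(
        field_name=kymo.field_name + "_envelope",
        times=kymo.times,
        positions=kymo.positions,
        values=out,
        axis_origin=kymo.axis_origin,
        units=kymo.units,
        positions_t=kymo.positions_t,
    )


def _apex_at(apex_track, times):
    if callable(apex_track):
        return np.asarray(apex_track(times), dtype=float)
    apex_track = np.asarray(apex_track, dtype=float)
    if apex_track.ndim == 2:  # (times, L) pairs
        return np.interp(times, apex_track[:, 0], apex_track[:, 1])
    if len(apex_track) != len(times):
        raise ValueError("apex_track length does not match kymograph times")
    return apex_track


def _bin_kymo(kymo: Kymograph, apex_L, edges):
    cellpos = kymo.cell_positions()
    if kymo.axis_origin == "from_base":
        d = apex_L[:, None] - cellpos
    else:
        d = cellpos + np.zeros_like(kymo.values)
    good = ~kymo.mask & np.isfinite(kymo.values) & np.isfinite(d)
    sums, _ = np.histogram(d[good], bins=edges, weights=kymo.values[good])
    counts, _ = np.histogram(d[good], bins=edges)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts.astype(float)


def time_average_profiles(
    elong_kymo: Kymograph,
    diff_kymo: Kymograph | None,
    apex_track,
    bin_width: float = 15.0,
    d_max: float | None = None,
) -> ProfilePair:
    """Time-average kymographs in the apex-attached frame.

    Because the growth profile is steady relative to the apex, rebinning
    every cell to its distance from the apex and averaging over time
    recovers the spatial profiles of the mean elongation rate and of the
    differential-elongation envelope.  ``bin_width`` defaults to 15 mm —
    the sigmoid transition width, so the transition itself stays resolved.

    ``apex_track`` gives the apex arclength position per kymograph time
    (array, (t, L) table, or callable).
    """
    L1 = _apex_at(apex_track, elong_kymo.times)
    if d_max is None:
        d_max = float(np.nanmax(L1))
    edges = np.arange(0.0, d_max + bin_width, bin_width)
    mean_rate, counts_mean = _bin_kymo(elong_kymo, L1, edges)
    if diff_kymo is not None:
        L2 = _apex_at(apex_track, diff_kymo.times)
        diff_rate, counts_diff = _bin_kymo(diff_kymo, L2, edges)
    else:
        diff_rate = np.full(len(edges) - 1, np.nan)
        counts_diff = np.zeros(len(edges) - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ProfilePair(
        apex_dist=centers,
        mean_rate=mean_rate,
        diff_rate_envelope=diff_rate,
        counts_mean=counts_mean,
        counts_diff=counts_diff,
    )


def differential_from_curvature(curv_kymo: Kymograph, width: float) -> Kymograph:
    """Differential elongation rate estimated from a curvature kymograph.

    Uses the leading-order kinematic equivalence δĖ ≈ W · ∂C/∂t, valid in
    the thin-beam regime |C|·W ≪ 1 where curvature advection is
    negligible.
    """
    vals = np.where(curv_kymo.mask, np.nan, curv_kymo.values)
    dCdt = np.gradient(vals, curv_kymo.times, axis=0)
    return Kymograph(
        field_name="differential_elongation_from_curvature",
        times=curv_kymo.times,
        positions=curv_kymo.positions,
        values=width * dCdt,
        axis_origin=curv_kymo.axis_origin,
        units="1/h",
        positions_t=curv_kymo.positions_t,
    )
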