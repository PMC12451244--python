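"""Model fitting and the local-contraction decision.

Three layers of inference, in increasing ambition:

1. profile fits — the time-averaged mean elongation profile is fitted to
   the growth-law sigmoid; the differential-elongation envelope is then
   fitted with its shape *fixed* to the normalized derivative of that
   sigmoid, leaving only the amplitude free;
2. the amplitude relation — a back-of-the-envelope inversion linking the
   apex nutation amplitude A to the differential-growth amplitude,
   δE_max ≈ A·R/(T·L_bz): the differential growth accumulated over one
   period, divided by the beam radius, gives curvature, which integrated
   over the bending zone gives the apex deviation (order of magnitude —
   the exact closed form carries an extra 2π);
3. the wavelet-kymograph fit — free growth-law parameters are tuned so the
   simulated apparent-elongation energy map matches the observed one.

The contraction test then asks whether the fitted law forces one lateral
face to shrink somewhere: min over position, phase and face of Ė ± δĖ/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .containers import ProfilePair
from .model import (
    GrowthLawParams,
    ParameterError,
    bending_envelope,
    differential_elongation,
    face_rates,
    mean_elongation_profile,
    simulate,
)
from .projection import ProjectionSetup, apparent_elongation
from .spectral import WaveletEnergyMap, energy_kymograph

__all__ = [
    "FitError",
    "FitResult",
    "fit_mean_profile",
    "fit_differential_profile",
    "amplitude_relation",
    "fit_wavelet_kymograph",
    "contraction_test",
    "EQ6_PREFACTOR",
]

# O(1) prefactor of the amplitude relation; the leading-order inversion uses 1.
# (The exact small-amplitude closed form would carry 2π — see docs/methods.md.)
EQ6_PREFACTOR = 1.0


class FitError(RuntimeError):
    """Fit failed or target is unidentifiable."""


@dataclass
class FitResult:
    """Outcome of a model fit.

    ``free_params`` maps names to ``(estimate, ci_low, ci_high)``;
    ``fixed_params`` maps names to values with their provenance recorded.
    """

    free_params: dict
    fixed_params: dict
    fixed_provenance: str
    objective: float
    converged: bool
    diagnostics: dict = dc_field(default_factory=dict)
    contraction_flag: bool | None = None
    contraction_margin: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.free_params) & set(self.fixed_params)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        if not np.isfinite(self.objective):
            raise ValueError("objective must be finite at the reported optimum")

    def estimates(self) -> dict:
        return {k: v[0] for k, v in self.free_params.items()}

    def to_json(self, **kwargs) -> str:
        def _clean(x):
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            if isinstance(x, np.bool_):
                return bool(x)
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        d = {
            "free_params": _clean(self.free_params),
            "fixed_params": _clean(self.fixed_params),
            "fixed_provenance": self.fixed_provenance,
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "diagnostics": _clean(self.diagnostics),
            "contraction_flag": None if self.contraction_flag is None else bool(self.contraction_flag),
            "contraction_margin": None
            if self.contraction_margin is None
            else float(self.contraction_margin),
            "seed": self.seed,
        }
        return json.dumps(d, indent=2, **kwargs)


def _sigmoid(d, Edot_max, L_gz, lam):
    return 0.5 * Edot_max * (1.0 - np.tanh((d - L_gz) / lam))


def fit_mean_profile(
    profile: ProfilePair,
    n_boot: int = 200,
    seed: int = 0,
) -> FitResult:
    """Weighted least-squares fit of the growth-law sigmoid to a profile.

    Bins are weighted by √count.  Confidence intervals (95 %) come from a
    bootstrap over bins.  A profile with no decay inside the window (or
    with a fitted transition outside it) raises :class:`FitError` rather
    than returning a silent estimate.
    """
    d = np.asarray(profile.apex_dist, dtype=float)
    y = np.asarray(profile.mean_rate, dtype=float)
    w = np.asarray(profile.counts_mean, dtype=float)
    good = np.isfinite(y) & (w > 0)
    if good.sum() < 8:
        raise FitError(f"need >= 8 valid bins, got {int(good.sum())}")
    d, y, w = d[good], y[good], w[good]
    ymax = y.max()
    if ymax <= 0 or y.min() > 0.5 * ymax:
        raise FitError("profile shows no decay inside the window: length scale unidentifiable")
    span = d.max() - d.min()
    p0 = (ymax, float(d[np.argmin(np.abs(y - ymax / 2))]), span / 8.0)
    bounds = ([0.0, 0.0, 1e-3], [10.0 * ymax, d.max() + span, span])
    sigma = 1.0 / np.sqrt(w)

    def _fit(di, yi, si):
        popt, _ = optimize.curve_fit(
            _sigmoid, di, yi, p0=p0, sigma=si, bounds=bounds, maxfev=20000
        )
        return popt

    try:
        popt = _fit(d, y, sigma)
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    if popt[1] >= d.max():
        raise FitError("fitted transition lies beyond the measured window (boundary)")
    resid = y - _sigmoid(d, *popt)
    rng = np.random.default_rng(seed)
    boots = []
    idx_all = np.arange(len(d))
    for _ in range(n_boot):
        idx = rng.choice(idx_all, size=len(d), replace=True)
        if len(np.unique(idx)) < 4:
            continue
        try:
            boots.append(_fit(d[idx], y[idx], sigma[idx]))
        except RuntimeError:
            continue
    boots = np.array(boots) if boots else popt[None, :]
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    names = ("Edot_max", "L_gz", "lambda_gz")
    return FitResult(
        free_params={n: (float(popt[i]), float(lo[i]), float(hi[i])) for i, n in enumerate(names)},
        fixed_params={},
        fixed_provenance="",
        objective=float(np.sum((resid / sigma) ** 2)),
        converged=True,
        diagnostics={
            "rms_residual": float(np.sqrt(np.mean(resid**2))),
            "n_bins": int(len(d)),
            "n_boot_ok": int(len(boots)),
        },
        seed=seed,
    )


def fit_differential_profile(profile: ProfilePair, mean_fit: FitResult) -> FitResult:
    """Fit the differential-envelope amplitude with its shape held fixed.

    The envelope shape is the normalized derivative of the fitted mean
    sigmoid — sech² centred on the fitted ``L_gz`` with the fitted width —
    so a single amplitude is estimated in closed form (weighted projection).
    """
    est = mean_fit.estimates()
    L_gz, lam = est["L_gz"], est["lambda_gz"]
    d = np.asarray(profile.apex_dist, dtype=float)
    y = np.asarray(profile.diff_rate_envelope, dtype=float)
    w = np.asarray(profile.counts_diff, dtype=float)
    good = np.isfinite(y) & (w > 0)
    if good.sum() < 3:
        raise FitError("too few valid envelope bins")
    d, y, w = d[good], y[good], w[good]
    g = 1.0 / np.cosh((d - L_gz) / lam) ** 2
    denom = np.sum(w * g * g)
    if denom <= 0:
        raise FitError("envelope shape vanishes over the measured bins")
    amp = float(np.sum(w * g * y) / denom)
    resid = y - amp * g
    # delta-method standard error from the weighted projection
    se = float(np.sqrt(np.sum(w * resid**2) / max(good.sum() - 1, 1) / denom))
    return FitResult(
        free_params={"dE_max": (amp, amp - 1.96 * se, amp + 1.96 * se)},
        fixed_params={"L_gz": L_gz, "lambda_gz": lam},
        fixed_provenance="shape fixed to the derivative of the fitted mean-profile sigmoid",
        objective=float(np.sum(w * resid**2)),
        converged=True,
        diagnostics={"rms_residual": float(np.sqrt(np.mean(resid**2)))},
    )


def amplitude_relation(A: float, R: float, T: float, L_bz: float) -> float:
    """Differential-growth amplitude implied by the apex nutation amplitude.

    δE_max ≈ A·R / (T·L_bz): over one period the differential growth
    δE_max·T, divided by the radius R, sets the local curvature, which
    integrated over the bending-zone length L_bz gives the apex deviation
    A.  An order-of-magnitude inversion (prefactor :data:`EQ6_PREFACTOR`).
    """
    for name, v in (("A", A), ("R", R), ("T", T), ("L_bz", L_bz)):
        if not np.isfinite(v) or v <= 0:
            raise ParameterError(f"{name} must be positive, got {v!r}")
    return EQ6_PREFACTOR * A * R / (T * L_bz)


def _energy_distance(obs: WaveletEnergyMap, sim: WaveletEnergyMap) -> float:
    """Frobenius distance between per-position-normalized energy maps."""
    a, b = obs.energy, sim.energy
    good = np.isfinite(a) & np.isfinite(b)
    if not good.any():
        return np.inf
    return float(np.sqrt(np.sum((a[good] - b[good]) ** 2) / good.sum()))


def simulate_energy_map(
    params: GrowthLawParams,
    positions: np.ndarray,
    periods: np.ndarray,
    t_end: float | None = None,
    dt: float | None = None,
    n_markers: int = 161,
    time_stride: int = 4,
    face: str = "outer",
) -> WaveletEnergyMap:
    """Forward model: simulate → project (side view) → wavelet energy map.

    ``face='outer'`` observes a lateral face (carrying the δĖ/2
    modulation); ``'midline'`` ablates the material oscillation and keeps
    only the geometric projection term.
    """
    traj = simulate(params, t_end=t_end, dt=dt, n_markers=n_markers)
    kymo = apparent_elongation(traj, ProjectionSetup("side"), face=face, positions=positions)
    from .containers import Kymograph

    sub = Kymograph(
        field_name=kymo.field_name,
        times=kymo.times[::time_stride],
        positions=kymo.positions,
        values=kymo.values[::time_stride],
        axis_origin=kymo.axis_origin,
        units=kymo.units,
    )
    return energy_kymograph(sub, periods)


def fit_wavelet_kymograph(
    observed: WaveletEnergyMap,
    fixed: dict,
    free_names: Sequence[str],
    bounds: dict | None = None,
    n_grid: int = 4,
    seed: int = 0,
    sim_kwargs: dict | None = None,
) -> FitResult:
    """Fit free growth-law parameters to an observed wavelet energy map.

    Minimizes the Frobenius distance between the per-position-normalized
    observed map and the map of a forward simulation (simulate → side-view
    apparent rate → wavelet energy), over the named free parameters.  A
    coarse grid search seeds a Nelder–Mead refinement; deterministic given
    the grids.  ``fixed`` holds parameters measured independently and
    frozen before fitting (at minimum the period T and the geometry).  A
    flat objective across the grid raises :class:`FitError` instead of
    reporting an arbitrary estimate.
    """
    if observed.normalization != "per_position":
        raise FitError("observed map must be per-position normalized")
    free_names = list(free_names)
    overlap = set(free_names) & set(fixed)
    if overlap:
        raise FitError(f"parameters both free and fixed: {sorted(overlap)}")
    defaults = GrowthLawParams().to_dict()
    bounds = dict(bounds or {})
    for name in free_names:
        if name not in bounds:
            ref = defaults[name] if defaults.get(name) else 0.02
            bounds[name] = (0.25 * ref, 4.0 * ref)
    sim_kwargs = dict(sim_kwargs or {})

    def make_params(x):
        d = dict(defaults)
        d.update(fixed)
        d.update({n: float(v) for n, v in zip(free_names, x)})
        return GrowthLawParams.from_dict(d)

    cache = {}

    def objective(x):
        key = tuple(np.round(np.asarray(x, float), 10))
        if key in cache:
            return cache[key]
        try:
            p = make_params(x)
            sim = simulate_energy_map(p, observed.positions, observed.periods, **sim_kwargs)
            val = _energy_distance(observed, sim)
        except (ParameterError, ValueError):
            val = np.inf
        cache[key] = val
        return val

    axes = [np.linspace(bounds[n][0], bounds[n][1], n_grid) for n in free_names]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    vals = np.array([objective(p) for p in pts])
    if not np.isfinite(vals).any():
        raise FitError("objective not finite anywhere on the coarse grid")
    finite = vals[np.isfinite(vals)]
    if np.ptp(finite) < 1e-10:
        raise FitError("objective is flat over the parameter grid: unidentifiable")
    x0 = pts[int(np.nanargmin(np.where(np.isfinite(vals), vals, np.nan)))]
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-5, "maxfev": 80},
    )
    xbest = res.x if res.fun <= objective(x0) else x0
    fbest = min(float(res.fun), float(objective(x0)))
    p_best = make_params(xbest)
    flag, margin = contraction_test(p_best)
    # crude uncertainty: half the local grid spacing
    half = {n: 0.5 * (axes[i][1] - axes[i][0]) for i, n in enumerate(free_names)}
    return FitResult(
        free_params={
            n: (float(xbest[i]), float(xbest[i] - half[n]), float(xbest[i] + half[n]))
            for i, n in enumerate(free_names)
        },
        fixed_params=dict(fixed),
        fixed_provenance="measured and fixed before fitting",
        objective=fbest,
        converged=bool(res.success or fbest < np.nanmin(vals[np.isfinite(vals)]) + 1e-12),
        diagnostics={
            "grid_best": float(np.nanmin(np.where(np.isfinite(vals), vals, np.nan))),
            "n_evals": len(cache),
        },
        contraction_flag=flag,
        contraction_margin=margin,
        seed=seed,
    )


def contraction_test(params: GrowthLawParams, n_space: int = 2001):
    """Does the growth law force a local tissue contraction?

    Evaluates the minimum over position and oscillation phase of the two
    face elongation rates Ė ± δĖ/2; at the sine extrema the worse face
    rate is Ė(s') − δE_max·g(s')/2, so the spatial minimum of that
    quantity is the margin.  ``flag`` is True iff the margin is negative.
    δE_max > Ė_max is a sufficient condition when the envelope is centred
    at the sigmoid midpoint (there Ė = Ė_max/2 and g = 1); the *exact*
    threshold is lower because both rates decay basally at different
    speeds — see docs/methods.md.
    """
    sp = np.linspace(0.0, params.L0, n_space)
    Edot = mean_elongation_profile(params, sp)
    g = bending_envelope(params, sp)
    worst = Edot - 0.5 * params.dE_max * g  # worse face at the sine extremum
    margin = float(worst.min())
    return margin < 0.0, margin
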