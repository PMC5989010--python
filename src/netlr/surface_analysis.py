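"""Reduced two-parameter firing-rate surface and correlation susceptibility.

Freezing all effective parameters except the mean inhibitory conductance
g_I and the spike threshold theta at their population averages turns the
single-cell rate into a surface F(g_I, theta).  Because inhibitory common
input dominates pairwise correlations in these networks, the quantity

    S_hat = (dF/dg_I)^2 / F

("correlation susceptibility") captures how strongly a shared inhibitory
fluctuation translates into spike-count correlation for a cell at that
operating point.  Whether correlation rises or falls with rate along a
family of cells depends on the direction d**x** the family takes through the
(g_I, theta) plane:

    dS_hat/dF = (grad S_hat . dx) / (grad F . dx),

and the fraction of directions with a positive product is
(pi - arccos cos_angle(grad S_hat, grad F)) / pi.

Display units: F in Hz, S_hat in Hz per unit g_I^2 (g_I dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import fokker_planck as fp
from .network_model import EffectiveCell, sample_thresholds
from .self_consistency import PopulationSummary

__all__ = ["RateSurface", "PathSpec", "AlignmentReport", "rate_surface",
           "path_profile", "alignment", "sign_map", "motif_regression",
           "default_axes"]


@dataclass
class RateSurface:
    """F and S_hat on a (g_I, theta) grid, with gradient helpers.

    ``F`` is in Hz, indexed [i_gI, j_theta]; ``S_hat`` is masked (NaN) where
    F vanishes.  ``frozen`` records the population-averaged parameters the
    surface was built from.
    """

    gI_axis: np.ndarray
    theta_axis: np.ndarray
    F: np.ndarray
    S_hat: np.ndarray
    frozen: dict
    _interp: dict = field(default_factory=dict, repr=False)

    def gradients(self):
        """(dF/dgI, dF/dtheta), (dS/dgI, dS/dtheta) on the grid, centered
        differences with one-sided stencils at the boundaries."""
        dF = np.gradient(self.F, self.gI_axis, self.theta_axis)
        dS = np.gradient(self.S_hat, self.gI_axis, self.theta_axis)
        return dF, dS

    def _get_interp(self, name: str):
        if not self._interp:
            (dFg, dFt), (dSg, dSt) = self.gradients()
            for key, Z in (("F", self.F), ("S", self.S_hat), ("dFg", dFg),
                           ("dFt", dFt), ("dSg", dSg), ("dSt", dSt)):
                self._interp[key] = RegularGridInterpolator(
                    (self.gI_axis, self.theta_axis), Z, bounds_error=False,
                    fill_value=np.nan)
        return self._interp[name]

    def gradients_at(self, point):
        """(grad F, grad S_hat) at an interior point, bilinear interpolation
        of the grid gradients."""
        pt = np.atleast_2d(point)
        gF = np.array([self._get_interp("dFg")(pt)[0],
                       self._get_interp("dFt")(pt)[0]])
        gS = np.array([self._get_interp("dSg")(pt)[0],
                       self._get_interp("dSt")(pt)[0]])
        return gF, gS

    @property
    def center(self):
        return (0.5 * (self.gI_axis[0] + self.gI_axis[-1]),
                0.5 * (self.theta_axis[0] + self.theta_axis[-1]))


@dataclass
class PathSpec:
    """A straight-line path through the (theta, g_I) plane.

    ``family`` is one of radial / horizontal / vertical / custom.  Names
    follow the plane as conventionally drawn with theta on the horizontal
    axis: *horizontal* paths vary theta at fixed g_I (how threshold
    heterogeneity moves a network's cells through the plane), *vertical*
    paths vary g_I at fixed theta.  Radial paths pass through ``anchor``
    (the grid center by default) along ``direction`` given as
    (d_gI, d_theta).
    """

    family: str = "radial"
    anchor: tuple | None = None    # (g_I, theta)
    direction: tuple | None = None
    n_samples: int = 101

    def points(self, surface: RateSurface):
        g0, t0 = self.anchor if self.anchor is not None else surface.center
        if self.family == "horizontal":
            d = np.array([0.0, 1.0])       # varying theta
        elif self.family == "vertical":
            d = np.array([1.0, 0.0])       # varying g_I
        elif self.family in ("radial", "custom"):
            if self.direction is None:
                raise ValueError(f"{self.family} path needs a direction")
            d = np.asarray(self.direction, dtype=float)
        else:
            raise ValueError(f"unknown path family {self.family!r}")
        if not np.any(d != 0):
            raise ValueError("path direction must be nonzero")
        d = d / np.hypot(*d)
        # span the full grid bounding box along the direction
        lo = np.array([surface.gI_axis[0], surface.theta_axis[0]])
        hi = np.array([surface.gI_axis[-1], surface.theta_axis[-1]])
        ts = []
        for dim in range(2):
            if d[dim] != 0:
                ts.extend([(lo[dim] - [g0, t0][dim]) / d[dim],
                           (hi[dim] - [g0, t0][dim]) / d[dim]])
        s_lo = max(t for t in ts if t <= 0) if any(t <= 0 for t in ts) else 0.0
        s_hi = min(t for t in ts if t >= 0) if any(t >= 0 for t in ts) else 0.0
        s = np.linspace(s_lo, s_hi, self.n_samples)
        pts = np.stack([g0 + s * d[0], t0 + s * d[1]], axis=1)
        inside = np.all((pts >= lo - 1e-12) & (pts <= hi + 1e-12), axis=1)
        return s[inside], pts[inside], d


@dataclass
class AlignmentReport:
    """Gradient alignment of F and S_hat at one point."""

    point: tuple
    grad_F: np.ndarray
    grad_S: np.ndarray
    cos_angle: float
    fraction_increasing: float

    def as_dict(self) -> dict:
        return {"point": list(self.point),
                "grad_F": self.grad_F.tolist(),
                "grad_S": self.grad_S.tolist(),
                "cos_angle": self.cos_angle,
                "fraction_increasing": self.fraction_increasing}


def default_axes(summary: PopulationSummary, theta_cv: float = 0.2,
                 n: int = 61):
    """Default grid: theta over the 1-99% log-normal quantiles, g_I over
    [0.5, 1.5] times the solved population mean."""
    th = sample_thresholds(2, theta_cv, 0.01, 0.99)
    gI = np.linspace(0.5 * summary.mean_gI, 1.5 * summary.mean_gI, n)
    theta = np.linspace(th[0], th[-1], n)
    return gI, theta


def rate_surface(gI_axis: np.ndarray, theta_axis: np.ndarray,
                 frozen: PopulationSummary | dict,
                 intrinsic_tau_m: float = 20.0, tau_ref: float = 2.0,
                 v_reset: float = 0.0, E_E: float = 6.5, E_I: float = -0.5,
                 grid: fp.VoltageGrid | None = None) -> RateSurface:
    """Evaluate F(g_I, theta) and S_hat on a grid of effective cells.

    ``frozen`` supplies the population-averaged mean_gE, sigma_gE, sigma_gI
    and sigma_sqrt_tau_m; every grid point is an independent effective cell
    with those values and the axis (g_I, theta).  S_hat is computed by
    centered finite differences of F along the g_I axis and masked where F
    is numerically zero.
    """
    if isinstance(frozen, PopulationSummary):
        frozen = frozen.as_dict()
    gI_axis = np.asarray(gI_axis, dtype=float)
    theta_axis = np.asarray(theta_axis, dtype=float)
    gE = frozen["mean_gE"]
    sgE2 = frozen["sigma_gE"] ** 2
    sgI2 = frozen["sigma_gI"] ** 2
    sigma = frozen["sigma_sqrt_tau_m"] / np.sqrt(intrinsic_tau_m)
    GI, TH = np.meshgrid(gI_axis, theta_axis, indexing="ij")
    g0 = 1.0 + gE + GI
    E_rev = (gE * E_E + GI * E_I) / g0
    cells = EffectiveCell(
        g0=g0.ravel(), E_rev=E_rev.ravel(),
        sigma_gE2=np.full(GI.size, sgE2), sigma_gI2=np.full(GI.size, sgI2),
        sigma=np.full(GI.size, sigma), theta=TH.ravel(),
        tau_m=intrinsic_tau_m, tau_ref=tau_ref, v_reset=v_reset,
        E_E=E_E, E_I=E_I)
    F = fp.steady_rate(cells, grid).reshape(GI.shape) * 1e3   # Hz
    dF_dgI = np.gradient(F, gI_axis, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = dF_dgI**2 / F
    S[F <= 0] = np.nan
    return RateSurface(gI_axis=gI_axis, theta_axis=theta_axis, F=F, S_hat=S,
                       frozen=dict(frozen))


def path_profile(surface: RateSurface, path: PathSpec,
                 grad_tol_factor: float = 1e-12):
    """F, S_hat and dS_hat/dF along a straight path.

    Bilinear interpolation of the surface and its gradients; the directional
    ratio is masked (NaN) where |grad F . dx| falls below the division
    guard.
    """
    s, pts, d = path.points(surface)
    F = surface._get_interp("F")(pts)
    S = surface._get_interp("S")(pts)
    dFdir = (surface._get_interp("dFg")(pts) * d[0]
             + surface._get_interp("dFt")(pts) * d[1])
    dSdir = (surface._get_interp("dSg")(pts) * d[0]
             + surface._get_interp("dSt")(pts) * d[1])
    guard = grad_tol_factor * np.nanmax(np.abs(
        np.stack(surface.gradients()[0])))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(dFdir) > guard, dSdir / dFdir, np.nan)
    return {"s": s, "gI": pts[:, 0], "theta": pts[:, 1],
            "F": F, "S_hat": S, "dS_dF": ratio}


def alignment(surface: RateSurface, point) -> AlignmentReport:
    """Gradient-alignment statistics at one point.

    fraction_increasing = (pi - arccos cos_angle) / pi is the fraction of
    directions through the point along which S_hat increases with F.
    """
    gF, gS = surface.gradients_at(point)
    nF, nS = np.linalg.norm(gF), np.linalg.norm(gS)
    if not np.isfinite(nF * nS) or nF == 0 or nS == 0:
        raise ValueError(f"gradient undefined or zero at point {point}")
    cos = float(np.clip(gF @ gS / (nF * nS), -1.0, 1.0))
    frac = (np.pi - np.arccos(cos)) / np.pi
    return AlignmentReport(point=tuple(point), grad_F=gF, grad_S=gS,
                           cos_angle=cos, fraction_increasing=float(frac))


def sign_map(surface: RateSurface, point, n_directions: int = 360):
    """Sign of (grad S_hat . x)(grad F . x) over directions x on the circle.

    The fraction of positive directions equals the closed-form alignment
    fraction up to the 1/n_directions discretization.
    """
    gF, gS = surface.gradients_at(point)
    phi = 2 * np.pi * np.arange(n_directions) / n_directions
    x = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    signs = np.sign((x @ gS) * (x @ gF)).astype(int)
    return {"angles": phi, "signs": signs,
            "fraction_positive": float(np.mean(signs > 0))}


def motif_regression(total: np.ndarray, contributions: dict | list):
    """Coefficient of determination of the total correlation against each
    single motif contribution (simple OLS with intercept).

    Returns per-contribution R^2; a constant regressor yields NaN.
    """
    total = np.asarray(total, dtype=float)
    if total.size < 3:
        raise ValueError("need at least 3 pairs for a regression")
    items = (contributions.items() if isinstance(contributions, dict)
             else enumerate(contributions))
    out = {}
    for name, x in items:
        x = np.asarray(x, dtype=float)
        ok = np.isfinite(x) & np.isfinite(total)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            out[name] = np.nan
            continue
        r = np.corrcoef(x[ok], total[ok])[0, 1]
        out[name] = float(r * r)
    return out
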