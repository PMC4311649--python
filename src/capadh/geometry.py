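"""Axisymmetric meniscus geometry: elliptic meridian, surface area, volume.

The meniscus pulled up by a small tip is modelled as a surface of revolution
of an elliptic meridian

    y(x) = b * sqrt(1 - (x/a)**2) + c ,        r_tip <= |x| <= a,

where ``x`` is the radial distance from the symmetry (pull) axis, ``y`` the
height above the undisturbed flat liquid surface, ``a`` the horizontal
semi-axis (outer radius where the profile meets the bath), ``b`` the vertical
extent and ``c`` a vertical offset that absorbs any residual baseline
mismatch of the fit (ideally ``y(a) = c ~ 0``).  ``r_tip`` is the radius of
the tip--liquid contact line where the meniscus attaches.

All quantities are in SI units (metres); pixel-to-metre conversion happens
once at the imaging boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, optimize

from .errors import (
    DomainError,
    FitConvergenceError,
    FitDegeneracyError,
    NumericalError,
)

__all__ = [
    "MeniscusProfile",
    "ProfileFit",
    "profile_eval",
    "surface_area",
    "meniscus_volume",
    "fit_profile",
    "revolution_area",
    "revolution_volume",
]

#: default absolute quadrature tolerances (design choice; see docs/methods.md)
AREA_EPSABS = 1e-12  # m^2
VOLUME_EPSABS = 1e-15  # m^3


def _elliptic_meridian(x, a, b, c):
    """The meridian function y(x) of the elliptic profile model.

    Kept in one place so the algebraic form is a one-line change.  Valid for
    |x| <= a; callers are responsible for domain checks.
    """
    u = np.asarray(x, dtype=float) / a
    return b * np.sqrt(np.clip(1.0 - u * u, 0.0, None)) + c


def _meridian_extended(x, a, b, c):
    """Analytic continuation of the meridian beyond |x| = a.

    For |x| > a the square root is continued as ``c - b*sqrt(u^2 - 1)`` so
    that least-squares residuals keep a nonzero gradient when noisy points
    fall slightly outside the current ellipse estimate.
    """
    u = np.asarray(x, dtype=float) / a
    q = 1.0 - u * u
    return c + b * np.sign(q) * np.sqrt(np.abs(q))


@dataclass(frozen=True)
class MeniscusProfile:
    """Fitted elliptic meridian of the axisymmetric meniscus.

    Parameters
    ----------
    a, b, c :
        Shape parameters of the elliptic meridian (m).  ``a > 0``, ``b >= 0``.
    r_tip :
        Tip--water contact radius (m); ``0 <= r_tip < a``.
    axis_x :
        Position of the symmetry axis in the image frame (m).
    baseline_y :
        Height of the undisturbed flat surface in the image frame (m).
        Heights returned by :func:`profile_eval` are relative to it.
    """

    a: float
    b: float
    c: float
    r_tip: float = 0.0
    axis_x: float = 0.0
    baseline_y: float = 0.0

    def __post_init__(self):
        for name in ("a", "b", "c", "r_tip", "axis_x", "baseline_y"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"MeniscusProfile.{name} must be finite, got {v!r}")
        if self.a <= 0:
            raise DomainError(f"semi-axis a must be positive, got {self.a}")
        if self.b < 0:
            raise DomainError(f"vertical extent b must be >= 0, got {self.b}")
        if self.r_tip < 0:
            raise DomainError(f"contact radius r_tip must be >= 0, got {self.r_tip}")
        if self.r_tip >= self.a:
            raise DomainError(
                f"contact radius r_tip={self.r_tip} must be smaller than a={self.a}"
            )

    @property
    def tip_height(self) -> float:
        """Height of the meniscus at the contact line, y(r_tip), above baseline."""
        return float(_elliptic_meridian(self.r_tip, self.a, self.b, self.c))

    def with_params(self, **kw) -> "MeniscusProfile":
        return replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(
            {
                "a_m": self.a,
                "b_m": self.b,
                "c_m": self.c,
                "r_tip_m": self.r_tip,
                "axis_x_m": self.axis_x,
                "baseline_y_m": self.baseline_y,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "MeniscusProfile":
        d = json.loads(s)
        return cls(
            a=d["a_m"],
            b=d["b_m"],
            c=d["c_m"],
            r_tip=d["r_tip_m"],
            axis_x=d.get("axis_x_m", 0.0),
            baseline_y=d.get("baseline_y_m", 0.0),
        )


@dataclass
class ProfileFit:
    """Result of fitting the elliptic meridian to extracted edge points."""

    profile: MeniscusProfile
    rms_residual: float
    n_points: int
    pixel_scale: float | None = None
    #: parameter sensitivity to per-point coordinate perturbations,
    #: d(a,b,c,axis_x)/d(point displacement), shape (4, n_points); None for
    #: profiles injected from ground truth.  Used for pixel-error propagation.
    point_sensitivity: np.ndarray | None = field(default=None, repr=False)
    #: the fitted edge points, shape (n_points, 2); used to group points into
    #: contiguous features (left/right flank) during error propagation.
    points: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.rms_residual < 0:
            raise DomainError("rms_residual must be >= 0")
        if self.n_points < 0:
            raise DomainError("n_points must be >= 0")

    def to_json(self) -> str:
        d = json.loads(self.profile.to_json())
        d.update(
            {
                "rms_residual_m": self.rms_residual,
                "n_points": self.n_points,
                "pixel_scale_m_per_px": self.pixel_scale,
            }
        )
        return json.dumps(d)

    @classmethod
    def exact(cls, profile: MeniscusProfile) -> "ProfileFit":
        """Wrap a ground-truth profile as a zero-residual fit."""
        return cls(profile=profile, rms_residual=0.0, n_points=0)


def profile_eval(profile: MeniscusProfile, x):
    """Evaluate the meridian height above the baseline at radial coordinate x.

    ``x`` may be signed (distance from the symmetry axis); the profile is even
    in x.  Values outside ``[r_tip, a]`` (in absolute value) raise
    :class:`DomainError`.
    """
    xr = np.abs(np.asarray(x, dtype=float))
    tol = 1e-12 * profile.a
    if np.any(xr < profile.r_tip - tol) or np.any(xr > profile.a + tol):
        raise DomainError(
            f"radial coordinate outside [{profile.r_tip}, {profile.a}]"
        )
    xr = np.clip(xr, profile.r_tip, profile.a)
    out = _elliptic_meridian(xr, profile.a, profile.b, profile.c)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def _quad(fun, lo, hi, epsabs, epsrel=1e-11, what="integral"):
    val, err, info, *rest = integrate.quad(
        fun, lo, hi, epsabs=epsabs, epsrel=epsrel, limit=200, full_output=1
    )
    if rest:  # quad appended a warning message: not converged
        raise NumericalError(
            f"{what} quadrature did not converge: {rest[0]} "
            f"(estimate {val}, error {err})"
        )
    return val, err


def surface_area(profile: MeniscusProfile, *, epsabs: float = AREA_EPSABS,
                 return_error: bool = False):
    """Area of the surface of revolution of the meridian over [r_tip, a].

    Computed by adaptive quadrature of the parametric surface-of-revolution
    integrand; the substitution ``x = a sin(theta)`` removes the vertical-
    tangent singularity of y'(x) at the outer radius.  The result is always
    at least the area of the flat annulus ``pi (a^2 - r_tip^2)``.
    """
    a, b, r = profile.a, profile.b, profile.r_tip
    theta0 = math.asin(min(1.0, r / a))
    # the default epsabs is quoted for millimetre-scale menisci; shrink it
    # with the profile so micrometre-scale results stay relatively accurate
    eps = min(epsabs, epsabs * (max(a, b) / 1e-3) ** 2) + 1e-30

    def integrand(t):
        s, co = math.sin(t), math.cos(t)
        return a * s * math.hypot(a * co, b * s)

    val, err = _quad(integrand, theta0, math.pi / 2, eps / (2 * math.pi),
                     what="surface area")
    area = 2 * math.pi * val
    return (area, 2 * math.pi * err) if return_error else area


def meniscus_volume(profile: MeniscusProfile, *, epsabs: float = VOLUME_EPSABS,
                    return_error: bool = False):
    """Volume of liquid raised above the undisturbed flat surface.

    Shell integration ``V = int_{r_tip}^{a} 2 pi x y(x) dx``.  Zero for a
    flat profile (b = 0, c = 0); the ``c`` term contributes
    ``pi c (a^2 - r_tip^2)`` and is ~0 for a properly normalized fit.
    """
    a, b, c, r = profile.a, profile.b, profile.c, profile.r_tip
    eps = min(epsabs, epsabs * (max(a, b) / 1e-3) ** 3) + 1e-30

    def integrand(x):
        return 2 * math.pi * x * float(_elliptic_meridian(x, a, b, c))

    val, err = _quad(integrand, r, a, eps, what="meniscus volume")
    return (val, err) if return_error else val


def revolution_area(f, r0: float, r1: float, df=None, *,
                    epsabs: float = AREA_EPSABS) -> float:
    """Lateral area of the surface obtained by rotating y = f(x) about the
    y axis over [r0, r1]; generic quadrature helper for arbitrary meridians.

    ``df`` is the derivative of f; estimated by central differences if absent.
    """
    if df is None:
        h = 1e-7 * max(abs(r1 - r0), 1e-12)

        def df(x, _f=f, _h=h):  # noqa: E731 - simple numeric derivative
            return (_f(x + _h) - _f(x - _h)) / (2 * _h)

    def integrand(x):
        return 2 * math.pi * x * math.hypot(1.0, df(x))

    val, _ = _quad(integrand, r0, r1, epsabs, what="revolution area")
    return val


def revolution_volume(f, r0: float, r1: float, *,
                      epsabs: float = VOLUME_EPSABS) -> float:
    """Shell-integration volume under y = f(x) rotated about the y axis."""

    def integrand(x):
        return 2 * math.pi * x * f(x)

    val, _ = _quad(integrand, r0, r1, epsabs, what="revolution volume")
    return val


# ---------------------------------------------------------------------------
# profile fitting
# ---------------------------------------------------------------------------


def _check_degeneracy(pts: np.ndarray):
    if len(pts) < 8:
        raise FitDegeneracyError(
            f"need at least 8 edge points to fit the profile, got {len(pts)}"
        )
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[0] == 0 or s[1] / s[0] < 1e-9:
        raise FitDegeneracyError("edge points are collinear; profile underdetermined")


def _initial_guess(pts: np.ndarray, axis_hint):
    x, y = pts[:, 0], pts[:, 1]
    if axis_hint is None:
        top = pts[np.argsort(y)[-max(2, len(pts) // 10):]]
        ax0 = float(top[:, 0].mean())
    else:
        ax0 = float(axis_hint)
    span = np.abs(x - ax0).max()
    a0 = 1.05 * span if span > 0 else 1.0
    c0 = float(y.min())
    b0 = max(float(y.max() - y.min()) * 1.2, 1e-9 * a0)
    return a0, b0, c0, ax0


def _orthogonal_residuals(pts, a, b, c, ax):
    """Signed euclidean distance from each point to the elliptic meridian.

    The closest point on the parametric arc (a sin t, b cos t + c) is found
    by a coarse grid followed by Newton refinement; the sign is positive for
    points outside the ellipse.
    """
    dx = np.abs(pts[:, 0] - ax)
    dy = pts[:, 1] - c
    t = np.linspace(0.0, np.pi / 2, 128)
    ex, ey = a * np.sin(t), b * np.cos(t)
    d2 = (dx[:, None] - ex[None, :]) ** 2 + (dy[:, None] - ey[None, :]) ** 2
    ti = t[np.argmin(d2, axis=1)]
    for _ in range(12):  # Newton on d/dt of squared distance
        s, co = np.sin(ti), np.cos(ti)
        g = (a * s - dx) * a * co - (b * co - dy) * b * s
        gp = (a * co) ** 2 + (a * s - dx) * (-a * s) + (b * s) ** 2 - (b * co - dy) * b * co
        step = np.where(np.abs(gp) > 1e-300, g / np.where(gp == 0, 1.0, gp), 0.0)
        ti = np.clip(ti - np.clip(step, -0.5, 0.5), 0.0, np.pi / 2)
    s, co = np.sin(ti), np.cos(ti)
    dist = np.hypot(dx - a * s, dy - b * co)
    sign = np.where((dx / a) ** 2 + (dy / max(b, 1e-300)) ** 2 >= 1.0, 1.0, -1.0)
    return sign * dist


def fit_profile(edge_points, side_hint: str = "both", *, r_tip: float = 0.0,
                residuals: str = "vertical", axis_hint: float | None = None,
                pixel_scale: float | None = None,
                max_nfev: int = 2000) -> ProfileFit:
    """Least-squares fit of the elliptic meridian to meniscus edge points.

    Parameters
    ----------
    edge_points :
        (n, 2) array of (x, y) coordinates in metres; y relative to the
        (already normalized) baseline.
    side_hint :
        "both" when points cover both flanks; "left"/"right" for a single
        flank, in which case ``axis_hint`` is required and the axis is held
        fixed.
    r_tip :
        Contact radius to attach to the returned profile (not estimated from
        the flank points).
    residuals :
        "vertical" (default) minimizes y-residuals; "orthogonal" minimizes
        point-to-curve euclidean distance, which is better conditioned for
        slender menisci with near-vertical flanks.
    axis_hint :
        Optional initial (or, for single-flank data, fixed) axis position.

    Returns
    -------
    ProfileFit
        Fit result with rms residual (m) and the point->parameter sensitivity
        matrix used for pixel-quantization error propagation.

    The fit is invariant under rigid horizontal translation of the inputs.
    """
    pts = np.asarray(edge_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError("edge_points must be an (n, 2) array")
    _check_degeneracy(pts)
    if side_hint not in ("both", "left", "right"):
        raise DomainError(f"unknown side_hint {side_hint!r}")
    single_flank = side_hint in ("left", "right")
    if single_flank and axis_hint is None:
        raise FitDegeneracyError(
            "single-flank fit requires an axis estimate (axis_hint)"
        )
    if residuals not in ("vertical", "orthogonal"):
        raise DomainError(f"unknown residual mode {residuals!r}")

    a0, b0, c0, ax0 = _initial_guess(pts, axis_hint)
    if not single_flank and axis_hint is None:
        # one flank alone is a monotone x(y) branch: strong |corr(x, y)|;
        # two flanks mirror each other and decorrelate x from y
        r = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
        left = np.count_nonzero(pts[:, 0] < ax0)
        if abs(r) > 0.8 or min(left, len(pts) - left) < 2:
            raise FitDegeneracyError(
                "points cover a single flank; provide axis_hint/side_hint"
            )

    scale = max(a0, b0)

    def unpack(p):
        a, b, c = p[0], p[1], p[2]
        ax = ax0 if single_flank else p[3]
        return a, b, c, ax

    def resid(p):
        a, b, c, ax = unpack(p)
        if residuals == "vertical":
            return pts[:, 1] - _meridian_extended(np.abs(pts[:, 0] - ax), a, b, c)
        return _orthogonal_residuals(pts, a, b, c, ax)

    jac = "2-point"
    if residuals == "vertical":

        def jac(p):  # analytic jacobian of the vertical residuals
            a, b, c, ax = unpack(p)
            dx = pts[:, 0] - ax
            u = np.abs(dx) / a
            q = 1.0 - u * u
            sq = np.sqrt(np.maximum(np.abs(q), 1e-14))
            s = np.sign(q) * sq
            dm_da = b * u * u / (a * sq)
            dm_db = s
            dm_dc = np.ones_like(u)
            dm_dax = b * u * np.sign(dx) / (a * sq)
            cols = [dm_da, dm_db, dm_dc] + ([] if single_flank else [dm_dax])
            return -np.column_stack(cols)

    p0 = [a0, b0, c0] + ([] if single_flank else [ax0])
    lo = [1e-12, 0.0, -np.inf] + ([] if single_flank else [-np.inf])
    res = optimize.least_squares(
        resid, p0, jac=jac, bounds=(lo, np.inf),
        x_scale=[scale, scale, scale] + ([] if single_flank else [scale]),
        max_nfev=max_nfev, xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    a, b, c, ax = unpack(res.x)
    profile = MeniscusProfile(a=a, b=b, c=c, r_tip=min(r_tip, a * (1 - 1e-12)),
                              axis_x=ax)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    fit = ProfileFit(profile=profile, rms_residual=rms, n_points=len(pts),
                     pixel_scale=pixel_scale)
    if not res.success:
        raise FitConvergenceError(
            f"profile fit did not converge: {res.message}", best_fit=fit
        )
    # sensitivity of (a, b, c, axis_x) to a unit displacement of each point
    # (vertical displacement for vertical residuals, normal displacement for
    # orthogonal ones): dp = (J^T J)^{-1} J^T dr,  dr = d(data).
    J = res.jac
    JTJ = J.T @ J
    try:
        S = np.linalg.solve(JTJ, J.T)
    except np.linalg.LinAlgError:
        S = np.linalg.pinv(JTJ) @ J.T
    if single_flank:  # pad the (fixed) axis row for a uniform 4 x n shape
        S = np.vstack([S, np.zeros((1, S.shape[1]))])
    fit.point_sensitivity = S
    fit.points = pts
    return fit
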