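"""Energy, force and elasticity from fitted meniscus geometry.

The adhesion force of a tip pulled off a liquid bath is obtained from the
energetic route: per frame, the energy needed to build the meniscus is

    E = sigma * (A_meniscus - A_flat) + sigma* * A_contact ,

where ``A_flat = pi (a^2 - r_tip^2)`` is the flat annulus the meniscus
replaced and the contact term is constant during pulling (the contact patch
does not change), so the pull force at tip height y,

    F = dE/dy ,

is independent of the unknown tip--liquid interface tension ``sigma*``.  The
derivative is estimated by local finite differences on the per-frame energy
samples, one-sided at the snap-off frame.  Hooke's law then gives the spring
constant ``D = F / dy`` from the elongation released at snap-off, and in
bending mode the cantilever end-slope relation gives Young's modulus.

Measurement uncertainty is reported in the dual convention used throughout:
a statistical error (from fit residual noise, and across replicates the
standard error of the mean) and a systematic error obtained by propagating a
+-0.5 px quantization of every extracted image coordinate through the whole
chain (worst case and Monte Carlo).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import geometry
from .errors import (
    DataError,
    DomainError,
    InsufficientDataError,
    NonMonotoneEnergyWarning,
    SmallDeflectionWarning,
)
from .geometry import MeniscusProfile, ProfileFit

__all__ = [
    "FluidProperties",
    "ContactPatch",
    "EnergyResult",
    "FrameRecord",
    "PullSequence",
    "BendingSpecimen",
    "MeasurementResult",
    "meniscus_energy",
    "energy_derivative",
    "adhesion_force",
    "weight_force",
    "spring_constant",
    "force_elongation_curve",
    "youngs_modulus_bending",
    "elongation_at_snapoff",
    "systematic_error",
    "analyze_sequence",
    "aggregate_replicates",
    "aggregate_values",
]

#: small-deflection validity bound for the bending formula (rad)
ALPHA_VALIDITY = math.radians(10.0)


@dataclass(frozen=True)
class FluidProperties:
    """Liquid properties: surface tension (N/m), density (kg/m^3), gravity."""

    surface_tension: float = 0.07275
    density: float = 998.0
    gravity: float = 9.81

    def __post_init__(self):
        if self.surface_tension <= 0 or self.density <= 0 or self.gravity <= 0:
            raise DomainError("fluid properties must be positive")

    @classmethod
    def water(cls) -> "FluidProperties":
        """Water at ~22 degC: sigma = 0.07275 N/m, rho = 998 kg/m^3."""
        return cls()


@dataclass(frozen=True)
class ContactPatch:
    """Tip--liquid contact area and (optional) interface tension sigma*."""

    area: float = 0.0
    interface_tension: float | None = None

    def __post_init__(self):
        if self.area < 0:
            raise DomainError("contact area must be >= 0")


@dataclass(frozen=True)
class EnergyResult:
    """Meniscus formation energy; ``includes_contact`` is False when sigma*
    is unknown and the reported value omits the constant sigma* * A term."""

    value: float
    includes_contact: bool


@dataclass
class FrameRecord:
    """One analyzed frame of a pull sequence.

    ``tip_position`` is the absolute tip height in the image frame (m).
    ``tip_from_fit`` marks tips derived from the fitted meniscus apex (the
    attachment point), whose pixel error propagates through the fit rather
    than being an independent image coordinate.
    """

    stage_position: float
    timestamp: float = 0.0
    fit: ProfileFit | None = None
    tip_position: float | None = None
    tip_from_fit: bool = False
    baseline_y: float = 0.0
    bending_angle: float | None = None

    @property
    def analyzable(self) -> bool:
        return self.fit is not None and self.tip_position is not None


@dataclass
class PullSequence:
    """Ordered frames of one pull-off experiment.

    ``snap_index`` points at the last frame with a connected meniscus; frames
    after it are post-snap-off (relaxed) frames carrying only a tip position.
    """

    frames: list
    snap_index: int
    pixel_scale: float
    mode: str = "tension"

    def __post_init__(self):
        if not 0 <= self.snap_index < len(self.frames):
            raise DataError("snap_index outside the frame range")
        if self.mode not in ("tension", "bending"):
            raise DataError(f"unknown mode {self.mode!r}")
        s = np.array([f.stage_position for f in self.frames])
        d = np.diff(s)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise DataError("stage positions must be strictly monotone")
        if len(self.pre_frames) < 2:
            raise InsufficientDataError(
                "need at least 2 analyzable frames before snap-off"
            )

    @property
    def pre_frames(self) -> list:
        return [f for f in self.frames[: self.snap_index + 1] if f.analyzable]

    @property
    def snap_frame(self) -> FrameRecord:
        return self.frames[self.snap_index]

    @property
    def relaxed_frame(self) -> FrameRecord | None:
        for f in self.frames[self.snap_index + 1:]:
            if f.tip_position is not None and f.fit is None:
                return f
        return None


@dataclass(frozen=True)
class BendingSpecimen:
    """Cantilever (bending-spring) specimen: free length l, diameter d,
    mount tilt relative to horizontal (rad)."""

    length: float
    diameter: float
    tilt: float = 0.0

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise DomainError("specimen length and diameter must be positive")

    @property
    def second_moment(self) -> float:
        """Second moment of area of the circular cross-section, pi d^4 / 64."""
        return math.pi * self.diameter**4 / 64.0


@dataclass
class MeasurementResult:
    """One CAT measurement: adhesion force F (N), elongation at snap-off (m),
    spring constant D (N/m), optional Young's modulus (N/m^2), meniscus
    weight force (N), with per-quantity statistical and systematic errors.

    Error dictionaries are keyed "F", "dy", "D", "E_Y"; ``systematic`` holds
    the worst-case (headline) numbers, ``systematic_mc`` the Monte-Carlo
    ones.  Unit conversions (uN, mN/m, N/cm^2) happen at the reporting layer.
    """

    adhesion_force: float
    elongation: float | None
    spring_constant: float | None
    weight_force: float
    youngs_modulus: float | None = None
    statistical: dict = field(default_factory=dict)
    systematic: dict = field(default_factory=dict)
    systematic_mc: dict = field(default_factory=dict)
    warnings: tuple = ()


# ---------------------------------------------------------------------------
# energy and derivative estimators
# ---------------------------------------------------------------------------


def _flat_annulus(profile: MeniscusProfile) -> float:
    return math.pi * (profile.a**2 - profile.r_tip**2)


def _sigma_energy(profile: MeniscusProfile, fluid: FluidProperties) -> float:
    """The sigma term of the meniscus energy (J): added surface energy."""
    return fluid.surface_tension * (geometry.surface_area(profile) - _flat_annulus(profile))


def meniscus_energy(profile: MeniscusProfile, fluid: FluidProperties,
                    contact: ContactPatch | None = None) -> EnergyResult:
    """Minimum energy to build the meniscus from the flat surface.

    Returns ``sigma (A_meniscus - A_flat) + sigma* A_contact``.  When the
    interface tension is unknown the result carries only the sigma term and
    is flagged as up-to-a-constant; the force is unaffected either way.
    """
    e = _sigma_energy(profile, fluid)
    if contact is not None and contact.interface_tension is not None:
        return EnergyResult(e + contact.interface_tension * contact.area, True)
    return EnergyResult(e, False)


def _lagrange_derivative(y3, e3, at):
    """Derivative at ``at`` of the quadratic through three (y, E) samples."""
    (y0, y1, y2), (e0, e1, e2) = y3, e3
    d = e0 * (2 * at - y1 - y2) / ((y0 - y1) * (y0 - y2))
    d += e1 * (2 * at - y0 - y2) / ((y1 - y0) * (y1 - y2))
    d += e2 * (2 * at - y0 - y1) / ((y2 - y0) * (y2 - y1))
    return d


def energy_derivative(y, E, *, stencil: int = 3) -> float:
    """dE/dy at the last sample (the snap-off frame).

    ``stencil=2`` uses the backward two-point difference, ``stencil=3`` the
    one-sided three-point (local quadratic) stencil, exact for quadratic
    E(y).  Samples need not be uniformly spaced.  Additive constants in E
    (for example an unknown sigma* contact term) cancel exactly.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    if y.shape != E.shape or y.ndim != 1 or len(y) < 2:
        raise InsufficientDataError("need >= 2 (y, E) samples for a derivative")
    if np.any(np.diff(y) == 0):
        raise DomainError("tip heights must be distinct")
    if stencil not in (2, 3):
        raise DomainError("stencil must be 2 or 3")
    E = E - E[-1]  # pivot: additive constants cancel without precision loss
    if stencil == 3 and len(y) >= 3:
        return float(_lagrange_derivative(y[-3:], E[-3:], y[-1]))
    return float((E[-1] - E[-2]) / (y[-1] - y[-2]))


def _derivative_per_sample(y, E, stencil: int = 3) -> np.ndarray:
    """dE/dy at every sample: central local quadratic inside, one-sided at
    the ends (matching :func:`energy_derivative` at the last sample)."""
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    n = len(y)
    out = np.empty(n)
    if n < 3 or stencil == 2:
        g = np.diff(E) / np.diff(y)
        out[0], out[-1] = g[0], g[-1]
        for i in range(1, n - 1):
            out[i] = 0.5 * (g[i - 1] + g[i])
        return out
    for i in range(n):
        j = min(max(i - 1, 0), n - 3)
        out[i] = _lagrange_derivative(y[j:j + 3], E[j:j + 3], y[i])
    return out


def _frame_energies(seq: PullSequence, fluid: FluidProperties):
    frames = seq.pre_frames
    y = np.array([f.tip_position for f in frames])
    E = np.array([_sigma_energy(f.fit.profile, fluid) for f in frames])
    return frames, y, E


def adhesion_force(seq: PullSequence, fluid: FluidProperties,
                   *, stencil: int = 3) -> float:
    """Adhesion force of the tip: dE/dy evaluated at the snap-off frame (N).

    Warns (:class:`NonMonotoneEnergyWarning`) when the energy samples are not
    monotone in tip height beyond the expected noise.
    """
    frames, y, E = _frame_energies(seq, fluid)
    if len(frames) < 2:
        raise InsufficientDataError("need >= 2 fitted frames before snap-off")
    dE = np.diff(E) * np.sign(np.diff(y))
    if np.any(dE < 0) and E[-1] > E[0]:
        _warnings.warn(
            "meniscus energy not monotone in tip height; force estimate may "
            "be noise-limited", NonMonotoneEnergyWarning, stacklevel=2,
        )
    return energy_derivative(y, E, stencil=stencil)


def weight_force(profile: MeniscusProfile, fluid: FluidProperties) -> float:
    """Weight of the liquid raised in the meniscus, rho g V (N)."""
    return fluid.density * fluid.gravity * geometry.meniscus_volume(profile)


def spring_constant(force: float, elongation: float) -> float:
    """Hooke's-law spring constant D = F / dy (N/m)."""
    if elongation <= 0:
        raise DomainError(
            f"elongation must be positive to resolve a stiffness, got {elongation}"
        )
    return force / elongation


def elongation_at_snapoff(seq: PullSequence) -> float:
    """Elongation dy released at snap-off (m), from the tip recoil between
    the snap-off frame and the first relaxed frame, net of stage motion."""
    relaxed = seq.relaxed_frame
    snap = seq.snap_frame
    if relaxed is None:
        raise InsufficientDataError("no relaxed (post-snap-off) frame with a tip")
    if snap.tip_position is None:
        raise InsufficientDataError("snap-off frame has no tip position")
    return (relaxed.tip_position - snap.tip_position) - (
        relaxed.stage_position - snap.stage_position
    )


@dataclass
class ForceElongationCurve:
    """Per-frame (elongation, force) samples with errors and a linear fit.

    ``slope`` is a least-squares spring-constant estimate and ``r_squared``
    the linearity diagnostic of the Hookean model.
    """

    elongation: np.ndarray
    force: np.ndarray
    force_systematic: np.ndarray
    elongation_systematic: float
    slope: float
    intercept: float
    r_squared: float
    relative_reference: bool


def force_elongation_curve(seq: PullSequence, fluid: FluidProperties,
                           *, stencil: int = 3) -> ForceElongationCurve:
    """Force--elongation curve over the pull: per-frame force from the same
    dE/dy estimator and per-frame elongation from tip-vs-stage displacement.

    When no relaxed frame is available the elongations are relative to the
    first frame (offset unknown); the slope and linearity are unaffected.
    """
    frames, y, E = _frame_energies(seq, fluid)
    if len(frames) < 3:
        raise InsufficientDataError("force-elongation curve needs >= 3 frames")
    F = _derivative_per_sample(y, E, stencil)
    s = np.array([f.stage_position for f in frames])
    relaxed = seq.relaxed_frame
    if relaxed is not None:
        ref = relaxed.stage_position - relaxed.tip_position
        relative = False
    else:
        ref = s[0] - y[0]
        relative = True
    dy = (s - y) - ref
    lin = stats.linregress(dy, F)
    h = 0.5 * seq.pixel_scale
    # per-point error scale: a coherent +-0.5 px on the frame's vertical
    # extent b divided by the local stencil span of the derivative
    force_syst = np.empty_like(F)
    for i, f in enumerate(frames):
        dEdb = _energy_gradient(f.fit.profile, fluid)[1]
        span = abs(y[min(i + 1, len(y) - 1)] - y[max(i - 1, 0)])
        force_syst[i] = abs(dEdb) * h / max(span / 2, 1e-300)
    return ForceElongationCurve(
        elongation=dy,
        force=F,
        force_systematic=force_syst,
        elongation_systematic=2 * h,
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        r_squared=float(lin.rvalue**2),
        relative_reference=relative,
    )


def youngs_modulus_bending(force: float, specimen: BendingSpecimen,
                           alpha: float, *, angle_form: str = "sin") -> float:
    """Young's modulus from the cantilever end-slope relation (N/m^2).

    For an elastic bar of length l and circular diameter d, clamped at one
    end and pulled down at the free end with force F until the end makes the
    angle alpha with the liquid surface,

        E = 32 F l^2 / (pi d^4 sin(alpha)) ,

    with ``I = pi d^4 / 64``; ``angle_form="tan"`` selects the tangent
    variant of the end-slope term.  The force is projected onto the beam
    normal with cos(tilt) for a tilted mount.  Valid in the small-deflection
    regime; a warning is issued beyond alpha = 10 deg.
    """
    if force <= 0:
        raise DomainError("force must be positive")
    if not 0 < alpha < math.pi / 2:
        raise DomainError("bending angle must lie in (0, pi/2)")
    if angle_form not in ("sin", "tan"):
        raise DomainError("angle_form must be 'sin' or 'tan'")
    if alpha > ALPHA_VALIDITY:
        _warnings.warn(
            f"bending angle {math.degrees(alpha):.1f} deg beyond the "
            "small-deflection validity bound (10 deg); modulus estimate "
            "degrades with alpha", SmallDeflectionWarning, stacklevel=2,
        )
    slope_term = math.sin(alpha) if angle_form == "sin" else math.tan(alpha)
    f_normal = force * math.cos(specimen.tilt)
    return f_normal * specimen.length**2 / (2 * specimen.second_moment * slope_term)


# ---------------------------------------------------------------------------
# pixel-quantization (systematic) and statistical error propagation
# ---------------------------------------------------------------------------


def _energy_gradient(profile: MeniscusProfile, fluid: FluidProperties):
    """Numeric gradient of the sigma-energy wrt (a, b, c, r_tip)."""
    out = []
    for name in ("a", "b", "c", "r_tip"):
        v = getattr(profile, name)
        eps = 1e-6 * profile.a
        hi = profile.with_params(**{name: v + eps})
        lo_v = v - eps
        if name == "r_tip" and lo_v < 0:
            lo_v = 0.0
        lo = profile.with_params(**{name: lo_v})
        out.append((_sigma_energy(hi, fluid) - _sigma_energy(lo, fluid)) / (v + eps - lo_v))
    return np.array(out)


def _tip_gradient(profile: MeniscusProfile):
    """Gradient of the apex (tip attachment) height wrt (a, b, c, r_tip)."""
    a, b, c, r = profile.a, profile.b, profile.c, profile.r_tip
    q = max(1.0 - (r / a) ** 2, 1e-15)
    s = math.sqrt(q)
    return np.array([b * r**2 / (a**3 * s), s, 1.0, -b * r / (a**2 * s)])


class _Chain:
    """Linearized measurement chain F(dE_k, dy_k), dy(d tips), D = F/dy."""

    def __init__(self, seq: PullSequence, fluid: FluidProperties, stencil: int):
        self.frames, self.y, self.E = _frame_energies(seq, fluid)
        self.stencil = stencil
        self.F0 = energy_derivative(self.y, self.E, stencil=stencil)
        n = len(self.frames)
        epsE = 1e-7 * (np.abs(self.E).max() + 1e-300)
        epsy = 1e-7 * (np.ptp(self.y) + 1e-300)
        self.dF_dE = np.zeros(n)
        self.dF_dy = np.zeros(n)
        for k in range(n):
            Ep = self.E.copy(); Ep[k] += epsE
            self.dF_dE[k] = (energy_derivative(self.y, Ep, stencil=stencil) - self.F0) / epsE
            yp = self.y.copy(); yp[k] += epsy
            self.dF_dy[k] = (energy_derivative(yp, self.E, stencil=stencil) - self.F0) / epsy
        self.snap_pos = n - 1

    def frame_vectors(self, k, fluid):
        """Per-frame (dF/dp, d dy/dp) for p = (a, b, c, axis, r_tip) where the
        axis has no effect on energy or tip height."""
        f = self.frames[k]
        p = f.fit.profile
        gE = _energy_gradient(p, fluid)  # wrt (a, b, c, r_tip)
        gy = _tip_gradient(p) if f.tip_from_fit else np.zeros(4)
        dF = self.dF_dE[k] * gE + self.dF_dy[k] * gy
        # elongation depends on the snap-frame tip only (negatively)
        ddy = -gy if k == self.snap_pos else np.zeros(4)
        order = [0, 1, 2, None, 3]  # map to (a, b, c, axis, r_tip)
        dF5 = np.array([0.0 if i is None else dF[i] for i in order])
        ddy5 = np.array([0.0 if i is None else ddy[i] for i in order])
        return dF5, ddy5


def _error_propagation(seq: PullSequence, fluid: FluidProperties, *,
                       stencil: int = 3, n_mc: int = 200, seed: int = 0,
                       specimen: BendingSpecimen | None = None,
                       angle_form: str = "sin",
                       angle_window: float | None = None):
    """Propagate +-0.5 px per extracted coordinate through the full chain.

    Returns (worst_case, monte_carlo, statistical) dictionaries keyed by
    quantity ("F", "dy", "D", "E_Y").  Worst case is the first-order L1
    bound (adversarial signs on every coordinate); Monte Carlo draws each
    coordinate uniformly in (-0.5, 0.5) px; the statistical error replaces
    the half-pixel amplitude by each frame's rms fit residual (gaussian).
    """
    h = 0.5 * seq.pixel_scale
    chain = _Chain(seq, fluid, stencil)
    rng = np.random.default_rng(seed)
    relaxed = seq.relaxed_frame
    have_dy = relaxed is not None and seq.snap_frame.tip_position is not None
    dy0 = elongation_at_snapoff(seq) if have_dy else None

    worst = {"F": 0.0, "dy": 0.0}
    mcF = np.zeros(n_mc)
    mcdy = np.zeros(n_mc)
    varF_stat = 0.0
    vardy_stat = 0.0

    for k, f in enumerate(chain.frames):
        dF5, ddy5 = chain.frame_vectors(k, fluid)
        S = f.fit.point_sensitivity
        sigma_pt = f.fit.rms_residual
        if S is not None and S.shape[1] > 0:
            # per-point coordinates through the fit: params (a, b, c, axis).
            # Worst case: quantization acts coherently along each contiguous
            # edge feature (left / right flank), adversarially across
            # features and frames; Monte Carlo: independent per point.
            vF = dF5[:4] @ S          # dF per unit point displacement
            vdy = ddy5[:4] @ S
            if f.fit.points is not None:
                sides = np.sign(f.fit.points[:, 0] - f.fit.profile.axis_x)
            else:
                sides = np.ones(S.shape[1])
            for side in (-1.0, 1.0):
                sel = sides == side if (sides == side).any() else None
                if sel is not None:
                    worst["F"] += h * abs(vF[sel].sum())
                    worst["dy"] += h * abs(vdy[sel].sum())
            draws = rng.uniform(-h, h, size=(S.shape[1], n_mc))
            mcF += vF @ draws
            mcdy += vdy @ draws
            varF_stat += float(np.sum((vF * sigma_pt) ** 2))
            vardy_stat += float(np.sum((vdy * sigma_pt) ** 2))
        else:
            # visually assessed parameters: +-0.5 px on a, b, c directly
            for j in (0, 1, 2):
                worst["F"] += h * abs(dF5[j])
                worst["dy"] += h * abs(ddy5[j])
                d = rng.uniform(-h, h, size=n_mc)
                mcF += dF5[j] * d
                mcdy += ddy5[j] * d
        # r_tip: one extracted width coordinate per frame
        worst["F"] += h * abs(dF5[4])
        worst["dy"] += h * abs(ddy5[4])
        d = rng.uniform(-h, h, size=n_mc)
        mcF += dF5[4] * d
        mcdy += ddy5[4] * d
        # baseline of this frame: shifts the absolute tip height only
        if f.tip_from_fit:
            dF_b = chain.dF_dy[k]
            ddy_b = -1.0 if k == chain.snap_pos else 0.0
            worst["F"] += h * abs(dF_b)
            worst["dy"] += h * abs(ddy_b)
            d = rng.uniform(-h, h, size=n_mc)
            mcF += dF_b * d
            mcdy += ddy_b * d
        # independently tracked tip: one coordinate
        if not f.tip_from_fit and f.tip_position is not None:
            worst["F"] += h * abs(chain.dF_dy[k])
            extra = -1.0 if k == chain.snap_pos else 0.0
            worst["dy"] += h * abs(extra)
            d = rng.uniform(-h, h, size=n_mc)
            mcF += chain.dF_dy[k] * d
            mcdy += extra * d
            varF_stat += (chain.dF_dy[k] * sigma_pt) ** 2

    rms_med = float(np.median([f.fit.rms_residual for f in chain.frames]))
    if have_dy:
        # relaxed tip edge: one coordinate, d(dy)/d(tip_rel) = +1
        worst["dy"] += h
        mcdy += rng.uniform(-h, h, size=n_mc)
        vardy_stat += rms_med**2

    out_worst = {"F": worst["F"]}
    out_mc = {"F": float(np.std(mcF))}
    out_stat = {"F": math.sqrt(varF_stat)}
    if have_dy:
        out_worst["dy"] = worst["dy"]
        out_mc["dy"] = float(np.std(mcdy))
        out_stat["dy"] = math.sqrt(vardy_stat)
        if dy0 > 0:
            D0 = chain.F0 / dy0
            # combine per-draw (shared coordinates stay correlated)
            mcD = (chain.F0 + mcF) / (dy0 + mcdy) - D0
            out_mc["D"] = float(np.std(mcD))
            out_worst["D"] = abs(D0) * (worst["F"] / abs(chain.F0) + worst["dy"] / dy0)
            out_stat["D"] = abs(D0) * math.sqrt(
                (out_stat["F"] / chain.F0) ** 2 + (out_stat["dy"] / dy0) ** 2
            )
    if specimen is not None and seq.snap_frame.bending_angle is not None:
        alpha = seq.snap_frame.bending_angle
        win = angle_window if angle_window else 100 * seq.pixel_scale
        dalpha = 2 * h / win  # two centerline endpoints at +-0.5 px
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", SmallDeflectionWarning)
            E0 = youngs_modulus_bending(chain.F0, specimen, alpha,
                                        angle_form=angle_form)
            dE_dalpha = (
                youngs_modulus_bending(chain.F0, specimen, alpha * (1 + 1e-6),
                                       angle_form=angle_form) - E0
            ) / (alpha * 1e-6)
        dE_dF = E0 / chain.F0
        out_worst["E_Y"] = abs(dE_dF) * worst["F"] + abs(dE_dalpha) * dalpha
        d1 = rng.uniform(-h, h, size=n_mc)
        d2 = rng.uniform(-h, h, size=n_mc)
        out_mc["E_Y"] = float(np.std(dE_dF * mcF + dE_dalpha * (d1 - d2) / win))
        out_stat["E_Y"] = abs(dE_dF) * out_stat["F"]
    return out_worst, out_mc, out_stat


def systematic_error(seq: PullSequence, fluid: FluidProperties, *,
                     stencil: int = 3, n_mc: int = 200, seed: int = 0,
                     specimen: BendingSpecimen | None = None,
                     angle_form: str = "sin",
                     angle_window: float | None = None):
    """Per-quantity systematic error from the +-0.5 px camera quantization.

    Returns ``(worst_case, monte_carlo)`` dictionaries keyed "F", "dy", "D"
    (and "E_Y" in bending mode).  The worst-case number is the headline
    systematic error; both scale linearly with the pixel size and vanish in
    the perfect-camera limit.
    """
    worst, mc, _ = _error_propagation(
        seq, fluid, stencil=stencil, n_mc=n_mc, seed=seed, specimen=specimen,
        angle_form=angle_form, angle_window=angle_window,
    )
    return worst, mc


def analyze_sequence(seq: PullSequence, fluid: FluidProperties | None = None, *,
                     specimen: BendingSpecimen | None = None,
                     stencil: int = 3, angle_form: str = "sin",
                     n_mc: int = 200, seed: int = 0,
                     angle_window: float | None = None) -> MeasurementResult:
    """Full evaluation of one pull sequence into a MeasurementResult."""
    fluid = fluid or FluidProperties.water()
    warn_msgs = []
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        F = adhesion_force(seq, fluid, stencil=stencil)
        try:
            dy = elongation_at_snapoff(seq)
        except InsufficientDataError:
            dy = None
        D = spring_constant(F, dy) if dy is not None and dy > 0 else None
        FG = weight_force(seq.pre_frames[-1].fit.profile, fluid)
        EY = None
        if (seq.mode == "bending" and specimen is not None
                and seq.snap_frame.bending_angle is not None):
            EY = youngs_modulus_bending(F, specimen,
                                        seq.snap_frame.bending_angle,
                                        angle_form=angle_form)
        warn_msgs = [str(w.message) for w in caught]
    worst, mc, stat = _error_propagation(
        seq, fluid, stencil=stencil, n_mc=n_mc, seed=seed, specimen=specimen,
        angle_form=angle_form, angle_window=angle_window,
    )
    return MeasurementResult(
        adhesion_force=F, elongation=dy, spring_constant=D,
        weight_force=FG, youngs_modulus=EY,
        statistical=stat, systematic=worst, systematic_mc=mc,
        warnings=tuple(warn_msgs),
    )


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplicateSummary:
    """mean +- statistical (SEM) +- systematic, in the reporting convention
    'value followed by the associated statistical and systematic error'."""

    mean: float
    sem: float
    systematic: float
    n: int


def aggregate_values(values, systematics=None) -> ReplicateSummary:
    """Aggregate replicate values: mean, standard error of the mean, and the
    pooled systematic error (mean of per-measurement systematics -- a bias-
    like error is not reduced by averaging replicates)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InsufficientDataError("need >= 2 replicates to aggregate")
    sem = float(np.std(v, ddof=1) / math.sqrt(len(v)))
    syst = float(np.mean(systematics)) if systematics is not None else 0.0
    return ReplicateSummary(mean=float(np.mean(v)), sem=sem, systematic=syst,
                            n=len(v))


def aggregate_replicates(results) -> dict:
    """Aggregate a list of MeasurementResult into per-quantity summaries."""
    if len(results) < 2:
        raise InsufficientDataError("need >= 2 replicates to aggregate")
    out = {}
    for key, attr in (("F", "adhesion_force"), ("D", "spring_constant"),
                      ("E_Y", "youngs_modulus")):
        vals = [getattr(r, attr) for r in results]
        if any(v is None for v in vals):
            continue
        systs = [r.systematic.get(key, 0.0) for r in results]
        out[key] = aggregate_values(vals, systs)
    return out
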