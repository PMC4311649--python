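"""Ground-truth synthetic CAT experiments: parameter families, rendered
backlit frames, and an Euler--Bernoulli beam oracle.

Every generator emits its full truth alongside the data, and all randomness
flows from one explicit seed, so any stage of the analysis chain can be
tested round-trip without laboratory data.

The meniscus evolution is a parametric family: over the pull, the vertical
extent ``b`` of the elliptic meridian grows linearly with the control
parameter while the outer radius ``a`` shrinks slightly and ``c`` stays
fixed.  Energies and forces along the family come from closed-form
ellipse-zone area/volume expressions (independent of the quadrature used by
the analysis code), so the analytic force oracle does not depend on the
particular family chosen.

Default scales emulate the floating-fern trichome experiments: a tip contact
radius of ~40 um whose pull-off force sits at the contact-line capillary
scale 2 pi sigma r (~20 uN), a Hookean structure of 2 N/m, a 768 x 576
8-bit camera, and a 120 um/s pull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import integrate, ndimage, optimize

from .errors import ConfigError, GenerationError, NumericalError, RenderError
from .geometry import MeniscusProfile, ProfileFit, _elliptic_meridian
from .imaging import Frame
from .mechanics import FluidProperties, FrameRecord, PullSequence

__all__ = [
    "CameraModel",
    "MeniscusFamily",
    "SyntheticTruth",
    "FamilyRecord",
    "BeamSolution",
    "ellipse_zone_area",
    "ellipse_zone_volume",
    "generate_pull_family",
    "render_frames",
    "beam_oracle",
    "sample_experiment_geometries",
    "truth_from_dict",
]


# ---------------------------------------------------------------------------
# closed-form ellipse-zone area and volume (analytic oracles)
# ---------------------------------------------------------------------------


def ellipse_zone_area(a: float, b: float, r_tip: float = 0.0) -> float:
    """Closed-form area of the elliptic meridian revolved over [r_tip, a].

    With ``x = a sin(t)``, ``y = b cos(t)`` the area reduces to
    ``2 pi a \\int_0^{u_t} sqrt(b^2 + (a^2 - b^2) u^2) du`` with
    ``u_t = sqrt(1 - (r_tip/a)^2)``, which integrates in elementary
    functions (asinh for oblate a > b, asin for prolate a < b).
    """
    u = math.sqrt(max(0.0, 1.0 - (r_tip / a) ** 2))
    m = a * a - b * b
    if b == 0.0:
        return math.pi * (a * a - r_tip * r_tip)
    if abs(m) < 1e-12 * a * a:
        return 2 * math.pi * a * b * u
    if m > 0:
        sm = math.sqrt(m)
        val = 0.5 * u * math.sqrt(b * b + m * u * u) \
            + b * b / (2 * sm) * math.asinh(sm * u / b)
    else:
        sm = math.sqrt(-m)
        val = 0.5 * u * math.sqrt(b * b + m * u * u) \
            + b * b / (2 * sm) * math.asin(sm * u / b)
    return 2 * math.pi * a * val


def ellipse_zone_volume(a: float, b: float, c: float = 0.0,
                        r_tip: float = 0.0) -> float:
    """Closed-form shell-integration volume of the meridian over [r_tip, a]:
    ``2 pi b a^2/3 (1 - (r/a)^2)^{3/2} + pi c (a^2 - r^2)``."""
    q = max(0.0, 1.0 - (r_tip / a) ** 2)
    return (2 * math.pi / 3) * b * a * a * q**1.5 \
        + math.pi * c * (a * a - r_tip * r_tip)


# ---------------------------------------------------------------------------
# truth description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Backlit CCD emulation: 768 x 576 8-bit frames by default, with a
    Gaussian optical blur and additive Gaussian read noise."""

    pixel_scale: float = 0.6e-6  # m / px
    width: int = 768
    height: int = 576
    blur_sigma_px: float = 1.0
    noise_sigma: float = 3.0  # gray levels


@dataclass(frozen=True)
class MeniscusFamily:
    """Linear-in-control meniscus family: the hump grows in height (b) and
    spreads slightly in outer radius (a) as the tip rises; c fixed.

    The defaults describe a slender near-snap-off meniscus on a 25 um tip
    whose pull force grows to the contact-line capillary scale (~20 uN) at
    snap-off, with the raised liquid weight two orders of magnitude below
    the pull force throughout.
    """

    r_tip: float = 20e-6
    a_start: float = 28e-6
    a_end: float = 47e-6
    b_start: float = 90e-6
    b_end: float = 190e-6
    c: float = 0.0

    def params(self, u: float):
        a = self.a_start + (self.a_end - self.a_start) * u
        b = self.b_start + (self.b_end - self.b_start) * u
        return a, b, self.c

    def profile(self, u: float) -> MeniscusProfile:
        a, b, c = self.params(u)
        return MeniscusProfile(a=a, b=b, c=c, r_tip=self.r_tip)

    def tip_height(self, u: float) -> float:
        a, b, c = self.params(u)
        return float(_elliptic_meridian(self.r_tip, a, b, c))

    def sigma_energy(self, u: float, fluid: FluidProperties) -> float:
        a, b, _c = self.params(u)
        flat = math.pi * (a * a - self.r_tip**2)
        return fluid.surface_tension * (ellipse_zone_area(a, b, self.r_tip) - flat)

    def force(self, u: float, fluid: FluidProperties, du: float = 1e-6) -> float:
        """Analytic pull force dE/dy_tip along the family (closed forms)."""
        dE = self.sigma_energy(u + du, fluid) - self.sigma_energy(u - du, fluid)
        dy = self.tip_height(u + du) - self.tip_height(u - du)
        return dE / dy


@dataclass(frozen=True)
class SyntheticTruth:
    """Complete description of a synthetic CAT experiment."""

    family: MeniscusFamily = MeniscusFamily()
    spring_constant: float = 2.0  # N/m (Hookean tension spring)
    fluid: FluidProperties = FluidProperties()
    camera: CameraModel = CameraModel()
    seed: int = 0
    pull_speed: float = 120e-6  # m/s
    free_length: float = 2e-3  # structure length between stage and tip (m)
    snap_rule: tuple = ("frames", None)  # ("frames", None) | ("force", F) | ("height", y)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snap_rule"] = list(self.snap_rule)
        return d


@dataclass
class FamilyRecord:
    """Ground truth emitted with every generated sequence."""

    u: np.ndarray
    tip_height: np.ndarray
    energy: np.ndarray
    force: np.ndarray
    elongation: np.ndarray
    profiles: list
    spring_constant: float
    snap_force: float
    snap_elongation: float
    truth: SyntheticTruth


def _solve_snap(truth: SyntheticTruth) -> float:
    rule, value = truth.snap_rule
    if rule == "frames":
        return 1.0
    if rule == "force":
        f = lambda u: truth.family.force(u, truth.fluid) - value  # noqa: E731
    elif rule == "height":
        f = lambda u: truth.family.tip_height(u) - value  # noqa: E731
    else:
        raise ConfigError(f"unknown snap rule {rule!r}")
    try:
        return float(optimize.brentq(f, 1e-4, 2.0))
    except ValueError as exc:
        raise GenerationError(f"snap rule {truth.snap_rule} not reached: {exc}")


def generate_pull_family(truth: SyntheticTruth, n_frames: int):
    """Generate a pure-parameter pull sequence with its analytic truth.

    Returns ``(PullSequence, FamilyRecord)``: per-frame ground-truth
    profiles, analytic energy/force from the closed-form family, Hookean
    elongation ``dy = F / D``, plus one relaxed post-snap-off frame.
    """
    if n_frames < 3:
        raise GenerationError("need at least 3 frames before snap-off")
    u_snap = _solve_snap(truth)
    u = np.linspace(0.0, u_snap, n_frames)
    fam, fluid, D = truth.family, truth.fluid, truth.spring_constant
    E = np.array([fam.sigma_energy(ui, fluid) for ui in u])
    y = np.array([fam.tip_height(ui) for ui in u])
    if np.any(np.diff(E) < -1e-9 * np.abs(E).max()) or np.any(np.diff(y) <= 0):
        raise GenerationError(
            "unphysical family: negative area/energy increments or "
            "non-increasing tip height during the pull"
        )
    F = np.array([fam.force(ui, fluid) for ui in u])
    dy = F / D
    stage = y + truth.free_length + dy
    t = (stage - stage[0]) / truth.pull_speed
    profiles = [fam.profile(ui) for ui in u]
    frames = [
        FrameRecord(
            stage_position=float(stage[k]), timestamp=float(t[k]),
            fit=ProfileFit.exact(profiles[k]), tip_position=float(y[k]),
            tip_from_fit=True,
        )
        for k in range(n_frames)
    ]
    # relaxed frame: meniscus gone, structure recoiled to natural length
    du = u[1] - u[0] if n_frames > 1 else 0.1
    stage_post = stage[-1] + max(du * (stage[-1] - stage[0]), 1e-6)
    frames.append(FrameRecord(
        stage_position=float(stage_post),
        timestamp=float((stage_post - stage[0]) / truth.pull_speed),
        fit=None, tip_position=float(stage_post - truth.free_length),
    ))
    seq = PullSequence(frames=frames, snap_index=n_frames - 1,
                       pixel_scale=truth.camera.pixel_scale, mode="tension")
    rec = FamilyRecord(
        u=u, tip_height=y, energy=E, force=F, elongation=dy,
        profiles=profiles, spring_constant=D, snap_force=float(F[-1]),
        snap_elongation=float(dy[-1]), truth=truth,
    )
    return seq, rec


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


def _render_scene(camera: CameraModel, axis_col: float, baseline_row: float,
                  surface_px, fiber_half_px: float, fiber_bottom_row: float,
                  supersample: int = 4) -> np.ndarray:
    """Rasterize one scene (before blur/noise) with area-weighted edges.

    ``surface_px(xr_px)`` maps radial distance (px) to the liquid surface row
    offset above the baseline (px, >= 0); the fiber is a vertical bar of
    half-width ``fiber_half_px`` from the top of the frame down to
    ``fiber_bottom_row``.
    """
    ss = supersample
    W, H = camera.width, camera.height
    cols = (np.arange(W * ss) + 0.5) / ss - 0.5
    rows = (np.arange(H * ss) + 0.5) / ss - 0.5
    xr = np.abs(cols - axis_col)
    surf_row = baseline_row - surface_px(xr)  # row index of the surface
    dark = rows[:, None] > surf_row[None, :]
    fiber_cols = xr <= fiber_half_px
    dark |= fiber_cols[None, :] & (rows[:, None] < fiber_bottom_row)
    cover = dark.reshape(H, ss, W, ss).mean(axis=(1, 3))
    return 255.0 * (1.0 - cover)


def render_frames(truth: SyntheticTruth, n_frames: int, *,
                  supersample: int = 4):
    """Render a full pull sequence as backlit 8-bit frames.

    Returns ``(frames, truth_sequence, record)`` where ``truth_sequence`` is
    the noise-free :class:`PullSequence` of ground-truth profiles and
    ``record`` the :class:`FamilyRecord`.  Deterministic for a fixed seed
    (byte-identical frames).  Raises :class:`RenderError` when the scene
    does not fit the camera field of view.
    """
    seq, rec = generate_pull_family(truth, n_frames)
    cam = truth.camera
    scale = cam.pixel_scale
    rng = np.random.default_rng(truth.seed)
    axis_col = (cam.width - 1) / 2.0
    baseline_row = round(0.72 * cam.height)

    fam = rec.truth.family
    r_tip_px = fam.r_tip / scale
    a_max_px = max(p.a for p in rec.profiles) / scale
    tip_max_px = max(
        max(rec.tip_height) / scale,
        (seq.frames[-1].tip_position) / scale,
    )
    if axis_col - a_max_px < 0.12 * cam.width:
        raise RenderError("meniscus outer radius leaves no far-field columns")
    if baseline_row - tip_max_px < 8:
        raise RenderError("meniscus/tip exceeds the top of the field of view")

    frames = []
    for k, fr in enumerate(seq.frames):
        if fr.fit is not None:
            p = fr.fit.profile

            def surface(xr_px, p=p):
                xr = np.asarray(xr_px) * scale
                out = np.zeros_like(xr)
                inside = xr <= p.a
                out[inside] = _elliptic_meridian(
                    np.clip(xr[inside], p.r_tip, p.a), p.a, p.b, p.c
                ) / scale
                return out

            fiber_bottom = baseline_row - fr.tip_position / scale
            img = _render_scene(cam, axis_col, baseline_row, surface,
                                r_tip_px, fiber_bottom, supersample)
        else:  # relaxed frame: flat bath, free fiber above it
            def surface(xr_px):
                return np.zeros_like(np.asarray(xr_px, dtype=float))

            fiber_bottom = baseline_row - fr.tip_position / scale
            img = _render_scene(cam, axis_col, baseline_row, surface,
                                r_tip_px, fiber_bottom, supersample)
        if cam.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, cam.blur_sigma_px)
        if cam.noise_sigma > 0:
            img = img + rng.normal(0.0, cam.noise_sigma, size=img.shape)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        frames.append(Frame(image=img, timestamp=fr.timestamp,
                            stage_position=fr.stage_position,
                            pixel_scale=scale))
    return frames, seq, rec


# ---------------------------------------------------------------------------
# Euler--Bernoulli cantilever oracle
# ---------------------------------------------------------------------------


@dataclass
class BeamSolution:
    """Deflection of an end-loaded cantilever: arc length s, tangent angle
    theta(s), coordinates (x, y) with y downward-positive deflection, the
    end-slope angle alpha and the vertical tip deflection."""

    s: np.ndarray
    theta: np.ndarray
    x: np.ndarray
    y: np.ndarray
    alpha: float
    tip_deflection: float


def beam_oracle(e_modulus: float, length: float, diameter: float,
                force: float, *, model: str = "elastica",
                n_nodes: int = 201) -> BeamSolution:
    """Numerically integrated cantilever with a point end load.

    ``model="elastica"`` solves the geometrically exact rod
    ``EI theta'' = -F cos(theta)``, ``theta(0) = 0``, ``theta'(l) = 0``;
    ``model="linear"`` is the small-deflection closed form (tip deflection
    ``F l^3 / 3EI``, end slope ``F l^2 / 2EI``).  Serves as ground truth for
    the bending-mode modulus inversion and angle measurement.
    """
    if e_modulus <= 0 or length <= 0 or diameter <= 0 or force < 0:
        raise GenerationError("beam parameters must be positive (force >= 0)")
    I = math.pi * diameter**4 / 64.0
    s = np.linspace(0.0, length, n_nodes)
    k = force / (e_modulus * I)
    if force == 0.0:
        z = np.zeros_like(s)
        return BeamSolution(s=s, theta=z, x=s.copy(), y=z.copy(),
                            alpha=0.0, tip_deflection=0.0)
    theta_lin = k * (length * s - s * s / 2.0)
    if model == "linear":
        y = k * (length * s**2 / 2.0 - s**3 / 6.0)
        alpha = math.atan(k * length**2 / 2.0)
        return BeamSolution(s=s, theta=np.arctan(np.gradient(y, s)), x=s.copy(),
                            y=y, alpha=alpha, tip_deflection=float(y[-1]))
    if model != "elastica":
        raise ConfigError(f"unknown beam model {model!r}")

    def rhs(si, Y):
        return np.vstack([Y[1], -k * np.cos(Y[0])])

    def bc(Y0, Yl):
        return np.array([Y0[0], Yl[1]])

    guess = np.vstack([theta_lin, k * (length - s)])
    sol = integrate.solve_bvp(rhs, bc, s, guess, tol=1e-8, max_nodes=50000)
    if sol.status != 0:
        raise NumericalError(f"elastica BVP failed: {sol.message}")
    theta = sol.sol(s)[0]
    x = integrate.cumulative_trapezoid(np.cos(theta), s, initial=0.0)
    y = integrate.cumulative_trapezoid(np.sin(theta), s, initial=0.0)
    return BeamSolution(s=s, theta=theta, x=x, y=y, alpha=float(theta[-1]),
                        tip_deflection=float(y[-1]))


# ---------------------------------------------------------------------------
# experiment-scale geometry sampler (weight-force study)
# ---------------------------------------------------------------------------


def sample_experiment_geometries(n: int, seed: int = 0,
                                 fluid: FluidProperties | None = None):
    """Sample near-snap-off meniscus geometries at experiment scale.

    Tip contact radii are drawn uniformly in 10--50 um and meniscus heights
    in 0.3--2 mm.  The outer radius ``a`` is then solved so that the analytic
    pull force of the family sits 5--50% above the contact-line capillary
    scale ``2 pi sigma r_tip`` -- the force scale at which real menisci
    detach (and the exact lower bound of the elliptic family as a -> r_tip),
    which is what makes near-snap-off menisci slender.  The outer radius
    always stays far below the 2.7 mm capillary length of water.  Returns a
    list of ``(profile, analytic_force)`` pairs.
    """
    fluid = fluid or FluidProperties.water()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        r = rng.uniform(10e-6, 50e-6)
        b = rng.uniform(0.3e-3, 2.0e-3)
        lam = rng.uniform(1.05, 1.5)
        f_target = 2 * math.pi * fluid.surface_tension * r * lam

        def force_of_a(a, r=r, b=b):
            da = 1e-8 * a
            dA = ellipse_zone_area(a, b + da, r) - ellipse_zone_area(a, b - da, r)
            q = math.sqrt(1.0 - (r / a) ** 2)
            return fluid.surface_tension * dA / (2 * da) / q

        # bracket on the slender (prolate) branch where the force grows with a
        a_lo = r * (1 + 1e-6)
        a_hi = r * 1.2
        cap = min(1.05 * b, 2.7e-3)
        while force_of_a(a_hi) < f_target and a_hi < cap:
            a_hi = min(a_hi * 1.5, cap)
        a = optimize.brentq(
            lambda a: force_of_a(a) - f_target, a_lo, a_hi, xtol=1e-12
        )
        out.append((MeniscusProfile(a=a, b=b, c=0.0, r_tip=r), f_target))
    return out


# ---------------------------------------------------------------------------
# scenario dictionaries (YAML schema)
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {
    "seed", "n_frames", "camera", "family", "spring_constant", "fluid",
    "pull_speed", "free_length", "snap_rule",
}
_CAMERA_KEYS = {"pixel_scale", "width", "height", "blur_sigma_px", "noise_sigma"}
_FAMILY_KEYS = {"r_tip", "a_start", "a_end", "b_start", "b_end", "c"}
_FLUID_KEYS = {"surface_tension", "density", "gravity"}


def _check_keys(d: dict, allowed: set, where: str):
    unknown = sorted(set(d) - allowed)
    if unknown:
        raise ConfigError(f"unknown {where} keys: {', '.join(unknown)}")


def truth_from_dict(d: dict) -> tuple[SyntheticTruth, int]:
    """Build a SyntheticTruth from a scenario dictionary (YAML content).

    Unknown keys are rejected with an error listing them.  Returns the truth
    and the number of pre-snap-off frames.
    """
    if not isinstance(d, dict):
        raise ConfigError("scenario must be a mapping")
    _check_keys(d, _SCENARIO_KEYS, "scenario")
    cam_d = d.get("camera", {})
    _check_keys(cam_d, _CAMERA_KEYS, "camera")
    fam_d = d.get("family", {})
    _check_keys(fam_d, _FAMILY_KEYS, "family")
    fl_d = d.get("fluid", {})
    _check_keys(fl_d, _FLUID_KEYS, "fluid")
    snap = d.get("snap_rule", ["frames", None])
    if not (isinstance(snap, (list, tuple)) and len(snap) == 2):
        raise ConfigError("snap_rule must be a [rule, value] pair")
    truth = SyntheticTruth(
        family=MeniscusFamily(**fam_d),
        spring_constant=float(d.get("spring_constant", 2.0)),
        fluid=FluidProperties(**fl_d),
        camera=CameraModel(**cam_d),
        seed=int(d.get("seed", 0)),
        pull_speed=float(d.get("pull_speed", 120e-6)),
        free_length=float(d.get("free_length", 2e-3)),
        snap_rule=(snap[0], snap[1]),
    )
    return truth, int(d.get("n_frames", 8))
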