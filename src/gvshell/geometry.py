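"""Closed-form and numeric geometry of the gas-vesicle helix.

The shell is modelled on a left-handed helix that winds around a cylinder
of radius ``r_max`` for ``t_cyl`` turns and then spirals into a conical cap
whose radius decreases linearly to zero over ``t_cap`` turns.  Everything in
this module is analytic geometry on that curve: symmetry conversions
(pitch/units-per-turn vs. rise/twist), arc lengths, inter-monomer spacing,
diameter-to-polymorph conversions and a handful of small identities used to
reason about accessory-protein binding and wall mechanics.

All lengths are in Angstrom; angles in degrees at the API surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "HelicalSymmetry",
    "VesicleSpec",
    "CurvePoint",
    "symmetry_convert",
    "symmetry_invert",
    "spacing_on_helix",
    "units_from_diameter",
    "diameter_increment",
    "cap_turns",
    "curve_point",
    "curve_velocity",
    "arc_length",
    "t_at_arc_length",
    "rib_hbond_angle",
    "magic_angle",
    "gvpc_geometry",
    "GvpCGeometry",
]

Handedness = Literal["left", "right"]

_NM_TO_ANG = 10.0


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class HelicalSymmetry:
    """Helical lattice parameters: pitch, units per turn and handedness.

    ``rise``/``twist`` are derived views of the same lattice; the sign
    convention makes the twist negative for a left-handed helix.
    """

    pitch: float
    units_per_turn: float
    handedness: Handedness = "left"

    def __post_init__(self) -> None:
        _check_positive(pitch=self.pitch, units_per_turn=self.units_per_turn)
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness must be 'left' or 'right', got {self.handedness!r}")

    @property
    def rise(self) -> float:
        return self.pitch / self.units_per_turn

    @property
    def twist(self) -> float:
        sign = -1.0 if self.handedness == "left" else 1.0
        return sign * 360.0 / self.units_per_turn

    @classmethod
    def from_rise_twist(cls, rise: float, twist: float) -> "HelicalSymmetry":
        _check_positive(rise=rise)
        if twist == 0 or not np.isfinite(twist):
            raise ValueError(f"twist must be non-zero and finite, got {twist!r}")
        handedness: Handedness = "left" if twist < 0 else "right"
        units_per_turn = 360.0 / abs(twist)
        return cls(pitch=rise * units_per_turn, units_per_turn=units_per_turn,
                   handedness=handedness)


def symmetry_convert(pitch: float, units_per_turn: float,
                     handedness: Handedness = "left") -> tuple[float, float]:
    """Convert (pitch, units per turn) to (rise, twist in degrees)."""
    sym = HelicalSymmetry(pitch, units_per_turn, handedness)
    return sym.rise, sym.twist


def symmetry_invert(rise: float, twist: float) -> tuple[float, float]:
    """Inverse of :func:`symmetry_convert`: recover (pitch, units per turn)."""
    sym = HelicalSymmetry.from_rise_twist(rise, twist)
    return sym.pitch, sym.units_per_turn


def spacing_on_helix(r: float, pitch: float, units_per_turn: float) -> float:
    """Helix-path length per subunit: sqrt((2*pi*r)^2 + P^2) / ut.

    At r = 0 this degenerates to the rise of a straight stack.
    """
    if r < 0:
        raise ValueError(f"radius must be non-negative, got {r!r}")
    _check_positive(pitch=pitch, units_per_turn=units_per_turn)
    return math.hypot(2.0 * math.pi * r, pitch) / units_per_turn


def units_from_diameter(
    diameter_nm: float,
    reference: tuple[float, float] = (35.6, 92.93),
    sigma_nm: float | None = None,
    mode: str = "reference",
    lateral_spacing: float = 12.07,
) -> tuple[float, int] | tuple[float, int, float]:
    """Monomers per helical turn for a vesicle of the given diameter.

    The default ``reference`` mode scales the solved polymorph
    (35.6 nm <-> 92.93 units per turn) proportionally, which reproduces the
    printed mature-vesicle counts.  ``mode='circumference'`` instead divides
    the circumference by ``lateral_spacing`` (in Angstrom).

    Rounding to integer is half-away-from-zero.  If ``sigma_nm`` is given the
    linearly propagated standard deviation of the unit count is appended.
    """
    _check_positive(diameter_nm=diameter_nm)
    d_ref, ut_ref = reference
    if mode == "reference":
        ut = ut_ref * diameter_nm / d_ref
        sigma_ut = None if sigma_nm is None else ut_ref * sigma_nm / d_ref
    elif mode == "circumference":
        ut = math.pi * diameter_nm * _NM_TO_ANG / lateral_spacing
        sigma_ut = None if sigma_nm is None else math.pi * sigma_nm * _NM_TO_ANG / lateral_spacing
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nearest = _round_half_away(ut)
    if sigma_ut is None:
        return ut, nearest
    return ut, nearest, sigma_ut


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def diameter_increment(lateral_spacing: float) -> float:
    """Diameter change per monomer added to a helical turn: spacing / pi."""
    _check_positive(lateral_spacing=lateral_spacing)
    return lateral_spacing / math.pi


@dataclass(frozen=True)
class VesicleSpec:
    """Parameters of the piecewise cylinder-plus-cone helical curve.

    The curve runs ``t_cyl`` turns at constant radius ``r_max`` and then
    ``t_cap`` turns of linearly shrinking radius, where
    ``t_cap = r_max / (pitch * sin(alpha))``.
    """

    r_max: float = 178.4
    cone_angle_alpha: float = 25.0
    t_cyl: float = 5.0
    pitch: float = 48.8
    spacing: float = 12.07
    n_omit_tip: int = 4
    handedness: Handedness = "left"

    def __post_init__(self) -> None:
        _check_positive(pitch=self.pitch, spacing=self.spacing)
        if self.r_max < 0:
            raise ValueError("r_max must be non-negative")
        if not 0.0 < self.cone_angle_alpha <= 90.0:
            raise ValueError("cone angle alpha must be in (0, 90] degrees")
        if self.t_cyl < 0:
            raise ValueError("t_cyl must be non-negative")
        if self.n_omit_tip < 0:
            raise ValueError("n_omit_tip must be non-negative")

    @property
    def t_cap(self) -> float:
        return self.r_max / (self.pitch * math.sin(math.radians(self.cone_angle_alpha)))

    @property
    def t_end(self) -> float:
        return self.t_cyl + self.t_cap

    @property
    def y_sign(self) -> float:
        # the minus sign in y(t) encodes left-handedness
        return -1.0 if self.handedness == "left" else 1.0


def cap_turns(spec: VesicleSpec) -> float:
    """Number of helical turns in the conical cap: r_max / (P sin alpha)."""
    return spec.t_cap


@dataclass(frozen=True)
class CurvePoint:
    """A point on the parametric shell curve at parameter ``t`` (turns)."""

    t: float
    position: np.ndarray = field(repr=False)
    radius: float
    local_helix_angle: float


def _radius(t: float, spec: VesicleSpec) -> float:
    if t < spec.t_cyl:
        return spec.r_max
    return spec.r_max * (1.0 - (t - spec.t_cyl) / spec.t_cap)


def curve_point(t: float, spec: VesicleSpec) -> CurvePoint:
    """Evaluate the piecewise parametric curve at ``t`` turns.

    x(t) = r(t) cos(2 pi t);  y(t) = -r(t) sin(2 pi t)  (left-handed);
    z(t) = P t on the cylinder, P t_cyl + P cos(alpha) (t - t_cyl) on the cone.
    """
    if not (0.0 <= t <= spec.t_end + 1e-12):
        raise ValueError(f"t={t} outside curve domain [0, {spec.t_end}]")
    t = min(t, spec.t_end)
    r = max(_radius(t, spec), 0.0)
    phi = 2.0 * math.pi * t
    x = r * math.cos(phi)
    y = spec.y_sign * r * math.sin(phi)
    alpha = math.radians(spec.cone_angle_alpha)
    if t < spec.t_cyl:
        z = spec.pitch * t
        dz = spec.pitch
    else:
        z = spec.pitch * spec.t_cyl + spec.pitch * math.cos(alpha) * (t - spec.t_cyl)
        dz = spec.pitch * math.cos(alpha)
    # climb angle of the tangent relative to the circumferential direction
    angle = math.degrees(math.atan2(dz, 2.0 * math.pi * r)) if r > 0 else 90.0
    return CurvePoint(t=t, position=np.array([x, y, z]), radius=r, local_helix_angle=angle)


def curve_velocity(t: float, spec: VesicleSpec) -> np.ndarray:
    """d(position)/dt of the parametric curve (one-sided at the seam)."""
    if not (0.0 <= t <= spec.t_end + 1e-12):
        raise ValueError(f"t={t} outside curve domain [0, {spec.t_end}]")
    t = min(t, spec.t_end)
    r = max(_radius(t, spec), 0.0)
    phi = 2.0 * math.pi * t
    alpha = math.radians(spec.cone_angle_alpha)
    if t < spec.t_cyl:
        dr = 0.0
        dz = spec.pitch
    else:
        dr = -spec.r_max / spec.t_cap
        dz = spec.pitch * math.cos(alpha)
    two_pi = 2.0 * math.pi
    dx = dr * math.cos(phi) - r * two_pi * math.sin(phi)
    dy = spec.y_sign * (dr * math.sin(phi) + r * two_pi * math.cos(phi))
    return np.array([dx, dy, dz])


def _speed(t: float, spec: VesicleSpec) -> float:
    r = max(_radius(t, spec), 0.0)
    alpha = math.radians(spec.cone_angle_alpha)
    if t < spec.t_cyl:
        return math.hypot(2.0 * math.pi * r, spec.pitch)
    dr = spec.r_max / spec.t_cap
    dz = spec.pitch * math.cos(alpha)
    return math.sqrt((2.0 * math.pi * r) ** 2 + dz * dz + dr * dr)


def arc_length(spec: VesicleSpec, t0: float, t1: float) -> float:
    """Arc length of the curve between parameters ``t0`` and ``t1`` (turns).

    Adaptive quadrature split at the cylinder/cone seam, relative tolerance
    better than 1e-9.
    """
    if t1 < t0:
        raise ValueError(f"reversed interval: t0={t0} > t1={t1}")
    for t in (t0, t1):
        if not (0.0 <= t <= spec.t_end + 1e-12):
            raise ValueError(f"t={t} outside curve domain [0, {spec.t_end}]")
    if t0 == t1:
        return 0.0
    total = 0.0
    breaks = sorted({t0, t1, min(max(spec.t_cyl, t0), t1)})
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b > a:
            val, _ = quad(_speed, a, b, args=(spec,), epsrel=1e-12, epsabs=1e-12, limit=200)
            total += val
    return total


def t_at_arc_length(spec: VesicleSpec, s: float) -> float:
    """Invert arc length: the parameter t at which arc(0, t) == s.

    Bisection refined to 1e-10 turns.
    """
    total = arc_length(spec, 0.0, spec.t_end)
    if not 0.0 <= s <= total * (1 + 1e-12):
        raise ValueError(f"arc length {s} outside [0, {total}]")
    if s == 0.0:
        return 0.0
    if s >= total:
        return spec.t_end
    return brentq(lambda t: arc_length(spec, 0.0, t) - s, 0.0, spec.t_end, xtol=1e-10)


def rib_hbond_angle(hairpin_tilt: float) -> float:
    """Angle of inter-strand backbone H-bonds to the cylinder axis.

    H-bonds run perpendicular to the strand direction, so a strand tilted by
    ``hairpin_tilt`` degrees from the long axis puts them at 90 - |tilt|.
    """
    if abs(hairpin_tilt) > 90.0:
        raise ValueError("hairpin tilt must satisfy |tilt| <= 90 degrees")
    return 90.0 - abs(hairpin_tilt)


def magic_angle() -> float:
    """arctan(sqrt(2)) in degrees: equal transverse and longitudinal wall stress."""
    return math.degrees(math.atan(math.sqrt(2.0)))


@dataclass(frozen=True)
class GvpCGeometry:
    repeat_span: float
    tetrad_span: float
    repeat_phase: float
    outer_spacing: float
    monomers_bound: int


def gvpc_geometry(
    n_res: int = 33,
    rise_per_res: float = 1.5,
    inner_spacing: float = 12.1,
    r_inner: float = 1.0,
    r_binding: float = 1.0,
    monomers_per_repeat: int = 4,
    n_repeats: int = 5,
) -> GvpCGeometry:
    """Span/phase arithmetic for an all-helical accessory-protein repeat.

    ``repeat_span``: axial span of one perfectly alpha-helical repeat.
    ``outer_spacing``: lateral monomer spacing scaled radially outward from
    ``r_inner`` to the binding radius ``r_binding``.
    ``repeat_phase``: relative rotation of consecutive repeats assuming
    100 degrees per residue, modulo full turns.
    """
    _check_positive(n_res=n_res, rise_per_res=rise_per_res, inner_spacing=inner_spacing,
                    r_inner=r_inner, r_binding=r_binding,
                    monomers_per_repeat=monomers_per_repeat, n_repeats=n_repeats)
    if r_binding < r_inner:
        raise ValueError("binding radius must be >= inner radius")
    repeat_span = n_res * rise_per_res
    outer_spacing = inner_spacing * r_binding / r_inner
    tetrad_span = monomers_per_repeat * outer_spacing
    repeat_phase = (100.0 * n_res) % 360.0
    monomers_bound = n_repeats * monomers_per_repeat
    return GvpCGeometry(repeat_span=repeat_span, tetrad_span=tetrad_span,
                        repeat_phase=repeat_phase, outer_spacing=outer_spacing,
                        monomers_bound=monomers_bound)
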