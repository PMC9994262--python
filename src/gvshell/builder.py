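"""Pseudo-atomic shell construction.

A monomer template is replicated along the parametric cylinder-plus-cone
curve of :mod:`gvshell.geometry`: points are laid down at a fixed arc-length
spacing, each monomer is transported there by a rigid frame, four optional
correction rotations about landmark atoms adapt monomers to the shrinking
cone, and a complete vesicle is obtained by duplicating the half shell with
a 180-degree rotation about the two-fold (D1) x-axis.

Landmark conventions (residue-indexed, backbone atom names):

* pivot          — midpoint of the carbonyl O of residues 28 and 42
* hairpin plane  — least-squares plane through CA of residues 23..49
* sheet plane    — least-squares plane through CB of residues 24..33
* hinge axis     — line from CA 23 to CA 49
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import geometry
from .geometry import VesicleSpec, curve_point, curve_velocity
from .structure_io import (ATOMIC_MASS, atom_array_from_arrays,
                           read_structure_file, write_structure_file)

__all__ = [
    "MonomerTemplate",
    "CorrectionSchedule",
    "Placement",
    "ShellModel",
    "LandmarkError",
    "load_monomer",
    "align_curve_to_pivot",
    "generate_placements",
    "local_frame",
    "apply_correction",
    "build_half_shell",
    "duplicate_d1",
    "helical_expand",
    "clash_report",
    "model_mass",
    "write_structure",
    "chain_label",
]

HAIRPIN_RANGE = (23, 49)
SHEET_CB_RANGE = (24, 33)
NTERM_RANGE = (2, 23)
PIVOT_RESIDUES = (28, 42)
TILT_PIVOT_RESIDUE = 36

CORRECTION_NAMES = ("helixangle", "monomer_tilt", "beta_tilt", "nterm_tilt")


class LandmarkError(ValueError):
    """A required landmark atom is missing from a monomer template."""


@dataclass(frozen=True)
class MonomerTemplate:
    """Atom records of a single wall monomer plus landmark lookups."""

    atom_names: np.ndarray
    res_ids: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("template contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom_index(self, atom_name: str, res_id: int) -> int:
        mask = (self.atom_names == atom_name) & (self.res_ids == res_id)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise LandmarkError(f"missing landmark atom {atom_name} {res_id}")
        return int(idx[0])

    def atom_coord(self, atom_name: str, res_id: int) -> np.ndarray:
        return self.coords[self.atom_index(atom_name, res_id)]

    @property
    def pivot(self) -> np.ndarray:
        a, b = PIVOT_RESIDUES
        return 0.5 * (self.atom_coord("O", a) + self.atom_coord("O", b))

    def missing_landmarks(self) -> list[str]:
        missing: list[str] = []
        for res in PIVOT_RESIDUES + (TILT_PIVOT_RESIDUE,):
            if not self._has("O", res):
                missing.append(f"O {res}")
        for res in range(HAIRPIN_RANGE[0], HAIRPIN_RANGE[1] + 1):
            if not self._has("CA", res):
                missing.append(f"CA {res}")
        for res in range(SHEET_CB_RANGE[0], SHEET_CB_RANGE[1] + 1):
            if not self._has("CB", res):
                missing.append(f"CB {res}")
        for res in range(NTERM_RANGE[0], NTERM_RANGE[1] + 1):
            if not np.any(self.res_ids == res):
                missing.append(f"any-atom {res}")
        return missing

    def _has(self, atom_name: str, res_id: int) -> bool:
        return bool(np.any((self.atom_names == atom_name) & (self.res_ids == res_id)))

    def validate(self) -> None:
        missing = self.missing_landmarks()
        if missing:
            raise LandmarkError("template lacks required landmark atoms: "
                                + ", ".join(missing))

    @property
    def mass(self) -> float:
        """Sum of per-element masses in Da (pseudo-atom level)."""
        return float(sum(ATOMIC_MASS.get(el.upper(), 0.0) for el in self.elements))

    def with_coords(self, coords: np.ndarray) -> "MonomerTemplate":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MonomerTemplate":
        return self.with_coords(self.coords @ np.asarray(rotation).T + translation)

    def to_atom_array(self, chain_id: str = "A"):
        return atom_array_from_arrays(self.coords, self.atom_names, self.res_ids,
                                      self.elements, chain_id=chain_id,
                                      occupancy=self.occupancy)

    @classmethod
    def from_atom_array(cls, atoms) -> "MonomerTemplate":
        return cls(
            atom_names=np.asarray(atoms.atom_name),
            res_ids=np.asarray(atoms.res_id, dtype=int),
            elements=np.asarray(atoms.element),
            coords=np.asarray(atoms.coord, dtype=float),
            occupancy=np.asarray(atoms.get_annotation("occupancy"), dtype=float)
            if "occupancy" in atoms.get_annotation_categories()
            else np.ones(atoms.array_length()),
        )


def load_monomer(path: str | PathLike, chain: str | None = None) -> MonomerTemplate:
    """Load and landmark-validate a monomer from a PDB/mmCIF file."""
    atoms = read_structure_file(path)
    if chain is not None:
        atoms = atoms[atoms.chain_id == chain]
    else:
        first = atoms.chain_id[0]
        atoms = atoms[atoms.chain_id == first]
    template = MonomerTemplate.from_atom_array(atoms)
    template.validate()
    return template


# ---------------------------------------------------------------------------
# correction rotations


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points``.

    Sign fixed deterministically: the first component of largest magnitude
    is made positive.  Raises for (near-)collinear input.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate plane fit: landmark atoms are collinear")
    normal = vt[2]
    lead = np.argmax(np.abs(normal))
    if normal[lead] < 0:
        normal = -normal
    return normal


def _rotate_about(coords: np.ndarray, center: np.ndarray, axis: np.ndarray,
                  angle_deg: float, mask: np.ndarray | None = None) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    out = coords.copy()
    sel = slice(None) if mask is None else mask
    out[sel] = rot.apply(coords[sel] - center) + center
    return out


def apply_correction(template: MonomerTemplate, which: str,
                     angle_deg: float) -> MonomerTemplate:
    """Apply one of the four landmark-pivot correction rotations.

    ``helixangle`` and ``monomer_tilt`` rotate the whole monomer;
    ``beta_tilt`` moves only residues 23-49 and ``nterm_tilt`` only 2-23
    (both hinging about the CA23-CA49 line).
    """
    if not np.isfinite(angle_deg):
        raise ValueError("correction angle must be finite")
    if which not in CORRECTION_NAMES:
        raise ValueError(f"unknown correction {which!r}; expected one of {CORRECTION_NAMES}")
    if angle_deg == 0.0:
        return template
    if which == "helixangle":
        center = template.pivot
        ca = np.array([template.atom_coord("CA", r)
                       for r in range(HAIRPIN_RANGE[0], HAIRPIN_RANGE[1] + 1)])
        axis = _fit_plane_normal(ca)
        mask = None
    elif which == "monomer_tilt":
        center = template.atom_coord("O", TILT_PIVOT_RESIDUE)
        cb = np.array([template.atom_coord("CB", r)
                       for r in range(SHEET_CB_RANGE[0], SHEET_CB_RANGE[1] + 1)])
        axis = _fit_plane_normal(cb)
        mask = None
    else:
        a = template.atom_coord("CA", HAIRPIN_RANGE[0])
        b = template.atom_coord("CA", HAIRPIN_RANGE[1])
        center = a
        axis = b - a
        if which == "beta_tilt":
            mask = (template.res_ids >= HAIRPIN_RANGE[0]) & (template.res_ids <= HAIRPIN_RANGE[1])
        else:
            mask = (template.res_ids >= NTERM_RANGE[0]) & (template.res_ids <= NTERM_RANGE[1])
    return template.with_coords(_rotate_about(template.coords, center, axis,
                                              angle_deg, mask))


@dataclass(frozen=True)
class CorrectionSchedule:
    """Per-monomer correction angles as piecewise-linear functions of t.

    All four corrections vanish in the cylinder.  Across the cone the three
    manually set parameters ramp linearly from zero to their ``*_cone`` value
    at the tip-region boundary and on to ``*_tip`` at the very tip; the
    helix-angle correction is computed analytically from the curve
    (difference between the local and the cylindrical helix angle), never
    tuned.
    """

    monomer_tilt_cone: float = 0.0
    monomer_tilt_tip: float | None = None
    beta_tilt_cone: float = 0.0
    beta_tilt_tip: float | None = None
    nterm_tilt_cone: float = 0.0
    nterm_tilt_tip: float | None = None
    tip_fraction: float = 0.15
    helixangle_analytic: bool = True

    @classmethod
    def zero(cls) -> "CorrectionSchedule":
        return cls(helixangle_analytic=False)

    def _ramp(self, t: float, spec: VesicleSpec, cone_value: float,
              tip_value: float | None) -> float:
        if t < spec.t_cyl or spec.t_cap <= 0:
            return 0.0
        t_tip = spec.t_cyl + (1.0 - self.tip_fraction) * spec.t_cap
        if t <= t_tip:
            frac = (t - spec.t_cyl) / (t_tip - spec.t_cyl) if t_tip > spec.t_cyl else 1.0
            return cone_value * frac
        if tip_value is None:
            tip_value = cone_value
        frac = (t - t_tip) / (spec.t_end - t_tip)
        return cone_value + (tip_value - cone_value) * frac

    def values(self, t: float, spec: VesicleSpec) -> dict[str, float]:
        helix = 0.0
        if self.helixangle_analytic and t >= spec.t_cyl:
            ref = math.degrees(math.atan2(spec.pitch, 2.0 * math.pi * spec.r_max))
            helix = curve_point(t, spec).local_helix_angle - ref
        return {
            "helixangle": helix,
            "monomer_tilt": self._ramp(t, spec, self.monomer_tilt_cone, self.monomer_tilt_tip),
            "beta_tilt": self._ramp(t, spec, self.beta_tilt_cone, self.beta_tilt_tip),
            "nterm_tilt": self._ramp(t, spec, self.nterm_tilt_cone, self.nterm_tilt_tip),
        }


# ---------------------------------------------------------------------------
# placement


def align_curve_to_pivot(template: MonomerTemplate, spec: VesicleSpec,
                         allow_radial_shift: bool = True,
                         radial_tol: float = 1e-6,
                         ) -> tuple[MonomerTemplate, dict[str, float]]:
    """Seat the seed monomer so its pivot lies on the curve start.

    Equivalent to the published adjustment of the curve phase (z-shift plus
    z-rotation) expressed as the inverse transform on the monomer: the pivot
    is brought to azimuth 0 and z = 0.  A residual radial mismatch between
    pivot radius and ``r_max`` cannot be removed by those two degrees of
    freedom; it is corrected by a radial shift when ``allow_radial_shift``
    or rejected otherwise.
    """
    pivot = template.pivot
    azimuth = math.degrees(math.atan2(pivot[1], pivot[0]))
    z_shift = -pivot[2]
    rot = Rotation.from_euler("z", -azimuth, degrees=True)
    coords = rot.apply(template.coords)
    coords[:, 2] += z_shift
    radius = math.hypot(pivot[0], pivot[1])
    radial_shift = spec.r_max - radius
    if abs(radial_shift) > radial_tol:
        if not allow_radial_shift:
            raise ValueError(
                f"pivot radius {radius:.3f} differs from r_max {spec.r_max:.3f}; "
                "a z-shift and z-rotation alone cannot seat the monomer")
        coords[:, 0] += radial_shift
    report = {"z_rotation": -azimuth, "z_shift": z_shift, "radial_shift": radial_shift}
    return template.with_coords(coords), report


def generate_placements(spec: VesicleSpec) -> np.ndarray:
    """Curve parameters t of all placed monomers on a half shell.

    Points start at t = 0 with consecutive arc-length separations equal to
    ``spec.spacing``.  Each monomer claims one full spacing of arc, so the
    number of points is floor(total length / spacing); the last
    ``spec.n_omit_tip`` points toward the tip are then dropped.
    """
    total = geometry.arc_length(spec, 0.0, spec.t_end)
    n_points = int(math.floor(total / spec.spacing))
    if n_points < 1:
        raise ValueError(
            f"spacing {spec.spacing} exceeds total curve length {total:.3f}")
    ts = np.empty(n_points)
    ts[0] = 0.0
    t_prev = 0.0
    for k in range(1, n_points):
        # Newton from the previous point; the local speed makes this converge
        # in a few iterations to well below 1e-10 turns
        t = t_prev + spec.spacing / geometry._speed(t_prev, spec)
        t = min(t, spec.t_end)
        for _ in range(60):
            f = geometry.arc_length(spec, t_prev, t) - spec.spacing
            if abs(f) < 1e-10:
                break
            t = min(max(t - f / geometry._speed(t, spec), t_prev), spec.t_end)
        ts[k] = t_prev = t
    if spec.n_omit_tip:
        ts = ts[: n_points - spec.n_omit_tip]
    if len(ts) == 0:
        raise ValueError("all placements were omitted by n_omit_tip")
    return ts


def local_frame(t: float, spec: VesicleSpec) -> tuple[np.ndarray, np.ndarray, bool]:
    """Orthonormal frame at curve parameter t.

    Returns ``(Q, origin, at_tip)`` where the columns of Q are the
    outward-radial, binormal and tangent unit vectors (Gram-Schmidt
    orthogonalized, right-handed).  At the tip singularity (radius -> 0) the
    radial direction is taken from the azimuth limit and flagged.
    """
    point = curve_point(t, spec)
    velocity = curve_velocity(t, spec)
    tangent = velocity / np.linalg.norm(velocity)
    at_tip = point.radius < 1e-9
    phi = 2.0 * math.pi * t
    radial = np.array([math.cos(phi), spec.y_sign * math.sin(phi), 0.0])
    radial = radial - np.dot(radial, tangent) * tangent
    norm = np.linalg.norm(radial)
    if norm < 1e-12:
        raise ValueError(f"degenerate frame at t={t}")
    radial /= norm
    binormal = np.cross(tangent, radial)
    q = np.column_stack([radial, binormal, tangent])
    return q, point.position, at_tip


@dataclass(frozen=True)
class Placement:
    t: float
    rotation: np.ndarray = field(repr=False)
    translation: np.ndarray = field(repr=False)
    corrections: dict = field(default_factory=dict)
    chain_id: str = "A"


@dataclass
class ShellModel:
    """Placed monomer instances forming a half or complete vesicle."""

    placements: list[Placement]
    template: MonomerTemplate
    spec: VesicleSpec | None = None
    is_full: bool = False

    @property
    def n_monomers(self) -> int:
        return len(self.placements)

    def monomer_coords(self, placement: Placement) -> np.ndarray:
        tpl = self.template
        for name in CORRECTION_NAMES:
            angle = placement.corrections.get(name, 0.0)
            if angle:
                tpl = apply_correction(tpl, name, angle)
        return tpl.coords @ placement.rotation.T + placement.translation

    def pivot_positions(self) -> np.ndarray:
        pivot = self.template.pivot
        return np.array([p.rotation @ pivot + p.translation for p in self.placements])

    def all_coords(self) -> np.ndarray:
        return np.concatenate([self.monomer_coords(p) for p in self.placements])

    def to_atom_array(self):
        import biotite.structure as struc

        arrays = []
        for placement in self.placements:
            arr = self.template.to_atom_array(chain_id=placement.chain_id)
            arr.coord = self.monomer_coords(placement).astype(np.float32)
            arrays.append(arr)
        out = arrays[0]
        for arr in arrays[1:]:
            out += arr
        return out

    def placement_table(self):
        import pandas as pd

        pivot = self.template.pivot
        rows = []
        for i, p in enumerate(self.placements):
            pos = p.rotation @ pivot + p.translation
            row = {"index": i, "chain": p.chain_id, "t": p.t,
                   "x": pos[0], "y": pos[1], "z": pos[2]}
            for name in CORRECTION_NAMES:
                row[name] = p.corrections.get(name, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def chain_label(index: int, prefix: str = "") -> str:
    """Deterministic base-26 chain identifier: A..Z, AA..AZ, ..."""
    letters = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        letters = string.ascii_uppercase[rem] + letters
    return prefix + letters


def build_half_shell(template: MonomerTemplate, spec: VesicleSpec,
                     schedule: CorrectionSchedule | None = None,
                     align: bool = True) -> ShellModel:
    """Place one corrected monomer copy at every curve point of a half shell."""
    template.validate()
    if schedule is None:
        schedule = CorrectionSchedule()
    if align:
        template, _ = align_curve_to_pivot(template, spec)
    ts = generate_placements(spec)
    q0, p0, _ = local_frame(0.0, spec)
    placements = []
    for k, t in enumerate(ts):
        q, p, _ = local_frame(float(t), spec)
        rotation = q @ q0.T
        translation = p - rotation @ p0
        placements.append(Placement(
            t=float(t), rotation=rotation, translation=translation,
            corrections=schedule.values(float(t), spec),
            chain_id=chain_label(k),
        ))
    return ShellModel(placements=placements, template=template, spec=spec)


def duplicate_d1(half: ShellModel, prefix: str = "x") -> ShellModel:
    """Complete the vesicle: add a copy rotated 180 degrees about the x axis."""
    if half.is_full:
        raise ValueError("model is already a complete (duplicated) vesicle")
    rx = np.diag([1.0, -1.0, -1.0])
    mirrored = [Placement(t=p.t, rotation=rx @ p.rotation,
                          translation=rx @ p.translation,
                          corrections=dict(p.corrections),
                          chain_id=prefix + p.chain_id)
                for p in half.placements]
    return ShellModel(placements=half.placements + mirrored,
                      template=half.template, spec=half.spec, is_full=True)


def helical_expand(template: MonomerTemplate, rise: float, twist: float,
                   n: int, per_rib: int | None = None) -> ShellModel:
    """Expand a seed monomer by an iterated screw operation about z.

    ``per_rib`` only affects chain labelling (rib-major grouping of the
    15-subunit style segments); geometry is the pure screw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    placements = []
    for k in range(n):
        rot = Rotation.from_euler("z", k * twist, degrees=True).as_matrix()
        placements.append(Placement(
            t=float(k), rotation=rot,
            translation=np.array([0.0, 0.0, k * rise]),
            corrections={}, chain_id=chain_label(k)))
    return ShellModel(placements=placements, template=template, spec=None)


def clash_report(model: ShellModel, cutoff: float = 2.0,
                 atom_names: Sequence[str] | None = ("N", "CA", "C", "O", "CB"),
                 ) -> list[tuple[str, str, str, str, float]]:
    """Inter-chain atom pairs closer than ``cutoff`` Angstrom.

    Uses a k-d tree (spatial binning; no full O(N^2) scan).  Entries are
    ``(chain_a, chain_b, atom_a, atom_b, distance)`` in deterministic order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if model.n_monomers == 0:
        return []
    if atom_names is not None:
        mask = np.isin(model.template.atom_names, list(atom_names))
    else:
        mask = np.ones(model.template.n_atoms, dtype=bool)
    labels = []
    coords = []
    for placement in model.placements:
        coords.append(model.monomer_coords(placement)[mask])
        names = model.template.atom_names[mask]
        res = model.template.res_ids[mask]
        labels.extend((placement.chain_id, f"{nm}:{ri}") for nm, ri in zip(names, res))
    coords = np.concatenate(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    report = []
    for i, j in pairs:
        ci, ai = labels[i]
        cj, aj = labels[j]
        if ci == cj:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        entry = (ci, cj, ai, aj, d) if (ci, ai) <= (cj, aj) else (cj, ci, aj, ai, d)
        report.append(entry)
    report.sort()
    return report


def model_mass(model: ShellModel, per_monomer_mass: float | None = None) -> float:
    """Total mass in Da: monomer count times per-monomer mass."""
    if per_monomer_mass is None:
        per_monomer_mass = model.template.mass
        if per_monomer_mass <= 0:
            raise ValueError("template has no atom masses; pass per_monomer_mass")
    return model.n_monomers * per_monomer_mass


def write_structure(model: ShellModel, path: str | PathLike,
                    fmt: str | None = None) -> None:
    """Export a shell model as mmCIF (any size) or PDB (within format limits)."""
    if model.n_monomers == 0:
        raise ValueError("refusing to write an empty model")
    write_structure_file(model.to_atom_array(), path, fmt=fmt)
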