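"""Synthetic ground-truth inputs for every stage of the pipeline.

Generators here are first-class, deterministic-by-seed code: a toy
backbone-level wall monomer carrying every landmark atom the builder's
correction rotations reference, noisy sigmoid collapse curves, projected
cylinder/helical-lattice images, and analytic pore scenes with known
bottlenecks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .builder import MonomerTemplate
from .collapse import CollapseCurve, sigmoid
from .pore import PoreScene
from .projection import ProjectionImage

__all__ = [
    "ToyMonomerSpec",
    "make_toy_monomer",
    "make_collapse_curve",
    "make_cylinder_image",
    "make_lattice_image",
    "make_slit_scene",
    "slit_scene_analytic_bottleneck",
]


@dataclass(frozen=True)
class ToyMonomerSpec:
    """Layout of the idealized coil-helix-hairpin-helix wall monomer."""

    first_res: int = 1
    last_res: int = 66
    arm_end: int = 7          # N-arm: first_res .. arm_end
    helix1: tuple[int, int] = (8, 22)
    hairpin: tuple[int, int] = (23, 49)
    turn_res: int = 36
    helix2: tuple[int, int] = (50, 66)
    hairpin_tilt: float = -36.0  # degrees, relative to the cylinder axis
    seat_radius: float = 178.4   # pivot distance from the z axis
    strand_rise: float = 3.5     # Angstrom per strand residue
    strand_sep: float = 4.7      # inter-strand distance
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        order = (self.first_res, self.arm_end, self.helix1[0], self.helix1[1],
                 self.hairpin[0], self.turn_res, self.hairpin[1],
                 self.helix2[0], self.helix2[1])
        if any(b <= a for a, b in zip(order[:-1], order[1:])) \
                or self.last_res < self.helix2[1]:
            raise ValueError(f"invalid region boundaries: {order}")
        if abs(self.hairpin_tilt) > 90:
            raise ValueError("hairpin tilt must be within +-90 degrees")


def _helix_trace(n: int, rise: float = 1.5, radius: float = 2.3,
                 phase0: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix CA trace along the local long axis (w)."""
    i = np.arange(n)
    phase = np.radians(phase0 + 100.0 * i)
    return np.column_stack([radius * np.cos(phase), radius * np.sin(phase), rise * i])


def make_toy_monomer(spec: ToyMonomerSpec | None = None) -> MonomerTemplate:
    """Deterministic backbone-level (CA/CB/O) pseudo-monomer.

    Built in a local frame (u = lateral, v = out-of-sheet, w = hairpin long
    axis), then rotated so the hairpin axis makes ``hairpin_tilt`` degrees
    with the global z axis with the sheet facing outward (+x), and seated
    with its pivot (midpoint of carbonyl O 28/42) at (seat_radius, 0, 0) —
    the canonical seed pose of the shell builder.
    """
    if spec is None:
        spec = ToyMonomerSpec()
    names: list[str] = []
    res_ids: list[int] = []
    coords: list[np.ndarray] = []

    def add(name: str, res: int, xyz) -> None:
        names.append(name)
        res_ids.append(res)
        coords.append(np.asarray(xyz, float))

    h23, h49 = spec.hairpin
    n_strand1 = spec.turn_res - 1 - h23  # residues h23 .. turn-1
    half = 0.5 * n_strand1 * spec.strand_rise

    # strand 1: res 23 .. 35 descending in w at u = 0
    for j, res in enumerate(range(h23, spec.turn_res)):
        w = half - j * spec.strand_rise
        add("CA", res, (0.0, 0.0, w))
        add("O", res, (0.0, 1.2 * (-1) ** j, w + 0.6))
        if res > h23:
            add("CB", res, (-0.8, 1.3 * (-1) ** j, w))
    # beta turn at the hairpin tip
    add("CA", spec.turn_res, (0.5 * spec.strand_sep, 0.5, -half - 2.2))
    add("O", spec.turn_res, (0.5 * spec.strand_sep, 1.7, -half - 2.6))
    # strand 2: res 37 .. 49 ascending in w at u = strand_sep
    for j, res in enumerate(range(spec.turn_res + 1, h49 + 1)):
        w = -half + j * spec.strand_rise
        add("CA", res, (spec.strand_sep, 0.0, w))
        add("O", res, (spec.strand_sep, -1.2 * (-1) ** j, w - 0.6))
        if res < h49:
            add("CB", res, (spec.strand_sep + 0.8, -1.3 * (-1) ** j, w))

    # helix 1 (res 8..22) alongside strand 1
    n_h1 = spec.helix1[1] - spec.helix1[0] + 1
    trace1 = _helix_trace(n_h1)
    trace1 = trace1[:, [0, 1, 2]] * np.array([0.6, 1.0, 1.0])
    trace1 += np.array([-5.0, 0.0, half - 1.5 * (n_h1 - 1) - 4.0])
    for j, res in enumerate(range(spec.helix1[0], spec.helix1[1] + 1)):
        add("CA", res, trace1[j])
        add("O", res, trace1[j] + (0.0, 1.1, 0.5))
    # N-terminal arm (res 1..7) extended below helix 1
    for j, res in enumerate(range(spec.first_res, spec.arm_end + 1)):
        add("CA", res, (-5.0 - 0.4 * j, 0.8, trace1[0][2] - 3.4 * (spec.arm_end + 1 - res)))
        add("O", res, (-5.0 - 0.4 * j, 2.0, trace1[0][2] - 3.4 * (spec.arm_end + 1 - res) + 0.5))
    # helix 2 (res 50..66) on the far side of the sheet
    n_h2 = spec.helix2[1] - spec.helix2[0] + 1
    trace2 = _helix_trace(n_h2, phase0=40.0) * np.array([0.6, 1.0, -1.0])
    trace2 += np.array([spec.strand_sep + 4.5, 0.0, half + 2.0])
    for j, res in enumerate(range(spec.helix2[0], spec.helix2[1] + 1)):
        add("CA", res, trace2[j])
        add("O", res, trace2[j] + (0.0, -1.1, -0.5))

    xyz = np.array(coords)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        xyz = xyz + rng.normal(0.0, spec.jitter, xyz.shape)

    # local -> global: v -> +x (outward), u/w tilted by hairpin_tilt about x
    theta = math.radians(spec.hairpin_tilt)
    u_g = np.array([0.0, math.cos(theta), math.sin(theta)])
    v_g = np.array([1.0, 0.0, 0.0])
    w_g = np.array([0.0, -math.sin(theta), math.cos(theta)])
    rot = np.column_stack([u_g, v_g, w_g])
    xyz = xyz @ rot.T

    template = MonomerTemplate(
        atom_names=np.array(names), res_ids=np.array(res_ids, int),
        elements=np.array(["O" if n == "O" else "C" for n in names]),
        coords=xyz, occupancy=np.ones(len(names)))
    # seat the pivot on the curve start
    xyz = xyz + (np.array([spec.seat_radius, 0.0, 0.0]) - template.pivot)
    template = template.with_coords(xyz)
    template.validate()
    return template


def make_collapse_curve(p0: float, k: float, noise_sd: float = 0.0,
                        p_min: float = 0.0, p_max: float = 10.0,
                        step: float = 0.5, n_replicates: int = 1,
                        seed: int = 0) -> list[CollapseCurve]:
    """Noisy logistic collapse curves on a regular pressure grid."""
    if k <= 0:
        raise ValueError("k must be positive")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    pressures = np.arange(p_min, p_max + step / 2, step)
    curves = []
    for rep in range(n_replicates):
        od = sigmoid(pressures, p0, k)
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, od.shape)
        od = np.clip(od, 0.0, None)
        curves.append(CollapseCurve(pressures, od, replicate=rep))
    return curves


def make_cylinder_image(diameter: float, length: float = 600.0,
                        pixel: float = 2.0, blur_sigma: float = 3.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        n_samples: int = 200_000) -> ProjectionImage:
    """Side-view projection of a hollow cylinder shell of known diameter.

    The ground-truth rim-to-rim distance equals ``diameter``; noise is
    additive Gaussian with ``noise_sd`` given as a fraction of the rim peak.
    """
    if diameter <= 0 or length <= 0:
        raise ValueError("diameter and length must be positive")
    rng = np.random.default_rng(seed)
    radius = diameter / 2.0
    margin = 6.0 * blur_sigma + 10.0
    n_cols = int(round((diameter + 2 * margin) / pixel))
    n_rows = int(round(length / pixel))
    theta = (np.arange(n_samples) + 0.5) / n_samples * 2.0 * np.pi
    u = radius * np.cos(theta)
    edges = (np.arange(n_cols + 1) - n_cols / 2.0) * pixel
    hist, _ = np.histogram(u, bins=edges)
    row = hist.astype(float) / n_samples
    data = np.tile(row, (n_rows, 1))
    if blur_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=blur_sigma / pixel,
                                       mode="constant", truncate=6.0)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd * data.max(), data.shape)
    return ProjectionImage(data=data, pixel_size=pixel)


def rim_calibration(pixel: float = 2.0, blur_sigma: float = 3.0,
                    diameters=(340.0, 348.0, 356.0, 364.0, 372.0)) -> float:
    """Mean offset (true diameter - measured rim distance) at these imaging
    parameters.

    The peak-to-peak rim distance of a projected shell is systematically
    pulled inward by the asymmetric density shoulder inside the rim; this
    calibrates the offset on noiseless synthetic cylinders so measured rim
    distances can be corrected before polymorph assignment.
    """
    from .projection import width_profile

    offsets = []
    for d in diameters:
        image = make_cylinder_image(d, pixel=pixel, blur_sigma=blur_sigma)
        offsets.append(d - width_profile(image).rim_distance)
    return float(np.mean(offsets))


def make_lattice_image(pitch: float = 48.8, units_per_turn: float = 92.93,
                       diameter: float = 356.0, pixel: float = 2.0,
                       n_turns: float = 20.0, blur_sigma: float = 2.0,
                       noise_sd: float = 0.0, seed: int = 0) -> ProjectionImage:
    """Projection of point scatterers on a left-handed helical lattice.

    Ground truth: the first layer line of the power spectrum sits at
    ``1 / pitch``.
    """
    if pitch <= 0 or units_per_turn <= 0 or diameter <= 0:
        raise ValueError("helical parameters must be positive")
    rng = np.random.default_rng(seed)
    radius = diameter / 2.0
    n = int(n_turns * units_per_turn)
    k = np.arange(n)
    z = k * pitch / units_per_turn
    phi = -2.0 * np.pi * k / units_per_turn
    u = radius * np.cos(phi)
    margin = 6.0 * blur_sigma + 10.0
    n_rows = int(round(n_turns * pitch / pixel))
    n_cols = int(round((diameter + 2 * margin) / pixel))
    row_edges = np.arange(n_rows + 1) * pixel
    col_edges = (np.arange(n_cols + 1) - n_cols / 2.0) * pixel
    data, _, _ = np.histogram2d(z, u, bins=[row_edges, col_edges])
    if blur_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=blur_sigma / pixel,
                                       mode="constant", truncate=6.0)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd * data.max(), data.shape)
    return ProjectionImage(data=data, pixel_size=pixel)


def make_slit_scene(gap: float, atom_radius: float = 1.7,
                    wall_extent: float = 8.0, wall_spacing: float = 0.6,
                    depth: float = 8.0) -> PoreScene:
    """Two coplanar atom walls separated by a slit of known clearance.

    Atoms tile the z = 0 plane except for a strip of width ``gap``
    (center-to-center between the innermost atom rows).  A path from one
    side of the plane to the other must thread the strip; the analytic
    bottleneck is ``2 * (gap/2 - atom_radius)``.  The search box is clamped
    inside the wall extent so routes cannot leak around the edges.
    """
    if gap <= 2.0 * atom_radius:
        raise ValueError(f"impassable slit: gap {gap} <= sphere diameter "
                         f"{2 * atom_radius}")
    nx = int(round(2 * wall_extent / wall_spacing))
    xs = np.linspace(-wall_extent, wall_extent, nx + 1)
    ys = gap / 2.0 + np.arange(int(round(wall_extent / wall_spacing))) * wall_spacing
    gx, gy = np.meshgrid(xs, ys)
    upper = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    lower = upper * np.array([1.0, -1.0, 1.0])
    centers = np.vstack([upper, lower])
    radii = np.full(len(centers), atom_radius)
    start = np.array([0.0, 0.0, -depth])
    end = np.array([0.0, 0.0, depth])
    pad = 1.0
    box_min = np.array([-wall_extent + pad, -(wall_extent + gap / 2) + pad, -depth - pad])
    box_max = np.array([wall_extent - pad, wall_extent + gap / 2 - pad, depth + pad])
    return PoreScene(centers, radii, start, end, box_min=box_min, box_max=box_max)


def slit_scene_analytic_bottleneck(gap: float, atom_radius: float = 1.7) -> float:
    """Ground-truth bottleneck diameter of :func:`make_slit_scene`."""
    return 2.0 * (gap / 2.0 - atom_radius)
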