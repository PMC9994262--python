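"""Projection-image analysis: width profiles, polymorph ladders, layer lines.

Image convention: row index (axis 0) runs along the helix/tube axis, column
index (axis 1) across the tube; the origin sits at the image center and the
Fourier transform is shown with zero frequency centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from . import geometry

__all__ = [
    "ProjectionImage",
    "WidthProfile",
    "LayerLineSpectrum",
    "PeakDetectionError",
    "project_density",
    "width_profile",
    "polymorph_ladder",
    "layer_line_spectrum",
    "save_png",
]


class PeakDetectionError(RuntimeError):
    """Raised when the expected rim peaks cannot be located."""


@dataclass(frozen=True)
class ProjectionImage:
    """A 2D density image with physical pixel size (Angstrom per pixel)."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, float)
        if data.ndim != 2:
            raise ValueError("projection image must be 2D")
        if not np.all(np.isfinite(data)):
            raise ValueError("projection image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class WidthProfile:
    """Across-tube intensity profile with the two rim peaks located."""

    profile: np.ndarray
    pixel_size: float
    peak_positions: np.ndarray  # Angstrom, relative to profile start
    rim_distance: float  # Angstrom, peak to peak

    def aligned(self) -> tuple[np.ndarray, np.ndarray]:
        """Profile coordinates (Angstrom) shifted so the left peak sits at 0."""
        x = np.arange(len(self.profile)) * self.pixel_size - self.peak_positions[0]
        return x, self.profile


def project_density(source, view_axis: str = "y", pixel: float = 2.0,
                    blur_sigma: float = 3.0, weights: np.ndarray | None = None,
                    pad: float | None = None) -> ProjectionImage:
    """Project atom positions onto a 2D grid of Gaussian-blurred density.

    ``source`` is an (N, 3) coordinate array or an object with
    ``all_coords()`` (e.g. a ShellModel).  Atoms are integrated along
    ``view_axis``; rows of the image run along z (the helix axis) unless the
    view is down z itself, in which case rows/columns are x/y.  The total
    integrated density equals the sum of the atom weights.
    """
    if pixel <= 0:
        raise ValueError("pixel size must be positive")
    coords = source.all_coords() if hasattr(source, "all_coords") else np.asarray(source, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("need a non-empty (N, 3) coordinate array")
    axis_index = {"x": 0, "y": 1, "z": 2}[view_axis]
    kept = [i for i in range(3) if i != axis_index]
    # rows along z where possible, so tubes stand upright in the image
    if 2 in kept:
        kept = [2] + [i for i in kept if i != 2]
    rows, cols = coords[:, kept[0]], coords[:, kept[1]]
    if weights is None:
        weights = np.ones(len(coords))
    margin = (pad if pad is not None else 6.0 * blur_sigma) + 2.0 * pixel
    row_edges = np.arange(rows.min() - margin, rows.max() + margin + pixel, pixel)
    col_edges = np.arange(cols.min() - margin, cols.max() + margin + pixel, pixel)
    hist, _, _ = np.histogram2d(rows, cols, bins=[row_edges, col_edges], weights=weights)
    if blur_sigma > 0:
        hist = ndimage.gaussian_filter(hist, sigma=blur_sigma / pixel,
                                       mode="constant", truncate=6.0)
    return ProjectionImage(data=hist, pixel_size=pixel)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom != 0:
            return i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i)


def width_profile(image: ProjectionImage, min_height_frac: float = 0.5) -> WidthProfile:
    """Mean-over-rows profile with the two dominant rim peaks.

    Peaks are local maxima above ``min_height_frac`` of the global maximum,
    refined to sub-pixel positions by parabolic interpolation; the rim
    distance is the left-to-right peak separation in Angstrom.
    """
    profile = image.data.mean(axis=0)
    span = profile.max() - profile.min()
    if span <= 0:
        raise PeakDetectionError("flat image: no rim peaks detectable")
    baseline = profile.min()
    peaks, props = find_peaks(profile - baseline, height=min_height_frac * span)
    if len(peaks) < 2:
        raise PeakDetectionError(
            f"found {len(peaks)} rim peak(s), need 2; adjust min_height_frac")
    order = np.argsort(props["peak_heights"])[::-1][:2]
    chosen = np.sort(peaks[order])
    refined = np.array([_parabolic_refine(profile, int(i)) for i in chosen])
    positions = refined * image.pixel_size
    return WidthProfile(profile=profile, pixel_size=image.pixel_size,
                        peak_positions=positions,
                        rim_distance=float(positions[1] - positions[0]))


def polymorph_ladder(rim_distance: float, lateral_spacing: float = 12.0,
                     n: int = 3, reference: tuple[float, float] = (35.6, 92.93),
                     ) -> list[tuple[float, int]]:
    """Candidate (diameter, units-per-turn) pairs around a measured width.

    Neighboring polymorphs differ by one monomer per turn, i.e. by
    ``lateral_spacing / pi`` in diameter.  ``n`` candidates are listed on
    each side of the nearest one; ``n = 0`` gives only the nearest.
    """
    if rim_distance <= 0 or lateral_spacing <= 0:
        raise ValueError("rim distance and spacing must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    step = geometry.diameter_increment(lateral_spacing)
    ut_real, nearest = geometry.units_from_diameter(rim_distance / 10.0,
                                                    reference=reference)
    ladder = []
    for units in range(nearest - n, nearest + n + 1):
        if units <= 0:
            continue
        diameter = rim_distance + (units - ut_real) * step
        ladder.append((diameter, units))
    return ladder


@dataclass(frozen=True)
class LayerLineSpectrum:
    """Cumulative in-plane-rotated power spectrum with layer-line readout."""

    power: np.ndarray = field(repr=False)
    pixel_size: float
    axial_freqs: np.ndarray = field(repr=False)
    first_layer_line: float  # Angstrom

    def meridional_profile(self) -> np.ndarray:
        """Power summed across each axial-frequency row."""
        return self.power.sum(axis=1)


def layer_line_spectrum(images: list[ProjectionImage],
                        angles: np.ndarray | None = None,
                        dc_guard: int = 2) -> LayerLineSpectrum:
    """Sum in-plane-rotated power spectra and read off the first layer line.

    Each segment is rotated by its in-plane angle (degrees) so the tube axis
    is vertical, its centered 2D power spectrum computed, and all spectra
    summed.  The first layer line is the strongest axial frequency outside a
    ``dc_guard``-bin exclusion zone around the equator; its reciprocal is
    returned in Angstrom.
    """
    if not images:
        raise ValueError("need at least one segment image")
    if angles is None:
        angles = np.zeros(len(images))
    if len(angles) != len(images):
        raise ValueError("one in-plane angle per image required")
    pixel = images[0].pixel_size
    shape = images[0].data.shape
    total = np.zeros(shape)
    for image, angle in zip(images, angles):
        if image.data.shape != shape or image.pixel_size != pixel:
            raise ValueError("all segments must share shape and pixel size")
        data = image.data
        if angle:
            data = ndimage.rotate(data, angle, reshape=False, order=1)
        spectrum = np.fft.fftshift(np.abs(np.fft.fft2(data)) ** 2)
        total += spectrum
    freqs = np.fft.fftshift(np.fft.fftfreq(shape[0], d=pixel))
    profile = total.sum(axis=1)
    center = np.argmin(np.abs(freqs))
    masked = profile.copy()
    lo = max(center - dc_guard, 0)
    masked[lo:center + dc_guard + 1] = -np.inf
    peak = int(np.argmax(masked))
    spacing = float(1.0 / abs(freqs[peak]))
    return LayerLineSpectrum(power=total, pixel_size=pixel, axial_freqs=freqs,
                             first_layer_line=spacing)


def save_png(image: ProjectionImage, path) -> None:
    """8-bit PNG preview, min-max scaled."""
    from PIL import Image

    data = image.data
    span = data.max() - data.min()
    scaled = (data - data.min()) / span if span > 0 else np.zeros_like(data)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(path)
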