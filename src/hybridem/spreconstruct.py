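"""Toy-scale single-particle reconstruction by projection matching.

Orientations use ZYZ intrinsic Euler angles (φ, θ, ψ) in degrees, the
SPIDER-style convention: a particle image with angles (φ, θ, ψ) is the
line integral of the volume along the direction R·ẑ after sampling the
volume at R·o for image-plane points o, with R = Rz(φ)·Ry(θ)·Rz(ψ).
ψ is the in-plane rotation; (x, y) shifts in voxels are applied to the
projected image. Everything is deliberately small-scale: cubic volumes of
32–64 voxels and a few hundred images reconstruct in seconds to minutes
on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from hybridem.emmap import (FilterParams, _radial_frequencies, compute_fsc,
                            lowpass_to_resolution, resolution_at, tanh_transfer)
from hybridem.structio import GridMap


class ReconstructionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Orientations and images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationParams:
    """ZYZ Euler angles in degrees plus in-plane shifts in voxels."""

    phi: float
    theta: float
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            "ZYZ", [self.phi, self.theta, self.psi], degrees=True
        ).as_matrix()

    def view_direction(self) -> np.ndarray:
        """Unit projection direction R·ẑ (independent of ψ)."""
        return self.rotation_matrix() @ np.array([0.0, 0.0, 1.0])


@dataclass
class ParticleImage:
    """Square, even-sized 2-D image; ``truth`` is set only for synthetic data."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    truth: OrientationParams | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        n, m = self.pixels.shape
        if n != m or n % 2:
            raise ReconstructionError(f"particle images must be square and even-sized, got {n}×{m}")


def direction_error_deg(a: OrientationParams, b: OrientationParams) -> float:
    """Angle in degrees between two projection directions."""
    cos = float(np.clip(np.dot(a.view_direction(), b.view_direction()), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def _volume_values(volume) -> np.ndarray:
    v = volume.values if isinstance(volume, GridMap) else np.asarray(volume, dtype=float)
    if v.ndim != 3 or len(set(v.shape)) != 1:
        raise ReconstructionError(f"volume must be cubic, got shape {v.shape}")
    return v


def _centered_affine(vol: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    c = (np.array(vol.shape) - 1) / 2.0
    return ndimage.affine_transform(vol, matrix, offset=c - matrix @ c,
                                    order=1, mode="constant", cval=0.0)


def project(volume, orientation: OrientationParams) -> ParticleImage:
    """Project a cubic volume along the orientation's viewing axis.

    Trilinear interpolation; the image sum matches the volume sum to well
    under a percent for objects padded away from the box edge.
    """
    vol = _volume_values(volume)
    rot = orientation.rotation_matrix()
    rotated = _centered_affine(vol, rot)
    img = rotated.sum(axis=2)
    if orientation.shift_x or orientation.shift_y:
        img = ndimage.shift(img, (orientation.shift_x, orientation.shift_y),
                            order=1, mode="constant", cval=0.0)
    pix = volume.voxel_size if isinstance(volume, GridMap) else 1.0
    return ParticleImage(img, pixel_size=pix)


def _inplane_rotate(img: np.ndarray, psi_deg: float) -> np.ndarray:
    """Image of the same projection at in-plane angle ψ, given the ψ=0 image."""
    c, s = np.cos(np.radians(psi_deg)), np.sin(np.radians(psi_deg))
    m = np.array([[c, -s], [s, c]])
    ctr = (np.array(img.shape) - 1) / 2.0
    return ndimage.affine_transform(img, m, offset=ctr - m @ ctr,
                                    order=1, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# Reference projections
# ---------------------------------------------------------------------------

def sphere_directions(angular_step: float) -> list[tuple[float, float]]:
    """Quasi-uniform (φ, θ) grid over the full sphere at the given step.

    θ is sampled at the step; φ at step/sin θ; each pole appears once.
    """
    if not 0 < angular_step <= 90:
        raise ReconstructionError(f"angular step must be in (0°, 90°], got {angular_step}")
    out: list[tuple[float, float]] = []
    n_theta = int(round(180.0 / angular_step))
    for i in range(n_theta + 1):
        theta = i * 180.0 / n_theta
        if theta < 1e-9 or theta > 180.0 - 1e-9:
            out.append((0.0, theta))
            continue
        n_phi = max(1, int(np.ceil(360.0 * np.sin(np.radians(theta)) / angular_step)))
        for k in range(n_phi):
            out.append((k * 360.0 / n_phi, theta))
    return out


def reference_set(volume, angular_step: float) -> list[tuple[ParticleImage, OrientationParams]]:
    """Reference projections on a quasi-uniform sphere grid (ψ = 0)."""
    refs = []
    for phi, theta in sphere_directions(angular_step):
        op = OrientationParams(phi, theta, 0.0)
        refs.append((project(volume, op), op))
    return refs


# ---------------------------------------------------------------------------
# Projection matching
# ---------------------------------------------------------------------------

def bandlimit_2d(pixels: np.ndarray, stop_band: float,
                 fall_off: float = 0.3) -> np.ndarray:
    """Tanh low-pass of a 2-D image (stop band in cycles/pixel)."""
    h = tanh_transfer(_radial_frequencies(pixels.shape),
                      FilterParams(stop_band, fall_off))
    return np.fft.ifft2(np.fft.fft2(pixels) * h).real


def _unit_rows(mat: np.ndarray) -> np.ndarray:
    mat = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return mat / norms


class ReferenceLibrary:
    """Reference projections expanded over an in-plane rotation grid.

    Rows are mean-subtracted and unit-normalized so a dot product with a
    normalized image is the normalized cross-correlation. When
    ``match_lowpass`` (a stop-band frequency in cycles/pixel) is given,
    references — and, in :func:`assign_orientations`, the images — are
    band-limited before matching, which suppresses pure-noise frequencies
    beyond the signal's resolution.
    """

    def __init__(self, references: Sequence[tuple[ParticleImage, OrientationParams]],
                 in_plane_step: float, match_lowpass: float | None = None):
        if not references:
            raise ReconstructionError("empty reference set")
        if not in_plane_step > 0:
            raise ReconstructionError("in-plane step must be > 0")
        self.size = references[0][0].pixels.shape[0]
        self.match_lowpass = match_lowpass
        psis = np.arange(0.0, 360.0, in_plane_step)
        rows, meta = [], []
        for ref_index, (img, op) in enumerate(references):
            if img.pixels.shape[0] != self.size:
                raise ReconstructionError("reference image sizes differ")
            pix = img.pixels
            if match_lowpass is not None:
                pix = bandlimit_2d(pix, match_lowpass)
            for psi in psis:
                rows.append(_inplane_rotate(pix, psi).ravel())
                meta.append((ref_index, op.phi, op.theta, psi))
        self.matrix = _unit_rows(np.array(rows))
        self.meta = meta


def _shift_grid(radius: int) -> list[tuple[int, int]]:
    r = int(radius)
    return [(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1)]


def assign_orientations(images: Sequence[ParticleImage], library: ReferenceLibrary,
                        shift_radius: int = 1) -> list[tuple[OrientationParams, float]]:
    """Best reference (with in-plane angle and integer shift) per image.

    Exhaustive over the library's angular/in-plane grid and integer shifts
    within ``shift_radius``; ties break to the lowest library index. The
    score is the normalized cross-correlation of the matched pair.
    """
    shifts = _shift_grid(shift_radius)
    results = []
    for block_start in range(0, len(images), 64):
        block = images[block_start:block_start + 64]
        variants = []
        for im in block:
            if im.pixels.shape[0] != library.size:
                raise ReconstructionError(
                    f"image size {im.pixels.shape[0]} != reference size {library.size}")
            pix = im.pixels
            if library.match_lowpass is not None:
                pix = bandlimit_2d(pix, library.match_lowpass)
            for (dx, dy) in shifts:
                v = pix if (dx, dy) == (0, 0) else ndimage.shift(
                    pix, (-dx, -dy), order=1, mode="constant", cval=0.0)
                variants.append(v.ravel())
        scores = _unit_rows(np.array(variants)) @ library.matrix.T
        scores = scores.reshape(len(block), len(shifts), -1)
        for i in range(len(block)):
            flat = scores[i]
            si, li = np.unravel_index(np.argmax(flat), flat.shape)
            _, phi, theta, psi = library.meta[li]
            dx, dy = shifts[si]
            op = OrientationParams(phi, theta, psi, float(dx), float(dy))
            results.append((op, float(flat[si, li])))
    return results


def assign_orientation(image: ParticleImage,
                       references: Sequence[tuple[ParticleImage, OrientationParams]],
                       in_plane_step: float = 15.0,
                       shift_radius: int = 1,
                       match_lowpass: float | None = None,
                       ) -> tuple[OrientationParams, float]:
    lib = ReferenceLibrary(references, in_plane_step, match_lowpass)
    return assign_orientations([image], lib, shift_radius)[0]


# ---------------------------------------------------------------------------
# Back-projection
# ---------------------------------------------------------------------------

def _ramp_filter(img: np.ndarray) -> np.ndarray:
    n = img.shape[0]
    fx = np.fft.fftfreq(n)
    f2d = np.sqrt(fx[:, None] ** 2 + fx[None, :] ** 2)
    weight = np.maximum(f2d, 0.5 / n)
    return np.fft.ifft2(np.fft.fft2(img) * weight).real


def backproject(images: Sequence[ParticleImage],
                orientations: Sequence[OrientationParams],
                weighted: bool = True) -> GridMap:
    """Real-space back-projection with per-image 2-D ramp (r) weighting.

    The result is the mean over images, so duplicating the image set
    leaves the reconstruction unchanged.
    """
    if len(images) == 0:
        raise ReconstructionError("no images to back-project")
    if len(images) != len(orientations):
        raise ReconstructionError("images and orientations differ in length")
    n = images[0].pixels.shape[0]
    vol = np.zeros((n, n, n))
    for im, op in zip(images, orientations):
        img = im.pixels
        if op.shift_x or op.shift_y:
            img = ndimage.shift(img, (-op.shift_x, -op.shift_y),
                                order=1, mode="constant", cval=0.0)
        if weighted:
            img = _ramp_filter(img)
        rep = np.repeat(img[:, :, None], n, axis=2)
        vol += _centered_affine(rep, op.rotation_matrix().T)
    vol /= len(images)
    return GridMap(vol, images[0].pixel_size)


# ---------------------------------------------------------------------------
# Iterative refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinementSchedule:
    """Projection-matching schedule.

    ``subset_size`` restricts each cycle to a seeded random subset of the
    reference grid (the small-reference-set cycling protocol); ``None``
    matches against the full grid every iteration.
    """

    iterations: int = 8
    angular_step: float = 15.0
    in_plane_step: float | None = None
    shift_radius: int = 1
    subset_size: int | None = None
    lowpass_resolution: float | None = None
    match_lowpass: float | None = 0.3  # cycles/pixel stop band for matching

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ReconstructionError("iterations must be ≥ 0")
        if not self.angular_step > 0:
            raise ReconstructionError("angular step must be > 0")


def refine(images: Sequence[ParticleImage], initial_volume: GridMap,
           schedule: RefinementSchedule, seed: int = 0,
           ) -> tuple[GridMap, list[dict]]:
    """Iterative projection matching against an updating volume.

    Per iteration: build references from the current volume, assign every
    image an orientation, back-project. Diagnostics carry the mean match
    score, the half-set FSC-0.5 resolution, and — when images hold
    ground-truth orientations — the median viewing-direction error. If the
    mean score drops on two consecutive iterations the loop stops early
    and reports divergence.
    """
    rng = np.random.default_rng(seed)
    volume = initial_volume
    diagnostics: list[dict] = []
    in_plane = schedule.in_plane_step or schedule.angular_step
    drops = 0
    prev_score = -np.inf
    for it in range(schedule.iterations):
        refs = reference_set(volume, schedule.angular_step)
        if schedule.subset_size is not None and schedule.subset_size < len(refs):
            idx = rng.choice(len(refs), size=schedule.subset_size, replace=False)
            refs = [refs[i] for i in sorted(idx)]
        library = ReferenceLibrary(refs, in_plane, schedule.match_lowpass)
        assigned = assign_orientations(images, library, schedule.shift_radius)
        orientations = [op for op, _ in assigned]
        scores = np.array([s for _, s in assigned])
        volume = backproject(images, orientations)
        if schedule.lowpass_resolution is not None:
            volume = lowpass_to_resolution(volume, schedule.lowpass_resolution)
        entry = {"iteration": it, "mean_score": float(scores.mean())}
        half_a = backproject(images[0::2], orientations[0::2])
        half_b = backproject(images[1::2], orientations[1::2])
        entry["fsc_resolution"] = resolution_at(
            compute_fsc(half_a, half_b), 0.5, volume.voxel_size)
        if all(im.truth is not None for im in images):
            errs = [direction_error_deg(im.truth, op)
                    for im, op in zip(images, orientations)]
            entry["median_angular_error"] = float(np.median(errs))
        diagnostics.append(entry)
        # plateau jitter in the mean score is not divergence; only count
        # drops beyond a small tolerance
        if entry["mean_score"] < prev_score - 1e-3:
            drops += 1
            if drops >= 2:
                entry["diverged"] = True
                break
        else:
            drops = 0
        prev_score = entry["mean_score"]
    return volume, diagnostics
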