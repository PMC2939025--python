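"""Density simulation, Fourier filtering, FSC, and contour thresholds.

Spatial frequencies are measured in cycles/voxel throughout so that filter
parameters quoted against digitized images (e.g. a stop-band of 0.28 and a
fall-off of 0.45 for the hyperbolic-tangent low-pass) plug in directly.
Simulated density places one unit-weight isotropic Gaussian per
non-hydrogen atom with FWHM equal to the nominal resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from hybridem.structio import GridMap, StructureModel

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class MapError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Density simulation
# ---------------------------------------------------------------------------

def simulate_map(model, resolution: float, voxel_size: float,
                 shape: int | tuple[int, int, int],
                 origin: np.ndarray | None = None) -> GridMap:
    """Simulate a density map from coordinates.

    Each (non-hydrogen) atom contributes a unit-weight isotropic Gaussian
    with FWHM = ``resolution``; the grid integral is therefore proportional
    to the atom count. ``model`` may be a :class:`StructureModel` or an
    N×3 coordinate array. When ``origin`` is omitted the grid is centered
    on the coordinate centroid. Atoms outside the box raise an error.
    """
    if resolution < 2.0 * voxel_size:
        raise MapError(
            f"resolution {resolution} Å under-samples voxel {voxel_size} Å (Nyquist)"
        )
    if isinstance(model, StructureModel):
        xyz = np.array([a.position for a in model.atoms
                        if (a.element or "X").upper() != "H"])
    else:
        xyz = np.asarray(model, dtype=float)
    if xyz.size == 0:
        raise MapError("no atoms to simulate")
    if np.isscalar(shape):
        shape = (int(shape),) * 3
    shape = tuple(int(s) for s in shape)
    if origin is None:
        center = xyz.mean(axis=0)
        origin = center - voxel_size * (np.array(shape) - 1) / 2.0
    origin = np.asarray(origin, dtype=float)

    frac = (xyz - origin) / voxel_size
    inside = np.all((frac >= 0) & (frac <= np.array(shape) - 1), axis=1)
    if not inside.all():
        raise MapError(f"{int((~inside).sum())} atoms fall outside the simulation box")

    values = np.zeros(shape)
    base = np.floor(frac).astype(int)
    t = frac - base
    # trilinear splat of unit weight per atom
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                idx = np.minimum(base + (dx, dy, dz), np.array(shape) - 1)
                np.add.at(values, (idx[:, 0], idx[:, 1], idx[:, 2]), w)
    sigma_vox = resolution * FWHM_TO_SIGMA / voxel_size
    values = ndimage.gaussian_filter(values, sigma_vox, mode="constant")
    return GridMap(values, voxel_size, origin)


# ---------------------------------------------------------------------------
# Hyperbolic-tangent low-pass filter
# ---------------------------------------------------------------------------

@dataclass
class FilterParams:
    """Stop-band frequency (cycles/voxel) and dimensionless fall-off width."""

    stop_band: float
    fall_off: float

    def __post_init__(self) -> None:
        if not 0 < self.stop_band <= 0.5:
            raise MapError(f"stop_band must be in (0, 0.5], got {self.stop_band}")
        if not self.fall_off > 0:
            raise MapError(f"fall_off must be > 0, got {self.fall_off}")


def tanh_transfer(freq: np.ndarray, params: FilterParams) -> np.ndarray:
    """Radial transfer function of the tanh low-pass filter.

    H(f) ∝ ½ [tanh(π(f+fs)/(2 w fs)) − tanh(π(f−fs)/(2 w fs))], the form
    used by the SPARX single-particle package, normalized by its value at
    f = 0 so the DC term passes exactly (H(0) = 1) and H decreases
    monotonically with f.
    """
    fs, w = params.stop_band, params.fall_off
    a = np.pi / (2.0 * w * fs)

    def raw(f):
        return 0.5 * (np.tanh(a * (f + fs)) - np.tanh(a * (f - fs)))

    return raw(np.asarray(freq, dtype=float)) / raw(0.0)


def _radial_frequencies(shape: tuple[int, ...]) -> np.ndarray:
    axes = np.meshgrid(*[np.fft.fftfreq(n) for n in shape], indexing="ij")
    return np.sqrt(sum(ax * ax for ax in axes))


def tanh_lowpass(grid_map: GridMap, params: FilterParams) -> GridMap:
    """Apply the tanh low-pass filter in Fourier space (DC preserved)."""
    f = _radial_frequencies(grid_map.values.shape)
    h = tanh_transfer(f, params)
    filtered = np.fft.ifftn(np.fft.fftn(grid_map.values) * h).real
    out = grid_map.copy()
    out.values = filtered
    return out


def lowpass_to_resolution(grid_map: GridMap, resolution: float,
                          fall_off: float = 0.25) -> GridMap:
    """Tanh low-pass with the stop band placed at 1/resolution."""
    fs = min(0.5, grid_map.voxel_size / resolution)
    return tanh_lowpass(grid_map, FilterParams(fs, fall_off))


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------

class FSCCurve(NamedTuple):
    frequencies: np.ndarray   # shell centers, cycles/voxel
    correlations: np.ndarray  # in [−1, 1]
    shell_counts: np.ndarray  # Fourier voxels per shell


def compute_fsc(a: GridMap, b: GridMap) -> FSCCurve:
    """Shell-wise normalized cross-spectral correlation of two maps.

    Shells are one Fourier voxel wide; shell 0 holds the DC term only, so
    two maps with equal-sign nonzero means score 1 there.
    """
    if a.values.shape != b.values.shape:
        raise MapError(f"grid mismatch: {a.values.shape} vs {b.values.shape}")
    if not np.isclose(a.voxel_size, b.voxel_size, rtol=1e-6):
        raise MapError("voxel sizes differ")
    n = a.values.shape[0]
    fa, fb = np.fft.fftn(a.values), np.fft.fftn(b.values)
    shell = np.rint(_radial_frequencies(a.values.shape) * n).astype(int)
    n_shells = n // 2 + 1
    sel = shell < n_shells
    idx = shell[sel]
    cross = np.bincount(idx, weights=(fa * np.conj(fb)).real[sel], minlength=n_shells)
    pa = np.bincount(idx, weights=np.abs(fa[sel]) ** 2, minlength=n_shells)
    pb = np.bincount(idx, weights=np.abs(fb[sel]) ** 2, minlength=n_shells)
    counts = np.bincount(idx, minlength=n_shells)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = np.where(denom > 0, cross / denom, 0.0)
    freqs = np.arange(n_shells) / n
    return FSCCurve(freqs, np.clip(fsc, -1.0, 1.0), counts)


def resolution_at(curve: FSCCurve, threshold: float, voxel_size: float) -> float:
    """Resolution (Å) at the first downward threshold crossing of an FSC.

    Linearly interpolated between shells; if the curve never drops below
    the threshold the Nyquist limit (2 × voxel size) is returned.
    """
    f, c = curve.frequencies, curve.correlations
    for i in range(1, len(f)):
        if c[i] < threshold <= c[i - 1]:
            # linear interpolation in frequency
            t = (c[i - 1] - threshold) / (c[i - 1] - c[i])
            fc = f[i - 1] + t * (f[i] - f[i - 1])
            return float(voxel_size / fc)
    return 2.0 * voxel_size


def write_fsc_table(curve: FSCCurve, destination) -> None:
    """Two-column (frequency, correlation) delimited text."""
    np.savetxt(destination, np.column_stack([curve.frequencies, curve.correlations]),
               fmt="%.6f", delimiter="\t", header="freq_cyc_per_voxel\tfsc")


# ---------------------------------------------------------------------------
# Contour thresholds
# ---------------------------------------------------------------------------

@dataclass
class ContourSpec:
    """Isosurface level expressed in standard deviations above the mean."""

    n_sigma: float


def contour_threshold(grid_map: GridMap, spec: ContourSpec | float) -> float:
    """mean + n_sigma × sd over the whole (unmasked) grid."""
    n_sigma = spec.n_sigma if isinstance(spec, ContourSpec) else float(spec)
    sd = float(grid_map.values.std())
    if sd == 0:
        raise MapError("contour threshold is undefined for a constant map")
    return float(grid_map.values.mean()) + n_sigma * sd
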