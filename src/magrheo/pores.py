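"""Pore-size analysis of 3D fiber networks by maximal inscribed spheres.

A fluorescence volume of a collagen network is segmented into a fibril
phase and a fluid phase; the pore size at a location is the diameter of
the largest sphere that fits into the fluid phase there.  Spheres are
found greedily on the anisotropy-aware Euclidean distance transform of the
fluid phase: the voxel with the largest distance to any fibril is accepted
as a pore centre with that distance as its radius, the voxels it covers
are suppressed, and the process repeats until the remaining maxima fall
below a minimum radius.  By construction every sphere lies entirely in the
fluid phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, transform

__all__ = [
    "LabeledVolume3D", "PoreSet", "PoreStatistics",
    "rescale_volume", "segment_fibrils", "fit_pore_spheres",
    "pore_statistics", "acquisition_sampling_um_per_px",
]


@dataclass
class LabeledVolume3D:
    """A 3D scalar or binary volume with per-axis voxel sizes.

    Axis order is (z, y, x) matching the array layout; ``voxel_size_zyx``
    is in µm per voxel and is carried through every distance computation.
    For binary volumes True marks the fibril phase.
    """

    voxels: np.ndarray
    voxel_size_zyx: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = "intensity"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if self.kind not in ("intensity", "binary"):
            raise ValueError("kind must be 'intensity' or 'binary'")
        vs = tuple(float(v) for v in self.voxel_size_zyx)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel sizes must be positive")
        self.voxel_size_zyx = vs
        if self.kind == "binary":
            self.voxels = self.voxels.astype(bool)


def acquisition_sampling_um_per_px(extent_um: float, n_px: int,
                                   rescale_factor: float = 1.0) -> float:
    """Physical sampling (µm per pixel) of an acquired axis after optional
    down-rescaling, e.g. a 100 µm field recorded at 2048 px and rescaled to
    37.5% samples at 100/(2048*0.375) ≈ 0.13 µm/px."""
    if not (extent_um > 0 and n_px > 0 and 0 < rescale_factor <= 1):
        raise ValueError("extent, pixel count and rescale factor must be positive")
    return extent_um / (round(n_px * rescale_factor))


def rescale_volume(v: LabeledVolume3D, xy_factor: float) -> LabeledVolume3D:
    """Resample the lateral (y, x) axes by ``xy_factor``, keeping the
    physical extent: voxel sizes grow by the inverse factor.

    Intensity volumes use linear interpolation with anti-aliasing; binary
    volumes use nearest-neighbour so they stay binary.
    """
    if not 0 < xy_factor <= 1:
        raise ValueError("xy_factor must lie in (0, 1]")
    if xy_factor == 1.0:
        return LabeledVolume3D(v.voxels.copy(), v.voxel_size_zyx, v.kind)
    new_yx = (round(v.voxels.shape[1] * xy_factor),
              round(v.voxels.shape[2] * xy_factor))
    if min(new_yx) < 16:
        raise ValueError("rescaling would leave fewer than 16 px laterally")
    if v.kind == "binary":
        out = transform.resize(v.voxels, (v.voxels.shape[0], *new_yx),
                               order=0, preserve_range=True,
                               anti_aliasing=False).astype(bool)
    else:
        out = transform.resize(v.voxels.astype(float),
                               (v.voxels.shape[0], *new_yx),
                               order=1, preserve_range=True, anti_aliasing=True)
    vz, vy, vx = v.voxel_size_zyx
    new_vs = (vz,
              vy * v.voxels.shape[1] / new_yx[0],
              vx * v.voxels.shape[2] / new_yx[1])
    return LabeledVolume3D(out, new_vs, v.kind)


def segment_fibrils(v: LabeledVolume3D, sigma_vox: float = 1.0,
                    local: bool = False, local_block: int = 33) -> LabeledVolume3D:
    """Segment bright fibrils from an intensity volume.

    Gaussian pre-smoothing (sigma in voxels) followed by a global Otsu
    threshold; ``local=True`` switches to a local adaptive (per-plane
    local-threshold) mode for uneven illumination.  A binary input passes
    through unchanged.
    """
    if v.kind == "binary":
        return LabeledVolume3D(v.voxels.copy(), v.voxel_size_zyx, "binary")
    img = np.asarray(v.voxels, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("constant intensity volume cannot be segmented")
    sm = ndimage.gaussian_filter(img, sigma_vox)
    if local:
        block = int(local_block) | 1
        mask = np.empty(sm.shape, dtype=bool)
        for z in range(sm.shape[0]):
            thr = filters.threshold_local(sm[z], block_size=block,
                                          method="gaussian")
            mask[z] = sm[z] > thr
    else:
        thr = filters.threshold_otsu(sm)
        mask = sm > thr
        # Otsu always splits, even pure background noise: require the two
        # classes to be separated by more than the background spread
        if mask.any() and not mask.all():
            m_bg, m_fg = sm[~mask].mean(), sm[mask].mean()
            if m_fg - m_bg < max(3.0 * sm[~mask].std(), 2.0 * sm.std()):
                warnings.warn("intensity classes are not separable; "
                              "treating the volume as fibril-free",
                              stacklevel=2)
                mask = np.zeros_like(mask)
    return LabeledVolume3D(mask, v.voxel_size_zyx, "binary")


@dataclass
class PoreSet:
    """Maximal inscribed spheres in the fluid phase.

    ``centers_um`` are (z, y, x) physical coordinates; radii in µm, in
    decreasing order of acceptance.
    """

    centers_um: np.ndarray
    radii_um: np.ndarray
    min_radius_um: float
    voxel_size_zyx: tuple[float, float, float]

    def __len__(self) -> int:
        return self.radii_um.size

    def to_frame(self):
        import pandas as pd
        if len(self) == 0:
            return pd.DataFrame(columns=["cz_um", "cy_um", "cx_um", "r_um"])
        return pd.DataFrame({"cz_um": self.centers_um[:, 0],
                             "cy_um": self.centers_um[:, 1],
                             "cx_um": self.centers_um[:, 2],
                             "r_um": self.radii_um})


def fit_pore_spheres(binary: LabeledVolume3D, min_radius_um: float | None = None,
                     max_pores: int = 100000) -> PoreSet:
    """Greedy maximal-sphere packing of the fluid phase.

    The Euclidean distance transform of the fluid phase (anisotropic voxel
    sizes respected) gives, at each voxel, the radius of the largest
    fibril-free sphere centred there.  The largest remaining value is
    accepted as a pore; all voxels inside the accepted sphere are
    suppressed (a candidate centre inside an accepted sphere can never be
    accepted), and the loop repeats until the maximum falls below
    ``min_radius_um`` (default: 2 voxels — sub-resolution pores are noise).
    """
    if binary.kind != "binary":
        raise ValueError("pore detection needs a binary volume")
    fluid = ~binary.voxels
    vs = np.asarray(binary.voxel_size_zyx)
    if min_radius_um is None:
        min_radius_um = 2.0 * float(vs.min())
    if not fluid.any():
        return PoreSet(centers_um=np.empty((0, 3)), radii_um=np.empty(0),
                       min_radius_um=min_radius_um,
                       voxel_size_zyx=binary.voxel_size_zyx)
    edt = ndimage.distance_transform_edt(fluid, sampling=vs)
    shape = np.array(edt.shape)
    centers, radii = [], []
    flat = edt.ravel()  # view: suppression below writes through to edt
    # radii come from the original transform and are only ever zeroed, so a
    # single descending sort enumerates candidates in acceptance order
    cand = np.flatnonzero(flat >= min_radius_um)
    order = cand[np.argsort(flat[cand])[::-1]]
    for imax in order:
        if len(radii) >= max_pores:
            break
        r = float(flat[imax])
        if r == 0.0:  # suppressed by an earlier sphere
            continue
        center_vox = np.array(np.unravel_index(imax, edt.shape))
        centers.append(center_vox * vs)
        radii.append(r)
        # suppress all voxels covered by the accepted sphere
        lo = np.maximum(np.floor(center_vox - r / vs).astype(int), 0)
        hi = np.minimum(np.ceil(center_vox + r / vs).astype(int) + 1, shape)
        zz, yy, xx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                                 indexing="ij")
        dz = (zz - center_vox[0]) * vs[0]
        dy = (yy - center_vox[1]) * vs[1]
        dx = (xx - center_vox[2]) * vs[2]
        inside = dz ** 2 + dy ** 2 + dx ** 2 <= r ** 2
        sub = edt[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = 0.0
    return PoreSet(centers_um=np.asarray(centers).reshape(-1, 3),
                   radii_um=np.asarray(radii), min_radius_um=min_radius_um,
                   voxel_size_zyx=binary.voxel_size_zyx)


@dataclass(frozen=True)
class PoreStatistics:
    count: int
    mean_diameter_um: float
    median_diameter_um: float
    mean_radius_um: float
    median_radius_um: float

    @property
    def empty(self) -> bool:
        return self.count == 0


def pore_statistics(pores: PoreSet) -> PoreStatistics:
    """Summary of pore sizes; diameters and radii are both reported (the
    convention of downstream plots differs)."""
    if len(pores) == 0:
        warnings.warn("empty pore set", stacklevel=2)
        return PoreStatistics(0, np.nan, np.nan, np.nan, np.nan)
    r = pores.radii_um
    return PoreStatistics(count=int(r.size),
                          mean_diameter_um=float(np.mean(2 * r)),
                          median_diameter_um=float(np.median(2 * r)),
                          mean_radius_um=float(np.mean(r)),
                          median_radius_um=float(np.median(r)))
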