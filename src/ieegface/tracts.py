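"""White matter tract endpoint density maps and electrode overlap.

Per subject and tract, streamlines (already in MNI mm space) are cleaned
of outliers, reoriented so all first/last nodes form coherent endpoint
collections, and their endpoints counted on a 1 mm isotropic voxel grid;
counts are smoothed with a normalized 3 mm-radius spherical kernel.
Across subjects, per-voxel densities are thresholded (default 0.01 on the
smoothed counts, i.e. at least two endpoints within the kernel radius),
binarized, and summed into a subject-count mask.  The overlap matrix reports, per (ROI, response
class) group of electrode sites, the proportion of site coordinates whose
voxel is supported by at least ``validity_threshold`` subjects
(default 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SyntheticStreamlineSet

DENSITY_THRESHOLD = 0.01
VALIDITY_THRESHOLD = 100
SMOOTHING_RADIUS_MM = 3.0


# --------------------------------------------------------------------------
# voxel grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """1 mm isotropic grid: voxel (i,j,k) covers [origin + ijk, origin + ijk + 1).

    Membership is the floor of the mm coordinate relative to the origin
    (half-open voxels), so the mapping is deterministic.
    """

    origin: tuple
    shape: tuple

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, 3] = np.asarray(self.origin, dtype=float)
        return aff

    def voxel_of(self, xyz) -> np.ndarray:
        return np.floor(np.asarray(xyz, dtype=float)
                        - np.asarray(self.origin, dtype=float)).astype(int)

    def contains(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        shape = np.asarray(self.shape)
        return np.all((ijk >= 0) & (ijk < shape), axis=-1)


def mni_grid() -> VoxelGrid:
    """Standard 1 mm MNI bounding box (181 x 217 x 181)."""
    return VoxelGrid(origin=(-90.0, -126.0, -72.0), shape=(181, 217, 181))


def bounding_grid(sets, pad_mm: float = 8.0) -> VoxelGrid:
    """Smallest common grid covering every point of the given sets."""
    pts = np.concatenate([np.concatenate(s.streamlines) for s in sets])
    lo = np.floor(pts.min(axis=0) - pad_mm)
    hi = np.ceil(pts.max(axis=0) + pad_mm)
    return VoxelGrid(origin=tuple(lo), shape=tuple((hi - lo).astype(int) + 1))


# --------------------------------------------------------------------------
# streamline cleaning and reorientation
# --------------------------------------------------------------------------

def _lengths(streamlines) -> np.ndarray:
    return np.array([np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1))
                     for s in streamlines])


def _centroids(streamlines) -> np.ndarray:
    return np.array([np.mean(s, axis=0) for s in streamlines])


def clean_streamline_outliers(sset: SyntheticStreamlineSet,
                              n_sd: float = 4.0) -> SyntheticStreamlineSet:
    """Drop streamlines > ``n_sd`` SD from the tract centroid or mean length.

    Both criteria apply; zero-SD (identical streamlines) means no removal.
    Raises if cleaning would empty the tract.
    """
    sl = sset.streamlines
    if len(sl) < 2:
        raise ValueError("need >= 2 streamlines to estimate outliers")
    lengths = _lengths(sl)
    cents = _centroids(sl)
    dist = np.linalg.norm(cents - cents.mean(axis=0), axis=1)

    keep = np.ones(len(sl), dtype=bool)
    sd_d = dist.std()
    if sd_d > 0:
        keep &= (dist - dist.mean()) <= n_sd * sd_d
    sd_l = lengths.std()
    if sd_l > 0:
        keep &= np.abs(lengths - lengths.mean()) <= n_sd * sd_l
    if not keep.any():
        raise ValueError(f"outlier cleaning removed all streamlines of "
                         f"{sset.tract_name}")
    return SyntheticStreamlineSet(sset.tract_name, sset.subject_id,
                                  [s for s, k in zip(sl, keep) if k])


def reorient_streamlines(sset: SyntheticStreamlineSet,
                         reference: tuple | None = None
                         ) -> SyntheticStreamlineSet:
    """Align streamline directions so first/last nodes form two collections.

    Each streamline is reversed iff swapping its ends reduces the summed
    squared distance of its endpoints to the reference endpoint pair (by
    default the first streamline's ends); flipping only reverses the point
    order.  Passing an explicit ``reference = (p_first, p_last)`` keeps the
    collections consistent across subjects of the same tract.
    """
    sl = [np.asarray(s) for s in sset.streamlines]
    if reference is None:
        if len(sl) <= 1:
            return SyntheticStreamlineSet(sset.tract_name, sset.subject_id, sl)
        ref0, ref1 = sl[0][0], sl[0][-1]
    else:
        ref0, ref1 = (np.asarray(p, dtype=float) for p in reference)
    out = []
    for s in sl:
        same = (np.sum((s[0] - ref0) ** 2) + np.sum((s[-1] - ref1) ** 2))
        swapped = (np.sum((s[0] - ref1) ** 2) + np.sum((s[-1] - ref0) ** 2))
        out.append(s[::-1] if swapped < same else s)
    return SyntheticStreamlineSet(sset.tract_name, sset.subject_id, out)


# --------------------------------------------------------------------------
# endpoint density volumes
# --------------------------------------------------------------------------

@dataclass
class EndpointDensityVolume:
    data: np.ndarray
    grid: VoxelGrid
    tract_name: str
    subject_id: str
    collection: str  # 'first' or 'last'


def _spherical_kernel(radius_mm: float):
    """Offsets and normalized weights of a uniform sphere of voxel centers."""
    r = int(np.floor(radius_mm))
    ax = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = ii ** 2 + jj ** 2 + kk ** 2 <= radius_mm ** 2
    offs = np.column_stack([ii[inside], jj[inside], kk[inside]])
    w = np.full(len(offs), 1.0 / len(offs))
    return offs, w


def endpoint_density_map(sset: SyntheticStreamlineSet, collection: str,
                         grid: VoxelGrid,
                         smoothing_radius_mm: float = SMOOTHING_RADIUS_MM
                         ) -> EndpointDensityVolume:
    """Count first or last streamline nodes per 1 mm voxel, then smooth.

    The spherical smoothing kernel is normalized, so the voxel sum equals
    the streamline count for interior endpoints; radius 0 skips smoothing.
    """
    if collection not in ("first", "last"):
        raise ValueError("collection must be 'first' or 'last'")
    if not sset.streamlines:
        raise ValueError("empty streamline set")
    pts = np.array([s[0] if collection == "first" else s[-1]
                    for s in sset.streamlines])
    vox = grid.voxel_of(pts)
    if not np.all(grid.contains(vox)):
        raise ValueError("grid does not cover all endpoints")

    data = np.zeros(grid.shape)
    if smoothing_radius_mm > 0:
        offs, w = _spherical_kernel(smoothing_radius_mm)
        targets = vox[:, None, :] + offs[None, :, :]  # (n, m, 3)
        weights = np.broadcast_to(w, targets.shape[:2]).ravel()
        targets = targets.reshape(-1, 3)
        ok = grid.contains(targets)
        np.add.at(data, tuple(targets[ok].T), weights[ok])
    else:
        np.add.at(data, tuple(vox.T), 1.0)
    return EndpointDensityVolume(data=data, grid=grid,
                                 tract_name=sset.tract_name,
                                 subject_id=sset.subject_id,
                                 collection=collection)


# --------------------------------------------------------------------------
# group masks
# --------------------------------------------------------------------------

@dataclass
class GroupEndpointMask:
    counts: np.ndarray          # per-voxel number of subjects
    grid: VoxelGrid
    tract_name: str
    n_subjects: int
    density_threshold: float = DENSITY_THRESHOLD
    normalized: bool = False


def group_endpoint_mask(volumes, density_threshold: float = DENSITY_THRESHOLD,
                        normalized: bool = False) -> GroupEndpointMask:
    """Threshold (strictly >) each subject's density, binarize, and sum.

    The default thresholds the raw smoothed counts: with the
    total-preserving spherical kernel (123 voxels at radius 3), 0.01 means
    at least two endpoints within the kernel radius of the voxel.  With
    ``normalized`` the threshold instead applies to the density divided by
    the subject's total endpoint mass; note that the same kernel then caps
    the attainable density at 1/123 per voxel, so thresholds must be far
    below 0.01 to be reachable.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("no volumes")
    g0 = volumes[0].grid
    counts = np.zeros(g0.shape)
    for v in volumes:
        if v.grid != g0:
            raise ValueError("all volumes must share the same grid")
        d = v.data
        if normalized:
            total = d.sum()
            d = d / total if total > 0 else d
        counts += (d > density_threshold)
    return GroupEndpointMask(counts=counts, grid=g0,
                             tract_name=volumes[0].tract_name,
                             n_subjects=len(volumes),
                             density_threshold=density_threshold,
                             normalized=normalized)


def subject_density_maps(streamline_sets, grid: VoxelGrid | None = None,
                         collection: str = "first",
                         smoothing_radius_mm: float = SMOOTHING_RADIUS_MM,
                         clean: bool = True) -> dict:
    """Per-tract group masks from raw streamline sets (full chain)."""
    sets = list(streamline_sets)
    grid = grid or bounding_grid(sets)
    by_tract: dict = {}
    references: dict = {}
    for s in sets:
        if clean and len(s.streamlines) >= 2:
            s = clean_streamline_outliers(s)
        # one endpoint-pair reference per tract so the first/last
        # collections agree across subjects
        s = reorient_streamlines(s, references.get(s.tract_name))
        references.setdefault(s.tract_name,
                              (s.streamlines[0][0], s.streamlines[0][-1]))
        vol = endpoint_density_map(s, collection, grid, smoothing_radius_mm)
        by_tract.setdefault(s.tract_name, []).append(vol)
    return {t: group_endpoint_mask(vols) for t, vols in by_tract.items()}


# --------------------------------------------------------------------------
# overlap matrix
# --------------------------------------------------------------------------

@dataclass
class OverlapMatrix:
    table: pd.DataFrame         # rows (roi, response_class) x tract columns
    dropped_columns: list = field(default_factory=list)
    validity_threshold: int = VALIDITY_THRESHOLD


def compute_overlap(site_table: pd.DataFrame, masks: dict,
                    validity_threshold: int = VALIDITY_THRESHOLD
                    ) -> OverlapMatrix:
    """Proportion of each site group inside each tract's valid voxels.

    ``site_table`` needs columns roi, response_class, x, y, z.  A site is
    inside a mask iff the voxel containing its coordinate is supported by
    at least ``validity_threshold`` subjects.  Sites outside the grid
    count as not-inside (with a warning).  Tract columns with zero overlap
    for every group are dropped from the emitted table (and recorded).
    """
    rows = []
    groups = site_table.groupby(["roi", "response_class"], sort=True)
    for (roi, cls), grp in groups:
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
        entry = {"roi": roi, "response_class": cls, "n_sites": len(grp)}
        for tract, mask in masks.items():
            vox = mask.grid.voxel_of(xyz)
            ok = mask.grid.contains(vox)
            if not np.all(ok):
                warnings.warn(f"{int(np.sum(~ok))} site(s) of {roi}/{cls} "
                              "outside the mask grid; counted as not inside",
                              stacklevel=2)
            inside = np.zeros(len(grp), dtype=bool)
            if ok.any():
                v = vox[ok]
                inside[ok] = mask.counts[v[:, 0], v[:, 1], v[:, 2]] \
                    >= validity_threshold
            entry[tract] = float(inside.mean())
        rows.append(entry)
    table = pd.DataFrame(rows)
    dropped = [t for t in masks if (table[t] == 0).all()]
    return OverlapMatrix(table=table.drop(columns=dropped),
                         dropped_columns=dropped,
                         validity_threshold=validity_threshold)
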