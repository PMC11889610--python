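"""Structural feature extraction from binary lesion masks.

Given a lesion mask on a voxel grid, a parcel atlas, and a population
streamline set, this module quantifies: lesion volume, percent damage per
ROI, percent tract disconnection, voxel-wise disconnection maps, and
lesion-induced increases in structural shortest path length (SSPL) between
parcels. Streamline-lesion intersection is defined as sharing at least one
voxel index (binary masks, atlas streamlines; no partial-volume weighting).
Coordinates are 0-based voxel indices throughout; physical volumes come
from the voxel-size product.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "VoxelGrid",
    "ParcelAtlas",
    "StreamlineAtlas",
    "StructuralFeatures",
    "lesion_volume",
    "roi_damage",
    "tract_disconnection",
    "disconnection_map",
    "sspl_delta",
    "sspl_matrix",
    "flip_and_smooth",
    "extract_structural_features",
    "PROJECTION_TRACTS",
    "COMMISSURAL_TRACTS",
]

#: motor projection tracts: corticospinal, corticostriatal, corticothalamic,
#: frontopontine, parietopontine
PROJECTION_TRACTS = ("CST", "CS", "CT", "FPT", "PPT")
#: corpus callosum segments carrying motor commissural connections
COMMISSURAL_TRACTS = ("CC_mid_anterior", "CC_central", "CC_mid_posterior")


@dataclass
class VoxelGrid:
    """A binary mask on a regular voxel grid."""

    mask: np.ndarray               # bool/0-1, 3-d
    voxel_size: tuple = (1.0, 1.0, 1.0)   # mm per axis

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-d")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        self.mask = self.mask.astype(bool)

    @property
    def shape(self):
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @classmethod
    def from_nifti(cls, path) -> "VoxelGrid":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(mask=(np.asarray(img.dataobj) > 0.5), voxel_size=zooms)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine),
                 str(path))


@dataclass
class ParcelAtlas:
    """Integer parcel labels per voxel (0 = background) with a name table."""

    labels: np.ndarray
    names: dict                    # id -> name

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self._ids = {name: pid for pid, name in self.names.items()}
        for pid, name in self.names.items():
            if not (self.labels == pid).any():
                raise ValueError(f"parcel {name!r} (id {pid}) is empty")

    def parcel_id(self, name: str) -> int:
        try:
            return self._ids[name]
        except KeyError:
            raise KeyError(f"unknown parcel {name!r}") from None

    def parcel_mask(self, name: str) -> np.ndarray:
        return self.labels == self.parcel_id(name)

    def parcel_of_voxel(self, ijk) -> int:
        return int(self.labels[tuple(ijk)])


@dataclass
class StreamlineAtlas:
    """Population streamlines as voxel-index polylines with tract labels."""

    streamlines: list              # list of ndarray (n_points, 3) int
    tract_labels: list             # tract name per streamline
    shape: tuple = None            # grid shape for validation

    def __post_init__(self):
        self.streamlines = [np.asarray(s, dtype=int)
                            for s in self.streamlines]
        if len(self.streamlines) != len(self.tract_labels):
            raise ValueError("one tract label per streamline required")
        if self.shape is not None:
            hi = np.array(self.shape)
            for s in self.streamlines:
                if (s < 0).any() or (s >= hi).any():
                    raise ValueError("streamline voxel index outside grid")

    def tract_indices(self, tract: str) -> np.ndarray:
        idx = np.array([i for i, t in enumerate(self.tract_labels)
                        if t == tract])
        if idx.size == 0:
            raise KeyError(f"unknown or empty tract {tract!r}")
        return idx

    @property
    def tracts(self) -> set:
        return set(self.tract_labels)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for lab, s in zip(self.tract_labels, self.streamlines):
                fh.write(json.dumps({"tract": lab,
                                     "voxels": s.tolist()}) + "\n")

    @classmethod
    def from_jsonl(cls, path, shape=None) -> "StreamlineAtlas":
        lines, labels = [], []
        with open(path) as fh:
            for row in fh:
                rec = json.loads(row)
                labels.append(rec["tract"])
                lines.append(np.asarray(rec["voxels"], dtype=int))
        return cls(streamlines=lines, tract_labels=labels, shape=shape)


@dataclass
class StructuralFeatures:
    """Per-subject structural summary."""

    lesion_volume: float                       # mm^3
    roi_damage: dict                           # name -> %
    tract_disconnection: dict                  # name -> %
    projection_mean: float                     # mean over 5 motor tracts, %
    commissural_mean: float                    # mean over 3 CC segments, %
    sspl_delta: dict                           # (roi_a, roi_b) -> hops/inf
    disconnection_map: np.ndarray = field(default=None, repr=False)

    def to_row(self) -> dict:
        row = {"lesion_volume": self.lesion_volume,
               "projection_mean": self.projection_mean,
               "commissural_mean": self.commissural_mean}
        row.update({f"damage_{k}": v for k, v in self.roi_damage.items()})
        row.update({f"disc_{k}": v
                    for k, v in self.tract_disconnection.items()})
        row.update({f"sspl_{a}_{b}": v
                    for (a, b), v in self.sspl_delta.items()})
        return row


def lesion_volume(grid: VoxelGrid) -> float:
    """Lesion size in mm^3: lesioned voxel count times voxel volume."""
    return float(grid.mask.sum()) * grid.voxel_volume


def roi_damage(grid: VoxelGrid, atlas: ParcelAtlas, roi_name: str) -> float:
    """Percent of the ROI's voxels overlapped by the lesion."""
    roi = atlas.parcel_mask(roi_name)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError(f"ROI {roi_name!r} is empty")
    return 100.0 * int((grid.mask & roi).sum()) / n_roi


def _streamline_hits(grid: VoxelGrid, streamlines) -> np.ndarray:
    """Boolean per streamline: does it share any voxel with the lesion."""
    m = grid.mask
    return np.array([bool(m[s[:, 0], s[:, 1], s[:, 2]].any())
                     for s in streamlines])


def tract_disconnection(grid: VoxelGrid, atlas: StreamlineAtlas,
                        tract_name: str) -> float:
    """Percent of the tract's streamlines intersecting the lesion."""
    idx = atlas.tract_indices(tract_name)
    hits = _streamline_hits(grid, [atlas.streamlines[i] for i in idx])
    return 100.0 * hits.sum() / idx.size


def disconnection_map(grid: VoxelGrid, atlas: StreamlineAtlas) -> np.ndarray:
    """Voxel-wise percent of traversing streamlines that hit the lesion.

    Voxels traversed by no streamline are 0.
    """
    through = np.zeros(grid.shape, dtype=np.int64)
    discon = np.zeros(grid.shape, dtype=np.int64)
    hits = _streamline_hits(grid, atlas.streamlines)
    for s, hit in zip(atlas.streamlines, hits):
        uniq = np.unique(s, axis=0)
        through[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
        if hit:
            discon[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    out = np.zeros(grid.shape, dtype=float)
    nz = through > 0
    out[nz] = 100.0 * discon[nz] / through[nz]
    return out


def _parcel_graph(atlas: ParcelAtlas, streams: StreamlineAtlas,
                  grid: VoxelGrid | None = None,
                  min_intact: int = 1) -> nx.Graph:
    """Parcel graph; an edge survives a lesion if >= min_intact supporting
    streamlines avoid it."""
    support: dict = {}
    lesioned = (_streamline_hits(grid, streams.streamlines)
                if grid is not None
                else np.zeros(len(streams.streamlines), dtype=bool))
    for s, hit in zip(streams.streamlines, lesioned):
        pa = atlas.parcel_of_voxel(s[0])
        pb = atlas.parcel_of_voxel(s[-1])
        if pa == 0 or pb == 0 or pa == pb:
            continue
        key = (min(pa, pb), max(pa, pb))
        support.setdefault(key, 0)
        if not hit:
            support[key] += 1
    g = nx.Graph()
    g.add_nodes_from(atlas.names)
    g.add_edges_from(k for k, n_ok in support.items()
                     if n_ok >= min_intact)
    return g


def sspl_delta(atlas: ParcelAtlas, streams: StreamlineAtlas,
               grid: VoxelGrid, pair: tuple, min_intact: int = 1) -> float:
    """Lesion-induced increase in structural shortest path length.

    SSPL between two parcels is the minimum number of parcel-to-parcel
    white-matter edges traversed (BFS hop count on the parcel graph). The
    delta is lesioned minus intact; a pair disconnected by the lesion
    yields ``math.inf`` (explicit sentinel, never a silently large number).

    Raises if the pair is unreachable in the intact atlas (atlas defect).
    """
    a, b = (atlas.parcel_id(pair[0]), atlas.parcel_id(pair[1]))
    intact = _parcel_graph(atlas, streams, None, min_intact)
    try:
        base = nx.shortest_path_length(intact, a, b)
    except nx.NetworkXNoPath:
        raise ValueError(
            f"pair {pair} unreachable in the intact atlas") from None
    lesioned = _parcel_graph(atlas, streams, grid, min_intact)
    try:
        after = nx.shortest_path_length(lesioned, a, b)
    except nx.NetworkXNoPath:
        return math.inf
    return float(after - base)


def sspl_matrix(atlas: ParcelAtlas, streams: StreamlineAtlas,
                grid: VoxelGrid | None = None,
                min_intact: int = 1) -> dict:
    """All-pairs SSPL (hop counts) on the (optionally lesioned) graph."""
    g = _parcel_graph(atlas, streams, grid, min_intact)
    out = {}
    for a, da in nx.all_pairs_shortest_path_length(g):
        for b, d in da.items():
            out[(a, b)] = float(d)
    return out


def flip_and_smooth(grid: VoxelGrid, fwhm_mm: float = 2.0,
                    flip_axis: int | None = None,
                    binarize: bool = False) -> VoxelGrid | np.ndarray:
    """Gaussian-smooth a lesion mask and optionally mirror it.

    Used to pool left- and right-hemisphere lesions for group heatmaps:
    smoothing at the stated FWHM, then a midline mirror along ``flip_axis``
    when the affected hemisphere must be flipped. With ``binarize`` the
    smoothed map is re-thresholded at 0.5 and returned as a VoxelGrid;
    otherwise the float map is returned.
    """
    from scipy import ndimage

    data = grid.mask.astype(float)
    if fwhm_mm > 0:
        sigma = [fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / v
                 for v in grid.voxel_size]
        data = ndimage.gaussian_filter(data, sigma=sigma)
    if flip_axis is not None:
        data = np.flip(data, axis=flip_axis)
    if binarize:
        return VoxelGrid(mask=(data >= 0.5).astype(np.uint8),
                         voxel_size=grid.voxel_size)
    return data


def extract_structural_features(
    grid: VoxelGrid,
    atlas: ParcelAtlas,
    streams: StreamlineAtlas,
    roi_names=("cM1", "cS1", "cS2", "iM1", "iS1", "iS2"),
    sspl_pairs=(("cM1", "cS1"), ("cS1", "cS2"), ("cM1", "cS2")),
    min_intact: int = 1,
    with_map: bool = False,
) -> StructuralFeatures:
    """Full structural summary for one subject."""
    damage = {r: roi_damage(grid, atlas, r) for r in roi_names}
    disc = {t: tract_disconnection(grid, streams, t)
            for t in PROJECTION_TRACTS + COMMISSURAL_TRACTS}
    proj = float(np.mean([disc[t] for t in PROJECTION_TRACTS]))
    comm = float(np.mean([disc[t] for t in COMMISSURAL_TRACTS]))
    sspl = {tuple(p): sspl_delta(atlas, streams, grid, p, min_intact)
            for p in sspl_pairs}
    dmap = disconnection_map(grid, streams) if with_map else None
    return StructuralFeatures(
        lesion_volume=lesion_volume(grid), roi_damage=damage,
        tract_disconnection=disc, projection_mean=proj,
        commissural_mean=comm, sspl_delta=sspl, disconnection_map=dmap)
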