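"""Atlas-based feature extraction.

Converts voxel-space data into the regional feature space used by the rest of
the pipeline: mean metric value per atlas region (weighted volumes, FA, MD),
streamline counts per region, region-averaged BOLD time series, and
subject-level Pearson functional-connectivity matrices.

The atlas is a 3-D integer label volume (0 = background).  Metric volumes must
be pre-aligned voxel-for-voxel with the atlas; no resampling or registration
is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LabelVolume",
    "ROITimeSeries",
    "region_mean",
    "streamline_counts",
    "roi_timeseries",
    "fc_matrix",
    "load_nifti",
    "save_nifti",
    "load_streamlines",
    "save_streamlines",
]


@dataclass
class LabelVolume:
    """Integer parcellation volume with voxel size in mm (corner-origin grid)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("label volume must be a non-empty 3-D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer-valued")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.data)
        return ids[ids != 0]


@dataclass
class ROITimeSeries:
    """T x R matrix of region-averaged signals."""

    data: np.ndarray
    region_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a T x R matrix")
        if self.data.shape[0] < 8:
            raise ValueError("time series must have at least 8 time points")
        if np.isnan(self.data).any():
            raise ValueError("time series contains missing values")


def _region_index(atlas: LabelVolume, region_ids=None) -> np.ndarray:
    if region_ids is None:
        region_ids = atlas.region_ids
    return np.asarray(region_ids)


def region_mean(metric: np.ndarray, atlas: LabelVolume, region_ids=None) -> np.ndarray:
    """Mean metric value over the voxels of each atlas region.

    Background voxels (label 0) are ignored.  A region id with no voxels
    yields NaN and a warning rather than a silent zero.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.shape != atlas.data.shape:
        raise ValueError(
            f"metric shape {metric.shape} does not match atlas shape {atlas.data.shape}"
        )
    ids = _region_index(atlas, region_ids)
    flat_labels = atlas.data.ravel()
    flat_metric = metric.ravel()
    n_bins = int(flat_labels.max()) + 1
    sums = np.bincount(flat_labels, weights=flat_metric, minlength=n_bins)
    counts = np.bincount(flat_labels, minlength=n_bins)
    out = np.full(len(ids), np.nan)
    for k, rid in enumerate(ids):
        if rid < n_bins and counts[rid] > 0:
            out[k] = sums[rid] / counts[rid]
        else:
            warnings.warn(f"region {rid} has no voxels; mean set to NaN", stacklevel=2)
    return out


def _points_to_voxels(points: np.ndarray, atlas: LabelVolume) -> np.ndarray:
    # nearest-voxel membership: floor(world coordinate / voxel size), corner origin
    vox = np.floor(points / np.asarray(atlas.voxel_size)).astype(int)
    return vox


def streamline_counts(
    streamlines, atlas: LabelVolume, region_ids=None
) -> np.ndarray:
    """Number of streamlines with at least one point inside each region.

    A streamline contributes at most once per region, but may contribute to
    several regions.  Points falling outside the grid are ignored; a
    streamline that is entirely out of the grid triggers a warning.
    """
    ids = _region_index(atlas, region_ids)
    pos = {int(rid): k for k, rid in enumerate(ids)}
    counts = np.zeros(len(ids), dtype=int)
    shape = np.asarray(atlas.data.shape)
    for sl in streamlines:
        pts = np.asarray(sl, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("each streamline must be an (n>=2) x 3 polyline")
        vox = _points_to_voxels(pts, atlas)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        if not inside.any():
            warnings.warn("streamline entirely outside the atlas grid", stacklevel=2)
            continue
        vox = vox[inside]
        hit = np.unique(atlas.data[vox[:, 0], vox[:, 1], vox[:, 2]])
        for rid in hit:
            if rid != 0 and int(rid) in pos:
                counts[pos[int(rid)]] += 1
    return counts


def roi_timeseries(
    bold: np.ndarray, atlas: LabelVolume, region_ids=None, subject_id: str = ""
) -> ROITimeSeries:
    """Average a 4-D BOLD series (x, y, z, t) within each atlas region."""
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4 or bold.shape[:3] != atlas.data.shape:
        raise ValueError("BOLD series must be 4-D with spatial shape equal to the atlas")
    ids = _region_index(atlas, region_ids)
    flat_labels = atlas.data.ravel()
    n_bins = int(flat_labels.max()) + 1
    counts = np.bincount(flat_labels, minlength=n_bins)
    T = bold.shape[3]
    series = np.empty((T, len(ids)))
    flat_bold = bold.reshape(-1, T)
    for k, rid in enumerate(ids):
        if rid >= n_bins or counts[rid] == 0:
            warnings.warn(f"region {rid} has no voxels; series set to NaN", stacklevel=2)
            series[:, k] = np.nan
            continue
        series[:, k] = flat_bold[flat_labels == rid].mean(axis=0)
    labels = [atlas.labels.get(int(r), f"R{int(r):03d}") for r in ids]
    ts = ROITimeSeries.__new__(ROITimeSeries)
    ts.data = series
    ts.region_labels = labels
    ts.subject_id = subject_id
    return ts


def fc_matrix(ts: ROITimeSeries | np.ndarray, region_labels=None) -> np.ndarray:
    """Pearson functional-connectivity matrix of region-averaged signals.

    Entry (i, j) is the Pearson correlation of columns i and j; the matrix is
    symmetric with unit diagonal.  A constant (zero-variance) column is an
    error naming the offending region, never a silent NaN.
    """
    if isinstance(ts, ROITimeSeries):
        data = ts.data
        region_labels = ts.region_labels
    else:
        data = np.asarray(ts, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("need a T x R matrix with T >= 3")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        name = region_labels[bad] if region_labels is not None else str(bad)
        raise ValueError(f"region {name} has a constant time series")
    corr = np.corrcoef(data, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# volume / streamline file formats (NIfTI via nibabel; TCK/TRK via
# nibabel.streamlines; a JSON polyline dialect for small text fixtures)

def load_nifti(path: str | Path, as_labels: bool = False):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if as_labels:
        return LabelVolume(np.rint(data).astype(int), voxel_size)
    return data.astype(float), voxel_size


def save_nifti(data: np.ndarray, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_streamlines(path: str | Path) -> list[np.ndarray]:
    path = Path(path)
    if path.suffix == ".json":
        import json

        with open(path) as fh:
            return [np.asarray(sl, dtype=float) for sl in json.load(fh)]
    import nibabel as nib

    tractogram = nib.streamlines.load(str(path))
    return [np.asarray(sl, dtype=float) for sl in tractogram.streamlines]


def save_streamlines(streamlines, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        import json

        with open(path, "w") as fh:
            json.dump([np.asarray(sl).tolist() for sl in streamlines], fh)
        return
    import nibabel as nib

    tractogram = nib.streamlines.Tractogram(
        [np.asarray(sl, dtype=float) for sl in streamlines], affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(tractogram, str(path))
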