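"""Voxel-wise map computation on 4-D diffusion-weighted volumes.

Processing chain for acquired (or synthetic) DW-MRI data:

1. geometric mean of the direction volumes per (waveform, b) group, with
   opposite-polarity pairs combined multiplicatively first so background
   gradient cross-terms cancel;
2. normalization of every group by its b = 0 volume and 3-D median filtering;
3. voxel-wise TDD contrast maps (difference of the two normalized maps of a
   waveform pair at matched b);
4. voxel-wise ADC maps per waveform from a log-linear fit over all b-values;
5. ROI statistics with Tukey-fence outlier exclusion
   (reject outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]).

Volumes are NIfTI-1 files with a JSON sidecar carrying per-volume b-value,
waveform id, effective diffusion time, direction and gradient polarity;
FSL-style bval/bvec files are also readable.  Motion, eddy-current and
susceptibility corrections are upstream of this module: inputs are assumed
co-registered.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "VolumeMeta",
    "DwImageSet",
    "RoiStats",
    "direction_geomean",
    "normalize_and_filter",
    "contrast_map",
    "adc_map",
    "roi_stats",
    "read_bvals_bvecs",
]


@dataclass(frozen=True)
class VolumeMeta:
    """Acquisition metadata of one 4-D volume."""

    b: float  # s/mm^2
    waveform_id: str
    td_ms: float
    direction: tuple = (1.0, 0.0, 0.0)
    polarity: int = 1

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "waveform_id": self.waveform_id,
            "td_ms": self.td_ms,
            "direction": list(self.direction),
            "polarity": self.polarity,
        }


@dataclass
class DwImageSet:
    """4-D DW volume stack with per-volume metadata.

    ``data`` has shape (x, y, z, n_volumes); ``meta[i]`` describes volume i.
    ``normalized`` marks sets whose volumes are S_b/S0 maps (enforced
    idempotence of the normalization stage).
    """

    data: np.ndarray
    meta: list
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size_mm: tuple = (3.0, 3.0, 5.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be a 4-D array (x, y, z, volume)")
        if self.data.shape[3] != len(self.meta):
            raise ValueError(
                f"{self.data.shape[3]} volumes but {len(self.meta)} metadata records"
            )

    # -- indexing helpers ---------------------------------------------------
    def volumes(
        self,
        waveform_id: Optional[str] = None,
        b: Optional[float] = None,
        polarity: Optional[int] = None,
    ) -> list:
        out = []
        for i, m in enumerate(self.meta):
            if waveform_id is not None and m.waveform_id != waveform_id:
                continue
            if b is not None and not np.isclose(m.b, b, rtol=1e-3, atol=0.5):
                continue
            if polarity is not None and m.polarity != polarity:
                continue
            out.append(i)
        return out

    def waveform_ids(self) -> list:
        seen = []
        for m in self.meta:
            if m.waveform_id not in seen:
                seen.append(m.waveform_id)
        return seen

    def b_values(self, waveform_id: str) -> list:
        bs = []
        for m in self.meta:
            if m.waveform_id == waveform_id and not any(
                np.isclose(m.b, x) for x in bs
            ):
                bs.append(float(m.b))
        return sorted(bs)

    def validate(self) -> None:
        """Check the acquisition structure needed by the pipeline."""
        for wid in self.waveform_ids():
            if not self.volumes(waveform_id=wid, b=0.0):
                raise ValueError(f"waveform {wid!r} has no b=0 volume")

    # -- IO -----------------------------------------------------------------
    def save(self, stem) -> tuple:
        """Write <stem>.nii + <stem>.json sidecar."""
        stem = Path(stem)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, 1.0))
        nii = stem.with_suffix(".nii")
        nib.save(img, nii)
        sidecar = stem.with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "voxel_size_mm": list(self.voxel_size_mm),
                    "normalized": self.normalized,
                    "volumes": [m.to_dict() for m in self.meta],
                },
                fh,
                indent=1,
            )
        return nii, sidecar

    @classmethod
    def load(cls, stem) -> "DwImageSet":
        stem = Path(stem)
        nii = stem if stem.suffix == ".nii" else stem.with_suffix(".nii")
        img = nib.load(nii)
        with open(nii.with_suffix(".json")) as fh:
            side = json.load(fh)
        meta = [
            VolumeMeta(
                b=float(m["b"]),
                waveform_id=m["waveform_id"],
                td_ms=float(m["td_ms"]),
                direction=tuple(m["direction"]),
                polarity=int(m["polarity"]),
            )
            for m in side["volumes"]
        ]
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            meta=meta,
            affine=img.affine,
            voxel_size_mm=tuple(side["voxel_size_mm"]),
            normalized=bool(side.get("normalized", False)),
        )


def read_bvals_bvecs(bval_path, bvec_path) -> tuple:
    """FSL-style bval/bvec readers (whitespace-separated, bvecs 3 x n)."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError("bval/bvec length mismatch")
    return bvals, bvecs


def direction_geomean(
    image_set: DwImageSet, waveform_id: str, b: float
) -> np.ndarray:
    """Voxel-wise geometric mean over the direction volumes of one group.

    Opposite-polarity volumes along the same direction are combined
    multiplicatively first: for signals ``exp(-b(D +/- eps))`` the background
    gradient cross-term ``eps`` cancels in ``sqrt(S+ . S-)``.  Non-positive
    voxels yield NaN (masked) rather than propagating through the log.
    """
    idx = image_set.volumes(waveform_id=waveform_id, b=b)
    if not idx:
        raise ValueError(f"no volumes for waveform {waveform_id!r} at b={b}")
    # group by direction, pairing +/- polarity
    groups: dict = {}
    for i in idx:
        key = tuple(np.round(image_set.meta[i].direction, 6))
        groups.setdefault(key, []).append(i)
    factors = []
    for key, ids in groups.items():
        vols = image_set.data[..., ids].astype(float)
        with np.errstate(invalid="ignore"):
            vols = np.where(vols > 0, vols, np.nan)
        # multiplicative polarity combination, then a per-direction value
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
            factors.append(np.exp(np.nanmean(np.log(vols), axis=-1)))
    stack = np.stack(factors, axis=-1)
    with np.errstate(invalid="ignore"):
        out = np.exp(np.mean(np.log(stack), axis=-1))
    return out


def normalize_and_filter(
    image_set: DwImageSet,
    median_size: int = 3,
    s0_threshold: float = 0.0,
    supersample: int = 1,
) -> DwImageSet:
    """Direction-averaged, b0-normalized, median-filtered S_b/S0 maps.

    One output volume per (waveform, b>0) group.  The 3-D median kernel is a
    3x3x3 neighbourhood on the native grid by default ("half the voxel size"
    rounds up to one voxel); ``supersample > 1`` applies the filter on a
    voxel-replicated grid instead and decimates back.  Voxels with S0 at or
    below ``s0_threshold`` are masked NaN.  Idempotent: a normalized set is
    returned unchanged.
    """
    if image_set.normalized:
        return image_set
    image_set.validate()
    out_vols = []
    out_meta = []
    for wid in image_set.waveform_ids():
        s0 = direction_geomean(image_set, wid, 0.0)
        s0 = np.where(s0 > s0_threshold, s0, np.nan)
        for b in image_set.b_values(wid):
            if b == 0.0:
                continue
            sb = direction_geomean(image_set, wid, b)
            ratio = sb / s0
            filt = _masked_median(ratio, median_size, supersample)
            out_vols.append(filt)
            m0 = image_set.meta[image_set.volumes(waveform_id=wid, b=b)[0]]
            out_meta.append(
                VolumeMeta(b=b, waveform_id=wid, td_ms=m0.td_ms, direction=(0, 0, 0))
            )
    return DwImageSet(
        data=np.stack(out_vols, axis=-1),
        meta=out_meta,
        affine=image_set.affine,
        voxel_size_mm=image_set.voxel_size_mm,
        normalized=True,
    )


def _masked_median(vol: np.ndarray, size: int, supersample: int = 1) -> np.ndarray:
    """Median filter that preserves the NaN mask of the input."""
    mask = np.isnan(vol)
    filled = np.where(mask, np.nanmedian(vol) if not mask.all() else 0.0, vol)
    if supersample > 1:
        big = np.repeat(
            np.repeat(np.repeat(filled, supersample, 0), supersample, 1),
            supersample,
            2,
        )
        big = median_filter(big, size=size, mode="nearest")
        filt = big[::supersample, ::supersample, ::supersample]
    else:
        filt = median_filter(filled, size=size, mode="nearest")
    return np.where(mask, np.nan, filt)


def contrast_map(
    normalized: DwImageSet, pair: tuple, b: float
) -> np.ndarray:
    """Voxel-wise TDD contrast map for a (long-td, short-td) waveform pair.

    ``pair`` lists waveform ids, long diffusion time first; both members must
    be present at ``b``.  Masked (NaN) where either input is masked.
    """
    if not normalized.normalized:
        raise ValueError("contrast_map expects a normalized image set")
    vols = []
    tds = []
    for wid in pair:
        idx = normalized.volumes(waveform_id=wid, b=b)
        if len(idx) != 1:
            raise ValueError(
                f"expected one normalized volume for {wid!r} at b={b}, got {len(idx)}"
            )
        vols.append(normalized.data[..., idx[0]])
        tds.append(normalized.meta[idx[0]].td_ms)
    if tds[0] <= tds[1]:
        raise ValueError(
            f"pair ordering: td({pair[0]})={tds[0]} must exceed td({pair[1]})={tds[1]}"
        )
    return vols[0] - vols[1]


def adc_map(normalized: DwImageSet, waveform_id: str) -> np.ndarray:
    """Voxel-wise ADC (mm^2/s) for one waveform from all its b-values.

    Ordinary least squares of ``-ln(S/S0)`` against b, including the implicit
    (b=0, ln 1) point.  Voxels with fewer than two valid points are NaN.
    """
    if not normalized.normalized:
        raise ValueError("adc_map expects a normalized image set")
    idx = normalized.volumes(waveform_id=waveform_id)
    if not idx:
        raise ValueError(f"no volumes for waveform {waveform_id!r}")
    bs = np.array([0.0] + [normalized.meta[i].b for i in idx])
    if bs.size < 2:
        raise ValueError("need at least one non-zero b-value")
    sig = np.concatenate(
        [np.ones(normalized.data.shape[:3] + (1,)), normalized.data[..., idx]],
        axis=-1,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(sig > 0, -np.log(sig), np.nan)
    valid = np.isfinite(y)
    n = valid.sum(axis=-1).astype(float)
    bsafe = np.broadcast_to(bs, y.shape)
    bx = np.where(valid, bsafe, 0.0)
    yx = np.where(valid, y, 0.0)
    sb = bx.sum(-1)
    sy = yx.sum(-1)
    sbb = (bx * bx).sum(-1)
    sby = (bx * yx).sum(-1)
    denom = n * sbb - sb * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where((n >= 2) & (denom > 0), (n * sby - sb * sy) / denom, np.nan)
    return slope  # per (s/mm^2) == mm^2/s


@dataclass(frozen=True)
class RoiStats:
    """ROI summary after Tukey-fence outlier exclusion."""

    roi_id: str
    mean: float
    sd: float
    n_before: int
    n_after: int


def roi_stats(map_volume: np.ndarray, roi_mask: np.ndarray, roi_id: str = "roi") -> RoiStats:
    """Mean +/- SD within a mask, excluding Tukey-fence outliers.

    Values beyond 1.5 interquartile ranges above Q3 or below Q1 are excluded
    (linear-interpolation quantiles).  NaN voxels are ignored up front.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != map_volume.shape:
        raise ValueError("ROI mask shape must match the map")
    vals = map_volume[mask]
    vals = vals[np.isfinite(vals)]
    n_before = int(vals.size)
    if n_before == 0:
        raise ValueError("ROI is empty (or fully masked)")
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    iqr = q3 - q1
    keep = (vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)
    kept = vals[keep]
    if kept.size == 0:
        raise ValueError("all ROI voxels excluded by the outlier fences")
    return RoiStats(
        roi_id=roi_id,
        mean=float(kept.mean()),
        sd=float(kept.std(ddof=1)) if kept.size > 1 else 0.0,
        n_before=n_before,
        n_after=int(kept.size),
    )
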