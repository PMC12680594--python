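"""Shared containers for image volumes, vessel networks and emission traces.

Physical coordinates are always micrometres.  Arrays are indexed (z, y, x)
and the voxel with index ``i`` along an axis has its physical centre at
``i * spacing_um[axis]``; anisotropic spacing (z coarser than in-plane) is
the norm for light-sheet and confocal stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageVolume",
    "VesselNetwork",
    "EmissionTrace",
    "ridge_intervessel_distance",
]

_CHANNELS = ("vascular", "drug", "label")


@dataclass
class ImageVolume:
    """A 3D scalar field with per-axis voxel spacing in µm.

    Parameters
    ----------
    voxels
        Non-negative 3D array, indexed (z, y, x).
    spacing_um
        Voxel edge lengths ``(z, y, x)`` in µm; all positive.
    channel
        One of ``"vascular"``, ``"drug"`` or ``"label"``.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    channel: str = "label"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive lengths")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}")
        if np.issubdtype(self.voxels.dtype, np.floating) and np.any(
            self.voxels < 0
        ):
            raise ValueError("voxels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical span from first to last voxel centre along each axis."""
        return tuple(
            (n - 1) * s for n, s in zip(self.voxels.shape, self.spacing_um)
        )

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar with the spacing."""
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.voxels))
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"spacing_um": list(self.spacing_um), "channel": self.channel}
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        path = Path(path)
        voxels = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            voxels=voxels,
            spacing_um=tuple(meta["spacing_um"]),
            channel=meta.get("channel", "label"),
        )


@dataclass
class VesselNetwork:
    """Ground-truth vessel geometry: centreline polylines plus radii.

    ``segments`` is a list of ``(points, radius_um)`` where ``points`` is an
    ``(n, 3)`` array of (z, y, x) positions in µm and ``radius_um`` a single
    positive radius for the whole segment.  ``box_um`` is the (z, y, x)
    physical extent that contains every point.
    """

    segments: list[tuple[np.ndarray, float]]
    box_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.box_um = tuple(float(b) for b in self.box_um)
        cleaned = []
        for pts, r in self.segments:
            pts = np.atleast_2d(np.asarray(pts, dtype=float))
            if pts.shape[1] != 3:
                raise ValueError("segment points must be (n, 3)")
            if r <= 0:
                raise ValueError("all radii must be positive")
            if np.any(pts < -1e-9) or np.any(
                pts > np.asarray(self.box_um) + 1e-9
            ):
                raise ValueError("segment points fall outside the bounding box")
            cleaned.append((pts, float(r)))
        self.segments = cleaned

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def radii_um(self) -> np.ndarray:
        return np.array([r for _, r in self.segments])

    def to_frame(self) -> pd.DataFrame:
        """One row per polyline vertex: segment id, x, y, z, radius."""
        rows = []
        for sid, (pts, r) in enumerate(self.segments):
            for z, y, x in pts:
                rows.append((sid, x, y, z, r))
        return pd.DataFrame(
            rows, columns=["segment_id", "x_um", "y_um", "z_um", "radius_um"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, box_um: Sequence[float] | None = None
    ) -> "VesselNetwork":
        segments = []
        for _, grp in frame.groupby("segment_id", sort=True):
            pts = grp[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
            segments.append((pts, float(grp["radius_um"].iloc[0])))
        if box_um is None:
            allpts = np.vstack([p for p, _ in segments])
            box_um = tuple(allpts.max(axis=0))
        return cls(segments=segments, box_um=tuple(box_um))

    @classmethod
    def from_csv(
        cls, path: str | Path, box_um: Sequence[float] | None = None
    ) -> "VesselNetwork":
        return cls.from_frame(pd.read_csv(path), box_um=box_um)


@dataclass
class EmissionTrace:
    """Per-pulse ultraharmonic amplitudes for the sonication controller.

    ``baseline_samples`` holds the calibration recording (low, constant
    pressure).  Treatment emissions may depend on the commanded pressure, so
    they are exposed through :meth:`emission`, which the controller calls at
    run time with the pulse index and the pressure it is about to deliver.
    """

    baseline_samples: np.ndarray
    n_pulses: int
    _emission_fn: Callable[[int, float], float]
    seed: int | None = None
    baseline_pressure_kPa: float = field(default=28.0)

    def __post_init__(self) -> None:
        self.baseline_samples = np.asarray(self.baseline_samples, dtype=float)
        if self.baseline_samples.size < 1:
            raise ValueError("baseline must contain at least one sample")
        if not np.all(np.isfinite(self.baseline_samples)):
            raise ValueError("baseline amplitudes must be finite")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")

    def emission(self, pulse: int, pressure_kPa: float) -> float:
        """Ultraharmonic amplitude of ``pulse`` delivered at ``pressure_kPa``."""
        if not 0 <= pulse < self.n_pulses:
            raise IndexError("pulse index outside the trace")
        value = float(self._emission_fn(pulse, float(pressure_kPa)))
        if not np.isfinite(value):
            raise ValueError("emission amplitude must be finite")
        return value


def ridge_intervessel_distance(
    distance_um: np.ndarray,
    lumen_mask: np.ndarray,
    tissue_mask: np.ndarray,
    spacing_um: Sequence[float],
) -> tuple[float, np.ndarray]:
    """Tissue inter-vessel distance from the ridge of a distance field.

    The ridge is the topographic crest of the vessel distance field: the
    midlines where the influence zones of distinct vessels meet.  It is
    detected as the boundary between Voronoi regions of distinct lumen
    components, which is robust to the staircase artifacts of discrete
    distance transforms; when the lumen forms a single connected component
    the detector falls back to axis-wise strict local maxima.  The tissue
    inter-vessel distance is twice the mean ridge value, i.e. the mean
    surface-to-surface spacing between nearest vessels.

    Voxels closer to the volume border than to their nearest vessel are
    excluded (their true nearest vessel may lie outside the field of view).

    Returns ``(ivd_um, ridge_mask)``.
    """
    from scipy import ndimage

    d = np.asarray(distance_um, dtype=float)
    lumen = np.asarray(lumen_mask, dtype=bool)
    tissue = np.asarray(tissue_mask, dtype=bool)
    if not np.any(lumen & tissue):
        raise ValueError("no lumen voxels inside the tissue mask")

    candidate = tissue & ~lumen & (d > 0)
    components, n_comp = ndimage.label(lumen, structure=np.ones((3, 3, 3)))
    ridge = np.zeros_like(candidate)
    if n_comp >= 2:
        _, idx = ndimage.distance_transform_edt(
            ~lumen, sampling=tuple(spacing_um), return_indices=True
        )
        comp_of = components[tuple(idx)]
        for axis in range(3):
            same_lo = comp_of == np.roll(comp_of, 1, axis=axis)
            same_hi = comp_of == np.roll(comp_of, -1, axis=axis)
            sl_first = [slice(None)] * 3
            sl_first[axis] = slice(0, 1)
            same_lo[tuple(sl_first)] = True
            sl_last = [slice(None)] * 3
            sl_last[axis] = slice(-1, None)
            same_hi[tuple(sl_last)] = True
            ridge |= ~(same_lo & same_hi)
    else:
        for axis in range(3):
            lo = np.roll(d, 1, axis=axis)
            hi = np.roll(d, -1, axis=axis)
            sl_first = [slice(None)] * 3
            sl_first[axis] = slice(0, 1)
            lo[tuple(sl_first)] = -np.inf
            sl_last = [slice(None)] * 3
            sl_last[axis] = slice(-1, None)
            hi[tuple(sl_last)] = -np.inf
            # strict on at least one side, so directions along which the
            # field is flat (e.g. along a vessel's axis) do not qualify
            ridge |= (d >= lo) & (d >= hi) & ((d > lo) | (d > hi))
    ridge &= candidate

    # guard zone: drop ridge voxels whose nearest vessel could be outside
    # the imaged volume
    border = np.full_like(d, np.inf)
    for axis, s in enumerate(spacing_um):
        idx = np.arange(d.shape[axis], dtype=float)
        dist_axis = np.minimum(idx, idx[::-1]) * float(s)
        shape = [1, 1, 1]
        shape[axis] = -1
        border = np.minimum(border, dist_axis.reshape(shape))
    guarded = ridge & (border >= d)
    if not np.any(guarded):
        # volume too small to contain complete inter-vessel midlines:
        # fall back to the unguarded ridge (a border-limited lower bound)
        guarded = ridge
    if not np.any(guarded):
        raise ValueError("empty ridge set; volume too small for the vasculature")
    return float(2.0 * d[guarded].mean()), guarded
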