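"""Image stacks, label masks, and the readers/writers shared by every stage.

Conventions
-----------
* Pixel indices are 0-based and ordered ``(slice, row, col)``; cine stacks
  carry the cardiac phase as a trailing fourth axis ``(slice, row, col, phase)``.
* The mm frame has its origin at the corner of the first voxel; mm positions
  refer to pixel centers, so pixel ``(r, c)`` sits at
  ``((r + 0.5) * spacing_row, (c + 0.5) * spacing_col)``.
* Masks are per-slice PNGs encoded 0/255 and named
  ``{label}_s{slice:02d}_p{phase:02d}.png``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import nibabel as nib
import tifffile
from matplotlib.path import Path as _MplPath
from PIL import Image

MODALITIES = ("cine", "lge-magnitude", "lge-psir", "b1", "ttc-photo")

MASK_LABELS = (
    "myocardium",
    "blood_pool",
    "infarct_hyper",
    "infarct_hypo",
    "remote_roi",
    "fwhm_roi",
    "noise_roi",
    "papillary",
)


@dataclass
class ImageStack:
    """A raster volume with physical spacing metadata.

    Parameters
    ----------
    voxels
        Array of shape ``(slice, row, col)`` or ``(slice, row, col, phase)``.
    pixel_spacing
        In-plane spacing ``(row_mm, col_mm)`` in mm/pixel.
    slice_thickness_mm
        Slice thickness in mm (slices are assumed contiguous, no gap).
    modality
        One of :data:`MODALITIES`.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness_mm: float
    modality: str = "cine"
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(
                f"voxels must be 3D or 4D (slice,row,col[,phase]); got {self.voxels.ndim}D"
            )
        sr, sc = self.pixel_spacing
        if sr <= 0 or sc <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        if self.slice_thickness_mm <= 0:
            raise ValueError(f"slice thickness must be positive, got {self.slice_thickness_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape2d(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    @property
    def n_phases(self) -> int | None:
        return self.voxels.shape[3] if self.voxels.ndim == 4 else None

    @property
    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.pixel_spacing, self.slice_thickness_mm)

    def phase(self, p: int) -> "ImageStack":
        """Extract one cardiac phase as a 3D stack."""
        if self.voxels.ndim != 4:
            raise ValueError("stack has no phase axis")
        return replace(self, voxels=self.voxels[..., p])


def voxel_volume_mm3(pixel_spacing: tuple[float, float], slice_thickness_mm: float) -> float:
    """Volume of one voxel in mm³ from in-plane spacing and slice thickness."""
    return float(pixel_spacing[0] * pixel_spacing[1] * slice_thickness_mm)


@dataclass
class LabelMaskSet:
    """Per-slice binary masks keyed by anatomical label.

    ``masks[label]`` is a boolean array ``(slice, row, col)`` aligned to a
    reference :class:`ImageStack` at ``phase_index`` (or to a 3D stack).
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    phase_index: int | None = None

    def __post_init__(self) -> None:
        for label, m in self.masks.items():
            self.masks[label] = np.asarray(m, dtype=bool)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.masks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.masks

    def labels(self) -> list[str]:
        return sorted(self.masks)

    def validate(self, stack: ImageStack | None = None) -> None:
        """Check shape agreement and anatomical consistency.

        Myocardium and blood pool must be disjoint; infarct labels must lie
        inside the myocardium.
        """
        shapes = {label: m.shape for label, m in self.masks.items()}
        if stack is not None:
            expected = (stack.n_slices, *stack.shape2d)
            for label, shape in shapes.items():
                if shape != expected:
                    raise ValueError(f"mask {label!r} shape {shape} != stack shape {expected}")
        elif len({s for s in shapes.values()}) > 1:
            raise ValueError(f"mask shapes disagree: {shapes}")
        if "myocardium" in self.masks and "blood_pool" in self.masks:
            if np.any(self.masks["myocardium"] & self.masks["blood_pool"]):
                raise ValueError("myocardium and blood_pool masks overlap")
        for label in ("infarct_hyper", "infarct_hypo"):
            if label in self.masks and "myocardium" in self.masks:
                outside = self.masks[label] & ~self.masks["myocardium"]
                if np.any(outside):
                    idx = np.argwhere(outside)[:5]
                    raise ValueError(
                        f"{label} extends outside myocardium at (slice,row,col) {idx.tolist()} ..."
                    )


# -- PNG masks -----------------------------------------------------------------


def read_mask_png(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Read a single-slice binary mask from PNG; nonzero pixels are True."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse RGB(A) to one channel
        arr = arr[..., :3].max(axis=-1)
    if arr.shape != tuple(shape):
        raise ValueError(f"mask {path} has shape {arr.shape}, expected {tuple(shape)}")
    return arr > 0


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit 0/255 PNG (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got {mask.ndim}D")
    Image.fromarray(np.where(mask.astype(bool), 255, 0).astype(np.uint8)).save(path)
    return path


def mask_filename(label: str, slice_index: int, phase_index: int = 0) -> str:
    return f"{label}_s{slice_index:02d}_p{phase_index:02d}.png"


def write_mask_set(masks: LabelMaskSet, out_dir: str | Path, phase_index: int | None = None) -> list[Path]:
    """Write every slice of every label as PNG under ``out_dir``."""
    out_dir = Path(out_dir)
    p = phase_index if phase_index is not None else (masks.phase_index or 0)
    written = []
    for label, vol in masks.masks.items():
        for s in range(vol.shape[0]):
            written.append(write_mask_png(vol[s], out_dir / mask_filename(label, s, p)))
    return written


def read_mask_set(in_dir: str | Path, labels: list[str], n_slices: int,
                  shape: tuple[int, int], phase_index: int = 0) -> LabelMaskSet:
    """Read per-slice PNGs written by :func:`write_mask_set`."""
    in_dir = Path(in_dir)
    masks = {}
    for label in labels:
        vol = np.zeros((n_slices, *shape), dtype=bool)
        for s in range(n_slices):
            vol[s] = read_mask_png(in_dir / mask_filename(label, s, phase_index), shape)
        masks[label] = vol
    return LabelMaskSet(masks=masks, phase_index=phase_index)


# -- contours ------------------------------------------------------------------


def contours_to_mask(polygons, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize closed polygon(s) to a binary mask by pixel-center inclusion.

    ``polygons`` is one ``(N, 2)`` array of ``(row, col)`` pixel coordinates or
    a list of them; multiple polygons are OR-combined. An annulus is obtained
    by subtracting the endocardial fill from the epicardial fill. A pixel is
    included iff its center lies inside or on the polygon boundary. The
    polygon is treated as closed (last vertex joins the first); a degenerate
    polygon with fewer than 3 distinct vertices yields an empty mask.
    """
    if isinstance(polygons, np.ndarray) and polygons.ndim == 2:
        polygons = [polygons]
    out = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    centers = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2:
            raise ValueError(f"polygon must be (N,2), got {poly.shape}")
        if len(np.unique(poly, axis=0)) < 3:  # degenerate: zero area
            continue
        path = _MplPath(poly, closed=False)
        # the sign of `radius` follows the polygon winding; querying both
        # signs with a tiny radius counts boundary centers as inside
        # regardless of orientation
        inside = (path.contains_points(centers, radius=1e-9)
                  | path.contains_points(centers, radius=-1e-9))
        out |= inside.reshape(shape)
    return out


# -- stacks --------------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` to NIfTI (``.nii``/``.nii.gz``) or TIFF.

    NIfTI stores spacing in the affine/zooms; TIFF gets a JSON sidecar
    ``<path>.json`` with spacing, thickness and modality.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = "".join(path.suffixes)
    if suffix.endswith((".nii", ".nii.gz")):
        # nibabel expects (x, y, z[, t]); we map (slice,row,col[,phase]) -> (col,row,slice[,phase])
        data = np.moveaxis(stack.voxels, (0, 1, 2), (2, 1, 0))
        zooms = (stack.pixel_spacing[1], stack.pixel_spacing[0], stack.slice_thickness_mm)
        affine = np.diag([*zooms, 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(zooms + ((1.0,) if data.ndim == 4 else ()))
        img.header["descrip"] = stack.modality.encode()[:79]
        nib.save(img, str(path))
    elif suffix.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, stack.voxels)
        sidecar = {
            "pixel_spacing": list(stack.pixel_spacing),
            "slice_thickness_mm": stack.slice_thickness_mm,
            "modality": stack.modality,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported stack format: {path.name} (use .nii[.gz] or .tif[f])")
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`, restoring spacing metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = "".join(path.suffixes)
    if suffix.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.moveaxis(np.asarray(img.dataobj), (2, 1, 0), (0, 1, 2))
        modality = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "cine"
        return ImageStack(
            voxels=data,
            pixel_spacing=(float(zooms[1]), float(zooms[0])),
            slice_thickness_mm=float(zooms[2]),
            modality=modality if modality in MODALITIES else "cine",
        )
    if suffix.endswith((".tif", ".tiff")):
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise ValueError(
                f"TIFF stack {path} lacks its spacing sidecar {sidecar_path.name}; "
                "pixel spacing metadata is required"
            )
        meta = json.loads(sidecar_path.read_text())
        return ImageStack(
            voxels=tifffile.imread(path),
            pixel_spacing=tuple(meta["pixel_spacing"]),
            slice_thickness_mm=meta["slice_thickness_mm"],
            modality=meta["modality"],
        )
    raise ValueError(f"unsupported stack format: {path.name}")
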