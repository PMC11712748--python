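"""File I/O: volumes (NIfTI/NRRD), structure sets, fluence maps, DICOM-RT.

Volumes round-trip exactly (values, spacing, origin) through SimpleITK.
Structure sets are stored either as one labelmap plus a JSON role manifest
or as one mask file per structure.  Fluence maps use a plain-text matrix
dialect with a header (grid size, pixel size, beam id) for TPS-style
exchange.  A minimal DICOM-RT reader (CT series + RTSTRUCT contour
rasterisation) feeds the same in-memory types.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fluence import FluenceMap
from .volumes import Role, StructureSet, VoxelVolume

__all__ = [
    "read_volume", "write_volume",
    "read_structures", "write_structures",
    "read_fluence", "write_fluence",
    "read_dicom_ct", "read_dicom_rtstruct",
]

_FORMATS = {".nii": "nifti", ".gz": "nifti", ".nrrd": "nrrd", ".mha": "meta"}


def _check_format(path: Path) -> None:
    if path.suffix.lower() not in _FORMATS:
        raise ValueError(
            f"unsupported volume format {path.suffix!r}; use .nii/.nii.gz/.nrrd/.mha"
        )


def write_volume(volume: VoxelVolume, path) -> Path:
    import SimpleITK as sitk

    path = Path(path)
    _check_format(path)
    # SimpleITK arrays are (z, y, x); ours are (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing_mm))
    img.SetOrigin(tuple(volume.origin_mm))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def read_volume(path, unit: str = "HU") -> VoxelVolume:
    import SimpleITK as sitk

    path = Path(path)
    _check_format(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelVolume(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()), unit=unit)


def write_structures(structures: StructureSet, out_dir, mode: str = "labelmap") -> Path:
    """Store a structure set as labelmap+manifest or one mask per structure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"mode": mode, "structures": {}}
    ref = structures.reference

    if mode == "labelmap":
        label = np.zeros(ref.shape, dtype=np.float64)
        overlap_layers: list[tuple[str, int]] = []
        for i, name in enumerate(structures.names, start=1):
            label[structures[name]] = i  # later structures win on overlap
            overlap_layers.append((name, i))
        # overlapping structures make a single labelmap lossy; store each
        # mask's own file when any overlap exists
        total = sum(int(structures[n].sum()) for n in structures.names)
        if total != int((label > 0).sum()):
            return write_structures(structures, out_dir, mode="masks")
        write_volume(ref.with_values(label, unit="unitless"), out_dir / "labelmap.nrrd")
        for name, i in overlap_layers:
            manifest["structures"][name] = {
                "label": i,
                "role": structures.roles[name].value,
                "rx_gy": structures.rx_gy.get(name),
            }
    elif mode == "masks":
        for name in structures.names:
            write_volume(
                ref.with_values(structures[name].astype(np.float64), unit="unitless"),
                out_dir / f"{name}.nrrd",
            )
            manifest["structures"][name] = {
                "file": f"{name}.nrrd",
                "role": structures.roles[name].value,
                "rx_gy": structures.rx_gy.get(name),
            }
    else:
        raise ValueError(f"unknown structure mode {mode!r}")

    (out_dir / "structures.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def read_structures(in_dir, reference: VoxelVolume) -> StructureSet:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "structures.json").read_text())
    structures = StructureSet(reference)

    if manifest["mode"] == "labelmap":
        label_vol = read_volume(in_dir / "labelmap.nrrd", unit="unitless")
        _check_grid(label_vol, reference)
        for name, info in manifest["structures"].items():
            mask = label_vol.values == info["label"]
            structures.add(name, mask, Role(info["role"]), rx_gy=info.get("rx_gy"))
    else:
        for name, info in manifest["structures"].items():
            mv = read_volume(in_dir / info["file"], unit="unitless")
            _check_grid(mv, reference)
            structures.add(name, mv.values > 0.5, Role(info["role"]),
                           rx_gy=info.get("rx_gy"))
    return structures


def _check_grid(mask_vol: VoxelVolume, reference: VoxelVolume) -> None:
    if mask_vol.shape != reference.shape or not np.allclose(
        mask_vol.spacing_mm, reference.spacing_mm
    ):
        raise ValueError(
            f"mask grid {mask_vol.shape}/{mask_vol.spacing_mm} does not match "
            f"reference {reference.shape}/{reference.spacing_mm}"
        )


# -- fluence text format ------------------------------------------------------

_FLUENCE_MAGIC = "# hnplan-fluence v1"


def write_fluence(fmap: FluenceMap, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"{_FLUENCE_MAGIC}\n"
        f"# beam {fmap.beam_index} pixel_mm {fmap.pixel_mm!r} "
        f"shape {fmap.values.shape[0]} {fmap.values.shape[1]} "
        f"jaw_clipped {int(fmap.jaw_clipped)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, fmap.values, fmt="%.17g")
    return path


def read_fluence(path) -> FluenceMap:
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _FLUENCE_MAGIC:
            raise ValueError(f"{path}: not an hnplan fluence file (header {magic!r})")
        fields = fh.readline().split()
        # "# beam I pixel_mm P shape NU NV jaw_clipped C"
        beam = int(fields[2])
        pixel_mm = float(fields[4])
        shape = (int(fields[6]), int(fields[7]))
        clipped = bool(int(fields[9]))
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if values.shape != shape:
        raise ValueError(f"{path}: header says {shape}, matrix is {values.shape}")
    if shape != (128, 128):
        raise ValueError(f"{path}: fluence grid must be 128 x 128, got {shape}")
    return FluenceMap(values, beam, pixel_mm, jaw_clipped=clipped)


# -- optional DICOM-RT ingest -------------------------------------------------

def read_dicom_ct(series_dir) -> VoxelVolume:
    """Read a single-frame CT series (sorted by slice position) as a volume."""
    import pydicom

    files = sorted(Path(series_dir).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {series_dir}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)  # row, column spacing
    zs = [float(s.ImagePositionPatient[2]) for s in slices]
    dz = zs[1] - zs[0] if len(zs) > 1 else float(getattr(first, "SliceThickness", 1.0))
    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        arr = arr * float(getattr(s, "RescaleSlope", 1.0)) + float(
            getattr(s, "RescaleIntercept", 0.0)
        )
        planes.append(arr)  # (rows=y, cols=x)
    values = np.stack(planes, axis=-1).transpose(1, 0, 2)  # -> (x, y, z)
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        zs[0],
    )
    return VoxelVolume(values, (dx, dy, dz), origin, unit="HU")


def read_dicom_rtstruct(path, reference: VoxelVolume,
                        roles: dict[str, str] | None = None,
                        rx_gy: dict[str, float] | None = None) -> StructureSet:
    """Rasterise RTSTRUCT planar contours onto the reference grid.

    ``roles`` maps ROI names to role strings (default OAR, 'body'->BODY by
    name); contours are filled per axial slice with an even-odd polygon rule.
    """
    import pydicom
    from matplotlib.path import Path as MplPath

    ds = pydicom.dcmread(str(path))
    roi_names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    structures = StructureSet(reference)
    roles = roles or {}
    rx_gy = rx_gy or {}

    xg = reference.axis_coords(0)
    yg = reference.axis_coords(1)
    XX, YY = np.meshgrid(xg, yg, indexing="ij")
    grid_pts = np.column_stack([XX.ravel(), YY.ravel()])
    zg = reference.axis_coords(2)

    for roi in ds.ROIContourSequence:
        name = roi_names[int(roi.ReferencedROINumber)]
        mask = np.zeros(reference.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, float).reshape(-1, 3)
            k = int(np.argmin(np.abs(zg - pts[0, 2])))
            poly = MplPath(pts[:, :2])
            inside = poly.contains_points(grid_pts).reshape(XX.shape)
            mask[:, :, k] ^= inside  # even-odd rule for holes
        key = name.strip().lower().replace(" ", "_")
        role = roles.get(name, roles.get(key, "BODY" if key == "body" else "OAR"))
        structures.add(key, mask, Role(role), rx_gy=rx_gy.get(name, rx_gy.get(key)))
    return structures
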