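"""NIfTI input/output for studies, label volumes and masks.

One imaging *study* is a co-registered set of volumes acquired at a single
time point: T1 post-contrast and T2/FLAIR intensities, the labeled brain
domain, and manual segmentation masks (enhancing tumor, edema, optionally
necrotic core and resection cavity).  A plain-text manifest (``key = value``
per line) names the files and the acquisition day so a study can be loaded
with one path.

Conventions: masks are 0/1 integer volumes; tissue labels follow the code
table in :mod:`gliosim.grids`; voxel spacing is taken from the NIfTI header
zooms and affine orientation is otherwise ignored (inputs are assumed
co-registered).  Resection-cavity voxels are relabeled as CSF at load time:
the cavity is fluid-filled, carries no cells and admits no flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

from .grids import VALID_LABELS, TissueLabel, VoxelGrid

__all__ = [
    "ImagingStudy",
    "StudyPair",
    "read_volume",
    "load_study",
    "load_study_manifest",
    "write_volume",
    "write_study",
    "write_result_masks",
]

REQUIRED_KEYS = ("t1c", "t2", "labels", "enhancing", "edema")
OPTIONAL_KEYS = ("necrotic", "cavity")


@dataclass
class ImagingStudy:
    """Co-registered intensity volumes and segmentations at one time point."""

    grid: VoxelGrid
    t1c: np.ndarray
    t2: np.ndarray
    enhancing_mask: np.ndarray
    edema_mask: np.ndarray
    necrotic_mask: Optional[np.ndarray] = None
    cavity_mask: Optional[np.ndarray] = None
    day: int = 0

    def __post_init__(self) -> None:
        dims = self.grid.dims
        self.t1c = np.asarray(self.t1c, dtype=float)
        self.t2 = np.asarray(self.t2, dtype=float)
        self.enhancing_mask = np.asarray(self.enhancing_mask).astype(bool)
        self.edema_mask = np.asarray(self.edema_mask).astype(bool)
        if self.necrotic_mask is not None:
            self.necrotic_mask = np.asarray(self.necrotic_mask).astype(bool)
        if self.cavity_mask is not None:
            self.cavity_mask = np.asarray(self.cavity_mask).astype(bool)
        self.day = int(self.day)

        vols = {
            "t1c": self.t1c,
            "t2": self.t2,
            "enhancing": self.enhancing_mask,
            "edema": self.edema_mask,
        }
        if self.necrotic_mask is not None:
            vols["necrotic"] = self.necrotic_mask
        if self.cavity_mask is not None:
            vols["cavity"] = self.cavity_mask
        for name, v in vols.items():
            if v.shape != dims:
                raise ValueError(f"{name} volume shape {v.shape} != grid dims {dims}")
        for name in ("t1c", "t2"):
            v = vols[name]
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} intensities must be finite")
            if v.min() < 0:
                raise ValueError(f"{name} intensities must be >= 0")

        named = [("enhancing", self.enhancing_mask), ("edema", self.edema_mask)]
        if self.necrotic_mask is not None:
            named.append(("necrotic", self.necrotic_mask))
        for i in range(len(named)):
            for j in range(i + 1, len(named)):
                overlap = int(np.count_nonzero(named[i][1] & named[j][1]))
                if overlap:
                    raise ValueError(
                        f"masks '{named[i][0]}' and '{named[j][0]}' overlap "
                        f"in {overlap} voxel(s)"
                    )
        tissue = self.grid.tissue_mask
        for name, m in named:
            outside = int(np.count_nonzero(m & ~tissue))
            if outside:
                raise ValueError(
                    f"mask '{name}' covers {outside} voxel(s) outside "
                    "gray/white tissue (BACKGROUND or CSF)"
                )

    @property
    def enhancing_count(self) -> int:
        return int(np.count_nonzero(self.enhancing_mask))


@dataclass
class StudyPair:
    """A baseline and follow-up study separated by a positive interval."""

    baseline: ImagingStudy
    followup: ImagingStudy

    def __post_init__(self) -> None:
        if self.baseline.grid.dims != self.followup.grid.dims:
            raise ValueError(
                f"baseline dims {self.baseline.grid.dims} != "
                f"followup dims {self.followup.grid.dims}"
            )
        if self.interval_days <= 0:
            raise ValueError(
                f"followup day {self.followup.day} must exceed baseline day "
                f"{self.baseline.day}"
            )

    @property
    def interval_days(self) -> int:
        return self.followup.day - self.baseline.day


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(
    path: Path | str,
    expected_grid: Optional[VoxelGrid] = None,
    kind: str = "intensity",
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D NIfTI volume; returns (array, spacing-in-mm).

    ``kind`` selects validation: ``"intensity"`` (finite values),
    ``"label"`` (codes from the tissue table), ``"mask"`` (0/1).  If
    ``expected_grid`` is given, the volume dimensions must match it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3-D image (ndim={data.ndim})")
    spacing = _spacing_from_header(img)
    if expected_grid is not None and tuple(data.shape) != expected_grid.dims:
        raise ValueError(
            f"{path}: dims {tuple(data.shape)} do not match expected "
            f"{expected_grid.dims}"
        )
    if kind == "label":
        codes = set(np.unique(data).astype(int).tolist())
        bad = codes - VALID_LABELS
        if bad or not np.all(data == np.round(data)):
            raise ValueError(
                f"{path}: invalid tissue label code(s) {sorted(bad) or data.dtype}; "
                f"expected {sorted(VALID_LABELS)}"
            )
        data = data.astype(np.uint8)
    elif kind == "mask":
        vals = set(np.unique(data).astype(float).tolist())
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"{path}: mask must be 0/1, found values {sorted(vals)}")
        data = data.astype(np.uint8)
    elif kind == "intensity":
        data = data.astype(float)
        if not np.all(np.isfinite(data)):
            raise ValueError(f"{path}: non-finite intensity values")
    else:
        raise ValueError(f"unknown volume kind '{kind}'")
    return data, spacing


def write_volume(
    data: np.ndarray, spacing: tuple[float, float, float], path: Path | str
) -> Path:
    """Write a 3-D volume as NIfTI with the given spacing in the header."""
    path = Path(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.bool_):
        data = data.astype(np.uint8)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, path)
    return path


def load_study(paths: Mapping[str, Path | str], day: int) -> ImagingStudy:
    """Load and validate one study from named NIfTI files.

    ``paths`` must contain ``t1c, t2, labels, enhancing, edema`` and may
    contain ``necrotic`` and ``cavity``.  Overlapping masks or dimension
    mismatches are errors, never silently resolved.
    """
    missing = [k for k in REQUIRED_KEYS if k not in paths or paths[k] is None]
    if missing:
        raise ValueError(f"missing required study file(s): {missing}")

    labels, spacing = read_volume(paths["labels"], kind="label")
    grid = VoxelGrid(labels=labels, spacing=spacing)
    t1c, _ = read_volume(paths["t1c"], expected_grid=grid, kind="intensity")
    t2, _ = read_volume(paths["t2"], expected_grid=grid, kind="intensity")
    enh, _ = read_volume(paths["enhancing"], expected_grid=grid, kind="mask")
    ede, _ = read_volume(paths["edema"], expected_grid=grid, kind="mask")
    nec = cav = None
    if paths.get("necrotic") is not None:
        nec, _ = read_volume(paths["necrotic"], expected_grid=grid, kind="mask")
    if paths.get("cavity") is not None:
        cav, _ = read_volume(paths["cavity"], expected_grid=grid, kind="mask")
        # fluid-filled cavity: no cells, no flux
        grid.labels[cav.astype(bool)] = TissueLabel.CSF

    return ImagingStudy(
        grid=grid,
        t1c=t1c,
        t2=t2,
        enhancing_mask=enh.astype(bool),
        edema_mask=ede.astype(bool),
        necrotic_mask=None if nec is None else nec.astype(bool),
        cavity_mask=None if cav is None else cav.astype(bool),
        day=day,
    )


def _parse_manifest(path: Path) -> dict[str, str]:
    entries: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    return entries


def load_study_manifest(path: Path | str) -> ImagingStudy:
    """Load a study described by a plain-text manifest.

    The manifest lists one ``key = value`` pair per line with keys
    ``t1c, t2, labels, enhancing, edema`` (required), ``necrotic, cavity``
    (optional) naming NIfTI files (relative paths resolve against the
    manifest's directory) and ``day`` (integer acquisition day).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    entries = _parse_manifest(path)
    if "day" not in entries:
        raise ValueError(f"{path}: manifest is missing the 'day' entry")
    day = int(entries.pop("day"))
    paths: dict[str, Path] = {}
    for key, value in entries.items():
        if key not in REQUIRED_KEYS + OPTIONAL_KEYS:
            raise ValueError(f"{path}: unknown manifest key '{key}'")
        p = Path(value)
        paths[key] = p if p.is_absolute() else path.parent / p
    return load_study(paths, day=day)


def write_study(study: ImagingStudy, out_dir: Path | str, stem: str = "study") -> Path:
    """Write a study's volumes plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacing = study.grid.spacing
    files = {
        "t1c": (f"{stem}_t1c.nii.gz", study.t1c),
        "t2": (f"{stem}_t2.nii.gz", study.t2),
        "labels": (f"{stem}_labels.nii.gz", study.grid.labels),
        "enhancing": (f"{stem}_enhancing.nii.gz", study.enhancing_mask),
        "edema": (f"{stem}_edema.nii.gz", study.edema_mask),
    }
    if study.necrotic_mask is not None:
        files["necrotic"] = (f"{stem}_necrotic.nii.gz", study.necrotic_mask)
    if study.cavity_mask is not None:
        files["cavity"] = (f"{stem}_cavity.nii.gz", study.cavity_mask)
    lines = []
    for key, (name, data) in files.items():
        write_volume(data, spacing, out_dir / name)
        lines.append(f"{key} = {name}")
    lines.append(f"day = {study.day}")
    manifest = out_dir / f"{stem}_manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def write_result_masks(result, grid: VoxelGrid, out_dir: Path | str) -> dict[str, Path]:
    """Write a scenario's simulated enhancing/edema masks as binary NIfTI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("sim_enhancing_mask", "sim_edema_mask"):
        mask = getattr(result, name)
        if mask.shape != grid.dims:
            raise ValueError(
                f"{name} shape {mask.shape} does not match grid dims {grid.dims}"
            )
    idx = getattr(result, "index", 0)
    paths = {
        "enhancing": out_dir / f"scenario{idx:02d}_enhancing.nii.gz",
        "edema": out_dir / f"scenario{idx:02d}_edema.nii.gz",
    }
    write_volume(result.sim_enhancing_mask, grid.spacing, paths["enhancing"])
    write_volume(result.sim_edema_mask, grid.spacing, paths["edema"])
    return paths
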