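"""File formats: concatenated-triplet TIFFs, quantitative outputs, and the
calibration file.

Inputs are greyscale TIFFs — a single 3M x N page for 2D, multi-page for
3D — with the three phase images concatenated row-wise. Outputs are four
32-bit float TIFFs (stacks in 3D) in photon units plus a YAML manifest
recording the units, the calibration digest and the depth table. The
calibration file is versioned human-readable YAML so that downstream tools
never have to guess units or provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml
from numpy.typing import NDArray

from .calibration import ContrastFit, GainFit
from .errors import FormatError, LayoutError
from .reconstruction import CalibrationProfile, QuantResult

CALIBRATION_SCHEMA = "quantsim-calibration/1"
MANIFEST_SCHEMA = "quantsim-manifest/1"

_REQUIRED_CALIB_FIELDS = (
    "gain_dn_per_photon",
    "offset_dn",
    "read_noise_var_dn2",
    "modulation_contrast",
)

OUTPUT_NAMES = ("widefield", "sectioned", "widefield_noise", "sectioned_noise")


@dataclass(frozen=True)
class CalibrationFileRecord:
    """On-disk form of a calibration: four numbers plus provenance."""

    gain_dn_per_photon: float
    offset_dn: float
    read_noise_var_dn2: float
    modulation_contrast: float
    schema_version: str = CALIBRATION_SCHEMA
    metadata: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_profile(
        cls, profile: CalibrationProfile, metadata: Mapping[str, str] | None = None
    ) -> "CalibrationFileRecord":
        meta = dict(profile.created_with)
        if metadata:
            meta.update(metadata)
        return cls(
            gain_dn_per_photon=profile.gain.gain_dn_per_photon,
            offset_dn=profile.gain.offset_dn,
            read_noise_var_dn2=profile.gain.read_noise_var_dn2,
            modulation_contrast=profile.contrast.modulation_contrast,
            metadata=meta,
        )

    def to_profile(self) -> CalibrationProfile:
        return CalibrationProfile(
            gain=GainFit(
                gain_dn_per_photon=self.gain_dn_per_photon,
                offset_dn=self.offset_dn,
                read_noise_var_dn2=self.read_noise_var_dn2,
            ),
            contrast=ContrastFit(modulation_contrast=self.modulation_contrast),
            created_with=dict(self.metadata),
        )


def write_calibration(record: CalibrationFileRecord, path: str | Path) -> Path:
    """Write a calibration record as versioned YAML at full precision."""
    path = Path(path)
    doc = {
        "schema_version": record.schema_version,
        **{name: float(getattr(record, name)) for name in _REQUIRED_CALIB_FIELDS},
        "metadata": dict(record.metadata),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=False))
    return path


def read_calibration(path: str | Path) -> CalibrationFileRecord:
    """Read a calibration file, validating schema version and fields.

    Raises
    ------
    FormatError
        On unknown schema versions or missing required fields — never a
        silent fallback, since mis-read calibration silently corrupts
        every downstream photon number.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except OSError as exc:
        raise FormatError(f"cannot read calibration file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise FormatError(f"calibration file {path} is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"calibration file {path} does not hold a mapping")
    version = doc.get("schema_version")
    if version != CALIBRATION_SCHEMA:
        raise FormatError(
            f"calibration file {path} has schema version {version!r}; this "
            f"reader supports {CALIBRATION_SCHEMA!r} only"
        )
    missing = [name for name in _REQUIRED_CALIB_FIELDS if name not in doc]
    if missing:
        raise FormatError(
            f"calibration file {path} is missing required fields: {', '.join(missing)}"
        )
    return CalibrationFileRecord(
        schema_version=version,
        metadata=dict(doc.get("metadata") or {}),
        **{name: float(doc[name]) for name in _REQUIRED_CALIB_FIELDS},
    )


def read_concatenated_tiff(path: str | Path) -> tuple[list[NDArray[np.float64]], dict]:
    """Read a single- or multi-page greyscale concatenated-triplet TIFF.

    Returns (pages, provenance): each page is a float64 3M x N array with
    bit depth untouched numerically; provenance records the source dtype,
    page count, dimensions and file digest.

    Raises
    ------
    FormatError
        Non-greyscale data (convert RGB to greyscale first) or a row
        count not divisible by three.
    """
    path = Path(path)
    try:
        raw = tifffile.imread(path)
        source_dtype = str(np.asarray(raw).dtype)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 2:
        pages = [arr]
    elif arr.ndim == 3 and arr.shape[-1] not in (3, 4):
        pages = [arr[k] for k in range(arr.shape[0])]
    else:
        raise FormatError(
            f"TIFF {path} has shape {arr.shape}; expected greyscale pages "
            "(convert RGB/RGBA images to single-channel greyscale first)"
        )
    for k, page in enumerate(pages):
        if page.shape[0] % 3 != 0:
            raise FormatError(
                f"TIFF {path} page {k} has {page.shape[0]} rows, not divisible "
                "by 3; expected three phase images concatenated row-wise"
            )
    provenance = {
        "path": str(path),
        "pages": len(pages),
        "shape": tuple(pages[0].shape),
        "source_dtype": source_dtype,
        "sha256": file_digest(path),
    }
    return [page.astype(np.float64) for page in pages], provenance


def write_concatenated_tiff(
    pages: Sequence[NDArray[np.floating]] | NDArray[np.floating],
    path: str | Path,
    *,
    dtype: str = "uint16",
) -> Path:
    """Write simulated concatenated triplets in the raw-acquisition layout."""
    path = Path(path)
    if isinstance(pages, np.ndarray) and pages.ndim == 2:
        pages = [pages]
    stack = np.stack([np.asarray(p) for p in pages]).astype(dtype)
    data = stack[0] if stack.shape[0] == 1 else stack
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_quant_outputs(
    results: Sequence[QuantResult],
    out_dir: str | Path,
    *,
    calib: CalibrationProfile | None = None,
    stem: str = "",
) -> dict[str, Path]:
    """Write the four photon-unit images (stacks if >1 depth) plus manifest.

    Images are 32-bit float TIFF — integer grey levels cannot represent
    sub-photon noise-map values. The manifest records the unit contract
    ("photons"), the calibration digest and the depth table.
    """
    results = list(results)
    if not results:
        raise LayoutError("no results to write")
    shape = results[0].shape
    for r in results:
        if r.shape != shape:
            raise LayoutError(f"inconsistent result dimensions: {r.shape} vs {shape}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = f"{stem}_" if stem else ""
    written: dict[str, Path] = {}
    for name in OUTPUT_NAMES:
        planes = np.stack([r.images()[name] for r in results]).astype(np.float32)
        data = planes[0] if planes.shape[0] == 1 else planes
        target = out_dir / f"{prefix}{name}.tif"
        tifffile.imwrite(
            target,
            data,
            photometric="minisblack",
            description="pixel unit: photons",
        )
        written[name] = target
    manifest = {
        "schema_version": MANIFEST_SCHEMA,
        "pixel_unit": "photons",
        "calibration_digest": calib.digest if calib is not None else None,
        "noise_model": "shot + read noise, delta-method propagation",
        "widefield_estimator": "mean of three phases (single-exposure equivalent)",
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "depths": [
            {"depth_index": r.depth_index, "depth_um": r.depth_um} for r in results
        ],
        "images": {name: written[name].name for name in OUTPUT_NAMES},
    }
    manifest_path = out_dir / f"{prefix}manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    written["manifest"] = manifest_path
    return written


def write_histograms(
    histograms: Mapping[str, tuple[NDArray[np.float64], NDArray[np.int64]]],
    path: str | Path,
) -> Path:
    """Export histogram tables as tab-delimited text (image, bin edges, count)."""
    path = Path(path)
    lines = ["image\tbin_left\tbin_right\tcount"]
    for name, (edges, counts) in histograms.items():
        for k, count in enumerate(counts):
            lines.append(f"{name}\t{edges[k]:.6g}\t{edges[k + 1]:.6g}\t{int(count)}")
    path.write_text("\n".join(lines) + "\n")
    return path
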