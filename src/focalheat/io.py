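"""TIFF / JSON-sidecar / CSV input and output.

Images travel as TIFF (8/16-bit integer or 32-bit float, single page or
stack) with a JSON metadata sidecar (exposure_s, ambient_C, pixel_size_um,
optional gate window and acquisition times).  Temperature fields are written
as 32-bit float multi-page TIFFs (one page per z slice); profiles and sweep
tables as CSV with a comment header embedding the package version and config
hash, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .heat_model import TemperatureField
from .thermometry import TemperatureMap

SIDECAR_SUFFIX = ".json"
REQUIRED_IMAGE_METADATA = ("exposure_s", "ambient_C", "pixel_size_um")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def sidecar_path(image_path: str | Path) -> Path:
    p = Path(image_path)
    return p.with_suffix(SIDECAR_SUFFIX)


def write_image(
    path: str | Path,
    image: np.ndarray,
    metadata: dict,
    *,
    dtype=np.float32,
) -> Path:
    """Write an image (or stack) plus its JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    tifffile.imwrite(path, arr.astype(dtype))
    meta = dict(metadata)
    meta.setdefault("focalheat_version", __version__)
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_image(path: str | Path, *, require_metadata: bool = True):
    """Read a TIFF plus sidecar; returns (array, metadata dict).

    Raises a ValueError naming every required metadata field that is missing.
    """
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    sc = sidecar_path(path)
    meta: dict = {}
    if sc.exists():
        meta = json.loads(sc.read_text())
    elif require_metadata:
        raise ValueError(f"missing metadata sidecar {sc}")
    if require_metadata:
        missing = [k for k in REQUIRED_IMAGE_METADATA if k not in meta]
        if missing:
            raise ValueError(
                f"sidecar {sc} missing required fields: {', '.join(missing)}"
            )
    return arr, meta


def write_field(path: str | Path, field: TemperatureField, extra: dict | None = None) -> Path:
    """Temperature field as 32-bit float multi-page TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, field.values.astype(np.float32))
    spacing = {
        "dx_um": float(np.diff(field.x_um).mean()) if field.x_um.size > 1 else None,
        "dy_um": float(np.diff(field.y_um).mean()) if field.y_um.size > 1 else None,
        "dz_um": float(np.diff(field.z_um).mean()) if field.z_um.size > 1 else None,
    }
    meta = {
        "kind": "temperature_field",
        "ambient_C": field.ambient_c,
        "phase": field.phase_label,
        "grid_spacing_um": spacing,
        "x0_um": float(field.x_um[0]),
        "y0_um": float(field.y_um[0]),
        "z0_um": float(field.z_um[0]),
        "focalheat_version": __version__,
    }
    meta.update(extra or {})
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_map(path: str | Path, tmap: TemperatureMap, extra: dict | None = None) -> Path:
    """Temperature map as 32-bit float TIFF (masked pixels NaN) + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = np.where(tmap.mask, tmap.delta_t, np.nan).astype(np.float32)
    tifffile.imwrite(path, out)
    meta = {
        "kind": "temperature_map",
        "ambient_C": tmap.ambient_c,
        "pixel_size_um": tmap.pixel_size_um,
        "n_valid": tmap.n_valid,
        "n_masked": int(tmap.mask.size - tmap.n_valid),
        "n_out_of_range": int(tmap.out_of_range.sum()),
        "focus_center": list(tmap.focus_center) if tmap.focus_center else None,
        "focalheat_version": __version__,
    }
    meta.update(extra or {})
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_table(path: str | Path, df: pd.DataFrame, *, config: dict | None = None) -> Path:
    """CSV with a reproducibility comment header (version + config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# focalheat_version={__version__}\n"
    if config is not None:
        header += f"# config_hash={config_hash(config)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.6g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_calibration_table(path: str | Path):
    """CSV with columns temperature_C, intensity -> (temps, intensities)."""
    df = read_table(path)
    cols = {c.lower(): c for c in df.columns}
    t_col = next((cols[c] for c in ("temperature_c", "temperature", "t_c") if c in cols), None)
    i_col = next((cols[c] for c in ("intensity", "mean_intensity", "i") if c in cols), None)
    if t_col is None or i_col is None:
        raise ValueError(
            "calibration table needs temperature_C and intensity columns; "
            f"found {list(df.columns)}"
        )
    return df[t_col].to_numpy(float), df[i_col].to_numpy(float)
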