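"""Shared table/image readers and writers and the run manifest.

Tables are RFC-4180 CSV (or TSV) with a required header row; images are
TIFF (grayscale or multi-channel). All coordinates in CSV site/trace
files are 0-based (row, col).
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class SchemaError(ValueError):
    pass


def read_table(path: str | Path, required: list[str] | None = None
               ) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s) "
                f"{', '.join(missing)}; found {list(df.columns)}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)
    return path


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_image(array: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), array)
    return path


def write_manifest(out_dir: str | Path, subcommand: str,
                   params: dict, seed: int | None = None) -> Path:
    """Machine-readable record of a run: inputs, parameters, seed."""
    import memphys

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "memphys",
        "version": memphys.__version__,
        "subcommand": subcommand,
        "parameters": {k: str(v) for k, v in params.items()},
        "seed": seed,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
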