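"""Photon-count frame-stack storage: multi-page TIFF with a JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["save_stack", "load_stack"]


def save_stack(path, stack: np.ndarray, frame_period: float | None = None,
               **metadata) -> None:
    """Write a (n_frames, rows, cols) count stack as 16-bit multi-page TIFF.

    A JSON sidecar (same name, ``.json``) records shape, dtype, the frame
    period in seconds, and any extra metadata keys.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, rows, cols)")
    if stack.min() < 0 or stack.max() > np.iinfo(np.uint16).max:
        raise ValueError("counts outside the uint16 range")
    path = Path(path)
    tifffile.imwrite(path, stack.astype(np.uint16))
    sidecar = {"shape": list(stack.shape), "dtype": "uint16",
               "frame_period_s": frame_period}
    sidecar.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_stack(path) -> tuple[np.ndarray, dict]:
    """Read a stack written by :func:`save_stack`; returns (stack, sidecar)."""
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return np.asarray(stack), sidecar
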