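"""Array stacks on disk: 32-bit float multi-page TIFF + JSON sidecar.

Every stack written by the package carries a sidecar (same path with
``.json`` appended) recording the axis order, units and pixel size, so a
stack can never be silently misinterpreted.  Reading refuses stacks
without a sidecar or with missing axis/unit declarations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


class SidecarError(ValueError):
    pass


def write_stack(
    path,
    data: np.ndarray,
    axes: str,
    units: str,
    pixel_size_um: float,
    **extra,
) -> Path:
    """Write a float32 TIFF stack plus its JSON sidecar.

    ``axes`` names the dimensions outer-to-inner, e.g. ``"step,angle,pixel"``
    or ``"row,col"``; ``units`` the physical unit of the values.
    """
    path = Path(path)
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim not in (2, 3):
        raise ValueError("stacks must be 2-D or 3-D")
    if len(axes.split(",")) != arr.ndim:
        raise ValueError("axes declaration does not match array rank")
    # 3-D stacks as grayscale pages, never as RGB planes
    tifffile.imwrite(path, arr, photometric="minisblack")
    sidecar = {
        "axes": axes,
        "units": units,
        "pixel_size_um": float(pixel_size_um),
        "shape": list(arr.shape),
        "dtype": "float32",
        **extra,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_stack(path, expect_axes: str | None = None):
    """Read a stack and its sidecar; returns ``(array, sidecar_dict)``.

    Raises :class:`SidecarError` for a missing sidecar, missing axis/unit
    declarations, or an axis order differing from ``expect_axes``.
    """
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise SidecarError(
            f"no sidecar {sidecar_path.name}: refusing to guess axis order; "
            "write stacks with talbotct.io.write_stack"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("axes", "units"):
        if key not in meta:
            raise SidecarError(f"sidecar lacks required field {key!r}")
    if expect_axes is not None and meta["axes"] != expect_axes:
        raise SidecarError(
            f"axis order mismatch: sidecar says {meta['axes']!r}, "
            f"expected {expect_axes!r}"
        )
    arr = tifffile.imread(path)
    if list(arr.shape) != meta.get("shape", list(arr.shape)):
        raise SidecarError("sidecar shape does not match the TIFF")
    return arr, meta
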