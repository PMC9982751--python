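"""Image, mask, and landmark-sidecar IO.

Images are 8-bit grayscale PNG by default, or 16-bit grayscale TIFF via
``dialect='tiff16'``; both round-trip losslessly.  Masks are 1-bit PNG.
Each image carries a JSON sidecar ``<stem>.json`` with the landmark
coordinates (and optional grade/seed metadata)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from PIL import Image as PILImage

from .core import (FundusImage, ImageFormatError, Landmarks,
                   MissingSidecarError, as_bool_mask)


def sidecar_path(image_path) -> Path:
    return Path(image_path).with_suffix(".json")


def write_landmarks(path, landmarks: Landmarks, grade: Optional[str] = None,
                    meta: Optional[dict] = None) -> None:
    payload = landmarks.to_dict()
    if grade is not None:
        payload["grade"] = grade
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks(path) -> tuple[Landmarks, Optional[str], dict]:
    path = Path(path)
    if not path.exists():
        raise MissingSidecarError(f"landmark sidecar not found: {path}")
    try:
        payload = json.loads(path.read_text())
        lm = Landmarks.from_dict(payload)
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise MissingSidecarError(f"malformed landmark sidecar {path}: {exc}")
    return lm, payload.get("grade"), payload.get("meta", {})


def write_image(path, image: FundusImage, dialect: str = "png8") -> None:
    """Write pixels plus the landmark sidecar; lossless for both dialects."""
    path = Path(path)
    pixels = image.pixels
    if dialect == "png8":
        if pixels.dtype != np.uint8:
            raise ImageFormatError("png8 dialect requires uint8 pixels")
        PILImage.fromarray(pixels, mode="L").save(path)
    elif dialect == "tiff16":
        tifffile.imwrite(path, pixels.astype(np.uint16))
    else:
        raise ImageFormatError(f"unknown dialect {dialect!r}")
    write_landmarks(sidecar_path(path), image.landmarks, image.grade,
                    image.meta or None)


def read_image(path, dialect: Optional[str] = None) -> FundusImage:
    """Read pixels and the landmark sidecar back into a FundusImage."""
    path = Path(path)
    if dialect is None:
        dialect = "tiff16" if path.suffix.lower() in (".tif", ".tiff") else "png8"
    try:
        if dialect == "png8":
            with PILImage.open(path) as im:
                pixels = np.array(im.convert("L"), dtype=np.uint8, copy=True)
        elif dialect == "tiff16":
            pixels = tifffile.imread(path).astype(np.uint16)
        else:
            raise ImageFormatError(f"unknown dialect {dialect!r}")
    except (OSError, ValueError) as exc:
        raise ImageFormatError(f"cannot read image {path}: {exc}")
    lm, grade, meta = read_landmarks(sidecar_path(path))
    return FundusImage(pixels=pixels, landmarks=lm, grade=grade,
                       eye_id=path.stem, meta=meta)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 1-bit PNG."""
    mask = as_bool_mask(mask)
    im = PILImage.fromarray(mask.astype(np.uint8) * 255, mode="L")
    im.convert("1", dither=PILImage.Dither.NONE).save(path, bits=1)


def read_mask(path) -> np.ndarray:
    # decode via mode 'L' with an explicit copy: numpy views of PIL's
    # bit-packed mode-'1' buffer do not survive the image being closed
    try:
        with PILImage.open(path) as im:
            arr = np.array(im.convert("L"), dtype=np.uint8, copy=True)
        return arr > 127
    except (OSError, ValueError) as exc:
        raise ImageFormatError(f"cannot read mask {path}: {exc}")
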