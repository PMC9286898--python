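"""Fuse one compound vector and one disease vector into a grayscale image.

A pair (compound, disease) with normalized feature vectors
``b = [b_1..b_Dc]`` and ``a = [a_1..a_Dd]`` is encoded as the additive matrix

    M[r, c] = (b_r + a_c) / 2

so every compound feature spans a row and every disease feature a column
(reference scale: 5270 x 322).  Because both inputs lie in [0, 1], so does M,
and it maps directly onto an 8-bit grayscale image with
``pixel = round(255 * M)``.  The matrix is rank-2 by construction: the image
carries the two vectors side by side rather than any multiplicative
interaction, and the downstream convolutional classifier learns the
interaction from the joint picture.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CDRMatrix",
    "CDRImage",
    "build_matrix",
    "to_grayscale",
    "render_for_cnn",
    "write_png",
    "read_png",
]


@dataclass(frozen=True)
class CDRMatrix:
    """The fused compound x disease feature matrix for one pair."""

    compound_id: str
    disease_id: str
    values: np.ndarray  # shape (D_c, D_d), entries in [0, 1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CDRImage:
    """8-bit grayscale rendering of a :class:`CDRMatrix`."""

    pixels: np.ndarray  # uint8, shape (H, W)
    compound_id: str = ""
    disease_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def build_matrix(
    compound: np.ndarray,
    disease: np.ndarray,
    compound_id: str = "",
    disease_id: str = "",
    transpose: bool = False,
) -> CDRMatrix:
    """Build the additive relationship matrix ``(b_r + a_c) / 2``.

    Rows index compound features, columns disease features; ``transpose=True``
    exposes the opposite orientation.  Both vectors must already be
    normalized to [0, 1].
    """
    b = np.asarray(compound, dtype=float).ravel()
    a = np.asarray(disease, dtype=float).ravel()
    for label, v in (("compound", b), ("disease", a)):
        if v.size == 0:
            raise ValueError(f"{label} vector is empty")
        if not np.isfinite(v).all():
            raise ValueError(f"{label} vector contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError(
                f"{label} vector is not normalized to [0, 1] "
                f"(range [{v.min():g}, {v.max():g}])"
            )
    values = np.add.outer(b, a) / 2.0
    if transpose:
        values = values.T
    return CDRMatrix(compound_id=compound_id, disease_id=disease_id, values=values)


def to_grayscale(matrix: CDRMatrix) -> CDRImage:
    """Quantize matrix entries in [0, 1] to 8-bit pixels.

    ``pixel = round(255 * value)`` with round-half-away-from-zero (so a value
    whose scaled form is exactly 127.5 becomes 128), clamped to [0, 255].
    """
    vals = matrix.values
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValueError("matrix entries must lie in [0, 1]")
    pixels = np.floor(255.0 * vals + 0.5)  # half-away-from-zero for x >= 0
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)
    return CDRImage(
        pixels=pixels, compound_id=matrix.compound_id, disease_id=matrix.disease_id
    )


def _bilinear_resize(pixels: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Align-corners bilinear interpolation on a 2-D grid."""
    h, w = pixels.shape
    th, tw = target
    src = pixels.astype(float)
    rows = np.linspace(0.0, h - 1.0, th) if th > 1 else np.array([(h - 1) / 2.0])
    cols = np.linspace(0.0, w - 1.0, tw) if tw > 1 else np.array([(w - 1) / 2.0])
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    top = src[np.ix_(r0, c0)] * (1 - fc) + src[np.ix_(r0, c1)] * fc
    bot = src[np.ix_(r1, c0)] * (1 - fc) + src[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def render_for_cnn(image: CDRImage, target: tuple[int, int]) -> CDRImage:
    """Resize an image to the network's input geometry (bilinear, deterministic).

    Resizing to the image's own shape returns identical pixels.  The result is
    re-quantized with the same half-away-from-zero rule as
    :func:`to_grayscale`.
    """
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError(f"target dims must be >= 1, got {target}")
    if image.pixels.size == 0:
        raise ValueError("cannot resize an empty image")
    if (th, tw) == image.pixels.shape:
        return image
    resized = _bilinear_resize(image.pixels, (th, tw))
    pixels = np.clip(np.floor(resized + 0.5), 0, 255).astype(np.uint8)
    return CDRImage(
        pixels=pixels, compound_id=image.compound_id, disease_id=image.disease_id
    )


def write_png(image: CDRImage, path: str | Path) -> None:
    """Write an 8-bit single-channel PNG; the write/read round trip is pixel-exact."""
    try:
        Image.fromarray(image.pixels, mode="L").save(Path(path), format="PNG")
    except OSError as exc:
        raise OSError(f"failed to write PNG {path}: {exc}") from exc


def read_png(
    path: str | Path, compound_id: str = "", disease_id: str = "", rgb: str = "error"
) -> CDRImage:
    """Read an 8-bit grayscale PNG.

    A multi-channel PNG raises by default; ``rgb="luminance"`` instead
    converts via PIL's ITU-R 601-2 transform.
    """
    try:
        img = Image.open(Path(path))
        img.load()
    except OSError as exc:
        raise OSError(f"failed to read PNG {path}: {exc}") from exc
    if img.mode != "L":
        if rgb == "luminance":
            img = img.convert("L")
        else:
            raise ValueError(
                f"{path}: expected 8-bit grayscale, got mode {img.mode!r} "
                "(pass rgb='luminance' to convert)"
            )
    return CDRImage(
        pixels=np.asarray(img, dtype=np.uint8),
        compound_id=compound_id,
        disease_id=disease_id,
    )


def pair_image_name(compound_id: str, disease_id: str) -> str:
    """Canonical file name for one pair's image."""
    return f"{compound_id}__{disease_id}.png"
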