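"""Small numpy-only image helpers shared by scalogram rendering and the
classifier's augmentation: separable bilinear resize and crop/pad."""

from __future__ import annotations

import numpy as np


def bilinear_resize(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a 2-D scalar field (separable, edge-aligned)."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    oh, ow = out_shape
    if (h, w) == (oh, ow):
        return img.copy()
    # resize columns (time axis) first, then rows
    x_old = np.linspace(0.0, 1.0, w)
    x_new = np.linspace(0.0, 1.0, ow)
    tmp = np.empty((h, ow))
    for i in range(h):
        tmp[i] = np.interp(x_new, x_old, img[i])
    y_old = np.linspace(0.0, 1.0, h)
    y_new = np.linspace(0.0, 1.0, oh)
    out = np.empty((oh, ow))
    for j in range(ow):
        out[:, j] = np.interp(y_new, y_old, tmp[:, j])
    return out


def resize_rgb(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize each channel of an (H, W, 3) image."""
    return np.stack(
        [bilinear_resize(img[:, :, c], out_shape) for c in range(img.shape[2])],
        axis=-1,
    )


def shift_rows(img: np.ndarray, offset: int, fill: float = 0.0) -> np.ndarray:
    """Shift rows down by ``offset`` (negative = up), zero-filling vacated rows."""
    out = np.full_like(img, fill)
    h = img.shape[0]
    if offset >= h or -offset >= h:
        return out
    if offset >= 0:
        out[offset:] = img[: h - offset]
    else:
        out[: h + offset] = img[-offset:]
    return out


def crop_or_pad_rows(img: np.ndarray, n_rows: int, fill: float = 0.0) -> np.ndarray:
    """Crop or zero-pad at the bottom so the image has exactly n_rows rows."""
    h = img.shape[0]
    if h == n_rows:
        return img
    if h > n_rows:
        return img[:n_rows]
    pad = np.full((n_rows - h,) + img.shape[1:], fill)
    return np.concatenate([img, pad], axis=0)
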