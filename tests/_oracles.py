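"""Shared brute-force oracles used by several test modules."""

import numpy as np


def warp_oracle(img: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Brute-force per-pixel bilinear sampling on normalized coordinates."""
    h, w = img.shape
    out = np.zeros_like(img, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            yn = -1 + 2 * i / (h - 1) if h > 1 else 0.0
            xn = -1 + 2 * j / (w - 1) if w > 1 else 0.0
            xs = theta[0, 0] * xn + theta[0, 1] * yn + theta[0, 2]
            ys = theta[1, 0] * xn + theta[1, 1] * yn + theta[1, 2]
            jx = (xs + 1) * (w - 1) / 2
            iy = (ys + 1) * (h - 1) / 2
            i0, j0 = int(np.floor(iy)), int(np.floor(jx))
            fi, fj = iy - i0, jx - j0
            acc = 0.0
            for di, wi in ((0, 1 - fi), (1, fi)):
                for dj, wj in ((0, 1 - fj), (1, fj)):
                    ii, jj = i0 + di, j0 + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        acc += wi * wj * img[ii, jj]
            out[i, j] = acc
    return out
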