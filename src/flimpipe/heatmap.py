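"""Heat-map rendering: SNR-weighted inverse-distance interpolation of
point measurements and alpha-blended overlay onto white-light frames."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeatMap", "interpolate", "overlay"]


@dataclass
class HeatMap:
    """Per-pixel parameter estimate, defined where ``support_mask`` holds."""

    values: np.ndarray
    support_mask: np.ndarray


def _snr_weight(snr_db: np.ndarray, mode: str) -> np.ndarray:
    if mode == "amplitude":
        return 10.0 ** (np.asarray(snr_db, dtype=float) / 20.0)
    if mode == "db":
        return np.clip(np.asarray(snr_db, dtype=float), 1e-6, None)
    if mode == "none":
        return np.ones(len(snr_db))
    raise ValueError(f"unknown SNR weighting mode {mode!r}")


def interpolate(
    points,
    frame_size,
    power: float = 2.0,
    radius: float = 30.0,
    snr_weighting: str = "amplitude",
) -> HeatMap:
    """Shepard inverse-distance interpolation combined with SNR weighting.

    ``points`` is an iterable of (x, y, value, snr_db).  Pixel q gets
    ``sum_i w_i v_i / sum_i w_i`` with ``w_i = s(snr_i) / d(q, i)^power``
    over measurements within ``radius``; a pixel coincident with a
    measurement takes that value exactly; pixels with no measurement in
    range fall outside the support mask.
    """
    if power <= 0 or radius <= 0:
        raise ValueError("power and radius must be positive")
    pts = [(float(x), float(y), float(v), float(s)) for x, y, v, s in points]
    if not pts:
        raise ValueError("interpolate requires at least one measurement")
    w, h = frame_size
    num = np.zeros((h, w))
    den = np.zeros((h, w))
    exact = {}
    sw = _snr_weight([p[3] for p in pts], snr_weighting)
    r_int = int(np.ceil(radius))
    for (x, y, v, _), s in zip(pts, sw):
        x0, x1 = max(0, int(np.floor(x - r_int))), min(w, int(np.ceil(x + r_int)) + 1)
        y0, y1 = max(0, int(np.floor(y - r_int))), min(h, int(np.ceil(y + r_int)) + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - x, yy - y)
        inside = d <= radius
        zero = inside & (d == 0.0)
        if zero.any():
            for ry, rx in zip(*np.nonzero(zero)):
                exact[(y0 + ry, x0 + rx)] = v
        contrib = inside & (d > 0.0)
        wgt = np.zeros_like(d)
        wgt[contrib] = s / d[contrib] ** power
        num[y0:y1, x0:x1] += wgt * v
        den[y0:y1, x0:x1] += wgt
    mask = den > 0
    values = np.full((h, w), np.nan)
    values[mask] = num[mask] / den[mask]
    for (row, col), v in exact.items():
        values[row, col] = v
        mask[row, col] = True
    return HeatMap(values=values, support_mask=mask)


def overlay(
    frame: np.ndarray,
    heatmap: HeatMap,
    colormap: str = "jet",
    alpha: float = 0.6,
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Alpha-blend the color-mapped heat map onto a frame inside the
    support mask; pixels outside the mask are returned untouched."""
    import matplotlib

    if frame.shape[:2] != heatmap.values.shape:
        raise ValueError(
            f"frame {frame.shape[:2]} and heat map {heatmap.values.shape} dimensions differ"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    vals = heatmap.values
    mask = heatmap.support_mask
    lo = np.nanmin(vals[mask]) if vmin is None else vmin
    hi = np.nanmax(vals[mask]) if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((np.nan_to_num(vals, nan=lo) - lo) / span, 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    colored = (cmap(norm)[:, :, :3] * 255).astype(float)
    out = frame.astype(float).copy()
    out[mask] = (1.0 - alpha) * out[mask] + alpha * colored[mask]
    return np.clip(out, 0, 255).astype(np.uint8)
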