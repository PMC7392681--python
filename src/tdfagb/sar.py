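"""L-band SAR predictor layers: calibration to gamma-naught, Lee despeckling,
the normalized difference backscatter index (NDBI), per-pixel Haralick
texture layers, and plot-footprint feature extraction.

The processing chain applied by :func:`build_sar_stack` is

    DN -> gamma0 (dB) -> 3x3 Lee filter (dB, additive-noise approximation)
       -> NDBI on linear power -> 32-level quantization -> windowed GLCM
       textures (8 measures x {HH, HV, NDBI} bands = 24 layers)

Digital numbers convert to backscatter with gamma0 = 10 log10(DN^2) - 83.0;
NDBI = (HH - HV) / (HH + HV) on linear power so it is bounded in [-1, 1].
Texture measures are computed from a symmetric, normalized gray-level
co-occurrence matrix per 3x3 window, averaged over the four directions
0, 45, 90 and 135 degrees at a shift of one pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.ndimage import uniform_filter

from .grids import Grid

logger = logging.getLogger(__name__)

__all__ = [
    "TextureConfig",
    "SARStack",
    "dn_to_gamma0",
    "gamma0_to_dn",
    "lee_filter",
    "compute_ndbi",
    "compute_glcm_textures",
    "build_sar_stack",
    "extract_plot_features",
    "TEXTURE_MEASURES",
    "PLOT_RADIUS_M",
]

#: canonical measure order of the texture layers
TEXTURE_MEASURES = ("hom", "cont", "dis", "ent", "asm", "mean", "var", "cor")

#: radius (m) of a circle of 1 ha, the field sampling-unit footprint
PLOT_RADIUS_M = float(np.sqrt(1e4 / np.pi))

_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees


@dataclass(frozen=True)
class TextureConfig:
    """Windowed-GLCM settings: odd window, 4 fixed directions, 1-px shift."""

    window: int = 3
    gray_levels: int = 32
    shift: int = 1

    def __post_init__(self):
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("texture window must be odd and >= 3")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.shift != 1:
            raise ValueError("only a 1-pixel co-occurrence shift is supported")


@dataclass
class SARStack:
    """Co-registered gamma-naught, NDBI and texture layers on one grid."""

    grid: Grid
    hh: np.ndarray
    hv: np.ndarray
    ndbi: np.ndarray
    textures: dict = field(default_factory=dict)

    def layers(self) -> dict:
        out = {"HH": self.hh, "HV": self.hv, "NDBI": self.ndbi}
        out.update(self.textures)
        return out


def dn_to_gamma0(dn: np.ndarray) -> np.ndarray:
    """Calibrate digital numbers to gamma-naught (dB); DN = 0 -> no-data."""
    dn = np.asarray(dn, dtype=float)
    if np.nanmin(dn) < 0:
        raise ValueError("negative digital numbers are invalid")
    out = np.full(dn.shape, np.nan)
    ok = dn > 0
    out[ok] = 10.0 * np.log10(dn[ok] ** 2) - 83.0
    return out


def gamma0_to_dn(gamma0_db: np.ndarray) -> np.ndarray:
    """Inverse calibration: gamma-naught (dB) back to digital numbers."""
    g = np.asarray(gamma0_db, dtype=float)
    return 10.0 ** ((g + 83.0) / 20.0)


def lee_filter(image: np.ndarray, window: int = 3, noise_sd: float = 1.0) -> np.ndarray:
    """Local-statistics Lee filter on a dB image (additive-noise form).

    output = local mean + W * (center - local mean) with
    W = max(0, 1 - noise_sd^2 / local variance); constant regions pass
    through unchanged.  ``noise_sd`` is the speckle noise standard deviation
    on the dB scale.
    """
    if window % 2 != 1:
        raise ValueError("Lee filter window must be odd")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    img = np.asarray(image, dtype=float)
    nan = np.isnan(img)
    filled = np.where(nan, 0.0, img)
    count = uniform_filter((~nan).astype(float), window, mode="nearest")
    mean = uniform_filter(filled, window, mode="nearest") / np.maximum(count, 1e-12)
    mean2 = uniform_filter(filled**2, window, mode="nearest") / np.maximum(count, 1e-12)
    var = np.maximum(mean2 - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.clip(1.0 - noise_sd**2 / var, 0.0, 1.0)
    w[var == 0] = 0.0
    out = mean + w * (img - mean)
    out[nan] = np.nan
    return out


def compute_ndbi(hh_db: np.ndarray, hv_db: np.ndarray, scale: str = "linear") -> np.ndarray:
    """NDBI = (HH - HV) / (HH + HV).

    Computed by default on linear power (dB inputs are linearized first) so
    the index lies in [-1, 1]; ``scale='db'`` applies the ratio directly to
    the dB values for comparison.  Zero denominators yield no-data.
    """
    hh = np.asarray(hh_db, dtype=float)
    hv = np.asarray(hv_db, dtype=float)
    if hh.shape != hv.shape:
        raise ValueError(f"HH {hh.shape} and HV {hv.shape} are not co-registered")
    if scale == "linear":
        a = 10.0 ** (hh / 10.0)
        b = 10.0 ** (hv / 10.0)
    elif scale == "db":
        a, b = hh, hv
    else:
        raise ValueError(f"unknown scale {scale!r}")
    den = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / den
    out[den == 0] = np.nan
    return out


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Per-band min-max quantization to integer gray levels; NaN -> -1."""
    b = np.asarray(band, dtype=float)
    finite = np.isfinite(b)
    q = np.full(b.shape, -1, dtype=np.int64)
    if not finite.any():
        return q
    lo, hi = b[finite].min(), b[finite].max()
    if hi == lo:
        q[finite] = 0
        return q
    q[finite] = np.minimum((b[finite] - lo) / (hi - lo) * levels, levels - 1).astype(np.int64)
    return q


@njit(cache=True)
def _glcm_textures_kernel(q, half, levels, offsets):  # pragma: no cover - numba
    nrows, ncols = q.shape
    ndir = offsets.shape[0]
    out = np.full((8, nrows, ncols), np.nan)
    counts = np.zeros((levels, levels))
    for r in range(nrows):
        r0 = max(r - half, 0)
        r1 = min(r + half, nrows - 1)
        for c in range(ncols):
            c0 = max(c - half, 0)
            c1 = min(c + half, ncols - 1)
            acc = np.zeros(8)
            ok_dirs = 0
            for d in range(ndir):
                dr = offsets[d, 0]
                dc = offsets[d, 1]
                counts[:, :] = 0.0
                total = 0.0
                for i in range(r0, r1 + 1):
                    j2r = i + dr
                    if j2r < r0 or j2r > r1:
                        continue
                    for j in range(c0, c1 + 1):
                        j2c = j + dc
                        if j2c < c0 or j2c > c1:
                            continue
                        a = q[i, j]
                        b = q[j2r, j2c]
                        if a < 0 or b < 0:
                            continue
                        counts[a, b] += 1.0
                        counts[b, a] += 1.0  # symmetric matrix
                        total += 2.0
                if total == 0.0:
                    continue
                hom = 0.0
                cont = 0.0
                dis = 0.0
                ent = 0.0
                asm = 0.0
                mu = 0.0
                for a in range(levels):
                    rowsum = 0.0
                    for b in range(levels):
                        p = counts[a, b] / total
                        if p > 0.0:
                            diff = a - b
                            hom += p / (1.0 + diff * diff)
                            cont += p * diff * diff
                            dis += p * abs(diff)
                            ent -= p * np.log(p)
                            asm += p * p
                            rowsum += p
                    mu += a * rowsum
                var = 0.0
                cov = 0.0
                for a in range(levels):
                    for b in range(levels):
                        p = counts[a, b] / total
                        if p > 0.0:
                            var += (a - mu) * (a - mu) * p
                            cov += (a - mu) * (b - mu) * p
                cor = cov / var if var > 0.0 else 0.0
                acc[0] += hom
                acc[1] += cont
                acc[2] += dis
                acc[3] += ent
                acc[4] += asm
                acc[5] += mu
                acc[6] += var
                acc[7] += cor
                ok_dirs += 1
            if ok_dirs > 0:
                for k in range(8):
                    out[k, r, c] = acc[k] / ok_dirs
    return out


def compute_glcm_textures(band: np.ndarray, config: TextureConfig | None = None) -> dict:
    """Per-pixel Haralick texture measures of one band.

    The band is quantized by per-band min-max scaling; each pixel's window
    yields one symmetric, normalized co-occurrence matrix per direction, the
    eight measures are computed per direction and averaged over the four
    directions.  Returns ``{measure: raster}`` in :data:`TEXTURE_MEASURES`
    order.  Correlation of a constant window is defined as 0.
    """
    config = config or TextureConfig()
    band = np.asarray(band, dtype=float)
    if min(band.shape) < config.window:
        raise ValueError("texture window larger than raster")
    q = quantize(band, config.gray_levels)
    offsets = np.asarray(_DIRECTIONS, dtype=np.int64)
    stack = _glcm_textures_kernel(q, config.window // 2, config.gray_levels, offsets)
    return {m: stack[k] for k, m in enumerate(TEXTURE_MEASURES)}


def build_sar_stack(
    hh_dn: np.ndarray,
    hv_dn: np.ndarray,
    grid: Grid,
    texture_config: TextureConfig | None = None,
    lee_window: int = 3,
    lee_noise_sd: float = 1.0,
    despeckle: bool = True,
    compute_textures: bool = True,
) -> SARStack:
    """Full predictor stack from HH/HV digital-number rasters."""
    if hh_dn.shape != grid.shape or hv_dn.shape != grid.shape:
        raise ValueError("DN rasters do not match the grid geometry")
    hh = dn_to_gamma0(hh_dn)
    hv = dn_to_gamma0(hv_dn)
    if despeckle:
        hh = lee_filter(hh, lee_window, lee_noise_sd)
        hv = lee_filter(hv, lee_window, lee_noise_sd)
    ndbi = compute_ndbi(hh, hv)
    textures: dict = {}
    if compute_textures:
        for name, band in (("HH", hh), ("HV", hv), ("NDBI", ndbi)):
            for measure, raster in compute_glcm_textures(band, texture_config).items():
                textures[f"{name}_{measure}"] = raster
    return SARStack(grid=grid, hh=hh, hv=hv, ndbi=ndbi, textures=textures)


def extract_plot_features(
    layers: dict,
    grid: Grid,
    units: pd.DataFrame,
    radius_m: float = PLOT_RADIUS_M,
) -> pd.DataFrame:
    """Mean of every layer over each unit's 1-ha circular footprint.

    ``units`` needs unit_id, x, y (footprint centre).  Units whose centroid
    falls outside the raster extent are dropped (logged); edge footprints
    average over the available pixels with the coverage fraction reported in
    the ``footprint_coverage`` column.
    """
    names = list(layers)
    for name in names:
        if layers[name].shape != grid.shape:
            raise ValueError(f"layer {name!r} does not match the grid")
    span = int(np.ceil(radius_m / grid.px)) + 1
    rows = []
    for _, u in units.iterrows():
        if not grid.contains(u["x"], u["y"]):
            logger.info("unit %r centroid outside raster extent; dropped", u["unit_id"])
            continue
        rc, cc = grid.rowcol(u["x"], u["y"])
        rr, cols = np.mgrid[rc - span : rc + span + 1, cc - span : cc + span + 1]
        px_x, px_y = grid.xy(rr, cols)
        incircle = (px_x - u["x"]) ** 2 + (px_y - u["y"]) ** 2 <= radius_m**2
        if not incircle.any():  # radius below half a pixel: nearest pixel
            incircle = (rr == rc) & (cols == cc)
        full = int(incircle.sum())
        inraster = incircle & (rr >= 0) & (rr < grid.nrows) & (cols >= 0) & (cols < grid.ncols)
        npx = int(inraster.sum())
        if npx == 0:
            logger.info("unit %r footprint entirely off-raster; dropped", u["unit_id"])
            continue
        if npx < full:
            logger.info("unit %r has partial footprint (%d/%d px)", u["unit_id"], npx, full)
        rec = {"unit_id": u["unit_id"], "footprint_coverage": npx / full}
        ridx, cidx = rr[inraster], cols[inraster]
        for name in names:
            rec[name] = float(np.nanmean(layers[name][ridx, cidx]))
        rows.append(rec)
    return pd.DataFrame(rows)
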