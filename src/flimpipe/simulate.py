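"""Synthetic instrument and tissue simulator with known ground truth.

Generates everything the analysis consumes: time-multiplexed waveform
records (IRF-convolved exponential decays plus white Gaussian noise at a
target per-channel SNR), white-light frames with a blue aiming-beam spot
on a pink tissue-like background, grayscale annotation maps, and
multi-patient cohorts spanning the three imaging contexts.

Class parameter values are simulator assumptions chosen to produce
realistic contrast, not published tissue constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .coregistration import BINARY_GROUPING, CONDITION_CODES
from .decay import RawRecord
from .instrument import InstrumentModel, generate_irf

__all__ = [
    "CONTEXTS",
    "Region",
    "generate_annotation_map",
    "generate_waveform",
    "make_tissue_background",
    "render_aiming_beam_frame",
    "TissueClassModel",
    "default_class_models",
    "complementary_class_models",
    "Scan",
    "Patient",
    "generate_cohort",
]

CONTEXTS = ("in_vivo_pre", "ex_vivo", "tumor_bed")

CODE_OF = {cond: code for code, cond in CONDITION_CODES.items()}


# ---------------------------------------------------------------------------
# annotation maps


@dataclass(frozen=True)
class Region:
    """A labeled region: rectangle (x0, y0, x1, y1, half-open), ellipse
    (cx, cy, rx, ry) or polygon (vertices)."""

    condition: str
    kind: str  # "rectangle" | "ellipse" | "polygon"
    params: tuple

    def mask(self, shape) -> np.ndarray:
        h, w = shape
        if self.kind == "rectangle":
            x0, y0, x1, y1 = self.params
            m = np.zeros(shape, dtype=bool)
            m[max(0, int(y0)) : max(0, int(y1)), max(0, int(x0)) : max(0, int(x1))] = True
            return m
        if self.kind == "ellipse":
            cx, cy, rx, ry = self.params
            yy, xx = np.ogrid[:h, :w]
            return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        if self.kind == "polygon":
            from skimage.draw import polygon

            verts = np.asarray(self.params, dtype=float)
            rr, cc = polygon(verts[:, 1], verts[:, 0], shape)
            m = np.zeros(shape, dtype=bool)
            m[rr, cc] = True
            return m
        raise ValueError(f"unknown region kind {self.kind!r}")


def generate_annotation_map(regions, frame_size, code_of=None) -> np.ndarray:
    """Paint labeled regions into an 8-bit grayscale annotation image.

    Overlapping regions with different conditions are rejected (the ground
    truth would be ambiguous); there is no blending, so the image contains
    exactly the configured code values.
    """
    code_of = CODE_OF if code_of is None else code_of
    w, h = frame_size
    img = np.zeros((h, w), dtype=np.uint8)
    for region in regions:
        code = code_of[region.condition]
        m = region.mask((h, w))
        clash = (img != 0) & m & (img != code)
        if clash.any():
            raise ValueError(
                f"region {region.condition!r} overlaps a differently labeled region"
            )
        img[m] = code
    return img


# ---------------------------------------------------------------------------
# waveforms


def generate_waveform(
    lifetimes,
    weights,
    irf: np.ndarray,
    model: InstrumentModel,
    target_snr: float | None,
    rng: np.random.Generator,
    amplitude: float = 1.0,
    point_index: int = 0,
    truncation_tolerance: float = 0.01,
) -> tuple:
    """Simulate one record; returns (RawRecord, ground-truth dict).

    Each channel window holds ``weight * amplitude`` units of decay
    integral (trapezoid, window-normalized) of an IRF-convolved
    mono-exponential, plus white Gaussian noise scaled so the realized
    per-channel SNR (peak over noise sigma) matches ``target_snr`` dB.
    ``target_snr=None`` disables noise.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0) and weights.sum() > 0:
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
    dt = model.sampling_interval
    n = model.samples_per_channel
    t = model.window_times
    record = np.full(model.record_length, model.background_level, dtype=float)
    flags = []
    sigmas = np.zeros(model.n_channels)
    amp_factor = 10.0 ** (-(target_snr or 0.0) / 20.0)
    for ch in range(model.n_channels):
        if weights[ch] <= 0:
            continue
        decay = np.exp(-t / lifetimes[ch])
        if decay[-1] > truncation_tolerance * decay[0]:
            flags.append(f"truncation_ch{ch + 1}")
        sig = np.convolve(irf, decay)[:n]
        area = np.trapezoid(sig, dx=dt)
        sig = sig * (weights[ch] * amplitude / area)
        record[model.channel_slice(ch)] += sig
        if target_snr is not None:
            sigmas[ch] = sig.max() * amp_factor
    if target_snr is not None:
        ref = sigmas[sigmas > 0].mean() if np.any(sigmas > 0) else amplitude * amp_factor
        sigmas[sigmas == 0] = ref
        record[: model.baseline_samples] += rng.normal(0.0, ref, model.baseline_samples)
        for ch in range(model.n_channels):
            record[model.channel_slice(ch)] += rng.normal(0.0, sigmas[ch], n)
    included = weights[:3]
    truth = {
        "tau_ch1": lifetimes[0],
        "tau_ch2": lifetimes[1],
        "tau_ch3": lifetimes[2],
        "ratio_ch1": included[0] / included.sum() if included.sum() > 0 else np.nan,
        "ratio_ch2": included[1] / included.sum() if included.sum() > 0 else np.nan,
        "ratio_ch3": included[2] / included.sum() if included.sum() > 0 else np.nan,
        "target_snr": np.nan if target_snr is None else target_snr,
    }
    rec = RawRecord(samples=record, time_base=dt, point_index=point_index, flags=tuple(flags))
    return rec, truth


# ---------------------------------------------------------------------------
# frames


def make_tissue_background(frame_size, rng: np.random.Generator) -> np.ndarray:
    """Low-saturation pink tissue-like background, uint8 RGB (H, W, 3)."""
    w, h = frame_size
    base = np.array([0.78, 0.60, 0.62])
    texture = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=max(2.0, min(w, h) / 40.0))
    span = texture.max() - texture.min()
    if span > 0:
        texture = (texture - texture.min()) / span - 0.5
    img = base[None, None, :] + 0.12 * texture[:, :, None]
    return (np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)


SPOT_COLOR = np.array([60.0, 70.0, 255.0])  # 455 nm continuous-wave beam


def render_aiming_beam_frame(
    background: np.ndarray,
    center,
    radius: float,
    spot: bool = True,
    strength: float = 0.95,
) -> np.ndarray:
    """Composite a Gaussian-profile blue spot onto a background frame.

    The spot hue/saturation are separable from the pink background in HSV
    space.  With ``spot=False`` the background is returned unchanged.
    """
    frame = background.copy()
    if not spot:
        return frame
    if radius <= 0:
        raise ValueError("spot radius must be positive")
    h, w = frame.shape[:2]
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"spot center {center} outside frame {(w, h)}")
    half = int(np.ceil(3 * radius))
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * radius**2)) * strength
    patch = frame[y0:y1, x0:x1].astype(float)
    blended = patch * (1.0 - g[:, :, None]) + SPOT_COLOR[None, None, :] * g[:, :, None]
    frame[y0:y1, x0:x1] = np.clip(blended, 0, 255).astype(np.uint8)
    return frame


# ---------------------------------------------------------------------------
# tissue classes


@dataclass
class TissueClassModel:
    """Per-class, per-channel decay parameters and context offsets."""

    label: str
    lifetime_mean: np.ndarray
    lifetime_sd: np.ndarray
    weights: np.ndarray
    weight_sd: np.ndarray
    context_shift: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lifetime_mean = np.asarray(self.lifetime_mean, dtype=float)
        self.lifetime_sd = np.asarray(self.lifetime_sd, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.weight_sd = np.asarray(self.weight_sd, dtype=float)
        if np.any(self.lifetime_mean <= 0):
            raise ValueError("lifetime means must be positive")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("spectral weights must be >= 0 and sum to 1")

    def shifted(self, context: str):
        dlt, dw = self.context_shift.get(context, (np.zeros(4), np.zeros(4)))
        return self.lifetime_mean + np.asarray(dlt), self.weights + np.asarray(dw)

    def sample(self, context: str, rng: np.random.Generator, n: int = 1):
        """Draw per-point true (lifetimes, weights); shapes (n, 4)."""
        lt_mean, w_mean = self.shifted(context)
        lt = rng.normal(lt_mean, self.lifetime_sd, (n, 4)).clip(0.2, None)
        w = rng.normal(w_mean, self.weight_sd, (n, 4)).clip(1e-3, None)
        w = w / w.sum(axis=1, keepdims=True)
        return lt, w


_EX_VIVO_SHIFT = (np.array([0.5, 0.2, 0.05, 0.1]), np.array([0.03, -0.015, -0.015, 0.0]))
_TB_PERIPHERY_SHIFT = (np.array([0.15, 0.05, 0.02, 0.0]), np.array([0.01, -0.005, -0.005, 0.0]))
_SHIFTS = {"ex_vivo": _EX_VIVO_SHIFT, "tumor_bed": _TB_PERIPHERY_SHIFT}

_HEALTHY_LT = np.array([5.2, 4.2, 3.8, 3.0])
_HEALTHY_W = np.array([0.36, 0.30, 0.24, 0.10])
_LT_SD = np.array([0.25, 0.25, 0.25, 0.25])
_W_SD = np.array([0.02, 0.02, 0.02, 0.01])
_CANCER_DLT = np.array([-0.6, -0.5, -0.3, 0.0])
_CANCER_DW = np.array([-0.08, 0.01, 0.07, 0.0])


def default_class_models(contrast: float = 1.0) -> dict:
    """Healthy / cancer / tumor-bed models; ``contrast`` scales the
    cancer-vs-healthy mean separation (0 gives identical distributions)."""
    healthy = TissueClassModel(
        "healthy_epithelium", _HEALTHY_LT, _LT_SD, _HEALTHY_W, _W_SD, dict(_SHIFTS)
    )
    cancer_w = _HEALTHY_W + contrast * _CANCER_DW
    cancer = TissueClassModel(
        "cancer",
        _HEALTHY_LT + contrast * _CANCER_DLT,
        _LT_SD,
        cancer_w / cancer_w.sum(),
        _W_SD,
        dict(_SHIFTS),
    )
    tumor_bed = TissueClassModel(
        "tumor_bed",
        np.array([3.9, 4.0, 3.7, 2.8]),
        _LT_SD * 1.4,
        np.array([0.30, 0.31, 0.27, 0.12]),
        _W_SD * 1.4,
        {},
    )
    return {m.label: m for m in (healthy, cancer, tumor_bed)}


def complementary_class_models(per_param_d: float = 1.0) -> dict:
    """Cancer contrast split over two complementary parameters (CH2
    lifetime and CH3 intensity ratio), each with standardized shift
    ``per_param_d``; all other parameters are matched."""
    models = default_class_models(0.0)
    dlt = np.array([0.0, per_param_d * _LT_SD[1], 0.0, 0.0])
    dw = np.array([-per_param_d * _W_SD[2], 0.0, per_param_d * _W_SD[2], 0.0])
    cancer_w = _HEALTHY_W + dw
    models["cancer"] = TissueClassModel(
        "cancer", _HEALTHY_LT + dlt, _LT_SD, cancer_w / cancer_w.sum(), _W_SD, dict(_SHIFTS)
    )
    return models


# ---------------------------------------------------------------------------
# scans and cohorts


@dataclass
class Scan:
    """All simulated input streams for one patient in one context."""

    patient_id: int
    context: str
    records: list
    ground_truth: pd.DataFrame
    annotation: np.ndarray
    background: np.ndarray
    spot_radius: float
    frame_size: tuple

    def frames(self):
        """Yield (point_index, RGB frame) with the beam at each scan point."""
        for _, row in self.ground_truth.iterrows():
            yield int(row.point_index), render_aiming_beam_frame(
                self.background, (row.x, row.y), self.spot_radius
            )


@dataclass
class Patient:
    patient_id: int
    scans: dict


def _scan_geometry(frame_size, rng):
    w, h = frame_size
    jx = rng.uniform(-0.02, 0.02) * w
    jy = rng.uniform(-0.02, 0.02) * h
    cx, cy = w / 2 + jx, h / 2 + jy
    rx, ry = 0.10 * w, 0.16 * h
    gap = max(25.0, 0.03 * w)
    band_w = 0.12 * w
    y0, y1 = 0.25 * h, 0.75 * h
    left = (cx - rx - gap - band_w, y0, cx - rx - gap, y1)
    right = (cx + rx + gap, y0, cx + rx + gap + band_w, y1)
    return (cx, cy, rx, ry), left, right, gap


def _sample_in_rect(rect, margin, n, rng):
    x0, y0, x1, y1 = rect
    xs = rng.uniform(x0 + margin, x1 - margin, n)
    ys = rng.uniform(y0 + margin, y1 - margin, n)
    return np.column_stack([xs, ys])


def _sample_in_ellipse(ellipse, margin, n, rng):
    cx, cy, rx, ry = ellipse
    pts = np.empty((n, 2))
    k = 0
    while k < n:
        u = rng.uniform(-1, 1, (2 * (n - k), 2))
        keep = (u**2).sum(axis=1) <= 1.0
        sel = u[keep][: n - k]
        pts[k : k + sel.shape[0], 0] = cx + sel[:, 0] * (rx - margin)
        pts[k : k + sel.shape[0], 1] = cy + sel[:, 1] * (ry - margin)
        k += sel.shape[0]
    return pts


def _build_scan(
    patient_id,
    context,
    model,
    irf,
    class_models,
    patient_lt_offset,
    patient_w_offset,
    n_points,
    snr_mean,
    snr_sd,
    spot_radius,
    rng,
):
    frame_size = model.frame_size
    ellipse, left, right, gap = _scan_geometry(frame_size, rng)
    cx, cy, rx, ry = ellipse
    if context == "tumor_bed":
        center_condition = "tumor_bed"
        center_region = Region("tumor_bed", "rectangle", (cx - rx, cy - ry, cx + rx, cy + ry))
        center_rect = (cx - rx, cy - ry, cx + rx, cy + ry)
    else:
        center_condition = "cancer"
        center_region = Region("cancer", "ellipse", ellipse)
        center_rect = None
    regions = [
        center_region,
        Region("healthy_epithelium", "rectangle", left),
        Region("healthy_epithelium", "rectangle", right),
    ]
    annotation = generate_annotation_map(regions, frame_size)

    n_center = int(round(0.45 * n_points))
    n_gap = max(2, int(round(0.10 * n_points)))
    n_healthy = n_points - n_center - n_gap
    margin = 4.0
    if center_rect is not None:
        pts_center = _sample_in_rect(center_rect, margin, n_center, rng)
    else:
        pts_center = _sample_in_ellipse(ellipse, margin, n_center, rng)
    nh_left = n_healthy // 2
    pts_healthy = np.vstack(
        [
            _sample_in_rect(left, margin, nh_left, rng),
            _sample_in_rect(right, margin, n_healthy - nh_left, rng),
        ]
    )
    # corridor points between the center region and the right band exercise
    # the unlabeled / near-boundary paths downstream
    gx0, gx1 = cx + rx + 2.0, cx + rx + gap - 2.0
    pts_gap = np.column_stack(
        [rng.uniform(gx0, gx1, n_gap), rng.uniform(cy - ry / 2, cy + ry / 2, n_gap)]
    )
    pts = np.vstack([pts_center, pts_healthy, pts_gap])
    conds = (
        [center_condition] * n_center
        + ["healthy_epithelium"] * n_healthy
        + ["gap"] * n_gap
    )
    order = np.lexsort((pts[:, 0], np.round(pts[:, 1] / 40.0)))
    pts = pts[order]
    conds = [conds[i] for i in order]

    records = []
    truth_rows = []
    for i, ((x, y), cond) in enumerate(zip(pts, conds)):
        cls = class_models[cond if cond != "gap" else "healthy_epithelium"]
        lt, wts = cls.sample(context, rng)
        lt = (lt[0] + patient_lt_offset).clip(0.2, None)
        wts = (wts[0] + patient_w_offset).clip(1e-3, None)
        wts = wts / wts.sum()
        snr = float(np.clip(rng.normal(snr_mean, snr_sd), 20.0, 60.0))
        rec, truth = generate_waveform(
            lt, wts, irf, model, snr, rng, point_index=i
        )
        records.append(rec)
        truth_rows.append(
            {"point_index": i, "x": x, "y": y, "condition": cond, **truth}
        )
    gt = pd.DataFrame(truth_rows)
    background = make_tissue_background(frame_size, rng)
    return Scan(
        patient_id=patient_id,
        context=context,
        records=records,
        ground_truth=gt,
        annotation=annotation,
        background=background,
        spot_radius=spot_radius,
        frame_size=frame_size,
    )


def generate_cohort(
    n_patients: int,
    model: InstrumentModel | None = None,
    seed: int = 0,
    class_models: dict | None = None,
    n_points: int = 120,
    snr_mean: float = 42.0,
    snr_sd: float = 5.0,
    contexts=CONTEXTS,
    spot_radius: float = 10.0,
    patient_lifetime_sd: float = 0.15,
    patient_weight_sd: float = 0.01,
) -> list:
    """Simulate a cohort; fully reproducible from ``seed``.

    Each patient carries one scan per requested context: pre-resection
    (cancer plus healthy periphery), ex vivo (context-shifted copy) and a
    tumor bed with no residual cancer.  Patient-level parameter offsets are
    shared across that patient's scans and classes.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    model = model or InstrumentModel()
    class_models = class_models or default_class_models()
    irf = generate_irf(model)
    root = np.random.SeedSequence(seed)
    patients = []
    for pid, pseed in enumerate(root.spawn(n_patients), start=1):
        prng = np.random.default_rng(pseed)
        lt_off = prng.normal(0.0, patient_lifetime_sd, 4)
        w_off = prng.normal(0.0, patient_weight_sd, 4)
        scans = {}
        for context in contexts:
            scans[context] = _build_scan(
                pid,
                context,
                model,
                irf,
                class_models,
                lt_off,
                w_off,
                n_points,
                snr_mean,
                snr_sd,
                spot_radius,
                prng,
            )
        patients.append(Patient(patient_id=pid, scans=scans))
    return patients
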