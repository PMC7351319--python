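"""Histology-annotation coregistration and the measurement filter chain.

Annotations are 8-bit grayscale images whose pixel values encode tissue
conditions.  Measurements pick up the condition of the annotated pixel they
fall on, or of the nearest annotated pixel within a fixed radius; points
whose neighborhood mixes binary-disparate conditions are excluded, as are
points failing the per-channel SNR threshold and the per-patient,
per-context MAD outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import cKDTree

__all__ = [
    "CONDITION_CODES",
    "BINARY_GROUPING",
    "AnnotationMap",
    "assign_labels",
    "exclude_heterogeneous",
    "filter_snr",
    "mad_filter",
    "apply_filters",
    "FLIM_PARAMETERS",
]

#: pixel value -> tissue condition (values are a package convention; any
#: code table can be supplied to AnnotationMap)
CONDITION_CODES = {
    0: "none",
    40: "thin_epithelium",
    60: "thick_epithelium",
    85: "healthy_epithelium",
    100: "dysplasia",
    120: "ulceration",
    170: "cancer",
    255: "tumor_bed",
}

#: condition -> binary class; benign fine-grained conditions group to healthy
BINARY_GROUPING = {
    "thin_epithelium": "healthy",
    "thick_epithelium": "healthy",
    "healthy_epithelium": "healthy",
    "dysplasia": "healthy",
    "ulceration": "healthy",
    "tumor_bed": "healthy",
    "cancer": "cancer",
}

FLIM_PARAMETERS = [
    "lifetime_ch1",
    "lifetime_ch2",
    "lifetime_ch3",
    "intratio_ch1",
    "intratio_ch2",
    "intratio_ch3",
]


@dataclass
class AnnotationMap:
    """Grayscale annotation image plus its code table and binary grouping."""

    image: np.ndarray
    code_table: dict = field(default_factory=lambda: dict(CONDITION_CODES))
    binary_grouping: dict = field(default_factory=lambda: dict(BINARY_GROUPING))

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        present = set(np.unique(self.image).tolist()) - {0}
        unknown = present - set(self.code_table)
        if unknown:
            raise ValueError(f"pixel values without a code-table entry: {sorted(unknown)}")
        conditions = {c for c in self.code_table.values() if c != "none"}
        ungrouped = conditions - set(self.binary_grouping)
        if ungrouped:
            raise ValueError(f"conditions without a binary group: {sorted(ungrouped)}")

    def condition_of(self, code: int) -> str:
        return self.code_table.get(int(code), "none")

    def binary_of(self, condition: str):
        return self.binary_grouping.get(condition)

    def annotated_pixels(self):
        """(coords (n,2) as (x, y) pixel centers, codes (n,))."""
        rows, cols = np.nonzero(self.image)
        coords = np.column_stack([cols, rows]).astype(float)
        return coords, self.image[rows, cols]

    # -- PNG round trip (lossless by construction) -------------------------

    def to_png(self, path):
        Image.fromarray(self.image, mode="L").save(path, format="PNG")

    @classmethod
    def from_png(cls, path, code_table=None, binary_grouping=None):
        img = np.asarray(Image.open(path).convert("L"))
        kwargs = {}
        if code_table is not None:
            kwargs["code_table"] = code_table
        if binary_grouping is not None:
            kwargs["binary_grouping"] = binary_grouping
        return cls(image=img, **kwargs)


def assign_labels(points: pd.DataFrame, amap: AnnotationMap, radius: float = 10.0) -> pd.DataFrame:
    """Attach tissue conditions to positioned measurements.

    A point lying on an annotated pixel takes that pixel's condition;
    otherwise it takes the condition of the nearest annotated pixel within
    ``radius`` (Euclidean, inclusive); otherwise it is unlabeled.
    """
    out = points.copy()
    conditions = []
    binaries = []
    h, w = amap.image.shape
    coords, codes = amap.annotated_pixels()
    tree = cKDTree(coords) if coords.size else None
    for x, y in zip(out["x"].to_numpy(), out["y"].to_numpy()):
        cond = None
        if np.isfinite(x) and np.isfinite(y):
            col, row = int(round(x)), int(round(y))
            if 0 <= row < h and 0 <= col < w and amap.image[row, col] != 0:
                cond = amap.condition_of(amap.image[row, col])
            elif tree is not None:
                dist, idx = tree.query([x, y], k=1)
                if dist <= radius:
                    cond = amap.condition_of(codes[idx])
        conditions.append(cond if cond is not None else "")
        binaries.append(amap.binary_of(cond) if cond else "")
    out["condition"] = conditions
    out["binary"] = binaries
    out["unlabeled"] = out["condition"] == ""
    return out


def exclude_heterogeneous(points: pd.DataFrame, amap: AnnotationMap, radius: float = 10.0) -> pd.DataFrame:
    """Flag points whose radius-neighborhood mixes binary-disparate
    conditions (e.g. cancer next to healthy)."""
    out = points.copy()
    coords, codes = amap.annotated_pixels()
    groups = np.array([amap.binary_of(amap.condition_of(c)) or "" for c in codes])
    tree = cKDTree(coords) if coords.size else None
    flagged = []
    for x, y in zip(out["x"].to_numpy(), out["y"].to_numpy()):
        het = False
        if tree is not None and np.isfinite(x) and np.isfinite(y):
            idx = tree.query_ball_point([x, y], r=radius)
            if idx:
                local = set(groups[idx]) - {""}
                het = len(local) >= 2
        flagged.append(het)
    out["heterogeneity_excluded"] = flagged
    return out


def filter_snr(points: pd.DataFrame, threshold: float = 30.0) -> pd.DataFrame:
    """Pass iff SNR >= threshold on every analysis channel (inclusive bound;
    missing SNR fails)."""
    out = points.copy()
    snrs = out[["snr_ch1", "snr_ch2", "snr_ch3"]].to_numpy(dtype=float)
    ok = np.all(np.nan_to_num(snrs, nan=-np.inf) >= threshold, axis=1)
    out["snr_pass"] = ok
    return out


def mad_filter(values, k: float = 2.5) -> np.ndarray:
    """Keep mask for the raw-MAD outlier rule.

    keep x iff |x - median| <= k * MAD with MAD = median(|x - median|)
    (no normal-consistency factor).  With MAD == 0 only values equal to
    the median survive, which keeps everything when all values are equal.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad_filter requires at least one value")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    return np.abs(v - med) <= k * mad


def apply_filters(
    labeled: pd.DataFrame,
    snr_threshold: float = 30.0,
    mad_k: float = 2.5,
) -> tuple:
    """Run the SNR and per-parameter MAD rules on one patient+context table.

    Expects label columns from assign_labels/exclude_heterogeneous.  Adds
    ``snr_pass``, per-parameter ``mad_pass_*`` masks (computed on the
    SNR-passing, labeled, non-heterogeneous subset), an aggregate
    ``mad_pass`` and ``analysis_ok``.  Returns (table, accounting dict).
    """
    df = filter_snr(labeled, snr_threshold)
    base = (~df["unlabeled"]) & (~df["heterogeneity_excluded"]) & df["snr_pass"]
    for p in FLIM_PARAMETERS:
        col = f"mad_pass_{p}"
        df[col] = False
        vals = df.loc[base, p].to_numpy(dtype=float)
        if vals.size:
            df.loc[base, col] = mad_filter(vals, mad_k)
    mad_cols = [f"mad_pass_{p}" for p in FLIM_PARAMETERS]
    df["mad_pass"] = df[mad_cols].all(axis=1) & base
    df["analysis_ok"] = df["mad_pass"]
    accounting = {
        "n_points": int(len(df)),
        "unlabeled": int(df["unlabeled"].sum()),
        "heterogeneity_excluded": int((df["heterogeneity_excluded"] & ~df["unlabeled"]).sum()),
        "snr_removed": int((base.index.size and (~df["snr_pass"] & ~df["unlabeled"] & ~df["heterogeneity_excluded"]).sum())),
        "mad_removed": int((base & ~df["mad_pass"]).sum()),
        "analyzed": int(df["analysis_ok"].sum()),
    }
    return df, accounting
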