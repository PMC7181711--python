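"""Fixed 1128-element radiomic feature catalog for perfusion map sets.

For each of the 8 perfusion maps (PE, AUC, TP, MTT, T0, MaxIP, AvgIP,
StdIP) the catalog holds 140 features:

* 20 first-order (histogram) statistics of the finite in-mask voxels;
* 78 co-occurrence texture features: 6 GLCM properties (contrast,
  dissimilarity, homogeneity, energy, correlation, entropy) on each of the
  13 unique 3D direction offsets at distance 1;
* 42 direction-averaged co-occurrence features: the same 6 properties on
  the direction-averaged GLCM at distances 1–7.

Together with the 8 ROI-level conventional bolus parameters this gives
8 x 140 + 8 = 1128 features, in a fixed order shared by every table the
pipeline writes.

Maps are quantized to 32 grey levels by equal-width binning between the
in-mask finite min and max (parametric maps have no absolute scale, so the
min–max normalization makes texture features invariant to positive affine
rescaling of a map).  NaN voxels (outside the VOI or unfittable) are
excluded everywhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from dceus.bolus import ROI_FEATURE_NAMES
from dceus.maps import MAP_NAMES, PerfusionMapSet

__all__ = [
    "FIRST_ORDER_NAMES",
    "GLCM_PROPS",
    "OFFSETS_13",
    "DISTANCES",
    "LABEL_COLS",
    "feature_catalog",
    "quantize_map",
    "first_order_features",
    "glcm_3d",
    "glcm_properties",
    "texture_features",
    "extract_features",
    "percent_change",
]

log = logging.getLogger(__name__)

N_LEVELS = 32
DISTANCES = tuple(range(1, 8))

FIRST_ORDER_NAMES = (
    "mean", "std", "variance", "skewness", "kurtosis", "min", "max", "range",
    "p5", "p10", "p25", "median", "p75", "p90", "p95", "iqr",
    "entropy", "energy", "uniformity", "cov",
)

GLCM_PROPS = ("contrast", "dissimilarity", "homogeneity", "energy",
              "correlation", "entropy")

#: The 13 unique direction offsets of the 26-neighborhood (one per +/- pair),
#: fixed lexicographic order on (dz, dy, dx) with the first nonzero positive.
OFFSETS_13 = tuple(
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in ((-1, 0, 1) if dz else (0, 1))
    for dx in ((-1, 0, 1) if (dz or dy) else (1,))
)
assert len(OFFSETS_13) == 13

LABEL_COLS = ("subject", "day", "replicate", "cohort", "arm")


def _offset_tag(off):
    return "o" + "".join(f"{v:+d}" for v in off)


def feature_catalog() -> list[str]:
    """The ordered names of all 1128 features."""
    names: list[str] = []
    for m in MAP_NAMES:
        for s in FIRST_ORDER_NAMES:
            names.append(f"{m}_fo_{s}")
        for off in OFFSETS_13:
            for p in GLCM_PROPS:
                names.append(f"{m}_glcm_d1_{_offset_tag(off)}_{p}")
        for d in DISTANCES:
            for p in GLCM_PROPS:
                names.append(f"{m}_glcm_avg_d{d}_{p}")
    names.extend(f"roi_{n}" for n in ROI_FEATURE_NAMES)
    assert len(names) == 1128 and len(set(names)) == 1128
    return names


# ---------------------------------------------------------------------------
# quantization and first-order statistics
# ---------------------------------------------------------------------------

def quantize_map(map3d, mask, n_levels: int = N_LEVELS):
    """Equal-width binning of finite in-mask values into ``n_levels`` levels.

    Returns an integer volume with -1 marking excluded voxels (off-mask or
    NaN).  A constant map maps to level 0 everywhere in-mask.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    map3d = np.asarray(map3d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    valid = mask & np.isfinite(map3d)
    out = np.full(map3d.shape, -1, dtype=np.int16)
    if valid.sum() < 2:
        raise ValueError("need at least 2 finite in-mask values")
    v = map3d[valid]
    lo, hi = v.min(), v.max()
    if hi <= lo:
        out[valid] = 0
        return out
    q = np.floor((map3d[valid] - lo) / (hi - lo) * n_levels).astype(np.int16)
    out[valid] = np.minimum(q, n_levels - 1)
    return out


def first_order_features(map3d, mask, n_levels: int = N_LEVELS) -> dict[str, float]:
    """The 20 first-order statistics over finite in-mask voxels.

    Percentiles use linear interpolation between order statistics; std and
    variance are population (divide-by-N); entropy (bits) and uniformity
    are computed on the 32-bin equal-width histogram normalized to sum 1;
    energy is the sum of squared intensities.  Fewer than 8 finite voxels
    flags the whole block as missing (NaN).
    """
    map3d = np.asarray(map3d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    v = map3d[mask & np.isfinite(map3d)]
    if v.size < 8:
        return {n: np.nan for n in FIRST_ORDER_NAMES}
    mean = float(v.mean())
    std = float(v.std())
    pcts = np.percentile(v, [5, 10, 25, 50, 75, 90, 95])
    hist, _ = np.histogram(v, bins=n_levels)
    p = hist / hist.sum()
    nz = p[p > 0]
    return {
        "mean": mean,
        "std": std,
        "variance": std**2,
        "skewness": float(sps.skew(v)) if std > 0 else 0.0,
        "kurtosis": float(sps.kurtosis(v)) if std > 0 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "p5": float(pcts[0]),
        "p10": float(pcts[1]),
        "p25": float(pcts[2]),
        "median": float(pcts[3]),
        "p75": float(pcts[4]),
        "p90": float(pcts[5]),
        "p95": float(pcts[6]),
        "iqr": float(pcts[4] - pcts[2]),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "energy": float((v**2).sum()),
        "uniformity": float((p**2).sum()),
        "cov": std / mean if mean != 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# 3D grey-level co-occurrence matrices
# ---------------------------------------------------------------------------

def _pair_views(q, offset):
    sl_a, sl_b = [], []
    for o, s in zip(offset, q.shape):
        if abs(o) >= s:
            return None, None
        if o >= 0:
            sl_a.append(slice(0, s - o))
            sl_b.append(slice(o, s))
        else:
            sl_a.append(slice(-o, s))
            sl_b.append(slice(0, s + o))
    return q[tuple(sl_a)], q[tuple(sl_b)]


def glcm_3d(quantized, mask=None, offset_zyx=(0, 0, 1), n_levels: int | None = None):
    """Symmetric, normalized 3D co-occurrence matrix at one offset.

    Counts ordered voxel pairs (p, p + offset) whose endpoints are both
    valid (in-mask, finite: level >= 0), symmetrizes by adding the reverse
    direction, and normalizes to sum 1.  Returns None when the offset
    yields no valid pair (the corresponding properties become missing).
    """
    q = np.asarray(quantized)
    if not any(offset_zyx):
        raise ValueError("offset must be nonzero")
    if mask is not None:
        q = np.where(np.asarray(mask, dtype=bool), q, -1)
    L = int(n_levels if n_levels is not None else q.max() + 1)
    if L < 1:
        return None
    if L > 64:
        raise ValueError("more than 64 grey levels")
    a, b = _pair_views(q, offset_zyx)
    if a is None:
        return None
    # invalid pairs (either endpoint excluded) collapse onto a sentinel bin
    codes = a.astype(np.int64) * L + b
    codes[(a < 0) | (b < 0)] = L * L
    counts = np.bincount(codes.ravel(), minlength=L * L + 1)[: L * L]
    total = counts.sum()
    if total == 0:
        return None
    counts = counts.reshape(L, L).astype(float)
    counts = counts + counts.T
    return counts / counts.sum()


def glcm_properties(P) -> dict[str, float]:
    """The 6 catalog properties of one normalized GLCM.

    Correlation is undefined (NaN) when a marginal variance is zero
    (e.g. a constant volume).
    """
    if P is None:
        return {p: np.nan for p in GLCM_PROPS}
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    diff = i[:, None] - i[None, :]
    pi = P.sum(axis=1)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    nz = P[P > 0]
    if var > 1e-12:
        corr = float(((i[:, None] * i[None, :] * P).sum() - mu * mu) / var)
    else:
        corr = np.nan
    return {
        "contrast": float((P * diff**2).sum()),
        "dissimilarity": float((P * np.abs(diff)).sum()),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
        "energy": float((P**2).sum()),
        "correlation": corr,
        "entropy": float(-(nz * np.log2(nz)).sum()),
    }


def texture_features(map3d, mask, n_levels: int = N_LEVELS,
                     distances=DISTANCES) -> dict[str, float]:
    """The 120 co-occurrence features of one map.

    6 properties on each of the 13 distance-1 direction GLCMs, plus the
    same 6 on the direction-averaged GLCM (mean of the 13 matrices) at each
    distance in ``distances``.
    """
    try:
        q = quantize_map(map3d, mask, n_levels)
    except ValueError:
        out = {}
        for off in OFFSETS_13:
            for p in GLCM_PROPS:
                out[f"glcm_d1_{_offset_tag(off)}_{p}"] = np.nan
        for d in distances:
            for p in GLCM_PROPS:
                out[f"glcm_avg_d{d}_{p}"] = np.nan
        return out

    out: dict[str, float] = {}
    per_distance_mats: dict[int, list] = {}
    for d in distances:
        mats = [glcm_3d(q, None, tuple(o * d for o in off), n_levels)
                for off in OFFSETS_13]
        per_distance_mats[d] = mats

    for off, P in zip(OFFSETS_13, per_distance_mats[1]):
        props = glcm_properties(P)
        for p in GLCM_PROPS:
            out[f"glcm_d1_{_offset_tag(off)}_{p}"] = props[p]
    for d in distances:
        mats = [m for m in per_distance_mats[d] if m is not None]
        avg = np.mean(mats, axis=0) if mats else None
        props = glcm_properties(avg)
        for p in GLCM_PROPS:
            out[f"glcm_avg_d{d}_{p}"] = props[p]
    return out


# ---------------------------------------------------------------------------
# catalog assembly and longitudinal tables
# ---------------------------------------------------------------------------

def extract_features(mapset: PerfusionMapSet, roi_block: dict[str, float]) -> pd.Series:
    """All 1128 catalog features of one map set, in catalog order.

    A map that is entirely NaN contributes 140 missing values; the
    remaining maps are still computed.
    """
    values: dict[str, float] = {}
    for m in MAP_NAMES:
        vol = mapset.maps[m]
        fo = first_order_features(vol, mapset.voi_mask)
        for s, v in fo.items():
            values[f"{m}_fo_{s}"] = v
        tex = texture_features(vol, mapset.voi_mask)
        for k, v in tex.items():
            values[f"{m}_{k}"] = v
    for n in ROI_FEATURE_NAMES:
        values[f"roi_{n}"] = float(roi_block.get(n, np.nan))
    catalog = feature_catalog()
    return pd.Series([values[n] for n in catalog], index=catalog, dtype=float)


def percent_change(table: pd.DataFrame, baseline_day: int = 0) -> pd.DataFrame:
    """Percent change from the pre-treatment baseline, per subject.

    Each feature value maps to 100 * (value_day - value_baseline) /
    value_baseline; baseline rows are removed from the output; a zero
    baseline yields a missing value rather than +/-inf; subjects without a
    baseline row are dropped with a warning.
    """
    feats = [c for c in table.columns if c not in LABEL_COLS]
    labels = [c for c in LABEL_COLS if c in table.columns]
    base = (table[table["day"] == baseline_day]
            .drop_duplicates("subject").set_index("subject"))
    post = table[table["day"] != baseline_day]
    missing = sorted(set(post["subject"]) - set(base.index))
    for subject in missing:
        log.warning("subject %s has no baseline (day %s); dropped",
                    subject, baseline_day)
    post = post[post["subject"].isin(base.index)]
    B = base.loc[post["subject"], feats].to_numpy(dtype=float)
    V = post[feats].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc = 100.0 * (V - B) / np.where(B == 0, np.nan, B)
    return pd.concat(
        [post[labels].reset_index(drop=True),
         pd.DataFrame(pc, columns=feats)], axis=1)
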