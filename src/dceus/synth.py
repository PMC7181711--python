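"""Synthetic 4D DCE-US cohorts with known ground truth.

Every downstream stage (voxel-wise fitting, feature extraction, selection,
classification, histology correlation) is exercised on simulated data that
emulate the study design of a longitudinal anti-angiogenic treatment
experiment:

* cohort A — treatment-responsive tumor line, treated + control arms,
  imaged on days 0, 1, 3, 7, 10;
* cohort B — treatment-resistant line, same arms and days;
* cohort C — test–retest: two consecutive bolus acquisitions of the same
  tumor within one session (identical truth, independent noise);
* cohort D — separate day-0/day-1 test cohort with a synthetic microvessel
  density (MVD) ground truth correlated with mean perfusion.

Each tumor is an ellipsoidal VOI whose voxel-wise lognormal bolus
parameters (AUC, mu, sigma, t0) are spatially correlated random fields.
Treatment multiplies the AUC field down by the responder effect, more
strongly at the rim (anti-angiogenic therapy hits the smallest, peripheral
vessels first); late days convert a core fraction of the VOI to
zero-perfusion necrosis.  Each acquisition carries an injection-to-
injection global intensity scale jitter plus voxel noise.  Generation is a
pure function of the cohort spec: reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from dceus.bolus import lognormal_model, derived_params

__all__ = [
    "PhantomTruth",
    "CohortSpec",
    "SyntheticDataset",
    "generate_phantom",
    "apply_necrosis",
    "truth_for_day",
    "simulate_bolus_4d",
    "generate_cohorts",
    "CohortCollection",
    "engineered_feature_tables",
]

log = logging.getLogger(__name__)

# parameter ranges of the voxel-wise truth fields (units: a.u.*s, log-s, -, s)
_AUC_RANGE = (30.0, 100.0)
_MU_RANGE = (1.8, 2.5)
_SIGMA_RANGE = (0.3, 0.7)
_T0_RANGE = (4.0, 7.0)      # narrow arrival-time dispersion across voxels
_GLOBAL_SCALE_SDLOG = 0.25  # between-tumor lognormal spread of overall AUC
_MVD_NOISE_SD = 8.0         # a.u., additive noise of the MVD ground truth
_REF_HETEROGENEITY = 4.0    # voxels; reference correlation length


@dataclass
class PhantomTruth:
    """Voxel-wise ground truth of one simulated tumor."""

    shape_zyx: tuple[int, int, int]
    spacing_zyx: tuple[float, float, float]
    mask: np.ndarray
    auc_field: np.ndarray
    mu_field: np.ndarray
    sigma_field: np.ndarray
    t0_field: np.ndarray
    necrosis_mask: np.ndarray
    mvd_truth: float

    def __post_init__(self) -> None:
        for f in (self.mask, self.auc_field, self.mu_field, self.sigma_field,
                  self.t0_field, self.necrosis_mask):
            if f.shape != tuple(self.shape_zyx):
                raise ValueError("all truth fields must share shape_zyx")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if np.any(self.sigma_field[self.mask] <= 0):
            raise ValueError("sigma_field must be > 0 inside the mask")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort run."""

    n_per_group: int = 10
    days: tuple[int, ...] = (0, 1, 3, 7, 10)
    responder_effect: float = 0.4
    nonresponder_effect: float = 0.0
    necrosis_growth: float = 0.1
    noise_model: str = "gaussian"          # or 'multiplicative_gamma'
    noise_level: float = 0.05              # sigma as a fraction of local PE
    scale_jitter_sigma: float = 0.25       # lognormal sdlog, per acquisition
    frame_rate_hz: float = 2.0
    duration_s: float = 180.0
    shape_zyx: tuple[int, int, int] = (32, 32, 32)
    spacing_zyx: tuple[float, float, float] = (0.5, 0.5, 0.5)
    heterogeneity_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.responder_effect <= 1 and 0 <= self.nonresponder_effect <= 1):
            raise ValueError("effects must be in [0, 1]")
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("frame_rate_hz and duration_s must be > 0")
        if self.noise_model not in ("gaussian", "multiplicative_gamma"):
            raise ValueError("unknown noise_model")

    @property
    def frame_times_s(self) -> np.ndarray:
        n = int(round(self.duration_s * self.frame_rate_hz))
        return np.arange(n) / self.frame_rate_hz


@dataclass
class SyntheticDataset:
    """One simulated 4D acquisition with its labels and ground truth."""

    volume4d: np.ndarray
    frame_times_s: np.ndarray
    mask: np.ndarray
    truth: PhantomTruth
    subject_id: str
    day: int
    cohort: str
    arm: str
    replicate: int = 1


def _radius_field(shape_zyx) -> np.ndarray:
    """Normalized ellipsoidal radius (0 center, 1 at the VOI boundary)."""
    axes = [np.arange(s) - (s - 1) / 2.0 for s in shape_zyx]
    semi = [0.38 * s for s in shape_zyx]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.sqrt((zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2)


def _smooth_field(rng, shape, scale) -> np.ndarray:
    """Gaussian-smoothed white noise, normalized by the theoretical std at
    the reference correlation length, so larger scales give flatter fields
    (variance -> 0 as scale -> infinity) instead of being re-amplified."""
    noise = rng.standard_normal(shape)
    smoothed = gaussian_filter(noise, sigma=scale, mode="nearest")
    ref_std = (2.0 * np.sqrt(np.pi) * _REF_HETEROGENEITY) ** -1.5
    return smoothed / ref_std


def _map_range(z, lo, hi):
    from scipy.stats import norm

    return lo + (hi - lo) * norm.cdf(z)


def generate_phantom(shape_zyx=(32, 32, 32), spacing_zyx=(0.5, 0.5, 0.5),
                     heterogeneity_scale: float = 4.0, seed=0) -> PhantomTruth:
    """Ellipsoidal tumor phantom with spatially correlated parameter fields.

    ``heterogeneity_scale`` is the correlation length (voxels) of the
    smoothed random fields; larger values give flatter, more homogeneous
    tumors.  MVD ground truth is a stated monotone function of the mean
    in-mask AUC plus seeded Gaussian noise.  Deterministic given the seed.
    """
    shape_zyx = tuple(int(s) for s in shape_zyx)
    if any(s < 8 for s in shape_zyx):
        raise ValueError("each axis must have at least 8 voxels")
    if heterogeneity_scale <= 0:
        raise ValueError("heterogeneity_scale must be > 0")
    rng = np.random.default_rng(seed)
    mask = _radius_field(shape_zyx) <= 1.0

    g = float(np.exp(rng.normal(0.0, _GLOBAL_SCALE_SDLOG)))
    auc = _map_range(_smooth_field(rng, shape_zyx, heterogeneity_scale),
                     *_AUC_RANGE) * g
    mu = _map_range(_smooth_field(rng, shape_zyx, heterogeneity_scale), *_MU_RANGE)
    sig = _map_range(_smooth_field(rng, shape_zyx, heterogeneity_scale),
                     *_SIGMA_RANGE)
    t0 = _map_range(_smooth_field(rng, shape_zyx, heterogeneity_scale), *_T0_RANGE)

    necrosis = np.zeros(shape_zyx, dtype=bool)
    mvd = float(max(0.0, auc[mask].mean() + rng.normal(0.0, _MVD_NOISE_SD)))
    return PhantomTruth(
        shape_zyx=shape_zyx,
        spacing_zyx=tuple(float(s) for s in spacing_zyx),
        mask=mask,
        auc_field=auc,
        mu_field=mu,
        sigma_field=sig,
        t0_field=t0,
        necrosis_mask=necrosis,
        mvd_truth=mvd,
    )


def apply_necrosis(truth: PhantomTruth, fraction: float) -> PhantomTruth:
    """Convert the most central ``fraction`` of the VOI to zero perfusion."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    r = _radius_field(truth.shape_zyx)
    necrotic = np.zeros_like(truth.mask)
    if fraction > 0:
        rin = r[truth.mask]
        cut = np.quantile(rin, fraction)
        necrotic = truth.mask & (r <= cut)
    auc = truth.auc_field.copy()
    auc[necrotic] = 0.0
    return replace(truth, auc_field=auc, necrosis_mask=necrotic)


def truth_for_day(truth: PhantomTruth, spec: CohortSpec, arm: str,
                  responder: bool, day: int) -> PhantomTruth:
    """Ground truth at one imaging day under the treatment model.

    Treated tumors have their AUC field attenuated multiplicatively from
    day 1 onward, compounding per post-baseline scan and stronger at the
    rim (weight 0.5 at the core to 1.0 at the boundary).  From the third
    post-baseline scan onward a growing core fraction of the responding
    treated tumors becomes necrotic (therapy-induced necrosis follows the
    vascular response; the resistant line and the controls keep their
    perfused core).
    """
    days = sorted(spec.days)
    k = sum(1 for d in days if 0 < d <= day)  # index among post-baseline scans
    effect = spec.responder_effect if responder else spec.nonresponder_effect
    out = truth
    if arm == "treated" and effect > 0 and k > 0:
        rim = 0.5 + 0.5 * np.clip(_radius_field(truth.shape_zyx), 0.0, 1.0)
        atten = (1.0 - effect * rim) ** k
        out = replace(out, auc_field=out.auc_field * atten)
        late = max(0, k - 2)
        if spec.necrosis_growth > 0 and late > 0 and responder:
            out = apply_necrosis(out, min(1.0, spec.necrosis_growth * late))
    return out


def simulate_bolus_4d(truth: PhantomTruth, spec: CohortSpec, seed) -> np.ndarray:
    """Simulate one 4D acquisition (t, z, y, x) from a truth object.

    Every in-mask, non-necrotic voxel's TIC is the lognormal bolus model at
    the frame times; necrotic and out-of-mask voxels are background noise
    only.  The whole acquisition is multiplied by a lognormal injection
    scale jitter, then voxel noise is added per the spec's noise model and
    intensities are clipped at zero.
    """
    rng = np.random.default_rng(seed)
    t = spec.frame_times_s
    shape = truth.shape_zyx
    perfused = truth.mask & ~truth.necrosis_mask & (truth.auc_field > 0)

    auc = truth.auc_field[perfused]
    mu = truth.mu_field[perfused]
    sig = truth.sigma_field[perfused]
    t0 = truth.t0_field[perfused]
    pe, _, mtt = derived_params(auc, mu, sig, t0)

    slowest = np.max(t0 + 5.0 * mtt) if auc.size else 0.0
    if slowest > spec.duration_s:
        log.warning("duration %.0fs truncates the slowest voxel transit (%.0fs)",
                    spec.duration_s, slowest)

    clean = lognormal_model(t[None, :], auc[:, None], mu[:, None],
                            sig[:, None], t0[:, None])

    jitter = 1.0
    if spec.scale_jitter_sigma > 0:
        jitter = float(np.exp(rng.normal(0.0, spec.scale_jitter_sigma)))
    clean = clean * jitter

    vol = np.zeros((t.size,) + shape, dtype=float)
    flat = vol.reshape(t.size, -1)
    idx = np.flatnonzero(perfused.ravel())

    ref_pe = float(np.median(pe)) * jitter if pe.size else 1.0
    bg_sigma = 0.02 * ref_pe * (1.0 if spec.noise_level > 0 else 0.0)

    if spec.noise_level > 0:
        if spec.noise_model == "gaussian":
            sigma_v = spec.noise_level * pe[:, None] * jitter + bg_sigma
            noisy = clean + rng.normal(0.0, 1.0, clean.shape) * sigma_v
        else:  # multiplicative_gamma speckle surrogate
            k = 1.0 / spec.noise_level**2
            noisy = clean * rng.gamma(k, 1.0 / k, clean.shape)
            noisy = noisy + rng.normal(0.0, bg_sigma, clean.shape)
        flat[:, idx] = noisy.T
        background = rng.normal(0.0, bg_sigma, (t.size, flat.shape[1] - idx.size))
        other = np.setdiff1d(np.arange(flat.shape[1]), idx, assume_unique=False)
        flat[:, other] = background
        np.maximum(vol, 0.0, out=vol)
    else:
        flat[:, idx] = clean.T
    return vol


@dataclass
class CohortCollection:
    """Lazy handle on a generated study: manifest plus per-row realization."""

    spec: CohortSpec
    manifest: pd.DataFrame

    def datasets(self, cohort: str | None = None) -> Iterator[SyntheticDataset]:
        rows = self.manifest
        if cohort is not None:
            rows = rows[rows["cohort"] == cohort]
        cache_key, truth = None, None
        for _, row in rows.iterrows():
            key = (row["cohort"], row["subject"])
            if key != cache_key:
                truth = _subject_truth(self.spec, row["cohort"], row["subject_index"])
                cache_key = key
            yield _realize(self.spec, truth, row)

    def write(self, outdir) -> Path:
        """Persist every acquisition as NIfTI-1 + JSON frame times + manifest."""
        import json

        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        man = self.manifest.copy()
        vols, masks = [], []
        for ds in self.datasets():
            stem = f"{ds.cohort}_{ds.subject_id}_d{ds.day}_r{ds.replicate}"
            sz, sy, sx = self.spec.spacing_zyx
            aff = np.diag([sx, sy, sz, 1.0])
            vol_xyzt = np.transpose(ds.volume4d, (3, 2, 1, 0))
            nib.save(nib.Nifti1Image(vol_xyzt.astype(np.float32), aff),
                     outdir / f"{stem}_vol.nii.gz")
            nib.save(nib.Nifti1Image(
                np.transpose(ds.mask.astype(np.uint8), (2, 1, 0)), aff),
                outdir / f"{stem}_mask.nii.gz")
            (outdir / f"{stem}_times.json").write_text(
                json.dumps({"frame_times_s": ds.frame_times_s.tolist()}))
            vols.append(str(outdir / f"{stem}_vol.nii.gz"))
            masks.append(str(outdir / f"{stem}_mask.nii.gz"))
        man["path_volume"] = vols
        man["path_mask"] = masks
        man.to_csv(outdir / "manifest.csv", index=False)
        return outdir


def engineered_feature_tables(seed, n_subjects=20, n_per_arm=10,
                              days=(1, 3, 7, 10)):
    """Feature-level cohort tables with known selection outcomes.

    Bypasses the imaging chain to exercise the statistical selection
    machinery directly.  Three features:

    * ``good`` — repeatable (shared subject effect in the test–retest
      cohort), 3-SD treated-vs-control shift in the responder line at every
      day, completely treatment-insensitive (constant) in the resistant
      line: must be selected;
    * ``noise`` — no subject effect (ICC ~ 0): must fail repeatability;
    * ``nonspecific`` — repeatable but shifted equally in both tumor
      lines: must fail the resistant-line specificity criterion.

    Returns (repeat_table, responder_table, nonresponder_table).
    """
    rng = np.random.default_rng(seed)
    subj = rng.normal(50.0, 15.0, n_subjects)
    rep = pd.DataFrame({
        "subject": np.repeat([f"s{i}" for i in range(n_subjects)], 2),
        "day": 0, "cohort": "C", "arm": "none",
        "replicate": np.tile([1, 2], n_subjects),
        "good": np.repeat(subj, 2) + rng.normal(0, 1.0, 2 * n_subjects),
        "noise": rng.normal(50.0, 15.0, 2 * n_subjects),
        "nonspecific": np.repeat(subj, 2) + rng.normal(0, 1.0, 2 * n_subjects),
    })

    def arm_table(cohort, shift_good, shift_nonspec):
        rows = []
        for day in days:
            for arm, shifted in (("treated", True), ("control", False)):
                g = rng.normal(0.0, 3.0, n_per_arm) + (shift_good if shifted else 0.0)
                ns = rng.normal(0.0, 3.0, n_per_arm) + (shift_nonspec if shifted else 0.0)
                for i in range(n_per_arm):
                    rows.append({"subject": f"{cohort}{arm[0]}{i}", "day": day,
                                 "cohort": cohort, "arm": arm, "replicate": 1,
                                 "good": g[i], "noise": rng.normal(),
                                 "nonspecific": ns[i]})
        return pd.DataFrame(rows)

    resp = arm_table("A", shift_good=-9.0, shift_nonspec=-9.0)
    nonresp = arm_table("B", shift_good=0.0, shift_nonspec=-9.0)
    nonresp["good"] = 0.0  # flat: no treated/control difference at all
    return rep, resp, nonresp


_COHORT_IDS = {"A": 1, "B": 2, "C": 3, "D": 4}


def _subject_truth(spec: CohortSpec, cohort: str, subject_index: int) -> PhantomTruth:
    seed = np.random.SeedSequence(
        [spec.seed, _COHORT_IDS[cohort], int(subject_index), 7])
    return generate_phantom(spec.shape_zyx, spec.spacing_zyx,
                            spec.heterogeneity_scale, seed)


def _realize(spec: CohortSpec, truth: PhantomTruth, row) -> SyntheticDataset:
    responder = row["cohort"] in ("A", "C", "D")
    truth_day = truth_for_day(truth, spec, row["arm"], responder, int(row["day"]))
    noise_seed = np.random.SeedSequence(
        [spec.seed, _COHORT_IDS[row["cohort"]], int(row["subject_index"]),
         int(row["day"]), int(row["replicate"]), 11])
    vol = simulate_bolus_4d(truth_day, spec, noise_seed)
    return SyntheticDataset(
        volume4d=vol,
        frame_times_s=spec.frame_times_s,
        mask=truth.mask,
        truth=truth_day,
        subject_id=row["subject"],
        day=int(row["day"]),
        cohort=row["cohort"],
        arm=row["arm"],
        replicate=int(row["replicate"]),
    )


def generate_cohorts(spec: CohortSpec) -> CohortCollection:
    """Build the four-cohort study manifest; acquisitions realize lazily.

    Cohort A (responder line) and B (resistant line): ``n_per_group``
    treated + control subjects each, imaged on every day of
    ``spec.days``.  Cohort C: 2*n subjects, day-0 test–retest replicate
    pairs (same truth, independent noise).  Cohort D: n treated + n
    control, days 0 and 1, with the MVD ground truth recomputed from the
    day-1 perfusion so treatment-induced changes propagate to histology.
    """
    if spec.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rows = []

    def add(cohort, subject_index, subject, day, arm, replicate=1, mvd=np.nan):
        rows.append(dict(cohort=cohort, subject_index=subject_index,
                         subject=subject, day=day, arm=arm,
                         replicate=replicate, mvd=mvd))

    n = spec.n_per_group
    for cohort in ("A", "B"):
        for i in range(2 * n):
            arm = "treated" if i < n else "control"
            subject = f"{cohort}{i + 1:02d}"
            for day in spec.days:
                add(cohort, i, subject, day, arm)
    for i in range(2 * n):
        subject = f"C{i + 1:02d}"
        for rep in (1, 2):
            add("C", i, subject, 0, "none", replicate=rep)
    for i in range(2 * n):
        arm = "treated" if i < n else "control"
        subject = f"D{i + 1:02d}"
        truth = _subject_truth(spec, "D", i)
        t1 = truth_for_day(truth, spec, arm, True, 1)
        mvd_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, _COHORT_IDS["D"], i, 23]))
        mvd = float(max(0.0, t1.auc_field[t1.mask].mean()
                        + mvd_rng.normal(0.0, _MVD_NOISE_SD)))
        for day in (0, 1):
            add("D", i, subject, day, arm, mvd=mvd if day == 1 else np.nan)

    manifest = pd.DataFrame(rows)
    manifest["subject"] = manifest["subject"].astype(str)
    return CohortCollection(spec=spec, manifest=manifest)
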