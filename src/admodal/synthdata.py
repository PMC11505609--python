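"""Ground-truthed synthetic inputs for every analysis arm.

The study's raw data (fluorescence micrographs, GC-MS isotopologue tables,
diffusion-weighted volumes, cohort tables) are not deposited, so each
generator here emulates one input modality at the study's stated conditions
and emits the ground truth needed to score the downstream quantification:

* :func:`gen_fluorescence_image` — plaque-like blobs, filamentous glia and
  punctate nuclei on a flat background at the study pixel scales
  (2.02 um/px at 5x, 0.5128 um/px at 20x), with per-object centers, masks
  and exact positive-pixel counts;
* :func:`gen_mids` — replicate mass-isotopomer tables for
  [U-13C]glucose / [1,2-13C]acetate / [U-13C]glutamine labeling, produced by
  convolving known true MIDs with natural 13C abundance plus multiplicative
  lognormal noise (MS abundances are positive with roughly proportional
  error);
* :func:`gen_dki_volume` — multi-compartment Gaussian diffusion signals on
  the 5 b0 + 4 x 30-direction scheme with optional Rician noise, plus
  analytic MD/FA/MK ground-truth maps;
* :func:`gen_cohort` — genotype x age x ROI tables from an additive linear
  model with subject random intercepts, with the generating effects stored.

Every generator is a pure function of its spec (including the seed): same
spec, same bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import line_aa

from .dki import (
    DKIFit,
    GradientScheme,
    metrics as dki_metrics,
    sphere_directions,
    study_scheme,
)
from .isotope import MID, correction_matrix

__all__ = [
    "ImagePhantomSpec",
    "TracerSpec",
    "DkiPhantomSpec",
    "CohortSpec",
    "gen_fluorescence_image",
    "gen_mids",
    "gen_dki_volume",
    "gen_cohort",
    "default_tracer_mids",
    "PIXEL_SIZE_5X_UM",
    "PIXEL_SIZE_20X_UM",
    "ROI_LABELS",
]

#: microscope pixel scales of the study (5x and 20x magnification)
PIXEL_SIZE_5X_UM = 2.02
PIXEL_SIZE_20X_UM = 0.5128

#: the eight pooled dMRI ROIs of the study design
ROI_LABELS = (
    "neocortex", "upper_cortex", "lower_cortex", "subiculum",
    "white_matter", "corpus_callosum", "cingulum", "hippocampal_commissure",
)


# ---------------------------------------------------------------------------
# fluorescence image phantom


@dataclass(frozen=True)
class ImagePhantomSpec:
    """Phantom layout for one fluorescence channel.

    Objects are plaque-like disks, filament polylines, and nucleus disks at
    ``foreground_level`` on a ``background_level`` background, plus Gaussian
    noise. Nuclei (and plaques) are non-overlapping by default so object
    counts are unambiguous; ``allow_touching`` disables the separation
    constraint to exercise the counter's failure mode.
    """

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = PIXEL_SIZE_20X_UM
    plaque_count: int = 0
    plaque_radius_px: float = 12.0
    filament_count: int = 0
    nucleus_count: int = 0
    nucleus_radius_px: float = 4.0
    background_level: float = 0.05
    foreground_level: float = 0.8
    noise_sd: float = 0.01
    seed: int = 0
    allow_touching: bool = False
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in ("plaque_count", "filament_count", "nucleus_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.background_level < self.foreground_level <= 1:
            raise ValueError("need 0 <= background_level < foreground_level <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _place_disks(rng, shape, count, radius, existing, min_sep, retries, what):
    """Rejection-sample disk centers on the integer pixel grid; ``existing``
    accumulates (cy, cx, separation) constraints across object classes."""
    h, w = shape
    margin = int(np.ceil(radius)) + 1
    if count > 0 and (h - 2 * margin <= 0 or w - 2 * margin <= 0):
        raise ValueError(f"{what}: radius {radius} too large for the image")
    centers = []
    for _ in range(count):
        for _attempt in range(retries + 1):
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            if all((cy - oy) ** 2 + (cx - ox) ** 2 >= sep * sep
                   for (oy, ox, sep) in existing):
                break
        else:
            raise RuntimeError(
                f"could not place {count} non-overlapping {what} objects "
                f"after {retries} retries; reduce {what}_count or radius"
            )
        centers.append((cy, cx))
        existing.append((cy, cx, min_sep))
    return centers


def gen_fluorescence_image(spec: ImagePhantomSpec):
    """Render a seeded phantom channel image plus its ground truth.

    Returns ``(image, truth)``: image is float in [0, 1]; truth holds
    per-class boolean masks and centers, the exact positive-pixel count of
    the union mask, and the object counts.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    img = np.full(shape, spec.background_level, dtype=float)
    truth: dict = {"centers": {}, "masks": {}}

    placed: list[tuple[int, int, float]] = []
    retries = spec.max_retries

    plaque_mask = np.zeros(shape, dtype=bool)
    sep = 0.0 if spec.allow_touching else 2 * spec.plaque_radius_px + 2
    centers = _place_disks(rng, shape, spec.plaque_count,
                           spec.plaque_radius_px,
                           placed if not spec.allow_touching else [],
                           sep, retries, "plaque")
    for cy, cx in centers:
        plaque_mask |= _disk_mask(shape, cy, cx, spec.plaque_radius_px)
    truth["centers"]["plaque"] = centers
    truth["masks"]["plaque"] = plaque_mask

    filament_mask = np.zeros(shape, dtype=bool)
    fil_starts = []
    for _ in range(spec.filament_count):
        y, x = int(rng.integers(0, shape[0])), int(rng.integers(0, shape[1]))
        fil_starts.append((y, x))
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(rng.integers(5, 12))):
            length = rng.uniform(8, 25)
            ang += rng.normal(0, 0.5)
            y2 = int(np.clip(y + length * np.sin(ang), 0, shape[0] - 1))
            x2 = int(np.clip(x + length * np.cos(ang), 0, shape[1] - 1))
            rr, cc, val = line_aa(y, x, y2, x2)
            keep = val >= 0.5
            filament_mask[rr[keep], cc[keep]] = True
            y, x = y2, x2
    truth["centers"]["filament"] = fil_starts
    truth["masks"]["filament"] = filament_mask

    nucleus_mask = np.zeros(shape, dtype=bool)
    sep = 0.0 if spec.allow_touching else 2 * spec.nucleus_radius_px + 2
    nuc_centers = _place_disks(rng, shape, spec.nucleus_count,
                               spec.nucleus_radius_px,
                               placed if not spec.allow_touching else [],
                               sep, retries, "nucleus")
    for cy, cx in nuc_centers:
        nucleus_mask |= _disk_mask(shape, cy, cx, spec.nucleus_radius_px)
    truth["centers"]["nucleus"] = nuc_centers
    truth["masks"]["nucleus"] = nucleus_mask

    positive = plaque_mask | filament_mask | nucleus_mask
    img[positive] = spec.foreground_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, shape)
    img = np.clip(img, 0.0, 1.0)

    truth["masks"]["positive"] = positive
    truth["positive_pixels"] = int(positive.sum())
    truth["n_objects"] = {
        "plaque": spec.plaque_count,
        "filament": spec.filament_count,
        "nucleus": spec.nucleus_count,
    }
    return img, truth


# ---------------------------------------------------------------------------
# isotopologue tables

#: tracer-only (pre-natural-abundance) MIDs emulating 60-min labeling of TCA
#: intermediates and amino acids in brain slices. Synthetic stand-in values
#: chosen once to resemble the qualitative labeling pattern of each
#: substrate (glycolytic M+3 from glucose, M+2 entry from acetate, M+5
#: glutamine backbone); they encode no measured data.
_DEFAULT_TRUE_MIDS: dict[str, dict[str, list[float]]] = {
    "U13C_glucose": {
        "lactate": [0.55, 0.02, 0.03, 0.40],
        "alanine": [0.60, 0.02, 0.03, 0.35],
        "citrate": [0.55, 0.05, 0.25, 0.05, 0.07, 0.02, 0.01],
        "alpha_ketoglutarate": [0.60, 0.05, 0.22, 0.05, 0.06, 0.02],
        "succinate": [0.65, 0.05, 0.22, 0.04, 0.04],
        "malate": [0.62, 0.05, 0.24, 0.04, 0.05],
        "glutamate": [0.58, 0.05, 0.24, 0.05, 0.06, 0.02],
        "glutamine": [0.66, 0.05, 0.19, 0.04, 0.05, 0.01],
        "gaba": [0.72, 0.05, 0.17, 0.03, 0.03],
        "aspartate": [0.64, 0.05, 0.23, 0.04, 0.04],
    },
    "12C13_acetate": {
        "citrate": [0.70, 0.03, 0.20, 0.02, 0.04, 0.008, 0.002],
        "alpha_ketoglutarate": [0.74, 0.03, 0.17, 0.02, 0.035, 0.005],
        "succinate": [0.76, 0.03, 0.17, 0.02, 0.02],
        "malate": [0.75, 0.03, 0.18, 0.02, 0.02],
        "glutamate": [0.73, 0.03, 0.18, 0.02, 0.035, 0.005],
        "glutamine": [0.62, 0.04, 0.26, 0.03, 0.045, 0.005],
        "gaba": [0.80, 0.03, 0.14, 0.02, 0.01],
        "aspartate": [0.77, 0.03, 0.16, 0.02, 0.02],
    },
    "U13C_glutamine": {
        "glutamine": [0.30, 0.02, 0.03, 0.03, 0.07, 0.55],
        "glutamate": [0.45, 0.03, 0.05, 0.04, 0.08, 0.35],
        "alpha_ketoglutarate": [0.50, 0.03, 0.05, 0.04, 0.08, 0.30],
        "succinate": [0.55, 0.04, 0.10, 0.06, 0.25],
        "malate": [0.58, 0.04, 0.12, 0.06, 0.20],
        "citrate": [0.60, 0.04, 0.08, 0.05, 0.15, 0.06, 0.02],
        "aspartate": [0.62, 0.04, 0.12, 0.06, 0.16],
        "gaba": [0.66, 0.04, 0.10, 0.08, 0.12],
    },
}


def default_tracer_mids(substrate: str) -> dict[str, MID]:
    """Built-in true MIDs (toy TCA labeling table) for a tracer substrate."""
    try:
        table = _DEFAULT_TRUE_MIDS[substrate]
    except KeyError:
        raise ValueError(f"unknown substrate {substrate!r}") from None
    out = {}
    for met, frac in table.items():
        f = np.asarray(frac, dtype=float)
        out[met] = MID(met, f.size - 1, f / f.sum())
    return out


@dataclass(frozen=True)
class TracerSpec:
    """Labeling-experiment spec: which tracer, true MIDs, distortion level."""

    substrate: str = "U13C_glucose"
    true_mids: dict[str, MID] | None = None
    p_natural: float = 0.0107
    noise_cv: float = 0.02
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substrate not in _DEFAULT_TRUE_MIDS:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if not 0.0 <= self.p_natural < 0.5:
            raise ValueError("p_natural must be in [0, 0.5)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        mids = self.true_mids or default_tracer_mids(self.substrate)
        for met, mid in mids.items():
            if abs(mid.fractions.sum() - 1.0) > 1e-12:
                raise ValueError(f"true MID for {met} does not sum to 1")
        object.__setattr__(self, "true_mids", mids)


def gen_mids(spec: TracerSpec, genotype: str = "WT",
             region: str = "cortex") -> pd.DataFrame:
    """Simulate replicate measured MID tables for one tracer condition.

    Each measured MID is the natural-abundance convolution of the true MID
    (the forward model that :func:`admodal.isotope.correct_mid` inverts)
    with multiplicative lognormal noise of coefficient of variation
    ``noise_cv``, renormalized to sum 1. Output is tidy with columns
    (sample_id, genotype, region, substrate, metabolite, n_carbons, m0..mN).
    """
    rng = np.random.default_rng(spec.seed)
    max_n = max(m.n_carbons for m in spec.true_mids.values())
    sigma = np.sqrt(np.log(1.0 + spec.noise_cv**2))
    rows = []
    for rep in range(spec.n_replicates):
        for met, mid in spec.true_mids.items():
            cm = correction_matrix(mid.n_carbons, spec.p_natural)
            measured = cm.matrix @ mid.fractions
            if spec.noise_cv > 0:
                noise = rng.lognormal(-0.5 * sigma**2, sigma, measured.size)
                measured = measured * noise
            measured = measured / measured.sum()
            row = {
                "sample_id": f"{genotype}_{region}_{spec.substrate}_r{rep + 1}",
                "genotype": genotype,
                "region": region,
                "substrate": spec.substrate,
                "metabolite": met,
                "n_carbons": mid.n_carbons,
            }
            for i in range(max_n + 1):
                row[f"m{i}"] = measured[i] if i <= mid.n_carbons else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DKI phantom


@dataclass(frozen=True)
class DkiPhantomSpec:
    """Multi-region, multi-compartment Gaussian diffusion phantom.

    ``regions`` maps region label -> list of (signal_fraction, 3x3 diffusion
    tensor in um^2/ms); fractions must sum to 1 per region and tensors must
    be symmetric positive-definite. Regions tile the volume as slabs along
    the first axis. ``snr`` is S0 / (Rician channel SD); None = noiseless.
    """

    shape: tuple[int, int, int] = (8, 8, 4)
    voxel_size_mm: tuple[float, float, float] = (0.15, 0.15, 0.2)
    regions: dict[str, list[tuple[float, np.ndarray]]] = field(
        default_factory=lambda: {"tissue": [(1.0, np.diag([1.2, 0.8, 0.6]))]}
    )
    scheme: GradientScheme | None = None
    s0: float = 100.0
    snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive or None")
        for label, comps in self.regions.items():
            fsum = sum(f for f, _ in comps)
            if abs(fsum - 1.0) > 1e-9:
                raise ValueError(f"region {label!r}: fractions sum to {fsum}")
            for _, D in comps:
                D = np.asarray(D, dtype=float)
                if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
                    raise ValueError(f"region {label!r}: tensor not symmetric")
                if np.any(np.linalg.eigvalsh(D) <= 0):
                    raise ValueError(
                        f"region {label!r}: tensor not positive-definite"
                    )
        if self.scheme is None:
            object.__setattr__(self, "scheme", study_scheme())


def mixture_truth(comps, directions=None) -> dict[str, float]:
    """Analytic MD/FA/MK of a Gaussian-mixture voxel.

    MD and FA come from the signal-fraction-weighted mean tensor; MK is the
    directional kurtosis of the mixture, K(n) = 3 Var_c[d_c(n)] / E[d_c(n)]^2
    (the exact b^2 cumulant of ln sum_c f_c exp(-b d_c(n))), averaged over a
    dense direction set.
    """
    g = sphere_directions(256) if directions is None else directions
    fracs = np.array([f for f, _ in comps])
    tensors = np.stack([np.asarray(D, dtype=float) for _, D in comps])
    Dbar = np.einsum("c,cij->ij", fracs, tensors)
    m = dki_metrics(DKIFit(1.0, Dbar, np.zeros((3, 3, 3, 3))))
    d_c = np.einsum("mi,cij,mj->cm", g, tensors, g)  # (C, M) directional ADCs
    mean_d = fracs @ d_c
    var_d = fracs @ (d_c - mean_d) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(mean_d > 0, 3.0 * var_d / mean_d**2, 0.0)
    return {"MD": m.MD, "FA": m.FA, "MK": float(k.mean())}


def gen_dki_volume(spec: DkiPhantomSpec):
    """Simulate a 4D diffusion-weighted volume with ground truth.

    Noiseless voxel signal: S(b, n) = S0 * sum_c f_c exp(-b n^T D_c n).
    Rician noise (|signal + complex Gaussian|, channel SD = S0/snr) is
    applied when ``snr`` is finite. Returns (volume, region label map,
    truth): truth holds per-voxel MD/FA/MK ground-truth maps, per-region
    metric values, region labels, and the applied noise sigma.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme
    shape = spec.shape
    labels = list(spec.regions)
    region_map = np.zeros(shape, dtype=int)
    edges = np.linspace(0, shape[0], len(labels) + 1).astype(int)
    for ridx in range(len(labels)):
        region_map[edges[ridx]: edges[ridx + 1]] = ridx

    b = scheme.b_values
    g = scheme.directions
    vol = np.empty(shape + (len(scheme),))
    truth_maps = {k: np.zeros(shape) for k in ("MD", "FA", "MK")}
    per_region = {}
    for ridx, label in enumerate(labels):
        comps = spec.regions[label]
        fracs = np.array([f for f, _ in comps])
        tensors = np.stack([np.asarray(D, dtype=float) for _, D in comps])
        d_app = np.einsum("mi,cij,mj->cm", g, tensors, g)
        sig = spec.s0 * (fracs @ np.exp(-b[None, :] * d_app))
        gt = mixture_truth(comps)
        sel = region_map == ridx
        vol[sel] = sig
        for k in truth_maps:
            truth_maps[k][sel] = gt[k]
        per_region[label] = gt
    sigma = 0.0
    if spec.snr is not None and np.isfinite(spec.snr):
        sigma = spec.s0 / spec.snr
        re = vol + rng.normal(0.0, sigma, vol.shape)
        im = rng.normal(0.0, sigma, vol.shape)
        vol = np.hypot(re, im)

    truth = {"maps": truth_maps, "regions": per_region, "sigma": sigma,
             "labels": labels}
    return vol, region_map, truth


# ---------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class CohortSpec:
    """Genotype x age x ROI cohort with subject random intercepts.

    Response for subject s (genotype g, age a) in ROI j:

        y = grand_mean + genotype_effect * x_g + age_effect * x_a
            + roi_effects[j]
            + ga * x_g * x_a + gr * x_g * q_j + ar * x_a * q_j
            + gar * x_g * x_a * q_j
            + subject_intercept_s + residual

    with contrast codes x in {-1/2, +1/2} (so each main effect equals the
    corresponding group mean difference) and q_j an alternating centered
    +/-1 ROI pattern carrying the ROI-involving interactions.
    ``interaction_effects`` keys: genotype_age, genotype_roi, age_roi,
    genotype_age_roi; missing keys default to 0.
    """

    n_per_group: int = 7
    grand_mean: float = 1.0
    genotype_effect: float = 0.0
    age_effect: float = 0.0
    roi_effects: tuple[float, ...] = tuple(0.0 for _ in ROI_LABELS)
    interaction_effects: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 0.1
    subject_sd: float = 0.05
    roi_labels: tuple[str, ...] = ROI_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if len(self.roi_effects) != len(self.roi_labels):
            raise ValueError("roi_effects length must match roi_labels")
        known = {"genotype_age", "genotype_roi", "age_roi", "genotype_age_roi"}
        unknown = set(self.interaction_effects) - known
        if unknown:
            raise ValueError(f"unknown interaction keys: {sorted(unknown)}")


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a long-format cohort table; generating effects in ``attrs``."""
    rng = np.random.default_rng(spec.seed)
    n_roi = len(spec.roi_labels)
    q = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(n_roi)])
    q -= q.mean()
    inter = {k: spec.interaction_effects.get(k, 0.0)
             for k in ("genotype_age", "genotype_roi", "age_roi",
                       "genotype_age_roi")}
    rows = []
    sid = 0
    for g_lab, x_g in (("WT", -0.5), ("5xFAD", 0.5)):
        for a_lab, x_a in (("2M", -0.5), ("6M", 0.5)):
            for _ in range(spec.n_per_group):
                sid += 1
                u = rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
                for j, roi in enumerate(spec.roi_labels):
                    y = (
                        spec.grand_mean
                        + spec.genotype_effect * x_g
                        + spec.age_effect * x_a
                        + spec.roi_effects[j]
                        + inter["genotype_age"] * x_g * x_a
                        + inter["genotype_roi"] * x_g * q[j]
                        + inter["age_roi"] * x_a * q[j]
                        + inter["genotype_age_roi"] * x_g * x_a * q[j]
                        + u
                        + rng.normal(0.0, spec.residual_sd)
                    )
                    rows.append(
                        dict(subject_id=f"s{sid:03d}", genotype=g_lab,
                             age=a_lab, roi=roi, value=y)
                    )
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {
        "grand_mean": spec.grand_mean,
        "genotype_effect": spec.genotype_effect,
        "age_effect": spec.age_effect,
        "roi_effects": list(spec.roi_effects),
        "interaction_effects": inter,
        "residual_sd": spec.residual_sd,
        "subject_sd": spec.subject_sd,
    }
    return df
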