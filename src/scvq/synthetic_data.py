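"""Synthetic inputs with known ground truth.

Two generators make every pipeline stage testable without any acquisition:

* **Vascular phantoms** — SWI-MinIP-like 2D slabs containing dark tubes whose
  centerlines come from three analytic families (straight line, circular arc,
  sinusoid).  Arc length, chord, tortuosity (arc/chord) and diameter of every
  tube are known in closed form or by adaptive quadrature, independently of
  the morphometry code they are used to validate.

* **Simulated cohorts** — subject tables with the group-mean structure of the
  reference cohort (per-sex vein-feature means with SE-derived spreads), an
  ordinal cognition stage drawn from a proportional-odds model on the
  subject's own features, and blood biomarkers tied to features and tea habit
  through a Gaussian copula calibrated to target Spearman correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.spatial import cKDTree

from . import reference_cohort as ref
from .io_minip import MinipSlab, SwiVolume

__all__ = [
    "Tube",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "analytic_tube_truth",
    "generate_phantom",
    "generate_phantom_volume",
    "generate_cohort",
    "default_phantom_spec",
    "default_cohort_spec",
]

DEFAULT_SEED = 20251008


class TubeOverlapError(ValueError):
    """Two tubes in a phantom spec intersect."""


@dataclass(frozen=True)
class Tube:
    """One synthetic vessel.  Geometry is in pixel units, radius in mm.

    family "line":     start (row, col), direction (dr, dc), length_px
    family "arc":      center (row, col), arc_radius_px, theta_start,
                       theta_extent (radians; 0 points along +col, increasing
                       toward +row)
    family "sinusoid": start (row, col), length_px along +col,
                       amplitude_px, wavelength_px
    """

    family: str
    side: str  # subject hemisphere: "left" | "right"
    radius_mm: float = 1.2
    start: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float] = (0.0, 1.0)
    length_px: float = 150.0
    center: tuple[float, float] = (0.0, 0.0)
    arc_radius_px: float = 60.0
    theta_start: float = 0.0
    theta_extent: float = math.pi
    amplitude_px: float = 8.0
    wavelength_px: float = 80.0

    def centerline(self, n: int = 2048) -> np.ndarray:
        """Dense (n, 2) polyline of (row, col) centerline samples."""
        t = np.linspace(0.0, 1.0, n)
        if self.family == "line":
            d = np.asarray(self.direction, dtype=float)
            d = d / np.linalg.norm(d)
            return np.asarray(self.start) + np.outer(t * self.length_px, d)
        if self.family == "arc":
            th = self.theta_start + t * self.theta_extent
            cr, cc = self.center
            return np.column_stack(
                [cr + self.arc_radius_px * np.sin(th),
                 cc + self.arc_radius_px * np.cos(th)]
            )
        if self.family == "sinusoid":
            x = t * self.length_px
            k = 2.0 * math.pi / self.wavelength_px
            r0, c0 = self.start
            return np.column_stack([r0 + self.amplitude_px * np.sin(k * x), c0 + x])
        raise ValueError(f"unknown tube family {self.family!r}")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth for one tube."""

    arc_length_mm: float
    chord_mm: float
    tortuosity: float
    diameter_mm: float
    hemisphere: str

    def __post_init__(self) -> None:
        assert self.tortuosity >= 1.0 - 1e-9


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (600, 600)
    pixel_mm: float = 0.8
    tubes: tuple[Tube, ...] = ()
    background: float = 200.0
    vessel_intensity: float = 40.0
    noise_sd: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.vessel_intensity >= self.background:
            raise ValueError("vessels must be darker than the background")
        for t in self.tubes:
            if t.radius_mm < self.pixel_mm:
                raise ValueError("tube radius must be at least one pixel")


def analytic_tube_truth(tube: Tube, pixel_mm: float = 0.8) -> PhantomTruth:
    """Closed-form (line, arc) or quadrature (sinusoid) truth for one tube."""
    if tube.family == "line":
        arc_px = float(tube.length_px)
    elif tube.family == "arc":
        arc_px = float(tube.arc_radius_px * tube.theta_extent)
    elif tube.family == "sinusoid":
        k = 2.0 * math.pi / tube.wavelength_px
        arc_px, _ = integrate.quad(
            lambda x: math.sqrt(1.0 + (tube.amplitude_px * k * math.cos(k * x)) ** 2),
            0.0, tube.length_px, epsrel=1e-8, limit=500,
        )
    else:
        raise ValueError(f"unknown tube family {tube.family!r}")
    if arc_px <= 0:
        raise ValueError("zero-length tube")
    line = tube.centerline(4097)
    chord_px = float(np.linalg.norm(line[-1] - line[0]))
    if chord_px == 0:
        raise ValueError("closed tube: chord undefined")
    return PhantomTruth(
        arc_length_mm=arc_px * pixel_mm,
        chord_mm=chord_px * pixel_mm,
        tortuosity=arc_px / chord_px,
        diameter_mm=2.0 * tube.radius_mm,
        hemisphere=tube.side,
    )


def _tube_support(tube: Tube, shape: tuple[int, int], pixel_mm: float) -> np.ndarray:
    """Boolean raster of pixel centers within one tube radius of the centerline."""
    r_px = tube.radius_mm / pixel_mm
    line = tube.centerline(int(max(2048, 8 * tube.length_px)))
    tree = cKDTree(line)
    r0 = int(max(0, math.floor(line[:, 0].min() - r_px - 1)))
    r1 = int(min(shape[0] - 1, math.ceil(line[:, 0].max() + r_px + 1)))
    c0 = int(max(0, math.floor(line[:, 1].min() - r_px - 1)))
    c1 = int(min(shape[1] - 1, math.ceil(line[:, 1].max() + r_px + 1)))
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                             indexing="ij")
    pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    dist, _ = tree.query(pts, k=1)
    out = np.zeros(shape, dtype=bool)
    out[rows.ravel()[dist <= r_px], cols.ravel()[dist <= r_px]] = True
    return out


def generate_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[MinipSlab, "VesselMask", list[PhantomTruth]]:
    """Rasterize a phantom slab, its truth mask, and per-tube analytic truth.

    Dark tubes on a bright background, Gaussian noise of ``spec.noise_sd``
    added, then quantized to 8 bits (the slab is returned windowed).  The
    truth mask is the noiseless tube support.  Deterministic given the seed.
    Overlapping tubes raise :class:`TubeOverlapError` naming the pair.
    """
    from .vessel_masks import VesselMask

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    supports = [_tube_support(t, spec.shape, spec.pixel_mm) for t in spec.tubes]
    for i in range(len(supports)):
        for j in range(i + 1, len(supports)):
            if (supports[i] & supports[j]).any():
                raise TubeOverlapError(f"tubes {i} and {j} overlap")
    mask = np.zeros(spec.shape, dtype=bool)
    for s in supports:
        mask |= s
    img = np.full(spec.shape, spec.background, dtype=float)
    img[mask] = spec.vessel_intensity
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    slab = MinipSlab(
        pixels=img, slab_start_mm=0.0, slab_thickness_mm=20.0,
        slice_range=(0, 19), pixel_spacing_mm=(spec.pixel_mm, spec.pixel_mm),
        windowed=True,
    )
    truth_mask = VesselMask(
        pixels=mask, pixel_spacing_mm=(spec.pixel_mm, spec.pixel_mm),
        provenance="annotation",
    )
    truths = [analytic_tube_truth(t, spec.pixel_mm) for t in spec.tubes]
    return slab, truth_mask, truths


def generate_phantom_volume(
    spec: PhantomSpec, n_slices: int = 21, dz_mm: float = 1.0,
    seed: int | None = None,
) -> SwiVolume:
    """Embed the phantom's tubes into a 3D volume for MinIP round-trip tests.

    Vessels occupy the middle third of the slice stack; elsewhere the volume
    is background (plus noise), so a minimum projection over the stack
    recovers the 2D phantom.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    _, truth_mask, _ = generate_phantom(replace(spec, noise_sd=0.0), seed=seed)
    vol = np.full((n_slices, *spec.shape), spec.background, dtype=float)
    lo, hi = n_slices // 3, 2 * n_slices // 3 + 1
    vol[lo:hi, truth_mask.pixels] = spec.vessel_intensity
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)
    return SwiVolume(voxels=vol, spacing_mm=(dz_mm, spec.pixel_mm, spec.pixel_mm))


def default_phantom_spec(noise_sd: float = 0.0) -> PhantomSpec:
    """Twelve non-overlapping tubes, six per hemisphere, mixing the families.

    Lengths are >= 150 px so skeleton-end effects stay well inside the
    recovery tolerances; radii are 1.2 mm (1.5 px at 0.8 mm pixels).
    """
    def L(side="right", **kw) -> Tube:
        return Tube(family="line", side=side, **kw)

    def A(side="right", **kw) -> Tube:
        return Tube(family="arc", side=side, **kw)

    def S(side="right", **kw) -> Tube:
        return Tube(family="sinusoid", side=side, **kw)

    half = math.pi / 2
    tubes = (
        # image-left half (subject right hemisphere under radiological display)
        L(start=(40, 40), direction=(0, 1), length_px=200),
        L(start=(80, 40), direction=(math.sin(0.4), math.cos(0.4)), length_px=180),
        A(center=(250, 150), arc_radius_px=60, theta_start=-half,
          theta_extent=math.pi),  # semicircle
        A(center=(560, 40), arc_radius_px=90, theta_start=-half,
          theta_extent=half),  # quarter circle
        S(start=(370, 60), length_px=160, amplitude_px=8, wavelength_px=80),
        S(start=(430, 100), length_px=160, amplitude_px=16, wavelength_px=80),
        # image-right half (subject left hemisphere)
        L(side="left", start=(40, 340), direction=(0, 1), length_px=200),
        L(side="left", start=(80, 340),
          direction=(math.sin(0.7), math.cos(0.7)), length_px=160),
        A(side="left", center=(250, 450), arc_radius_px=60, theta_start=-half,
          theta_extent=math.pi),
        A(side="left", center=(560, 340), arc_radius_px=90, theta_start=-half,
          theta_extent=half),
        S(side="left", start=(370, 360), length_px=160, amplitude_px=12,
          wavelength_px=80),
        S(side="left", start=(430, 400), length_px=160, amplitude_px=20,
          wavelength_px=100),
    )
    return PhantomSpec(tubes=tubes, noise_sd=noise_sd)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Stratum:
    name: str
    n: int
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    covariates: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated cohort.

    Vein features are drawn per stratum as normal variates with the stratum
    mean and an SE-derived standard deviation (sd = SE * sqrt(n), since the
    reference summaries report mean +/- SE).  ``ordinal_coeffs`` and
    ``thresholds`` define the proportional-odds model that generates the
    cognition stage; with no thresholds given they are derived from
    ``stage_probs`` at the cohort-mean linear predictor.  ``rank_corr``
    entries are target Spearman correlations realized through a Gaussian
    copula (latent Pearson rho = 2 sin(pi r_s / 6); the tea habit, being a
    3-level ordinal margin, gets an extra simulation-calibrated latent
    correlation so the *discretized* variable hits the target).
    """

    strata: tuple[Stratum, ...]
    ordinal_coeffs: dict[str, float]
    stage_probs: tuple[float, ...] = tuple(ref.STAGE_COUNTS / ref.STAGE_COUNTS.sum())
    thresholds: tuple[float, ...] | None = None
    tea_probs: tuple[float, ...] = tuple(ref.TEA_HABIT_COUNTS / ref.TEA_HABIT_COUNTS.sum())
    biomarkers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ref.BIOMARKERS)
    )
    rank_corr: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(ref.TARGET_RANK_CORRELATIONS)
    )
    number_right_share: float = 0.509
    seed: int = DEFAULT_SEED


def default_cohort_spec() -> CohortSpec:
    """Male/female strata with the reference per-sex feature summaries."""
    strata = []
    for sex, n in (("male", ref.MALE_N), ("female", ref.FEMALE_N)):
        summ = ref.SEX_SCV_MEAN_SE[sex]
        strata.append(Stratum(
            name=sex, n=n,
            feature_means={k: v[0] for k, v in summ.items()},
            feature_sds={k: ref.se_to_sd(v[1], n) for k, v in summ.items()},
            covariates={"sex": sex},
        ))
    return CohortSpec(
        strata=tuple(strata),
        # effect structure of the reference regression: right-hemisphere
        # curvature pushes toward worse stages, right-hemisphere length
        # weakly protects
        ordinal_coeffs={"curvature_right": 8.0, "length_right": -0.33},
    )


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    if w.min() >= 1e-10:
        return mat
    w = np.clip(w, 1e-10, None)
    out = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


import functools


@functools.lru_cache(maxsize=32)
def _calibrate_tea_latent_cached(target: float, tea_probs: tuple) -> float:
    return _calibrate_tea_latent(target, np.asarray(tea_probs))


def _calibrate_tea_latent(target: float, tea_probs: np.ndarray) -> float:
    """Latent correlation so the discretized tea level hits a target Spearman.

    Thresholding a latent normal into 3 ordered levels attenuates its rank
    correlation with a continuous partner; the inflation factor is found by
    root-finding on a fixed, derandomized common-random-number sample.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(1234567)
    u = rng.standard_normal(120_000)
    v = rng.standard_normal(120_000)
    qs = stats.norm.ppf(np.cumsum(tea_probs)[:-1])

    def spearman_at(rho: float) -> float:
        y = rho * u + math.sqrt(1 - rho**2) * v
        tea = np.digitize(u, qs)
        return stats.spearmanr(tea, y).statistic

    sign = 1.0 if target >= 0 else -1.0
    f = lambda r: sign * spearman_at(sign * r) - abs(target)  # increasing in r
    hi = min(0.999, abs(target) * 2.5 + 0.2)
    if f(hi) < 0:  # target unreachable; saturate
        return sign * hi
    return sign * brentq(f, 0.0, hi, xtol=1e-3)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Simulate one subject table.

    Columns: subject id, stratum covariates, the nine vein features
    (number_total = number_right + number_left by construction), tea_level
    (0 = none, 1 = occasional, 2 = daily), the biomarker concentrations, and
    the ordinal ``stage`` (0 = NC .. 3 = MCI) drawn from the
    proportional-odds model logit P(Y <= j) = theta_j - x'beta.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    bio_names = list(spec.biomarkers)
    tea_probs = np.asarray(spec.tea_probs)

    # latent copula dimensions: tea + every feature or biomarker that appears
    # in a rank-correlation target + remaining biomarkers
    corr_feats = sorted({a for a, _ in spec.rank_corr} - {"tea_level"})
    latents = ["tea_level"] + corr_feats + bio_names
    idx = {name: i for i, name in enumerate(latents)}
    C = np.eye(len(latents))
    for (a, b), rs in spec.rank_corr.items():
        if a == "tea_level" or b == "tea_level":
            other = b if a == "tea_level" else a
            rho = _calibrate_tea_latent_cached(float(rs), tuple(tea_probs))
            C[idx["tea_level"], idx[other]] = C[idx[other], idx["tea_level"]] = rho
        else:
            rho = 2.0 * math.sin(math.pi * rs / 6.0)
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = rho
    C = _nearest_psd(C)

    qs = stats.norm.ppf(np.cumsum(tea_probs)[:-1])
    rows = []
    sid = 0
    for stratum in spec.strata:
        z = rng.multivariate_normal(np.zeros(len(latents)), C, size=stratum.n,
                                    method="cholesky")
        for i in range(stratum.n):
            rec: dict = {"subject_id": sid, "stratum": stratum.name}
            rec.update(stratum.covariates)
            # correlated features use their copula latent, the rest fresh draws
            for feat in ref.SCV_FEATURES:
                if feat in ("number_total", "number_right", "number_left"):
                    continue
                zval = z[i, idx[feat]] if feat in idx else rng.standard_normal()
                val = stratum.feature_means[feat] + stratum.feature_sds[feat] * zval
                if feat.startswith("curvature"):
                    val = max(1.0, val)  # tortuosity cannot drop below 1
                rec[feat] = val
            ztot = (z[i, idx["number_total"]] if "number_total" in idx
                    else rng.standard_normal())
            total = max(0.0, stratum.feature_means["number_total"]
                        + stratum.feature_sds["number_total"] * ztot)
            share = np.clip(rng.normal(spec.number_right_share, 0.01), 0.0, 1.0)
            rec["number_right"] = int(round(total * share))
            rec["number_left"] = int(round(total)) - rec["number_right"]
            rec["number_total"] = rec["number_right"] + rec["number_left"]
            rec["tea_level"] = int(np.digitize(z[i, idx["tea_level"]], qs))
            for b in bio_names:
                mean, sd = spec.biomarkers[b]
                rec[b] = mean + sd * z[i, idx[b]]
            rows.append(rec)
            sid += 1
    df = pd.DataFrame(rows)

    # ordinal stage from the proportional-odds model
    beta_names = list(spec.ordinal_coeffs)
    beta = np.array([spec.ordinal_coeffs[k] for k in beta_names])
    xb = df[beta_names].to_numpy(dtype=float) @ beta if beta_names else np.zeros(len(df))
    probs = np.asarray(spec.stage_probs, dtype=float)
    probs = probs / probs.sum()
    if spec.thresholds is None:
        cum = np.cumsum(probs)[:-1]
        theta = np.log(cum / (1.0 - cum)) + xb.mean()
    else:
        theta = np.asarray(spec.thresholds, dtype=float)
    cum_p = 1.0 / (1.0 + np.exp(-(theta[None, :] - xb[:, None])))
    cum_p = np.hstack([np.zeros((len(df), 1)), cum_p, np.ones((len(df), 1))])
    cell = np.clip(np.diff(cum_p, axis=1), 0.0, None)
    cell /= cell.sum(axis=1, keepdims=True)
    u = rng.random(len(df))
    df["stage"] = (u[:, None] > np.cumsum(cell, axis=1)[:, :-1]).sum(axis=1)
    return df
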