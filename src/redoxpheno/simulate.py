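"""Synthetic data: two-channel biosensor scenes with known OxD ground truth,
calibration image pairs, and multi-genotype phenotype tables.

The biosensor scene generator emulates confocal ratio imaging of a cytosolic
roGFP2 sensor.  Per pixel, the 488-excited intensity interpolates linearly
between the fully reduced and fully oxidized calibration intensities as a
function of the ground-truth degree of oxidation, and the 405-excited
intensity is R(OxD)·I488 where R(OxD) is the exact inverse of the OxD
formula used downstream — so at zero noise the quantification pipeline
recovers the ground truth exactly.  Shot noise is Poisson on the intensity
counts with additive Gaussian read noise.

The phenotype generator draws per-group trait vectors from a multivariate
normal with a target correlation matrix (a Gaussian copula handles the
lateral-root count: rounded and floored at zero), with per-genotype ×
per-treatment mean shifts.  The shipped preset mirrors the observed stress
phenotyping patterns: salt and osmotic stress raise ROS and superoxide and
depress vitality; shoot and root vitality are strongly positively coupled;
ROS levels correlate negatively with vitality; and the shoot-ROS ↔
lateral-root coupling is genotype-specific (absent in some mutants, stronger
in others).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biosensor import CalibrationState
from .imaging import ImageStack

__all__ = [
    "BiosensorSceneSpec",
    "BiosensorScene",
    "generate_biosensor_stack",
    "PhenotypeSimSpec",
    "generate_phenotype_table",
    "fig8_preset",
    "TRAITS",
    "GENOTYPES",
    "TREATMENTS",
]

DEFAULT_CALIB = CalibrationState(r_red=0.3, r_ox=2.1, i488_red=400.0, i488_ox=130.0)


def ratio_for_oxd(oxd, calib: CalibrationState):
    """405/488 ratio whose downstream OxD evaluation returns ``oxd`` exactly.

    Inverse of OxD = (R−R_red)/(f·(R_ox−R) + (R−R_red)) with
    f = I488_red/I488_ox: a weighted mean of the calibration ratios.
    """
    oxd = np.asarray(oxd, dtype=float)
    f = calib.intensity_factor
    w = oxd * f
    return (w * calib.r_ox + (1.0 - oxd) * calib.r_red) / (w + (1.0 - oxd))


@dataclass(frozen=True)
class BiosensorSceneSpec:
    """Recipe for one synthetic two-channel biosensor scene.

    ``oxd_map`` may be a scalar (uniform field), a 2-D array, or one of the
    descriptors ``("gradient", lo, hi)`` (left→right linear ramp) and
    ``("two-region", a, b)`` (left/right halves).
    """

    oxd_map: object = 0.5
    shape: tuple[int, int] = (96, 96)
    calib: CalibrationState = DEFAULT_CALIB
    base_i488_red: float = 400.0
    poisson_noise: bool = True
    read_noise_sd: float = 10.0
    pixel_size: float = 1.0
    seed: int = 0

    def resolve_oxd(self) -> np.ndarray:
        m = self.oxd_map
        if isinstance(m, (int, float)):
            arr = np.full(self.shape, float(m))
        elif isinstance(m, np.ndarray):
            arr = m.astype(float)
        elif isinstance(m, (tuple, list)) and m and m[0] == "gradient":
            _, lo, hi = m
            arr = np.tile(np.linspace(lo, hi, self.shape[1]), (self.shape[0], 1))
        elif isinstance(m, (tuple, list)) and m and m[0] == "two-region":
            _, a, b = m
            arr = np.full(self.shape, float(a))
            arr[:, self.shape[1] // 2:] = float(b)
        else:
            raise ValueError(f"unrecognized oxd_map spec: {m!r}")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("OxD ground truth must lie in [0, 1]")
        if self.read_noise_sd < 0:
            raise ValueError("read noise sd must be nonnegative")
        return arr


@dataclass(frozen=True)
class BiosensorScene:
    """Sample stack, the DTT/H2O2 calibration stacks, and the ground truth."""

    sample: ImageStack
    calib_reduced: ImageStack
    calib_oxidized: ImageStack
    oxd_truth: np.ndarray
    spec: BiosensorSceneSpec


def _render(oxd: np.ndarray, spec: BiosensorSceneSpec, rng: np.random.Generator) -> ImageStack:
    calib = spec.calib
    scale = spec.base_i488_red / calib.i488_red
    i488 = scale * (calib.i488_red + oxd * (calib.i488_ox - calib.i488_red))
    i405 = ratio_for_oxd(oxd, calib) * i488
    channels = {}
    for name, expected in (("exc405", i405), ("exc488", i488)):
        img = expected
        if spec.poisson_noise:
            img = rng.poisson(np.maximum(expected, 0.0)).astype(float)
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=expected.shape)
        channels[name] = np.maximum(img, 0.0)
    return ImageStack(channels=channels, pixel_size=spec.pixel_size)


def generate_biosensor_stack(spec: BiosensorSceneSpec) -> BiosensorScene:
    """Render the sample scene plus fully reduced / fully oxidized
    calibration scenes (uniform OxD 0 and 1) under the same noise model.

    Identical seeds give bit-identical scenes.
    """
    oxd = spec.resolve_oxd()
    rng = np.random.default_rng(spec.seed)
    sample = _render(oxd, spec, rng)
    calib_red = _render(np.zeros(spec.shape), spec, rng)
    calib_ox = _render(np.ones(spec.shape), spec, rng)
    return BiosensorScene(
        sample=sample,
        calib_reduced=calib_red,
        calib_oxidized=calib_ox,
        oxd_truth=oxd,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Phenotype tables

TRAITS = [
    "primary_root_length",
    "lateral_root_count",
    "root_ros",
    "shoot_ros",
    "root_vitality",
    "shoot_vitality",
    "root_superoxide",
]

GENOTYPES = ["Col-0"] + [f"gpxl{i}" for i in range(1, 9)]
TREATMENTS = ["control", "NaCl50", "NaCl100", "mannitol100", "mannitol200"]


class SpecError(ValueError):
    """Invalid simulation specification (e.g. non-PSD correlation)."""


@dataclass(frozen=True)
class PhenotypeSimSpec:
    """Recipe for a multi-genotype, multi-treatment phenotype table.

    ``means[(genotype, treatment)][trait]`` gives group means; ``sds[trait]``
    the within-group standard deviations; ``correlation`` either one trait ×
    trait matrix (DataFrame) or a per-genotype dict of them.  ``n_per_group``
    defaults to 45 seedlings, the phenotyping replicate regime.
    """

    genotypes: tuple = tuple(GENOTYPES)
    treatments: tuple = tuple(TREATMENTS)
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    correlation: object = None
    n_per_group: int = 45
    seed: int = 0

    def correlation_for(self, genotype: str) -> pd.DataFrame:
        c = self.correlation
        if c is None:
            c = pd.DataFrame(np.eye(len(TRAITS)), index=TRAITS, columns=TRAITS)
        if isinstance(c, dict):
            c = c.get(genotype, c.get("default"))
            if c is None:
                raise SpecError(f"no correlation matrix for genotype {genotype!r}")
        return c


def _validate_correlation(c: pd.DataFrame, traits: list[str]) -> np.ndarray:
    mat = c.loc[traits, traits].to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise SpecError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise SpecError("correlation matrix must have unit diagonal")
    eig = np.linalg.eigvalsh(mat)
    if eig.min() < -1e-10:
        raise SpecError(
            f"correlation matrix is not positive semidefinite (min eig {eig.min():.3g})"
        )
    return mat


def generate_phenotype_table(spec: PhenotypeSimSpec) -> pd.DataFrame:
    """Draw the full phenotype table: one row per seedling.

    Within each genotype × treatment cell the trait vector is multivariate
    normal with the genotype's correlation matrix; the lateral-root count is
    a rounded Gaussian copula margin floored at 0; lengths are floored at a
    small positive value; intensities at 0.  Identical seeds give identical
    tables.
    """
    if spec.n_per_group < 2:
        raise SpecError("n_per_group must be at least 2")
    rng = np.random.default_rng(spec.seed)
    sds = {t: float(spec.sds.get(t, 1.0)) for t in TRAITS}
    rows = []
    chol_cache: dict[str, np.ndarray] = {}
    for geno in spec.genotypes:
        if geno not in chol_cache:
            mat = _validate_correlation(spec.correlation_for(geno), TRAITS)
            # eigen-based factor handles PSD-but-singular matrices
            w, v = np.linalg.eigh(mat)
            chol_cache[geno] = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        fac = chol_cache[geno]
        for treat in spec.treatments:
            mean = spec.means.get((geno, treat), {})
            mu = np.array([float(mean.get(t, 0.0)) for t in TRAITS])
            sd = np.array([sds[t] for t in TRAITS])
            z = rng.standard_normal((spec.n_per_group, len(TRAITS))) @ fac.T
            x = mu + sd * z
            df = pd.DataFrame(x, columns=TRAITS)
            df["lateral_root_count"] = (
                np.round(df["lateral_root_count"]).clip(lower=0).astype(int)
            )
            df["primary_root_length"] = df["primary_root_length"].clip(lower=1.0)
            for t in ("root_ros", "shoot_ros", "root_vitality",
                      "shoot_vitality", "root_superoxide"):
                df[t] = df[t].clip(lower=0.0)
            df.insert(0, "replicate", np.arange(1, spec.n_per_group + 1))
            df.insert(0, "treatment", treat)
            df.insert(0, "genotype", geno)
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Preset emulating the observed stress-phenotyping structure

_BASELINES = {
    "primary_root_length": 60.0,   # mm, 18-day-old primary root
    "lateral_root_count": 12.0,
    "root_ros": 1000.0,            # dye intensities in a.u.
    "shoot_ros": 1000.0,
    "root_vitality": 1000.0,
    "shoot_vitality": 1000.0,
    "root_superoxide": 1000.0,
}

_SDS = {
    "primary_root_length": 8.0,
    "lateral_root_count": 3.5,
    "root_ros": 180.0,
    "shoot_ros": 180.0,
    "root_vitality": 180.0,
    "shoot_vitality": 180.0,
    "root_superoxide": 180.0,
}

# treatment effects on the wild type: salt/osmotic stress raises ROS and
# superoxide, depresses vitality; 50 mM NaCl mildly promotes root growth
_TREAT_MULT = {
    "control":     {},
    "NaCl50":      {"primary_root_length": 1.10, "lateral_root_count": 0.95,
                    "root_ros": 1.55, "shoot_ros": 1.56, "root_vitality": 0.74,
                    "shoot_vitality": 0.80, "root_superoxide": 1.37},
    "NaCl100":     {"primary_root_length": 0.80, "lateral_root_count": 0.85,
                    "root_ros": 1.39, "shoot_ros": 2.27, "root_vitality": 0.29,
                    "shoot_vitality": 0.60, "root_superoxide": 1.59},
    "mannitol100": {"primary_root_length": 0.85, "lateral_root_count": 0.80,
                    "root_ros": 1.35, "shoot_ros": 1.80, "root_vitality": 0.45,
                    "shoot_vitality": 0.66, "root_superoxide": 1.00},
    "mannitol200": {"primary_root_length": 0.75, "lateral_root_count": 0.70,
                    "root_ros": 1.35, "shoot_ros": 1.80, "root_vitality": 0.30,
                    "shoot_vitality": 0.54, "root_superoxide": 1.50},
}

# genotype effects under control conditions: all mutants show elevated shoot
# ROS; growth and superoxide responses are isoform-specific
_GENO_MULT = {
    "Col-0": {},
    "gpxl1": {"primary_root_length": 0.85, "shoot_ros": 1.30},
    "gpxl2": {"shoot_ros": 1.25, "shoot_vitality": 0.85, "root_superoxide": 1.30},
    "gpxl3": {"primary_root_length": 0.85, "shoot_ros": 1.30,
              "shoot_vitality": 0.85, "root_superoxide": 1.30},
    "gpxl4": {"primary_root_length": 1.15, "shoot_ros": 1.35,
              "shoot_vitality": 0.85, "root_superoxide": 1.30},
    "gpxl5": {"lateral_root_count": 1.30, "shoot_ros": 1.25,
              "shoot_vitality": 0.85, "root_superoxide": 1.30},
    "gpxl6": {"primary_root_length": 1.15, "lateral_root_count": 1.25,
              "shoot_ros": 1.30, "shoot_vitality": 0.90},
    "gpxl7": {"shoot_ros": 1.40, "shoot_vitality": 0.85, "root_superoxide": 1.30},
    "gpxl8": {"primary_root_length": 1.15, "lateral_root_count": 1.25,
              "shoot_ros": 1.30, "shoot_vitality": 0.85},
}


def _loadings_correlation(lrc_loading: float) -> pd.DataFrame:
    """Two-factor correlation matrix: factor 1 is the oxidative-stress axis
    (ROS and superoxide up, vitality and root growth down), factor 2 a shared
    vitality factor pushing the shoot–root vitality correlation near +0.9.
    PSD by construction (R = LLᵀ off the diagonal, ones on it)."""
    l1 = {
        "primary_root_length": -0.30,
        "lateral_root_count": lrc_loading,
        "root_ros": 0.70,
        "shoot_ros": 0.75,
        "root_vitality": -0.80,
        "shoot_vitality": -0.82,
        "root_superoxide": 0.60,
    }
    l2 = {t: 0.0 for t in TRAITS}
    l2["root_vitality"] = 0.50
    l2["shoot_vitality"] = 0.50
    L = np.array([[l1[t], l2[t]] for t in TRAITS])
    mat = L @ L.T
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=TRAITS, columns=TRAITS)


def fig8_preset(n_per_group: int = 45, seed: int = 0) -> PhenotypeSimSpec:
    """Preset with the full genotype × treatment design and the correlation
    structure the downstream analysis expects: strong positive shoot–root
    vitality coupling, negative ROS–vitality coupling, and a shoot-ROS ↔
    lateral-root coupling that vanishes in gpxl1/5/7 and strengthens in
    gpxl4/6/8 relative to the wild type."""
    means = {}
    for geno in GENOTYPES:
        for treat in TREATMENTS:
            gm = _GENO_MULT[geno]
            tm = _TREAT_MULT[treat]
            means[(geno, treat)] = {
                t: _BASELINES[t] * gm.get(t, 1.0) * tm.get(t, 1.0) for t in TRAITS
            }
    correlation = {"default": _loadings_correlation(-0.55)}
    for geno in ("gpxl1", "gpxl5", "gpxl7"):
        correlation[geno] = _loadings_correlation(0.0)
    for geno in ("gpxl4", "gpxl6", "gpxl8"):
        correlation[geno] = _loadings_correlation(-0.80)
    return PhenotypeSimSpec(
        genotypes=tuple(GENOTYPES),
        treatments=tuple(TREATMENTS),
        means=means,
        sds=dict(_SDS),
        correlation=correlation,
        n_per_group=n_per_group,
        seed=seed,
    )
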