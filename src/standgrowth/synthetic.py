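"""Synthetic stand-inventory generator.

Emulates a single-year, cross-sectional forest inventory for five species
groups of an arid-basin study system (Spruce, Poplar, MixedWood, SandJujube,
PopulusEuphratica).  For each species the generator

1. samples stand ages from a truncated normal matched to the published
   inventory summary (mean, SD, min, max in years);
2. produces DBH from the species' age–DBH growth curve plus Gaussian noise
   (non-positive draws are resampled);
3. produces height from the DBH–height curve the same way; and
4. draws environmental covariates (elevation ``dem``, annual precipitation
   ``p``, cold-extreme index ``txn``) by a Gaussian copula so that each
   covariate hits a target Pearson correlation with DBH:
   ``cov = ρ·z_dbh + sqrt(1−ρ²)·ε`` rescaled into its physical range.

Covariates are generated *conditionally on* DBH — the analysis only assumes
a correlation structure, not a causal growth mechanism.  MixedWood's
heterogeneous composition is emulated by a two-component ±offset mixture in
the height residual process, which drives its DBH–height R² down to the
weak level real mixed stands show; the mixture is part of the noise model
and is disabled together with ``noise_sd_height = 0`` so that zero-noise
draws lie exactly on the generating curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import InventoryTable
from .errors import ProfileError
from .growth_models import ModelForm, predict

#: default covariate target correlations with DBH and physical ranges
DEFAULT_COVARIATE_TARGETS = {"dem": 0.52, "p": 0.41, "txn": 0.41}
DEFAULT_COVARIATE_RANGES = {
    "dem": (220.0, 3587.0),     # elevation, m
    "p": (143.2, 438.7),        # annual precipitation, mm
    "txn": (-27.56, -19.76),    # minimum of daily maximum temperature, degC
}


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated normal in original units (years for stand age)."""

    mean: float
    sd: float
    min: float
    max: float

    def dist(self):
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # mass of the *parent* normal inside [min, max]
        mass = (stats.norm.cdf((self.max - self.mean) / self.sd)
                - stats.norm.cdf((self.min - self.mean) / self.sd))
        if not np.isfinite(mass) or mass < 1e-6:
            raise ProfileError("truncation keeps < 1e-6 of the distribution mass")
        return self.dist().rvs(size=n, random_state=rng)


@dataclass(frozen=True)
class SpeciesProfile:
    """Generative truth for one species group."""

    species: str
    n_model: int
    n_test: int
    age_distribution: TruncatedNormal
    true_age_dbh: tuple[ModelForm, tuple[float, ...]]
    true_dbh_height: tuple[ModelForm, tuple[float, ...]]
    noise_sd_dbh: float
    noise_sd_height: float
    covariate_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_TARGETS))
    covariate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES))
    height_mixture_offset: float = 0.0  # ± offset (m) of the heterogeneity mixture
    dbh_range: tuple[float, float] = (3.0, 40.0)  # observed DBH span, cm

    @property
    def n_total(self) -> int:
        return self.n_model + self.n_test

    def with_noise(self, sd_dbh: float, sd_height: float) -> "SpeciesProfile":
        return replace(self, noise_sd_dbh=sd_dbh, noise_sd_height=sd_height)


def default_profiles() -> dict[str, SpeciesProfile]:
    """The five built-in species profiles.

    Age distributions reproduce the published inventory summaries; the
    generating curves are each species' optimal fitted equations for the
    age–DBH and DBH–height relations; covariate correlation targets are the
    published screening values for elevation, precipitation and the cold
    extreme.  Noise SDs default to 15% of the species' mean response, which
    puts the true form's modelling R² in the 0.6–0.8 band typical of such
    inventories.  Modelling sample sizes match the published regression
    degrees of freedom; test sizes keep the 70/30 proportion.
    """
    S, G, LOG, LIN, LGST = (
        ModelForm("s_curve"), ModelForm("growth"), ModelForm("logarithmic"),
        ModelForm("linear"), ModelForm("logistic"),
    )
    profiles = {
        "Spruce": SpeciesProfile(
            species="Spruce", n_model=2193, n_test=940,
            age_distribution=TruncatedNormal(112.91, 34.69, 16, 187),
            true_age_dbh=(G, (2.053, 0.008)),
            true_dbh_height=(S, (3.396, -12.923)),
            noise_sd_dbh=0.15 * 20.47, noise_sd_height=0.15 * 15.51,
            dbh_range=(6.0, 40.0),
        ),
        "Poplar": SpeciesProfile(
            species="Poplar", n_model=423, n_test=181,
            age_distribution=TruncatedNormal(20.58, 6.27, 9, 72),
            true_age_dbh=(S, (3.536, -17.461)),
            true_dbh_height=(S, (3.174, -8.341)),
            noise_sd_dbh=0.15 * 13.48, noise_sd_height=0.15 * 11.67,
            dbh_range=(6.0, 40.0),
        ),
        "MixedWood": SpeciesProfile(
            species="MixedWood", n_model=95, n_test=41,
            age_distribution=TruncatedNormal(26.29, 11.87, 11, 55),
            true_age_dbh=(LIN, (3.713, 0.39)),
            true_dbh_height=(LOG, (3.19, 1.678)),
            noise_sd_dbh=0.15 * 13.97, noise_sd_height=0.15 * 7.30,
            height_mixture_offset=2.0, dbh_range=(3.0, 40.0),
        ),
        "SandJujube": SpeciesProfile(
            species="SandJujube", n_model=19, n_test=8,
            age_distribution=TruncatedNormal(16.37, 9.85, 11, 25),
            true_age_dbh=(LGST, (19.835, 0.205, 16.246)),
            true_dbh_height=(S, (2.181, -4.99)),
            noise_sd_dbh=0.15 * 10.10, noise_sd_height=0.15 * 5.10,
            dbh_range=(6.0, 18.0),
        ),
        "PopulusEuphratica": SpeciesProfile(
            species="PopulusEuphratica", n_model=22, n_test=9,
            age_distribution=TruncatedNormal(29.18, 3.76, 13, 50),
            true_age_dbh=(S, (3.259, -16.799)),
            true_dbh_height=(S, (2.747, -8.481)),
            noise_sd_dbh=0.15 * 13.82, noise_sd_height=0.15 * 7.95,
            dbh_range=(6.0, 26.0),
        ),
    }
    return profiles


def _noisy_response(truth, x, noise_sd, rng, extra_offset=None):
    """Curve value plus Gaussian noise; non-positive draws are resampled."""
    form, params = truth
    mean = predict(form, np.asarray(params, float), x)
    offset = np.zeros(mean.size) if extra_offset is None else np.asarray(extra_offset)
    if noise_sd <= 0:
        out = mean + offset
        if np.any(out <= 0):
            raise ProfileError("generating curve produced non-positive values")
        return out
    out = mean + offset + rng.normal(0.0, noise_sd, size=mean.size)
    for _ in range(1000):
        bad = out <= 0
        if not np.any(bad):
            return out
        out[bad] = mean[bad] + offset[bad] + rng.normal(0.0, noise_sd, size=int(bad.sum()))
    raise ProfileError("could not draw positive responses; noise too large")


def generate_species(profile: SpeciesProfile, n: int, seed: int) -> InventoryTable:
    """Generate n plots for one species; fully seed-deterministic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    age = profile.age_distribution.sample(n, rng)
    dbh = _noisy_response(profile.true_age_dbh, age, profile.noise_sd_dbh, rng)
    mixture = None
    if profile.height_mixture_offset and profile.noise_sd_height > 0:
        mixture = profile.height_mixture_offset * rng.choice([-1.0, 1.0], size=n)
    height = _noisy_response(
        profile.true_dbh_height, dbh, profile.noise_sd_height, rng,
        extra_offset=mixture,
    )
    data = {
        "species": profile.species,
        "dbh_cm": dbh,
        "height_m": height,
        "age_yr": age,
    }
    sd_dbh = dbh.std()
    z_dbh = (dbh - dbh.mean()) / sd_dbh if sd_dbh > 0 else np.zeros(n)
    for name, rho in profile.covariate_targets.items():
        if not -1.0 < rho < 1.0:
            raise ProfileError(f"target correlation for {name} must be in (-1, 1)")
        eps = rng.standard_normal(n)
        z = rho * z_dbh + np.sqrt(1.0 - rho**2) * eps
        lo, hi = profile.covariate_ranges[name]
        center, scale = (lo + hi) / 2.0, (hi - lo) / 6.0
        data[name] = center + scale * z
    return InventoryTable(pd.DataFrame(data), list(profile.covariate_targets))


def generate_inventory(
    profiles=None, seed: int = 0, n_per_species=None
) -> InventoryTable:
    """Generate a pooled multi-species inventory table.

    Per-species sub-seeds are derived deterministically from ``seed``.
    ``n_per_species`` may be an int (same n for all), a mapping, or None to
    use each profile's published total sample size.
    """
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    tables = []
    for name in profiles:  # insertion order: deterministic
        sub_seed = int(rng.integers(0, 2**31 - 1))
        prof = profiles[name]
        if n_per_species is None:
            n = prof.n_total
        elif isinstance(n_per_species, dict):
            n = n_per_species[name]
        else:
            n = int(n_per_species)
        tables.append(generate_species(prof, n, sub_seed).df)
    df = pd.concat(tables, ignore_index=True)
    first = next(iter(profiles.values()))
    return InventoryTable(df, list(first.covariate_targets))


def summarize(table: InventoryTable) -> pd.DataFrame:
    """Per-species descriptive statistics in the inventory-report layout.

    One row per species × variable with mean, sd (sample, n−1), min, max.
    A single record reports sd = 0.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    rows = []
    for sp, grp in table.df.groupby("species", sort=False):
        for var in ("dbh_cm", "height_m", "age_yr"):
            v = grp[var].to_numpy(float)
            rows.append({
                "species": sp, "variable": var,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "min": float(v.min()), "max": float(v.max()),
                "n": int(v.size),
            })
    return pd.DataFrame(rows)
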