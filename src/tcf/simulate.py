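"""Synthetic septic-shock-like cohorts for end-to-end testing.

The generator emulates the statistical structure the pipeline assumes of a
real ICU cohort: mixed continuous (Gaussian and log-normal labs) and Boolean
(history-flag) features, a sparse logistic ground-truth signal with ~21 %
28-day mortality prevalence, per-feature MCAR missingness including some
features above the 30 % filtering bound, highly correlated feature pairs
(Gaussian-copula construction, target r >= 0.7), and near-constant Boolean
flags.  A multicenter variant perturbs means/scales and prevalence per
center while keeping the ground-truth coefficients, emulating between-center
heterogeneity.

Informative features are the alphabetically first continuous columns
(``c01``...), so their identity is known to tests that assert recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from tcf.cohort import CohortTable, ColumnSpec


@dataclass
class SyntheticCohortSpec:
    """Study-condition parameters of the generator.

    Defaults describe the cohort the end-to-end tests run on: 3000 ICU
    stays, 40 features (30 continuous, 10 Boolean), 5 informative continuous
    features with log-odds coefficients on the unit-Gaussian scale, 21 %
    outcome prevalence, two correlated noise pairs, two near-constant
    Boolean flags, and a missingness map with three features above the 30 %
    filter bound.
    """

    n_patients: int = 3000
    n_continuous: int = 30
    n_boolean: int = 10
    n_informative: int = 5
    coefficients: tuple[float, ...] = (1.2, -1.0, 0.9, 0.8, -0.7)
    prevalence: float = 0.21
    missingness: dict[str, float] | None = None
    correlated_pairs: tuple[tuple[str, str, float], ...] = (
        ("c08", "c09", 0.85),
        ("c10", "c11", 0.75),
    )
    near_constant_booleans: dict[str, float] = field(
        default_factory=lambda: {"b09": 0.95, "b10": 0.93}
    )
    boolean_rates: tuple[float, ...] = (0.15, 0.25, 0.35, 0.45, 0.30, 0.20, 0.40, 0.50)
    lognormal_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_continuous + self.n_boolean:
            raise ValueError("more informative features than features")
        if len(self.coefficients) != self.n_informative:
            raise ValueError("one coefficient per informative feature")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        for name, frac in (self.missingness or {}).items():
            if not 0 <= frac < 1:
                raise ValueError(f"missing fraction for {name!r} must be in [0,1)")
        for a, b, r in self.correlated_pairs:
            if abs(r) >= 1:
                raise ValueError(f"infeasible correlation target {r} for ({a},{b})")

    @property
    def continuous_names(self) -> list[str]:
        return [f"c{i + 1:02d}" for i in range(self.n_continuous)]

    @property
    def boolean_names(self) -> list[str]:
        return [f"b{i + 1:02d}" for i in range(self.n_boolean)]

    @property
    def informative_features(self) -> list[str]:
        return self.continuous_names[: self.n_informative]

    def default_missingness(self) -> dict[str, float]:
        """Three features above the 30 % bound, mild holes elsewhere."""
        mm = {"c12": 0.40, "c13": 0.35, "c14": 0.50}
        for name in self.continuous_names[14:20]:
            mm[name] = 0.10
        if self.n_boolean >= 8:
            mm["b08"] = 0.05
        if self.n_informative >= 1:
            mm[self.informative_features[-1]] = 0.08
        return {k: v for k, v in mm.items() if k in self.continuous_names + self.boolean_names}

    # -- (de)serialisation ------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        d["correlated_pairs"] = [list(p) for p in self.correlated_pairs]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "coefficients" in d:
            d["coefficients"] = tuple(d["coefficients"])
        if "correlated_pairs" in d:
            d["correlated_pairs"] = tuple(tuple(p) for p in d["correlated_pairs"])
        if "boolean_rates" in d:
            d["boolean_rates"] = tuple(d["boolean_rates"])
        return cls(**d)


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept b0 with mean sigmoid(b0 + eta) equal to the target."""
    return brentq(lambda b: expit(b + eta).mean() - prevalence, -30, 30)


def generate(
    spec: SyntheticCohortSpec,
    mean_shift: np.ndarray | None = None,
    scale_factor: np.ndarray | None = None,
    prevalence: float | None = None,
) -> CohortTable:
    """Draw one cohort from the spec.

    The latent standard-normal draws feed three things: informative features
    (Gaussian marginals, so the outcome model is exactly logistic in the
    observed features), noise features (some pushed through exp(0.5 z) for
    log-normal skew), and Gaussian-copula correlated pairs (the second
    member is r z_a + sqrt(1-r^2) eps with a Gaussian marginal, hitting the
    target Pearson r).  The outcome is drawn before missingness is applied.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    cnames, bnames = spec.continuous_names, spec.boolean_names
    z = {name: rng.standard_normal(n) for name in cnames}

    # correlated pairs share latent Gaussians; both members keep Gaussian marginals
    pair_members = set()
    for a, b, r in spec.correlated_pairs:
        z[b] = r * z[a] + np.sqrt(1 - r**2) * rng.standard_normal(n)
        pair_members.update((a, b))

    X = pd.DataFrame(index=range(n))
    n_lognormal = int(round(spec.lognormal_fraction * spec.n_continuous))
    skew_pool = [
        c
        for c in cnames
        if c not in spec.informative_features and c not in pair_members
    ][:n_lognormal]
    for i, name in enumerate(cnames):
        if name in skew_pool:
            X[name] = np.exp(0.5 * z[name]) * (5 + i)  # skewed lab-like marginal
        elif name in spec.informative_features or name in pair_members:
            X[name] = z[name]
        else:
            X[name] = z[name] * (1 + 0.1 * i) + i  # varied Gaussian marginal

    rates = list(spec.boolean_rates)
    for i, name in enumerate(bnames):
        p = spec.near_constant_booleans.get(name, rates[i % len(rates)])
        X[name] = rng.binomial(1, p, size=n).astype(float)

    if mean_shift is not None or scale_factor is not None:
        shift = np.zeros(spec.n_continuous) if mean_shift is None else np.asarray(mean_shift)
        scale = np.ones(spec.n_continuous) if scale_factor is None else np.asarray(scale_factor)
        for i, name in enumerate(cnames):
            X[name] = X[name] * scale[i] + shift[i]

    beta = np.asarray(spec.coefficients, dtype=float)
    eta = X[spec.informative_features].to_numpy() @ beta
    b0 = _calibrate_intercept(eta, prevalence if prevalence is not None else spec.prevalence)
    y = rng.binomial(1, expit(b0 + eta)).astype(float)

    mm = spec.missingness if spec.missingness is not None else spec.default_missingness()
    for name, frac in mm.items():
        if frac > 0:
            X.loc[rng.uniform(size=n) < frac, name] = np.nan

    specs = (
        [ColumnSpec(name, "continuous", "", "feature") for name in cnames]
        + [ColumnSpec(name, "boolean", "", "feature") for name in bnames]
        + [ColumnSpec("death28", "boolean", "", "outcome")]
    )
    frame = X.copy()
    frame["death28"] = y
    return CohortTable(specs, frame)


def generate_multicenter(
    spec: SyntheticCohortSpec,
    n_centers: int,
    shift_scale: float = 0.3,
    prevalence_overrides: Sequence[float] | None = None,
) -> list[CohortTable]:
    """Re-draw the cohort per center with perturbed marginals.

    Each center gets its own seed (derived from the base seed), continuous
    means shifted by N(0, shift_scale) and scales multiplied by
    exp(N(0, shift_scale/2)), and optionally its own outcome prevalence; the
    ground-truth coefficients are shared, emulating a common biology under
    covariate shift.
    """
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    if prevalence_overrides is not None and len(prevalence_overrides) != n_centers:
        raise ValueError("one prevalence per center")
    centers = []
    for c in range(n_centers):
        crng = np.random.default_rng([spec.seed, c + 1])
        shift = crng.normal(0, shift_scale, size=spec.n_continuous)
        scale = np.exp(crng.normal(0, shift_scale / 2, size=spec.n_continuous))
        if shift_scale == 0:
            shift, scale = None, None
        cspec = replace(spec, seed=int(crng.integers(0, 2**31 - 1)))
        prev = prevalence_overrides[c] if prevalence_overrides is not None else None
        centers.append(generate(cspec, shift, scale, prev))
    return centers
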