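"""Synthetic packaged-food supply generator with known fiber ground truth.

Each category profile draws a product's 100 g mass composition from a
Dirichlet over (sugar, starch, protein, saturated fat, unsaturated fat,
other), sodium from a log-normal, and true fiber from a linear relation in
starch and sugar with Gaussian noise, clamped into [0, other mass] so that
masses conserve.  Brands cluster compositions via a per-brand shift of the
Dirichlet concentration.  Fiber is *reported* on the label with probability
logistic(gamma0 + gamma1 * fiber), which reproduces the real-world bias of
high-fiber products being likelier to declare fiber.

Draw order (single generator seeded once, per profile in list order, then per
product): brand shift matrix; then per product: brand index, composition,
sodium, fiber noise, reporting uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd
import yaml

from fiberknn.products import Basis, ProductRecord, ProductTable

#: Mass components of the Dirichlet draw, in order, scaled to 100 g.
MASS_COMPONENTS = ("sugar", "starch", "protein", "saturated_fat", "unsaturated_fat", "other")


@dataclass(frozen=True)
class CategoryProfile:
    """Generative parameters of one food category.

    ``beta0 + beta1 * starch + beta2 * sugar`` (plus Normal(0, fiber_noise_sd)
    noise) is the true fiber relation; fiber is carved out of the "other"
    mass component so totals stay at 100 g.
    """

    name: str
    dirichlet_concentration: tuple[float, float, float, float, float, float]
    sodium_log_mean: float  # mg, natural-log scale
    sodium_log_sd: float
    beta0: float
    beta1: float
    beta2: float
    fiber_noise_sd: float = 0.25
    n_brands: int = 20
    brand_effect_sd: float = 0.3

    def __post_init__(self) -> None:
        if len(self.dirichlet_concentration) != 6:
            raise ValueError("dirichlet_concentration needs 6 entries")
        if any(a <= 0 for a in self.dirichlet_concentration):
            raise ValueError("dirichlet concentrations must be positive")
        if self.fiber_noise_sd < 0:
            raise ValueError("fiber_noise_sd must be >= 0")
        if self.n_brands < 1:
            raise ValueError("n_brands must be >= 1")


@dataclass(frozen=True)
class SupplySpec:
    """Full generator specification (serializable as YAML)."""

    profiles: tuple[CategoryProfile, ...]
    n_per_category: int = 100
    seed: int = 0
    reporting_gamma0: float = -4.0
    reporting_gamma1: float = 2.0
    carbohydrate_includes_fiber: bool = False  # False = "available carbohydrate" labels

    def __post_init__(self) -> None:
        if self.n_per_category < 1:
            raise ValueError("n_per_category must be >= 1")
        if not self.profiles:
            raise ValueError("at least one profile is required")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "n_per_category": self.n_per_category,
            "seed": self.seed,
            "reporting_gamma0": self.reporting_gamma0,
            "reporting_gamma1": self.reporting_gamma1,
            "carbohydrate_includes_fiber": self.carbohydrate_includes_fiber,
            "profiles": [
                {
                    "name": p.name,
                    "dirichlet_concentration": list(p.dirichlet_concentration),
                    "sodium_log_mean": p.sodium_log_mean,
                    "sodium_log_sd": p.sodium_log_sd,
                    "beta0": p.beta0,
                    "beta1": p.beta1,
                    "beta2": p.beta2,
                    "fiber_noise_sd": p.fiber_noise_sd,
                    "n_brands": p.n_brands,
                    "brand_effect_sd": p.brand_effect_sd,
                }
                for p in self.profiles
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SupplySpec":
        payload = yaml.safe_load(Path(path).read_text())
        profiles = tuple(
            CategoryProfile(
                name=p["name"],
                dirichlet_concentration=tuple(p["dirichlet_concentration"]),
                sodium_log_mean=p["sodium_log_mean"],
                sodium_log_sd=p["sodium_log_sd"],
                beta0=p["beta0"],
                beta1=p["beta1"],
                beta2=p["beta2"],
                fiber_noise_sd=p.get("fiber_noise_sd", 0.25),
                n_brands=p.get("n_brands", 20),
                brand_effect_sd=p.get("brand_effect_sd", 0.3),
            )
            for p in payload["profiles"]
        )
        return cls(
            profiles=profiles,
            n_per_category=payload.get("n_per_category", 100),
            seed=payload.get("seed", 0),
            reporting_gamma0=payload.get("reporting_gamma0", -4.0),
            reporting_gamma1=payload.get("reporting_gamma1", 2.0),
            carbohydrate_includes_fiber=payload.get("carbohydrate_includes_fiber", False),
        )


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# name, alpha(sugar, starch, protein, satfat, unsatfat, other), sodium ln-mean,
# ln-sd, beta0, beta1, beta2, n_brands.  Small alpha totals spread compositions
# widely (sparse neighborhoods); the juice archetype keeps E[fiber] below the
# negligible-density bound.
_ARCHETYPES = [
    ("breakfast_cereal", (8, 45, 9, 2, 5, 31), 6.0, 0.4, 0.5, 0.18, 0.05, 25),
    ("juice", (10, 0.5, 0.5, 0.2, 0.3, 18.5), 3.0, 0.7, 0.2, 0.10, 0.005, 20),
    ("bread", (4, 42, 9, 1, 3, 41), 6.1, 0.3, 1.0, 0.08, 0.03, 25),
    ("snack_bar", (25, 30, 8, 4, 8, 25), 5.0, 0.5, 2.0, 0.09, 0.08, 15),
    ("soup", (2, 5, 2, 1, 2, 88), 5.5, 0.4, 0.3, 0.12, 0.05, 15),
    ("nuts_seeds", (5, 12, 20, 8, 38, 17), 4.6, 0.8, 3.0, 0.20, 0.10, 15),
    ("pasta", (3, 70, 12, 1, 2, 12), 3.0, 0.9, 0.5, 0.04, 0.02, 15),
    ("biscuits", (22, 40, 6, 7, 9, 16), 5.9, 0.4, 0.5, 0.05, 0.03, 20),
    ("crisps", (3, 45, 6, 5, 20, 21), 6.4, 0.4, 0.8, 0.07, 0.05, 15),
    ("vegetables", (4, 8, 3, 0.5, 1, 83.5), 5.0, 0.6, 0.5, 0.15, 0.10, 20),
    ("fruit", (12, 4, 1, 0.3, 0.5, 82.2), 2.3, 0.8, 1.0, 0.20, 0.25, 20),
    ("ready_meal", (3, 12, 7, 3, 5, 70), 5.7, 0.4, 0.5, 0.08, 0.05, 20),
    ("cakes", (28, 35, 5, 8, 12, 12), 5.5, 0.4, 0.5, 0.03, 0.02, 20),
    ("grain_mix", (1.2, 3.0, 0.8, 0.3, 0.6, 4.1), 3.9, 0.5, 1.0, 0.20, 0.05, 10),
]


def make_default_profiles(
    n_categories: int,
    seed: int = 0,
    fiber_noise_sd: float = 0.25,
    brand_effect_sd: float = 0.3,
) -> list[CategoryProfile]:
    """The first ``n_categories`` of 14 fixed archetype profiles.

    Profiles are deterministic regardless of ``seed`` (the argument is kept
    so callers can thread one spec-wide seed through their configuration).
    Archetypes span high-fiber (cereal-like), negligible-fiber (juice-like),
    mid-fiber, and one deliberately diffuse composition (grain_mix) whose
    sparse neighborhoods exercise confidence stratification.
    """
    if not 1 <= n_categories <= len(_ARCHETYPES):
        raise ValueError(f"n_categories must be in [1, {len(_ARCHETYPES)}]")
    return [
        CategoryProfile(
            name=name,
            dirichlet_concentration=alpha,
            sodium_log_mean=s_mu,
            sodium_log_sd=s_sd,
            beta0=b0,
            beta1=b1,
            beta2=b2,
            fiber_noise_sd=fiber_noise_sd,
            n_brands=n_brands,
            brand_effect_sd=brand_effect_sd,
        )
        for name, alpha, s_mu, s_sd, b0, b1, b2, n_brands in _ARCHETYPES[:n_categories]
    ]


def generate_supply(
    spec: SupplySpec,
    return_composition: bool = False,
) -> tuple[ProductTable, dict[str, float]] | tuple[ProductTable, dict[str, float], pd.DataFrame]:
    """Generate an observed product table plus the true-fiber map.

    The observed table masks fiber on non-reporting products; the truth map
    carries every product's true fiber.  Fully reproducible from the spec's
    seed.  With ``return_composition`` a third value is returned: a DataFrame
    of the underlying mass components (fiber carved out of "other", so each
    row sums to 100 g).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProductRecord] = []
    truth: dict[str, float] = {}
    composition_rows: list[dict] = []
    for profile in spec.profiles:
        alpha = np.asarray(profile.dirichlet_concentration, dtype=float)
        brand_shift = rng.normal(0.0, profile.brand_effect_sd, size=(profile.n_brands, 6))
        for i in range(spec.n_per_category):
            brand_idx = int(rng.integers(profile.n_brands))
            comp = rng.dirichlet(alpha * np.exp(brand_shift[brand_idx])) * 100.0
            sugar, starch, protein, sat_fat, unsat_fat, other = comp
            sodium = float(rng.lognormal(profile.sodium_log_mean, profile.sodium_log_sd))
            eps = float(rng.normal(0.0, profile.fiber_noise_sd)) if profile.fiber_noise_sd > 0 else 0.0
            fiber_true = float(
                np.clip(profile.beta0 + profile.beta1 * starch + profile.beta2 * sugar + eps,
                        0.0, other)
            )
            u = float(rng.uniform())
            p_report = _sigmoid(spec.reporting_gamma0 + spec.reporting_gamma1 * fiber_true)
            reported = u < p_report

            carbohydrate = sugar + starch
            if spec.carbohydrate_includes_fiber:
                carbohydrate += fiber_true
            product_id = f"{profile.name}-{i:05d}"
            records.append(
                ProductRecord(
                    product_id=product_id,
                    brand=f"{profile.name}_brand{brand_idx:02d}",
                    category=profile.name,
                    basis=Basis.PER_100G,
                    total_sugar=float(sugar),
                    carbohydrate=float(carbohydrate),
                    protein=float(protein),
                    saturated_fat=float(sat_fat),
                    total_fat=float(sat_fat + unsat_fat),
                    sodium=sodium,
                    fiber=fiber_true if reported else None,
                    ingredients_text=f"{profile.name} blend (100%)",
                )
            )
            truth[product_id] = fiber_true
            if return_composition:
                composition_rows.append(
                    {
                        "product_id": product_id,
                        "sugar": sugar,
                        "starch": starch,
                        "protein": protein,
                        "saturated_fat": sat_fat,
                        "unsaturated_fat": unsat_fat,
                        "fiber": fiber_true,
                        "other": other - fiber_true,
                    }
                )
    table = ProductTable(records, provenance=f"synthetic seed={spec.seed}")
    if return_composition:
        return table, truth, pd.DataFrame(composition_rows)
    return table, truth


def write_truth_csv(truth: dict[str, float], path: str | Path) -> None:
    """Write the product_id -> true fiber map as a two-column CSV."""
    df = pd.DataFrame(
        {"product_id": list(truth), "true_fiber_g": list(truth.values())}
    )
    df.to_csv(path, index=False)
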