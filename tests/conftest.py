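import numpy as np
import pytest

from fiberknn.products import Basis, ProductRecord, ProductTable


def mk(
    pid,
    category="bread",
    brand="Acme",
    sugar=10.0,
    carb=30.0,
    protein=5.0,
    sat_fat=3.0,
    fat=8.0,
    sodium=200.0,
    fiber=None,
    ingredients="flour (80%), water",
    basis=Basis.PER_100G,
):
    """Shorthand record factory for tests."""
    return ProductRecord(
        product_id=pid,
        brand=brand,
        category=category,
        basis=basis,
        total_sugar=sugar,
        carbohydrate=carb,
        protein=protein,
        saturated_fat=sat_fat,
        total_fat=fat,
        sodium=sodium,
        fiber=fiber,
        ingredients_text=ingredients,
    )


def random_table(rng, n=50, n_categories=2, n_brands=5, with_fiber=True, prefix="p"):
    """Random well-formed product table with all panel nutrients present."""
    records = []
    for i in range(n):
        sugar = rng.uniform(0, 30)
        starch = rng.uniform(0, 50)
        sat = rng.uniform(0, 10)
        unsat = rng.uniform(0, 20)
        records.append(
            mk(
                f"{prefix}{i:04d}",
                category=f"cat{int(rng.integers(n_categories))}",
                brand=f"brand{int(rng.integers(n_brands))}",
                sugar=sugar,
                carb=sugar + starch,
                protein=rng.uniform(0, 25),
                sat_fat=sat,
                fat=sat + unsat,
                sodium=rng.uniform(0, 1500),
                fiber=float(rng.uniform(0, 12)) if with_fiber else None,
            )
        )
    return ProductTable(records, provenance="random test table")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    return ProductTable(
        [
            mk("p1", fiber=4.0),
            mk("p2", sugar=5.0, carb=20.0, fiber=2.0),
            mk("p3", category="soup", brand="Soupy", sugar=2.0, carb=6.0, fiber=1.0),
        ],
        provenance="fixture",
    )
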