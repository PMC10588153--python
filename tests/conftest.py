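import numpy as np
import pytest

from isletmorph import (
    IsletRecord,
    ShapeMetrics,
    SpecimenRecord,
    render_demo,
    simulate_cohort,
)


def make_specimen(
    circularities,
    areas=None,
    ferets=None,
    parenchyma_cm2=1.0,
    group="ANHH",
    specimen_id="S1",
):
    """Hand-built specimen with explicit per-islet values (helper)."""
    n = len(circularities)
    areas = [5000.0] * n if areas is None else areas
    ferets = [80.0] * n if ferets is None else ferets
    islets = [
        IsletRecord(
            islet_id=i + 1,
            metrics=ShapeMetrics(
                area=float(a),
                perimeter=float(np.sqrt(4 * np.pi * a / c)),
                max_feret=float(f),
                circularity=float(c),
            ),
            is_cluster=a > 100_000,
        )
        for i, (c, a, f) in enumerate(zip(circularities, areas, ferets))
    ]
    return SpecimenRecord(
        specimen_id=specimen_id,
        group=group,
        parenchyma_area_cm2=parenchyma_cm2,
        islets=islets,
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """One small render-friendly synthetic cohort, shared across tests."""
    return simulate_cohort(render_demo(seed=7))


def star_polygon(rng, n_min=5, n_max=60):
    """Random simple (star-shaped) polygon: sorted angles, positive radii."""
    n = int(rng.integers(n_min, n_max))
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    # keep angles distinct so edges cannot be degenerate
    theta = theta + np.linspace(0, 1e-6, n)
    r = rng.uniform(0.1, 10.0, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
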