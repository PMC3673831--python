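"""Shared fixtures: synthetic phantoms and cohorts generated at test time."""

import numpy as np
import pytest

from copdct import CohortConfig, PhantomSpec, TubeSpec, generate_cohort, generate_phantom

SP = 0.4  # mm, phantom voxel pitch used across airway fixtures


@pytest.fixture(scope="session")
def straight_tube_phantom():
    """Single straight airway (r=2 mm, t=1 mm) spanning the grid along z."""
    g = 64
    extent = (g - 1) * SP
    mid = extent / 2.0
    spec = PhantomSpec(
        grid_shape=(g, g, g),
        spacing=(SP, SP, SP),
        tubes=[TubeSpec((mid, mid, 0.0), (mid, mid, extent), 2.0, 1.0, generation_label=2)],
    )
    insp, exp, truth = generate_phantom(spec, seed=0)
    return {"insp": insp, "exp": exp, "truth": truth, "spec": spec,
            "mid": mid, "extent": extent, "radius": 2.0, "thickness": 1.0}


@pytest.fixture(scope="session")
def y_phantom():
    """One bifurcation: trachea-like parent plus two daughter tubes."""
    g = 72
    sp = 0.5
    extent = (g - 1) * sp
    mid = extent / 2.0
    z1 = extent * 0.45
    tubes = [
        TubeSpec((mid, mid, 2.0), (mid, mid, z1), 2.5, 1.0, generation_label=0),
        TubeSpec((mid, mid, z1), (mid - 8, mid, extent - 3), 2.0, 1.0, generation_label=1),
        TubeSpec((mid, mid, z1), (mid + 8, mid, extent - 3), 2.0, 1.0, generation_label=1),
    ]
    spec = PhantomSpec(grid_shape=(g, g, g), spacing=(sp, sp, sp), tubes=tubes)
    insp, exp, truth = generate_phantom(spec, seed=0)
    child_ends = [(mid - 8, mid, extent - 3), (mid + 8, mid, extent - 3)]
    return {"insp": insp, "truth": truth, "mid": mid, "extent": extent,
            "z1": z1, "child_ends": child_ends, "seed_mm": (mid, mid, 3.0)}


@pytest.fixture(scope="session")
def multi_tube_phantom():
    """Three parallel tubes of graded caliber for the Pi10 regression."""
    geometries = [(1.5, 0.8), (2.5, 1.0), (4.0, 1.2)]
    xs = [8.0, 24.0, 42.0]
    gx, gy, gz = int(54 / SP), int(16 / SP) + 1, int(24 / SP) + 1
    extent_z = (gz - 1) * SP
    tubes = [
        TubeSpec((x, 8.0, 0.0), (x, 8.0, extent_z), r, t, generation_label=2)
        for x, (r, t) in zip(xs, geometries)
    ]
    spec = PhantomSpec(grid_shape=(gx, gy, gz), spacing=(SP, SP, SP), tubes=tubes)
    insp, _, truth = generate_phantom(spec, seed=0)
    return {"insp": insp, "truth": truth, "geometries": geometries, "xs": xs,
            "extent_z": extent_z}


@pytest.fixture(scope="session")
def cohort_1140():
    """Default-condition cohort at the study's sample size."""
    return generate_cohort(CohortConfig(n=1140, seed=3))


@pytest.fixture(scope="session")
def cohort_5000():
    return generate_cohort(CohortConfig(n=5000, seed=1))
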