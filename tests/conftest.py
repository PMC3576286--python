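import numpy as np
import pytest

from degensim.trait_space import ResourceSchedule, make_grid, rectangular_resource


@pytest.fixture(scope="session")
def grid300():
    """The standard 300-point trait axis [0, 299]."""
    return make_grid(0, 299, 1.0)


@pytest.fixture(scope="session")
def rect_K(grid300):
    """Uniform rectangular carrying capacity, 100 units per cell."""
    return rectangular_resource(grid300, 0, 299, 100.0)


@pytest.fixture(scope="session")
def rect_schedule(rect_K):
    return ResourceSchedule.constant(rect_K)


@pytest.fixture(scope="session")
def ring32():
    """Small grid used as a periodic (wrap-around) oracle instance."""
    return make_grid(0, 31, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_demand(density, kernel, spacing, periodic):
    """O(n·m) double-loop reference for the kernel sum."""
    n = len(density)
    half = kernel.half_width
    w = kernel.weights
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for a in range(len(w)):
            k = a - half
            j = i - k
            if periodic:
                acc += w[a] * density[j % n]
            elif 0 <= j < n:
                acc += w[a] * density[j]
        out[i] = acc * spacing
    return out


def brute_share(density, capacity, kernel, spacing, demand_floor, periodic):
    """O(n·m) double-loop reference for the per-capita reachable capacity."""
    D = brute_demand(density, kernel, spacing, periodic)
    floor_abs = demand_floor * density.max(initial=0.0) * spacing
    ratio = np.where(D > floor_abs, capacity / np.where(D > floor_abs, D, 1.0), 0.0)
    return brute_demand(ratio, kernel, spacing, periodic)
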