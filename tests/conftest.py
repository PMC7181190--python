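import dataclasses

import numpy as np
import pytest

import nervect as nv
from nervect.phantom import TissueClass, build_phantom, example_nerve_spec


@pytest.fixture(scope="session")
def example_result():
    """One branching/plexus nerve phantom at mild noise, built once."""
    return build_phantom(example_nerve_spec(rng_seed=7, noise_sd=0.02))


@pytest.fixture(scope="session")
def example_pipeline(example_result):
    seeds = nv.seeds_from_truth(example_result)
    cfg = nv.PipelineConfig(min_fascicles=4)
    return nv.run_pipeline(example_result.volume, seeds, cfg,
                           annotation=example_result)


@pytest.fixture(scope="session")
def noise_free_result():
    """Same geometry, zero texture and zero noise: grey == tissue mean."""
    spec = example_nerve_spec(rng_seed=7, noise_sd=0.0)
    spec = dataclasses.replace(spec, tissue_sds={tc: 0.0 for tc in TissueClass})
    return build_phantom(spec)


# --- independent oracles -----------------------------------------------------

def median_oracle(data: np.ndarray) -> np.ndarray:
    """3x3x3 median by explicit symmetric padding and sort-and-pick."""
    padded = np.pad(data, 1, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3, 3))
    return np.median(windows.reshape(data.shape + (27,)), axis=-1)


def moving_average_oracle(data: np.ndarray) -> np.ndarray:
    """1x1x5 moving average along z as an explicit 5-term sum."""
    padded = np.pad(data, ((2, 2), (0, 0), (0, 0)), mode="symmetric")
    out = np.zeros_like(data)
    for k in range(5):
        out += padded[k:k + data.shape[0]]
    return out / 5.0


def flood_fill_oracle(in_range: np.ndarray, seeds, connectivity: int) -> np.ndarray:
    """Breadth-first flood fill over the in-range voxel set."""
    from collections import deque
    if connectivity == 6:
        steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        steps = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                 for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    out = np.zeros_like(in_range, dtype=bool)
    q = deque()
    for s in seeds:
        if in_range[s] and not out[s]:
            out[s] = True
            q.append(s)
    nz, ny, nx = in_range.shape
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in steps:
            p = (z + dz, y + dy, x + dx)
            if (0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx
                    and in_range[p] and not out[p]):
                out[p] = True
                q.append(p)
    return out
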