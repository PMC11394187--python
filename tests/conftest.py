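import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import stentmorph as sm


@pytest.fixture(scope="session")
def clean_case():
    spec = sm.preset("clean", 1)
    vol, truth = sm.render_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def encrusted_case():
    spec = sm.preset("encrusted", 0)
    vol, truth = sm.render_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def residual_case():
    spec = sm.preset("residual", 0)
    vol, truth = sm.render_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def distractor_case():
    spec = sm.preset("distractors", 7)
    vol, truth = sm.render_phantom(spec)
    return spec, vol, truth


def voxel_cylinder(radius_px: float, length: int = 40, pad: int = 6, axis: int = 2) -> np.ndarray:
    """Solid axis-aligned cylinder in voxel units (bool volume)."""
    side = int(2 * radius_px) + 2 * pad + 1
    c = side // 2
    x, y = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    disk = (x - c) ** 2 + (y - c) ** 2 <= radius_px**2
    m = np.zeros((side, side, length + 2 * pad), bool)
    for z in range(pad, pad + length):
        m[:, :, z] = disk
    if axis != 2:
        m = np.moveaxis(m, 2, axis)
    return m


def flood_fill_partition(mask: np.ndarray, adjacency: int) -> list[frozenset]:
    """Independent BFS flood-fill oracle: connected components as voxel sets."""
    from collections import deque

    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                s = abs(dx) + abs(dy) + abs(dz)
                if adjacency == 6 and s > 1:
                    continue
                if adjacency == 18 and s > 2:
                    continue
                offs.append((dx, dy, dz))
    todo = {tuple(v) for v in np.argwhere(mask)}
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        q = deque([seed])
        while q:
            p = q.popleft()
            for d in offs:
                n = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if n in todo:
                    todo.remove(n)
                    comp.add(n)
                    q.append(n)
        comps.append(frozenset(comp))
    return comps


def label_partition(labels: np.ndarray) -> list[frozenset]:
    """Component partition implied by a label volume, as voxel sets."""
    out = {}
    for v in np.argwhere(labels > 0):
        out.setdefault(int(labels[tuple(v)]), set()).add(tuple(v))
    return [frozenset(s) for s in out.values()]
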