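"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from plasmogram import phantom as ph


@pytest.fixture(scope="session")
def small_config() -> ph.PhantomConfig:
    """A cheap 13-frame, 4-well phantom for plumbing tests."""
    return ph.PhantomConfig(
        seed=42,
        duration_min=120.0,
        slit_pixels_per_well=8,
        wavelength_pixels=256,
        bf_image_size=96,
        radius_start_px=24.0,
        radius_end_px=28.0,
    )


@pytest.fixture(scope="session")
def small_spectral(small_config):
    return ph.render_spectral_stack(small_config)


def centroid_oracle(spectrum, lo, hi, threshold, axis=None):
    """Independent direct-summation centroid: explicit Python loop."""
    num = 0.0
    den = 0.0
    for i in range(lo, hi + 1):
        w = spectrum[i] - threshold
        if w < 0:
            w = 0.0
        pos = axis[i] if axis is not None else float(i)
        num += pos * w
        den += w
    return num / den if den > 0 else float("nan")


def flood_fill_oracle(mask: np.ndarray) -> int:
    """Pixel count of the largest 8-connected component with holes filled,
    by brute-force BFS (components on the mask, then background reachability
    from the border on the complement)."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    best = set()
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                comp = set()
                stack = [(sy, sx)]
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                if len(comp) > len(best):
                    best = comp
    comp_mask = np.zeros_like(mask, dtype=bool)
    for y, x in best:
        comp_mask[y, x] = True
    # background = 4-connected complement pixels reachable from the border
    outside = np.zeros_like(mask, dtype=bool)
    stack = [
        (y, x)
        for y in range(h)
        for x in range(w)
        if (y in (0, h - 1) or x in (0, w - 1)) and not comp_mask[y, x]
    ]
    for y, x in stack:
        outside[y, x] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not comp_mask[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                stack.append((ny, nx))
    return int(comp_mask.sum() + (~comp_mask & ~outside).sum())


def mannwhitney_exact_oracle(a, b):
    """Exact Mann-Whitney U and two-sided p by enumerating all label
    assignments of the pooled sample (no ties assumed)."""
    from itertools import combinations

    a = list(a)
    b = list(b)
    pooled = a + b
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    u_all = []
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )
        u_all.append(u)
    u_all = np.asarray(u_all)
    p_le = np.mean(u_all <= u_obs)
    p_ge = np.mean(u_all >= u_obs)
    p = min(1.0, 2 * min(p_le, p_ge))
    return u_obs, p
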