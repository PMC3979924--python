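"""Brute-force reference implementations used to cross-check the pipeline.

Deliberately naive: explicit moment sums, queue-based flood fill, exhaustive
threshold search.  They share no code with the package implementation.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def moments_ellipse_features(component: np.ndarray) -> tuple[float, float]:
    """(eccentricity, major_axis_length) from explicit second central moments.

    ``component`` is a boolean mask holding a single connected component.
    The ellipse with matching normalized second central moments has
    covariance eigenvalues l1 >= l2; its major-axis length is 4*sqrt(l1)
    and its eccentricity sqrt(1 - l2/l1).
    """
    rows, cols = np.nonzero(component)
    n = rows.size
    if n == 0:
        raise ValueError("empty component")
    rbar = rows.sum() / n
    cbar = cols.sum() / n
    mu20 = ((rows - rbar) ** 2).sum() / n
    mu02 = ((cols - cbar) ** 2).sum() / n
    mu11 = ((rows - rbar) * (cols - cbar)).sum() / n
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11 ** 2)
    l1 = (mu20 + mu02 + common) / 2
    l2 = (mu20 + mu02 - common) / 2
    ecc = np.sqrt(1 - l2 / l1) if l1 > 0 else 0.0
    return float(ecc), float(4 * np.sqrt(l1))


def flood_filled_area(component: np.ndarray) -> int:
    """Filled area of a single-component mask by border flood fill.

    Background pixels unreachable from the border of the (1-padded)
    component image are interior holes and count toward the filled area.
    The background flood moves with full (8-connected) steps, the standard
    hole definition: a diagonal gap in the boundary is an escape route.
    """
    comp = np.pad(np.asarray(component, bool), 1)
    h, w = comp.shape
    reached = np.zeros_like(comp)
    queue: deque[tuple[int, int]] = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not comp[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not comp[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    steps = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    while queue:
        r, c = queue.popleft()
        for dr, dc in steps:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not comp[rr, cc] and not reached[rr, cc]:
                reached[rr, cc] = True
                queue.append((rr, cc))
    return int(comp.sum() + (~comp & ~reached).sum())


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[np.ndarray]:
    """Connected components by breadth-first search; returns one mask each."""
    mask = np.asarray(mask, bool)
    if connectivity == 8:
        steps = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        comp = np.zeros_like(mask)
        queue = deque([(r0, c0)])
        seen[r0, c0] = comp[r0, c0] = True
        while queue:
            r, c = queue.popleft()
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = comp[rr, cc] = True
                    queue.append((rr, cc))
        comps.append(comp)
    return comps


def brute_otsu(image: np.ndarray) -> float:
    """Exhaustive Otsu: the inter-value midpoint maximizing between-class
    variance over all candidate thresholds."""
    values = np.sort(np.unique(np.asarray(image, float).ravel()))
    if values.size < 2:
        raise ValueError("constant image")
    best_thr, best_var = values[0], -1.0
    flat = np.asarray(image, float).ravel()
    for lo, hi in zip(values[:-1], values[1:]):
        thr = (lo + hi) / 2
        w0 = (flat <= thr).mean()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        var = w0 * w1 * (flat[flat > thr].mean() - flat[flat <= thr].mean()) ** 2
        if var > best_var:
            best_var, best_thr = var, thr
    return float(best_thr)


def random_blob_mask(rng: np.random.Generator, size: int = 48) -> np.ndarray:
    """A random smooth-ish blob mask for oracle-equivalence sweeps."""
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.normal(size=(size, size)), sigma=rng.uniform(1.5, 5.0))
    mask = field > np.quantile(field, rng.uniform(0.6, 0.92))
    return mask
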