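"""Independent oracles used to cross-check the pipeline.

Everything here is deliberately naive and exhaustive — pure-Python flood
fill, brute-force distance scans, full permutation enumeration — and shares
no code path with the package implementation it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def flood_fill_components(foreground: np.ndarray) -> list[set[tuple[int, int]]]:
    """Exhaustive BFS labeling of 8-connected components of a boolean mask."""
    h, w = foreground.shape
    seen = np.zeros_like(foreground, dtype=bool)
    components: list[set[tuple[int, int]]] = []
    for r0 in range(h):
        for c0 in range(w):
            if not foreground[r0, c0] or seen[r0, c0]:
                continue
            comp: set[tuple[int, int]] = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w
                                and foreground[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            components.append(comp)
    return components


def fill_holes(foreground: np.ndarray) -> np.ndarray:
    """Fill interior holes: background pixels not 4-connected to the border."""
    h, w = foreground.shape
    reach = np.zeros_like(foreground, dtype=bool)
    queue: deque[tuple[int, int]] = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not foreground[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not foreground[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if (0 <= rr < h and 0 <= cc < w and not foreground[rr, cc]
                    and not reach[rr, cc]):
                reach[rr, cc] = True
                queue.append((rr, cc))
    holes = ~foreground & ~reach
    return foreground | holes


def oracle_nuclei(pixels: np.ndarray, threshold: float, pixel_size_um: float,
                  min_diam_um: float, max_diam_um: float) -> list[set[tuple[int, int]]]:
    """Nucleus regions by exhaustive flood fill: threshold, fill holes,
    8-connected components, equivalent-diameter gate."""
    fg = fill_holes(pixels >= threshold)
    out = []
    for comp in flood_fill_components(fg):
        area = len(comp) * pixel_size_um**2
        eq_diam = 2.0 * np.sqrt(area / np.pi)
        if min_diam_um <= eq_diam <= max_diam_um:
            out.append(comp)
    return out


def region_distance_um(point_rc: tuple[int, int], region: set[tuple[int, int]],
                       pixel_size_um: float) -> float:
    """Brute-force Euclidean distance (pixel centers) from a pixel to a region."""
    pr, pc = point_rc
    arr = np.array(sorted(region))
    d2 = (arr[:, 0] - pr) ** 2 + (arr[:, 1] - pc) ** 2
    return float(np.sqrt(d2.min())) * pixel_size_um


def oracle_spots(pixels: np.ndarray, threshold: float, pixel_size_um: float,
                 nuclei: list[set[tuple[int, int]]], ring_width_um: float,
                 min_diam_um: float, max_diam_um: float,
                 ) -> list[tuple[set[tuple[int, int]], int]]:
    """Spot regions by exhaustive flood fill, replaying the detection rules.

    Candidates are supra-threshold pixels outside all nucleus regions;
    a candidate is in a ring when its nearest nucleus region lies within
    the ring width; components keep >= 50% in-ring area, are clipped to the
    ring of the majority owner, then pass the size gate. Returns
    (pixel set, owner index into *nuclei*).
    """
    nucleus_pixels = set().union(*nuclei) if nuclei else set()
    candidates = pixels >= threshold
    for (r, c) in nucleus_pixels:
        candidates[r, c] = False
    spots = []
    for comp in flood_fill_components(candidates):
        ownership = {}
        for px in comp:
            dists = [region_distance_um(px, reg, pixel_size_um) for reg in nuclei]
            if not dists:
                continue
            k = int(np.argmin(dists))
            if dists[k] <= ring_width_um:
                ownership[px] = k
        if 2 * len(ownership) < len(comp):
            continue
        owners, counts = np.unique(list(ownership.values()), return_counts=True)
        owner = int(owners[np.argmax(counts)])
        clipped = {px for px, k in ownership.items() if k == owner}
        area = len(clipped) * pixel_size_um**2
        eq_diam = 2.0 * np.sqrt(area / np.pi)
        if min_diam_um <= eq_diam <= max_diam_um:
            spots.append((clipped, owner))
    return spots


# ---------------------------------------------------------------------------
# rank-test oracles
# ---------------------------------------------------------------------------


def mw_u_statistic(x, y) -> float:
    """U statistic for sample x (count of x>y pairs, ties as half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mw_exact_bruteforce(x, y, sided: str = "two") -> float:
    """Exact Mann–Whitney p-value by full enumeration of group assignments."""
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y
    u_obs = mw_u_statistic(x, y)
    n_ge = n_le = total = 0
    for idx in combinations(range(len(pooled)), n1):
        chosen = set(idx)
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = mw_u_statistic(gx, gy)
        total += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
        if u <= u_obs + 1e-12:
            n_le += 1
    p_greater = n_ge / total
    p_less = n_le / total
    if sided == "greater":
        return p_greater
    if sided == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def ks_statistic_bruteforce(a, b) -> float:
    """D = sup |ECDF_a - ECDF_b| evaluated at every pooled jump point."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    d = 0.0
    for t in np.concatenate([a, b]):
        fa = np.mean(a <= t)
        fb = np.mean(b <= t)
        d = max(d, abs(fa - fb))
    return float(d)
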