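"""Independent brute-force re-implementations used as test oracles.

Everything here recomputes from first principles with plain Python loops and
sets — no shared code with the package's vectorized engines — so agreement is
meaningful.
"""

from __future__ import annotations

import math


def pixel_set_stats(pixels, layers):
    """(n, perimeter, bbox, sigmas) of a pixel set, computed from scratch."""
    n = len(pixels)
    sigmas = []
    for layer in layers:
        vals = [float(layer[r][c]) for r, c in pixels]
        mean = sum(vals) / n
        var = sum(v * v for v in vals) / n - mean * mean
        sigmas.append(math.sqrt(max(var, 0.0)))
    perimeter = 0
    for r, c in pixels:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) not in pixels:
                perimeter += 1
    rows = [r for r, _ in pixels]
    cols = [c for _, c in pixels]
    bbox = (min(rows), max(rows), min(cols), max(cols))
    return n, perimeter, bbox, sigmas


def direct_fusion_cost(
    pixels_a,
    pixels_b,
    layers,
    w_color=0.7,
    w_smooth=0.4,
    w_compact=0.6,
    layer_weights=None,
):
    """Fusion cost evaluated directly on the two pixel sets."""
    if layer_weights is None:
        layer_weights = [1.0] * len(layers)
    w_shape = 1.0 - w_color
    na, la, _, sa = pixel_set_stats(pixels_a, layers)
    nb, lb, _, sb = pixel_set_stats(pixels_b, layers)
    merged = set(pixels_a) | set(pixels_b)
    nm, lm, bboxm, sm = pixel_set_stats(merged, layers)
    dh_color = sum(
        wc * (nm * s_m - na * s_a - nb * s_b)
        for wc, s_m, s_a, s_b in zip(layer_weights, sm, sa, sb)
    )
    def shortest_side(pixels):
        rows = [r for r, _ in pixels]
        cols = [c for _, c in pixels]
        return min(max(rows) - min(rows) + 1, max(cols) - min(cols) + 1)

    bm = shortest_side(merged)
    dh_smooth = (
        nm * lm / bm
        - na * la / shortest_side(pixels_a)
        - nb * lb / shortest_side(pixels_b)
    )
    dh_compact = (
        lm * math.sqrt(nm) - la * math.sqrt(na) - lb * math.sqrt(nb)
    )
    return w_color * dh_color + w_shape * (w_smooth * dh_smooth + w_compact * dh_compact)


def greedy_mutual_merge(image, scale, w_color=0.7, w_smooth=0.4, w_compact=0.6):
    """Exhaustive mutual-best-fitting merge of one 2-D image; returns the
    final partition.

    Segments are keyed by the smallest flat pixel index they contain. Each
    round recomputes every pairwise cost from scratch, every segment names its
    cheapest neighbor (ties to the lowest neighbor id), and all mutually-best
    pairs with cost < scale**2 merge simultaneously.
    """
    layers = [image]
    rows = len(image)
    cols = len(image[0])
    threshold = scale * scale
    segs = {r * cols + c: {(r, c)} for r in range(rows) for c in range(cols)}

    def seg_of(pixel, mapping):
        return mapping[pixel]

    while True:
        owner = {}
        for sid, pixels in segs.items():
            for p in pixels:
                owner[p] = sid
        neighbors = {sid: set() for sid in segs}
        for (r, c), sid in owner.items():
            for dr, dc in ((1, 0), (0, 1)):
                q = (r + dr, c + dc)
                if q in owner and owner[q] != sid:
                    neighbors[sid].add(owner[q])
                    neighbors[owner[q]].add(sid)
        costs = {}
        for sid in segs:
            for nid in neighbors[sid]:
                key = (min(sid, nid), max(sid, nid))
                if key not in costs:
                    costs[key] = direct_fusion_cost(
                        segs[key[0]], segs[key[1]], layers, w_color, w_smooth, w_compact
                    )
        best = {}
        for sid in segs:
            cands = sorted(
                (costs[(min(sid, n), max(sid, n))], n) for n in neighbors[sid]
            )
            if cands:
                best[sid] = cands[0]
        merges = []
        for sid, (cost, nid) in best.items():
            if sid < nid and best.get(nid, (None, None))[1] == sid and cost < threshold:
                merges.append((sid, nid))
        if not merges:
            break
        for keep, drop in merges:
            segs[keep] = segs[keep] | segs[drop]
            del segs[drop]
    return {frozenset(p) for p in segs.values()}


def _on_segment(px, py, x1, y1, x2, y2, eps=1e-12):
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    if abs(cross) > eps * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
        return False
    if min(x1, x2) - eps <= px <= max(x1, x2) + eps and min(y1, y2) - eps <= py <= max(y1, y2) + eps:
        return True
    return False


def point_in_polygon(px, py, ring):
    """Boundary-inclusive even-odd test against a closed coordinate ring."""
    n = len(ring)
    inside = False
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if _on_segment(px, py, x1, y1, x2, y2):
            return True
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside
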