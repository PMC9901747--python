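"""Independent brute-force reference implementations used only by tests.

Everything here is written as a literal transcription of the operations'
definitions — explicit Python loops and set arithmetic — deliberately
sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math


def project_max_loop(stack):
    T = len(stack)
    H, W = len(stack[0]), len(stack[0][0])
    out = [[0] * W for _ in range(H)]
    for y in range(H):
        for x in range(W):
            out[y][x] = max(int(stack[t][y][x]) for t in range(T))
    return out


def project_std_loop(stack):
    """Population sd per pixel, rounded half-up."""
    T = len(stack)
    H, W = len(stack[0]), len(stack[0][0])
    out = [[0] * W for _ in range(H)]
    for y in range(H):
        for x in range(W):
            vals = [int(stack[t][y][x]) for t in range(T)]
            m = sum(vals) / T
            sd = math.sqrt(sum((v - m) ** 2 for v in vals) / T)
            out[y][x] = math.floor(sd + 0.5)
    return out


def mean_filter_loop(img, size):
    """Windowed mean with symmetric (edge-including) border reflection."""
    H, W = len(img), len(img[0])
    h = size // 2

    def reflect(i, n):
        # ... d c b a | a b c d | d c b a ...
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            else:
                i = 2 * n - i - 1
        return i

    out = [[0] * W for _ in range(H)]
    for y in range(H):
        for x in range(W):
            total = 0
            for dy in range(-h, h + 1):
                for dx in range(-h, h + 1):
                    total += int(img[reflect(y + dy, H)][reflect(x + dx, W)])
            out[y][x] = math.floor(total / (size * size) + 0.5)
    return out


def iom_sets(a: set, b: set) -> float:
    return len(a & b) / min(len(a), len(b))


def trace_loop(stack, labels):
    """Per-ROI mean intensity per frame via explicit loops."""
    T = len(stack)
    H, W = len(labels), len(labels[0])
    ids = sorted({labels[y][x] for y in range(H) for x in range(W)} - {0})
    out = []
    for k in ids:
        pix = [(y, x) for y in range(H) for x in range(W) if labels[y][x] == k]
        row = []
        for t in range(T):
            row.append(sum(int(stack[t][y][x]) for y, x in pix) / len(pix))
        out.append(row)
    return ids, out


def optimal_matching(seg_masks: dict, gt_masks: dict, threshold: float):
    """Exhaustive best one-to-one assignment: max TP, then max summed IoM.

    Returns (tp, fp, fn, pairs).
    """
    s_ids = sorted(seg_masks)
    g_ids = sorted(gt_masks)
    iom_of = {
        (s, g): iom_sets(seg_masks[s], gt_masks[g]) for s in s_ids for g in g_ids
    }
    best = (0, 0.0, [])
    k = min(len(s_ids), len(g_ids))
    for size in range(k, -1, -1):
        if size < best[0]:
            break
        for s_sub in itertools.combinations(s_ids, size):
            for g_perm in itertools.permutations(g_ids, size):
                pairs = [
                    (s, g)
                    for s, g in zip(s_sub, g_perm)
                    if iom_of[(s, g)] > threshold
                ]
                score = (len(pairs), sum(iom_of[p] for p in pairs))
                if score > best[:2]:
                    best = (score[0], score[1], pairs)
    tp = best[0]
    return tp, len(s_ids) - tp, len(g_ids) - tp, best[2]


def _components(pixels: set, connectivity: int) -> list[set]:
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    remaining = set(pixels)
    comps = []
    while remaining:
        seed = next(iter(remaining))
        comp = {seed}
        frontier = [seed]
        remaining.discard(seed)
        while frontier:
            y, x = frontier.pop()
            for dy, dx in nbrs:
                p = (y + dy, x + dx)
                if p in remaining:
                    remaining.discard(p)
                    comp.add(p)
                    frontier.append(p)
        comps.append(comp)
    return comps


def mlt_replay(img, junction, stopping, elimination, connectivity=8):
    """Set-based replay of the descending-threshold region rules.

    Returns {final id: pixel set} with final ids 1..K assigned in birth-id
    order, mirroring the contract of the segmentation routine.
    """
    H, W = len(img), len(img[0])
    regions: dict[int, dict] = {}  # id -> {pixels, frozen, birth}
    nid = 1
    for t in range(255, -1, -1):
        fg = {(y, x) for y in range(H) for x in range(W) if int(img[y][x]) >= t}
        for comp in _components(fg, connectivity):
            frozen_px = set()
            for r in regions.values():
                if r["frozen"]:
                    frozen_px |= r["pixels"]
            cprime = comp - frozen_px
            G = [
                i
                for i, r in regions.items()
                if not r["frozen"] and r["pixels"] & cprime
            ]
            touches_frozen = bool(comp & frozen_px)
            if not G:
                if not touches_frozen and cprime:
                    regions[nid] = {"pixels": cprime, "frozen": False, "birth": t}
                    nid += 1
                continue
            if len(G) == 1:
                r = regions[G[0]]
                if len(cprime) > stopping:
                    r["frozen"] = True
                else:
                    r["pixels"] = cprime
                continue
            total = sum(len(regions[g]["pixels"]) for g in G)
            if total > junction:
                for g in G:
                    regions[g]["frozen"] = True
                continue
            target = min(G)
            union = set()
            for g in G:
                union |= regions[g]["pixels"]
            regions[target]["birth"] = max(regions[g]["birth"] for g in G)
            for g in G:
                if g != target:
                    del regions[g]
            if len(cprime) > stopping:
                regions[target]["pixels"] = union
                regions[target]["frozen"] = True
            else:
                regions[target]["pixels"] = cprime
    survivors = sorted(
        i for i, r in regions.items() if len(r["pixels"]) >= elimination
    )
    return {
        new: regions[old]["pixels"] for new, old in enumerate(survivors, start=1)
    }
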