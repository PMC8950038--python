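"""Independent brute-force oracles used to validate the library metrics.

Everything here is deliberately written with python sets, dicts and
explicit loops -- no shared code with aswnet.metrics -- so agreement is
evidence of correctness, not of shared bugs.
"""

from __future__ import annotations

import numpy as np


def objects_as_sets(labels: np.ndarray) -> dict[int, set]:
    out: dict[int, set] = {}
    H, W = labels.shape
    for r in range(H):
        for c in range(W):
            l = int(labels[r, c])
            if l > 0:
                out.setdefault(l, set()).add((r, c))
    return out


def oracle_dice1(pred: np.ndarray, truth: np.ndarray) -> float:
    p = {(r, c) for r, c in zip(*np.nonzero(pred))}
    g = {(r, c) for r, c in zip(*np.nonzero(truth))}
    if not p and not g:
        return 1.0
    return 2.0 * len(p & g) / (len(p) + len(g))


def oracle_dice2(pred: np.ndarray, truth: np.ndarray) -> float:
    P = objects_as_sets(pred)
    G = objects_as_sets(truth)
    if not P and not G:
        return 1.0
    num = den = 0.0

    def best(obj, others):
        best_k, best_ov = None, 0
        for k in sorted(others):
            ov = len(obj & others[k])
            if ov > best_ov:
                best_k, best_ov = k, ov
        return best_k, best_ov

    for gk in sorted(G):
        pk, ov = best(G[gk], P)
        if pk is not None:
            num += 2.0 * ov
            den += len(G[gk]) + len(P[pk])
        else:
            den += len(G[gk])
    for pk in sorted(P):
        gk, ov = best(P[pk], G)
        if gk is not None:
            num += 2.0 * ov
            den += len(P[pk]) + len(G[gk])
        else:
            den += len(P[pk])
    return num / den if den > 0 else 0.0


def oracle_aji(pred: np.ndarray, truth: np.ndarray) -> float:
    """Aggregated Jaccard: greedy best-IoU over unused predictions,
    ground truth in increasing label order, ties to the smaller pred label."""
    P = objects_as_sets(pred)
    G = objects_as_sets(truth)
    if not P and not G:
        return 1.0
    used = set()
    C = U = 0
    for gk in sorted(G):
        g = G[gk]
        best_pk, best_iou = None, 0.0
        for pk in sorted(P):
            if pk in used:
                continue
            inter = len(g & P[pk])
            if inter == 0:
                continue
            iou = inter / len(g | P[pk])
            if iou > best_iou + 1e-15:
                best_pk, best_iou = pk, iou
        if best_pk is None:
            U += len(g)
        else:
            C += len(g & P[best_pk])
            U += len(g | P[best_pk])
            used.add(best_pk)
    for pk in P:
        if pk not in used:
            U += len(P[pk])
    return C / U if U > 0 else 1.0


def oracle_pq(pred: np.ndarray, truth: np.ndarray):
    """(dq, sq, pq, tp, fp, fn) from exhaustive IoU > 0.5 pairing."""
    P = objects_as_sets(pred)
    G = objects_as_sets(truth)
    ious = []
    matched_p = set()
    matched_g = set()
    for gk in G:
        for pk in P:
            iou = len(G[gk] & P[pk]) / len(G[gk] | P[pk])
            if iou > 0.5:
                assert gk not in matched_g and pk not in matched_p
                matched_g.add(gk)
                matched_p.add(pk)
                ious.append(iou)
    tp = len(ious)
    fp = len(P) - len(matched_p)
    fn = len(G) - len(matched_g)
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0, 0, 0, 0
    dq = tp / (tp + 0.5 * fp + 0.5 * fn)
    sq = sum(ious) / tp if tp else 0.0
    return dq, sq, dq * sq, tp, fp, fn


def flood_fill_count(binary: np.ndarray, connectivity: int = 8) -> int:
    """Connected-component count by explicit BFS."""
    H, W = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for r in range(H):
        for c in range(W):
            if binary[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < H and 0 <= nc < W and binary[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
    return count


def random_mask(rng: np.random.Generator, size: int = 32,
                max_objects: int = 5) -> np.ndarray:
    """Random instance mask of blobby rectangles/disks (may touch/overwrite)."""
    labels = np.zeros((size, size), dtype=np.int32)
    n = rng.integers(0, max_objects + 1)
    for lab in range(1, n + 1):
        shape = rng.integers(0, 2)
        r0, c0 = rng.integers(0, size, 2)
        if shape == 0:
            h, w = rng.integers(2, max(size // 3, 3), 2)
            labels[r0:r0 + h, c0:c0 + w] = lab
        else:
            rad = int(rng.integers(2, max(size // 4, 3)))
            rr, cc = np.mgrid[0:size, 0:size]
            labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad * rad] = lab
    return labels
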