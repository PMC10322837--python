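"""Brute-force reference implementations used only as test oracles.

Each function here is a deliberately naive, loop-based computation of a
quantity the package computes vectorized; the two must agree exactly.
"""

import math

import numpy as np


def otsu_exhaustive(values, n_bins=256):
    """Exhaustive between-class-variance search over all n_bins-1 cut points.

    Maximizes w0*w1*(mu0-mu1)^2 of the two-class histogram split. Bin
    centers are an affine function of the bin index, which rescales the
    between-class variance by the same positive factor at every cut, so the
    comparison is done on exact integer index moments (Fractions) and ties
    break toward the lowest cut with no floating-point ambiguity.
    """
    from fractions import Fraction

    v = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    total = int(hist.sum())
    best_var, best_edge = Fraction(-1), None
    for k in range(n_bins - 1):  # class 0 = bins 0..k
        n0 = int(hist[: k + 1].sum())
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = Fraction(int((hist[: k + 1] * np.arange(k + 1)).sum()), n0)
        mu1 = Fraction(int((hist[k + 1 :] * np.arange(k + 1, n_bins)).sum()), n1)
        var = Fraction(n0 * n1, total * total) * (mu0 - mu1) ** 2
        if var > best_var:  # strict: first (lowest) maximizer wins
            best_var, best_edge = var, edges[k + 1]
    return best_edge


def flood_fill_label(mask, connectivity=8):
    """Stack-based flood fill labeling in raster-scan first-encounter order."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=int)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    label = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and out[r0, c0] == 0:
                label += 1
                stack = [(r0, c0)]
                out[r0, c0] = label
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]
                            and mask[rr, cc]
                            and out[rr, cc] == 0
                        ):
                            out[rr, cc] = label
                            stack.append((rr, cc))
    return out


def measure_by_accumulation(labels, intensities=None):
    """Per-object area/centroid/diameter/mean via per-pixel accumulation."""
    labels = np.asarray(labels)
    n = int(labels.max())
    out = {}
    for lab in range(1, n + 1):
        rs, cs = np.where(labels == lab)
        if rs.size == 0:
            continue
        area = int(rs.size)
        rec = {
            "area": area,
            "centroid": (float(rs.mean()), float(cs.mean())),
            "diameter": 2.0 * math.sqrt(area / math.pi),
        }
        if intensities is not None:
            rec["mean_intensity"] = tuple(
                float(np.asarray(ch, dtype=float)[rs, cs].mean()) for ch in intensities
            )
        out[lab] = rec
    return out


def round_half_away(x):
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def relate_membership(children, parents):
    """Assign each child to the parent mask containing its rounded centroid."""
    children = np.asarray(children)
    parents = np.asarray(parents)
    out = {}
    for lab, rec in measure_by_accumulation(children).items():
        r = min(max(round_half_away(rec["centroid"][0]), 0), parents.shape[0] - 1)
        c = min(max(round_half_away(rec["centroid"][1]), 0), parents.shape[1] - 1)
        p = int(parents[r, c])
        out[lab] = p if p > 0 else "unrelated"
    return out


def filter_survivors(labels, min_d=0.0, max_d=None, discard_border=False):
    """Per-object diameter/border test; returns surviving original labels in order."""
    labels = np.asarray(labels)
    keep = []
    for lab, rec in measure_by_accumulation(labels).items():
        d = rec["diameter"]
        if d < min_d:
            continue
        if max_d is not None and d > max_d:
            continue
        if discard_border:
            rs, cs = np.where(labels == lab)
            if (
                rs.min() == 0
                or cs.min() == 0
                or rs.max() == labels.shape[0] - 1
                or cs.max() == labels.shape[1] - 1
            ):
                continue
        keep.append(lab)
    return keep
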