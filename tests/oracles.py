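"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written as naive loops / literal formula
transcriptions, sharing no code with the package implementation.
"""

import math
from itertools import combinations

import numpy as np


def brute_glcm(quantized, mask, offset, n_bins):
    """Double-loop symmetric co-occurrence counting for one offset."""
    counts = np.zeros((n_bins, n_bins))
    shape = quantized.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb = tuple(idx[k] + offset[k] for k in range(3))
        if all(0 <= nb[k] < shape[k] for k in range(3)) and mask[nb]:
            counts[quantized[idx], quantized[nb]] += 1
            counts[quantized[nb], quantized[idx]] += 1
    return counts


def brute_haralick(P):
    """Literal transcription of the 12 co-occurrence statistics.

    Scalar loops throughout; log base 2; sum variance computed against the
    sum average (corrected reading of the original definition).
    """
    ng = P.shape[0]
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum = [0.0] * (2 * ng - 1)
    p_diff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    def h(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    asm = sum(P[i][j] ** 2 for i in range(ng) for j in range(ng))
    contrast = sum((i - j) ** 2 * P[i][j] for i in range(ng) for j in range(ng))
    if sd_x > 0 and sd_y > 0:
        correlation = (
            sum(i * j * P[i][j] for i in range(ng) for j in range(ng)) - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        correlation = 0.0
    sum_square = sum((i - mu_x) ** 2 * P[i][j] for i in range(ng) for j in range(ng))
    sum_average = sum(k * p_sum[k] for k in range(2 * ng - 1))
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    sum_entropy = h(p_sum)
    entropy = h([P[i][j] for i in range(ng) for j in range(ng)])
    mu_d = sum(k * p_diff[k] for k in range(ng))
    difference_variance = sum((k - mu_d) ** 2 * p_diff[k] for k in range(ng))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * ng - 1))
    difference_entropy = h(p_diff)
    hx = h(px)
    hy = h(py)
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i][j] > 0
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_square": sum_square,
        "sum_average": sum_average,
        "idm": idm,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "sum_variance": sum_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
    }


def brute_cliffs_delta(a, b):
    gt = sum(1 for x in a for y in b if x > y)
    lt = sum(1 for x in a for y in b if x < y)
    return (gt - lt) / (len(a) * len(b))


def exact_mann_whitney_p(a, b):
    """Two-sided exact rank-sum p by enumeration of all label assignments.

    Valid for small untied samples only.
    """
    a, b = list(a), list(b)
    na = len(a)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in a)
    all_ranks = list(range(1, len(pooled) + 1))
    ws = [sum(c) for c in combinations(all_ranks, na)]
    mean_w = na * (len(pooled) + 1) / 2
    extreme = sum(1 for w in ws if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return extreme / len(ws)


def brute_surface_faces(mask):
    """Count exposed voxel faces by scanning all 6 neighbours per voxel."""
    faces = 0
    shape = mask.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for axis in range(3):
            for d in (-1, 1):
                nb = list(idx)
                nb[axis] += d
                nb = tuple(nb)
                if not (0 <= nb[axis] < shape[axis]) or not mask[nb]:
                    faces += 1
    return faces
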