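"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written with plain Python loops and dictionaries, on
purpose: these are slow, transparent reimplementations used only to
check the package's vectorized code paths.
"""

import math

import numpy as np


def otsu_bruteforce(pixels, n_bins=256):
    """Exhaustive between-class-variance maximizer over histogram cuts."""
    flat = [float(v) for v in np.asarray(pixels).ravel()]
    lo, hi = min(flat), max(flat)
    assert hi > lo
    counts, edges = np.histogram(flat, bins=n_bins, range=(lo, hi))
    centers = [(edges[i] + edges[i + 1]) / 2 for i in range(n_bins)]
    total = sum(counts)
    best_var, best_k = -1.0, None
    for k in range(n_bins - 1):  # cut between bin k and k+1
        n0 = sum(counts[: k + 1])
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = sum(c * v for c, v in zip(counts[: k + 1], centers[: k + 1])) / n0
        mu1 = sum(c * v for c, v in zip(counts[k + 1:], centers[k + 1:])) / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return 0.5 * (centers[best_k] + centers[best_k + 1])


def quality_bruteforce(image, objects):
    """One-pass summation version of the background/SNR metrics."""
    in_object = set()
    for obj in objects:
        for r, c in obj.pixel_set:
            in_object.add((int(r), int(c)))
    bg_sum = bg_n = ob_sum = ob_n = 0.0
    rows, cols = image.pixels.shape
    for r in range(rows):
        for c in range(cols):
            v = float(image.pixels[r, c])
            if (r, c) in in_object:
                ob_sum += v
                ob_n += 1
            else:
                bg_sum += v
                bg_n += 1
    bg_av = bg_sum / bg_n
    ss = 0.0
    for r in range(rows):
        for c in range(cols):
            if (r, c) not in in_object:
                ss += (float(image.pixels[r, c]) - bg_av) ** 2
    bg_sd = math.sqrt(ss / bg_n)
    snr = None
    if bg_sd > 0 and ob_n > 0:
        signal = ob_sum / ob_n - bg_av
        if signal > 0:
            snr = 20.0 * math.log10(signal / bg_sd)
    return bg_av, bg_sd, snr


def glcm_stats_bruteforce(obj, image, levels=32, distance=1,
                          offsets=((0, 1), (1, 0), (1, 1), (1, -1))):
    """Ten Haralick statistics by direct pixel-pair enumeration (no GLCM array).

    Counts, per offset, every ordered pair of in-object pixels (both
    directions, for symmetry) in a dictionary, then evaluates each
    statistic from the empirical pair distribution with plain loops.
    """
    pix = {(int(r), int(c)) for r, c in obj.pixel_set}
    vals = {p: float(image.pixels[p]) for p in pix}
    vmin, vmax = min(vals.values()), max(vals.values())

    def level(p):
        if vmax == vmin:
            return 0
        q = int((vals[p] - vmin) / (vmax - vmin) * levels)
        return min(q, levels - 1)

    per_offset = []
    for dr, dc in offsets:
        pairs = {}
        n = 0
        for (r, c) in pix:
            q = (r + dr * distance, c + dc * distance)
            if q in pix:
                a, b = level((r, c)), level(q)
                pairs[(a, b)] = pairs.get((a, b), 0) + 1
                pairs[(b, a)] = pairs.get((b, a), 0) + 1
                n += 2
        if n:
            per_offset.append({k: v / n for k, v in pairs.items()})
    if not per_offset:
        per_offset = [{(0, 0): 1.0}]

    # average the normalized pair distributions over offsets
    P = {}
    for dist in per_offset:
        for k, v in dist.items():
            P[k] = P.get(k, 0.0) + v / len(per_offset)

    px = {}
    for (i, j), p in P.items():
        px[i] = px.get(i, 0.0) + p
    mu = sum(i * w for i, w in px.items())
    var = sum((i - mu) ** 2 * w for i, w in px.items())

    contrast = sum(p * (i - j) ** 2 for (i, j), p in P.items())
    correlation = (
        sum(p * (i - mu) * (j - mu) for (i, j), p in P.items()) / var if var > 0 else 0.0
    )
    energy = sum(p * p for p in P.values())
    entropy = -sum(p * math.log(p) for p in P.values() if p > 0)
    homogeneity = sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items())
    maxprob = max(P.values())
    shade = sum(p * (i + j - 2 * mu) ** 3 for (i, j), p in P.items())
    tendency = sum(p * (i + j - 2 * mu) ** 2 for (i, j), p in P.items())

    hx = -sum(w * math.log(w) for w in px.values() if w > 0)
    hxy1 = -sum(
        p * math.log(px[i] * px[j]) for (i, j), p in P.items() if px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log(px[i] * px[j])
        for i in px
        for j in px
        if px[i] * px[j] > 0
    )
    if hx > 0:
        info1 = (entropy - hxy1) / hx
        info2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    else:
        info1 = info2 = 0.0

    return {
        "Texture contrast": contrast,
        "Texture correlation": correlation,
        "Texture energy": energy,
        "Texture entropy": entropy,
        "Texture homogeneity": homogeneity,
        "Texture maxprob": maxprob,
        "Texture clustershade": shade,
        "Texture clustertendency": tendency,
        "Texture correlation info1": info1,
        "Texture correlation info2": info2,
    }
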