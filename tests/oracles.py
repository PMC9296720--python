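"""Independent brute-force oracles for the texture features.

Everything here is written with explicit Python loops and dictionaries,
deliberately sharing no code (and no vectorisation tricks) with the
implementation under test.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_first_order(levels: list[int]) -> dict[str, float]:
    n = len(levels)
    mu = sum(levels) / n
    m2 = sum((x - mu) ** 2 for x in levels) / n
    if m2 == 0:
        return {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0, "entropy": 0.0}
    m3 = sum((x - mu) ** 3 for x in levels) / n
    m4 = sum((x - mu) ** 4 for x in levels) / n
    sd = math.sqrt(m2)
    ent = 0.0
    for count in Counter(levels).values():
        h = count / n
        ent -= h * math.log2(h)
    return {
        "variance": m2,
        "skewness": m3 / sd**3,
        "kurtosis": m4 / sd**4 - 3.0,
        "entropy": ent,
    }


def brute_glcm(slices, masks, n_g, distance, directions):
    """Symmetric co-occurrence probabilities via per-pixel loops."""
    counts = [[0] * n_g for _ in range(n_g)]
    total = 0
    for lvl, msk in zip(slices, masks):
        h, w = len(lvl), len(lvl[0])
        for r in range(h):
            for c in range(w):
                if not msk[r][c]:
                    continue
                for dr, dc in directions:
                    r2, c2 = r + dr * distance, c + dc * distance
                    if 0 <= r2 < h and 0 <= c2 < w and msk[r2][c2]:
                        i, j = lvl[r][c] - 1, lvl[r2][c2] - 1
                        counts[i][j] += 1
                        counts[j][i] += 1
                        total += 2
    return [[counts[i][j] / total for j in range(n_g)] for i in range(n_g)]


def brute_glcm_features(p) -> dict[str, float]:
    n_g = len(p)
    contrast = energy = homogeneity = 0.0
    mx = my = 0.0
    for i in range(n_g):
        for j in range(n_g):
            contrast += (i - j) ** 2 * p[i][j]
            energy += p[i][j] ** 2
            homogeneity += p[i][j] / (1 + abs(i - j))
            mx += (i + 1) * p[i][j]
            my += (j + 1) * p[i][j]
    vx = vy = cov = 0.0
    for i in range(n_g):
        for j in range(n_g):
            vx += (i + 1 - mx) ** 2 * p[i][j]
            vy += (j + 1 - my) ** 2 * p[i][j]
            cov += (i + 1 - mx) * (j + 1 - my) * p[i][j]
    sxsy = math.sqrt(vx) * math.sqrt(vy)
    correlation = 1.0 if sxsy == 0 else cov / sxsy
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def _lines(h, w, step):
    """All maximal pixel paths through an h x w grid along `step`."""
    sr, sc = step
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - sr, c - sc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    out = []
    for r, c in starts:
        line = []
        while 0 <= r < h and 0 <= c < w:
            line.append((r, c))
            r, c = r + sr, c + sc
        out.append(line)
    return out


def brute_glrlm(slices, masks, directions):
    """Run counts via explicit line walking; returns (p_dict, n_r, n_p)."""
    runs: Counter = Counter()
    n_masked = 0
    for lvl, msk in zip(slices, masks):
        h, w = len(lvl), len(lvl[0])
        n_masked += sum(1 for r in range(h) for c in range(w) if msk[r][c])
        for d in directions:
            sr, sc = d
            if sr < 0 or (sr == 0 and sc < 0):
                sr, sc = -sr, -sc
            for line in _lines(h, w, (sr, sc)):
                current = None
                length = 0
                for r, c in line:
                    if msk[r][c] and lvl[r][c] == current:
                        length += 1
                    else:
                        if current is not None and length:
                            runs[(current, length)] += 1
                        current, length = (lvl[r][c], 1) if msk[r][c] else (None, 0)
                if current is not None and length:
                    runs[(current, length)] += 1
    n_r = sum(runs.values())
    n_p = n_masked * len(directions)
    return dict(runs), n_r, n_p


def brute_glrlm_features(runs: dict, n_r: int, n_p: int) -> dict[str, float]:
    out = {k: 0.0 for k in
           ("SRE", "LRE", "GLN", "RLN", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE")}
    by_level: Counter = Counter()
    by_length: Counter = Counter()
    for (i, j), n in runs.items():
        by_level[i] += n
        by_length[j] += n
        out["SRE"] += n / j**2
        out["LRE"] += n * j**2
        out["LGRE"] += n / i**2
        out["HGRE"] += n * i**2
        out["SRLGE"] += n / (i**2 * j**2)
        out["SRHGE"] += n * i**2 / j**2
        out["LRLGE"] += n * j**2 / i**2
        out["LRHGE"] += n * i**2 * j**2
    out["GLN"] = sum(v**2 for v in by_level.values())
    out["RLN"] = sum(v**2 for v in by_length.values())
    result = {k: v / n_r for k, v in out.items()}
    result["RP"] = n_r / n_p
    return result


def brute_all_19(slices, masks, n_g, distance, directions) -> dict[str, float]:
    """All 19 features from already-quantised levels, loops only."""
    pooled = [
        lvl[r][c]
        for lvl, msk in zip(slices, masks)
        for r in range(len(lvl))
        for c in range(len(lvl[0]))
        if msk[r][c]
    ]
    out = brute_first_order(pooled)
    out.update(brute_glcm_features(brute_glcm(slices, masks, n_g, distance, directions)))
    out.update(brute_glrlm_features(*brute_glrlm(slices, masks, directions)))
    return out
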