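"""Independent brute-force oracles for the texture features.

Everything here is written as direct enumeration with explicit Python
loops — voxel-pair enumeration for co-occurrence, line walking for runs,
flood fill for zones, per-voxel neighbour counting for dependence and
gray-tone difference — and scalar textbook formulas for the features.
No code is shared with the package implementation beyond the documented
conventions (13 directions, 26-connectivity, degenerate-case values).
"""

from __future__ import annotations

import math

import numpy as np

DIRS_13 = [(dx, dy, dz)
           for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
           if (dx, dy, dz) > (0, 0, 0)]
NEIGH_26 = [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def _voxels(mask):
    return [tuple(v) for v in np.argwhere(mask)]


def _entropy2(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


# ------------------------------------------------------------------ GLCM

def oracle_glcm_features(levels, mask):
    """24 GLCM features, averaged over directions, by pair enumeration."""
    ng = int(levels[mask].max())
    shape = levels.shape
    per_dir = []
    for d in DIRS_13:
        pairs = {}
        n_pairs = 0
        for v in _voxels(mask):
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, w) and mask[w]:
                a, b = int(levels[v]), int(levels[w])
                for key in ((a, b), (b, a)):  # symmetric matrix
                    pairs[key] = pairs.get(key, 0) + 1
                n_pairs += 2
        if n_pairs == 0:
            continue
        p = {k: c / n_pairs for k, c in pairs.items()}
        per_dir.append(_glcm_single(p, ng))
    out = {}
    for key in per_dir[0]:
        out[key] = sum(f[key] for f in per_dir) / len(per_dir)
    return out


def _glcm_single(p, ng):
    px = [0.0] * (ng + 1)
    py = [0.0] * (ng + 1)
    for (i, j), w in p.items():
        px[i] += w
        py[j] += w
    mu_x = sum(i * px[i] for i in range(1, ng + 1))
    mu_y = sum(j * py[j] for j in range(1, ng + 1))
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(1, ng + 1)))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(1, ng + 1)))

    p_sum = {}
    p_diff = {}
    for (i, j), w in p.items():
        p_sum[i + j] = p_sum.get(i + j, 0.0) + w
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + w

    f = {}
    f["Autocorrelation"] = sum(i * j * w for (i, j), w in p.items())
    f["ClusterProminence"] = sum((i + j - mu_x - mu_y) ** 4 * w
                                 for (i, j), w in p.items())
    f["ClusterShade"] = sum((i + j - mu_x - mu_y) ** 3 * w
                            for (i, j), w in p.items())
    f["ClusterTendency"] = sum((i + j - mu_x - mu_y) ** 2 * w
                               for (i, j), w in p.items())
    f["Contrast"] = sum((i - j) ** 2 * w for (i, j), w in p.items())
    f["Correlation"] = ((f["Autocorrelation"] - mu_x * mu_y)
                        / (sig_x * sig_y)) if sig_x * sig_y > 0 else 1.0
    da = sum(k * w for k, w in p_diff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _entropy2(p_diff.values())
    f["DifferenceVariance"] = sum((k - da) ** 2 * w
                                  for k, w in p_diff.items())
    f["Id"] = sum(w / (1 + abs(i - j)) for (i, j), w in p.items())
    f["Idm"] = sum(w / (1 + (i - j) ** 2) for (i, j), w in p.items())
    f["Idmn"] = sum(w / (1 + ((i - j) / ng) ** 2) for (i, j), w in p.items())
    f["Idn"] = sum(w / (1 + abs(i - j) / ng) for (i, j), w in p.items())

    hx = _entropy2(px)
    hy = _entropy2(py)
    hxy = _entropy2(p.values())
    hxy1 = -sum(w * math.log2(px[i] * py[j]) for (i, j), w in p.items())
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(1, ng + 1) for j in range(1, ng + 1)
                if px[i] * py[j] > 0)
    denom = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["InverseVariance"] = sum(w / (i - j) ** 2
                               for (i, j), w in p.items() if i != j)
    f["JointAverage"] = sum(i * w for (i, j), w in p.items())
    f["JointEnergy"] = sum(w ** 2 for w in p.values())
    f["JointEntropy"] = hxy
    f["MaximumProbability"] = max(p.values())
    f["MCC"] = _oracle_mcc(p, px, py, ng)
    f["SumAverage"] = sum(k * w for k, w in p_sum.items())
    f["SumEntropy"] = _entropy2(p_sum.values())
    f["SumSquares"] = sum((i - mu_x) ** 2 * w for (i, j), w in p.items())
    return f


def _oracle_mcc(p, px, py, ng):
    occ = [i for i in range(1, ng + 1) if px[i] > 0]
    if len(occ) <= 1:
        return 1.0
    n = len(occ)
    q = np.zeros((n, n))
    for a, ia in enumerate(occ):
        for b, ib in enumerate(occ):
            total = 0.0
            for k in occ:
                pik = p.get((ia, k), 0.0)
                pjk = p.get((ib, k), 0.0)
                if pik and pjk:
                    total += pik * pjk / (px[ia] * py[k])
            q[a, b] = total
    ev = sorted(np.real(np.linalg.eigvals(q)))
    return math.sqrt(max(0.0, ev[-2]))


# ----------------------------------------------------------------- GLRLM

def oracle_glrlm_counts(levels, mask, d):
    """Run counts {(level, length): count} along one direction by walking."""
    shape = levels.shape
    counts = {}
    for v in _voxels(mask):
        prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
        if (_inside(shape, prev) and mask[prev]
                and levels[prev] == levels[v]):
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            if (_inside(shape, nxt) and mask[nxt]
                    and levels[nxt] == levels[cur]):
                length += 1
                cur = nxt
            else:
                break
        key = (int(levels[v]), length)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _rlm_features(counts, n_voxels, prefix_map):
    total = sum(counts.values())
    per_level = {}
    per_size = {}
    for (i, s), c in counts.items():
        per_level[i] = per_level.get(i, 0) + c
        per_size[s] = per_size.get(s, 0) + c
    mu_i = sum(i * c for (i, s), c in counts.items()) / total
    mu_s = sum(s * c for (i, s), c in counts.items()) / total
    f = {}
    f[prefix_map["small"]] = sum(c / s ** 2 for (i, s), c in counts.items()) / total
    f[prefix_map["large"]] = sum(c * s ** 2 for (i, s), c in counts.items()) / total
    f[prefix_map["gln"]] = sum(v ** 2 for v in per_level.values()) / total
    f[prefix_map["glnn"]] = sum(v ** 2 for v in per_level.values()) / total ** 2
    f[prefix_map["sn"]] = sum(v ** 2 for v in per_size.values()) / total
    f[prefix_map["snn"]] = sum(v ** 2 for v in per_size.values()) / total ** 2
    f[prefix_map["pct"]] = total / n_voxels
    f[prefix_map["glv"]] = sum((i - mu_i) ** 2 * c
                               for (i, s), c in counts.items()) / total
    f[prefix_map["sv"]] = sum((s - mu_s) ** 2 * c
                              for (i, s), c in counts.items()) / total
    f[prefix_map["ent"]] = _entropy2(c / total for c in counts.values())
    f[prefix_map["lgl"]] = sum(c / i ** 2 for (i, s), c in counts.items()) / total
    f[prefix_map["hgl"]] = sum(c * i ** 2 for (i, s), c in counts.items()) / total
    f[prefix_map["slgl"]] = sum(c / (i ** 2 * s ** 2)
                                for (i, s), c in counts.items()) / total
    f[prefix_map["shgl"]] = sum(c * i ** 2 / s ** 2
                                for (i, s), c in counts.items()) / total
    f[prefix_map["llgl"]] = sum(c * s ** 2 / i ** 2
                                for (i, s), c in counts.items()) / total
    f[prefix_map["lhgl"]] = sum(c * i ** 2 * s ** 2
                                for (i, s), c in counts.items()) / total
    return f


GLRLM_MAP = {
    "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity", "snn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage", "glv": "GrayLevelVariance", "sv": "RunVariance",
    "ent": "RunEntropy", "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis",
    "slgl": "ShortRunLowGrayLevelEmphasis",
    "shgl": "ShortRunHighGrayLevelEmphasis",
    "llgl": "LongRunLowGrayLevelEmphasis",
    "lhgl": "LongRunHighGrayLevelEmphasis",
}

GLSZM_MAP = {
    "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity", "snn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage", "glv": "GrayLevelVariance", "sv": "ZoneVariance",
    "ent": "ZoneEntropy", "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis",
    "slgl": "SmallAreaLowGrayLevelEmphasis",
    "shgl": "SmallAreaHighGrayLevelEmphasis",
    "llgl": "LargeAreaLowGrayLevelEmphasis",
    "lhgl": "LargeAreaHighGrayLevelEmphasis",
}

GLDM_MAP = {
    "small": "SmallDependenceEmphasis", "large": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": None,
    "sn": "DependenceNonUniformity",
    "snn": "DependenceNonUniformityNormalized",
    "pct": None, "glv": "GrayLevelVariance", "sv": "DependenceVariance",
    "ent": "DependenceEntropy", "lgl": "LowGrayLevelEmphasis",
    "hgl": "HighGrayLevelEmphasis",
    "slgl": "SmallDependenceLowGrayLevelEmphasis",
    "shgl": "SmallDependenceHighGrayLevelEmphasis",
    "llgl": "LargeDependenceLowGrayLevelEmphasis",
    "lhgl": "LargeDependenceHighGrayLevelEmphasis",
}


def oracle_glrlm_features(levels, mask):
    n_vox = int(mask.sum())
    per_dir = []
    for d in DIRS_13:
        counts = oracle_glrlm_counts(levels, mask, d)
        per_dir.append(_rlm_features(counts, n_vox, GLRLM_MAP))
    return {k: sum(f[k] for f in per_dir) / len(per_dir)
            for k in per_dir[0]}


# ----------------------------------------------------------------- GLSZM

def oracle_glszm_counts(levels, mask):
    """Zone counts {(level, size): count} via explicit flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    counts = {}
    for v in _voxels(mask):
        if seen[v]:
            continue
        level = int(levels[v])
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGH_26:
                w = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if (_inside(shape, w) and mask[w] and not seen[w]
                        and int(levels[w]) == level):
                    seen[w] = True
                    stack.append(w)
        key = (level, size)
        counts[key] = counts.get(key, 0) + 1
    return counts


def oracle_glszm_features(levels, mask):
    counts = oracle_glszm_counts(levels, mask)
    return _rlm_features(counts, int(mask.sum()), GLSZM_MAP)


# ------------------------------------------------------------------ GLDM

def oracle_gldm_features(levels, mask, alpha=0):
    shape = levels.shape
    counts = {}
    for v in _voxels(mask):
        dep = 1
        for d in NEIGH_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (_inside(shape, w) and mask[w]
                    and abs(int(levels[w]) - int(levels[v])) <= alpha):
                dep += 1
        key = (int(levels[v]), dep)
        counts[key] = counts.get(key, 0) + 1
    feats = _rlm_features(counts, int(mask.sum()), GLDM_MAP)
    return {k: v for k, v in feats.items() if k is not None}


# ----------------------------------------------------------------- NGTDM

def oracle_ngtdm_features(levels, mask):
    shape = levels.shape
    ng = int(levels[mask].max())
    n_i = [0.0] * (ng + 1)
    s_i = [0.0] * (ng + 1)
    n_valid = 0
    for v in _voxels(mask):
        nb = []
        for d in NEIGH_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, w) and mask[w]:
                nb.append(int(levels[w]))
        if not nb:
            continue
        n_valid += 1
        i = int(levels[v])
        n_i[i] += 1
        s_i[i] += abs(i - sum(nb) / len(nb))
    if n_valid == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p_i = [n / n_valid for n in n_i]
    present = [i for i in range(1, ng + 1) if p_i[i] > 0]
    ngp = len(present)

    f = {}
    denom = sum(p_i[i] * s_i[i] for i in present)
    f["Coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        f["Contrast"] = (sum(p_i[a] * p_i[b] * (a - b) ** 2
                             for a in present for b in present)
                         / (ngp * (ngp - 1))
                         * sum(s_i[i] for i in present) / n_valid)
        bus_den = sum(abs(a * p_i[a] - b * p_i[b])
                      for a in present for b in present)
        f["Busyness"] = denom / bus_den if bus_den > 0 else 0.0
        f["Complexity"] = sum(
            abs(a - b) * (p_i[a] * s_i[a] + p_i[b] * s_i[b])
            / (p_i[a] + p_i[b])
            for a in present for b in present) / n_valid
        s_sum = sum(s_i[i] for i in present)
        f["Strength"] = (sum((p_i[a] + p_i[b]) * (a - b) ** 2
                             for a in present for b in present) / s_sum
                         if s_sum > 0 else 0.0)
    else:
        f["Contrast"] = f["Busyness"] = f["Complexity"] = f["Strength"] = 0.0
    return f


def oracle_all_texture(levels, mask, alpha=0):
    """All 75 texture features keyed ``<family>_<name>``."""
    out = {}
    for fam, feats in (
            ("glcm", oracle_glcm_features(levels, mask)),
            ("glrlm", oracle_glrlm_features(levels, mask)),
            ("glszm", oracle_glszm_features(levels, mask)),
            ("gldm", oracle_gldm_features(levels, mask, alpha)),
            ("ngtdm", oracle_ngtdm_features(levels, mask))):
        for k, v in feats.items():
            out[f"{fam}_{k}"] = v
    return out
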