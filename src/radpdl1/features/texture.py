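"""Texture feature formulas over the five matrix families (75 features).

Per filtered image: 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM.
GLCM and GLRLM features are computed per distance-1 direction and averaged
over the 13 unique 3D directions; GLSZM/GLDM/NGTDM use 26-connected
neighbourhoods and need no direction averaging.  All formulas operate on
the sparse (occupied-cell) matrix representation, so cost scales with the
voxel count, not with the square of the gray-level count.

Degenerate conventions (all documented, all finite):
- single-level GLCM: Correlation = 1, Imc1 = 0, Imc2 = 0, MCC = 1;
- InverseVariance sums only off-diagonal cells;
- NGTDM Coarseness returns 1e6 when its denominator vanishes (flat ROI);
  Busyness and Strength return 0 on a vanishing denominator;
- entropies use log2 with zero cells skipped;
- Idmn/Idn normalize the level difference by Ng = the number of
  discretization levels (the maximum level index).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import ArpackNoConvergence, LinearOperator, eigs

from . import matrices as mx
from .discretize import DiscretizedROI
from .matrices import SparseCounts, SparseGLCM

_COARSENESS_MAX = 1e6
_MCC_DENSE_LIMIT = 64


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------- GLCM

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
)


def _glcm_features_single(sp: SparseGLCM) -> dict[str, float]:
    ng = sp.ng
    w = sp.p
    iv = sp.i + 1.0  # level values
    jv = sp.j + 1.0
    levels = np.arange(1, ng + 1, dtype=np.float64)

    px = np.bincount(sp.i, weights=w, minlength=ng)
    py = np.bincount(sp.j, weights=w, minlength=ng)
    mu_x = float((levels * px).sum())
    mu_y = float((levels * py).sum())
    sig_x = float(np.sqrt(((levels - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((levels - mu_y) ** 2 * py).sum()))

    p_sum = np.bincount(sp.i + sp.j, weights=w, minlength=2 * ng - 1)
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_diff = np.bincount(np.abs(sp.i - sp.j), weights=w, minlength=ng)
    kdiff = np.arange(0, ng, dtype=np.float64)

    f: dict[str, float] = {}
    f["Autocorrelation"] = float((iv * jv * w).sum())
    cdev = iv + jv - mu_x - mu_y
    f["ClusterProminence"] = float((cdev ** 4 * w).sum())
    f["ClusterShade"] = float((cdev ** 3 * w).sum())
    f["ClusterTendency"] = float((cdev ** 2 * w).sum())
    adiff = np.abs(iv - jv)
    f["Contrast"] = float((adiff ** 2 * w).sum())
    if sig_x * sig_y > 0:
        f["Correlation"] = (f["Autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y)
    else:
        f["Correlation"] = 1.0
    da = float((kdiff * p_diff).sum())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _entropy(p_diff)
    f["DifferenceVariance"] = float(((kdiff - da) ** 2 * p_diff).sum())
    f["Id"] = float((w / (1.0 + adiff)).sum())
    f["Idm"] = float((w / (1.0 + adiff ** 2)).sum())
    f["Idmn"] = float((w / (1.0 + (adiff / ng) ** 2)).sum())
    f["Idn"] = float((w / (1.0 + adiff / ng)).sum())

    hx = _entropy(px)
    hy = _entropy(py)
    hxy = _entropy(w)
    hxy1 = float(-(w * np.log2(px[sp.i] * py[sp.j])).sum())
    hxy2 = hx + hy  # -sum px py log2(px py) factorizes exactly
    denom = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = adiff > 0
    f["InverseVariance"] = float((w[off] / adiff[off] ** 2).sum())
    f["JointAverage"] = mu_x
    f["JointEnergy"] = float((w ** 2).sum())
    f["JointEntropy"] = hxy
    f["MaximumProbability"] = float(w.max())
    f["MCC"] = _mcc(sp, px, py)
    f["SumAverage"] = float((ksum * p_sum).sum())
    f["SumEntropy"] = _entropy(p_sum)
    f["SumSquares"] = float(((iv - mu_x) ** 2 * w).sum())
    return f


def _mcc(sp: SparseGLCM, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest
    eigenvalue (by real part) of Q(a,b) = sum_k p(a,k) p(b,k) / (px(a) py(k)).

    Q is row-stochastic on occupied rows, so the leading eigenvalue is 1.
    Occupied levels are compacted first; small problems use dense
    eigendecomposition, large ones a matrix-free Arnoldi solve.
    """
    occ = np.flatnonzero(px > 0)
    n = occ.size
    if n <= 1:
        return 1.0
    rank = np.full(sp.ng, -1, dtype=np.int64)
    rank[occ] = np.arange(n)
    ri = rank[sp.i]
    rj = rank[sp.j]
    a_vals = sp.p / px[sp.i]            # A = p / px rows
    b_vals = sp.p / py[sp.j]            # B = p / py cols
    if n <= _MCC_DENSE_LIMIT:
        A = np.zeros((n, n))
        B = np.zeros((n, n))
        A[ri, rj] = a_vals
        B[ri, rj] = b_vals
        ev = np.sort(np.real(np.linalg.eigvals(A @ B.T)))
        return float(np.sqrt(max(0.0, ev[-2])))
    A = csr_matrix((a_vals, (ri, rj)), shape=(n, n))
    B = csr_matrix((b_vals, (ri, rj)), shape=(n, n))
    op = LinearOperator((n, n), matvec=lambda x: A @ (B.T @ x),
                        dtype=np.float64)
    v0 = np.full(n, 1.0 / np.sqrt(n))
    try:
        vals = eigs(op, k=2, which="LR", v0=v0,
                    return_eigenvectors=False, maxiter=5000)
    except ArpackNoConvergence as err:
        vals = err.eigenvalues
        if vals is None or vals.size < 2:
            return float("nan")
    ev = np.sort(np.real(vals))
    return float(np.sqrt(max(0.0, ev[-2])))


def glcm_features(droi: DiscretizedROI) -> dict[str, float]:
    mats = mx.glcm_per_direction(droi)
    if not mats:
        # pathological single-voxel ROI: the trivial one-cell matrix
        mats = [SparseGLCM(np.array([0]), np.array([0]), np.array([1.0]), 1)]
    acc = {n: 0.0 for n in GLCM_NAMES}
    for sp in mats:
        f = _glcm_features_single(sp)
        for n in GLCM_NAMES:
            acc[n] += f[n]
    return {n: acc[n] / len(mats) for n in GLCM_NAMES}


# ------------------------------------------------- GLRLM / GLSZM shared

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

_GLRLM_KEYMAP = {
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

_GLSZM_KEYMAP = {
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

GLSZM_NAMES = tuple(_GLSZM_KEYMAP[k] for k in _GLRLM_KEYMAP)


def _rlm_style_features(sc: SparseCounts,
                        names: dict[str, str]) -> dict[str, float]:
    """Shared formulas for run-length / size-zone style count matrices."""
    total = sc.total
    c = sc.count
    iv = sc.level + 1.0
    sv = sc.size.astype(np.float64)
    p = c / total
    per_level = np.bincount(sc.level, weights=c, minlength=sc.ng)
    per_size = np.bincount(sc.size, weights=c)
    mu_i = float((iv * p).sum())
    mu_s = float((sv * p).sum())
    f = {}
    f[names["small"]] = float((c / sv ** 2).sum() / total)
    f[names["large"]] = float((c * sv ** 2).sum() / total)
    f[names["gln"]] = float((per_level ** 2).sum() / total)
    f[names["glnn"]] = float((per_level ** 2).sum() / total ** 2)
    f[names["sn"]] = float((per_size ** 2).sum() / total)
    f[names["snn"]] = float((per_size ** 2).sum() / total ** 2)
    f[names["pct"]] = float(total / sc.n_voxels)
    f[names["glv"]] = float(((iv - mu_i) ** 2 * p).sum())
    f[names["sv"]] = float(((sv - mu_s) ** 2 * p).sum())
    f[names["ent"]] = _entropy(p)
    f[names["lgl"]] = float((c / iv ** 2).sum() / total)
    f[names["hgl"]] = float((c * iv ** 2).sum() / total)
    f[names["slgl"]] = float((c / (iv ** 2 * sv ** 2)).sum() / total)
    f[names["shgl"]] = float((c * iv ** 2 / sv ** 2).sum() / total)
    f[names["llgl"]] = float((c * sv ** 2 / iv ** 2).sum() / total)
    f[names["lhgl"]] = float((c * iv ** 2 * sv ** 2).sum() / total)
    return f


def glrlm_features(droi: DiscretizedROI) -> dict[str, float]:
    mats = mx.glrlm_per_direction(droi)
    acc = {n: 0.0 for n in GLRLM_NAMES}
    for sc in mats:
        f = _rlm_style_features(sc, _GLRLM_KEYMAP)
        for n in GLRLM_NAMES:
            acc[n] += f[n]
    return {n: acc[n] / len(mats) for n in GLRLM_NAMES}


def glszm_features(droi: DiscretizedROI) -> dict[str, float]:
    return _rlm_style_features(mx.glszm(droi), _GLSZM_KEYMAP)


# ---------------------------------------------------------------- GLDM

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_GLDM_KEYMAP = {
    "small": "SmallDependenceEmphasis", "large": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "_drop_glnn",
    "sn": "DependenceNonUniformity",
    "snn": "DependenceNonUniformityNormalized",
    "pct": "_drop_pct", "glv": "GrayLevelVariance",
    "sv": "DependenceVariance", "ent": "DependenceEntropy",
    "lgl": "LowGrayLevelEmphasis", "hgl": "HighGrayLevelEmphasis",
    "slgl": "SmallDependenceLowGrayLevelEmphasis",
    "shgl": "SmallDependenceHighGrayLevelEmphasis",
    "llgl": "LargeDependenceLowGrayLevelEmphasis",
    "lhgl": "LargeDependenceHighGrayLevelEmphasis",
}


def gldm_features(droi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    f = _rlm_style_features(mx.gldm(droi, alpha=alpha), _GLDM_KEYMAP)
    return {k: v for k, v in f.items() if not k.startswith("_drop")}


# ---------------------------------------------------------------- NGTDM

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def ngtdm_features(droi: DiscretizedROI) -> dict[str, float]:
    n_i, s_i, n_valid = mx.ngtdm(droi)
    if n_valid == 0:
        return {"Coarseness": _COARSENESS_MAX, "Contrast": 0.0,
                "Busyness": 0.0, "Complexity": 0.0, "Strength": 0.0}
    present = np.flatnonzero(n_i > 0)
    iv = present + 1.0
    p = n_i[present] / n_valid
    s = s_i[present]
    ngp = present.size

    f: dict[str, float] = {}
    denom = float((p * s).sum())
    f["Coarseness"] = 1.0 / denom if denom > 0 else _COARSENESS_MAX

    if ngp > 1:
        dij2 = (iv[:, None] - iv[None, :]) ** 2
        f["Contrast"] = (float((np.outer(p, p) * dij2).sum())
                         / (ngp * (ngp - 1)) * float(s.sum()) / n_valid)
        ipi = iv * p
        bus_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        f["Busyness"] = denom / bus_den if bus_den > 0 else 0.0
        ps = p * s
        adiff = np.abs(iv[:, None] - iv[None, :])
        f["Complexity"] = float(
            (adiff * (ps[:, None] + ps[None, :])
             / (p[:, None] + p[None, :])).sum()) / n_valid
        s_sum = float(s.sum())
        f["Strength"] = (float(((p[:, None] + p[None, :]) * dij2).sum())
                         / s_sum) if s_sum > 0 else 0.0
    else:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
        f["Complexity"] = 0.0
        f["Strength"] = 0.0
    return f


# ---------------------------------------------------------------- union

def texture_features(droi: DiscretizedROI) -> dict[str, float]:
    """All 75 texture features, keyed ``<family>_<FeatureName>``."""
    out: dict[str, float] = {}
    for fam, fn in (("glcm", glcm_features), ("glrlm", glrlm_features),
                    ("glszm", glszm_features), ("gldm", gldm_features),
                    ("ngtdm", ngtdm_features)):
        for name, val in fn(droi).items():
            out[f"{fam}_{name}"] = float(val)
    assert len(out) == 75
    return out
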