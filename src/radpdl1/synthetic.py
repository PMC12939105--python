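"""Synthetic lesion phantoms and cohorts with the statistical structure the
pipeline assumes.

No patient imaging is distributed with the package, so every stage is
exercised on phantoms: ellipsoidal lesions whose interior carries a
Gaussian-smoothed noise texture of controllable amplitude (``heterogeneity``,
in HU).  The latent heterogeneity drives the binary PD-L1-like label through
a logistic link, so textured lesions are systematically more likely to be
class 1 — the association the downstream attribution analysis should
rediscover.  Censored survival times hazard-depend on the label.

Covariate margins loosely mirror an advanced-NSCLC cohort (about half male,
~29% current smokers, ~14% ECOG >= 2); they are cosmetic, not calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit

from .types import LesionVolume

BACKGROUND_HU = -900.0  # air-like lung background


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one ellipsoidal lesion phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radii_mm: tuple[float, float, float] = (12.0, 10.0, 8.0)
    base_hu: float = -100.0
    heterogeneity: float = 30.0
    correlation_len_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        for r, n, s in zip(self.radii_mm, self.grid_shape, self.spacing_mm):
            if r <= 0:
                raise ValueError("radii must be positive")
            if 2 * r >= n * s:
                raise ValueError(
                    f"ellipsoid radius {r} mm does not fit a "
                    f"{n}-voxel axis at {s} mm spacing"
                )


def make_phantom(spec: PhantomSpec) -> LesionVolume:
    """Generate one textured ellipsoid lesion; deterministic given the seed.

    Interior = base_hu + heterogeneity * (smoothed, unit-variance noise);
    exterior is air-like background.  The smoothing length controls the
    spatial scale of the texture.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    centers = [(n - 1) / 2.0 * s for n, s in zip(shape, spec.spacing_mm)]
    grids = np.meshgrid(*[np.arange(n) * s for n, s in
                          zip(shape, spec.spacing_mm)], indexing="ij")
    ellip = sum(((g - c) / r) ** 2 for g, c, r in
                zip(grids, centers, spec.radii_mm))
    mask = ellip <= 1.0

    intens = np.full(shape, BACKGROUND_HU, dtype=np.float64)
    intens[mask] = spec.base_hu
    if spec.heterogeneity > 0:
        noise = rng.standard_normal(shape)
        sigma_vox = [spec.correlation_len_mm / s for s in spec.spacing_mm]
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        smooth /= smooth.std()  # unit variance over the grid
        intens[mask] += spec.heterogeneity * smooth[mask]
    return LesionVolume(intens, spec.spacing_mm, mask,
                        patient_id=f"phantom-{spec.seed}")


# ------------------------------------------------------------------ cohort

COVARIATE_COLUMNS = ("age", "sex_male", "current_smoker", "ecog_ge2",
                     "site", "stage_iv")


@dataclass
class SyntheticCohort:
    """Phantom volumes plus the per-patient clinical table.

    ``table`` columns: patient_id, label (NaN for unlabeled), is_labeled,
    heterogeneity, time_months, event, and the covariate columns.
    """

    volumes: list[LesionVolume]
    table: pd.DataFrame
    seed: int = 0

    def __post_init__(self) -> None:
        ids = self.table["patient_id"]
        if ids.duplicated().any():
            raise ValueError("patient IDs must be unique")
        if (self.table["time_months"] <= 0).any():
            raise ValueError("survival times must be positive")

    @property
    def labeled(self) -> pd.DataFrame:
        return self.table[self.table["is_labeled"]]

    @property
    def unlabeled(self) -> pd.DataFrame:
        return self.table[~self.table["is_labeled"]]


def _calibrated_intercept(z: np.ndarray, slope: float,
                          prevalence: float) -> float:
    """Intercept c so that mean(sigmoid(slope*z + c)) matches prevalence."""
    def gap(c: float) -> float:
        return float(expit(slope * z + c).mean() - prevalence)
    return optimize.brentq(gap, -50.0, 50.0)


def make_cohort(n_labeled: int = 120, n_unlabeled: int = 60,
                prevalence: float = 0.5, label_effect: float = 2.0,
                seed: int = 0, grid_shape: tuple[int, int, int] = (48, 48, 48),
                hazard_ratio: float = 0.39,
                censor_fraction: float = 0.3,
                make_volumes: bool = True) -> SyntheticCohort:
    """Generate a labeled + unlabeled phantom cohort.

    Heterogeneity varies across lesions; the label is Bernoulli with a
    logistic link of slope ``label_effect`` in the standardized
    heterogeneity, intercept calibrated to the requested prevalence.
    Survival hazard depends on the (latent) label via ``hazard_ratio``.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if n_labeled < 4:
        raise ValueError("need at least 4 labeled patients to split")
    rng = np.random.default_rng(seed)
    n = n_labeled + n_unlabeled

    het = rng.gamma(shape=4.0, scale=10.0, size=n)  # mean 40 HU, sd 20
    z = (het - het.mean()) / het.std()
    if label_effect != 0:
        c = _calibrated_intercept(z, label_effect, prevalence)
    else:
        c = float(np.log(prevalence / (1 - prevalence)))
    labels = (rng.random(n) < expit(label_effect * z + c)).astype(int)

    radii = rng.uniform(7.0, 13.0, size=(n, 3))
    phantom_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    volumes = []
    patient_ids = [f"P{i:04d}" for i in range(n)]
    if make_volumes:
        for i in range(n):
            spec = PhantomSpec(
                grid_shape=grid_shape,
                radii_mm=tuple(radii[i]),
                base_hu=-100.0,
                heterogeneity=float(het[i]),
                correlation_len_mm=2.0,
                seed=int(phantom_seeds[i]),
            )
            vol = make_phantom(spec)
            vol.patient_id = patient_ids[i]
            volumes.append(vol)

    time_months, event = make_survival(
        labels, hazard_ratio=hazard_ratio, censor_fraction=censor_fraction,
        seed=int(rng.integers(0, 2 ** 31 - 1)))

    is_labeled = np.zeros(n, dtype=bool)
    is_labeled[:n_labeled] = True
    table = pd.DataFrame({
        "patient_id": patient_ids,
        "label": np.where(is_labeled, labels.astype(float), np.nan),
        "true_label": labels,
        "is_labeled": is_labeled,
        "heterogeneity": het,
        "time_months": time_months,
        "event": event,
        "age": np.clip(rng.normal(66, 7, n), 35, 90).round(0),
        "sex_male": (rng.random(n) < 0.51).astype(int),
        "current_smoker": (rng.random(n) < 0.29).astype(int),
        "ecog_ge2": (rng.random(n) < 0.14).astype(int),
        "site": rng.integers(1, 4, n),
        "stage_iv": (rng.random(n) < 0.5).astype(int),
    })
    return SyntheticCohort(volumes, table, seed)


# ------------------------------------------------------------------ tabular

@dataclass
class TabularCohort:
    """Fast test double for the radiomics table."""

    X: np.ndarray
    y: np.ndarray
    beta_true: np.ndarray
    seed: int = 0


def make_tabular(n: int, p: int, k_informative: int, effect_size: float,
                 seed: int = 0, rho: float = 0.2) -> TabularCohort:
    """Correlated Gaussian features with a sparse logistic signal.

    X has exchangeable correlation ``rho``; the first ``k_informative``
    coefficients have magnitude ``effect_size`` with alternating signs and
    y ~ Bernoulli(sigmoid(X beta)).
    """
    if k_informative > p:
        raise ValueError("k_informative must be <= p")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n, 1))
    X = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:k_informative] = effect_size * np.where(
        np.arange(k_informative) % 2 == 0, 1.0, -1.0)
    y = (rng.random(n) < expit(X @ beta)).astype(int)
    return TabularCohort(X, y, beta, seed)


def make_semisup_benchmark(n_labeled: int = 60, n_unlabeled: int = 600,
                           n_test: int = 400, n_features: int = 20,
                           separation: float = 2.5, seed: int = 0):
    """Cluster-structured semi-supervised benchmark.

    Two Gaussian clusters (class-conditional, separation = distance between
    means in feature space); only a small labeled subset is revealed, so a
    supervised fit sees a noisy boundary that the unlabeled pool can refine.

    Returns ``(X_lab, y_lab, X_unlab, y_unlab_true, X_test, y_test)``.
    """
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(n_features)
    direction /= np.linalg.norm(direction)
    offset = separation / 2.0 * direction

    def draw(m: int):
        y = (rng.random(m) < 0.5).astype(int)
        X = rng.standard_normal((m, n_features)) + np.where(
            y[:, None] == 1, offset, -offset)
        return X, y

    X_lab, y_lab = draw(n_labeled)
    X_unlab, y_unlab = draw(n_unlabeled)
    X_test, y_test = draw(n_test)
    return X_lab, y_lab, X_unlab, y_unlab, X_test, y_test


# ------------------------------------------------------------------ survival

def make_survival(labels: np.ndarray, hazard_ratio: float = 0.39,
                  censor_fraction: float = 0.3, seed: int = 0,
                  baseline_median_months: float = 4.0):
    """Exponential event times with hazard lambda0 * hazard_ratio**label.

    Censoring is independent Uniform(0, u) with u tuned analytically so the
    expected censored fraction matches the request.  Returns
    ``(time_months, event)`` with event = 1 for observed progression.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_fraction < 1:
        raise ValueError("censor_fraction must be in [0, 1)")
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    lam0 = np.log(2.0) / baseline_median_months
    lam = lam0 * hazard_ratio ** labels
    t_event = rng.exponential(1.0 / lam)

    if censor_fraction == 0:
        return t_event, np.ones_like(labels)

    def expected_censored(u: float) -> float:
        # P(C < T) for C ~ U(0, u), T ~ Exp(lam) is (1 - e^{-lam u})/(lam u)
        with np.errstate(over="ignore"):
            frac = (1.0 - np.exp(-lam * u)) / (lam * u)
        return float(frac.mean())

    u = optimize.brentq(lambda v: expected_censored(v) - censor_fraction,
                        1e-6, 1e6)
    t_cens = rng.uniform(0.0, u, size=labels.size)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    return time, event
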