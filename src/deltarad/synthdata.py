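"""Synthetic phantoms and cohorts with known ground truth.

The imaging half builds pre/post-treatment CT phantom pairs: an ellipsoidal
tumor carrying a spatially correlated Gaussian-random-field HU texture on a
constant soft-tissue background, with an optional high-HU stent cylinder.
Treatment response is modelled as isotropic shrinkage of the tumor radii while
the underlying texture field is held fixed (mirroring clinical practice of
transferring the pre-treatment contour when the post-treatment tumor is
unclear), so a shrinkage factor of 1 reproduces the pre-treatment scan
bit-for-bit.

The statistical half simulates subject outcomes from known coefficients on
named features: exponential survival times with hazard
``baseline_hazard * exp(beta' x)`` under independent exponential censoring,
Bernoulli margin status through a logistic link, plus CA19-9 marker values
drawn log-normally with a treatment shift.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import RoiMask, VolumeGrid
from .preprocess import HU_WINDOW

__all__ = [
    "StentSpec", "PhantomSpec", "CohortSpec", "SubjectRecord",
    "make_phantom_pair", "simulate_cohort", "make_feature_table",
    "cohort_to_frame", "RESECTABILITY_LEVELS",
]

RESECTABILITY_LEVELS = ("resectable", "borderline", "locally_advanced", "metastatic")

#: Cohort mix of resectability categories (fractions of subjects).
_RESECTABILITY_PROBS = (0.552, 0.293, 0.138, 0.017)

# CA19-9 (U/mL) log-normal parameters: pre-treatment median ~290 with wide IQR;
# post = pre * lognormal shift giving median ratio ~0.2 and a >=50% decrease in
# roughly 70% of subjects.
_CA199_LOG_MU = np.log(290.0)
_CA199_LOG_SIGMA = 1.9
_CA199_SHIFT_MU = -1.6
_CA199_SHIFT_SIGMA = 1.6

_FIELD_CLIP_SIGMA = 5.0  # tumor texture clipped to mu +/- 5 sigma


@dataclass(frozen=True)
class StentSpec:
    """Cylindrical metal stent insert: axis-aligned, HU outside the soft-tissue
    window (typically ~3000 for metal)."""

    center: tuple[float, float, float]  # mm
    radius: float                       # mm
    axis: int                           # 0, 1 or 2
    hu: float = 3000.0
    half_length: float | None = None    # mm; None = spans the grid

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("stent radius must be positive")
        if self.axis not in (0, 1, 2):
            raise ValueError("stent axis must be 0, 1 or 2")
        if HU_WINDOW[0] <= self.hu <= HU_WINDOW[1]:
            raise ValueError(
                f"stent HU {self.hu} must lie outside the window {HU_WINDOW}")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one pre/post phantom pair."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_center: tuple[float, float, float] | None = None  # mm; None = grid centre
    tumor_radii: tuple[float, float, float] = (12.0, 10.0, 10.0)  # mm, pre-NAT
    shrinkage: float = 0.7            # radii multiplier after treatment, (0, 1]
    texture_mu: float = 60.0          # mean tumor HU
    texture_sigma: float = 30.0       # HU standard deviation of the texture field
    texture_corr_len: float = 3.0     # mm correlation length
    background_mu: float = 80.0       # HU of surrounding tissue
    stent: StentSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.tumor_radii):
            raise ValueError("tumor radii must be positive")
        if not 0 < self.shrinkage <= 1:
            raise ValueError("shrinkage must lie in (0, 1]")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return tuple((n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing))


def _ellipsoid_mask(spec: PhantomSpec, radii) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    c = spec.center_mm
    u = [(ax - ci) / ri for ax, ci, ri in zip(axes, c, radii)]
    return (u[0][:, None, None] ** 2 + u[1][None, :, None] ** 2
            + u[2][None, None, :] ** 2) <= 1.0


def _check_bounds(spec: PhantomSpec) -> None:
    c = spec.center_mm
    for ax, (n, s, ci, ri) in enumerate(
            zip(spec.grid_shape, spec.spacing, c, spec.tumor_radii)):
        if ci - ri < 0 or ci + ri > (n - 1) * s:
            raise ValueError(f"tumor extends beyond grid along axis {ax}")


def _texture_field(spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.grid_shape)
    sigmas = [spec.texture_corr_len / s for s in spec.spacing]
    smooth = gaussian_filter(white, sigma=sigmas, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    field = spec.texture_mu + spec.texture_sigma * smooth
    lim = _FIELD_CLIP_SIGMA * spec.texture_sigma
    return np.clip(field, spec.texture_mu - lim, spec.texture_mu + lim)


def _stent_voxels(spec: PhantomSpec) -> np.ndarray | None:
    st = spec.stent
    if st is None:
        return None
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    perp = [a for a in range(3) if a != st.axis]
    d2 = np.zeros(spec.grid_shape)
    for a in perp:
        shape = [1, 1, 1]
        shape[a] = spec.grid_shape[a]
        d2 = d2 + ((axes[a] - st.center[a]).reshape(shape)) ** 2
    inside = d2 <= st.radius ** 2
    if st.half_length is not None:
        shape = [1, 1, 1]
        shape[st.axis] = spec.grid_shape[st.axis]
        along = np.abs(axes[st.axis] - st.center[st.axis]).reshape(shape)
        inside &= along <= st.half_length
    return inside


def make_phantom_pair(spec: PhantomSpec) -> tuple[tuple[VolumeGrid, RoiMask],
                                                  tuple[VolumeGrid, RoiMask]]:
    """Build the (pre, post) phantom pair for one subject.

    Both scans share one texture realization; the post-treatment mask uses
    radii scaled by ``spec.shrinkage``.  Stent voxels are set to the stent HU
    in both volumes.
    """
    _check_bounds(spec)
    field = _texture_field(spec)
    stent = _stent_voxels(spec)
    pair = []
    for factor in (1.0, spec.shrinkage):
        radii = tuple(r * factor for r in spec.tumor_radii)
        m = _ellipsoid_mask(spec, radii)
        vol = np.full(spec.grid_shape, float(spec.background_mu))
        vol[m] = field[m]
        if stent is not None:
            vol[stent] = spec.stent.hu
        pair.append((VolumeGrid(vol, spec.spacing), RoiMask(m)))
    return pair[0], pair[1]


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Outcome-generating parameters for a simulated cohort.

    ``feature_betas`` are log-hazard coefficients per unit of the named
    features; ``margin_betas`` are log-odds coefficients for R1 margin.
    Hazard rates are per month.
    """

    n_subjects: int = 58
    feature_betas: Mapping[str, float] = field(default_factory=dict)
    margin_betas: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.04
    censor_rate: float = 0.02
    margin_intercept: float = -0.8
    dfs_hazard_ratio: float = 1.5
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


@dataclass
class SubjectRecord:
    """Clinical covariates and outcomes for one simulated subject."""

    id: str
    ca199_pre: float
    ca199_post: float
    ca199_delta_flag: int       # 1 if CA19-9 decreased by >= 50%
    resectability: str
    os_time: float              # months
    os_event: int
    dfs_time: float
    dfs_event: int
    margin: str                 # "R0" or "R1"

    def __post_init__(self) -> None:
        if self.os_time < 0 or self.dfs_time < 0:
            raise ValueError("times must be >= 0")
        if self.os_event not in (0, 1) or self.dfs_event not in (0, 1):
            raise ValueError("events must be 0/1")
        if self.ca199_pre < 0 or self.ca199_post < 0:
            raise ValueError("CA19-9 must be >= 0")
        if self.margin not in ("R0", "R1"):
            raise ValueError("margin must be R0 or R1")


def _linear_predictor(features: pd.DataFrame, betas: Mapping[str, float],
                      standardize: bool) -> np.ndarray:
    missing = [k for k in betas if k not in features.columns]
    if missing:
        raise KeyError(f"unknown feature name(s) in betas: {missing}")
    lp = np.zeros(len(features))
    for name, b in betas.items():
        x = features[name].to_numpy(dtype=float)
        if standardize:
            sd = x.std()
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        lp += b * x
    return lp


def simulate_cohort(cspec: CohortSpec, features: pd.DataFrame) -> list[SubjectRecord]:
    """Draw outcomes for every row of ``features`` under the cohort spec.

    Survival: ``os_time = min(T, C)`` with ``T ~ Exp(h0 * exp(beta' x))`` and
    independent ``C ~ Exp(censor_rate)``; the event flag marks ``T <= C``.
    DFS uses the same linear predictor with hazard scaled by
    ``dfs_hazard_ratio``.  Margin: R1 with probability
    ``logistic(intercept + gamma' x)``.
    """
    n = len(features)
    if n != cspec.n_subjects:
        raise ValueError(
            f"feature table has {n} rows but spec expects {cspec.n_subjects}")
    rng = np.random.default_rng(cspec.seed)
    lp_surv = _linear_predictor(features, cspec.feature_betas, cspec.standardize)
    lp_marg = _linear_predictor(features, cspec.margin_betas, cspec.standardize)

    haz_os = cspec.baseline_hazard * np.exp(lp_surv)
    t_os = rng.exponential(1.0 / haz_os)
    haz_dfs = haz_os * cspec.dfs_hazard_ratio
    t_dfs = rng.exponential(1.0 / haz_dfs)
    if cspec.censor_rate > 0:
        c_os = rng.exponential(1.0 / cspec.censor_rate, size=n)
        c_dfs = rng.exponential(1.0 / cspec.censor_rate, size=n)
    else:
        c_os = np.full(n, np.inf)
        c_dfs = np.full(n, np.inf)

    p_r1 = 1.0 / (1.0 + np.exp(-(cspec.margin_intercept + lp_marg)))
    r1 = rng.random(n) < p_r1

    ca_pre = rng.lognormal(_CA199_LOG_MU, _CA199_LOG_SIGMA, size=n)
    ca_post = ca_pre * rng.lognormal(_CA199_SHIFT_MU, _CA199_SHIFT_SIGMA, size=n)
    resec = rng.choice(len(RESECTABILITY_LEVELS), size=n, p=_RESECTABILITY_PROBS)

    records = []
    ids = [str(i) for i in features.index]
    for i in range(n):
        records.append(SubjectRecord(
            id=ids[i],
            ca199_pre=float(ca_pre[i]),
            ca199_post=float(ca_post[i]),
            ca199_delta_flag=int(ca_post[i] <= 0.5 * ca_pre[i]),
            resectability=RESECTABILITY_LEVELS[resec[i]],
            os_time=float(min(t_os[i], c_os[i])),
            os_event=int(t_os[i] <= c_os[i]),
            dfs_time=float(min(t_dfs[i], c_dfs[i])),
            dfs_event=int(t_dfs[i] <= c_dfs[i]),
            margin="R1" if r1[i] else "R0",
        ))
    return records


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Clinical table: one row per subject, documented column names."""
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("id")
    return df


def make_feature_table(n_subjects: int, n_features: int = 0,
                       names: Sequence[str] | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Standard-normal feature table used as input to ``simulate_cohort`` and
    the selection/classification test surfaces."""
    if names is None:
        names = [f"f{i:02d}" for i in range(n_features)]
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_subjects, len(names)))
    return pd.DataFrame(data, columns=list(names),
                        index=[f"s{i:03d}" for i in range(n_subjects)])
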