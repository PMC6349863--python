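"""Normative modelling and W-score maps.

A W-score is a covariate-adjusted Z-score: per location (surface vertex or
skeleton voxel) an OLS regression of the control cohort's values on age, sex
and intracranial volume provides the value expected for a given subject, and

    W = (raw value - expected value) / SD of the control residuals.

W-scores behave like Z-scores in controls — mean 0, SD about 1, with +/-1.65
marking the 95th/5th percentiles under normality — but are comparable across
subjects of different age, sex and head size. Signs follow the raw value:
positive W means thicker cortex, higher FA or higher MD than expected.

The residual SD uses the df-adjusted denominator n - 4 (intercept + 3
covariates), which makes the in-sample calibration exact: across the controls
used for the fit, each location's W-scores have mean 0 and sample SD
sqrt((n - 4)/(n - 1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, DataError
from .geometry import Geometry
from .types import COVARIATE_COLUMNS, NormativeModel, ScalarMap, WScoreMap

#: Relative degeneracy tolerance: locations with residual SD below this times
#: the map value scale are masked rather than producing unbounded W-scores.
DEGENERACY_RTOL = 1e-8

MIN_CONTROLS = 6  # covariates + 2


def _stack_maps(maps: list[ScalarMap]) -> tuple[np.ndarray, str, str]:
    if not maps:
        raise DataError("no maps supplied")
    modality, space, n_loc = maps[0].modality, maps[0].space, maps[0].n_locations
    for m in maps:
        if (m.modality, m.space) != (modality, space):
            raise DataError(
                f"map for {m.subject_id}: modality/space ({m.modality}, {m.space}) "
                f"does not match ({modality}, {space})"
            )
        if m.n_locations != n_loc:
            raise DataError(
                f"map for {m.subject_id}: {m.n_locations} locations, expected {n_loc}"
            )
    return np.stack([m.values for m in maps]), modality, space


def _design_matrix(
    covariates: pd.DataFrame, subject_ids: list[str]
) -> tuple[np.ndarray, list[int]]:
    """Build [1, age, sex, icv] rows in subject order; report constant columns."""
    cov = covariates.set_index("subject_id")
    missing = [s for s in subject_ids if s not in cov.index]
    if missing:
        raise DataError(f"missing covariates for subjects: {missing}")
    rows = cov.loc[subject_ids, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(subject_ids)), rows])
    constant = [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) == 0.0
    ]
    return X, constant


def fit_normative_model(
    control_maps: list[ScalarMap],
    covariates: pd.DataFrame,
    degeneracy_rtol: float = DEGENERACY_RTOL,
) -> NormativeModel:
    """Fit the per-location control regression value ~ 1 + age + sex + icv.

    All locations are fit at once by least squares on the stacked control
    matrix. If a covariate column is constant across controls (a rank-deficient
    design, e.g. a single-sex control group) it is dropped from the fit, its
    coefficient set to 0, and a warning is issued; the residual df shrinks
    accordingly. Locations whose residual SD is below
    ``degeneracy_rtol * scale`` (scale = median absolute map value, floored at
    the smallest positive SD scale) are flagged degenerate.
    """
    Y, modality, space = _stack_maps(control_maps)
    n = Y.shape[0]
    if n < MIN_CONTROLS:
        raise DataError(f"need at least {MIN_CONTROLS} controls, got {n}")
    subject_ids = [m.subject_id for m in control_maps]
    if "group" in covariates.columns:
        cov = covariates.set_index("subject_id")
        bad = [
            s for s in subject_ids
            if s in cov.index and cov.loc[s, "group"] != "control"
        ]
        if bad:
            raise DataError(f"non-control subjects in control fit: {bad}")
    X, constant_cols = _design_matrix(covariates, subject_ids)
    dropped = tuple(COVARIATE_COLUMNS[j - 1] for j in constant_cols)
    if dropped:
        warnings.warn(
            f"constant covariate column(s) {dropped} dropped from normative fit",
            stacklevel=2,
        )
    keep = [j for j in range(X.shape[1]) if j not in constant_cols]
    Xk = X[:, keep]
    beta_k, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
    coef = np.zeros((X.shape[1], Y.shape[1]))
    coef[keep] = beta_k
    resid = Y - Xk @ beta_k
    df = n - len(keep)
    resid_sd = np.sqrt((resid**2).sum(axis=0) / df)
    scale = float(np.median(np.abs(Y)))
    tol = degeneracy_rtol * max(scale, 1e-30)
    degenerate = resid_sd < tol
    return NormativeModel(
        coef=coef,
        resid_sd=resid_sd,
        n_controls=n,
        df_resid=df,
        degenerate=degenerate,
        modality=modality,
        space=space,
        dropped_covariates=dropped,
    )


def compute_wscore(
    smap: ScalarMap,
    covariate_row,
    model: NormativeModel,
    analysis_mask: np.ndarray | None = None,
) -> WScoreMap:
    """W-score one subject's map against a fitted normative model.

    ``covariate_row`` is any mapping with age/sex/icv (e.g. a DataFrame row).
    Degenerate model locations — and locations outside ``analysis_mask`` when
    given — are masked (W = NaN).
    """
    if smap.modality != model.modality or smap.space != model.space:
        raise DataError(
            f"map ({smap.modality}, {smap.space}) does not match model "
            f"({model.modality}, {model.space})"
        )
    if smap.n_locations != model.n_locations:
        raise DataError(
            f"map has {smap.n_locations} locations, model {model.n_locations}"
        )
    expected = model.predict(covariate_row)
    masked = model.degenerate.copy()
    if analysis_mask is not None:
        analysis_mask = np.asarray(analysis_mask, dtype=bool)
        if analysis_mask.shape != (model.n_locations,):
            raise DataError("analysis_mask length does not match model locations")
        masked |= ~analysis_mask
    w = np.full(model.n_locations, np.nan)
    ok = ~masked
    w[ok] = (smap.values[ok] - expected[ok]) / model.resid_sd[ok]
    return WScoreMap(smap.subject_id, smap.modality, smap.space, w, masked)


def compute_wscores(
    maps: list[ScalarMap],
    covariates: pd.DataFrame,
    model: NormativeModel,
    analysis_mask: np.ndarray | None = None,
) -> list[WScoreMap]:
    """Vector convenience: W-score many subjects against one model."""
    cov = covariates.set_index("subject_id")
    out = []
    for m in maps:
        if m.subject_id not in cov.index:
            raise DataError(f"missing covariates for subject {m.subject_id}")
        out.append(compute_wscore(m, cov.loc[m.subject_id], model, analysis_mask))
    return out


@dataclass
class CalibrationReport:
    """Per-location mean and sample SD (ddof=1) of a set of W-score maps."""

    mean: np.ndarray
    sd: np.ndarray
    n: int


def control_calibration(
    model: NormativeModel,
    control_maps: list[ScalarMap],
    covariates: pd.DataFrame,
) -> CalibrationReport:
    """Mean/SD of control W-scores per location.

    With the same controls the model was fit on, OLS residual algebra gives
    mean exactly 0 and sample SD exactly sqrt(df_resid / (n - 1)) at every
    non-degenerate location. With held-out controls from the same population
    both approach 0 and 1 as n grows.
    """
    wmaps = compute_wscores(control_maps, covariates, model)
    W = np.stack([wm.w for wm in wmaps])
    n = W.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(W, axis=0)
        sd = np.nanstd(W, axis=0, ddof=1)
    return CalibrationReport(mean=mean, sd=sd, n=n)


def insample_sd_constant(n_controls: int, n_params: int = 4) -> float:
    """Exact sample SD of in-sample W-scores: sqrt((n - p) / (n - 1))."""
    return float(np.sqrt((n_controls - n_params) / (n_controls - 1)))


_DIRECTIONS = {
    "thickness": "lower_is_abnormal",
    "FA": "lower_is_abnormal",
    "MD": "higher_is_abnormal",
}


def abnormality_direction(modality: str) -> str:
    """Which W-score tail marks damage: thinning and FA loss are low-tail, MD high-tail."""
    try:
        return _DIRECTIONS[modality]
    except KeyError:
        raise ConfigurationError(f"unknown modality {modality!r}") from None


def build_skeleton_mask(mean_fa_map: ScalarMap, threshold: float = 0.2) -> np.ndarray:
    """Restrict skeleton analyses to voxels with mean FA strictly above threshold.

    The threshold excludes voxels dominated by grey matter or CSF; the
    boundary value itself is excluded (strict ``>``).
    """
    if mean_fa_map.modality != "FA":
        raise DataError(
            f"skeleton mask requires an FA map, got {mean_fa_map.modality!r}"
        )
    return mean_fa_map.values > threshold


def mean_map(maps: list[ScalarMap], subject_id: str = "group-mean") -> ScalarMap:
    """Voxel/vertex-wise mean of a stack of maps (e.g. the mean-FA skeleton input)."""
    Y, modality, space = _stack_maps(maps)
    return ScalarMap(subject_id, modality, space, Y.mean(axis=0))


def _averaging_operator(geometry: Geometry) -> sp.csr_matrix:
    adj = geometry.surface_adjacency()
    n = geometry.n_vertices
    rows, cols, vals = [], [], []
    for i, nbrs in enumerate(adj):
        w = 1.0 / (1 + len(nbrs))
        rows.append(i)
        cols.append(i)
        vals.append(w)
        for j in nbrs:
            rows.append(i)
            cols.append(int(j))
            vals.append(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def smoothing_iterations(geometry: Geometry, fwhm_mm: float) -> int:
    """Iterations of neighbour averaging matching a Gaussian FWHM.

    One pass of uniform self+neighbour averaging on a 2-D grid graph with
    spacing h spreads variance 2 h^2 / (1 + d) along each axis (d = regular
    degree, 4 here). k passes approximate a Gaussian of per-axis variance
    k * v; we pick k so that matches sigma^2 = fwhm^2 / (8 ln 2).
    """
    if fwhm_mm == 0:
        return 0
    sigma2 = fwhm_mm**2 / (8.0 * np.log(2.0))
    v = 2.0 * geometry.vertex_spacing_mm**2 / 5.0
    return max(1, int(round(sigma2 / v)))


def smooth_surface_map(
    smap: ScalarMap, geometry: Geometry, fwhm_mm: float
) -> ScalarMap:
    """Smooth a surface map by iterated neighbour averaging.

    fwhm = 0 returns the input unchanged. On a regular closed grid graph the
    averaging operator is doubly stochastic, so constants are preserved
    exactly and the map mean never changes.
    """
    if smap.space != "surface":
        raise DataError("smoothing is defined for surface maps only")
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm_mm must be >= 0")
    if smap.n_locations != geometry.n_vertices:
        raise DataError(
            f"map has {smap.n_locations} vertices, geometry {geometry.n_vertices}"
        )
    k = smoothing_iterations(geometry, fwhm_mm)
    if k == 0:
        return ScalarMap(smap.subject_id, smap.modality, smap.space, smap.values.copy())
    A = _averaging_operator(geometry)
    x = smap.values.copy()
    for _ in range(k):
        x = A @ x
    return ScalarMap(smap.subject_id, smap.modality, smap.space, x)


def compute_global_pet_ratio(
    uptake,
    composite_regions=("frontal", "parietal", "temporal", "posterior_cingulate"),
    reference_region: str = "cerebellum",
) -> float:
    """Global amyloid uptake ratio: mean over the cortical composite / cerebellum."""
    ref = float(uptake[reference_region])
    if ref <= 0:
        raise DataError(f"reference region {reference_region!r} uptake must be > 0")
    vals = [float(uptake[r]) for r in composite_regions]
    return float(np.mean(vals) / ref)


def classify_amyloid(ratio: float, threshold: float = 1.5) -> bool:
    """Amyloid-positive iff the global uptake ratio is strictly above threshold."""
    if not np.isfinite(ratio):
        raise DataError("PET ratio must be finite")
    return bool(ratio > threshold)
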