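"""Core data containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

#: Covariate columns of the normative regression, in design-matrix order
#: (after the intercept). Sex is coded 0/1 with female = 1; ICV in mm^3.
COVARIATE_COLUMNS = ("age", "sex", "icv")

KNOWN_MODALITIES = ("thickness", "FA", "MD")
SPACES = ("surface", "skeleton")


@dataclass
class ScalarMap:
    """One subject's per-location values for one modality.

    ``values`` has one entry per location of the geometry's ``space``
    (surface vertex or skeleton voxel, 0-based, in geometry order).
    """

    subject_id: str
    modality: str
    space: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError(f"map for {self.subject_id}: values must be 1-D")
        if self.space not in SPACES:
            raise DataError(f"map for {self.subject_id}: unknown space {self.space!r}")
        if self.modality == "FA" and (
            np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1
        ):
            raise DataError(f"FA map for {self.subject_id}: values outside [0, 1]")
        if self.modality in ("MD", "thickness") and np.nanmin(self.values) < 0:
            raise DataError(
                f"{self.modality} map for {self.subject_id}: negative values"
            )

    @property
    def n_locations(self) -> int:
        return int(self.values.shape[0])


@dataclass
class LesionMask:
    """Binary white-matter-hyperintensity mask on the volume grid."""

    subject_id: str
    voxels: np.ndarray
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise DataError(f"mask for {self.subject_id}: voxels must be 3-D")
        bad = ~np.isin(vox, (0, 1))
        if bad.any():
            where = tuple(int(i) for i in np.argwhere(bad)[0])
            raise DataError(
                f"mask for {self.subject_id}: non-binary value "
                f"{vox[where]!r} at voxel {where}"
            )
        self.voxels = vox.astype(np.uint8)


@dataclass
class NormativeModel:
    """Per-location OLS fit of a control cohort: value ~ 1 + age + sex + icv.

    ``coef`` is (1 + n_covariates, n_locations): row 0 the intercept, then one
    row per covariate in :data:`COVARIATE_COLUMNS` order. ``resid_sd`` is the
    df-adjusted residual standard deviation (denominator ``df_resid``).
    Locations whose residual SD falls below the degeneracy tolerance are
    flagged and masked out of W-score maps instead of producing infinities.
    """

    coef: np.ndarray
    resid_sd: np.ndarray
    n_controls: int
    df_resid: int
    degenerate: np.ndarray
    modality: str
    space: str
    covariates: tuple[str, ...] = COVARIATE_COLUMNS
    dropped_covariates: tuple[str, ...] = ()

    @property
    def n_locations(self) -> int:
        return int(self.coef.shape[1])

    def predict(self, covariate_row) -> np.ndarray:
        """Expected control value at every location for one subject's covariates."""
        x = np.concatenate(
            ([1.0], [float(covariate_row[c]) for c in self.covariates])
        )
        return x @ self.coef


@dataclass
class WScoreMap:
    """Covariate-adjusted standardized deviation map for one subject.

    Positive values mean larger raw values than expected from controls
    (thicker cortex, higher FA, higher MD). ``masked`` marks locations with no
    defined W (degenerate model or excluded by the analysis mask); ``w`` is
    NaN there.
    """

    subject_id: str
    modality: str
    space: str
    w: np.ndarray
    masked: np.ndarray

    @property
    def n_locations(self) -> int:
        return int(self.w.shape[0])


@dataclass
class StatMap:
    """Per-location two-sample test results for one ordered contrast (A vs B).

    Positive t means group A > group B. ``in_mask`` marks locations that
    entered the test; outside it t and p are NaN and ``significant`` False.
    ``p_corrected`` is filled by FWE correction (NaN otherwise); FDR sets
    flags without per-location adjusted p.
    """

    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    in_mask: np.ndarray
    df: int
    correction: str  # none | FDR | FWE
    contrast: tuple[str, str]
    alpha: float
    space: str = "skeleton"
    p_corrected: np.ndarray | None = None
    grid_shape: tuple[int, ...] | None = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


@dataclass
class FrequencyMap:
    """Per-voxel lesion proportion for one group."""

    proportion: np.ndarray
    n_subjects: int
    group: str = ""

    def __post_init__(self) -> None:
        self.proportion = np.asarray(self.proportion, dtype=float)
        if ((self.proportion < 0) | (self.proportion > 1)).any():
            raise DataError("frequency map proportions outside [0, 1]")


@dataclass
class GlobalSummary:
    """Global-mean group comparison: ANCOVA (age/sex-adjusted) + diagnostics."""

    modality: str
    global_means: dict[str, float]  # subject_id -> global mean W
    group_of: dict[str, str]
    ancova_f: float
    ancova_p: float
    pairwise_p: dict[tuple[str, str], float]  # raw two-sided p per pair
    pairwise_p_bonferroni: dict[tuple[str, str], float]
    ks_p: dict[str, float] = field(default_factory=dict)  # per group
    bartlett_stat: float = float("nan")
    bartlett_p: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "ancova_f": self.ancova_f,
            "ancova_p": self.ancova_p,
            "pairwise_p": {" vs ".join(k): v for k, v in self.pairwise_p.items()},
            "pairwise_p_bonferroni": {
                " vs ".join(k): v for k, v in self.pairwise_p_bonferroni.items()
            },
            "ks_p": dict(self.ks_p),
            "bartlett_stat": self.bartlett_stat,
            "bartlett_p": self.bartlett_p,
        }
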