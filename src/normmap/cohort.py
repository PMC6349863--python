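"""Synthetic cohort generator with known ground truth.

Real small-vessel-disease imaging cohorts are not redistributable, so every
downstream stage of the package is exercised on simulated data whose
generating parameters (covariate effects, noise levels, group effects, lesion
probabilities) are recorded explicitly. The default demographics emulate a
three-patient-group design in which the monogenic-arteriopathy-like group is
substantially younger (57 +/- 7 years, n = 11) than the two sporadic groups
(72 +/- 8, n = 15 and 74 +/- 7, n = 101) — the age gap that motivates
covariate-adjusted W-scores in the first place.

Structural maps follow the linear-Gaussian model the normative fit assumes:

    value(loc) = baseline(loc) + beta_age*age + beta_sex*sex + beta_icv*icv
                 + group_effect(group, loc) + N(0, noise_sd)

with controls receiving zero group effect. Lesion masks are voxelwise
independent Bernoulli draws from a per-group probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .geometry import Geometry
from .types import COVARIATE_COLUMNS, LesionMask, ScalarMap

CONTROL = "control"

#: Patient-group demographics of the default design (age mean/SD in years,
#: female fraction): a young monogenic-like group and two older sporadic groups.
DEFAULT_GROUPS = {
    "typical_CADASIL": dict(n=11, age=(57.0, 7.0), female=0.455),
    "SVCI_with_variants": dict(n=15, age=(72.0, 8.0), female=0.60),
    "SVCI_without_variants": dict(n=101, age=(74.0, 7.0), female=0.614),
}


@dataclass(frozen=True)
class CohortSpec:
    """Demographic design of a synthetic cohort.

    ``group_sizes`` etc. are keyed by group label; the control group is
    configured by the ``n_controls`` / ``control_*`` fields (its demographics
    are a free design choice, not something the emulated study pins down).
    Identical seed implies an identical cohort.
    """

    n_controls: int = 56
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {g: v["n"] for g, v in DEFAULT_GROUPS.items()}
    )
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {g: v["age"] for g, v in DEFAULT_GROUPS.items()}
    )
    sex_proportion: dict[str, float] = field(
        default_factory=lambda: {g: v["female"] for g, v in DEFAULT_GROUPS.items()}
    )
    control_age_mean_sd: tuple[float, float] = (65.0, 8.0)
    control_sex_proportion: float = 0.55
    icv_mean_sd: tuple[float, float] = (1.45e6, 1.2e5)
    min_age: float = 18.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 1:
            raise ConfigurationError("n_controls must be >= 1")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigurationError(f"group_sizes[{g!r}] must be >= 1")
            if g not in self.age_mean_sd:
                raise ConfigurationError(f"age_mean_sd missing group {g!r}")
            if g not in self.sex_proportion:
                raise ConfigurationError(f"sex_proportion missing group {g!r}")
        for name, table in (("age_mean_sd", self.age_mean_sd),):
            for g, (_, sd) in table.items():
                if sd < 0:
                    raise ConfigurationError(f"{name}[{g!r}] SD must be >= 0")
        if self.control_age_mean_sd[1] < 0:
            raise ConfigurationError("control_age_mean_sd SD must be >= 0")
        if self.icv_mean_sd[1] < 0:
            raise ConfigurationError("icv_mean_sd SD must be >= 0")
        for g, p in {
            **self.sex_proportion,
            CONTROL: self.control_sex_proportion,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"sex_proportion[{g!r}] must be in [0, 1], got {p}"
                )

    @property
    def groups(self) -> list[str]:
        return list(self.group_sizes)


@dataclass
class EffectTruth:
    """Generating parameters of the synthetic maps — the recovery-test oracle.

    ``baseline`` and ``betas`` entries may be scalars (uniform across
    locations) or per-location arrays. ``group_effects[(group, modality)]`` is
    an additive per-location shift (scalar or array); absent keys mean zero
    effect. ``lesion_prob[group]`` is a per-voxel probability volume on the
    geometry grid.
    """

    baseline: dict[str, float | np.ndarray]
    betas: dict[str, dict[str, float | np.ndarray]]
    noise_sd: dict[str, float]
    group_effects: dict[tuple[str, str], float | np.ndarray] = field(
        default_factory=dict
    )
    lesion_prob: dict[str, np.ndarray] = field(default_factory=dict)
    space_of: dict[str, str] = field(
        default_factory=lambda: {"thickness": "surface", "FA": "skeleton", "MD": "skeleton"}
    )

    def validate(self, geometry: Geometry) -> None:
        for m, sd in self.noise_sd.items():
            if sd <= 0:
                raise ConfigurationError(f"noise_sd[{m!r}] must be > 0")
        for g, prob in self.lesion_prob.items():
            prob = np.asarray(prob)
            if prob.shape != geometry.grid_shape:
                raise ConfigurationError(
                    f"lesion_prob[{g!r}] shape {prob.shape} does not match "
                    f"grid {geometry.grid_shape}"
                )
            if np.nanmin(prob) < 0 or np.nanmax(prob) > 1:
                raise ConfigurationError(
                    f"lesion_prob[{g!r}] has probabilities outside [0, 1]"
                )
        for m in self.noise_sd:
            n = geometry.n_locations(self.space_of[m])
            for name, val in [("baseline", self.baseline.get(m, 0.0))] + [
                (f"betas[{c}]", self.betas.get(m, {}).get(c, 0.0))
                for c in COVARIATE_COLUMNS
            ]:
                arr = np.asarray(val, dtype=float)
                if arr.ndim not in (0, 1) or (arr.ndim == 1 and arr.shape[0] != n):
                    raise ConfigurationError(
                        f"{name} for modality {m!r} must be scalar or length {n}"
                    )
        for (g, m), eff in self.group_effects.items():
            if m not in self.space_of:
                raise ConfigurationError(f"group_effects modality {m!r} unknown")
            arr = np.asarray(eff, dtype=float)
            n = geometry.n_locations(self.space_of[m])
            if arr.ndim == 1 and arr.shape[0] != n:
                raise ConfigurationError(
                    f"group_effects[({g!r}, {m!r})] length {arr.shape[0]} != {n}"
                )

    @classmethod
    def toy(cls, geometry: Geometry, lesion_rate: float = 0.1) -> "EffectTruth":
        """Plausible default truth on the toy geometry.

        Covariate effects and noise are in each modality's native units:
        thickness in mm (~ -5 um/yr age slope), FA unitless on the skeleton,
        MD in um^2/ms. Each patient group gets a mild uniform lesion field
        plus a group-specific hotspot so frequency maps differ by group.
        """
        lesion = {}
        nx, ny, nz = geometry.grid_shape
        hotspots = {
            "typical_CADASIL": (slice(nx // 2, nx), slice(0, ny // 2)),
            "SVCI_with_variants": (slice(0, nx // 2), slice(ny // 2, ny)),
            "SVCI_without_variants": (slice(0, nx // 2), slice(ny // 2, ny)),
        }
        for g, sl in hotspots.items():
            prob = np.full(geometry.grid_shape, lesion_rate * 0.5)
            prob[sl[0], sl[1], :] = min(1.0, lesion_rate * 3)
            lesion[g] = prob
        return cls(
            baseline={"thickness": 2.5, "FA": 0.45, "MD": 0.80},
            betas={
                "thickness": {"age": -5e-3, "sex": 0.02, "icv": 1e-7},
                "FA": {"age": -2e-3, "sex": 0.0, "icv": 0.0},
                "MD": {"age": 3e-3, "sex": 0.0, "icv": 0.0},
            },
            noise_sd={"thickness": 0.25, "FA": 0.04, "MD": 0.05},
            lesion_prob=lesion,
        )

    def to_dict(self) -> dict:
        def ser(v):
            return v.tolist() if isinstance(v, np.ndarray) else v

        return {
            "baseline": {m: ser(v) for m, v in self.baseline.items()},
            "betas": {m: {c: ser(v) for c, v in d.items()} for m, d in self.betas.items()},
            "noise_sd": dict(self.noise_sd),
            "group_effects": {
                f"{g}|{m}": ser(v) for (g, m), v in self.group_effects.items()
            },
            "lesion_prob": {g: ser(np.asarray(v)) for g, v in self.lesion_prob.items()},
            "space_of": dict(self.space_of),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectTruth":
        def de(v):
            return np.asarray(v, dtype=float) if isinstance(v, list) else v

        ge = {}
        for key, v in d.get("group_effects", {}).items():
            g, m = key.split("|", 1)
            ge[(g, m)] = de(v)
        return cls(
            baseline={m: de(v) for m, v in d["baseline"].items()},
            betas={m: {c: de(v) for c, v in dd.items()} for m, dd in d["betas"].items()},
            noise_sd={m: float(v) for m, v in d["noise_sd"].items()},
            group_effects=ge,
            lesion_prob={g: np.asarray(v, dtype=float) for g, v in d.get("lesion_prob", {}).items()},
            space_of=dict(d.get("space_of", {"thickness": "surface", "FA": "skeleton", "MD": "skeleton"})),
        )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a covariate table (subject_id, group, age, sex, icv) from the spec.

    Ages are drawn from each group's normal law and redrawn below ``min_age``;
    sex is Bernoulli (female = 1); ICV normal. Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    plan = [(CONTROL, spec.n_controls, spec.control_age_mean_sd, spec.control_sex_proportion)]
    plan += [
        (g, spec.group_sizes[g], spec.age_mean_sd[g], spec.sex_proportion[g])
        for g in spec.group_sizes
    ]
    counter = 0
    icv_mean, icv_sd = spec.icv_mean_sd
    for group, n, (age_mean, age_sd), p_female in plan:
        for _ in range(n):
            age = rng.normal(age_mean, age_sd)
            while age < spec.min_age:
                age = rng.normal(age_mean, age_sd)
            rows.append(
                {
                    "subject_id": f"sub-{counter:04d}",
                    "group": group,
                    "age": float(age),
                    "sex": int(rng.random() < p_female),
                    "icv": float(rng.normal(icv_mean, icv_sd)),
                }
            )
            counter += 1
    return pd.DataFrame(rows)


def _per_location(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    return np.broadcast_to(arr, (n,)).copy() if arr.ndim == 0 else arr


def generate_scalar_maps(
    cohort: pd.DataFrame,
    truth: EffectTruth,
    geometry: Geometry,
    modality: str,
    seed: int,
) -> list[ScalarMap]:
    """Simulate one map per subject under the linear-Gaussian truth.

    FA maps are clipped to [0, 1] and thickness/MD to >= 0 after noise is
    added, so the declared physical ranges always hold (clipping is a rare
    event at the default noise levels).
    """
    if cohort.empty:
        raise DataError("cohort is empty")
    if modality not in truth.noise_sd:
        raise ConfigurationError(f"truth does not cover modality {modality!r}")
    truth.validate(geometry)
    space = truth.space_of[modality]
    n_loc = geometry.n_locations(space)
    rng = np.random.default_rng(seed)

    base = _per_location(truth.baseline.get(modality, 0.0), n_loc)
    betas = truth.betas.get(modality, {})
    beta_arr = {c: _per_location(betas.get(c, 0.0), n_loc) for c in COVARIATE_COLUMNS}
    sd = truth.noise_sd[modality]

    maps = []
    for row in cohort.itertuples(index=False):
        mean = base.copy()
        for c in COVARIATE_COLUMNS:
            mean += beta_arr[c] * float(getattr(row, c))
        eff = truth.group_effects.get((row.group, modality))
        if eff is not None and row.group != CONTROL:
            mean += _per_location(eff, n_loc)
        values = mean + rng.normal(0.0, sd, size=n_loc)
        if modality == "FA":
            values = np.clip(values, 0.0, 1.0)
        elif modality in ("MD", "thickness"):
            values = np.clip(values, 0.0, None)
        maps.append(ScalarMap(row.subject_id, modality, space, values))
    return maps


def generate_lesion_masks(
    cohort: pd.DataFrame,
    truth: EffectTruth,
    geometry: Geometry,
    seed: int,
    control_prob: float = 0.0,
) -> list[LesionMask]:
    """Draw one binary lesion mask per subject (voxelwise independent Bernoulli).

    Controls use a uniform ``control_prob`` (default lesion-free); each
    patient group must have a probability map in the truth.
    """
    truth.validate(geometry)
    if not 0.0 <= control_prob <= 1.0:
        raise ConfigurationError("control_prob must be in [0, 1]")
    groups = set(cohort["group"]) - {CONTROL}
    missing = groups - set(truth.lesion_prob)
    if missing:
        raise ConfigurationError(f"lesion_prob missing groups: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    masks = []
    ctrl_map = np.full(geometry.grid_shape, control_prob)
    for row in cohort.itertuples(index=False):
        prob = ctrl_map if row.group == CONTROL else np.asarray(truth.lesion_prob[row.group])
        vox = (rng.random(geometry.grid_shape) < prob).astype(np.uint8)
        masks.append(LesionMask(row.subject_id, vox, geometry.voxel_size_mm))
    return masks


#: Regions of the amyloid-PET composite (uptake averaged over these) and the
#: reference region used for the global uptake ratio.
PET_COMPOSITE_REGIONS = ("frontal", "parietal", "temporal", "posterior_cingulate")
PET_REFERENCE_REGION = "cerebellum"


def generate_pet_table(
    cohort: pd.DataFrame,
    positive_fraction: dict[str, float],
    seed: int,
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Simulate regional amyloid-PET uptake with a target positivity rate per group.

    Each subject is first drawn amyloid-positive with their group's
    probability; positives get a global uptake ratio strictly above the
    threshold (1.5 by default), negatives strictly below-or-equal. Regional
    uptake values are then constructed so that the composite mean over
    :data:`PET_COMPOSITE_REGIONS` divided by cerebellar uptake reproduces the
    drawn ratio exactly (zero-sum jitter across composite regions).
    """
    for g, p in positive_fraction.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"positive_fraction[{g!r}] must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    k = len(PET_COMPOSITE_REGIONS)
    for row in cohort.itertuples(index=False):
        p_pos = positive_fraction.get(row.group, 0.0)
        positive = rng.random() < p_pos
        if positive:
            ratio = threshold + abs(rng.normal(0.45, 0.20)) + 1e-6
        else:
            ratio = threshold - abs(rng.normal(0.35, 0.12))
            ratio = max(ratio, 0.6)
        cereb = rng.normal(1.0, 0.05)
        cereb = max(cereb, 0.5)
        composite_mean = ratio * cereb
        jitter = rng.normal(0.0, 0.03, size=k)
        jitter -= jitter.mean()  # preserve the composite mean exactly
        region_vals = np.clip(composite_mean + jitter, 0.05, None)
        region_vals += composite_mean - region_vals.mean()
        rec = {"subject_id": row.subject_id, PET_REFERENCE_REGION: float(cereb)}
        rec.update(dict(zip(PET_COMPOSITE_REGIONS, region_vals.astype(float))))
        rows.append(rec)
    return pd.DataFrame(rows)
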