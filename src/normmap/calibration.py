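"""Simulation studies of the pipeline's error rates and recovery power.

These drive the package's own quality checks and are useful when adapting the
workflow to new designs: how often does max-|t| permutation FWE reject under
a true null, is the uncorrected voxelwise rate at its nominal level, how much
of a planted deficit does BH-FDR recover and at what false-discovery cost.
Everything here runs the same public functions a user would call, on
synthetic cohorts of configurable size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortSpec, EffectTruth, generate_cohort, generate_scalar_maps
from .geometry import Geometry
from .inference import (
    check_variance_homogeneity,
    correct_fdr,
    correct_fwe_permutation,
    global_ancova,
    massuni_ttest,
)
from .types import WScoreMap
from .wscore import compute_wscores, fit_normative_model


def _wmaps(matrix: np.ndarray, offset: int = 0) -> list[WScoreMap]:
    return [
        WScoreMap(f"s{i + offset}", "FA", "skeleton", row, np.zeros(row.shape, bool))
        for i, row in enumerate(matrix)
    ]


@dataclass
class NullErrorRates:
    fwe_rate: float
    fwe_se: float
    uncorrected_rate: float
    uncorrected_se: float
    n_datasets: int
    n_locations: int


def null_fwe_study(
    n_datasets: int = 200,
    n_per_group: int = 10,
    n_locations: int = 300,
    n_perm: int = 199,
    alpha: float = 0.05,
    uncorrected_alpha: float = 0.001,
    seed: int = 0,
) -> NullErrorRates:
    """Family-wise and voxelwise type-I rates under the two-group null.

    Each dataset draws both groups' W-like maps from the same standard normal
    law; the FWE rate is the fraction of datasets with any permutation-FWE
    significant location, and the uncorrected rate pools per-location flags
    at ``uncorrected_alpha`` over all datasets.
    """
    rng = np.random.default_rng(seed)
    fwe_hits = 0
    flagged = 0
    total = 0
    perm_seeds = rng.integers(0, 2**31 - 1, size=n_datasets)
    for i in range(n_datasets):
        A = rng.standard_normal((n_per_group, n_locations))
        B = rng.standard_normal((n_per_group, n_locations))
        wa, wb = _wmaps(A), _wmaps(B, offset=n_per_group)
        fwe = correct_fwe_permutation(
            wa, wb, n_perm=n_perm, seed=int(perm_seeds[i]), alpha=alpha
        )
        fwe_hits += int(fwe.significant.any())
        raw = massuni_ttest(wa, wb, alpha=uncorrected_alpha)
        flagged += int(raw.significant.sum())
        total += int(raw.in_mask.sum())
    fwe_rate = fwe_hits / n_datasets
    unc = flagged / total
    return NullErrorRates(
        fwe_rate=fwe_rate,
        fwe_se=float(np.sqrt(alpha * (1 - alpha) / n_datasets)),
        uncorrected_rate=unc,
        uncorrected_se=float(
            np.sqrt(uncorrected_alpha * (1 - uncorrected_alpha) / total)
        ),
        n_datasets=n_datasets,
        n_locations=n_locations,
    )


def ancova_null_rejection_rate(
    n_reps: int = 500,
    n_per_group: int = 15,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I rate of the age/sex-adjusted group F test with identical groups."""
    rng = np.random.default_rng(seed)
    import pandas as pd

    rejections = 0
    for _ in range(n_reps):
        rows = []
        for g in ("g1", "g2", "g3"):
            for i in range(n_per_group):
                age = rng.uniform(50, 85)
                sex = int(rng.integers(0, 2))
                value = 0.02 * age + 0.1 * sex + rng.normal()
                rows.append((f"{g}-{i}", g, age, sex, 1.4e6, value))
        df = pd.DataFrame(
            rows, columns=["subject_id", "group", "age", "sex", "icv", "value"]
        )
        gs = global_ancova(
            dict(zip(df["subject_id"], df["value"])),
            df.drop(columns="value"),
            run_diagnostics=False,
        )
        rejections += int(gs.ancova_p < alpha)
    return rejections / n_reps


def bartlett_null_rejection_rate(
    n_reps: int = 500, n_per_group: int = 15, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I rate of Bartlett's test with equal-variance normal groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        groups = [rng.standard_normal(n_per_group) for _ in range(3)]
        rejections += int(check_variance_homogeneity(*groups)[1] < alpha)
    return rejections / n_reps


@dataclass
class RecoveryResult:
    sensitivity: float  # mean fraction of planted locations flagged
    false_discovery_proportion: float  # mean fraction of flags outside the region
    n_reps: int
    n_planted: int
    n_locations: int


def planted_fdr_recovery(
    n_reps: int = 12,
    n_controls: int = 150,
    n_per_group: int = 30,
    cohens_d: float = 1.0,
    n_planted: int = 400,
    q: float = 0.05,
    geometry: Geometry | None = None,
    seed: int = 0,
) -> RecoveryResult:
    """BH-FDR recovery of a planted regional cortical-thickness deficit.

    Two demographically identical patient groups are simulated; the affected
    group carries an additive deficit of ``cohens_d`` times the map noise SD
    on a contiguous block of ``n_planted`` vertices. The full pipeline path
    runs each replicate: normative fit on controls, patient W-scores,
    vertexwise t map, BH flags. Reports mean sensitivity inside the region
    and the mean proportion of flags outside it (the empirical FDP).
    """
    geometry = geometry or Geometry.toy()
    noise_sd = 0.25
    truth = EffectTruth(
        baseline={"thickness": 2.5},
        betas={"thickness": {"age": -5e-3, "sex": 0.02, "icv": 1e-7}},
        noise_sd={"thickness": noise_sd},
        group_effects={
            ("affected", "thickness"): np.concatenate(
                [
                    np.full(n_planted, -cohens_d * noise_sd),
                    np.zeros(geometry.n_vertices - n_planted),
                ]
            )
        },
    )
    spec_kwargs = dict(
        n_controls=n_controls,
        group_sizes={"affected": n_per_group, "reference": n_per_group},
        age_mean_sd={"affected": (70.0, 8.0), "reference": (70.0, 8.0)},
        sex_proportion={"affected": 0.5, "reference": 0.5},
    )
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(n_reps, 2))
    planted = np.zeros(geometry.n_vertices, dtype=bool)
    planted[:n_planted] = True

    sens, fdp = [], []
    for r in range(n_reps):
        cohort = generate_cohort(CohortSpec(seed=int(rep_seeds[r, 0]), **spec_kwargs))
        maps = generate_scalar_maps(
            cohort, truth, geometry, "thickness", seed=int(rep_seeds[r, 1])
        )
        map_of = {m.subject_id: m for m in maps}
        groups = cohort.groupby("group")["subject_id"].apply(list).to_dict()
        model = fit_normative_model([map_of[s] for s in groups["control"]], cohort)
        wa = compute_wscores([map_of[s] for s in groups["affected"]], cohort, model)
        wb = compute_wscores([map_of[s] for s in groups["reference"]], cohort, model)
        raw = massuni_ttest(wa, wb, contrast=("affected", "reference"))
        flags = correct_fdr(raw, q=q).significant
        n_flags = flags.sum()
        sens.append(flags[planted].mean())
        fdp.append((flags & ~planted).sum() / n_flags if n_flags else 0.0)
    return RecoveryResult(
        sensitivity=float(np.mean(sens)),
        false_discovery_proportion=float(np.mean(fdp)),
        n_reps=n_reps,
        n_planted=n_planted,
        n_locations=geometry.n_vertices,
    )
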