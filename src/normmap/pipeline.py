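"""End-to-end pipeline driver.

One YAML (or dict) config drives the whole workflow on synthetic or on-disk
data: simulate/load cohort and maps -> WMH frequency maps and group
comparison -> normative fits on controls -> patient W-score maps (smoothed on
the surface, FA-threshold-masked on the skeleton) -> corrected group
contrasts (FDR on the surface, permutation FWE on the skeleton) -> global
ANCOVA with Bonferroni post-hoc and distributional checks.

Outputs land in a deterministic directory layout::

    out/
      covariates.csv geometry.json truth.json     (synthetic mode)
      models/<modality>/  wmaps/<modality>/  freqmaps/  statmaps/
      summary.json  provenance.json

Deterministic stages are bit-identical across re-runs with the same config;
stochastic stages are reproducible through the config seed.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, io, lesions, wscore
from .cohort import (
    CONTROL,
    CohortSpec,
    EffectTruth,
    generate_cohort,
    generate_lesion_masks,
    generate_scalar_maps,
)
from .errors import ConfigurationError
from .geometry import Geometry
from .types import ScalarMap

DEFAULT_CONFIG = {
    "seed": 0,
    "modalities": ["thickness", "FA", "MD"],
    "contrasts": [
        ["SVCI_without_variants", "SVCI_with_variants"],
        ["typical_CADASIL", "SVCI_without_variants"],
        ["typical_CADASIL", "SVCI_with_variants"],
    ],
    "alpha": 0.05,
    "q": 0.05,
    "freq_alpha": 0.001,
    "n_perm": 1000,
    "smoothing_fwhm_mm": 20.0,
    "fa_threshold": 0.2,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Fill defaults and check field types/ranges; errors name the field."""
    out = {**DEFAULT_CONFIG, **cfg}
    for field in ("alpha", "q", "freq_alpha"):
        v = out[field]
        if not isinstance(v, (int, float)) or not 0 < v < 1:
            raise ConfigurationError(f"config field {field!r} must be in (0, 1)")
    if not isinstance(out["n_perm"], int) or out["n_perm"] < 1:
        raise ConfigurationError("config field 'n_perm' must be a positive integer")
    if "seed" not in out or not isinstance(out["seed"], int):
        raise ConfigurationError("config field 'seed' must be an integer")
    if out["smoothing_fwhm_mm"] < 0:
        raise ConfigurationError("config field 'smoothing_fwhm_mm' must be >= 0")
    if not isinstance(out["modalities"], list) or not out["modalities"]:
        raise ConfigurationError("config field 'modalities' must be a non-empty list")
    for c in out["contrasts"]:
        if not (isinstance(c, (list, tuple)) and len(c) == 2):
            raise ConfigurationError(
                "config field 'contrasts' must hold [groupA, groupB] pairs"
            )
    if "synthetic" not in out and "inputs" not in out:
        raise ConfigurationError("config needs a 'synthetic' or an 'inputs' block")
    return out


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_synthetic(cfg: dict, geometry: Geometry):
    syn = cfg["synthetic"] or {}
    spec_kwargs = {k: v for k, v in syn.get("cohort", {}).items()}
    if "age_mean_sd" in spec_kwargs:
        spec_kwargs["age_mean_sd"] = {
            g: tuple(v) for g, v in spec_kwargs["age_mean_sd"].items()
        }
    spec = CohortSpec(seed=cfg["seed"], **spec_kwargs)
    cohort = generate_cohort(spec)
    if "truth" in syn:
        truth = EffectTruth.from_dict(syn["truth"])
    else:
        truth = EffectTruth.toy(geometry)
        for item in syn.get("group_effects", []):
            g, m, val = item["group"], item["modality"], item["effect"]
            space = truth.space_of[m]
            n = geometry.n_locations(space)
            eff = np.zeros(n)
            sl = item.get("locations")
            eff[slice(*sl) if sl else slice(None)] = val
            truth.group_effects[(g, m)] = eff
    ss = np.random.SeedSequence(cfg["seed"])
    seeds = [int(s) for s in ss.generate_state(len(cfg["modalities"]) + 1) % (2**31)]
    maps = {
        m: generate_scalar_maps(cohort, truth, geometry, m, seeds[i])
        for i, m in enumerate(cfg["modalities"])
    }
    masks = (
        generate_lesion_masks(cohort, truth, geometry, seeds[-1])
        if truth.lesion_prob
        else []
    )
    return cohort, truth, maps, masks


def _load_inputs(cfg: dict, geometry: Geometry):
    inp = cfg["inputs"]
    cohort = io.read_covariates(inp["covariates"])
    maps: dict[str, list[ScalarMap]] = {}
    for m in cfg["modalities"]:
        src = inp["maps"][m]
        if str(src).endswith(".csv"):
            maps[m] = io.read_surface_maps(src, m)
        else:
            maps[m] = [
                io.read_skeleton_map(p, geometry, m, subject_id=Path(p).stem)
                for p in sorted(Path(src).glob("*.nii*"))
            ]
    masks = [
        io.read_lesion_mask(p) for p in sorted(Path(inp["masks"]).glob("*.nii*"))
    ] if inp.get("masks") else []
    return cohort, None, maps, masks


def run_pipeline(config, outdir) -> dict:
    """Run the full workflow; returns the summary dict (also written to disk)."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    geometry = (
        Geometry.from_dict(cfg["geometry"]) if "geometry" in cfg else Geometry.toy()
    )
    if "synthetic" in cfg:
        cohort, truth, maps, masks = _build_synthetic(cfg, geometry)
        io.write_covariates(cohort, out / "covariates.csv")
        io.write_geometry(geometry, out / "geometry.json")
        if truth is not None:
            io.write_truth(truth, out / "truth.json")
    else:
        cohort, truth, maps, masks = _load_inputs(cfg, geometry)

    summary: dict = {"modalities": {}, "lesions": {}, "groups": {}}
    by_group = cohort.groupby("group")["subject_id"].apply(list).to_dict()
    patient_groups = [g for g in by_group if g != CONTROL]
    summary["groups"] = {g: len(ids) for g, ids in by_group.items()}

    # --- lesion frequency maps and comparisons ------------------------------
    if masks:
        mask_of = {m.subject_id: m for m in masks}
        freqdir = out / "freqmaps"
        freqdir.mkdir(exist_ok=True)
        for g in patient_groups:
            fmap = lesions.build_frequency_map([mask_of[s] for s in by_group[g]], g)
            io.write_volume(fmap.proportion, freqdir / f"{g}_freq.nii", geometry.voxel_size_mm)
        for ga, gb in cfg["contrasts"]:
            if ga in by_group and gb in by_group:
                sm = lesions.compare_lesion_frequency(
                    [mask_of[s] for s in by_group[ga]],
                    [mask_of[s] for s in by_group[gb]],
                    alpha=cfg["freq_alpha"],
                    contrast=(ga, gb),
                )
                io.write_statmap(sm, geometry, out / "statmaps", f"wmhfreq_{ga}_vs_{gb}")
                summary["lesions"][f"{ga} vs {gb}"] = {
                    "n_significant": sm.n_significant,
                    "n_in_mask": int(sm.in_mask.sum()),
                }

    # --- normative models, W-maps, contrasts per modality -------------------
    perm_seed_pool = np.random.SeedSequence(cfg["seed"] + 1).generate_state(
        len(cfg["modalities"]) * max(1, len(cfg["contrasts"]))
    ) % (2**31)
    seed_iter = iter(int(s) for s in perm_seed_pool)

    for modality in cfg["modalities"]:
        mod_maps = maps[modality]
        space = mod_maps[0].space
        if space == "surface" and cfg["smoothing_fwhm_mm"] > 0:
            mod_maps = [
                wscore.smooth_surface_map(m, geometry, cfg["smoothing_fwhm_mm"])
                for m in mod_maps
            ]
        map_of = {m.subject_id: m for m in mod_maps}
        control_maps = [map_of[s] for s in by_group.get(CONTROL, []) if s in map_of]
        model = wscore.fit_normative_model(control_maps, cohort)
        io.write_normative_model(model, out / "models" / modality)

        analysis_mask = None
        if modality == "FA" or (space == "skeleton" and "FA" in maps):
            fa_maps = maps.get("FA")
            if fa_maps:
                mean_fa = wscore.mean_map(
                    [m for m in fa_maps if m.subject_id in by_group.get(CONTROL, [])]
                    or fa_maps
                )
                analysis_mask = wscore.build_skeleton_mask(mean_fa, cfg["fa_threshold"])

        patient_ids = [s for g in patient_groups for s in by_group[g]]
        wmaps = wscore.compute_wscores(
            [map_of[s] for s in patient_ids if s in map_of],
            cohort,
            model,
            analysis_mask,
        )
        io.write_wscore_maps(wmaps, geometry, out / "wmaps" / modality)
        w_of = {wm.subject_id: wm for wm in wmaps}

        mod_summary: dict = {
            "space": space,
            "direction": wscore.abnormality_direction(modality)
            if modality in ("thickness", "FA", "MD")
            else "unknown",
            "contrasts": {},
        }
        for ga, gb in cfg["contrasts"]:
            seed = next(seed_iter)
            if ga not in by_group or gb not in by_group:
                continue
            wa = [w_of[s] for s in by_group[ga] if s in w_of]
            wb = [w_of[s] for s in by_group[gb] if s in w_of]
            raw = inference.massuni_ttest(wa, wb, alpha=cfg["alpha"], contrast=(ga, gb))
            if space == "surface":
                corrected = inference.correct_fdr(raw, q=cfg["q"])
            else:
                corrected = inference.correct_fwe_permutation(
                    wa,
                    wb,
                    n_perm=cfg["n_perm"],
                    seed=seed,
                    alpha=cfg["alpha"],
                    contrast=(ga, gb),
                )
            io.write_statmap(
                corrected, geometry, out / "statmaps", f"{modality}_{ga}_vs_{gb}"
            )
            mod_summary["contrasts"][f"{ga} vs {gb}"] = {
                "correction": corrected.correction,
                "n_significant": corrected.n_significant,
                "n_in_mask": int(corrected.in_mask.sum()),
            }

        # global means + ANCOVA across patient groups
        if len(patient_groups) >= 2:
            gmeans = {
                wm.subject_id: float(np.nanmean(wm.w))
                for wm in wmaps
                if np.isfinite(np.nanmean(wm.w))
            }
            try:
                gs = inference.global_ancova(
                    gmeans, cohort, groups=patient_groups, modality=modality
                )
                mod_summary["global"] = gs.to_dict()
            except Exception as exc:  # degenerate toy configs
                mod_summary["global"] = {"error": str(exc)}
        summary["modalities"][modality] = mod_summary

    provenance = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "normmap_version": _safe_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _safe_version() -> str:
    try:
        return pkg_version("normmap")
    except Exception:
        return "unknown"
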