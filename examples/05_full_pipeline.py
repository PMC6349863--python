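"""Run the full pipeline from one config and inspect the summary.

Simulates the default cohort, plants a thickness deficit and an FA deficit in
the sporadic group, then runs: lesion frequency maps and comparisons ->
normative fits -> W-maps -> FDR-corrected surface contrasts, permutation-FWE
skeleton contrasts -> global ANCOVA with Bonferroni post hoc. Outputs land in
a results directory with a provenance record; re-running the same config is
bit-identical.
"""

import json

from normmap import run_pipeline

config = {
    "seed": 17,
    "n_perm": 500,
    "modalities": ["thickness", "FA", "MD"],
    "synthetic": {
        "group_effects": [
            {"group": "SVCI_without_variants", "modality": "thickness",
             "effect": -0.3, "locations": [0, 400]},
            {"group": "SVCI_without_variants", "modality": "FA",
             "effect": -0.05, "locations": [0, 300]},
        ],
    },
}

summary = run_pipeline(config, "scratch/pipeline_demo")
print(json.dumps(summary["modalities"]["thickness"]["contrasts"], indent=2))
print(json.dumps(summary["modalities"]["FA"]["contrasts"], indent=2))
ancova = summary["modalities"]["thickness"]["global"]
print("thickness global ANCOVA p:", round(ancova["ancova_p"], 4))
# Contrasts involving the group with the planted deficits show hundreds of
# significant locations; the contrast between the two unaffected groups
# should show essentially none.
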