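"""Stage 4 — burn-depth classification on POD 3.

Two analyses: (a) the wound-metadata categorization rules (primary
protocol rule + secondary time-to-heal criterion + depth-score QC) on the
24-wound fixture; (b) ROC/AUC binary classifiers on the simulated study's
POD-3 per-wound HI, reported alongside the published operating points
HI > 3.54 (partial thickness) and HI < 6.58 (PT-Deep).
"""

import json
from pathlib import Path

import pandas as pd

from rrsburn.classification import (
    WoundRecord,
    adjust_depth_score,
    depth_score_qc,
    primary_categorize,
    secondary_categorize,
)
from rrsburn.pipeline import classify_pod
from rrsburn.synthetic import make_wound_table_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"


def categorize_wounds() -> pd.DataFrame:
    df = make_wound_table_fixture()
    out = []
    for _, row in df.iterrows():
        rec = WoundRecord(
            int(row.pig_id), int(row.wound_id), row.block_temp_c, row.contact_s,
            heal_pod=None if pd.isna(row.heal_pod) else int(row.heal_pod),
            depth_um=row.depth_um, epidermis_missing=bool(row.epidermis_missing),
        )
        rec.primary_category = primary_categorize(rec.block_temp_c, rec.contact_s)
        secondary_categorize(rec)
        depth_ok = None
        if rec.included:
            depth = adjust_depth_score(rec.depth_um, rec.epidermis_missing)
            depth_ok = depth_score_qc(rec.final_category, depth)
        out.append({"pig_id": rec.pig, "wound_id": rec.wound_id,
                    "primary": rec.primary_category, "final": rec.final_category,
                    "depth_qc_pass": depth_ok})
    return pd.DataFrame(out)


def main() -> None:
    cat = categorize_wounds()
    cat.to_csv(RESULTS / "wound_categorization.csv", index=False)
    counts = cat.final.value_counts().to_dict()
    print("final category counts after both criteria:", counts)
    print(f"secondary criterion excluded {counts.get('Excluded', 0)} "
          "partial-thickness wounds")
    qc = cat[cat.final != "Excluded"].depth_qc_pass
    print(f"depth-score QC passed for {int(qc.sum())}/{len(qc)} retained wounds")

    per_wound = pd.read_csv(RESULTS / "indices.csv")
    report = classify_pod(per_wound, pod=3)
    (RESULTS / "classification_pod3.json").write_text(
        json.dumps(report, indent=2, default=float)
    )
    for pair in ("pt_vs_superficial", "ptdeep_vs_ptsuperficial", "fullthickness_vs_pt"):
        r = report[pair]
        print(f"{pair}: AUC {r['auc']:.3f} (SE {r['se']:.3f}, p {r['p']:.2e}), "
              f"Youden cutoff {r['youden_cutoff']:.2f}")
    print("confusion at published cutoffs:",
          report["confusion_pt_cutoff"], report["confusion_pt_deep_cutoff"])
    print(f"wrote {RESULTS / 'classification_pod3.json'}")


if __name__ == "__main__":
    main()
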