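"""Stage 5 — trend statistics, heatmap clustering, and correlations.

Aggregates the per-wound HI table into the category x day heatmap (POD-7
gaps imputed as mean(POD 3, POD 14)), clusters the category trajectories,
runs the per-day ANOVA with Tukey comparisons on POD 3, and correlates
depth with time-to-heal on the wound fixture.
"""

import json
from pathlib import Path

import pandas as pd

from rrsburn.stats_report import (
    heatmap_matrix,
    pearson,
    per_day_anova,
    plot_heatmap,
    tukey_hsd,
)
from rrsburn.synthetic import make_wound_table_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    per_wound = pd.read_csv(RESULTS / "indices.csv")

    hm = heatmap_matrix(per_wound, "HI", seed=42)
    hm.matrix.to_csv(RESULTS / "heatmap.csv")
    plot_heatmap(hm, RESULTS / "heatmap.png")
    print("heatmap row order (hierarchical):", hm.row_order)
    print("closest category trajectories (first merge):", hm.first_merge)
    print("k-means (k=2) labels:", hm.kmeans_labels)

    anova = {}
    for pod in sorted(per_wound.pod.unique()):
        try:
            f, p = per_day_anova(per_wound, "HI", int(pod))
            anova[int(pod)] = {"F": f, "p": p}
        except ValueError:
            continue
    print("\nper-day one-way ANOVA of HI across categories:")
    for pod, r in anova.items():
        print(f"  POD {pod:>2}: F = {r['F']:9.2f}, p = {r['p']:.2e}")

    tukey3 = tukey_hsd(per_wound, "HI", 3)
    tukey3.to_csv(RESULTS / "tukey_pod3.csv", index=False)
    print("\nTukey HSD on POD 3:")
    print(tukey3.to_string(index=False))

    wounds = make_wound_table_fixture()
    healed = wounds[wounds.heal_pod.notna() & (wounds.block_temp_c != 96)]
    r, p = pearson(healed.depth_um, healed.heal_pod.astype(float))
    print(f"\ndepth vs time-to-heal (healed categories): r = {r:.2f}, p = {p:.1e}")

    (RESULTS / "report.json").write_text(json.dumps(
        {"per_day_anova_hi": {str(k): v for k, v in anova.items()},
         "heatmap_first_merge": list(hm.first_merge),
         "heatmap_row_order": list(hm.row_order),
         "depth_vs_heal_r": r, "depth_vs_heal_p": p},
        indent=2, default=float))
    print(f"\nwrote {RESULTS / 'report.json'}")


if __name__ == "__main__":
    main()
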