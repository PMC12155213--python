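"""Stage 3 — Hemoglobin/Fluorescence Indices with outlier screening.

Normalizes every site against the four same-pig same-day healthy-skin
measurements, pools the central-site HI values per category-day for
ROUT screening at Q = 2%, and averages the survivors into one index per
wound per day.
"""

from pathlib import Path

import pandas as pd

from rrsburn.pipeline import screen_and_average, site_indices

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    coeffs = pd.read_csv(RESULTS / "coefficients.csv")
    sites = site_indices(coeffs)
    sites.to_csv(RESULTS / "site_indices.csv", index=False, float_format="%.6g")

    per_wound, removals = screen_and_average(sites, q=0.02)
    per_wound.to_csv(RESULTS / "indices.csv", index=False, float_format="%.6g")
    removals.to_csv(RESULTS / "outlier_removals.csv", index=False)

    healthy = sites[(sites.category == "healthy") & (sites.kind == "HI")]
    print(f"healthy-site HI mean (self-normalized): {healthy.value.mean():.4f}")
    print(f"ROUT removed {len(removals)} site values")
    hi = per_wound[per_wound.kind == "HI"]
    table = hi.pivot_table(index="category", columns="pod", values="value")
    print("\nper-category mean HI by assessment day:")
    print(table.round(2).to_string())
    print(f"\nwrote {RESULTS / 'indices.csv'}")


if __name__ == "__main__":
    main()
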