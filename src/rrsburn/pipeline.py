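"""End-to-end pipeline: configuration, orchestration, and input validation.

All numeric constants of the analysis — crop window, polynomial degree,
averaging window, outlier FDR level, published HI cutoffs, depth-QC
windows, secondary-criterion days — live in :class:`PipelineConfig`, are
overridable, and round-trip losslessly through YAML.  ``run_pipeline``
chains simulate -> decompose -> indices -> outlier screening -> per-wound
averaging -> classification -> report, persisting every intermediate; the
same config and seed reproduce the bundle bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pydantic

from . import classification as cls
from .grid import WavenumberGrid
from .indices import (
    IndexValue,
    Measurement,
    hemoglobin_index,
    fluorescence_index,
    per_wound_index,
)
from .outliers import rout_outliers
from .stats_report import heatmap_matrix, per_day_anova, plot_heatmap
from .synthetic import SimulationConfig, StudyDesign, iter_study
from .unmixing import decompose

__all__ = [
    "PipelineConfig",
    "decompose_study",
    "site_indices",
    "screen_and_average",
    "classify_pod",
    "run_pipeline",
    "validate_inputs",
]

logger = logging.getLogger(__name__)


class PipelineConfig(pydantic.BaseModel):
    """Flat, serializable bag of every tunable the analysis uses."""

    crop_low: float = 600.0
    crop_high: float = 1700.0
    baseline_degree: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-4
    window: int = 180
    despike_z: float = 8.0
    outlier_q: float = 0.02
    cutoff_pt: float = 3.54
    cutoff_pt_deep: float = 6.58
    depth_superficial_max: float = 250.0
    depth_pt_boundary: float = 680.0
    depth_full_min: float = 1750.0
    epidermis_addition: float = 100.0
    pt_heal_cutoff: int = 56
    study_end: int = 64
    n_frames: int = 180
    noise_sd: float = 0.01
    spike_prob: float = 0.005
    seed: int = 0
    # instrument metadata — recorded for provenance, never computed on
    laser_wavelength_nm: float = 441.0
    laser_power_mw: float = 8.9

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def decompose_study(
    design: StudyDesign,
    cfg: SimulationConfig,
    config: PipelineConfig | None = None,
    days: list[int] | None = None,
) -> pd.DataFrame:
    """Simulate and decompose every acquisition of (a day-subset of) a study.

    Streams acquisition by acquisition so memory stays bounded.  Returns a
    per-site coefficients table with the simulation truth alongside.
    """
    from .synthetic import default_libraries

    config = config or PipelineConfig()
    libs = list(default_libraries(cfg.grid).values())
    rows = []
    for meta, truth, frames in iter_study(design, cfg, days):
        coeffs = decompose(
            frames,
            libs,
            window=config.window,
            z_threshold=config.despike_z,
            low=config.crop_low,
            high=config.crop_high,
            degree=config.baseline_degree,
            max_iter=config.baseline_max_iter,
            tol=config.baseline_tol,
        )
        rows.append(
            {**meta, "a": coeffs.a, "b": coeffs.b, "m_r": coeffs.m_r,
             "m_o": coeffs.m_o, "c": coeffs.c,
             "residual_rms": coeffs.residual_rms,
             "true_a": truth.a, "true_b": truth.b, "true_c": truth.c}
        )
    return pd.DataFrame(rows)


def _measurement(row) -> Measurement:
    from .unmixing import SignalCoefficients

    wound = "healthy" if row["wound_id"] is None or pd.isna(row["wound_id"]) else int(row["wound_id"])
    return Measurement(
        wound=wound, pig=int(row["pig_id"]), pod=int(row["pod"]),
        site=row["site"],
        coefficients=SignalCoefficients(
            a=row["a"], b=row["b"], m_r=row["m_r"], m_o=row["m_o"], c=row["c"]
        ),
    )


def site_indices(coeffs: pd.DataFrame) -> pd.DataFrame:
    """Per-site HI and FI, normalized within each pig-day.

    Healthy sites are indexed against their own pig-day mean too (their HI
    averages to exactly 1 per pig-day), which makes the normalization
    auditable in the output.
    """
    rows = []
    for (pig, pod), group in coeffs.groupby(["pig_id", "pod"]):
        healthy = [
            _measurement(r) for _, r in group[group["site"].str.startswith("healthy")].iterrows()
        ]
        for _, r in group.iterrows():
            m = _measurement(r)
            hi = hemoglobin_index(m, healthy)
            fi = fluorescence_index(m, healthy)
            base = {
                "pig_id": int(pig), "wound_id": m.wound, "site": r["site"],
                "category": r.get("category", ""), "pod": int(pod),
            }
            rows.append({**base, "kind": "HI", "value": hi.value})
            rows.append({**base, "kind": "FI", "value": fi.value})
    return pd.DataFrame(rows)


def screen_and_average(
    site_table: pd.DataFrame, q: float = 0.02
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROUT screening on pooled category-day site values, then per-wound means.

    The pooling unit is all central-site values of one index kind for one
    category on one day (across pigs).  Returns ``(per_wound, removals)``.
    """
    wound_rows = []
    removal_rows = []
    sub = site_table[site_table["category"] != "healthy"]
    for (cat, pod, kind), group in sub.groupby(["category", "pod", "kind"]):
        res = rout_outliers(group["value"].to_numpy(), q=q)
        kept = group.iloc[np.nonzero(res.kept_mask)[0]]
        for _, r in group.iloc[np.nonzero(~res.kept_mask)[0]].iterrows():
            removal_rows.append(
                {"category": cat, "pod": pod, "kind": kind,
                 "pig_id": r["pig_id"], "wound_id": r["wound_id"],
                 "site": r["site"], "value": r["value"]}
            )
        for (pig, wound), sites in kept.groupby(["pig_id", "wound_id"]):
            vals = [
                IndexValue(wound, pig, pod, kind, v)
                for v in sites["value"].to_numpy()
            ]
            agg = per_wound_index(vals)
            if agg is None:
                continue
            wound_rows.append(
                {"pig_id": pig, "wound_id": wound, "category": cat,
                 "pod": pod, "kind": kind, "value": agg.value,
                 "flags": ";".join(agg.flags)}
            )
    return pd.DataFrame(wound_rows), pd.DataFrame(removal_rows)


def classify_pod(
    per_wound: pd.DataFrame,
    pod: int = 3,
    config: PipelineConfig | None = None,
) -> dict:
    """ROC comparisons and fixed-cutoff confusion tables on one day's HI.

    Pairings (deeper category = positive class): combined PT vs Superficial
    (direction greater), PT-Deep vs PT-Superficial (less), Full-thickness
    vs combined PT (less).  Reports each pair's AUC/SE/p, the data-derived
    Youden cutoff, and the confusion at the published cutoffs 3.54 / 6.58.
    """
    config = config or PipelineConfig()
    hi = per_wound[(per_wound["kind"] == "HI") & (per_wound["pod"] == pod)]
    by_cat = {
        cat: g["value"].to_numpy(dtype=float) for cat, g in hi.groupby("category")
    }
    pt = np.concatenate(
        [by_cat.get("PT-Superficial", []), by_cat.get("PT-Deep", [])]
    )
    report: dict = {"pod": pod, "cutoffs": {
        "pt": config.cutoff_pt, "pt_deep": config.cutoff_pt_deep}}

    def pair(name, pos, neg, direction):
        if len(pos) == 0 or len(neg) == 0:
            return
        r = cls.roc(pos, neg, direction=direction)
        report[name] = {
            "auc": r.auc, "se": r.auc_se, "p": r.p_value,
            "n_pos": r.n_pos, "n_neg": r.n_neg, "direction": direction,
            "youden_cutoff": cls.youden_cutoff(r),
        }

    pair("pt_vs_superficial", pt, by_cat.get("Superficial", []), "greater")
    pair("ptdeep_vs_ptsuperficial",
         by_cat.get("PT-Deep", []), by_cat.get("PT-Superficial", []), "less")
    pair("fullthickness_vs_pt", by_cat.get("Full-thickness", []), pt, "less")

    if len(pt) and len(by_cat.get("Superficial", [])):
        sup = by_cat["Superficial"]
        tp = sum(cls.classify_hi(v, config.cutoff_pt, "greater") for v in pt)
        fp = sum(cls.classify_hi(v, config.cutoff_pt, "greater") for v in sup)
        report["confusion_pt_cutoff"] = {
            "sensitivity": tp / len(pt),
            "specificity": (len(sup) - fp) / len(sup),
        }
    if len(by_cat.get("PT-Deep", [])) and len(by_cat.get("PT-Superficial", [])):
        deep, sup = by_cat["PT-Deep"], by_cat["PT-Superficial"]
        tp = sum(cls.classify_hi(v, config.cutoff_pt_deep, "less") for v in deep)
        fp = sum(cls.classify_hi(v, config.cutoff_pt_deep, "less") for v in sup)
        report["confusion_pt_deep_cutoff"] = {
            "sensitivity": tp / len(deep),
            "specificity": (len(sup) - fp) / len(sup),
        }
    return report


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    design: StudyDesign | None = None,
    days: list[int] | None = None,
) -> dict:
    """Simulated-study pipeline: generate, decompose, index, screen,
    classify, and report, persisting every stage under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = design or StudyDesign()
    cfg = SimulationConfig(
        n_frames=config.n_frames, noise_sd=config.noise_sd,
        spike_prob=config.spike_prob, seed=config.seed,
    )
    stamp = {"config_hash": config.hash()}
    config.to_yaml(out / "config.yaml")

    coeffs = decompose_study(design, cfg, config, days)
    coeffs.to_csv(out / "coefficients.csv", index=False)
    logger.info("decomposed %d acquisitions", len(coeffs))

    sites = site_indices(coeffs)
    sites.to_csv(out / "site_indices.csv", index=False)

    per_wound, removals = screen_and_average(sites, q=config.outlier_q)
    per_wound.to_csv(out / "indices.csv", index=False)
    removals.to_csv(out / "outlier_removals.csv", index=False)
    logger.info(
        "outlier screening removed %d site values across %d pools",
        len(removals), sites.groupby(["category", "pod", "kind"]).ngroups,
    )

    use_days = list(design.days if days is None else days)
    report: dict = {**stamp, "n_acquisitions": int(len(coeffs)),
                    "n_outliers_removed": int(len(removals))}
    if 3 in use_days:
        report["classification_pod3"] = classify_pod(per_wound, 3, config)
    anova = {}
    for pod in use_days:
        try:
            f, p = per_day_anova(per_wound, "HI", pod)
            anova[str(pod)] = {"F": f, "p": p}
        except ValueError:
            pass
    report["per_day_anova_hi"] = anova
    if len(use_days) > 1:
        hm = heatmap_matrix(per_wound, "HI", seed=config.seed)
        hm.matrix.to_csv(out / "heatmap.csv")
        plot_heatmap(hm, out / "heatmap.png")
        report["heatmap_first_merge"] = list(hm.first_merge)
        report["heatmap_row_order"] = list(hm.row_order)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def validate_inputs(
    frames_dir=None, libs_dir=None, wounds_csv=None, coefficients_csv=None
) -> dict:
    """Report-only validation of pipeline inputs.

    Checks CSV headers and grid uniformity of frame/library files, the
    wound-metadata schema, and — on a coefficients table — that every
    pig-day carries exactly 4 healthy sites (the HI equation averages
    four healthy measurements) and at most 2 central sites per wound-day.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    from .io import read_frames_csv, read_library_csv, read_wound_table_csv

    if libs_dir is not None:
        paths = sorted(Path(libs_dir).glob("*.csv"))
        if not paths:
            errors.append(f"no library CSVs found in {libs_dir}")
        for p in paths:
            try:
                read_library_csv(p)
            except (ValueError, OSError) as e:
                errors.append(f"library {p.name}: {e}")
    if frames_dir is not None:
        paths = sorted(Path(frames_dir).glob("*.csv"))
        if not paths:
            errors.append(f"no frame CSVs found in {frames_dir}")
        for p in paths:
            try:
                seq = read_frames_csv(p)
                if seq.n_frames < 3:
                    warnings_.append(f"frames {p.name}: only {seq.n_frames} frames")
            except (ValueError, OSError) as e:
                errors.append(f"frames {p.name}: {e}")
    if wounds_csv is not None:
        try:
            read_wound_table_csv(wounds_csv)
        except (ValueError, OSError) as e:
            errors.append(f"wound table: {e}")
    if coefficients_csv is not None:
        try:
            df = pd.read_csv(coefficients_csv)
            healthy = df[df["site"].astype(str).str.startswith("healthy")]
            for (pig, pod), g in healthy.groupby(["pig_id", "pod"]):
                if len(g) != 4:
                    errors.append(
                        f"pig {pig} POD {pod}: {len(g)} healthy sites; the HI "
                        "normalization requires exactly 4 healthy measurements"
                    )
            wound = df[~df["site"].astype(str).str.startswith("healthy")]
            for (pig, w, pod), g in wound.groupby(["pig_id", "wound_id", "pod"]):
                if len(g) > 2:
                    errors.append(
                        f"pig {pig} wound {w} POD {pod}: {len(g)} central sites (max 2)"
                    )
        except (ValueError, OSError, KeyError) as e:
            errors.append(f"coefficients table: {e}")
    return {"errors": errors, "warnings": warnings_, "ok": not errors}
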