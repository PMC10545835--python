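"""End-to-end orchestration: simulate/load -> fit -> correlate -> stage.

A single declarative :class:`PipelineConfig` (optionally loaded from YAML)
drives the whole analysis; one top-level seed is split deterministically
per stage (study generation uses the seed itself, cross-validation uses
seed + 1).  Outputs are plain CSV/JSON files: per-condition fitted-optics
tables (samples x days), per-fruit correlation tables, staging reports,
and a run log recording package versions, the seed, and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, asdict, fields as dataclass_fields

import numpy as np
import pandas as pd
import yaml

from .forward_model import SlabGeometry
from .instrument import TimeGrid
from .inverse_fit import FitConfig, fit_optical_properties
from .preprocess import difference_profile, savitzky_golay_smooth
from .staging import (
    StagingReport,
    assign_softening_classes,
    class_thresholds,
    fit_pca,
    pca_scores,
    select_components,
    train_classify_svm,
)
from .study_analysis import build_correlation_table
from .synthetic_data import StudyConfig, StudyDataset, generate_study
from . import io as kio

__all__ = [
    "StagingConfig",
    "PipelineConfig",
    "fit_study",
    "condition_difference_matrix",
    "run_pipeline",
]


@dataclass(frozen=True)
class StagingConfig:
    folds: int = 5
    kernel: str = "linear"
    C: float = 1.0
    n_classes: int = 3
    n_components: int = 3
    n_candidates: int = 10
    explicit_components: tuple | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative settings for one full pipeline run."""

    seed: int = 0
    simulate: bool = True
    fixture_dir: str | None = None
    smooth_before_fit: bool = False
    smooth_before_pca: bool = True
    sg_poly_order: int = 2
    sg_frame_length: int = 5
    study: StudyConfig = field(default_factory=StudyConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    staging: StagingConfig = field(default_factory=StagingConfig)
    out_dir: str = "kiwitrts-out"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_cls, payload: dict):
            allowed = {f.name for f in dataclass_fields(dc_cls)}
            unknown = set(payload) - allowed
            if unknown:
                raise ValueError(
                    f"unknown {dc_cls.__name__} key(s): {sorted(unknown)}"
                )
            return payload

        data = dict(data)
        build(cls, data)
        for key, sub_cls in (
            ("study", StudyConfig),
            ("fit", FitConfig),
            ("staging", StagingConfig),
        ):
            if key in data and isinstance(data[key], dict):
                payload = build(sub_cls, data[key])
                for tup_key in list(payload):
                    if isinstance(payload[tup_key], list):
                        payload[tup_key] = tuple(payload[tup_key])
                if key == "study" and "grid" in payload and isinstance(payload["grid"], dict):
                    payload["grid"] = TimeGrid(**payload["grid"])
                data[key] = sub_cls(**payload)
        # seed propagates into the study config unless the study sets its own
        cfg = cls(**data)
        if "study" not in data or data["study"].seed == StudyConfig().seed:
            cfg = cls(**{**data, "study": _replace_seed(cfg.study, cfg.seed)})
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _replace_seed(study: StudyConfig, seed: int) -> StudyConfig:
    d = asdict(study)
    d["grid"] = study.grid
    d["seed"] = seed
    for key in ("shelf_days", "cold_days", "mu_s0_clip", "mu_a_clip",
                "color_base", "color_base_sd", "color_slope"):
        d[key] = tuple(d[key])
    return StudyConfig(**d)


def fit_study(
    study: StudyDataset,
    fit_config: FitConfig | None = None,
    smooth: bool = False,
    sg_poly_order: int = 2,
    sg_frame_length: int = 5,
) -> pd.DataFrame:
    """Fit (mu_a, mu_s') for every TRP of a study; one row per (sample, day).

    The slab thickness for each fit is the fruit's measured diameter.
    """
    fit_config = fit_config or FitConfig()
    diameters = study.records.set_index(["sample_id", "day"])["diameter_mm"]
    rows = []
    for (sid, day), trp in study.trps.items():
        profile = trp
        if smooth:
            profile = savitzky_golay_smooth(trp, sg_poly_order, sg_frame_length)
        geom = SlabGeometry(thickness_s=float(diameters.loc[(sid, day)]))
        try:
            res = fit_optical_properties(profile, study.irf, geom, fit_config)
        except Exception as exc:
            raise RuntimeError(
                f"inverse fit failed for sample {sid} day {day}: {exc}"
            ) from exc
        rows.append(
            {
                "sample_id": sid,
                "condition": trp.meta.get("condition"),
                "day": day,
                "diameter_mm": geom.thickness_s,
                "mu_a": res.props.mu_a,
                "mu_s_prime": res.props.mu_s_prime,
                "amplitude": res.amplitude,
                "residual_norm": res.residual_norm,
                "converged": res.converged,
                "at_bound": ";".join(sorted(res.at_bound)),
            }
        )
    return pd.DataFrame(rows)


def condition_difference_matrix(
    study: StudyDataset,
    condition: str,
    smooth: bool = True,
    sg_poly_order: int = 2,
    sg_frame_length: int = 5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack day-0 difference spectra of one condition into a matrix.

    Returns (matrix, meta) where meta has one row per matrix row with
    sample_id, day, and firmness pulled from the study records.
    """
    recs = study.records[study.records["condition"] == condition]
    if recs.empty:
        raise ValueError(f"no records for condition {condition!r}")
    rows, meta = [], []
    firmness = recs.set_index(["sample_id", "day"])["firmness_N_cm2"]
    for sid in recs["sample_id"].unique():
        days = sorted(recs.loc[recs["sample_id"] == sid, "day"])
        day0 = days[0]
        prof0 = study.trps[(sid, day0)]
        if smooth:
            prof0 = savitzky_golay_smooth(prof0, sg_poly_order, sg_frame_length)
        for day in days:
            prof = study.trps[(sid, day)]
            if smooth:
                prof = savitzky_golay_smooth(prof, sg_poly_order, sg_frame_length)
            diff = difference_profile(prof, prof0)
            rows.append(diff.delta_counts)
            meta.append(
                {
                    "sample_id": sid,
                    "day": day,
                    "firmness_N_cm2": float(firmness.loc[(sid, day)]),
                }
            )
    return np.vstack(rows), pd.DataFrame(meta)


def _wide_fit_table(fits: pd.DataFrame, condition: str) -> pd.DataFrame:
    sub = fits[fits["condition"] == condition]
    out = {}
    for name in ("mu_a", "mu_s_prime"):
        wide = sub.pivot(index="sample_id", columns="day", values=name)
        wide.columns = pd.MultiIndex.from_product([[name], wide.columns])
        out[name] = wide
    return pd.concat(out.values(), axis=1)


def _stage_condition(
    study: StudyDataset,
    condition: str,
    cfg: PipelineConfig,
) -> tuple[StagingReport, pd.DataFrame]:
    matrix, meta = condition_difference_matrix(
        study, condition, cfg.smooth_before_pca, cfg.sg_poly_order, cfg.sg_frame_length
    )
    st = cfg.staging
    pca = fit_pca(matrix)
    scores = pca_scores(pca, matrix)
    labels = assign_softening_classes(
        meta["firmness_N_cm2"].to_numpy(), st.n_classes
    )
    selected = select_components(
        pca,
        scores,
        labels,
        k=st.n_components,
        n_candidates=st.n_candidates,
        explicit=list(st.explicit_components) if st.explicit_components else None,
    )
    report = train_classify_svm(
        scores[:, selected],
        labels,
        folds=st.folds,
        seed=cfg.seed + 1,
        C=st.C,
        kernel=st.kernel,
        thresholds=class_thresholds(meta["firmness_N_cm2"].to_numpy(), labels),
        selected_components=selected,
    )
    pc1 = pd.DataFrame(
        {
            "sample_id": meta["sample_id"],
            "day": meta["day"],
            "pc1_score": scores[:, 0],
        }
    )
    return report, pc1


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full analysis and write its bundle under ``config.out_dir``.

    Returns a dict with the in-memory objects: the study, the fits frame,
    per-condition correlation tables and staging reports, and the run log.
    Deterministic for a fixed config.
    """
    cfg = config or PipelineConfig()
    os.makedirs(cfg.out_dir, exist_ok=True)

    if cfg.simulate:
        study = generate_study(_replace_seed(cfg.study, cfg.seed))
    else:
        if not cfg.fixture_dir:
            raise ValueError("fixture_dir is required when simulate=False")
        study = kio.read_study(cfg.fixture_dir)

    fits = fit_study(
        study, cfg.fit, cfg.smooth_before_fit, cfg.sg_poly_order, cfg.sg_frame_length
    )
    fits_path = os.path.join(cfg.out_dir, "fits.csv")
    fits.to_csv(fits_path, index=False, float_format="%.6g")

    conditions = list(study.records["condition"].unique())
    correlations = {}
    reports = {}
    for cond in conditions:
        _wide_fit_table(fits, cond).to_csv(
            os.path.join(cfg.out_dir, f"fit_table_{cond}.csv"), float_format="%.6g"
        )
        report, pc1 = _stage_condition(study, cond, cfg)
        reports[cond] = report

        recs = study.records[study.records["condition"] == cond]
        merged = recs.merge(
            fits[["sample_id", "day", "mu_a", "mu_s_prime"]],
            on=["sample_id", "day"],
        ).merge(pc1, on=["sample_id", "day"])
        table = build_correlation_table(merged)
        correlations[cond] = table
        table.to_csv(
            os.path.join(cfg.out_dir, f"correlations_{cond}.csv"),
            float_format="%.2f",
        )
        np.savetxt(
            os.path.join(cfg.out_dir, f"confusion_{cond}.csv"),
            report.confusion_matrix,
            fmt="%d",
            delimiter=",",
        )
        with open(
            os.path.join(cfg.out_dir, f"staging_{cond}.json"), "w", encoding="utf-8"
        ) as fh:
            json.dump(
                {
                    "condition": cond,
                    "class_thresholds_N_cm2": report.class_thresholds,
                    "selected_components": report.selected_components,
                    "fold_accuracies": report.fold_accuracies,
                    "overall_accuracy": report.overall_accuracy,
                    "folds": report.folds,
                    "seed": report.seed,
                },
                fh,
                indent=2,
            )

    import sklearn
    import scipy

    log = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "versions": {
            "kiwitrts": _package_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "n_profiles": len(study.trps),
        "conditions": conditions,
        "config": cfg.to_dict(),
    }
    with open(os.path.join(cfg.out_dir, "run_log.json"), "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=str)

    return {
        "study": study,
        "fits": fits,
        "correlations": correlations,
        "staging": reports,
        "log": log,
    }


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("kiwitrts")
    except Exception:  # pragma: no cover
        return "unknown"
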