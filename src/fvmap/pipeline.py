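"""End-to-end pipeline: simulate -> fit -> segment -> summarize -> analyze.

A single JSON configuration object with fully materialized defaults drives
every stage; unknown keys are rejected so typos cannot silently fall back to
defaults. The SHA-256 hash of the canonical (sorted, whitespace-free) JSON is
stamped into every stage artifact; a resumed run refuses to mix stages
produced under different configurations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as fio
from .curve_processing import CantileverSpec, FitOptions, process_bundle
from .group_analysis import study_report
from .map_segmentation import segment_map
from .modulus_summary import build_study_table, summarize_eye
from .synthetic_data import (
    AcquisitionSpec,
    GroupSpec,
    PhantomSpec,
    StudyDesign,
    default_study_design,
    simulate_fv_bundle,
    simulate_study,
)

logger = logging.getLogger("fvmap")

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "config_hash"]

STAGES = ("simulate", "fit", "segment", "summarize", "analyze")


class ConfigError(ValueError):
    pass


def _dataclass_defaults(cls) -> dict:
    out = {}
    for f in dataclasses.fields(cls):
        if f.default is not dataclasses.MISSING:
            v = f.default
        elif f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
            v = f.default_factory()  # type: ignore[misc]
        else:
            continue
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def _merge_section(name: str, defaults: dict, override: dict) -> dict:
    unknown = set(override) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown keys in config section '{name}': {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(override)
    return merged


@dataclasses.dataclass
class PipelineConfig:
    """Fully materialized pipeline configuration.

    Construct with :meth:`from_dict` (or :meth:`load` for a JSON file); every
    section falls back to package defaults and unknown keys raise
    :class:`ConfigError`.
    """

    cantilever: dict
    acquisition: dict
    phantom: dict
    study: dict
    segmentation: dict
    summary: dict
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict | None = None) -> "PipelineConfig":
        cfg = dict(cfg or {})
        seed = int(cfg.pop("seed", 0))
        sections = {
            "cantilever": _dataclass_defaults(CantileverSpec),
            "acquisition": _dataclass_defaults(AcquisitionSpec),
            "phantom": _dataclass_defaults(PhantomSpec),
            "study": {
                "baseline_glial_modulus_pa": 15_000.0,
                "baseline_axon_modulus_pa": 5_000.0,
                "between_eye_cv": 0.15,
                "include_drug_control": True,
                "groups": None,  # list of group dicts, or None for the default arms
            },
            "segmentation": {
                "n_levels": 256,
                "lo_percentile": 1.0,
                "hi_percentile": 99.0,
                "log_scale": False,
            },
            "summary": {"method": "kde"},
            "fit": _dataclass_defaults(FitOptions),
        }
        merged = {}
        for name, defaults in sections.items():
            merged[name] = _merge_section(name, defaults, cfg.pop(name, {}))
        unknown = set(cfg)
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        fit = merged.pop("fit")
        obj = cls(seed=seed, **merged)
        obj.fit_options = fit  # type: ignore[attr-defined]
        return obj

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit"] = dict(self.fit_options)  # type: ignore[attr-defined]
        return d

    def hash(self) -> str:
        return config_hash(self.to_dict())

    # --- typed views -------------------------------------------------------
    def cantilever_spec(self) -> CantileverSpec:
        return CantileverSpec(**self.cantilever)

    def acquisition_spec(self) -> AcquisitionSpec:
        acq = dict(self.acquisition)
        if "contact_window_nm" in acq:
            acq["contact_window_nm"] = tuple(acq["contact_window_nm"])
        return AcquisitionSpec(**acq)

    def phantom_spec(self) -> PhantomSpec:
        ph = dict(self.phantom)
        if "axon_diameter_range_um" in ph:
            ph["axon_diameter_range_um"] = tuple(ph["axon_diameter_range_um"])
        ph["grid_n"] = self.acquisition["grid_n"]
        ph["roi_size_um"] = self.acquisition["roi_size_um"]
        return PhantomSpec(**ph)

    def study_design(self) -> StudyDesign:
        s = self.study
        if s["groups"] is None:
            return default_study_design(
                baseline_glial_pa=s["baseline_glial_modulus_pa"],
                baseline_axon_pa=s["baseline_axon_modulus_pa"],
                between_eye_cv=s["between_eye_cv"],
                include_drug_control=s["include_drug_control"],
                seed=self.seed,
            )
        groups = tuple(GroupSpec(**g) for g in s["groups"])
        return StudyDesign(
            groups=groups,
            baseline_glial_modulus_pa=s["baseline_glial_modulus_pa"],
            baseline_axon_modulus_pa=s["baseline_axon_modulus_pa"],
            between_eye_cv=s["between_eye_cv"],
            seed=self.seed,
        )

    def fit_options_spec(self) -> FitOptions:
        fo = dict(self.fit_options)  # type: ignore[attr-defined]
        if "modulus_bounds_pa" in fo:
            fo["modulus_bounds_pa"] = tuple(fo["modulus_bounds_pa"])
        return FitOptions(**fo)


def config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stamp(out: Path, stage: str, cfg_hash: str, seed: int, counts: dict) -> None:
    from . import __version__

    (out / f".{stage}.done.json").write_text(
        json.dumps(
            {
                "stage": stage,
                "config_hash": cfg_hash,
                "seed": seed,
                "version": __version__,
                "counts": counts,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / f".{stage}.done.json"
    if not marker.exists():
        return False
    info = json.loads(marker.read_text())
    if info.get("config_hash") != cfg_hash:
        raise ConfigError(
            f"stage '{stage}' in {out} was produced under config {info.get('config_hash')}, "
            f"current config is {cfg_hash}; refusing to mix"
        )
    return True


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = False) -> dict:
    """Run (or resume) the full pipeline into ``out_dir``.

    Stage products: ``eyes/<eye_id>/`` bundle directories, per-eye modulus
    maps and class masks, ``study_table.csv`` and ``report.json``/``.md``.
    Returns a dict with the report and per-stage counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    seed = config.seed
    cantilever = config.cantilever_spec()
    acquisition = config.acquisition_spec()
    fit_options = config.fit_options_spec()
    counts: dict = {}

    # simulate ------------------------------------------------------------
    eyes_dir = out / "eyes"
    if not (resume and _stage_done(out, "simulate", cfg_hash)):
        design = config.study_design()
        sims = simulate_study(
            design, config.phantom_spec(), cantilever, acquisition, simulate_bundles=True
        )
        eye_index = []
        for info, phantom, bundle in sims:
            bdir = eyes_dir / info.eye_id
            fio.save_bundle(
                bundle,
                bdir,
                phantom=phantom,
                extra_metadata={"config_hash": cfg_hash, "eye": dataclasses.asdict(info)},
            )
            eye_index.append(dataclasses.asdict(info))
        (out / "eyes.json").write_text(json.dumps(eye_index, indent=2) + "\n")
        counts["simulate"] = {"eyes": len(eye_index)}
        _stamp(out, "simulate", cfg_hash, seed, counts["simulate"])
        logger.info("simulated %d eyes", len(eye_index))

    eye_index = json.loads((out / "eyes.json").read_text())

    # fit -----------------------------------------------------------------
    if not (resume and _stage_done(out, "fit", cfg_hash)):
        n_invalid = 0
        for eye in eye_index:
            bdir = eyes_dir / eye["eye_id"]
            bundle = fio.load_bundle(bdir)
            mmap, qc = process_bundle(bundle, cantilever, fit_options)
            fio.save_map(mmap, bdir)
            qc.to_csv(bdir / "fit_qc.csv", index=False)
            n_invalid += int((~qc["valid"]).sum())
        counts["fit"] = {"eyes": len(eye_index), "invalid_pixels": n_invalid}
        _stamp(out, "fit", cfg_hash, seed, counts["fit"])
        logger.info("fitted %d bundles (%d invalid pixels)", len(eye_index), n_invalid)

    # segment -------------------------------------------------------------
    if not (resume and _stage_done(out, "segment", cfg_hash)):
        sizes = []
        for eye in eye_index:
            bdir = eyes_dir / eye["eye_id"]
            mmap = fio.load_map(bdir / "modulus_map.tiff")
            seg = segment_map(mmap, **config.segmentation)
            fio.save_mask(seg, bdir)
            sizes.append(int((seg.class_mask == 1).sum()))
        counts["segment"] = {"eyes": len(eye_index), "median_glial_pixels": int(np.median(sizes))}
        _stamp(out, "segment", cfg_hash, seed, counts["segment"])

    # summarize -----------------------------------------------------------
    table_path = out / "study_table.csv"
    if not (resume and _stage_done(out, "summarize", cfg_hash)):
        records = []
        for eye in eye_index:
            bdir = eyes_dir / eye["eye_id"]
            mmap = fio.load_map(bdir / "modulus_map.tiff")
            seg_mask = fio.load_mask(bdir / "class_mask.csv")
            seg_meta = json.loads((bdir / "class_mask.json").read_text())
            from .map_segmentation import SegmentationResult

            seg = SegmentationResult(
                threshold_pa=seg_meta["threshold_pa"],
                class_mask=seg_mask,
                between_class_variance=seg_meta["between_class_variance"],
                quantization=(
                    seg_meta["quantization"]["n_levels"],
                    seg_meta["quantization"]["lo_pa"],
                    seg_meta["quantization"]["hi_pa"],
                ),
            )
            records.append(
                summarize_eye(
                    mmap,
                    seg,
                    eye_id=eye["eye_id"],
                    group_label=eye["group_label"],
                    week=eye["week"],
                    side=eye["side"],
                    arm=eye["arm"],
                    method=config.summary["method"],
                )
            )
        table = build_study_table(records)
        fio.save_table(table, table_path)
        counts["summarize"] = {"rows": len(table)}
        _stamp(out, "summarize", cfg_hash, seed, counts["summarize"])

    # analyze -------------------------------------------------------------
    if not (resume and _stage_done(out, "analyze", cfg_hash)):
        table = fio.load_table(table_path)
        report = study_report(table)
        report["config_hash"] = cfg_hash
        report["seed"] = seed
        fio.save_report(report, out, table)
        counts["analyze"] = {"classes": len(report["classes"])}
        _stamp(out, "analyze", cfg_hash, seed, counts["analyze"])

    report = json.loads((out / "report.json").read_text())
    return {"report": report, "counts": counts, "config_hash": cfg_hash}
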