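"""On-disk formats for bundles, maps, masks, tables and reports.

All schemas use fixed physical units — nm for displacement, nN for force,
Pa for moduli — and every JSON artifact carries a ``schema_version`` plus,
when produced by the pipeline, the configuration hash and seed.

* Force-volume bundle: a directory with ``metadata.json`` and either a
  ``curves.h5`` HDF5 container (default) or, in portable mode, per-curve
  two-column TSV files (piezo_nm, force_nN). Ground truth, when present, is
  stored as ``truth_modulus.csv`` / ``truth_mask.csv``.
* Modulus map: 32-bit float TIFF (invalid pixels NaN) plus a CSV twin.
* Class mask: paletted PNG (axon/glial/invalid) plus a CSV twin.
* Study table: CSV with 9-significant-digit decimal floats.
* Report: JSON plus a Markdown rendering and optional figures.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curve_processing import CantileverSpec, ForceCurve, ModulusMap
from .map_segmentation import (
    LABEL_AXON,
    LABEL_GLIAL,
    LABEL_INVALID,
    SegmentationResult,
)
from .synthetic_data import AcquisitionSpec, ForceVolumeBundle, GroundTruthPhantom

SCHEMA_VERSION = 1
FLOAT_FORMAT = "%.9g"

__all__ = [
    "FileFormatError",
    "save_bundle",
    "load_bundle",
    "save_map",
    "load_map",
    "save_mask",
    "load_mask",
    "save_table",
    "load_table",
    "save_report",
]


class FileFormatError(RuntimeError):
    pass


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _read_json(path: Path) -> dict:
    if not path.exists():
        raise FileFormatError(f"missing required file: {path}")
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FileFormatError(f"malformed JSON in {path}: line {exc.lineno}, col {exc.colno}") from exc


def save_bundle(
    bundle: ForceVolumeBundle,
    out_dir,
    phantom: GroundTruthPhantom | None = None,
    portable: bool = False,
    extra_metadata: dict | None = None,
) -> Path:
    """Write a force-volume bundle directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "bundle_id": bundle.bundle_id,
        "grid_n": bundle.grid_n,
        "pixel_pitch_nm": bundle.pixel_pitch_nm,
        "seed": bundle.seed,
        "cantilever": dataclasses.asdict(bundle.cantilever),
        "acquisition": dataclasses.asdict(bundle.acquisition),
        "storage": "tsv" if portable else "hdf5",
        "curve_errors": {str(k): v for k, v in bundle.curve_errors.items()},
        "units": {"piezo": "nm", "force": "nN"},
    }
    if extra_metadata:
        meta.update(extra_metadata)
    _write_json(out / "metadata.json", meta)

    if portable:
        cdir = out / "curves"
        cdir.mkdir(exist_ok=True)
        for idx, curve in enumerate(bundle.curves):
            if curve is None:
                continue
            i, j = divmod(idx, bundle.grid_n)
            np.savetxt(
                cdir / f"r{i:04d}_c{j:04d}.tsv",
                np.column_stack([curve.piezo_nm, curve.force_nN]),
                fmt=FLOAT_FORMAT,
                delimiter="\t",
                header="piezo_nm\tforce_nN",
            )
    else:
        import h5py

        with h5py.File(out / "curves.h5", "w") as h5:
            for idx, curve in enumerate(bundle.curves):
                if curve is None:
                    continue
                g = h5.create_group(f"pixel_{idx:06d}")
                g.create_dataset("piezo_nm", data=curve.piezo_nm)
                g.create_dataset("force_nN", data=curve.force_nN)
                if curve.true_contact_index is not None:
                    g.attrs["true_contact_index"] = curve.true_contact_index
                if curve.true_modulus_pa is not None:
                    g.attrs["true_modulus_pa"] = curve.true_modulus_pa

    if phantom is not None:
        np.savetxt(out / "truth_modulus.csv", phantom.modulus_field, fmt=FLOAT_FORMAT, delimiter=",")
        np.savetxt(out / "truth_mask.csv", phantom.class_mask, fmt="%d", delimiter=",")
    return out


def load_bundle(bundle_dir) -> ForceVolumeBundle:
    """Read a bundle directory written by :func:`save_bundle`."""
    bdir = Path(bundle_dir)
    meta = _read_json(bdir / "metadata.json")
    grid_n = int(meta["grid_n"])
    cantilever = CantileverSpec(**meta["cantilever"])
    acq = meta["acquisition"]
    for key in ("axon_diameter_range_um", "contact_window_nm"):
        if key in acq:
            acq[key] = tuple(acq[key])
    acquisition = AcquisitionSpec(**acq)
    curves: list = [None] * (grid_n * grid_n)

    if meta.get("storage") == "tsv":
        cdir = bdir / "curves"
        for f in sorted(cdir.glob("r*_c*.tsv")):
            i, j = (int(f.stem[1:5]), int(f.stem[7:11]))
            data = np.loadtxt(f, delimiter="\t", skiprows=1, ndmin=2)
            curves[i * grid_n + j] = ForceCurve(piezo_nm=data[:, 0], force_nN=data[:, 1])
    else:
        import h5py

        h5path = bdir / "curves.h5"
        if not h5path.exists():
            raise FileFormatError(f"missing required file: {h5path}")
        with h5py.File(h5path, "r") as h5:
            for name, g in h5.items():
                idx = int(name.split("_")[1])
                curves[idx] = ForceCurve(
                    piezo_nm=g["piezo_nm"][()],
                    force_nN=g["force_nN"][()],
                    true_contact_index=int(g.attrs.get("true_contact_index", -1)) if "true_contact_index" in g.attrs else None,
                    true_modulus_pa=float(g.attrs["true_modulus_pa"]) if "true_modulus_pa" in g.attrs else None,
                )

    return ForceVolumeBundle(
        curves=curves,
        grid_n=grid_n,
        pixel_pitch_nm=float(meta["pixel_pitch_nm"]),
        cantilever=cantilever,
        acquisition=acquisition,
        seed=meta.get("seed"),
        bundle_id=meta.get("bundle_id", ""),
        curve_errors={int(k): v for k, v in meta.get("curve_errors", {}).items()},
    )


def save_map(mmap: ModulusMap, out_dir, stem: str = "modulus_map") -> Path:
    """Write a modulus map as float32 TIFF + CSV + sidecar metadata JSON."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values = np.where(mmap.valid_mask, mmap.values_pa, np.nan).astype(np.float32)
    tifffile.imwrite(out / f"{stem}.tiff", values)
    np.savetxt(out / f"{stem}.csv", values, fmt=FLOAT_FORMAT, delimiter=",")
    _write_json(
        out / f"{stem}.json",
        {
            "schema_version": SCHEMA_VERSION,
            "pixel_pitch_nm": mmap.pixel_pitch_nm,
            "provenance": mmap.provenance,
            "units": "Pa",
            "invalid_encoding": "NaN",
        },
    )
    return out / f"{stem}.tiff"


def load_map(path) -> ModulusMap:
    """Read a modulus map from TIFF or CSV (NaN encodes invalid pixels)."""
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"missing required file: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        values = np.asarray(tifffile.imread(path), dtype=float)
    else:
        try:
            values = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FileFormatError(f"malformed CSV map {path}: {exc}") from exc
    meta_path = path.with_suffix(".json")
    pitch = 0.0
    provenance = ""
    if meta_path.exists():
        meta = _read_json(meta_path)
        pitch = float(meta.get("pixel_pitch_nm", 0.0))
        provenance = meta.get("provenance", "")
    return ModulusMap(
        values_pa=values,
        valid_mask=np.isfinite(values) & (values > 0),
        pixel_pitch_nm=pitch,
        provenance=provenance,
    )


# PNG palette indices follow the CSV label values shifted by +1
_PALETTE = {LABEL_INVALID: (0, 0, 0), LABEL_AXON: (68, 119, 170), LABEL_GLIAL: (204, 102, 119)}


def save_mask(seg: SegmentationResult, out_dir, stem: str = "class_mask") -> Path:
    """Write a class mask as paletted PNG + CSV + segmentation report JSON."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = seg.class_mask
    img = np.zeros(mask.shape, dtype=np.uint8)
    img[mask == LABEL_AXON] = 1
    img[mask == LABEL_GLIAL] = 2
    pil = Image.fromarray(img, mode="P")
    palette = list(_PALETTE[LABEL_INVALID]) + list(_PALETTE[LABEL_AXON]) + list(_PALETTE[LABEL_GLIAL])
    pil.putpalette(palette + [0] * (768 - len(palette)))
    pil.save(out / f"{stem}.png")
    np.savetxt(out / f"{stem}.csv", mask, fmt="%d", delimiter=",")
    n_levels, lo_pa, hi_pa = seg.quantization
    _write_json(
        out / f"{stem}.json",
        {
            "schema_version": SCHEMA_VERSION,
            "threshold_pa": seg.threshold_pa,
            "between_class_variance": seg.between_class_variance,
            "quantization": {"n_levels": n_levels, "lo_pa": lo_pa, "hi_pa": hi_pa},
            "labels": {"invalid": LABEL_INVALID, "axon": LABEL_AXON, "glial": LABEL_GLIAL},
            "class_sizes": {
                "axon": int(np.sum(mask == LABEL_AXON)),
                "glial": int(np.sum(mask == LABEL_GLIAL)),
                "invalid": int(np.sum(mask == LABEL_INVALID)),
            },
        },
    )
    return out / f"{stem}.png"


def load_mask(path) -> np.ndarray:
    """Read a class-mask CSV (or PNG) back into a label array."""
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"missing required file: {path}")
    if path.suffix.lower() == ".png":
        from PIL import Image

        img = np.asarray(Image.open(path))
        mask = np.full(img.shape, LABEL_INVALID, dtype=np.int8)
        mask[img == 1] = LABEL_AXON
        mask[img == 2] = LABEL_GLIAL
        return mask
    try:
        return np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    except ValueError as exc:
        raise FileFormatError(f"malformed mask CSV {path}: {exc}") from exc


def save_table(table: pd.DataFrame, path) -> Path:
    """Write the study table as CSV with 9-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def load_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"missing required file: {path}")
    try:
        return pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FileFormatError(f"malformed table CSV {path}: {exc}") from exc


def save_report(report: dict, out_dir, table: pd.DataFrame | None = None) -> Path:
    """Write report.json + report.md (+ box/strip figures when a table is given)."""
    from .group_analysis import _render_markdown

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = dict(report)
    payload.setdefault("schema_version", SCHEMA_VERSION)
    _write_json(out / "report.json", payload)
    (out / "report.md").write_text(_render_markdown(report) + "\n")
    if table is not None:
        _save_figures(table, out)
    return out / "report.json"


def _save_figures(table: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for cls in sorted(table["tissue_class"].unique()):
        sub = table[(table["tissue_class"] == cls) & (table["side"] == "experimental")]
        weeks = sorted(sub["week"].unique())
        data = [sub.loc[sub["week"] == w, "typical_pa"] / 1000.0 for w in weeks]
        fig, ax = plt.subplots(figsize=(4.2, 3.2))
        ax.boxplot(data, tick_labels=[str(w) for w in weeks])
        for i, d in enumerate(data, start=1):
            ax.plot(np.full(len(d), i) + np.random.default_rng(0).uniform(-0.08, 0.08, len(d)),
                    d, "o", ms=3, alpha=0.6)
        ax.set_xlabel("duration of elevated IOP (weeks)")
        ax.set_ylabel("typical Young's modulus (kPa)")
        ax.set_title(cls)
        fig.tight_layout()
        fig.savefig(out / f"modulus_vs_week_{cls}.svg")
        plt.close(fig)
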