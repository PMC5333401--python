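"""Experiment-level wiring: simulate an image tree, analyse it, aggregate.

``simulate_experiment`` writes a synthetic experiment whose filenames
follow the platform convention (``day<d>/[<tag>_]Plate<id>_Strip<k>_<view>.png``)
plus a ``manifest.json`` recording the geometry, crop boxes, seed and
software version, and a ``plate_map.csv`` assigning treatments to wells.
``analyze_experiment`` consumes any directory laid out that way and
emits one trait row per well per view per session; ``aggregate_experiment``
reduces that table to treatment-level time courses.

Seeds: every well draws its growth seed from
``SeedSequence((seed, plate, strip, well))``, so a whole experiment is
reproducible from a single integer and individual wells can be re-grown
in isolation.  Each imaging session re-grows the well with the same seed
at the session's age; ontogeny is approximated per session, not tracked
between sessions.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .plates import PlateLayout, WellAddress, compose_image_name, parse_image_name, FilenameError
from .roots import SegmentationConfig, analyze_side_well, crop_wells
from .shoots import analyze_top_well
from .simulate import (
    GrowthParams,
    WellGeometry,
    phenotype_preset,
    render_rosette,
    render_side_view,
    render_strip,
    simulate_root_system,
)

__all__ = ["simulate_experiment", "analyze_experiment", "aggregate_experiment"]

#: Seedlings germinate and grow for a few days before treatment day 0.
BASE_AGE_DAYS = 3.0

TRAIT_COLUMNS = (
    ["root_mass", "invalid_mass"]
    + [f"q{i}{j}" for i in range(4) for j in range(4)]
    + ["leaf_area", "leaf_hue"]
)


def _well_seed(seed: int, plate: int, strip: int, well: int, session: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((seed, plate, strip, well, session))


def _to_uint8(image: np.ndarray) -> np.ndarray:
    return (np.clip(image, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def simulate_experiment(
    out_dir: str | Path,
    n_plates: int = 1,
    preset: str = "control",
    sessions: int = 1,
    seed: int = 0,
    geometry: WellGeometry | None = None,
    layout: PlateLayout | None = None,
    noise_sd: float = 0.02,
    experiment_tag: str | None = None,
    treatments: dict[int, GrowthParams] | None = None,
) -> dict:
    """Write a synthetic experiment image tree; returns the manifest.

    Assay strips grow under ``preset`` (or, if ``treatments`` maps strip
    index -> :class:`GrowthParams`, under those parameters); control
    strips always grow under the ``control`` preset.  Each session ``d``
    renders plants of age ``BASE_AGE_DAYS + d`` days.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if geometry is None:
        geometry = WellGeometry()
    if layout is None:
        layout = PlateLayout()
    control_params = phenotype_preset("control")
    preset_params = phenotype_preset(preset)

    files: list[dict] = []
    map_rows: list[dict] = []
    boxes_side = boxes_top = None
    for p in range(n_plates):
        plate_id = f"A{p + 1}"
        for strip in range(1, layout.strips_per_plate + 1):
            is_control = strip in layout.control_strip_positions
            if is_control:
                params, label = control_params, "control"
            elif treatments is not None and strip in treatments:
                params, label = treatments[strip], f"strip{strip}"
            else:
                params, label = preset_params, preset
            for well in range(1, layout.wells_per_strip + 1):
                map_rows.append(
                    {
                        "plate_id": plate_id,
                        "strip_index": strip,
                        "well_index": well,
                        "treatment": label,
                    }
                )
            for d in range(sessions):
                day_dir = out / f"day{d}"
                day_dir.mkdir(exist_ok=True)
                aged = GrowthParams(
                    **{
                        **params.__dict__,
                        "days": BASE_AGE_DAYS + d,
                    }
                )
                side_wells = []
                top_wells = []
                for well in range(1, layout.wells_per_strip + 1):
                    ss = _well_seed(seed, p, strip, well, d)
                    grow_seed, noise_seed, leaf_seed = [
                        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
                    ]
                    system = simulate_root_system(aged, geometry, seed=grow_seed)
                    side_wells.append(
                        render_side_view(
                            system, geometry, noise_sd=noise_sd, seed=noise_seed
                        )
                    )
                    n_leaves = 2 + int(round(0.8 * aged.days))
                    leaf_size = 5.0 + 1.3 * aged.days
                    top_wells.append(
                        render_rosette(
                            n_leaves,
                            leaf_size,
                            hue=110.0,
                            geometry=geometry,
                            noise_sd=noise_sd,
                            seed=leaf_seed,
                        )
                    )
                strip_side, boxes_side = render_strip(side_wells, background=0.08)
                strip_top, boxes_top = render_strip(top_wells, background=1.0)
                for view, img in (("Side", strip_side), ("Top", strip_top)):
                    addr = WellAddress(
                        plate_id=plate_id,
                        strip_index=strip,
                        view=view,
                        experiment_tag=experiment_tag,
                    )
                    name = compose_image_name(addr) + ".png"
                    iio.imwrite(day_dir / name, _to_uint8(img))
                    files.append({"day": d, "name": name})

    manifest = {
        "version": __version__,
        "seed": seed,
        "sessions": sessions,
        "n_plates": n_plates,
        "preset": preset,
        "noise_sd": noise_sd,
        "geometry": {
            "height_px": geometry.height_px,
            "width_px": geometry.width_px,
            "mm_per_px": geometry.mm_per_px,
            "top_view_px": geometry.top_view_px,
        },
        "crop_boxes_side": boxes_side,
        "crop_boxes_top": boxes_top,
        "files": sorted(files, key=lambda f: (f["day"], f["name"])),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    pd.DataFrame(map_rows).to_csv(out / "plate_map.csv", index=False)
    return manifest


def _empty_traits_frame() -> pd.DataFrame:
    cols = (
        ["experiment", "plate_id", "strip_index", "well_index", "view", "day"]
        + TRAIT_COLUMNS
        + ["hue_defined", "qc_flag"]
    )
    return pd.DataFrame(columns=cols)


def analyze_experiment(
    image_dir: str | Path,
    out_csv: str | Path | None = None,
    seg_config: SegmentationConfig | None = None,
    crop_boxes_side: list | None = None,
    crop_boxes_top: list | None = None,
) -> pd.DataFrame:
    """Extract per-well traits from every parseable image under ``image_dir``.

    Crop boxes default to the directory's ``manifest.json``.  Files whose
    names do not follow the convention are skipped with a warning; images
    that fail to read produce a QC-flagged row and the run continues.
    """
    root = Path(image_dir)
    manifest_path = root / "manifest.json"
    if (crop_boxes_side is None or crop_boxes_top is None) and manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        crop_boxes_side = crop_boxes_side or manifest.get("crop_boxes_side")
        crop_boxes_top = crop_boxes_top or manifest.get("crop_boxes_top")

    day_dirs = sorted(
        (d for d in root.glob("day*") if d.is_dir() and d.name[3:].isdigit()),
        key=lambda d: int(d.name[3:]),
    )
    sources = [(int(d.name[3:]), f) for d in day_dirs for f in sorted(d.iterdir())] + [
        (0, f) for f in sorted(root.iterdir()) if f.is_file()
    ]
    rows: list[dict] = []
    for day, path in sources:
        if path.suffix.lower() not in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
            continue
        try:
            addr = parse_image_name(path.name)
        except FilenameError as exc:
            warnings.warn(f"skipping {path.name}: {exc}", stacklevel=2)
            continue
        base = {
            "experiment": addr.experiment_tag or "",
            "plate_id": addr.plate_id,
            "strip_index": addr.strip_index,
            "view": addr.view,
            "day": day,
        }
        try:
            image = iio.imread(path)
        except Exception:
            rows.append({**base, "well_index": 0, "qc_flag": "read_error"})
            continue
        boxes = crop_boxes_side if addr.view == "Side" else crop_boxes_top
        if boxes is None:
            raise ValueError(
                "no crop boxes: provide them or a manifest.json in the image directory"
            )
        for well_addr, crop in crop_wells(image, boxes, addr):
            row = {**base, "well_index": well_addr.well_index, "qc_flag": ""}
            if addr.view == "Side":
                row.update(analyze_side_well(crop, seg_config).to_dict())
            else:
                row.update(analyze_top_well(crop).to_dict())
            rows.append(row)
    df = pd.DataFrame(rows) if rows else _empty_traits_frame()
    df = df.reindex(columns=_empty_traits_frame().columns)
    df = df.sort_values(
        ["day", "experiment", "plate_id", "strip_index", "view", "well_index"]
    ).reset_index(drop=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False, float_format="%.6f")
    return df


def traits_to_records(traits: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide per-well trait table into tidy (well, day, trait, value) records.

    Root traits come from Side rows, shoot traits from Top rows; undefined
    hues become missing values (dropped during aggregation).
    """
    side = traits[traits["view"] == "Side"]
    top = traits[traits["view"] == "Top"]
    root_cols = ["root_mass"] + [f"q{i}{j}" for i in range(4) for j in range(4)]
    parts = []
    if len(side):
        parts.append(
            side.melt(
                id_vars=["plate_id", "strip_index", "well_index", "day"],
                value_vars=[c for c in root_cols if c in side.columns],
                var_name="trait",
            )
        )
    if len(top):
        shoot = top.copy()
        shoot.loc[shoot["hue_defined"] == False, "leaf_hue"] = np.nan  # noqa: E712
        parts.append(
            shoot.melt(
                id_vars=["plate_id", "strip_index", "well_index", "day"],
                value_vars=[c for c in ("leaf_area", "leaf_hue") if c in shoot.columns],
                var_name="trait",
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["plate_id", "strip_index", "well_index", "day", "trait", "value"]
        )
    return pd.concat(parts, ignore_index=True)


def aggregate_experiment(
    traits_csv: str | Path | pd.DataFrame,
    plate_map_csv: str | Path | pd.DataFrame,
    out_csv: str | Path | None = None,
    plots_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Aggregate a per-well trait table into treatment time courses."""
    from .timecourse import aggregate

    traits = (
        traits_csv
        if isinstance(traits_csv, pd.DataFrame)
        else pd.read_csv(traits_csv)
    )
    plate_map = (
        plate_map_csv
        if isinstance(plate_map_csv, pd.DataFrame)
        else pd.read_csv(plate_map_csv)
    )
    records = traits_to_records(traits)
    agg = aggregate(records, plate_map)
    if out_csv is not None:
        agg.to_csv(out_csv, index=False, float_format="%.6f")
    if plots_dir is not None:
        _plot_timecourses(agg, Path(plots_dir))
    return agg


def _plot_timecourses(agg: pd.DataFrame, plots_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots_dir.mkdir(parents=True, exist_ok=True)
    for trait, sub in agg.groupby("trait"):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for treatment, curve in sub.groupby("treatment"):
            curve = curve.sort_values("day")
            ax.errorbar(
                curve["day"], curve["mean"], yerr=curve["se"], label=str(treatment),
                marker="o", capsize=2,
            )
        ax.set_xlabel("days after treatment")
        ax.set_ylabel(trait)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plots_dir / f"{trait}.png", dpi=120)
        plt.close(fig)


__all__.append("traits_to_records")
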