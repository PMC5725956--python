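"""Batch orchestration: images in, trait table and statistics out.

The measurement path per image is fixed and fully deterministic:

    segment -> clean -> trace -> smooth/resample -> calibrate -> orient
            -> organ profile

Images are grouped by the filename convention ``<group>_<specimen>_<position>``
(position A/B for fruit, A/B/C for endocarp; leaves take a single view and
may omit the position suffix).  Unreadable or failing images are skipped
with a logged reason; per-image warnings end up in a ``qc_warnings`` column
rather than only on stderr.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import contour as ct
from .endocarp import EndocarpParams, endocarp_profile
from .errors import EmptyGroupError, OrganMorphError
from .fruit import FruitParams, fruit_profile
from .leaf import LeafParams, leaf_profile
from .segmentation import (
    HSBRange,
    clean_mask,
    is_binary_image,
    mask_from_binary_image,
    threshold_hsb,
)

__all__ = ["RunConfig", "process_image", "run_batch", "write_trait_table"]

_FNAME_RE = re.compile(r"^(?P<group>.+)_(?P<specimen>[^_]+)_(?P<position>[ABC])$")
_FNAME_NOPOS_RE = re.compile(r"^(?P<group>.+)_(?P<specimen>[^_]+)$")

_ORGAN_POSITIONS = {"fruit": ("A", "B"), "leaf": ("A",), "endocarp": ("A", "B", "C")}


@dataclass
class RunConfig:
    organ: str  # fruit | leaf | endocarp
    pixels_per_cm: float
    hsb: HSBRange | None = None  # None: inputs must be pre-binarized
    invert: bool = True  # the HSB box usually describes the background
    window_frac: float = ct.DEFAULT_WINDOW_FRAC
    n_out: int = ct.DEFAULT_N_OUT
    orientation_mode: str = "principal-axis"
    fruit: FruitParams = field(default_factory=FruitParams)
    leaf: LeafParams = field(default_factory=LeafParams)
    endocarp: EndocarpParams = field(default_factory=EndocarpParams)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.organ not in _ORGAN_POSITIONS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be > 0")


def process_image(path, config: RunConfig) -> tuple[ct.Contour, list]:
    """Run the measurement path on one image; returns (contour, warnings)."""
    img = np.asarray(Image.open(path).convert("RGB"))
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if is_binary_image(img):
            mask = mask_from_binary_image(img)
        elif config.hsb is not None:
            mask = threshold_hsb(img, config.hsb, invert=config.invert)
        else:
            raise OrganMorphError(
                f"{path}: colour image but no HSB range configured"
            )
        mask = clean_mask(mask)
        c = ct.trace_boundary(mask)
        c = ct.smooth_resample(c, config.window_frac, config.n_out)
        c = ct.calibrate(c, config.pixels_per_cm)
        c = ct.normalize_orientation(c, config.orientation_mode)
        if config.organ == "leaf" and config.orientation_mode == "principal-axis":
            # principal-axis mode leaves the wider (blade) end up; leaves are
            # analyzed petiole-end up
            c = ct.flip_vertical(c)
    notes.extend(str(w.message) for w in caught)
    return c, notes


def _parse_name(stem: str) -> tuple[str, str, str]:
    m = _FNAME_RE.match(stem)
    if m:
        return m["group"], m["specimen"], m["position"]
    m = _FNAME_NOPOS_RE.match(stem)
    if m:
        return m["group"], m["specimen"], "A"
    raise OrganMorphError(f"filename {stem!r} does not match <group>_<specimen>[_<pos>]")


def run_batch(input_dir, config: RunConfig, output_dir=None) -> pd.DataFrame:
    """Measure every image under ``input_dir`` and assemble the trait table.

    Optionally writes ``traits.csv``, the statistics CSVs
    (``summary.csv``, ``anova.csv``, ``pairs.csv``) and a machine-readable
    ``run_log.json`` under ``output_dir``.  Raises
    :class:`EmptyGroupError` if a declared group yields no usable specimen.
    """
    input_dir = Path(input_dir)
    paths = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not paths:
        raise OrganMorphError(f"no images under {input_dir}")
    log: dict = {"config": _config_dict(config), "images": {}}

    specimens: dict[tuple, dict] = {}
    seen_groups = set()
    for p in paths:
        try:
            group, specimen, position = _parse_name(p.stem)
            seen_groups.add(group)
            c, notes = process_image(p, config)
        except OrganMorphError as exc:
            log["images"][p.name] = {"status": "skipped", "reason": str(exc)}
            continue
        specimens.setdefault((group, specimen), {})[position] = (c, notes)
        log["images"][p.name] = {"status": "ok", "warnings": notes}

    rows = []
    for (group, specimen), views in sorted(specimens.items()):
        notes = [n for _, ns in views.values() for n in ns]
        try:
            if config.organ == "fruit":
                traits = fruit_profile(views["A"][0],
                                       views.get("B", (None,))[0], config.fruit)
            elif config.organ == "leaf":
                traits = leaf_profile(views["A"][0], config.leaf)
            else:
                traits = endocarp_profile(
                    views.get("A", (None,))[0], views.get("B", (None,))[0],
                    views.get("C", (None,))[0], config.endocarp)
        except (OrganMorphError, KeyError) as exc:
            log["images"][f"{group}_{specimen}"] = {
                "status": "skipped", "reason": f"profile failed: {exc}"}
            continue
        row = {"group": group, "specimen": specimen}
        row.update(traits.as_row())
        row["qc_warnings"] = "; ".join(notes)
        rows.append(row)

    table = pd.DataFrame(rows)
    produced = set(table["group"]) if len(table) else set()
    missing = seen_groups - produced
    if missing:
        raise EmptyGroupError(f"groups with zero usable specimens: {sorted(missing)}")

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        write_trait_table(table, output_dir / "traits.csv")
        from .stats import stats_tables

        n_groups = table["group"].nunique()
        counts = table.groupby("group").size()
        if n_groups >= 2 and (counts >= 2).all():
            summary, anova, pairs = stats_tables(table, alpha=config.alpha)
            for name, df in (("summary", summary), ("anova", anova),
                             ("pairs", pairs)):
                _write_csv(df, output_dir / f"{name}.csv")
        with open(output_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)
    return table


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def write_trait_table(table: pd.DataFrame, path) -> None:
    """Write the trait table with 6-significant-digit numeric formatting."""
    _write_csv(table, path)


def _write_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, index=False)
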