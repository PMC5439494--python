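"""YAML configuration I/O for site, soil and rotation-schedule parameters.

Configuration files use field-sheet units (canopy covers and harvest indices
in percent, soil water contents in vol%); everything is converted to the
fractions the library uses internally on load, and back on save.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict
from pathlib import Path

import yaml

from .canopy import CropPhaseParams, RotationSchedule, RotationYear
from .forcing import SiteConfig
from .soil_water import SoilParams

__all__ = ["load_config", "save_config"]

# fields stored as percent / vol% in config files, fractions internally
_CROP_PERCENT_FIELDS = ("cc0", "hi", "hi_ini", "hi_length")
_SOIL_PERCENT_FIELDS = ("swc_fc", "swc_pwp", "swc_sat")


def _crop_from_file(d: dict) -> CropPhaseParams:
    d = dict(d)
    for f in _CROP_PERCENT_FIELDS:
        if f in d:
            d[f] = d[f] / 100.0
    return CropPhaseParams(**d)


def _crop_to_file(p: CropPhaseParams) -> dict:
    d = asdict(p)
    for f in _CROP_PERCENT_FIELDS:
        d[f] = d[f] * 100.0
    return d


def load_config(path: str | Path) -> tuple[SiteConfig, SoilParams, RotationSchedule]:
    """Read site, soil, and per-rotation-year crop parameters."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    site = SiteConfig(**raw["site"])
    soil_d = dict(raw["soil"])
    for f in _SOIL_PERCENT_FIELDS:
        if f in soil_d:
            soil_d[f] = soil_d[f] / 100.0
    soil = SoilParams(**soil_d)
    years = []
    for y in raw["rotation_years"]:
        emergence = y["emergence"]
        if not isinstance(emergence, _dt.date):
            emergence = _dt.date.fromisoformat(str(emergence))
        years.append(RotationYear(
            label=str(y["label"]),
            emergence=emergence,
            coppice=bool(y.get("coppice", False)),
            params=_crop_from_file(y["params"]),
        ))
    return site, soil, RotationSchedule(years=years)


def save_config(
    path: str | Path,
    site: SiteConfig,
    soil: SoilParams,
    schedule: RotationSchedule,
) -> None:
    soil_d = asdict(soil)
    for f in _SOIL_PERCENT_FIELDS:
        soil_d[f] = soil_d[f] * 100.0
    doc = {
        "site": asdict(site),
        "soil": soil_d,
        "rotation_years": [
            {
                "label": y.label,
                "emergence": y.emergence.isoformat(),
                "coppice": y.coppice,
                "params": _crop_to_file(y.params),
            }
            for y in schedule.years
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
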