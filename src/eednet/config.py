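"""Configuration objects for the simulator and the pipeline.

The shipped ``data/site_calibration.yaml`` holds the site-level location and
scale targets the generator emulates (transformed-scale biomarker means,
nutrient-density medians, deficiency prevalences, repeated-measure noise).
A :class:`SimConfig` selects how much of that design to draw (number of sites,
children per site, visit schedule, missingness) and carries the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

NUTRIENTS = [
    "iron", "zinc", "calcium", "vitamin_a", "vitamin_b6",
    "folate", "vitamin_b12", "vitamin_c", "protein",
]
#: diet variables retained in the multivariable network (folate and vitamin C
#: are screened out: collinear / no univariate signal)
NETWORK_NUTRIENTS = ["iron", "zinc", "calcium", "vitamin_a", "vitamin_b6", "vitamin_b12", "protein"]

EED_NODES = ["mpo", "neo", "aat", "lmz"]
INFLAMMATION_NODE = "agp"
OUTCOME_NODES = ["anemia", "low_ferritin", "high_tfr", "low_retinol", "low_zinc"]

_CAL_CACHE: dict[str, Any] | None = None


def load_calibration(path: str | Path | None = None) -> dict[str, Any]:
    """Load site calibration constants (the packaged defaults if no path)."""
    global _CAL_CACHE
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    if _CAL_CACHE is None:
        text = resources.files("eednet.data").joinpath("site_calibration.yaml").read_text()
        _CAL_CACHE = yaml.safe_load(text)
    return _CAL_CACHE


@dataclass
class SimConfig:
    """Settings for one synthetic cohort draw.

    ``site_effects`` maps observable name -> {site: latent-scale shift}; when
    empty, shifts are derived from the calibration file's site targets.
    ``missing_rates`` maps stream name (recalls, stool, lm, blood) to the
    probability that a scheduled observation is missing.
    """

    n_sites: int = 7
    children_per_site: int | dict[str, int] | None = None
    months: tuple[int, ...] = (9, 10, 11, 12, 13, 14, 15)
    stool_samples_per_child: int = 5
    lm_test_ages: tuple[int, ...] = (9, 15)
    site_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    calibration: dict[str, Any] = field(default_factory=load_calibration)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.stool_samples_per_child < 1 or self.stool_samples_per_child > 5:
            raise ValueError("stool_samples_per_child must be in 1..5")
        for stream, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {stream!r} outside [0, 1]: {rate}")
        if self.n_sites > len(self.calibration["sites"]):
            raise ValueError(
                f"n_sites={self.n_sites} exceeds the {len(self.calibration['sites'])} "
                "calibrated sites"
            )
        for obs, shifts in self.site_effects.items():
            missing = set(self.sites) - set(shifts)
            if missing:
                raise ValueError(f"site_effects[{obs!r}] missing sites: {sorted(missing)}")

    @property
    def sites(self) -> list[str]:
        return list(self.calibration["sites"][: self.n_sites])

    def n_children(self, site: str) -> int:
        if self.children_per_site is None:
            return int(self.calibration["children_per_site"][site])
        if isinstance(self.children_per_site, dict):
            return int(self.children_per_site[site])
        return int(self.children_per_site)

    def missing_rate(self, stream: str) -> float:
        return float(self.missing_rates.get(stream, 0.0))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cal = raw.pop("calibration_file", None)
        kwargs: dict[str, Any] = {}
        for key in ("n_sites", "children_per_site", "stool_samples_per_child",
                    "site_effects", "missing_rates", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "months" in raw:
            kwargs["months"] = tuple(raw["months"])
        if "lm_test_ages" in raw:
            kwargs["lm_test_ages"] = tuple(raw["lm_test_ages"])
        if cal:
            kwargs["calibration"] = load_calibration(cal)
        return cls(**kwargs)
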