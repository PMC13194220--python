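"""Run configuration with the published defaults.

Defaults reproduce the reference parameterization: 40 mm distal cutoff,
2 mm watershed margin, +/-30 degree rotation limits, objective weights
(a, b, c, d, e) = (105, 100, 4, 5, 60).  A YAML file with dotted sections
(frame / landmarks / initial / final) can override any subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .final_alignment import ObjectiveWeights
from .mesh_core import PlatePlanError


@dataclass(frozen=True)
class RunConfig:
    # frame
    z_cut_mm: float = 40.0
    side: str = "left"
    # landmarks
    area_factor: float = 4.0
    z_band_mm: float = 3.0
    poly_degree: int = 3
    slice_mm: float = 1.0
    # initial alignment
    margin_mm: float = 2.0
    contact_tol_mm: float = 0.05
    # final alignment
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    rot_limit_deg: float = 30.0
    ftol: float = 1e-6
    max_iter: int = 500

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise PlatePlanError(f"side must be left/right, got {self.side!r}")


_SECTIONS = {
    "frame": {"z_cut_mm": "z_cut_mm", "side": "side"},
    "landmarks": {
        "area_factor": "area_factor",
        "z_band_mm": "z_band_mm",
        "poly_degree": "poly_degree",
        "slice_mm": "slice_mm",
    },
    "initial": {"margin_mm": "margin_mm", "contact_tol_mm": "contact_tol_mm"},
    "final": {
        "rot_limit_deg": "rot_limit_deg",
        "ftol": "ftol",
        "max_iter": "max_iter",
    },
}


def load_config(path=None, side: str | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file and a side override."""
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        updates = {}
        for section, keys in _SECTIONS.items():
            for yaml_key, attr in keys.items():
                if yaml_key in raw.get(section, {}):
                    updates[attr] = raw[section][yaml_key]
        wraw = raw.get("final", {}).get("weights", {})
        if wraw:
            base = ObjectiveWeights()
            updates["weights"] = ObjectiveWeights(
                **{k: float(wraw.get(k, getattr(base, k))) for k in "abcde"}
            )
        cfg = replace(cfg, **updates)
    if side is not None:
        cfg = replace(cfg, side=side)
    return cfg
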