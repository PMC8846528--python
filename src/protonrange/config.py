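"""YAML/JSON run configuration -> phantom / beam / stopping-model objects."""

from __future__ import annotations

import json
from pathlib import Path

from .phantom import BeamSpec, MaterialComposition, PhantomSpec, StoppingModel, WATER_GEL

__all__ = ["load_config", "build_from_config"]


def load_config(path) -> dict:
    """Read a YAML or JSON config with ``phantom``, ``beam``, ``model`` keys."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def build_from_config(cfg: dict) -> tuple[PhantomSpec, BeamSpec, StoppingModel]:
    mat = WATER_GEL
    ph = cfg.get("phantom", {})
    if "material" in ph:
        m = ph["material"]
        mat = MaterialComposition(m["density_g_cm3"], m["mass_fractions"])
    phantom = PhantomSpec(
        size_mm=tuple(ph.get("size_mm", (100.0, 100.0, 400.0))),
        voxel_mm=tuple(ph.get("voxel_mm", (2.0, 2.0, 0.5))),
        material=mat,
    )
    b = cfg.get("beam", {})
    beam = BeamSpec(
        energy_MeV=float(b.get("energy_MeV", 80.0)),
        diameter_mm=float(b.get("diameter_mm", 10.0)),
        entry_xy_mm=tuple(b.get("entry_xy_mm", (0.0, 0.0))),
    )
    mo = cfg.get("model", {})
    mode = mo.get("mode", "bragg_kleeman")
    if mode == "bragg_kleeman":
        model = StoppingModel.bragg_kleeman(
            alpha_cm=float(mo.get("bk_alpha_cm", 0.0022)),
            p=float(mo.get("bk_p", 1.77)))
    elif mode == "table":
        model = StoppingModel.from_csv(mo["stopping_table_csv"])
    else:
        raise ValueError(f"unknown model mode {mode!r}")
    return phantom, beam, model
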