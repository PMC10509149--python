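"""YAML run-configuration: schema validation and object construction.

One config file describes a whole run: the beam, the material stack, the
dosimeter solution, the fibre optics, the camera acquisition and (for
simulations) the ground-truth yield model. Unknown keys and wrong types are
reported with their full key path.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np
import yaml

from . import chemistry, materials, simulate

__all__ = ["ConfigError", "load_config", "RunConfig", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """A config key is missing, unknown, or has the wrong type/value."""


DEFAULT_CONFIG: dict[str, Any] = {
    "beam": {
        "projectile": "proton",
        "energy_MeV": 64.0,
        "energy_spread_MeV": 0.3,
        "current_nA": 1.0,
        "diameter_mm": 8.0,
    },
    "stack": {
        "layers": [
            {"material": "pmma", "thickness_mm": 23.57},
            {"material": "super_fricke", "thickness_mm": 10.0, "sample": True},
        ]
    },
    "fricke": {},
    "optics": {
        "n_fibres": 20,
        "fibre_diameter_um": 250.0,
        "magnification": 8.0 / 9.0,
        "depth_offset_mm": 3.0,
        "path_length_cm": 0.8,
    },
    "acquisition": {
        "frame_period_s": 0.1,
        "duration_s": 60.0,
        "beam_on_time_s": 2.0,
        "noise_rel_intensity": 0.005,
        "flicker_rel": 0.0,
        "binning": 1,
    },
    "truth": {"yield_molec_per_100ev": 15.0},
    "elf": {"grid_step_mm": 0.01},
    "analysis": {"elf_floor_frac": 0.01, "single_charge": False, "scan": False},
    "seed": 1234,
}

_FRICKE_KEYS = {
    "conc_fe2_M": "conc_fe2",
    "conc_h2so4_M": "conc_h2so4",
    "conc_nacl_M": "conc_nacl",
    "conc_o2_M": "conc_o2",
    "epsilon_304": "epsilon_304",
    "density_g_cm3": "density",
    "dose_limit_fricke_Gy": "dose_limit_fricke",
    "dose_limit_super_Gy": "dose_limit_super",
    "dose_rate_limit_super_Gy_s": "dose_rate_limit_super",
}


def _require(d: dict, key: str, typ, path: str):
    if key not in d:
        raise ConfigError(f"missing key: {path}.{key}")
    v = d[key]
    if typ is float and isinstance(v, int) and not isinstance(v, bool):
        v = float(v)
    if not isinstance(v, typ):
        raise ConfigError(
            f"{path}.{key}: expected {getattr(typ, '__name__', typ)}, "
            f"got {type(v).__name__}"
        )
    return v


def _check_unknown(d: dict, allowed: set[str], path: str) -> None:
    extra = set(d) - allowed
    if extra:
        raise ConfigError(f"unknown key(s) at {path}: {sorted(extra)}")


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class RunConfig:
    """Validated configuration with constructed domain objects."""

    def __init__(self, raw: dict[str, Any]):
        if not isinstance(raw, dict):
            raise ConfigError("top level of the config must be a mapping")
        _check_unknown(set_path := raw, set(DEFAULT_CONFIG), "<root>")
        cfg = _merge(DEFAULT_CONFIG, raw)
        self.raw = cfg

        b = cfg["beam"]
        _check_unknown(b, {"projectile", "energy_MeV", "energy_spread_MeV",
                           "current_nA", "diameter_mm"}, "beam")
        try:
            projectile = materials.builtin_projectile(
                _require(b, "projectile", str, "beam")
            )
        except KeyError as exc:
            raise ConfigError(f"beam.projectile: {exc}") from None
        self.beam = materials.BeamSpec(
            projectile,
            mean_energy=_require(b, "energy_MeV", float, "beam"),
            energy_spread_sigma=_require(b, "energy_spread_MeV", float, "beam"),
            current=_require(b, "current_nA", float, "beam") * 1e-9,
            diameter=_require(b, "diameter_mm", float, "beam"),
        )

        st = cfg["stack"]
        _check_unknown(st, {"layers"}, "stack")
        layers, sample_index = [], None
        for i, layer in enumerate(_require(st, "layers", list, "stack")):
            path = f"stack.layers[{i}]"
            _check_unknown(layer, {"material", "thickness_mm", "sample"}, path)
            try:
                mat = materials.builtin_material(
                    _require(layer, "material", str, path)
                )
            except KeyError as exc:
                raise ConfigError(f"{path}.material: {exc}") from None
            layers.append((mat, _require(layer, "thickness_mm", float, path)))
            if layer.get("sample", False):
                if sample_index is not None:
                    raise ConfigError("stack: more than one sample layer")
                sample_index = i
        if sample_index is None:
            raise ConfigError("stack: no layer marked sample: true")
        self.stack = materials.MaterialStack(tuple(layers), sample_index)

        fr = cfg["fricke"]
        _check_unknown(fr, set(_FRICKE_KEYS), "fricke")
        overrides = {
            _FRICKE_KEYS[k]: _require(fr, k, float, "fricke") for k in fr
        }
        self.system = replace(chemistry.FrickeSystem(), **overrides)

        op = cfg["optics"]
        _check_unknown(op, {"n_fibres", "fibre_diameter_um", "magnification",
                            "depth_offset_mm", "path_length_cm"}, "optics")
        self.fibre_array = simulate.FibreArray(
            n_fibres=_require(op, "n_fibres", int, "optics"),
            fibre_diameter_um=_require(op, "fibre_diameter_um", float, "optics"),
            magnification=_require(op, "magnification", float, "optics"),
            depth_offset_mm=_require(op, "depth_offset_mm", float, "optics"),
        )
        self.path_length_cm = _require(op, "path_length_cm", float, "optics")

        ac = cfg["acquisition"]
        _check_unknown(ac, {"frame_period_s", "duration_s", "beam_on_time_s",
                            "noise_rel_intensity", "flicker_rel", "binning"},
                       "acquisition")
        self.acquisition = simulate.AcquisitionSpec(
            frame_period=_require(ac, "frame_period_s", float, "acquisition"),
            duration=_require(ac, "duration_s", float, "acquisition"),
            beam_on_time=_require(ac, "beam_on_time_s", float, "acquisition"),
            noise_rel_intensity=_require(
                ac, "noise_rel_intensity", float, "acquisition"
            ),
            flicker_rel=_require(ac, "flicker_rel", float, "acquisition"),
            binning=_require(ac, "binning", int, "acquisition"),
        )

        tr = cfg["truth"]
        _check_unknown(
            tr, {"yield_molec_per_100ev", "let_scaled", "diffusion_D_m2_s"},
            "truth",
        )
        self.truth_raw = tr

        el = cfg["elf"]
        _check_unknown(el, {"grid_step_mm", "import_tsv"}, "elf")
        self.elf_grid_step = _require(el, "grid_step_mm", float, "elf")
        self.elf_import = el.get("import_tsv")

        an = cfg["analysis"]
        _check_unknown(an, {"elf_floor_frac", "single_charge", "scan",
                            "n_points"}, "analysis")
        self.analysis = an
        self.seed = _require(cfg, "seed", int, "<root>")

    # -- derived constructions -------------------------------------------

    def depth_profile(self):
        from . import stopping

        if self.elf_import:
            return stopping.DepthProfile.from_tsv(self.elf_import)
        return stopping.bragg_elf_curve(
            self.beam, self.stack, grid_step=self.elf_grid_step
        )

    def ground_truth(self, profile=None) -> simulate.GroundTruth:
        if profile is None:
            profile = self.depth_profile()
        tr = self.truth_raw
        if "let_scaled" in tr:
            ls = tr["let_scaled"]
            g_lo = ls["g_min_molec_per_100ev"] * chemistry.MOL_PER_J_PER_MOLEC100EV
            g_hi = ls["g_max_molec_per_100ev"] * chemistry.MOL_PER_J_PER_MOLEC100EV
            rel = profile.elf / profile.elf.max() if profile.elf.max() > 0 else 0.0
            yields = g_hi - (g_hi - g_lo) * rel
        else:
            yields = np.full_like(
                profile.depth_grid,
                tr.get("yield_molec_per_100ev", 15.0)
                * chemistry.MOL_PER_J_PER_MOLEC100EV,
            )
        return simulate.GroundTruth(
            yield_profile=yields,
            elf=profile,
            beam=self.beam,
            system=self.system,
            diffusion_coeff=tr.get("diffusion_D_m2_s", simulate.FE3_DIFFUSION_COEFF),
            path_length_cm=self.path_length_cm,
        )


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML config file (or an already-parsed mapping)."""
    if isinstance(path_or_dict, dict):
        return RunConfig(path_or_dict)
    with open(path_or_dict) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(raw)
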