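"""Run configuration: YAML loading, validation, defaults, seed substreams."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from tfg.geometry import VectorDesign
from tfg.library import LibrarySpec, SubstitutionSpectrum
from tfg.screen import ScreenConfig

__all__ = ["RunConfig", "load_config", "default_config_dict", "stage_seed"]

# Offset of the mutagenized window start into the ORF (the upstream cloning
# site of the mutagenized fragment); chosen so the default in-ORF mutagenized
# length is 1,606 bp.
DEFAULT_WINDOW_ORF_OFFSET = 53

_DESIGN_KEYS = {
    "len5",
    "len_target",
    "len3",
    "dsb_pos",
    "dsb_offset_in_arm",
    "arm",
    "mutagenized_window",
}
_LIBRARY_KEYS = {
    "n_clones",
    "recombinant_fraction",
    "per_base_rate",
    "window",
    "spectrum",
    "transition_ratio",
}
_SCREEN_KEYS = {
    "n_transformants",
    "n_passages_selective",
    "cells_per_transfer",
    "final_density_cells",
    "nontransformed_survival_per_passage",
    "n_nontransformed_cells",
    "background_foar_fraction",
    "deleterious_missense_prob",
    "hypomorph_prob",
    "n_colonies_scored",
}
_TOP_KEYS = {"seed", "verbosity", "design", "library", "screen", "output"}
_OUTPUT_KEYS = {"outdir"}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, salted with the stage name.

    Adding a stage to a pipeline does not perturb the randomness of the
    others because each stream depends only on (global seed, stage name).
    """
    salt = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([global_seed, salt]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated pipeline configuration (design + library + screen blocks)."""

    design: VectorDesign
    library: LibrarySpec | None
    screen: ScreenConfig | None
    outdir: Path
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d: dict = {
            "seed": self.seed,
            "verbosity": self.verbosity,
            "design": {
                "len5": self.design.len5,
                "len_target": self.design.len_target,
                "len3": self.design.len3,
                "dsb_pos": self.design.dsb_pos,
                "mutagenized_window": list(self.design.mutagenized_window)
                if self.design.mutagenized_window
                else None,
            },
            "output": {"outdir": str(self.outdir)},
        }
        if self.library is not None:
            d["library"] = {
                "n_clones": self.library.n_clones,
                "recombinant_fraction": self.library.recombinant_fraction,
                "per_base_rate": self.library.per_base_rate,
                "window": list(self.library.window),
            }
        if self.screen is not None:
            s = asdict(self.screen)
            s.pop("seed", None)
            d["screen"] = s
        return d


def default_mutagenized_window(
    len5: int, len_target: int, dsb_pos: int
) -> tuple[int, int]:
    """Window from ``DEFAULT_WINDOW_ORF_OFFSET`` bp into the ORF to the DSB."""
    start = len5 + DEFAULT_WINDOW_ORF_OFFSET
    end = dsb_pos
    if start >= end:
        start, end = len5, len5 + len_target
    return (start, end)


def _reject_unknown(block: dict, allowed: set[str], name: str) -> None:
    for key in block:
        if key not in allowed:
            raise ValueError(f"unknown key '{key}' in {name} block")


def _build_design(block: dict) -> VectorDesign:
    _reject_unknown(block, _DESIGN_KEYS, "design")
    try:
        len5 = int(block.get("len5", 2500))
        len_target = int(block.get("len_target", 1659))
        len3 = int(block.get("len3", 800))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid arm length in design block: {exc}") from exc
    for name, v in (("len5", len5), ("len_target", len_target), ("len3", len3)):
        if v <= 0:
            raise ValueError(f"design key '{name}' must be positive, got {v}")
    L = len5 + len_target + len3
    if "dsb_pos" in block:
        dsb = int(block["dsb_pos"])
    else:
        offset = int(block.get("dsb_offset_in_arm", 400))
        arm = block.get("arm", "three-prime")
        if arm == "three-prime":
            # clamp so at least 1 bp of homology remains beyond the DSB
            dsb = len5 + len_target + min(offset, len3 - 1)
        elif arm == "five-prime":
            dsb = max(len5 - offset, 1)
        else:
            raise ValueError(f"design key 'arm' must be five-prime or three-prime, got {arm!r}")
    window = block.get("mutagenized_window")
    if window is None:
        window = default_mutagenized_window(len5, len_target, dsb)
    else:
        window = (int(window[0]), int(window[1]))
    try:
        return VectorDesign(len5, len_target, len3, dsb, window)
    except ValueError as exc:
        raise ValueError(f"invalid design block: {exc}") from exc


def _build_library(block: dict, design: VectorDesign, seed: int) -> LibrarySpec:
    _reject_unknown(block, _LIBRARY_KEYS, "library")
    spectrum_name = block.get("spectrum", "uniform")
    if spectrum_name == "uniform":
        spectrum = SubstitutionSpectrum.uniform()
    elif spectrum_name == "transition-biased":
        spectrum = SubstitutionSpectrum.transition_biased(
            float(block.get("transition_ratio", 4.0))
        )
    else:
        raise ValueError(
            f"library key 'spectrum' must be uniform or transition-biased, got {spectrum_name!r}"
        )
    window = block.get("window") or design.mutagenized_window
    try:
        return LibrarySpec(
            n_clones=int(block.get("n_clones", 17_000)),
            recombinant_fraction=float(block.get("recombinant_fraction", 0.9)),
            per_base_rate=float(block.get("per_base_rate", 1.0 / 434.0)),
            window=(int(window[0]), int(window[1])),
            spectrum=spectrum,
            seed=stage_seed(seed, "library"),
        )
    except ValueError as exc:
        raise ValueError(f"invalid library block: {exc}") from exc


def _build_screen(block: dict, seed: int) -> ScreenConfig:
    _reject_unknown(block, _SCREEN_KEYS, "screen")
    kwargs = {k: block[k] for k in block}
    try:
        return ScreenConfig(seed=stage_seed(seed, "screen"), **kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid screen block: {exc}") from exc


def config_from_dict(raw: dict, base_dir: Path | str = ".") -> RunConfig:
    """Validate a parsed configuration mapping and fill defaults."""
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top-level")
    seed = int(raw.get("seed", 0))
    verbosity = int(raw.get("verbosity", 1))
    design = _build_design(raw.get("design", {}) or {})
    library = None
    if "library" in raw:
        library = _build_library(raw["library"] or {}, design, seed)
    screen = None
    if "screen" in raw:
        if library is None:
            raise ValueError("screen requires library: add a library block")
        screen = _build_screen(raw["screen"] or {}, seed)
    out_block = raw.get("output", {}) or {}
    _reject_unknown(out_block, _OUTPUT_KEYS, "output")
    outdir = Path(base_dir) / out_block.get("outdir", "tfg_out")
    return RunConfig(design, library, screen, outdir, seed, verbosity)


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``overrides`` maps dotted keys (e.g. ``"library.n_clones"``) to values,
    mirroring the CLI ``--set key=value`` flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if overrides:
        for dotted, value in overrides.items():
            parts = dotted.split(".")
            node = raw if raw is not None else {}
            raw = node
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = value
    return config_from_dict(raw, base_dir=path.parent)


def default_config_dict() -> dict:
    """The study-condition defaults as a plain mapping (round-trips to YAML)."""
    cfg = config_from_dict(
        {"design": {}, "library": {}, "screen": {}, "seed": 0}, base_dir="."
    )
    return cfg.to_dict()
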