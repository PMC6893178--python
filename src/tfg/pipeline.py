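"""End-to-end pipeline: design profile -> library -> screen -> reports."""

from __future__ import annotations

import logging
from pathlib import Path

from tfg import io
from tfg.config import RunConfig, stage_seed
from tfg.geometry import retention_profile
from tfg.library import generate_template, simulate_library, summarize_library
from tfg.screen import simulate_screen
from tfg.stats import coverage_report

logger = logging.getLogger("tfg")

__all__ = ["run_pipeline"]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every configured stage and write its artifacts.

    Stages: retention profile of the design; synthetic template; library
    simulation (mutation TSV, clone metadata TSV, clone FASTA); screen
    simulation (colony TSV, aggregate JSON); coverage report JSON.  Outputs
    are byte-identical across runs with the same seed, and every JSON
    report echoes the seed and full configuration.

    Returns a mapping from artifact name to path.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    design = config.design
    echo = {"seed": config.seed, "config": config.to_dict()}

    logger.info("design: total homology %d bp, DSB at %d", design.total_homology, design.dsb_pos)
    profile = retention_profile(design)
    p_path = outdir / "design_profile.tsv"
    with open(p_path, "w") as fh:
        fh.write(io.COORD_COMMENT)
        profile.reset_index().to_csv(fh, sep="\t", index=False)
    artifacts["design_profile"] = p_path

    template, orf_interval = generate_template(
        design.len5, design.len_target, design.len3, seed=stage_seed(config.seed, "template")
    )
    t_path = outdir / "template.fasta"
    io.write_template_fasta(template, t_path)
    artifacts["template"] = t_path

    if config.library is None:
        return artifacts

    try:
        clones = simulate_library(template, config.library)
    except ValueError as exc:
        raise ValueError(f"library stage failed: {exc}") from exc
    io.write_mutation_table(clones, template, orf_interval, outdir / "library_mutations.tsv")
    io.write_clone_metadata(clones, outdir / "library_clones.tsv")
    io.write_clone_fasta(clones, template, outdir / "library_clones.fasta")
    artifacts["library_mutations"] = outdir / "library_mutations.tsv"
    artifacts["library_clones"] = outdir / "library_clones.tsv"
    artifacts["library_fasta"] = outdir / "library_clones.fasta"

    summary = summarize_library(clones, template, orf_interval, config.library.window)
    cov = coverage_report(
        n_clones=summary.n_clones,
        recombinant_fraction=summary.n_recombinant / summary.n_clones,
        mean_orf_mutations=summary.mean_mutations_per_clone_orf,
        orf_len=design.len_target,
        silent_fraction=summary.effect_fractions["silent"],
        n_transformants=config.screen.n_transformants if config.screen else None,
    )
    io.write_json_report(
        {**echo, "coverage": cov.to_dict(), "density_bp_per_mutation_window": summary.density_bp_per_mutation},
        outdir / "coverage.json",
    )
    artifacts["coverage"] = outdir / "coverage.json"

    if config.screen is None:
        return artifacts

    try:
        result = simulate_screen(clones, template, design, config.screen)
    except ValueError as exc:
        raise ValueError(f"screen stage failed: {exc}") from exc
    c_path = outdir / "screen_colonies.tsv"
    with open(c_path, "w") as fh:
        fh.write(io.COORD_COMMENT)
        result.colony_frame().to_csv(fh, sep="\t", index=False)
    io.write_json_report(
        {**echo, "screen": result.aggregate_report(design)}, outdir / "screen.json"
    )
    artifacts["screen_colonies"] = c_path
    artifacts["screen_report"] = outdir / "screen.json"
    return artifacts
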