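"""End-to-end pipeline: load -> extend -> condition -> knockout -> solve ->
report/screen/sweep, with a flat JSON config and a run log.

The pipeline is a thin composition of the library stages; its output is
identical to calling the stages by hand on the same inputs.  The config
``seed`` field is reserved for interface stability — every stage is
deterministic, so it is recorded in the log and otherwise unused.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

from .core import Model
from .fba import solve_lexicographic
from .io import load_model
from .knockout import apply_knockout, double_knockout_screen, single_knockout_screen
from .pathway import Condition, add_3hp_pathway, set_condition
from .report import our_sweep, write_flux_tsv, write_yield_json, yield_table

__all__ = ["RunConfig", "run_pipeline", "write_screen_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration mirroring the CLI flags."""

    model_path: str
    dialect: str = "native-json"
    add_pathway: bool = True
    gur: float = 15.0
    our: float = 10.0
    knockouts: List[str] = field(default_factory=list)
    objective: Optional[str] = None  # default: model biomass reaction
    secondary: str = "EX_3hp_e"
    screen_order: int = 0  # 0 = no screen, 1 = singles, 2 = pairs
    gene_subset_path: Optional[str] = None
    top_k: Optional[int] = None
    output_dir: str = "."
    seed: int = 0  # reserved; the pipeline is deterministic

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)


def write_screen_tsv(records, path) -> None:
    lines = [
        "gene_1\tgene_2\tgrowth_rate\trelative_growth_pct"
        "\t3hp_yield_cmol_pct\tn_reactions_disabled"
    ]
    for rec in records:
        genes = sorted(rec.genes)
        g1 = genes[0] if genes else ""
        g2 = genes[1] if len(genes) > 1 else ""
        lines.append(
            f"{g1}\t{g2}\t{rec.growth_rate:.6g}\t{rec.relative_growth:.4g}"
            f"\t{rec.threehp_yield:.4g}\t{len(rec.disabled_reactions)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages, writing reports to the output dir.

    Writes ``fluxes.tsv``, ``yields.json``, ``screen.tsv`` (when a
    screen order is set) and ``run.log``.  Stage failures propagate with
    the stage name attached; no partial report files are left behind for
    a stage that failed before producing them.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    pipe_logger = logging.getLogger("glyc3hp.pipeline.run")
    pipe_logger.setLevel(logging.INFO)
    pipe_logger.addHandler(handler)
    outputs = {"log": str(log_path)}
    try:
        pipe_logger.info("config: %s", json.dumps(asdict(config)))

        def stage(name, fn, *args, **kwargs):
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                pipe_logger.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            pipe_logger.info("stage %s complete", name)
            return result

        model = stage("load", load_model, config.model_path, config.dialect)
        if config.add_pathway:
            model = stage("extend", add_3hp_pathway, model)
        condition = Condition(config.gur, config.our)
        model = stage("condition", set_condition, model, condition)
        if config.knockouts:
            model = stage("knockout", apply_knockout, model, config.knockouts)
        primary = config.objective or model.biomass_reaction.id
        solution = stage(
            "solve", solve_lexicographic, model,
            primary=primary, secondary=config.secondary,
        )
        if not solution.optimal:
            raise RuntimeError(f"pipeline stage 'solve' failed: {solution.status}")
        pipe_logger.info(
            "solve: primary %s = %.6g, secondary %s = %.6g",
            primary, solution.primary_value,
            config.secondary, solution.objective_value,
        )
        report = stage("report", yield_table, solution, model)
        write_flux_tsv(solution, model, outdir / "fluxes.tsv")
        write_yield_json(report, outdir / "yields.json")
        outputs["fluxes"] = str(outdir / "fluxes.tsv")
        outputs["yields"] = str(outdir / "yields.json")

        if config.screen_order:
            if config.gene_subset_path:
                genes = [
                    g.strip()
                    for g in Path(config.gene_subset_path).read_text().split()
                    if g.strip()
                ]
            else:
                from .pathway import HETEROLOGOUS_GENES

                genes = sorted(model.genes - HETEROLOGOUS_GENES)
            screen_fn = (
                single_knockout_screen
                if config.screen_order == 1
                else double_knockout_screen
            )
            kwargs = dict(primary=primary, secondary=config.secondary,
                          progress_every=50)
            if config.screen_order == 2:
                kwargs["top_k"] = config.top_k
            records = stage("screen", screen_fn, model, genes, **kwargs)
            write_screen_tsv(records, outdir / "screen.tsv")
            outputs["screen"] = str(outdir / "screen.tsv")
        return outputs
    finally:
        pipe_logger.removeHandler(handler)
        handler.close()
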