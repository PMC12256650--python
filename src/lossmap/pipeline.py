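"""Config-driven orchestration of the analysis stages.

The config is a flat key=value text file ('#' starts a comment).  Stages run
in a fixed order (losses -> complement -> associations -> enrichment ->
pirna); a stage is enabled when its inputs are configured.  Identical
config + seed produces a byte-identical report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import complement as cm
from . import dollo, io, pirna, stats

log = logging.getLogger(__name__)

STAGE_ORDER = ("losses", "complement", "associations", "enrichment", "pirna")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    matrix: str | None = None
    tree: str | None = None
    polarity: str = "root-present"
    outgroups: tuple[str, ...] = ()
    assignment: str | None = None
    species_table: str | None = None
    x: str = "mirna_losses"
    y: str = "core_gene_losses"
    covariate: str | None = None
    gene_set: str | None = None
    annotations: str | None = None
    universe: str | None = None
    bed: str | None = None
    genome: str | None = None
    window: int = 2000
    fraction: float = 0.9
    shuffles: int = 10
    fdr: float = 0.05
    seed: int | None = None
    out_dir: str = "."
    stages: tuple[str, ...] = ()

    def enabled_stages(self) -> list[str]:
        if self.stages:
            return [s for s in STAGE_ORDER if s in self.stages]
        enabled: list[str] = []
        if self.matrix and self.tree:
            enabled.append("losses")
        if self.assignment:
            enabled.append("complement")
        if self.species_table:
            enabled.append("associations")
        if self.gene_set and self.annotations and self.universe:
            enabled.append("enrichment")
        if self.bed and self.genome:
            enabled.append("pirna")
        return enabled

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGE_ORDER:
                raise PipelineError(f"unknown stage {s!r}")
        for key in (
            "matrix", "tree", "assignment", "species_table",
            "gene_set", "annotations", "universe", "bed", "genome",
        ):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise PipelineError(f"{key} path does not exist: {value}")
        if "pirna" in self.enabled_stages() and self.seed is None:
            raise PipelineError("seed is mandatory when a stochastic stage is enabled")


_INT_KEYS = {"window", "shuffles", "seed"}
_FLOAT_KEYS = {"fraction", "fdr"}
_TUPLE_KEYS = {"outgroups", "stages"}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key=value config file."""
    values: dict[str, Any] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PipelineError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in RunConfig.__dataclass_fields__:
            raise PipelineError(f"{path}:{lineno}: unknown key {key!r}")
        if key in _INT_KEYS:
            values[key] = int(value)
        elif key in _FLOAT_KEYS:
            values[key] = float(value)
        elif key in _TUPLE_KEYS:
            values[key] = tuple(v.strip() for v in value.split(",") if v.strip())
        else:
            values[key] = value
    return RunConfig(**values)


def _stage_losses(config: RunConfig) -> dict:
    matrix = io.read_matrix(config.matrix)  # type: ignore[arg-type]
    tree = io.read_newick(config.tree)  # type: ignore[arg-type]
    polarity = dollo.PolaritySpec(mode=config.polarity, outgroups=config.outgroups)
    table = dollo.map_losses(matrix, tree, polarity)
    cumulative = {tip: dollo.cumulative_tip_losses(table, tip) for tip in tree.tips}
    return {"branch_events": table.to_payload(), "cumulative_tip_losses": cumulative}


def _stage_complement(config: RunConfig, report: dict) -> dict:
    assignment = cm.NodeAssignment.from_tsv(config.assignment)  # type: ignore[arg-type]
    expected_total = len(assignment.families)
    out: dict[str, Any] = {
        "node_counts": assignment.node_counts(),
        "expected_total": expected_total,
    }
    cumulative = report.get("losses", {}).get("cumulative_tip_losses")
    if cumulative:
        out["tip_loss_fractions"] = {
            tip: cm.loss_fraction(min(n, expected_total), expected_total).to_payload()
            for tip, n in cumulative.items()
        }
    return out


def _stage_associations(config: RunConfig) -> dict:
    rows = io.read_species_table(config.species_table)  # type: ignore[arg-type]
    frame = {col: [getattr(r, col) for r in rows] for col in io.SPECIES_COLUMNS[1:]}
    if config.x not in frame or config.y not in frame:
        raise PipelineError(f"unknown regression columns {config.x!r}/{config.y!r}")
    fit = stats.ols_fit(frame[config.x], frame[config.y])
    out: dict[str, Any] = {
        "x": config.x,
        "y": config.y,
        "ols": fit.to_payload(),
    }
    if config.covariate:
        if config.covariate not in frame:
            raise PipelineError(f"unknown covariate {config.covariate!r}")
        out["partial"] = stats.spearman_partial(
            frame[config.x], frame[config.y], frame[config.covariate],
            covariate_label=config.covariate,
        ).to_payload()
    return out


def _stage_enrichment(config: RunConfig) -> dict:
    gene_set = _read_lines(config.gene_set)  # type: ignore[arg-type]
    universe = _read_lines(config.universe)  # type: ignore[arg-type]
    annotations: dict[str, set[str]] = {}
    for raw in Path(config.annotations).read_text().splitlines():  # type: ignore[arg-type]
        if not raw.strip():
            continue
        term, gene = raw.split("\t")[:2]
        annotations.setdefault(term, set()).add(gene)
    results = stats.hypergeom_enrich(gene_set, annotations, universe)
    return {
        "n_terms": len(results),
        "fdr": config.fdr,
        "significant_terms": [r.term for r in results if r.q_value < config.fdr],
        "terms": [r.to_payload() for r in results],
    }


def _stage_pirna(config: RunConfig) -> dict:
    reads = io.read_bed(config.bed)  # type: ignore[arg-type]
    genome = io.read_genome_table(config.genome)  # type: ignore[arg-type]
    pirnas, _other = pirna.classify_length(reads)
    out: dict[str, Any] = {
        "n_reads": len(reads),
        "n_pirnas": len(pirnas),
        "length_histogram": {
            str(k): v for k, v in pirna.length_histogram(reads).items()
        },
        "pingpong": pirna.pingpong_profile(pirnas).to_payload(),
    }
    if pirnas:
        wc = pirna.window_counts(pirnas, genome, config.window)
        out["windows"] = wc.to_payload()
        out["dense_windows"] = [
            {"contig": c, "index": i, "count": n}
            for c, i, n in pirna.dense_windows(wc)
        ]
        out["clustering"] = pirna.clustering_ratio(
            pirnas,
            genome,
            window=config.window,
            fraction=config.fraction,
            n_shuffles=config.shuffles,
            seed=int(config.seed),  # type: ignore[arg-type]
        ).to_payload()
    return out


def _read_lines(path: str) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and write one consolidated JSON report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {}
    for stage in config.enabled_stages():
        log.info("running stage %s", stage)
        try:
            if stage == "losses":
                report["losses"] = _stage_losses(config)
            elif stage == "complement":
                report["complement"] = _stage_complement(config, report)
            elif stage == "associations":
                report["associations"] = _stage_associations(config)
            elif stage == "enrichment":
                report["enrichment"] = _stage_enrichment(config)
            elif stage == "pirna":
                report["pirna"] = _stage_pirna(config)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    parameters = {
        "stages": config.enabled_stages(),
        "window": config.window,
        "fraction": config.fraction,
        "shuffles": config.shuffles,
        "polarity": config.polarity,
        "fdr": config.fdr,
    }
    io.write_report(
        report, out_dir / "report.json", seed=config.seed, parameters=parameters
    )
    if "losses" in report:
        _write_branch_tsv(report["losses"]["branch_events"], out_dir / "branch_events.tsv")
    return report


def _write_branch_tsv(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("branch\tlosses\tgains\n")
        for row in payload["branches"]:
            fh.write(f"{row['branch']}\t{row['losses']}\t{row['gains']}\n")
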