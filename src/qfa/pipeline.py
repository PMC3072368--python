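"""End-to-end orchestration: raw density exports to interaction summaries.

:func:`run_pipeline` runs the full analysis for one query/control screen
pair — read ROD exports and layouts, assemble series, fit the logistic
model, filter, normalise, score interactions, summarise and plot — writing
every table and a structured stage log into an output directory.  The run
is deterministic given the inputs, and the effective configuration is
echoed into the output directory so every number is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gis import (Q_THRESHOLD, STRONG_THRESHOLD, apply_exclusions, gis_table,
                  normalize_fitness, strip_revertant_repeats,
                  summarize_interactions)
from .growth_model import DEFAULT_G0, fit_screen
from .rod_io import (assemble_series, read_layout, read_rod_export,
                     write_logistic_table)
from .viz import fitness_plot

logger = logging.getLogger("qfa")

#: Default query<->control temperature pairing (query C -> control C); the
#: high-temperature conditions pair with the nearest control temperature.
DEFAULT_TEMPERATURE_PAIRING = {
    "cdc13-1": {20.0: 20.0, 27.0: 27.0, 36.0: 37.0},
    "yku70D": {23.0: 20.0, 30.0: 27.0, 37.0: 37.0, 37.5: 37.0},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs, serialisable to a single YAML file."""

    query_rod: str = ""
    query_layout: str = ""
    control_rod: str = ""
    control_layout: str = ""
    dialect: dict[str, str] | None = None
    g0: float = DEFAULT_G0
    q_threshold: float = Q_THRESHOLD
    strong_threshold: float = STRONG_THRESHOLD
    temperature_pairing: dict = field(
        default_factory=lambda: {q: dict(t) for q, t in
                                 DEFAULT_TEMPERATURE_PAIRING.items()})
    exclude_orfs: list[str] = field(default_factory=list)
    revertant_check_rod: str = ""      # optional 36C screen for cdc13-1 QC
    revertant_check_layout: str = ""
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _load_and_fit(rod_path: str, layout_path: str, g0: float,
                  dialect, stage: str) -> pd.DataFrame:
    try:
        obs = read_rod_export(rod_path, dialect=dialect)
        annotations = read_layout(layout_path)
        series = assemble_series(obs, annotations)
        return fit_screen(series, g0=g0)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full comparison; returns the per-stage audit counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "effective_config.yaml")
    counts: dict[str, object] = {"version": __version__}

    if not config.query_rod or not config.control_rod:
        raise PipelineError("stage configure: query_rod and control_rod are required")

    query_fit = _load_and_fit(config.query_rod, config.query_layout,
                              config.g0, config.dialect, "fit-query")
    control_fit = _load_and_fit(config.control_rod, config.control_layout,
                                config.g0, config.dialect, "fit-control")
    counts["cultures_query"] = len(query_fit)
    counts["cultures_control"] = len(control_fit)
    counts["fits_converged"] = int(query_fit["converged"].sum()
                                   + control_fit["converged"].sum())
    write_logistic_table(query_fit, out / "logistic_query.tsv")
    write_logistic_table(control_fit, out / "logistic_control.tsv")

    if config.revertant_check_rod:
        check = _load_and_fit(config.revertant_check_rod,
                              config.revertant_check_layout,
                              config.g0, config.dialect, "fit-revertant-check")
        query_fit, stripped = strip_revertant_repeats(query_fit, check)
        counts["replicates_stripped"] = len(stripped)
    else:
        counts["replicates_stripped"] = 0

    query_fit, excl_q = apply_exclusions(query_fit, set(config.exclude_orfs))
    control_fit, _ = apply_exclusions(control_fit, set(config.exclude_orfs))
    counts["genes_excluded"] = int(excl_q["orf"].nunique())

    try:
        query_norm = normalize_fitness(query_fit)
        control_norm = normalize_fitness(control_fit)
    except Exception as exc:
        raise PipelineError(f"stage normalize: {exc}") from exc

    from .gis import classify_interactions
    records = classify_interactions(gis_table(control_norm, query_norm),
                                    config.q_threshold, config.strong_threshold)
    n_assayed = int(records["orf"].nunique())
    counts["n_assayed"] = n_assayed
    counts["significant_calls"] = int((records["classification"] != "none").sum())
    records.to_csv(out / "gis.tsv", sep="\t", index=False,
                   float_format="%.10g", lineterminator="\n")

    summary = summarize_interactions(records, n_assayed=n_assayed,
                                     screen=f"{config.query_rod}")
    pd.DataFrame([dataclasses.asdict(summary)]).to_csv(
        out / "summary.tsv", sep="\t", index=False, lineterminator="\n")

    fig, _ = fitness_plot(records, out / "fitness_plot.png",
                          q_threshold=config.q_threshold)
    import matplotlib.pyplot as plt
    plt.close(fig)

    with open(out / "stage_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", counts)
    return counts
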