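"""End-to-end pipeline orchestration: config, staged runs, manifest.

A run goes cohort -> filter -> descriptives -> pooled mining -> stratified
mining -> exports, writing every artifact as CSV/GraphML/JSON under one
output directory. Reruns with the same config and seed reproduce
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .arm import (
    MiningConfig,
    apriori,
    build_transactions,
    generate_rules,
    rank_rules,
    write_baskets,
    write_rules_csv,
)
from .descriptives import item_frequencies, item_frequencies_to_dataframe, summarize_by_sex
from .graph import rules_to_graph, write_edgelist_csv, write_graphml
from .records import filter_cohort, read_records, write_records
from .stratified import mine_by_age_group, presence_matrix, write_presence_csv
from .synthetic import DEFAULT_N, default_model, load_model, sample_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

# distinct exit codes per failure mode
EXIT_BAD_CONFIG = 2
EXIT_MISSING_INPUT = 3
EXIT_UNWRITABLE_OUTPUT = 4


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """Run configuration: input source, thresholds, output location.

    ``input_csv`` takes precedence; otherwise a synthetic cohort of
    ``synthetic_n`` records is drawn from ``model_path`` (default
    registry-emulation model when unset) with ``seed``.
    """

    output_dir: str = "out"
    input_csv: str | None = None
    synthetic_n: int = DEFAULT_N
    seed: int = 20260926
    model_path: str | None = None
    age_shift: bool = True
    include_principal: bool = False
    mining: MiningConfig = field(default_factory=MiningConfig)

    def validate(self) -> None:
        if self.synthetic_n < 1:
            raise PipelineError(
                f"synthetic_n must be >= 1: {self.synthetic_n}", EXIT_BAD_CONFIG
            )
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise PipelineError(
                f"input CSV not found: {self.input_csv}", EXIT_MISSING_INPUT
            )
        if self.model_path is not None and not Path(self.model_path).exists():
            raise PipelineError(
                f"model file not found: {self.model_path}", EXIT_MISSING_INPUT
            )


def load_config(path) -> PipelineConfig:
    """Load a YAML run configuration; mining thresholds validate on load."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    mining = payload.pop("mining", {})
    try:
        cfg = PipelineConfig(**payload, mining=MiningConfig(**mining))
    except (TypeError, ValueError) as e:
        raise PipelineError(f"invalid configuration: {e}", EXIT_BAD_CONFIG) from e
    return cfg


def _cohort(cfg: PipelineConfig):
    if cfg.input_csv is not None:
        logger.info("reading records from %s", cfg.input_csv)
        return read_records(cfg.input_csv), "csv"
    model = load_model(cfg.model_path) if cfg.model_path else default_model(cfg.age_shift)
    logger.info("sampling synthetic cohort: n=%d seed=%d", cfg.synthetic_n, cfg.seed)
    return sample_cohort(model, cfg.synthetic_n, cfg.seed), "synthetic"


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage and write artifacts plus a run manifest.

    Returns the output directory. Raises PipelineError (with a distinct
    exit code) for invalid config, missing inputs or unwritable output.
    """
    cfg.validate()
    try:
        cfg.mining = MiningConfig(**asdict(cfg.mining))
    except ValueError as e:
        raise PipelineError(f"invalid thresholds: {e}", EXIT_BAD_CONFIG) from e
    out = Path(cfg.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / ".write_test").write_text("")
        (out / ".write_test").unlink()
    except OSError as e:
        raise PipelineError(f"output dir not writable: {out}: {e}", EXIT_UNWRITABLE_OUTPUT) from e

    logger.info(
        "thresholds: support > %g, confidence > %g, lift %s %g",
        cfg.mining.min_support,
        cfg.mining.min_confidence,
        ">" if cfg.mining.lift_strict else ">=",
        cfg.mining.min_lift,
    )
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {**asdict(cfg), "mining": asdict(cfg.mining)},
        "stages": {},
    }

    t0 = time.perf_counter()
    raw, source = _cohort(cfg)
    manifest["stages"]["raw"] = {"records": len(raw), "source": source}

    cohort = filter_cohort(raw)
    manifest["stages"]["cohort"] = {"records": len(cohort)}
    write_records(cohort, out / "cohort.csv")

    summary = summarize_by_sex(cohort)
    summary.to_csv(out / "table1.csv", index=False)
    (out / "table1.txt").write_text(summary.to_string(index=False) + "\n", encoding="utf-8")

    tdb = build_transactions(cohort, include_principal=cfg.include_principal)
    freqs = item_frequencies(tdb)
    item_frequencies_to_dataframe(freqs).to_csv(out / "item_frequencies.csv", index=False)
    write_baskets(tdb, out / "baskets.txt")

    frequent = apriori(tdb, cfg.mining)
    pooled = rank_rules(generate_rules(frequent, tdb, cfg.mining))
    write_rules_csv(pooled, out / "rules_all.csv", cfg.mining.rounding)
    manifest["stages"]["pooled_mining"] = {
        "frequent_itemsets": len(frequent),
        "rules": len(pooled),
    }

    srs = mine_by_age_group(cohort, cfg.mining, include_principal=cfg.include_principal)
    strata_counts = {}
    for stratum in srs.strata():
        sdir = out / "strata" / stratum.replace("≥", "ge")
        sdir.mkdir(parents=True, exist_ok=True)
        write_rules_csv(list(srs.rules[stratum]), sdir / "rules.csv", cfg.mining.rounding)
        g = rules_to_graph(srs.rules[stratum])
        write_graphml(g, sdir / "network.graphml")
        write_edgelist_csv(g, sdir / "edges.csv")
        strata_counts[stratum] = {
            "records": srs.totals[stratum],
            "rules": len(srs.rules[stratum]),
        }
    manifest["stages"]["stratified"] = strata_counts
    write_presence_csv(presence_matrix(srs), out / "presence_matrix.csv")

    g = rules_to_graph(pooled)
    write_graphml(g, out / "network_all.graphml")
    write_edgelist_csv(g, out / "edges_all.csv")

    manifest["elapsed_s"] = round(time.perf_counter() - t0, 2)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, ensure_ascii=False)
    logger.info("pipeline finished in %.1fs -> %s", manifest["elapsed_s"], out)
    return out
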