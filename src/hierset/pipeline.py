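"""Config-driven end-to-end comparison pipeline.

A YAML (or JSON) config names the graph source, an optional term map and
timing file, and per condition a rule file and a downloaded CSV. The
pipeline expands each rule, compares it with its downloaded list, builds
the report tables and, when a timing file is present, fits the creation-
time model. All relative paths resolve against the config file's
directory.

Config schema::

    graph: ontology_edges.tsv            # edge table, or:
    # graph:
    #   concepts: sct2_Concept_....txt   # RF2 snapshot pair
    #   relationships: sct2_Relationship_....txt
    term_map: term_map.tsv               # optional
    timing: timing.tsv                   # optional
    out_prefix: report                   # default "report"
    formats: [csv, markdown]             # default both
    conditions:
      - name: condition_00
        rule_file: condition_00.rule
        downloaded_csv: condition_00_downloaded.csv
        exclude_from_summary: false      # optional
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from .errors import FormatError, HiersetError
from .metrics import ConditionComparison, build_condition_comparison
from .ontology import ConceptGraph, load_edge_table, load_rf2_snapshot
from .report import comparison_summaries, write_report
from .terms import TermMap, load_term_map
from .timing import TimeModel, fit_time_model, load_timing_observations
from .valuesets import load_rule_file
from .vsac import read_vsac_export

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    rows: List[ConditionComparison]
    summaries: Dict
    report_paths: Dict[str, str]
    time_model: Optional[TimeModel] = None


def _resolve(base_dir: str, path: str) -> str:
    return path if os.path.isabs(path) else os.path.join(base_dir, path)


def _load_graph(spec, base_dir: str) -> ConceptGraph:
    if isinstance(spec, str):
        return load_edge_table(_resolve(base_dir, spec))
    if isinstance(spec, dict) and {"concepts", "relationships"} <= set(spec):
        return load_rf2_snapshot(
            _resolve(base_dir, spec["concepts"]),
            _resolve(base_dir, spec["relationships"]),
        )
    raise FormatError(
        "config 'graph' must be an edge-table path or a "
        "{concepts, relationships} RF2 pair"
    )


def run_pipeline(config_file: str) -> PipelineResult:
    """Run the full comparison described by a config file.

    Component failures are re-raised with the condition name and stage
    attached so a multi-condition run fails with an actionable message.
    """
    with open(config_file, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "conditions" not in config or "graph" not in config:
        raise FormatError(f"{config_file}: config must define 'graph' and 'conditions'")
    base_dir = os.path.dirname(os.path.abspath(config_file))

    t0 = time.monotonic()
    graph = _load_graph(config["graph"], base_dir)
    logger.info(
        "stage=load_graph concepts=%d edges=%d duration=%.2fs",
        len(graph), len(graph.edges), time.monotonic() - t0,
    )

    term_map: Optional[TermMap] = None
    if config.get("term_map"):
        term_map = load_term_map(_resolve(base_dir, config["term_map"]))
        logger.info("stage=load_term_map terms=%d", len(term_map))

    rows: List[ConditionComparison] = []
    for cond in config["conditions"]:
        name = cond.get("name", cond.get("rule_file", "?"))
        t0 = time.monotonic()
        try:
            ivs = load_rule_file(
                _resolve(base_dir, cond["rule_file"]), name=name, condition_label=name
            )
            downloaded = read_vsac_export(_resolve(base_dir, cond["downloaded_csv"]))
            row = build_condition_comparison(
                downloaded,
                ivs,
                graph,
                term_map=term_map,
                exclude_from_summary=bool(cond.get("exclude_from_summary", False)),
            )
        except HiersetError as exc:
            exc.args = (f"condition {name!r} (stage=compare): {exc}",)
            raise
        logger.info(
            "stage=compare condition=%s n_downloaded=%d n_derived=%d duration=%.2fs",
            name, row.n_downloaded, row.n_derived, time.monotonic() - t0,
        )
        rows.append(row)

    time_model: Optional[TimeModel] = None
    if config.get("timing"):
        observations = load_timing_observations(_resolve(base_dir, config["timing"]))
        measured = [o for o in observations if o.measured]
        if len(measured) >= 2:
            time_model = fit_time_model(measured)
            logger.info(
                "stage=fit_time slope=%.4f intercept=%.4f n=%d",
                time_model.slope, time_model.intercept, len(measured),
            )

    out_prefix = _resolve(base_dir, config.get("out_prefix", "report"))
    formats = config.get("formats", ["csv", "markdown"])
    paths = write_report(rows, out_prefix, formats=formats)
    return PipelineResult(
        rows=rows,
        summaries=comparison_summaries(rows),
        report_paths=paths,
        time_model=time_model,
    )
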