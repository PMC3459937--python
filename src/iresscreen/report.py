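"""Function-group annotation of hits and the end-to-end pipeline driver.

Hit genes are assigned to coarse function groups from a user-supplied
term-mapping table (gene -> set of group labels); when a gene carries
several labels the highest-priority group wins, in the fixed order
gene expression > tumorigenesis/angiogenesis > cell signaling > cell cycle
> other > unknown.  Live ontology retrieval is deliberately out of scope:
the mapping table is a plain CSV so the grouping rule is testable offline.

``run_pipeline`` chains simulate -> normalize -> call -> secondary ->
annotate and writes every tabular artifact plus a plain-text report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import screen_io as sio
from .errors import ScreenError
from .hits import (CutoffPair, calibrate_cutoffs, call_genes, call_reactions,
                   frequency_distribution, summarize_screen)
from .normalize import aggregate_replicates, normalize_screen
from .secondary import run_secondary
from .synthetic import (PlantedRegulator, SimulationConfig,
                        simulate_primary_screen, simulate_secondary_screen)

logger = logging.getLogger(__name__)

FUNCTION_GROUPS = (
    "gene_expression",
    "tumorigenesis_angiogenesis",
    "cell_signaling",
    "cell_cycle",
    "other",
    "unknown",
)


def assign_group(gene_symbol: str, term_map: dict[str, set[str]]) -> str:
    """Highest-priority function group among a gene's labels.

    Genes absent from the map, or mapped to an empty label set, are
    ``unknown``.
    """
    labels = term_map.get(gene_symbol) or set()
    unknown_labels = set(labels) - set(FUNCTION_GROUPS)
    if unknown_labels:
        raise ScreenError(
            f"gene {gene_symbol}: unknown function group label(s) "
            f"{sorted(unknown_labels)}; allowed: {FUNCTION_GROUPS}"
        )
    for group in FUNCTION_GROUPS:
        if group in labels:
            return group
    return "unknown"


def read_term_map(path) -> dict[str, set[str]]:
    """Read a gene -> group-label mapping CSV (columns gene_symbol, group)."""
    df = pd.read_csv(path, dtype=str)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_symbol, set()).add(row.group)
    return out


def group_summary(hit_genes, term_map: dict[str, set[str]]) -> pd.DataFrame:
    """Whole-percent breakdown of hit genes by function group.

    Percentages are rounded to integers with largest-remainder
    reconciliation so they always sum to exactly 100 (ties broken in group
    priority order).
    """
    genes = list(hit_genes)
    if not genes:
        raise ScreenError("group_summary needs at least one hit gene")
    counts = {g: 0 for g in FUNCTION_GROUPS}
    for gene in genes:
        counts[assign_group(gene, term_map)] += 1
    exact = {g: 100.0 * c / len(genes) for g, c in counts.items()}
    floors = {g: int(exact[g]) for g in FUNCTION_GROUPS}
    remainder = 100 - sum(floors.values())
    by_frac = sorted(FUNCTION_GROUPS,
                     key=lambda g: (-(exact[g] - floors[g]), FUNCTION_GROUPS.index(g)))
    pct = dict(floors)
    for g in by_frac[:remainder]:
        pct[g] += 1
    return pd.DataFrame({
        "group": list(FUNCTION_GROUPS),
        "n_genes": [counts[g] for g in FUNCTION_GROUPS],
        "percent": [pct[g] for g in FUNCTION_GROUPS],
    })


def render_histogram(edges, counts, max_width: int = 50) -> str:
    """Plain-text frequency distribution (one bar per score bin)."""
    peak = max(int(c) for c in counts) or 1
    lines = []
    for lo, hi, c in zip(edges[:-1], edges[1:], counts):
        bar = "#" * max(1, round(max_width * int(c) / peak)) if c else ""
        lines.append(f"[{lo:8.1f}, {hi:8.1f})  {int(c):6d}  {bar}")
    return "\n".join(lines)


def _simulation_config(sim_cfg: dict) -> SimulationConfig:
    cfg = dict(sim_cfg)
    planted = tuple(
        PlantedRegulator(
            gene_symbol=p["gene_symbol"],
            effect_multiplier=float(p["effect_multiplier"]),
            ires_specific=bool(p.get("ires_specific", False)),
            toxic=bool(p.get("toxic", False)),
        )
        for p in cfg.pop("planted_regulators", [])
    )
    if "knockdown_efficiency_range" in cfg:
        cfg["knockdown_efficiency_range"] = tuple(cfg["knockdown_efficiency_range"])
    return SimulationConfig(planted_regulators=planted, **cfg)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    ``config`` keys:

    simulation
        :class:`SimulationConfig` fields (plus ``planted_regulators`` as a
        list of dicts); mutually exclusive with ``inputs``.
    inputs
        paths ``library``, ``layout``, ``measurements`` for a pre-existing
        screen.
    cutoffs
        ``up``/``down`` (fixed; defaults 250/80) or ``calibrate: true`` with
        ``target_hit_rate``/``grid``.
    secondary
        ``cap_tolerance``/``viability_floor``; secondary data is simulated
        for hit genes when the screen itself was simulated.
    annotation
        optional ``term_map`` CSV path.

    Returns the summary dict (also written to ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configuration"
    try:
        sim_config = None
        if "simulation" in config:
            stage = "simulate"
            sim_config = _simulation_config(config["simulation"])
            library, layout, measurements, truth = simulate_primary_screen(sim_config)
            truth.genes.to_csv(out / "ground_truth.csv", index=False)
        else:
            stage = "read inputs"
            paths = config["inputs"]
            library = sio.read_library(paths["library"])
            layout = sio.read_layout(paths["layout"])
            measurements = sio.read_measurements(paths["measurements"])
        sio.write_library(library, out / "library.csv")
        sio.write_layout(layout, out / "layout.csv")
        sio.write_measurements(measurements, out / "measurements.csv")

        stage = "normalize"
        normalized = normalize_screen(measurements, layout)
        normalized.to_csv(out / "normalized.csv", index=False)
        min_reps = int(config.get("min_replicates", 2))
        reactions = aggregate_replicates(normalized, layout, min_replicates=min_reps)
        reactions.to_csv(out / "reactions.csv", index=False)

        stage = "call"
        cut_cfg = config.get("cutoffs", {})
        if cut_cfg.get("calibrate"):
            cutoffs = calibrate_cutoffs(
                reactions.loc[reactions["usable"], "score"],
                target_hit_rate=float(cut_cfg.get("target_hit_rate", 0.10)),
                grid=float(cut_cfg.get("grid", 10.0)),
            )
        else:
            cutoffs = CutoffPair(up_cutoff=float(cut_cfg.get("up", 250.0)),
                                 down_cutoff=float(cut_cfg.get("down", 80.0)))
        logger.info("cut-offs: up >= %s, down <= %s (%s)",
                    cutoffs.up_cutoff, cutoffs.down_cutoff, cutoffs.derivation)
        calls = call_reactions(reactions, cutoffs)
        calls.to_csv(out / "calls.csv", index=False)
        classes = sio.gene_classes(library)
        gene_hits = call_genes(calls, classes)
        gene_hits.to_csv(out / "hits.csv", index=False)
        summary = {"cutoffs": {"up": cutoffs.up_cutoff, "down": cutoffs.down_cutoff,
                               "derivation": cutoffs.derivation},
                   "primary": summarize_screen(calls, gene_hits, classes)}

        stage = "secondary"
        sec_cfg = config.get("secondary", {})
        hit_genes = gene_hits.loc[gene_hits["hit"], "gene_symbol"].tolist()
        if hit_genes and sim_config is not None:
            sec_layout, sec_meas = simulate_secondary_screen(sim_config, hit_genes)
            cap_tol = float(sec_cfg.get("cap_tolerance", 0.25))
            via_floor = float(sec_cfg.get("viability_floor", 0.70))
            logger.info("secondary thresholds: cap tolerance ±%.0f%%, "
                        "viability floor %.0f%%", cap_tol * 100, via_floor * 100)
            sec_table, sec_summary = run_secondary(
                gene_hits, sec_meas, sec_layout, cutoffs,
                cap_tolerance=cap_tol, viability_floor=via_floor)
            sec_table.to_csv(out / "secondary.csv", index=False)
            summary["secondary"] = sec_summary
        else:
            pd.DataFrame(columns=["gene_symbol"]).to_csv(out / "secondary.csv",
                                                         index=False)

        stage = "annotate"
        ann_cfg = config.get("annotation", {})
        if hit_genes:
            term_map = (read_term_map(ann_cfg["term_map"])
                        if "term_map" in ann_cfg else {})
            groups = group_summary(hit_genes, term_map)
            groups.to_csv(out / "function_groups.csv", index=False)
            summary["function_groups"] = {
                row.group: int(row.percent) for row in groups.itertuples(index=False)
            }

        stage = "report"
        usable_scores = reactions.loc[reactions["usable"], "score"]
        report_lines = [
            "IRES screen analysis report",
            "===========================",
            "",
            f"cut-offs: up >= {cutoffs.up_cutoff}, down <= {cutoffs.down_cutoff} "
            f"({cutoffs.derivation})",
            "",
            "Frequency distribution of normalized reaction scores:",
        ]
        if len(usable_scores):
            edges, counts = frequency_distribution(usable_scores, bin_width=25.0)
            report_lines.append(render_histogram(edges, counts))
        report_lines += ["", "Summary:", json.dumps(summary, indent=2, sort_keys=True)]
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except (ScreenError, FileNotFoundError, KeyError) as exc:
        raise ScreenError(f"pipeline failed at stage {stage!r}: {exc}") from exc
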