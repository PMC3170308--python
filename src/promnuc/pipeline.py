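"""Pipeline orchestration: simulate -> classify -> profiles -> stability ->
expression, driven by a YAML config, with a JSON run manifest.

Each stage consumes only files named in the manifest (never in-memory state),
so any stage can be re-run independently, and re-running with the same
config and seed reproduces byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__, io
from .core import split_by_class
from .expression import (
    METHYLATION_FAMILY,
    expression_group_test,
    expression_matched_subset,
    label_modification,
)
from .profiles import occupancy_profile, relative_abundance, window_enrichment_test
from .promoters import annotate_all, class_feature_frequencies, classify_all
from .simulate import ACTIVATED, RESTING, SimConfig, simulate_all
from .stability import (
    compare_stability,
    mean_abs_min_distance,
    min_distances,
    stability_analysis,
)

log = logging.getLogger("promnuc")

_ANALYSIS_DEFAULTS = {
    "arch_threshold": 4,
    "flank": 5000,
    "halfwidth": 15,
    "profile_mode": "per_nucleosome",
    "enrichment_window": [100, 130],
    "enrichment_mark": "H3K4me3",
    "profile_mark": "H3",
    "relative_abundance_window": [-2000, 2000],
    "stability_window": [1, 200],
    "exclusion": 100,
    "bin_size": 15,
    "tata_window": 50,
    "min_rel_score": 0.75,
    "cpg_window": 200,
    "expression_window": [-500, 500],
    "methylation_marks": list(METHYLATION_FAMILY),
    "matched_range": [250, 750],
}

_TOP_KEYS = {"seed", "out_dir", "sim", "analysis"}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    out_dir: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, inputs: list, outputs: list, summary: dict) -> None:
        self.stages[stage] = {
            "inputs": [str(p) for p in inputs],
            "outputs": [str(p) for p in outputs],
            "summary": summary,
        }

    def as_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "out_dir": self.out_dir,
            "stages": self.stages,
        }


def load_config(config_path) -> dict:
    """Load and validate the YAML run config."""
    raw = yaml.safe_load(Path(config_path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    bad = sorted(set(raw) - _TOP_KEYS)
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    analysis = dict(_ANALYSIS_DEFAULTS)
    extra = sorted(set(raw.get("analysis", {})) - set(_ANALYSIS_DEFAULTS))
    if extra:
        raise ValueError(f"unknown analysis config keys: {extra}")
    analysis.update(raw.get("analysis", {}))
    sim = dict(raw.get("sim", {}))
    sim.setdefault("seed", int(raw.get("seed", 0)))
    return {
        "seed": int(raw.get("seed", 0)),
        "out_dir": raw.get("out_dir", "results/run"),
        "sim": SimConfig.from_dict(sim),
        "analysis": analysis,
    }


def _config_hash(config: dict) -> str:
    canon = json.dumps(
        {
            "seed": config["seed"],
            "sim": config["sim"].to_dict(),
            "analysis": config["analysis"],
        },
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()


def _win(pair) -> tuple[int, int]:
    return int(pair[0]), int(pair[1])


def run_pipeline(config_path, out_dir=None) -> RunManifest:
    """Execute all stages in dependency order; write the manifest JSON."""
    config = load_config(config_path)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    ana = config["analysis"]
    sim_cfg: SimConfig = config["sim"]
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config["seed"],
        version=__version__,
        out_dir=str(out),
    )
    log.info(
        "run: arch_threshold=%s flank=%s halfwidth=%s enrichment_window=%s "
        "stability_window=%s exclusion=%s min_rel_score=%s tata_window=%s cpg_window=%s",
        ana["arch_threshold"], ana["flank"], ana["halfwidth"], ana["enrichment_window"],
        ana["stability_window"], ana["exclusion"], ana["min_rel_score"],
        ana["tata_window"], ana["cpg_window"],
    )

    # ---- simulate ----------------------------------------------------
    sim = simulate_all(sim_cfg)
    paths = {
        "promoters": out / "promoters.tsv",
        "genome": out / "genome.fa",
        "cpg": out / "cpg.bed",
        "tfbs": out / "tfbs.bed",
        "expr": out / "expr.tsv",
        "config": out / "config_resolved.yaml",
    }
    io.write_promoters(sim.promoters, paths["promoters"])
    io.write_fasta(sim.genome, paths["genome"])
    io.write_intervals(sim.cpg_islands, paths["cpg"])
    io.write_points(sim.tfbs, paths["tfbs"])
    io.write_expression(sim.expression, paths["expr"])
    mark_paths: dict[tuple[str, str], Path] = {}
    for cond, sets in ((RESTING, sim.nucleosomes_resting), (ACTIVATED, sim.nucleosomes_activated)):
        for mark, ps in sets.items():
            p = out / f"{mark.replace('.', '')}_{cond}.bed"
            io.write_points(ps, p)
            mark_paths[(mark, cond)] = p
    paths["config"].write_text(
        yaml.safe_dump({"seed": config["seed"], "sim": sim_cfg.to_dict(), "analysis": ana}),
        encoding="utf-8",
    )
    manifest.record(
        "simulate",
        inputs=[config_path],
        outputs=list(paths.values()) + list(mark_paths.values()),
        summary={
            "n_promoters": len(sim.promoters),
            "n_broad": sum(p.arch_class == "broad" for p in sim.promoters),
            "n_peak": sum(p.arch_class == "peak" for p in sim.promoters),
        },
    )

    # ---- classify ----------------------------------------------------
    promoters = io.read_promoters(paths["promoters"])
    genome = io.read_fasta(paths["genome"])
    cpg = io.read_intervals(paths["cpg"])
    promoters = classify_all(promoters, threshold=int(ana["arch_threshold"]))
    promoters = annotate_all(
        promoters,
        genome=genome,
        cpg_islands=cpg,
        tata_window=int(ana["tata_window"]),
        min_rel_score=float(ana["min_rel_score"]),
        cpg_window=int(ana["cpg_window"]),
    )
    classified_path = out / "promoters_classified.tsv"
    io.write_promoters(promoters, classified_path)
    freqs = class_feature_frequencies(promoters)
    freqs_path = out / "feature_frequencies.json"
    io.write_json(freqs, freqs_path)
    manifest.record(
        "classify",
        inputs=[paths["promoters"], paths["genome"], paths["cpg"]],
        outputs=[classified_path, freqs_path],
        summary=freqs,
    )
    by_class = split_by_class(promoters)
    broad = by_class.get("broad", [])
    peak = by_class.get("peak", [])

    # ---- profiles ----------------------------------------------------
    mark = ana["profile_mark"]
    rest_path = mark_paths[(mark, RESTING)]
    rest = io.read_points(rest_path, fmt="bed", label=mark, condition=RESTING)
    flank = int(ana["flank"])
    hw = int(ana["halfwidth"])
    profile_outputs = []
    tracks = {}
    for cls, members in (("broad", broad), ("peak", peak)):
        if not members:
            log.info("profiles: class %s empty, skipped", cls)
            continue
        track = occupancy_profile(members, rest, flank=flank, halfwidth=hw, mode=ana["profile_mode"])
        p = out / f"profile_{mark.replace('.', '')}_{cls}.tsv"
        io.write_profile(track, p)
        profile_outputs.append(p)
        tracks[cls] = track
    profile_summary: dict = {"mark": mark, "mode": ana["profile_mode"], "n_tracks": len(tracks)}
    if "broad" in tracks and "peak" in tracks:
        ra_a, ra_b = _win(ana["relative_abundance_window"])
        ra = relative_abundance(
            tracks["broad"], tracks["peak"], (max(ra_a, -flank), min(ra_b, flank))
        )
        ra_path = out / f"relative_abundance_{mark.replace('.', '')}.tsv"
        io.write_profile(ra, ra_path)
        profile_outputs.append(ra_path)
        enr_points = io.read_points(
            mark_paths[(ana["enrichment_mark"], RESTING)], fmt="bed", label=ana["enrichment_mark"]
        )
        enr = window_enrichment_test(broad, peak, enr_points, _win(ana["enrichment_window"]), hw)
        enr_path = out / "enrichment_test.json"
        io.write_json(enr.as_dict(), enr_path)
        profile_outputs.append(enr_path)
        profile_summary["enrichment"] = enr.as_dict()
    else:
        log.info("profiles: enrichment test skipped (needs both classes)")
    manifest.record(
        "profiles",
        inputs=[classified_path, str(rest_path)],
        outputs=profile_outputs,
        summary=profile_summary,
    )

    # ---- stability ---------------------------------------------------
    stab_outputs = []
    if broad and peak:
        act = io.read_points(mark_paths[(mark, ACTIVATED)], fmt="bed", label=mark, condition=ACTIVATED)
        win = _win(ana["stability_window"])
        excl = int(ana["exclusion"])
        bins = int(ana["bin_size"])
        results = {}
        for cls, members in (("broad", broad), ("peak", peak)):
            res = stability_analysis(members, rest, act, win, excl, bins, class_label=cls)
            results[cls] = res
            dist_path = out / f"stability_distances_{cls}.tsv"
            with open(dist_path, "w", encoding="utf-8") as fh:
                fh.write("distance\n")
                for d in res.distances:
                    fh.write(f"{d}\n")
            binned_path = out / f"stability_binned_{cls}.tsv"
            res.binned.to_csv(binned_path, sep="\t", index=False)
            stab_outputs += [dist_path, binned_path]
        # genome-wide background: all resting centers, unfiltered
        bg_dist, _ = min_distances(rest, act)
        bg_mean, bg_used, bg_excl = mean_abs_min_distance(bg_dist, int(ana["exclusion"]))
        cmp_res = compare_stability(
            abs(results["broad"].distances[abs(results["broad"].distances) <= excl]),
            abs(results["peak"].distances[abs(results["peak"].distances) <= excl]),
        )
        summary = {
            "broad": results["broad"].summary(),
            "peak": results["peak"].summary(),
            "background": {"mean_abs": bg_mean, "n_used": bg_used, "n_excluded": bg_excl},
            "t_statistic": cmp_res.statistic,
            "p_value": cmp_res.p_value,
        }
        sum_path = out / "stability_summary.json"
        io.write_json(summary, sum_path)
        stab_outputs.append(sum_path)
        manifest.record(
            "stability",
            inputs=[classified_path, str(rest_path), str(mark_paths[(mark, ACTIVATED)])],
            outputs=stab_outputs,
            summary=summary,
        )
    else:
        reason = "stability skipped: requires both promoter classes"
        log.info(reason)
        manifest.record("stability", inputs=[], outputs=[], summary={"skipped": reason})

    # ---- expression --------------------------------------------------
    expr_outputs = []
    expr = io.read_expression(paths["expr"])
    fam_paths = [mark_paths[(m, RESTING)] for m in ana["methylation_marks"] if (m, RESTING) in mark_paths]
    if fam_paths and promoters:
        fam_sets = [io.read_points(p, fmt="bed", label=str(p)) for p in fam_paths]
        groups = label_modification(promoters, fam_sets, _win(ana["expression_window"]))
        labels_path = out / "modification_groups.tsv"
        with open(labels_path, "w", encoding="utf-8") as fh:
            fh.write("id\tgroup\n")
            for pid in sorted(groups):
                fh.write(f"{pid}\t{groups[pid]}\n")
        expr_outputs.append(labels_path)
        summary = {}
        for cls, members in (("broad", broad), ("peak", peak)):
            if not members:
                summary[cls] = {"skipped": "class empty"}
                continue
            try:
                cmp_ = expression_group_test(expr, promoters, groups, cls)
                summary[cls] = cmp_.as_dict()
            except ValueError as exc:
                summary[cls] = {"skipped": str(exc)}
                log.info("expression: %s", exc)
        matched = expression_matched_subset(expr, promoters, *map(float, ana["matched_range"]))
        m_by_class = split_by_class(matched)
        summary["matched_subset"] = {
            "range": list(ana["matched_range"]),
            "n_broad": len(m_by_class.get("broad", [])),
            "n_peak": len(m_by_class.get("peak", [])),
        }
        if m_by_class.get("broad") and m_by_class.get("peak"):
            enr_points = io.read_points(
                mark_paths[(ana["enrichment_mark"], RESTING)], fmt="bed", label=ana["enrichment_mark"]
            )
            m_enr = window_enrichment_test(
                m_by_class["broad"], m_by_class["peak"], enr_points, _win(ana["enrichment_window"]), hw
            )
            summary["matched_subset"]["enrichment"] = m_enr.as_dict()
        expr_path = out / "expression_summary.json"
        io.write_json(summary, expr_path)
        expr_outputs.append(expr_path)
        manifest.record(
            "expression",
            inputs=[classified_path, paths["expr"], *map(str, fam_paths)],
            outputs=expr_outputs,
            summary=summary,
        )
    else:
        manifest.record("expression", inputs=[], outputs=[], summary={"skipped": "no mark family or promoters"})

    manifest_path = out / "manifest.json"
    io.write_json(manifest.as_dict(), manifest_path)
    return manifest
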