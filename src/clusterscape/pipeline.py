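"""End-to-end orchestration: simulate -> metrics -> clusters -> enrichment
-> overlap -> gene-order evolution, from one config and one seed.

Every stage writes plain TSV outputs with headers into the run directory
and the pipeline is restartable from any stage given the prior outputs.
Identical (config, seed) reproduces all statistical outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    ClusterCallConfig,
    distance_decay,
    grow_clusters,
    median_within_cluster_r,
    nearest_coexpressed_gaps,
    sr_clusters,
)
from .enrichment import AnnotationTable, enriched_count_test
from .evolution import (
    bin_conservation,
    block_stats,
    cluster_conservation_test,
    coexpr_recombination_corr,
    logistic_conservation,
    orientation_tables,
    size_recombination_corr,
)
from .expression import (
    CoexpressionThresholds,
    ExpressionMatrix,
    TissueExpressionMatrix,
    compute_breadth,
    compute_tau,
    compute_thresholds,
)
from .genome import (
    GenomeMap,
    adjacent_pairs,
    annotate_conservation,
    load_genome,
    load_synteny,
    write_genome,
    write_pair_table,
)
from .housekeeping import (
    Cluster,
    call_hk_clusters,
    cluster_recombination_test,
    clusters_to_frame,
    encode_arm,
    filter_hk_clusters,
    transition_test,
)
from .overlap import containment_test
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "StageError", "run_pipeline", "STAGES"]

STAGES = ["simulate", "metrics", "clusters", "enrichment", "overlap", "evolution"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat analysis configuration; simulation knobs nest in ``sim``."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    tau_cutoff: float = 0.25
    max_gap: int = 3
    gap: int = 3
    window: int = 10
    n_pairs: int = 100_000
    n_windows: int = 10_000
    n_shuffles: int = 10_000
    n_random_filter: int = 10_000
    n_random_enrich: int = 10_000
    n_random_overlap: int = 10_000
    n_random_conserve: int = 1_000
    n_bins: int = 30
    alpha: float = 0.05
    node: str = "tree"
    exclude_arms: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim_keys = {f.name for f in dataclasses.fields(SimulationConfig)}
        pipe_keys = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        sim_raw = dict(raw.pop("sim", {}) or {})
        for k in list(raw):
            if k in sim_keys:
                sim_raw[k] = raw.pop(k)
        unknown = set(raw) - pipe_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad_sim = set(sim_raw) - sim_keys
        if bad_sim:
            raise ValueError(f"unknown simulation config keys: {sorted(bad_sim)}")
        return cls(sim=SimulationConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
    out_dir: str | Path,
    seed: int = 0,
    from_stage: str = "simulate",
    to_stage: str = "evolution",
) -> RunManifest:
    """Run the full analysis on a synthetic genome, writing TSVs + a report.

    ``from_stage`` restarts at a later stage, loading earlier outputs from
    ``out_dir``; ``to_stage`` stops after the named stage.  Raises
    :class:`StageError` naming the failing stage; earlier outputs are
    retained.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if from_stage not in STAGES or to_stage not in STAGES:
        raise ValueError(f"unknown stage; stages are {STAGES}")
    start_at = STAGES.index(from_stage)
    stop_at = STAGES.index(to_stage)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        seed=seed,
        version=__version__,
    )
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    report: dict[str, object] = {}
    ctx: dict[str, object] = {}

    def _run_stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        manifest.stages[name] = {
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %-10s done in %.2fs (%d outputs)", name, time.perf_counter() - t0, len(outputs))

    # ---------------- simulate ----------------
    def stage_simulate() -> list[Path]:
        bundle = simulate_all(cfg.sim, _stage_seed(seed, "simulate"))
        ctx.update(bundle)
        files = []
        write_genome(bundle["genome"], out / "genome.tsv")
        bundle["expression"].to_tsv(out / "expression.tsv")
        bundle["tissue"].to_tsv(out / "tissue_values.tsv", out / "tissue_detected.tsv")
        bundle["rates"].to_csv(out / "rates.tsv", sep="\t", float_format="%.17g")
        bundle["synteny"].to_frame().to_csv(out / "synteny.tsv", sep="\t", index=False)
        bundle["annotations"].to_csv(out / "annotations.tsv", sep="\t", index=False)
        pd.DataFrame(bundle["duplicates"], columns=["gene_a", "gene_b"]).to_csv(
            out / "duplicates.tsv", sep="\t", index=False
        )
        truth = bundle["truth"]
        pd.DataFrame(
            [
                {"kind": "type1", "index": i, "members": ",".join(cl)}
                for i, cl in enumerate(truth.type1_clusters)
            ]
            + [
                {"kind": "hk_run", "index": i, "members": ",".join(cl)}
                for i, cl in enumerate(truth.hk_runs)
            ]
        ).to_csv(out / "truth_clusters.tsv", sep="\t", index=False)
        if truth.pair_intact is not None:
            truth.pair_intact.to_csv(out / "truth_pair_intact.tsv", sep="\t", index=False)
        files = [
            out / n
            for n in (
                "genome.tsv", "expression.tsv", "tissue_values.tsv", "tissue_detected.tsv",
                "rates.tsv", "synteny.tsv", "annotations.tsv", "duplicates.tsv",
                "truth_clusters.tsv",
            )
        ]
        return files

    def load_simulated() -> None:
        ctx["genome"] = load_genome(out / "genome.tsv", format="tsv")
        ctx["expression"] = ExpressionMatrix.from_tsv(out / "expression.tsv")
        ctx["tissue"] = TissueExpressionMatrix.from_tsv(
            out / "tissue_values.tsv", out / "tissue_detected.tsv"
        )
        ctx["rates"] = pd.read_csv(out / "rates.tsv", sep="\t", index_col=0, float_precision="round_trip")
        ctx["synteny"] = load_synteny(out / "synteny.tsv")
        ctx["annotations"] = pd.read_csv(out / "annotations.tsv", sep="\t", dtype=str)
        dups = pd.read_csv(out / "duplicates.tsv", sep="\t", dtype=str)
        ctx["duplicates"] = list(dups.itertuples(index=False, name=None))

    # ---------------- metrics ----------------
    def stage_metrics() -> list[Path]:
        g: GenomeMap = ctx["genome"]
        tau = compute_tau(ctx["tissue"])
        breadth = compute_breadth(ctx["tissue"])
        pd.DataFrame({"tau": tau, "breadth": breadth}).to_csv(
            out / "metrics.tsv", sep="\t", index_label="gene_id", float_format="%.17g"
        )
        thr = compute_thresholds(
            ctx["expression"], g,
            n_pairs=cfg.n_pairs, n_windows=cfg.n_windows, window=cfg.window,
            seed=_stage_seed(seed, "metrics"),
        )
        ctx["tau"], ctx["breadth"], ctx["thresholds"] = tau, breadth, thr
        rows = [
            {"arm": arm, "pair_threshold": thr.pair_threshold.get(arm),
             "window_threshold": thr.window_threshold.get(arm)}
            for arm in g.arms
        ]
        pd.DataFrame(rows).to_csv(out / "thresholds.tsv", sep="\t", index=False, float_format="%.17g")
        return [out / "metrics.tsv", out / "thresholds.tsv"]

    def load_metrics() -> None:
        m = pd.read_csv(out / "metrics.tsv", sep="\t", index_col=0, float_precision="round_trip")
        ctx["tau"], ctx["breadth"] = m["tau"], m["breadth"]
        t = pd.read_csv(out / "thresholds.tsv", sep="\t", float_precision="round_trip")
        thr = CoexpressionThresholds()
        for r in t.itertuples():
            if not pd.isna(r.pair_threshold):
                thr.pair_threshold[str(r.arm)] = float(r.pair_threshold)
            if not pd.isna(r.window_threshold):
                thr.window_threshold[str(r.arm)] = float(r.window_threshold)
        ctx["thresholds"] = thr

    # ---------------- clusters ----------------
    def stage_clusters() -> list[Path]:
        g: GenomeMap = ctx["genome"]
        sseed = _stage_seed(seed, "clusters")
        arms = [a for a in g.arms if a not in cfg.exclude_arms]
        hk_tau: list[Cluster] = []
        hk_breadth: list[Cluster] = []
        transitions = []
        n_t = ctx["tissue"].n_tissues if "tissue" in ctx else cfg.sim.n_tissues
        for rule, marker, bucket in (
            ("tau_le_cutoff", ctx["tau"], hk_tau),
            ("breadth_all_tissues", ctx["breadth"], hk_breadth),
        ):
            for k, arm in enumerate(arms):
                ids = [x.id for x in g.genes_on(arm)]
                enc = encode_arm(arm, ids, marker, rule=rule, cutoff=cfg.tau_cutoff, n_tissues=n_t)
                obs, p, med = transition_test(enc, n_shuffles=cfg.n_shuffles, seed=sseed + k)
                transitions.append(
                    {"rule": rule, "arm": arm, "observed": obs, "null_median": med, "p": p}
                )
                called = call_hk_clusters(enc, max_gap=cfg.max_gap)
                called = filter_hk_clusters(
                    called, enc, n_random=cfg.n_random_filter, alpha=cfg.alpha,
                    seed=sseed + 1000 + k, max_gap=cfg.max_gap,
                )
                bucket.extend(called)
        pd.DataFrame(transitions).to_csv(out / "transitions.tsv", sep="\t", index=False)
        ccc = ClusterCallConfig(thresholds=ctx["thresholds"], window=cfg.window, gap=cfg.gap)
        sr = sr_clusters(ctx["expression"], g, ccc)
        t1 = grow_clusters(ctx["expression"], g, ccc)
        ctx["hk_tau"], ctx["hk_breadth"], ctx["sr"], ctx["type1"] = hk_tau, hk_breadth, sr, t1
        all_clusters = hk_tau + hk_breadth + sr + t1
        clusters_to_frame(all_clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
        report["n_hk_tau_filtered"] = sum(1 for c in hk_tau if c.passed_filter)
        report["n_hk_breadth_filtered"] = sum(1 for c in hk_breadth if c.passed_filter)
        report["n_sr"] = len(sr)
        report["n_type1"] = len(t1)
        report["median_type1_r"] = median_within_cluster_r(t1, ctx["expression"])
        gaps = nearest_coexpressed_gaps(t1, g)
        gaps.to_csv(out / "type1_gaps.tsv", sep="\t")
        try:
            rec = cluster_recombination_test(
                [c for c in hk_tau if c.passed_filter], ctx["rates"], "RP"
            )
            report["hk_tau_recomb_median"], report["genome_recomb_median"], report["hk_tau_recomb_p"] = rec
        except ValueError as exc:
            logger.warning("recombination comparison skipped: %s", exc)
        return [out / "transitions.tsv", out / "clusters.tsv", out / "type1_gaps.tsv"]

    def load_clusters() -> None:
        df = pd.read_csv(out / "clusters.tsv", sep="\t")
        buckets: dict[str, list[Cluster]] = {"hk_tau": [], "hk_breadth": [], "sr": [], "type1": []}
        g: GenomeMap = ctx["genome"]
        for r in df.itertuples():
            members = str(r.members).split(",") if isinstance(r.members, str) else []
            pos = sorted(g.position(m)[1] for m in members) if members else []
            buckets[r.type].append(
                Cluster(
                    type=r.type, arm=str(r.arm), member_ids=members,
                    span=int(r.span), n_marked=int(r.n_marked),
                    passed_filter=None if pd.isna(r.passed_filter) else bool(r.passed_filter),
                    p_filter=None if pd.isna(r.p_filter) else float(r.p_filter),
                    start_index=pos[0] if pos else None,
                    end_index=pos[-1] if pos else None,
                )
            )
        for k, v in buckets.items():
            ctx[k] = v

    # ---------------- enrichment ----------------
    def stage_enrichment() -> list[Path]:
        g: GenomeMap = ctx["genome"]
        ann_df = ctx["annotations"]
        term_of: dict[str, set[str]] = {}
        for r in ann_df.itertuples():
            term_of.setdefault(str(r.gene_id), set()).add(str(r.term))
        ann = AnnotationTable(term_of, {arm: [x.id for x in g.genes_on(arm)] for arm in g.arms})
        rows = []
        for name in ("type1", "sr"):
            clusters = [c for c in ctx[name] if len(c.member_ids) >= 2]
            if not clusters:
                continue
            obs, p = enriched_count_test(
                clusters, ann, n_random=cfg.n_random_enrich, alpha=cfg.alpha,
                seed=_stage_seed(seed, "enrichment"),
            )
            rows.append({"cluster_set": name, "n_clusters": len(clusters), "n_enriched": obs, "p": p})
            report[f"enriched_{name}"] = obs
            report[f"enriched_{name}_p"] = p
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return [out / "enrichment.tsv"]

    # ---------------- overlap ----------------
    def stage_overlap() -> list[Path]:
        g: GenomeMap = ctx["genome"]
        res = containment_test(
            ctx["type1"], ctx["sr"], g,
            n_random=cfg.n_random_overlap, seed=_stage_seed(seed, "overlap"),
        )
        pd.DataFrame(
            [
                {
                    "small": "type1", "large": "sr",
                    "observed_proportion": res.observed_proportion,
                    "null_max": res.null_max, "p": res.p, "n_random": res.n_random,
                }
            ]
        ).to_csv(out / "overlap.tsv", sep="\t", index=False)
        report["type1_in_sr_proportion"] = res.observed_proportion
        report["type1_in_sr_p"] = res.p
        return [out / "overlap.tsv"]

    # ---------------- evolution ----------------
    def stage_evolution() -> list[Path]:
        g: GenomeMap = ctx["genome"]
        synteny = ctx["synteny"]
        rates = ctx["rates"]
        pairs = adjacent_pairs(g)
        zs = ctx["expression"].zscores()
        m = ctx["expression"].values.shape[1]
        znp = zs.to_numpy()
        zidx = {gid: i for i, gid in enumerate(zs.index)}
        for p in pairs:
            ia, ib = zidx.get(p.left.id), zidx.get(p.right.id)
            if ia is None or ib is None:
                continue
            r = float(np.dot(znp[ia], znp[ib]) / m)
            p.coexpression = None if np.isnan(r) else r
        annotate_conservation(pairs, synteny, cfg.node)
        write_pair_table(pairs, out / "pairs.tsv")
        blocks = block_stats(synteny, g, rates, cfg.node)
        pd.DataFrame(
            [
                {
                    "block": b.id, "arm": b.arm, "size": b.size,
                    "mean_RP": b.mean_recomb.get("RP"), "mean_ACE": b.mean_recomb.get("ACE"),
                    "breakpoint_index": b.breakpoint_index,
                }
            for b in blocks
            ]
        ).to_csv(out / "blocks.tsv", sep="\t", index=False)
        stats_rows = []
        src = size_recombination_corr(blocks, "RP", exclude_nonrecombining=True)
        if src:
            stats_rows.append({"stat": "size_recomb_rho_RP", "value": src[0], "p": src[1], "n": src[2]})
            report["size_recomb_rho"] = src[0]
        binned, rho, pv = bin_conservation(pairs, synteny, cfg.node, n_bins=cfg.n_bins)
        stats_rows.append({"stat": "igd_bin_conservation_rho", "value": rho, "p": pv, "n": binned.n_bins})
        report["igd_conservation_rho"] = rho
        table, chi, dof, pv, pct = orientation_tables(pairs, synteny, cfg.node)
        stats_rows.append({"stat": "orientation_chi_sq", "value": chi, "p": pv, "n": int(table.to_numpy().sum())})
        report["orientation_chi_sq"] = chi
        fit = logistic_conservation(pairs, synteny, cfg.node)
        stats_rows.append({"stat": "logit_coef_igd", "value": fit.params["igd"], "p": fit.lrt_p["igd"], "n": fit.n})
        stats_rows.append(
            {"stat": "logit_coef_top_coexpr", "value": fit.params["top_coexpr"], "p": fit.lrt_p["top_coexpr"], "n": fit.n}
        )
        crc = coexpr_recombination_corr(pairs, rates, "RP")
        if crc:
            stats_rows.append({"stat": "coexpr_recomb_rho_RP", "value": crc[0], "p": crc[1], "n": crc[2]})
        cseed = _stage_seed(seed, "evolution")
        for name in ("hk_tau", "hk_breadth", "sr"):
            clusters = [
                c for c in ctx[name] if (c.passed_filter is not False) and len(c.member_ids) >= 2
            ]
            if not clusters:
                continue
            try:
                obs, pv = cluster_conservation_test(
                    clusters, synteny, g, cfg.node,
                    n_random=cfg.n_random_conserve, seed=cseed,
                )
            except ValueError as exc:
                logger.warning("conservation test for %s skipped: %s", name, exc)
                continue
            stats_rows.append({"stat": f"conservation_{name}_landmarks", "value": obs, "p": pv, "n": len(clusters)})
            report[f"conservation_{name}_p"] = pv
        pd.DataFrame(stats_rows).to_csv(out / "evolution.tsv", sep="\t", index=False)
        return [out / "pairs.tsv", out / "blocks.tsv", out / "evolution.tsv"]

    stage_fns = {
        "simulate": stage_simulate,
        "metrics": stage_metrics,
        "clusters": stage_clusters,
        "enrichment": stage_enrichment,
        "overlap": stage_overlap,
        "evolution": stage_evolution,
    }
    loaders = {"simulate": load_simulated, "metrics": load_metrics, "clusters": load_clusters}
    for i, stage in enumerate(STAGES):
        if i > stop_at:
            break
        if i < start_at:
            try:
                if stage in loaders:
                    loaders[stage]()
            except FileNotFoundError as exc:
                raise StageError(stage, f"missing prior output: {exc}") from exc
            continue
        _run_stage(stage, stage_fns[stage])
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")
    manifest.write(out / "manifest.json")
    return manifest
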