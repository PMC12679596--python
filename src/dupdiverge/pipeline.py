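"""Pipeline orchestration: simulate -> patterns -> acr -> dynamics -> trajectories.

A run is driven by a :class:`RunConfig` (YAML-loadable), executes stages in
dependency order on a working directory, and writes per-stage TSVs plus a
manifest echoing the resolved configuration and seed. All randomness flows
from the run seed through deterministically derived child seeds, so an
identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import accessibility, conservation, patterns, trajectory
from .io import (
    CountsTable,
    load_genome,
    read_bed,
    read_gff3,
    read_newick,
    read_pairs,
    read_quads,
)
from .simulate import SynthConfig, simulate_study


@dataclass
class RunConfig:
    workdir: str = "run"
    seed: int = 0
    simulate: bool = True
    input_dir: Optional[str] = None  # defaults to <workdir>/inputs when simulating
    # thresholds (printed defaults)
    coexpr_high: float = 0.9
    coexpr_low: float = 0.5
    fc: float = 1.0
    sd: float = 1.0
    conserved_B: float = 0.1
    stricter_B: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    qc_rho: float = 0.75
    de_lfc: float = 1.0
    de_alpha: float = 0.05
    k1_distance: float = trajectory.K1_DISTANCE
    max_within: float = trajectory.MAX_WITHIN
    # flags
    mask_self: bool = False
    pooled_jaccard: bool = False
    strict_recent_split: bool = True
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self):
        for name, lo, hi in (
            ("coexpr_high", 0, 1), ("coexpr_low", 0, 1), ("conserved_B", 0, 1),
            ("qc_rho", -1, 1), ("de_alpha", 0, 1), ("k1_distance", 0, 2),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw.pop("synth", {}).items()
        })
        raw = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()}
        return cls(synth=synth, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        def conv(x):
            if isinstance(x, tuple):
                return list(x)
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            return x
        return {k: conv(v) for k, v in d.items()}


STAGE_ORDER = ("simulate", "patterns", "acr", "dynamics", "trajectories")


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGE_ORDER) -> Path:
    """Run the requested stages; returns the results directory."""
    work = Path(cfg.workdir)
    results = work / "results"
    results.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    cfg.synth.seed = cfg.seed if cfg.synth.seed == 0 else cfg.synth.seed
    indir = Path(cfg.input_dir) if cfg.input_dir else work / "inputs"

    if "simulate" in stages and cfg.simulate:
        simulate_study(cfg.synth, indir)
        log.append(f"simulate: wrote synthetic study to {indir.name}")

    _require(indir / "pairs.tsv", "acr/patterns stages need pairs.tsv")
    pairs = read_pairs(indir / "pairs.tsv")

    summary: dict = {}

    if "patterns" in stages:
        calls_all = []
        for tsv in sorted(indir.glob("counts_*.tsv")):
            tissue = tsv.stem.replace("counts_", "")
            if tissue == "trajectory":
                continue
            counts = CountsTable.from_tsv(tsv)
            calls = patterns.classify_pairs(counts, pairs, tissue, rho_min=cfg.qc_rho)
            calls_all.append(calls)
            log.append(f"patterns[{tissue}]: {len(calls)} pairs classified")
        if calls_all:
            calls_df = pd.concat(calls_all, ignore_index=True)
            calls_df.to_csv(results / "pattern_calls.tsv", sep="\t", index=False)
            # shared simplified categories across conditions (tissues)
            shared = (
                calls_df.pivot_table(
                    index=["gene1", "gene2"], columns="tissue",
                    values="simplified", aggfunc="first",
                )
                .apply(lambda row: patterns.shared_categories(list(row)), axis=1)
                .rename("n_shared")
                .reset_index()
            )
            shared.to_csv(results / "shared_categories.tsv", sep="\t", index=False)
            xtab = (
                calls_df.merge(pairs, on=["gene1", "gene2"])
                .groupby(["mechanism", "pattern"]).size().rename("n").reset_index()
            )
            xtab.to_csv(results / "mechanism_by_pattern.tsv", sep="\t", index=False)
            summary["pattern_counts"] = (
                calls_df.groupby(["tissue", "pattern"]).size().rename("n")
                .reset_index().to_dict("records")
            )
            summary["shared_category_counts"] = (
                shared.groupby("n_shared").size().rename("n").reset_index()
                .to_dict("records")
            )

    if "acr" in stages:
        genome = _load_genome_any(indir / "genome.fa")
        genes = read_gff3(indir / "genes.gff3")
        acrs = read_bed(indir / "acrs.bed")
        assoc = conservation.associate_acrs(acrs, genes)
        acrs_by_gene: dict[str, list] = {}
        for a in acrs:
            gid = assoc.get(a.acr_id)
            if gid is not None:
                acrs_by_gene.setdefault(gid, []).append(a)
        chrom_lengths = {c: len(genome[c]) for c in genome}
        pair_rows = []
        for row in pairs.itertuples(index=False):
            rec = conservation.pair_acr_summary(
                (row.gene1, row.gene2), acrs_by_gene, genome, genes,
                chrom_lengths, conserved_b=cfg.conserved_B, mask_self=cfg.mask_self,
            )
            rec["pair_id"] = getattr(row, "pair_id", f"{row.gene1}|{row.gene2}")
            pair_rows.append(rec)
        pair_df = pd.DataFrame(pair_rows)
        pair_df.to_csv(results / "acr_pair_summary.tsv", sep="\t", index=False)
        log.append(f"acr: {len(pair_df)} pairs scored")
        summary["acr_pair_means"] = {
            k: float(pair_df[k].mean())
            for k in ("frac_conserved", "mean_B_conserved", "mean_M_conserved", "frac_unblasted")
        }
        quads_path = indir / "quads.tsv"
        if quads_path.exists():
            quads = read_quads(quads_path)
            qrecs = []
            for q in quads.itertuples(index=False):
                recs = conservation.quad_conservation(
                    [q.gene1, q.gene2, q.gene3, q.gene4], acrs_by_gene, genome,
                    genes, chrom_lengths, conserved_b=cfg.conserved_B,
                )
                for r in recs:
                    qrecs.append({"set_id": q.set_id, **dataclasses.asdict(r)})
            qdf = pd.DataFrame(qrecs)
            qdf.to_csv(results / "acr_quad_conservation.tsv", sep="\t", index=False)
            if len(qdf):
                states = qdf.drop_duplicates(["set_id", "acr_id"])["state"]
                summary["conservation_state_proportions"] = (
                    states.value_counts(normalize=True).sort_index().round(6).to_dict()
                )
            log.append(f"acr: {len(qdf)} quad ACR alignments")

    if "dynamics" in stages:
        acc_path = indir / "accessibility.tsv"
        if acc_path.exists():
            acc = pd.read_csv(acc_path, sep="\t")
            rows = []
            for entity, sub in acc.groupby("entity"):
                prof = sub.pivot_table(
                    index="acr_id", columns="condition", values="present", aggfunc="first"
                ).fillna(0)
                d = accessibility.jaccard_distance(prof, pooled=cfg.pooled_jaccard)
                rows.append({"entity": entity, "distance": d, "n_acrs": prof.shape[0]})
            dyn = pd.DataFrame(rows).sort_values("entity")
            dyn.to_csv(results / "accessibility_distance.tsv", sep="\t", index=False)
            summary["mean_accessibility_distance"] = float(dyn["distance"].mean())
            log.append(f"dynamics: {len(dyn)} entities")

    if "trajectories" in stages:
        spec_path = indir / "specificity.tsv"
        quads_path = indir / "quads.tsv"
        if spec_path.exists() and quads_path.exists():
            de_flags = pd.read_csv(spec_path, sep="\t", index_col=0)
            quads = read_quads(quads_path)
            rows = []
            for q in quads.itertuples(index=False):
                tree_file = indir / "trees" / f"{q.set_id}.nwk"
                tree = read_newick(tree_file) if tree_file.exists() else None
                call = trajectory.infer_trajectory(
                    q.set_id, de_flags, [q.gene1, q.gene2, q.gene3, q.gene4],
                    tree=tree, strict_recent_split=cfg.strict_recent_split,
                    k1_distance=cfg.k1_distance, max_within=cfg.max_within,
                )
                rows.append(
                    {
                        "set_id": call.set_id,
                        "k": call.k,
                        "sizes": ":".join(map(str, call.sizes)),
                        "scenario": call.scenario,
                        "scenario_name": call.scenario_name,
                        "recent_match": call.recent_match,
                    }
                )
            tdf = pd.DataFrame(rows)
            tdf.to_csv(results / "trajectory_calls.tsv", sep="\t", index=False)
            summary["scenario_counts"] = (
                tdf.groupby("scenario").size().rename("n").reset_index().to_dict("records")
            )
            log.append(f"trajectories: {len(tdf)} sets called")

    manifest = {
        "config": cfg.to_jsonable(),
        "seed": cfg.seed,
        "stages": list(stages),
        "log": log,
    }
    (results / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    (results / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    return results


def _require(path: Path, msg: str) -> None:
    if not path.exists():
        raise FileNotFoundError(f"{msg}: {path}")


def _load_genome_any(path: Path) -> dict[str, str]:
    _require(path, "acr stage needs genome.fa")
    return load_genome(path)
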