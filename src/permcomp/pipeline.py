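"""End-to-end orchestration: simulate or ingest tables, bin/filter,
transform, run the per-platform MANCOVA with stepwise selection, the
per-category ANCOVAs, the repeated-measures ANCOVA with its Measurements
row, the qPCR ANCOVAs and the cohort table, and write a reproducible
result bundle (TSV tables plus a manifest).

Identical configuration (including the seed) produces a byte-identical
bundle: every analysis draws its permutation seed from one master stream in
a fixed stage order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import cohort_table
from .model_selection import CandidatePool, SelectionTrace, stepwise_select
from .permanova import ModelTerm, PartitionResult, euclidean_distances
from .repeated_measures import rm_permutation_ancova
from .synthetic_cohort import (
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    read_cohort,
    simulate_cohort,
)
from .tables_io import CLR_CATEGORIES, COVARIATES, align_tables, filter_min_reads
from .transforms import clr_transform, default_epsilon, empirical_logit

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["term", "kind", "df", "r2", "p", "fdr"]


@dataclass
class RunConfig:
    """A full pipeline run: inputs (or a simulate block), candidate pool,
    and inference settings."""

    seed: int
    simulate: SimulationConfig | None = None
    input_dir: str | None = None
    platforms: list[str] | None = None
    pool: str | dict = "full"  # "full", "mains", or {mains: [...], interactions: [...]}
    alpha: float = 0.05
    permutations: int = 999
    pseudocount: float = 0.5
    epsilon: float | None = None  # None -> data-adaptive per qPCR target
    min_reads: int = 100
    outdir: str = "results"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("config needs either a simulate block or an input_dir")

    def candidate_pool(self) -> CandidatePool:
        if isinstance(self.pool, dict):
            return CandidatePool(
                mains=tuple(self.pool.get("mains", COVARIATES)),
                interactions=tuple(map(tuple, self.pool.get("interactions", ()))),
            )
        if self.pool == "full":
            return CandidatePool.full(COVARIATES)
        if self.pool == "mains":
            return CandidatePool.mains_only(COVARIATES)
        raise ValueError(f"unknown pool spec {self.pool!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if data.get("simulate") is not None:
            data["simulate"] = config_from_dict(data["simulate"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "input_dir": self.input_dir,
            "platforms": self.platforms,
            "pool": self.pool,
            "alpha": self.alpha,
            "permutations": self.permutations,
            "pseudocount": self.pseudocount,
            "epsilon": self.epsilon,
            "min_reads": self.min_reads,
            "outdir": self.outdir,
        }
        out["simulate"] = (
            config_to_dict(self.simulate) if self.simulate is not None else None
        )
        return out


def default_config_yaml() -> str:
    """The full default configuration (simulated null cohort) as YAML."""
    config = RunConfig(seed=0, simulate=SimulationConfig())
    return yaml.safe_dump(config.to_dict(), sort_keys=False)


def _result_table(result: PartitionResult) -> pd.DataFrame:
    table = result.table.copy()
    if "fdr" not in table.columns:
        table["fdr"] = np.nan
    table = table[RESULT_COLUMNS]
    tail = pd.DataFrame(
        [
            {"term": "Residual", "kind": "residual", "df": result.residual_df,
             "r2": result.residual_ss / result.total_ss, "p": np.nan, "fdr": np.nan},
            {"term": "Total", "kind": "total", "df": result.residual_df + int(result.table["df"].sum()),
             "r2": 1.0, "p": np.nan, "fdr": np.nan},
        ]
    )
    return pd.concat([table, tail], ignore_index=True)


def _trace_table(trace: SelectionTrace) -> pd.DataFrame:
    if trace.final is None:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return _result_table(trace.final)


def _union_terms(traces: dict[str, SelectionTrace]) -> list[ModelTerm]:
    """Union of selected terms across platforms: mains first (first-seen
    order), then interactions."""
    seen: dict[str, ModelTerm] = {}
    for trace in traces.values():
        if trace.final is None:
            continue
        for _, row in trace.steps.iterrows():
            name = row["term"]
            if name not in seen:
                if row["kind"] == "main":
                    seen[name] = ModelTerm.main(name)
                else:
                    a, b = name.split("*")
                    seen[name] = ModelTerm.interaction(a, b)
    mains = [t for t in seen.values() if t.kind == "main"]
    inters = [t for t in seen.values() if t.kind == "interaction"]
    return mains + inters


@dataclass
class RunResult:
    """All result tables of one pipeline run, before/after writing."""

    cohort: pd.DataFrame
    mancova: dict[str, SelectionTrace]
    ancova: dict[str, dict[str, SelectionTrace]]  # platform -> category -> trace
    repeated: dict[str, PartitionResult]  # category -> result
    qpcr: dict[str, SelectionTrace]  # target -> trace
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def run(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full analysis sequence on simulated or ingested tables."""
    master = np.random.default_rng(config.seed)

    def next_seed() -> int:
        return int(master.integers(2**31 - 1))

    # ---- inputs -----------------------------------------------------------
    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
        metadata, counts, qpcr = cohort.metadata, cohort.counts, cohort.qpcr
    else:
        metadata, counts, qpcr = read_cohort(config.input_dir)
    if config.platforms:
        counts = {p: counts[p] for p in config.platforms}
    if not counts:
        raise ValueError("stage inputs: no count tables to analyze")

    counts = {p: filter_min_reads(t, config.min_reads) for p, t in counts.items()}
    aligned = align_tables(metadata, counts, qpcr=qpcr)
    pool = config.candidate_pool()
    pool_vars = set(pool.mains)

    def complete(meta: pd.DataFrame) -> pd.DataFrame:
        cols = [c for c in meta.columns if c in pool_vars or c == "phenotype"]
        keep = meta[cols].notna().all(axis=1)
        if (~keep).any():
            logger.info("dropping %d subject(s) with missing pooled covariates",
                        int((~keep).sum()))
        return meta.loc[keep]

    tables: dict[str, pd.DataFrame] = {}

    # ---- cohort table -----------------------------------------------------
    cohort_df = cohort_table(metadata)
    tables["cohort_table"] = cohort_df

    # ---- per-platform MANCOVA with stepwise selection ---------------------
    mancova: dict[str, SelectionTrace] = {}
    clr_by_platform: dict[str, pd.DataFrame] = {}
    for platform, (meta_p, counts_p) in aligned.per_platform.items():
        meta_p = complete(meta_p)
        clr = clr_transform(counts_p.loc[meta_p.index], config.pseudocount)
        clr_by_platform[platform] = clr
        d = euclidean_distances(clr)
        trace = stepwise_select(
            d, pool, meta_p, alpha=config.alpha,
            n_permutations=config.permutations, seed=next_seed(),
        )
        mancova[platform] = trace
        tables[f"mancova_{platform}"] = _trace_table(trace)
        logger.info("MANCOVA %s: selected %s (%s)", platform, trace.selected,
                    trace.stopping_reason)

    # ---- per-category ANCOVAs (parallel per platform) ---------------------
    ancova: dict[str, dict[str, SelectionTrace]] = {}
    for platform, clr in clr_by_platform.items():
        meta_p = aligned.per_platform[platform][0]
        meta_p = complete(meta_p)
        ancova[platform] = {}
        parts = []
        for category in CLR_CATEGORIES:
            trace = stepwise_select(
                clr[category].to_numpy(), pool, meta_p, alpha=config.alpha,
                n_permutations=config.permutations, seed=next_seed(),
            )
            ancova[platform][category] = trace
            part = _trace_table(trace)
            if len(part):
                part.insert(0, "category", category)
                parts.append(part)
        tables[f"ancova_{platform}"] = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["category", *RESULT_COLUMNS])
        )

    # ---- repeated-measures ANCOVA across platforms ------------------------
    repeated: dict[str, PartitionResult] = {}
    complete_meta = complete(metadata.loc[aligned.complete_cases])
    rm_parts = []
    for category in CLR_CATEGORIES:
        union = _union_terms(
            {p: ancova[p][category] for p in ancova}
        )
        wide = pd.DataFrame(
            {
                p: clr_by_platform[p][category].reindex(complete_meta.index)
                for p in clr_by_platform
            }
        ).dropna()
        if not union or len(wide) < 3:
            continue
        result = rm_permutation_ancova(
            wide, union, complete_meta.loc[wide.index],
            n_permutations=config.permutations, seed=next_seed(),
        )
        from .model_selection import bh_fdr

        result.table["fdr"] = bh_fdr(result.table["p"].to_numpy())
        repeated[category] = result
        part = _result_table(result)
        part.insert(0, "category", category)
        rm_parts.append(part)
    if rm_parts:
        tables["repeated_measures"] = pd.concat(rm_parts, ignore_index=True)
    else:
        tables["repeated_measures"] = pd.DataFrame(columns=["category", *RESULT_COLUMNS])

    # ---- qPCR ANCOVAs -----------------------------------------------------
    qpcr_traces: dict[str, SelectionTrace] = {}
    meta_all = complete(metadata)
    for target in sorted(qpcr["target"].unique()) if len(qpcr) else []:
        sub = qpcr[qpcr["target"] == target].set_index("subject_id")
        ids = [i for i in meta_all.index if i in sub.index]
        freq = sub.loc[ids, "relative_frequency"].to_numpy(dtype=float)
        eps = config.epsilon if config.epsilon is not None else default_epsilon(freq)
        y = empirical_logit(freq, eps)
        trace = stepwise_select(
            y, pool, meta_all.loc[ids], alpha=config.alpha,
            n_permutations=config.permutations, seed=next_seed(),
        )
        qpcr_traces[target] = trace
        tables[f"qpcr_{target}"] = _trace_table(trace)

    result = RunResult(
        cohort=cohort_df, mancova=mancova, ancova=ancova,
        repeated=repeated, qpcr=qpcr_traces, tables=tables,
    )
    if write:
        write_bundle(result, config)
    return result


def write_bundle(result: RunResult, config: RunConfig) -> Path:
    """Write every result table as TSV plus a manifest; returns the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    config_dict = config.to_dict()
    canonical = yaml.safe_dump(config_dict, sort_keys=True)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "permcomp_version": __version__,
        "tables": sorted(result.tables),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir
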