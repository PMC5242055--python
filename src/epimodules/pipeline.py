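"""Config-driven end-to-end orchestration.

The pipeline runs: context interval derivation and locus association ->
distance-decay correlation profile estimation -> per-interval Cholesky
decorrelation and weighted Stouffer aggregation -> quantile-permutation size
adjustment -> cross-context normalization -> gene-level combination with
bootstrap null -> network module discovery. All intermediate tables are
written as TSV, together with a JSON run manifest; re-running with the same
config and seed reproduces every output byte for byte.

A single global seed fans out to per-stage seeds derived by hashing the
stage name, so adding a stage never perturbs the randomness of earlier
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from epimodules import combine as comb
from epimodules import correlation as corr
from epimodules import genome_context as gc
from epimodules import modules as mod
from epimodules import normalize as norm
from epimodules import scoring

logger = logging.getLogger(__name__)

EXPRESSION_CONTEXT = "expression"


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: stable hash of (global seed, stage name), < 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ContextConfig:
    name: str
    track: str
    rule: str = "gene_body"                 # promoter_window | gene_body | custom_bed
    upstream_bp: int = 1000
    downstream_bp: int = 500
    bed_path: str = ""
    flank_bp: int = 0
    max_link_distance: int = 50_000
    weight: float = 1.0
    direction: int = 0
    locus_weighting: str = "uniform"        # uniform | tss_distance_decay
    halflife_bp: float = 1000.0

    def to_definition(self) -> gc.ContextDefinition:
        if self.rule == "promoter_window":
            interval_rule = ("promoter_window", self.upstream_bp, self.downstream_bp)
        elif self.rule == "gene_body":
            interval_rule = ("gene_body",)
        elif self.rule == "custom_bed":
            interval_rule = ("custom_bed", self.bed_path, self.flank_bp)
        else:
            raise ValueError(f"context {self.name}: unknown rule {self.rule!r}")
        weighting = (
            ("tss_distance_decay", self.halflife_bp)
            if self.locus_weighting == "tss_distance_decay"
            else ("uniform",)
        )
        return gc.ContextDefinition(
            name=self.name,
            track_id=self.track,
            interval_rule=interval_rule,
            context_weight=self.weight,
            direction_coefficient=self.direction,
            locus_weighting=weighting,
        )


@dataclass
class RunConfig:
    """Validated configuration for a full run. Unknown keys are rejected."""

    genes_bed: str = ""
    tracks: dict[str, dict] = field(default_factory=dict)   # track_id -> {path, one_based}
    expression: str = ""
    expression_weight: float = 1.0
    expression_direction: int = 1
    network_edges: str = ""
    contexts: list[ContextConfig] = field(default_factory=list)

    # Monte-Carlo parameters
    n_bins: int = 500
    n_resamples: int = 500
    n_null_distributions: int = 100
    n_strata: int = 10
    n_boot: int = 1000
    significance_threshold: float = 0.05
    combiner: str = "stouffer"

    normalization: str = "logit_rescale"

    module_algorithm: str = "spinglass"     # spinglass | mwcs | both
    gamma: float = 0.5
    min_module_size: int = 8
    max_module_size: int = 100
    high_score_alpha: float = 0.05

    seed: int = 0
    out_dir: str = "run_output"

    def __post_init__(self) -> None:
        total_weight = sum(c.weight for c in self.contexts) + (
            self.expression_weight if self.expression else 0.0
        )
        if total_weight <= 0:
            raise ValueError("at least one context (or expression) must have positive weight")
        if self.normalization not in ("logit_rescale", "boxcox", "none"):
            raise ValueError(f"unknown normalization method {self.normalization!r}")
        if self.module_algorithm not in ("spinglass", "mwcs", "both", "none"):
            raise ValueError(f"unknown module algorithm {self.module_algorithm!r}")
        if self.combiner not in comb.AGGREGATORS:
            raise ValueError(f"unknown combiner {self.combiner!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        ctxs = []
        ctx_known = {f.name for f in dataclasses.fields(ContextConfig)}
        for c in data.get("contexts", []):
            bad = set(c) - ctx_known
            if bad:
                raise ValueError(f"unknown context keys: {sorted(bad)}")
            ctxs.append(ContextConfig(**c))
        data["contexts"] = ctxs
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def score_contexts(config: RunConfig) -> tuple[dict[str, dict[str, tuple[float, int]]], pd.DataFrame]:
    """Run annotation -> correlation -> combination -> size adjustment per context.

    Returns (per-gene component tables mapping context -> (adjusted_p,
    direction), and the flat context-score DataFrame).
    """
    genes = gc.load_gene_bed(config.genes_bed)
    loci_by_track = {
        tid: gc.load_score_track(spec["path"], tid, one_based=bool(spec.get("one_based", False)))
        for tid, spec in config.tracks.items()
    }
    aggregate = comb.AGGREGATORS[config.combiner]

    rows = []
    component_tables: dict[str, dict[str, tuple[float, int]]] = {}

    for ctx_cfg in config.contexts:
        cdef = ctx_cfg.to_definition()
        skeletons = gc.derive_intervals(genes, cdef, max_link_distance=ctx_cfg.max_link_distance)
        assocs = gc.associate_loci(skeletons, loci_by_track[cdef.track_id], cdef)
        populated = [a for a in assocs if a.n > 0]
        logger.info("context %s: %d/%d intervals carry data", cdef.name, len(populated), len(assocs))
        if not populated:
            continue

        pairs = corr.neighbor_distances(populated, config.significance_threshold)
        profile = None
        if pairs:
            profile = corr.estimate_profile(
                pairs,
                context_name=cdef.name,
                n_bins=config.n_bins,
                n_resamples=config.n_resamples,
                seed=stage_seed(config.seed, f"profile:{cdef.name}"),
            )

        raw_scores: list[tuple[float, int]] = []
        directions: list[int] = []
        per_gene: list[gc.IntervalAssociation] = []
        for assoc in populated:
            z = comb.z_transform(assoc.p_values())
            if profile is not None and assoc.n > 1:
                icorr = corr.interval_matrix(assoc, profile)
                z_star = comb.decorrelate(z, icorr)
            else:
                z_star = z
            raw = aggregate(z_star, assoc.locus_weights)
            direction = comb.assign_direction(assoc.effects(), assoc.locus_weights, z)
            raw_scores.append((raw, assoc.n))
            directions.append(direction)
            per_gene.append(assoc)

        adjusted = comb.quantile_permutation_adjust(
            raw_scores,
            n_null_distributions=config.n_null_distributions,
            n_strata=config.n_strata,
            seed=stage_seed(config.seed, f"adjust:{cdef.name}"),
        )
        for assoc, (raw, n), adj, d in zip(per_gene, raw_scores, adjusted, directions):
            component_tables.setdefault(assoc.gene_id, {})[cdef.name] = (float(adj), int(d))
            rows.append(
                {"gene_id": assoc.gene_id, "context": cdef.name, "n": n,
                 "raw": raw, "adjusted_p": float(adj), "direction": d}
            )

    if config.expression:
        expr = pd.read_csv(config.expression, sep="\t")
        z_expr = comb.z_transform(np.clip(expr["pvalue"].to_numpy(float), comb.P_FLOOR_DEFAULT, 1.0))
        adjusted = comb.quantile_permutation_adjust(
            [(float(z), 1) for z in z_expr],
            n_null_distributions=config.n_null_distributions,
            n_strata=config.n_strata,
            seed=stage_seed(config.seed, "adjust:expression"),
        )
        for (_, row), adj in zip(expr.iterrows(), adjusted):
            d = 1 if row["effect"] >= 0 else -1
            component_tables.setdefault(str(row["gene_id"]), {})[EXPRESSION_CONTEXT] = (float(adj), d)
            rows.append(
                {"gene_id": str(row["gene_id"]), "context": EXPRESSION_CONTEXT, "n": 1,
                 "raw": float(comb.z_transform(float(np.clip(row["pvalue"], comb.P_FLOOR_DEFAULT, 1.0)))),
                 "adjusted_p": float(adj), "direction": d}
            )

    return component_tables, pd.DataFrame(rows)


def _all_context_defs(config: RunConfig) -> list[gc.ContextDefinition]:
    defs = [c.to_definition() for c in config.contexts]
    if config.expression:
        defs.append(
            gc.ContextDefinition(
                name=EXPRESSION_CONTEXT,
                track_id=EXPRESSION_CONTEXT,
                interval_rule=("gene_body",),
                context_weight=config.expression_weight,
                direction_coefficient=config.expression_direction,
            )
        )
    return defs


def score_genes(
    config: RunConfig,
    component_tables: dict[str, dict[str, tuple[float, int]]],
) -> dict[str, scoring.GeneScore]:
    """Normalize contexts, combine per gene, and attach bootstrap p-values."""
    context_defs = _all_context_defs(config)

    # cross-context normalization of adjusted p-values (rank-preserving)
    per_context: dict[str, list] = {}
    index: dict[str, list[str]] = {}
    for gene, table in component_tables.items():
        for name, (adj_p, _) in table.items():
            per_context.setdefault(name, []).append(adj_p)
            index.setdefault(name, []).append(gene)
    normalized, _reports = norm.normalize_contexts(
        {k: np.asarray(v) for k, v in per_context.items()}, method=config.normalization
    )
    for name, values in normalized.items():
        for gene, value in zip(index[name], values):
            direction = component_tables[gene][name][1]
            component_tables[gene][name] = (float(value), direction)

    statistics = {
        gene: scoring.combine_gene(table, context_defs)
        for gene, table in component_tables.items()
        if any(n in {d.name for d in context_defs if d.context_weight > 0} for n in table)
    }
    combined_p = scoring.bootstrap_gene_p(
        statistics,
        component_tables,
        context_defs,
        n_boot=config.n_boot,
        seed=stage_seed(config.seed, "bootstrap"),
    )
    out = {}
    for gene, stat in statistics.items():
        out[gene] = scoring.GeneScore(
            gene_id=gene,
            combined_p=combined_p[gene],
            statistic=float(stat),
            contexts_used=sorted(component_tables[gene]),
            component_table=dict(component_tables[gene]),
        )
    return out


def gene_scores_frame(gene_scores: dict[str, scoring.GeneScore]) -> pd.DataFrame:
    contexts = sorted({c for gs in gene_scores.values() for c in gs.contexts_used})
    rows = []
    for gid in sorted(gene_scores):
        gs = gene_scores[gid]
        row = {
            "gene_id": gid,
            "statistic": gs.statistic,
            "combined_p": gs.combined_p,
            "fisher_score": gs.fisher_score,
        }
        for c in contexts:
            if c in gs.component_table:
                row[f"p_{c}"] = gs.component_table[c][0]
                row[f"dir_{c}"] = gs.component_table[c][1]
            else:
                row[f"p_{c}"] = np.nan
                row[f"dir_{c}"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    component_tables, context_frame = score_contexts(config)
    context_frame.to_csv(out / "context_scores.tsv", sep="\t", index=False, float_format="%.10g")

    gene_scores = score_genes(config, component_tables)
    frame = gene_scores_frame(gene_scores)
    frame.to_csv(out / "gene_scores.tsv", sep="\t", index=False, float_format="%.10g")

    module_list: list[mod.Module] = []
    if config.network_edges and config.module_algorithm != "none":
        edges = _read_edge_list(config.network_edges)
        network = mod.build_scored_network(edges, gene_scores)
        if config.module_algorithm in ("spinglass", "both"):
            module_list += mod.spinglass_modules(
                network,
                gamma=config.gamma,
                min_size=config.min_module_size,
                max_size=config.max_module_size,
                seed=stage_seed(config.seed, "spinglass"),
            )
        if config.module_algorithm in ("mwcs", "both"):
            offset = scoring.background_threshold(
                {g: gs.fisher_score for g, gs in gene_scores.items()},
                alpha=config.high_score_alpha,
                seed=stage_seed(config.seed, "background"),
            )
            module_list.append(mod.greedy_mwcs(network, offset))
        genes_df, summary_df = mod.modules_to_frames(module_list)
        genes_df.to_csv(out / "module_genes.tsv", sep="\t", index=False)
        summary_df.to_csv(out / "module_summary.tsv", sep="\t", index=False, float_format="%.10g")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes_scored": len(gene_scores),
        "n_modules": len(module_list),
        "package_version": _version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _version() -> str:
    from epimodules import __version__
    return __version__


def _read_edge_list(path: str) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise gc.ParseError(f"{path}: edge lines need two tab-separated node ids")
            edges.append((parts[0], parts[1]))
    return edges


def compare_context_scores(
    score_table: pd.DataFrame, context_a: str, context_b: str
) -> tuple[pd.DataFrame, float]:
    """Per-gene paired (score, direction) comparison of two contexts.

    Returns the paired table and the sign-concordance rate (fraction of
    genes where both contexts agree in direction). Raises when no gene has
    both contexts scored.
    """
    cols = [f"p_{context_a}", f"dir_{context_a}", f"p_{context_b}", f"dir_{context_b}"]
    for c in cols:
        if c not in score_table.columns:
            raise ValueError(f"context column {c!r} missing from score table")
    paired = score_table[["gene_id", *cols]].dropna(subset=cols[::2])
    paired = paired[(paired[cols[1]] != 0) & (paired[cols[3]] != 0)]
    if paired.empty:
        raise ValueError(f"no genes scored in both {context_a!r} and {context_b!r}")
    concordance = float((paired[cols[1]] == paired[cols[3]]).mean())
    return paired.reset_index(drop=True), concordance
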