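"""Synthetic genomes, score tracks and interaction networks with planted signal.

The generator emulates the statistical structure of differential epigenomic
data: per-locus Z scores that are spatially correlated over short distances
(modifications such as DNA methylation are highly correlated between nearby
CpGs), folded into two-sided p-values with signed effects, plus a per-gene
expression table and a gene interaction network with an optional planted
community. A subset of "planted" genes carries a mean shift on their locus Z
scores (and their expression Z), providing ground truth for recovery tests.

Effect signs for planted loci agree with the shift direction with
probability 0.9 by default, so direction-assignment logic is exercised with
realistic discordance. Genes are tiled on a single synthetic chromosome by
default; a multi-chromosome layout is available to exercise per-chromosome
interval logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENE_LENGTH = 5_000
GENE_SPACING = 15_000
PROMOTER_UP, PROMOTER_DOWN = 1_000, 500


@dataclass
class SimulationConfig:
    """Stated world for the synthetic data generator.

    Defaults describe a desk-scale experiment: 2000 genes, 3 contexts
    (promoter methylation, gene-body methylation, expression), 5-20 loci per
    epigenomic context per gene (~1e5 loci total), exponential distance
    decay of locus correlation with a 1 kb length scale, and 5% planted
    genes shifted by +3 on the Z scale.
    """

    n_genes: int = 2000
    n_loci_per_context: tuple[int, int] = (5, 20)
    corr_model: tuple = ("exp_decay", 1000.0)   # or ("independent",), ("block", rho)
    planted_genes: frozenset[str] = frozenset()
    n_planted: int = 100
    effect_shift: float = 3.0
    sign_agreement: float = 0.9
    # ("erdos_renyi", p) or ("planted_partition", sizes, p_in, p_cross[, p_bg]):
    # first block = planted community at density p_in, linked to the rest at
    # p_cross; background-background density p_bg (defaults to p_cross).
    network_model: tuple = ("erdos_renyi", 0.005)
    n_chromosomes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_loci_per_context
        if lo < 1 or hi < lo:
            raise ValueError("n_loci_per_context must be a (lo, hi) range with 1 <= lo <= hi")
        if not (0.0 <= self.sign_agreement <= 1.0):
            raise ValueError("sign_agreement must be a probability")
        if self.corr_model[0] == "exp_decay" and self.corr_model[1] <= 0:
            raise ValueError("exp_decay length scale must be positive")
        if self.corr_model[0] == "block" and not (0.0 <= self.corr_model[1] < 1.0):
            raise ValueError("block correlation must be in [0, 1)")


def gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(n)]


def _correlation_matrix(positions: np.ndarray, corr_model: tuple) -> np.ndarray:
    n = len(positions)
    kind = corr_model[0]
    if kind == "independent" or n == 1:
        return np.eye(n)
    if kind == "exp_decay":
        lam = float(corr_model[1])
        d = np.abs(positions[:, None] - positions[None, :]).astype(float)
        return np.exp(-d / lam)
    if kind == "block":
        rho = float(corr_model[1])
        mat = np.full((n, n), rho)
        np.fill_diagonal(mat, 1.0)
        return mat
    raise ValueError(f"unknown correlation model {kind!r}")


def _draw_correlated_z(positions: np.ndarray, corr_model: tuple, rng: np.random.Generator) -> np.ndarray:
    sigma = _correlation_matrix(positions, corr_model)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(len(positions)))
    return chol @ rng.standard_normal(len(positions))


def _z_to_effect_p(
    z: np.ndarray, shift, sign_agreement: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fold signed Z into two-sided p and a signed effect.

    For unshifted loci the effect is the Z value itself. For planted loci the
    effect sign matches the shift direction with probability
    ``sign_agreement`` and is flipped otherwise. ``shift`` may be a scalar or
    a per-locus array.
    """
    shift = np.broadcast_to(np.asarray(shift, dtype=float), np.shape(z))
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    agree = rng.random(len(z)) < sign_agreement
    sign = np.where(agree, np.sign(shift), -np.sign(shift))
    effect = np.where(shift == 0.0, z, sign * np.abs(z))
    return effect, p


def simulate_genome(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write gene BED, methylation track TSV, expression TSV, enhancer BED and truth file.

    Genes are tiled with fixed spacing; each gene receives loci in its
    promoter ([TSS-1000, TSS+500)) and body, with Z drawn from the configured
    spatial correlation model. Planted genes carry a biologically coherent
    dysregulation signature: expression and gene-body methylation Z shifted
    by ``+effect_shift``, promoter methylation Z by ``-effect_shift``
    (promoter methylation anticorrelates with expression). Returns a dict of
    output paths keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ids = gene_ids(config.n_genes)

    planted = set(config.planted_genes)
    if not planted and config.n_planted > 0:
        planted = set(rng.choice(ids, size=min(config.n_planted, len(ids)), replace=False))

    # gene layout: tiled, alternating strands, split over chromosomes
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    bed_rows = []
    layout: dict[str, tuple[str, int, int, str]] = {}
    for i, gid in enumerate(ids):
        chrom = f"chrS{i // per_chrom + 1}"
        start = (i % per_chrom) * GENE_SPACING + PROMOTER_UP + 1
        end = start + GENE_LENGTH
        strand = "+" if i % 2 == 0 else "-"
        layout[gid] = (chrom, start, end, strand)
        bed_rows.append(f"{chrom}\t{start}\t{end}\t{gid}\t0\t{strand}")
    bed_path = out / "genes.bed"
    bed_path.write_text("\n".join(bed_rows) + "\n")

    lo, hi = config.n_loci_per_context
    track_rows = []
    for gid in ids:
        chrom, start, end, strand = layout[gid]
        tss = start if strand == "+" else end
        if strand == "+":
            prom = (max(0, tss - PROMOTER_UP), tss + PROMOTER_DOWN)
        else:
            prom = (max(0, tss - PROMOTER_DOWN), tss + PROMOTER_UP)
        base_shift = config.effect_shift if gid in planted else 0.0
        # one correlated draw per gene over promoter + body loci (one assay
        # value per position); coherent planted signal: promoter methylation
        # moves opposite to expression (B_promoter = -1 biology), gene body
        # moves with it
        if strand == "+":
            body_only = (prom[1], end)
        else:
            body_only = (start, prom[0])
        n_prom = int(rng.integers(lo, hi + 1))
        n_body = int(rng.integers(lo, hi + 1))
        pos_prom = rng.choice(np.arange(*prom), size=min(n_prom, prom[1] - prom[0]), replace=False)
        pos_body = rng.choice(np.arange(*body_only), size=min(n_body, body_only[1] - body_only[0]), replace=False)
        positions = np.concatenate([pos_prom, pos_body])
        shifts = np.concatenate(
            [np.full(len(pos_prom), -base_shift), np.full(len(pos_body), base_shift)]
        )
        order = np.argsort(positions)
        positions, shifts = positions[order], shifts[order]
        z = _draw_correlated_z(positions, config.corr_model, rng) + shifts
        effect, p = _z_to_effect_p(z, shifts, config.sign_agreement, rng)
        for pos, e, pv in zip(positions, effect, p):
            track_rows.append((chrom, int(pos), float(e), float(pv)))
    track = pd.DataFrame(track_rows, columns=["chrom", "position", "effect", "pvalue"])
    track = track.sort_values(["chrom", "position"], kind="stable").drop_duplicates(
        subset=["chrom", "position"], keep="first"
    )
    track_path = out / "methylation.tsv"
    track.to_csv(track_path, sep="\t", index=False, float_format="%.10g")

    # expression: one signed effect + p per gene
    z_expr = rng.standard_normal(config.n_genes)
    expr_rows = []
    for i, gid in enumerate(ids):
        shift = config.effect_shift if gid in planted else 0.0
        z = z_expr[i] + shift
        eff, p = _z_to_effect_p(np.array([z]), shift, config.sign_agreement, rng)
        expr_rows.append((gid, float(eff[0]), float(p[0])))
    expr = pd.DataFrame(expr_rows, columns=["gene_id", "effect", "pvalue"])
    expr_path = out / "expression.tsv"
    expr.to_csv(expr_path, sep="\t", index=False, float_format="%.10g")

    # enhancers: one peak 2-3 kb upstream of every 4th gene's TSS
    enh_rows = []
    for i, gid in enumerate(ids):
        if i % 4:
            continue
        chrom, start, end, strand = layout[gid]
        tss = start if strand == "+" else end
        peak_lo = max(0, tss - 3000) if strand == "+" else tss + 2000
        enh_rows.append(f"{chrom}\t{peak_lo}\t{peak_lo + 1000}\tpeak_{gid}")
    enh_path = out / "enhancers.bed"
    enh_path.write_text("\n".join(enh_rows) + "\n")

    truth_path = out / "planted_genes.txt"
    truth_path.write_text("\n".join(sorted(planted)) + "\n")
    return {
        "genes": bed_path,
        "methylation": track_path,
        "expression": expr_path,
        "enhancers": enh_path,
        "planted": truth_path,
    }


def simulate_network(
    config: SimulationConfig,
    out_dir: str | Path,
    planted: set[str] | None = None,
) -> tuple[Path, Path]:
    """Write an edge-list TSV and a planted-community truth file.

    ``planted_partition(sizes, p_in, p_cross[, p_bg])`` puts the planted
    genes (the shifted ones, by default) into the first block with internal
    edge density ``p_in``, linked to the background at ``p_cross``; the
    background itself has density ``p_bg`` (defaulting to ``p_cross``). A
    realistic interactome background is connected with mean degree around 6,
    i.e. ``p_bg`` well above ``p_cross``. If the planted block comes out
    disconnected the graph is regenerated with a bumped seed (logged).
    ``erdos_renyi(p)`` gives an unstructured background graph.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = gene_ids(config.n_genes)
    kind = config.network_model[0]

    if kind == "erdos_renyi":
        p = float(config.network_model[1])
        g = nx.fast_gnp_random_graph(config.n_genes, p, seed=int(config.seed))
        g = nx.relabel_nodes(g, dict(enumerate(ids)))
        members: list[str] = []
    elif kind == "planted_partition":
        if len(config.network_model) == 4:
            _, sizes, p_in, p_cross = config.network_model
            p_bg = p_cross
        else:
            _, sizes, p_in, p_cross, p_bg = config.network_model
        if sum(sizes) != config.n_genes:
            raise ValueError("planted_partition sizes must sum to n_genes")
        if planted is None:
            planted = set()
        members = sorted(planted)[: sizes[0]]
        rest = [g for g in ids if g not in set(members)]
        ordering = members + rest
        for attempt in range(20):
            seed_i = int(config.seed) + attempt
            g = nx.stochastic_block_model(sizes, _block_probs(len(sizes), p_in, p_cross, p_bg), seed=seed_i)
            g = nx.relabel_nodes(g, dict(enumerate(ordering)))
            if len(members) == 0 or nx.is_connected(g.subgraph(members)):
                if attempt:
                    logger.info("planted community disconnected; regenerated with seed %d", seed_i)
                break
        else:
            raise RuntimeError("could not realize a connected planted community in 20 attempts")
    else:
        raise ValueError(f"unknown network model {kind!r}")

    edge_path = out / "network_edges.tsv"
    with open(edge_path, "w") as fh:
        for u, v in sorted((min(a, b), max(a, b)) for a, b in g.edges):
            fh.write(f"{u}\t{v}\n")
    truth_path = out / "planted_community.txt"
    truth_path.write_text("\n".join(members) + ("\n" if members else ""))
    return edge_path, truth_path


def _block_probs(n_blocks: int, p_in: float, p_cross: float, p_bg: float) -> list[list[float]]:
    """First block is the planted community (density ``p_in``); edges touching it
    use ``p_cross``; the remaining background uses ``p_bg``."""
    probs = []
    for i in range(n_blocks):
        row = []
        for j in range(n_blocks):
            if i == j == 0:
                row.append(p_in)
            elif i == 0 or j == 0:
                row.append(p_cross)
            else:
                row.append(p_bg)
        probs.append(row)
    return probs
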