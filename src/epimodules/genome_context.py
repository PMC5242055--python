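"""Gene annotations, genomic contexts, and locus-to-interval association.

All coordinates are 0-based half-open (BED convention). Score tracks that are
declared 1-based in the run configuration are shifted by -1 at load time so a
single convention holds internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with BED-style coordinates.

    The transcription start site (TSS) is ``start`` on the '+' strand and
    ``end`` on the '-' strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class Locus:
    """One genomic position carrying a signed effect and a p-value."""

    track_id: str
    chrom: str
    position: int
    effect: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"locus {self.chrom}:{self.position}: p must be in (0, 1]")
        if self.position < 0:
            raise ValueError(f"locus {self.chrom}:{self.position}: negative position")


@dataclass(frozen=True)
class ContextDefinition:
    """A gene-anchored interval class within which locus evidence is aggregated.

    Parameters
    ----------
    name
        Context label, e.g. ``promoter``, ``body``, ``enhancer_active``.
    track_id
        Which score track supplies the loci for this context.
    interval_rule
        One of ``("promoter_window", upstream_bp, downstream_bp)``,
        ``("gene_body",)``, or ``("custom_bed", path, flank_bp)``.
    context_weight
        Nonnegative weight of this context in the final gene-level
        combination (the w.j of the weighted Stouffer step).
    direction_coefficient
        +1 if the context's effect direction is expected to agree with the
        phenotype direction, -1 if opposed (e.g. promoter methylation vs
        expression), 0 for agnostic contexts that contribute magnitude only.
    locus_weighting
        ``("uniform",)`` or ``("tss_distance_decay", halflife_bp)`` giving the
        per-locus weights w_ijk inside the interval.
    """

    name: str
    track_id: str
    interval_rule: tuple = ("gene_body",)
    context_weight: float = 1.0
    direction_coefficient: int = 0
    locus_weighting: tuple = ("uniform",)

    def __post_init__(self) -> None:
        if self.context_weight < 0:
            raise ValueError(f"context {self.name}: negative context_weight")
        if self.direction_coefficient not in (-1, 0, 1):
            raise ValueError(f"context {self.name}: direction_coefficient must be -1, 0 or +1")
        kind = self.interval_rule[0]
        if kind not in ("promoter_window", "gene_body", "custom_bed"):
            raise ValueError(f"context {self.name}: unknown interval rule {kind!r}")
        if kind == "promoter_window":
            up, down = self.interval_rule[1], self.interval_rule[2]
            if up < 0 or down < 0:
                raise ValueError(f"context {self.name}: promoter window sizes must be >= 0")
        if self.locus_weighting[0] not in ("uniform", "tss_distance_decay"):
            raise ValueError(f"context {self.name}: unknown locus weighting")


@dataclass
class IntervalAssociation:
    """A gene x context interval together with the loci that fall inside it.

    Loci are sorted ascending by position; ``locus_weights`` is aligned with
    ``loci``. Empty associations (``n == 0``) are retained and flagged so that
    missing data is visible downstream rather than silently dropped.
    """

    gene_id: str
    context_name: str
    chrom: str
    start: int
    end: int
    tss: int
    loci: list[Locus] = field(default_factory=list)
    locus_weights: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.loci)

    @property
    def missing_data(self) -> bool:
        return self.n == 0

    def positions(self) -> np.ndarray:
        return np.array([l.position for l in self.loci], dtype=np.int64)

    def p_values(self) -> np.ndarray:
        return np.array([l.p for l in self.loci], dtype=float)

    def effects(self) -> np.ndarray:
        return np.array([l.effect for l in self.loci], dtype=float)


# ---------------------------------------------------------------------------
# readers


def load_gene_bed(path: str) -> list[GeneModel]:
    """Read a gene annotation BED file (>= 4 columns, tab-delimited).

    Column 6, when present, is the strand; rows without one default to '+'
    (logged). Duplicate gene ids and malformed coordinates raise
    :class:`ParseError` naming the offending line.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    n_defaulted = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            else:
                strand = "+"
                n_defaulted += 1
            genes.append(GeneModel(name, chrom, start, end, strand))
    if n_defaulted:
        logger.warning("%s: %d rows lacked a strand column; defaulted to '+'", path, n_defaulted)
    return genes


def load_score_track(path: str, track_id: str, one_based: bool = False) -> list[Locus]:
    """Read a per-locus score track: TSV with header chrom/position/effect/pvalue.

    ``one_based=True`` shifts positions by -1 into the internal 0-based
    convention. Rows with p outside (0, 1] raise :class:`ParseError`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "position", "effect", "pvalue"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    shift = -1 if one_based else 0
    loci = []
    for row in df.itertuples(index=False):
        pos = int(row.position) + shift
        try:
            loci.append(Locus(track_id, str(row.chrom), pos, float(row.effect), float(row.pvalue)))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    loci.sort(key=lambda l: (l.chrom, l.position))
    return loci


def _load_interval_bed(path: str) -> list[tuple[str, int, int]]:
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            intervals.append((fields[0], start, end))
    return intervals


# ---------------------------------------------------------------------------
# interval derivation


def derive_intervals(
    genes: Sequence[GeneModel],
    ctx: ContextDefinition,
    max_link_distance: int = 50_000,
) -> list[IntervalAssociation]:
    """Derive the genomic interval of ``ctx`` for every gene (loci not yet attached).

    ``promoter_window(up, down)`` spans [TSS - up, TSS + down) in the gene's
    orientation: on the '-' strand "upstream" extends to larger coordinates.
    ``gene_body`` is [start, end). ``custom_bed`` intervals (optionally
    flanked) are each assigned to the gene whose TSS is nearest within
    ``max_link_distance`` bp; ties break to the lexicographically smaller
    gene id. Intervals truncated at 0 are logged.
    """
    kind = ctx.interval_rule[0]
    out: list[IntervalAssociation] = []

    if kind == "custom_bed":
        path, flank = ctx.interval_rule[1], int(ctx.interval_rule[2])
        raw = _load_interval_bed(path)
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, start, end in raw:
            start = max(0, start - flank)
            end = end + flank
            candidates = by_chrom.get(chrom, [])
            if not candidates:
                continue
            mid = (start + end) // 2
            best = min(
                candidates, key=lambda g: (abs(g.tss - mid), g.gene_id)
            )
            if abs(best.tss - mid) <= max_link_distance:
                out.append(
                    IntervalAssociation(best.gene_id, ctx.name, chrom, start, end, best.tss)
                )
        return out

    n_truncated = 0
    for g in genes:
        if kind == "gene_body":
            start, end = g.start, g.end
        else:  # promoter_window
            up, down = int(ctx.interval_rule[1]), int(ctx.interval_rule[2])
            if g.strand == "+":
                start, end = g.tss - up, g.tss + down
            else:
                start, end = g.tss - down, g.tss + up
            if start < 0:
                start = 0
                n_truncated += 1
        out.append(IntervalAssociation(g.gene_id, ctx.name, g.chrom, start, end, g.tss))
    if n_truncated:
        logger.warning("context %s: %d promoter intervals truncated at 0", ctx.name, n_truncated)
    return out


def _locus_weights(
    positions: np.ndarray, tss: int, weighting: tuple
) -> np.ndarray:
    if weighting[0] == "uniform":
        return np.ones(len(positions), dtype=float)
    halflife = float(weighting[1])
    d = np.abs(positions.astype(float) - tss)
    return np.power(2.0, -d / halflife)


def associate_loci(
    intervals: Iterable[IntervalAssociation],
    loci: Sequence[Locus],
    ctx: ContextDefinition,
) -> list[IntervalAssociation]:
    """Attach to each interval all loci with start <= position < end (same chrom).

    Loci are binary-searched against sorted positions per chromosome; every
    interval comes back with its loci sorted by position and per-locus weights
    computed from ``ctx.locus_weighting``. Empty intervals are retained with
    the ``missing_data`` flag set.
    """
    by_chrom: dict[str, list[Locus]] = {}
    for l in sorted(loci, key=lambda l: (l.chrom, l.position)):
        by_chrom.setdefault(l.chrom, []).append(l)
    pos_by_chrom = {
        chrom: np.array([l.position for l in ls], dtype=np.int64)
        for chrom, ls in by_chrom.items()
    }

    out = []
    for iv in intervals:
        hit: list[Locus] = []
        if iv.chrom in pos_by_chrom:
            positions = pos_by_chrom[iv.chrom]
            lo = int(np.searchsorted(positions, iv.start, side="left"))
            hi = int(np.searchsorted(positions, iv.end, side="left"))
            hit = by_chrom[iv.chrom][lo:hi]
        weights = _locus_weights(
            np.array([l.position for l in hit], dtype=np.int64), iv.tss, ctx.locus_weighting
        )
        out.append(
            IntervalAssociation(
                iv.gene_id, iv.context_name, iv.chrom, iv.start, iv.end, iv.tss,
                loci=list(hit), locus_weights=[float(w) for w in weights],
            )
        )
    return out
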