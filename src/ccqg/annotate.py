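"""QTL annotation: interval-to-gene overlap and gene-rank enrichment.

A QTL support interval is intersected with a pre-resolved gene table
(0-based half-open coordinates; ortholog mapping happens upstream of this
package).  Member genes are then tested for enrichment of high positions
in a supplied disorder-implication ranking of the whole genome (rank 1 =
most implicated): by default a one-sided rank-sum test of member ranks
against all other ranked genes, with a resampling alternative that draws
random same-size gene sets as the reference oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError

GENE_COLUMNS = ("gene_id", "chrom", "start", "end")


@dataclass(frozen=True)
class GeneRanking:
    """gene_id -> rank mapping over a ranked genome of size G."""

    ranks: pd.Series
    genome_size: int

    def __post_init__(self):
        r = self.ranks.astype(int)
        if r.index.duplicated().any():
            raise InvalidArgumentError("duplicate gene IDs in ranking")
        if r.duplicated().any():
            raise InvalidArgumentError("ranks must be unique")
        if len(r) and (r.min() < 1 or r.max() > self.genome_size):
            raise InvalidArgumentError(
                "ranks must be positive integers <= genome size"
            )
        object.__setattr__(self, "ranks", r)

    @classmethod
    def from_scores(
        cls, scores: pd.Series, higher_is_implicated: bool = True
    ) -> "GeneRanking":
        """Rank genes from implication scores (rank 1 = most implicated);
        any order-preserving rescaling of the scores yields the same
        ranking."""
        order = scores.rank(
            ascending=not higher_is_implicated, method="first"
        ).astype(int)
        return cls(order, genome_size=len(scores))


def genes_in_interval(interval, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes whose [start, end) overlaps the support interval by >= 1 bp.

    ``interval`` is a QtlInterval or a (chrom, start_bp, end_bp) tuple;
    strand is ignored; an unknown chromosome yields an empty result with a
    warning.
    """
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            raise InvalidArgumentError(f"gene table lacks column {col!r}")
    if hasattr(interval, "chrom"):
        chrom, start, end = interval.chrom, interval.start_bp, interval.end_bp
    else:
        chrom, start, end = interval
    sub = genes[genes["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        warnings.warn(f"no genes on chromosome {chrom!r}")
        return sub
    hit = (sub["start"] < end) & (sub["end"] > start)
    return sub[hit].reset_index(drop=True)


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided enrichment of a QTL's genes toward low (implicated) ranks."""

    qtl_id: str
    genes: tuple[str, ...]
    ranks: tuple[int, ...]
    statistic: float
    p_value: float
    method: str

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise InvalidArgumentError("P must lie in (0, 1]")


def rank_enrichment(
    gene_ids,
    ranking: GeneRanking,
    method: str = "ranksum",
    n_resample: int = 10_000,
    seed: int | None = None,
    qtl_id: str = "QTL",
) -> EnrichmentResult:
    """Are a QTL's genes enriched for high implication (small ranks)?

    ``ranksum`` compares member ranks against all other ranked genes
    (one-sided, alternative: members rank smaller).  ``resampling`` draws
    ``n_resample`` random gene sets of the same size from the whole ranked
    genome and reports the add-one tail probability of a mean rank at most
    as small as observed.
    """
    ranks = ranking.ranks
    member = ranks.loc[ranks.index.intersection(pd.Index(gene_ids))]
    if member.empty:
        raise InvalidArgumentError("no member genes present in the ranking")
    others = ranks.drop(member.index)
    if others.empty:
        # members exhaust the ranked genome: no enrichment is possible
        return EnrichmentResult(
            qtl_id, tuple(member.index), tuple(member), float(member.mean()),
            1.0, method,
        )
    if method == "ranksum":
        stat, p = stats.mannwhitneyu(
            member.to_numpy(), others.to_numpy(), alternative="less"
        )
        return EnrichmentResult(
            qtl_id, tuple(member.index), tuple(member), float(stat),
            float(max(p, np.nextafter(0, 1))), method,
        )
    if method == "resampling":
        rng = np.random.default_rng(seed)
        pool = ranks.to_numpy()
        k = len(member)
        obs = member.to_numpy().mean()
        keys = rng.random((n_resample, len(pool)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        means = pool[idx].mean(axis=1)
        p = (1 + int((means <= obs + 1e-12).sum())) / (n_resample + 1)
        return EnrichmentResult(
            qtl_id, tuple(member.index), tuple(member), float(obs), p, method
        )
    raise InvalidArgumentError(f"unknown method {method!r}")
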