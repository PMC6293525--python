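"""Plain-text readers and writers for every pipeline interface.

Conventions: founder alleles and genotypes are CSV with markers as rows
(marker, chrom, bp, cM, then one column per founder or line; missing =
"NA"); true mosaics are BED-like TSV with 0-based half-open bp; descent
probabilities are written both long (line, chrom, start, end, founder,
prob) and wide (one row per line x interval with eight founder columns);
phenotypes are tidy CSV, one row per animal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import GeneRanking
from .genmap import GeneticMap
from .herit import KinshipMatrix
from .hmm import DescentProbabilities
from .scan import PermutationResult, QtlInterval, ScanResult
from .simulate import (
    BP_PER_CM,
    CC_FOUNDERS,
    FounderHaplotypes,
    GenotypeMatrix,
    MosaicGenome,
)

MAP_COLUMNS = ["marker", "chrom", "bp", "cM"]


# -- founders and genotypes -------------------------------------------------


def write_founders(founders: FounderHaplotypes, path) -> None:
    df = founders.gmap.markers[MAP_COLUMNS].copy()
    for i, name in enumerate(founders.founders):
        df[name] = founders.alleles[i]
    df.to_csv(path, index=False)


def read_founders(path, chrom_lengths=None) -> FounderHaplotypes:
    df = pd.read_csv(path, dtype={"chrom": str})
    names = [c for c in df.columns if c not in MAP_COLUMNS]
    gmap = GeneticMap(df[MAP_COLUMNS], chrom_lengths=chrom_lengths)
    alleles = df[names].to_numpy().T.astype(np.uint8)
    return FounderHaplotypes(gmap, alleles, tuple(names))


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = geno.gmap.markers[MAP_COLUMNS].copy()
    for i, lid in enumerate(geno.line_ids):
        col = geno.calls[i].astype(object)
        col[geno.calls[i] == -1] = "NA"
        df[lid] = col
    df.to_csv(path, index=False)


def read_genotypes(path, chrom_lengths=None) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"chrom": str}, na_values=["NA"])
    lines = [c for c in df.columns if c not in MAP_COLUMNS]
    gmap = GeneticMap(df[MAP_COLUMNS], chrom_lengths=chrom_lengths)
    calls = df[lines].to_numpy(dtype=float).T
    calls = np.where(np.isnan(calls), -1, calls).astype(np.int8)
    return GenotypeMatrix(gmap, tuple(lines), calls)


# -- mosaics ----------------------------------------------------------------


def write_mosaics(mosaics: Sequence[MosaicGenome], path,
                  bp_per_cm: int = BP_PER_CM) -> None:
    pd.concat([m.to_frame(bp_per_cm) for m in mosaics]).to_csv(
        path, sep="\t", index=False
    )


def read_mosaics(path, bp_per_cm: int = BP_PER_CM) -> list[MosaicGenome]:
    """Rebuild mosaics from the BED-like TSV (cM recovered at the writer's
    bp-per-cM scale; funnel order is not stored and reads back as
    identity)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for lid, sub in df.groupby("line", sort=False):
        haps: list[dict] = [{}, {}]
        lengths: dict[str, float] = {}
        for (chrom, h), seg in sub.groupby(["chrom", "haplotype"], sort=False):
            segs = [
                (r.start_bp / bp_per_cm, r.end_bp / bp_per_cm, int(r.founder))
                for r in seg.itertuples()
            ]
            haps[int(h) - 1][chrom] = segs
            lengths[chrom] = max(lengths.get(chrom, 0.0), segs[-1][1])
        out.append(
            MosaicGenome(
                line_id=str(lid),
                funnel=tuple(range(8)),
                hap1=haps[0],
                hap2=haps[1],
                chrom_lengths=lengths,
            )
        )
    return out


# -- descent probabilities --------------------------------------------------


def write_descent_long(probs: DescentProbabilities, path) -> None:
    iv = probs.intervals
    L, M = probs.n_lines, probs.n_intervals
    df = pd.DataFrame(
        {
            "line": np.repeat(list(probs.line_ids), M * 8),
            "chrom": np.tile(np.repeat(iv["chrom"].to_numpy(), 8), L),
            "start_bp": np.tile(np.repeat(iv["start_bp"].to_numpy(), 8), L),
            "end_bp": np.tile(np.repeat(iv["end_bp"].to_numpy(), 8), L),
            "founder": np.tile(list(probs.founders), L * M),
            "prob": probs.p.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_descent_wide(probs: DescentProbabilities, path) -> None:
    iv = probs.intervals
    L, M = probs.n_lines, probs.n_intervals
    df = pd.DataFrame(
        {
            "line": np.repeat(list(probs.line_ids), M),
            "chrom": np.tile(iv["chrom"].to_numpy(), L),
            "start_bp": np.tile(iv["start_bp"].to_numpy(), L),
            "end_bp": np.tile(iv["end_bp"].to_numpy(), L),
            "cm": np.tile(iv["cm"].to_numpy(), L),
            "cm_width": np.tile(iv["cm_width"].to_numpy(), L),
        }
    )
    for f, name in enumerate(probs.founders):
        df[name] = probs.p[:, :, f].reshape(-1)
    df.to_csv(path, index=False, float_format="%.8g")


def read_descent_wide(path) -> DescentProbabilities:
    df = pd.read_csv(path, dtype={"chrom": str})
    meta = ["line", "chrom", "start_bp", "end_bp", "cm", "cm_width"]
    founders = [c for c in df.columns if c not in meta]
    lines = list(dict.fromkeys(df["line"]))
    M = len(df) // len(lines)
    iv = df.iloc[:M][["chrom", "start_bp", "end_bp", "cm", "cm_width"]]
    p = df[founders].to_numpy().reshape(len(lines), M, len(founders))
    # renormalize away round-off from the text representation
    p = p / p.sum(axis=2, keepdims=True)
    return DescentProbabilities(
        tuple(lines), iv.reset_index(drop=True), p, tuple(founders)
    )


# -- simple tables ----------------------------------------------------------


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"line": str, "batch": str, "origin": str})


def write_kinship(k: KinshipMatrix, path) -> None:
    k.to_frame().to_csv(path)


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(tuple(df.index.astype(str)), df.to_numpy())


def write_scan(scan: ScanResult, path) -> None:
    scan.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_permutations(perm: PermutationResult, path) -> None:
    pd.DataFrame({"max_logp": perm.maxima}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_qtls(qtls: Sequence[QtlInterval], path) -> None:
    rows = [
        (
            q.trait,
            q.chrom,
            q.start_bp,
            q.end_bp,
            q.peak_start_bp,
            q.peak_end_bp,
            q.peak_logp,
            q.permuted_p if q.permuted_p is not None else "NA",
        )
        for q in qtls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "trait", "chrom", "start_bp", "end_bp",
            "peak_start_bp", "peak_end_bp", "peak_logp", "permuted_p",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_table(path) -> pd.DataFrame:
    """BED-compatible TSV: chrom, start, end, gene_id[, score, strand]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "gene_id" not in df.columns:  # headerless BED
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            dtype={"chrom": str},
        )
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    out = genes.copy()
    if "score" not in out.columns:
        out["score"] = 0
    out[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", index=False
    )


def read_ranking(path) -> GeneRanking:
    df = pd.read_csv(path)
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "rank"]
    s = pd.Series(df["rank"].to_numpy(int), index=df["gene_id"].astype(str))
    return GeneRanking(s, genome_size=int(s.max()))


def write_ranking(ranking: GeneRanking, path) -> None:
    pd.DataFrame(
        {"gene_id": ranking.ranks.index, "rank": ranking.ranks.to_numpy()}
    ).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
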