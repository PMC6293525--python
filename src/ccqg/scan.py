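"""Haplotype-dosage genome scans with permutation thresholds.

At each genomic interval, weighted least squares regresses corrected and
normalized CC line means on the eight founder-descent probability columns
(intercept plus seven free founder contrasts; weights are the number of
animals behind each line mean).  The interval's score is
LogP = -log10 of the F-test P-value against the intercept-only weighted
model.  Genome-wide significance thresholds come from permuting line means
across lines (weights stay attached to the lines) and recording the
genome-wide maximum LogP of each permutation; support intervals are the
maximal contiguous run around a peak with LogP >= peak - 1.

The scan deliberately contains no kinship or covariate term: phenotypes
are corrected upstream, and polygenic inflation under heritable traits is
a documented property of this design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import InvalidArgumentError
from .hmm import DescentProbabilities

LOGP_CAP = 300.0
MIN_LINES = 10


def _align(values, line_ids) -> np.ndarray:
    if isinstance(values, pd.Series):
        try:
            return values.loc[list(line_ids)].to_numpy(float)
        except KeyError as exc:
            raise InvalidArgumentError(f"line {exc} missing from values") from None
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(line_ids),):
        raise InvalidArgumentError("values must align with probability lines")
    return arr


class _ScanEngine:
    """Per-interval weighted designs factored once, reused across
    permutations.  Absent founders (zero probability in every line) are
    dropped with a flag; remaining rank deficiency is absorbed by a
    rank-revealing QR."""

    def __init__(self, probs: DescentProbabilities, weights: np.ndarray):
        P = probs.p
        L, M, _ = P.shape
        if np.any(weights <= 0):
            raise InvalidArgumentError("weights must be positive")
        self.sw = np.sqrt(weights)
        self.swn = self.sw / np.linalg.norm(self.sw)
        self.n_lines = L
        self.n_intervals = M
        self.df_num = np.zeros(M, dtype=int)
        self.df_den = np.zeros(M, dtype=int)
        self.reduced = np.zeros(M, dtype=bool)
        width = 0
        qs = []
        ones = np.ones(L)
        for m in range(M):
            pm = P[:, m, :]
            present = np.flatnonzero(pm.max(axis=0) > 1e-8)
            cols = pm[:, present[:-1]] if len(present) > 1 else np.empty((L, 0))
            X = np.column_stack([ones, cols]) * self.sw[:, None]
            Q, R, _ = linalg.qr(X, mode="economic", pivoting=True)
            d = np.abs(np.diag(R))
            rank = int((d > max(d[0], 1e-300) * 1e-10).sum())
            qs.append(Q[:, :rank])
            self.df_num[m] = rank - 1
            self.df_den[m] = L - rank
            self.reduced[m] = len(present) < 8 or rank < X.shape[1]
            width = max(width, rank)
        self.Q = np.zeros((M, L, width))
        for m, q in enumerate(qs):
            self.Q[m, :, : q.shape[1]] = q

    def logp_many(self, Y: np.ndarray, block: int = 512) -> np.ndarray:
        """LogP for each interval (rows) and each phenotype column of Y."""
        Yw = Y * self.sw[:, None]
        tot = (Yw**2).sum(axis=0)
        rss0 = tot - (self.swn @ Yw) ** 2
        M, K = self.n_intervals, Y.shape[1]
        logp = np.zeros((M, K))
        dfn = self.df_num[:, None]
        dfd = self.df_den[:, None]
        for a in range(0, M, block):
            b = min(a + block, M)
            proj = np.einsum("mlp,lk->mpk", self.Q[a:b], Yw)
            rss1 = np.maximum(tot[None, :] - (proj**2).sum(axis=1), 0.0)
            num = np.maximum(rss0[None, :] - rss1, 0.0)
            ok = (dfn[a:b] > 0) & (dfd[a:b] > 0) & (rss1 > 1e-300)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (num / dfn[a:b]) / (rss1 / dfd[a:b])
                p = stats.f.sf(F, dfn[a:b], dfd[a:b])
                lp = np.where(p > 0, -np.log10(p), LOGP_CAP)
            logp[a:b] = np.where(ok, np.minimum(lp, LOGP_CAP), 0.0)
        return logp

    def logp(self, y: np.ndarray) -> np.ndarray:
        return self.logp_many(y[:, None])[:, 0]


@dataclass
class ScanResult:
    """Per-interval association scores for one trait."""

    table: pd.DataFrame  # chrom, start_bp, end_bp, cm, logp, df_num, reduced
    trait: str
    line_ids: tuple[str, ...]
    weights: np.ndarray
    engine: _ScanEngine | None = field(default=None, repr=False)

    @property
    def logp(self) -> np.ndarray:
        return self.table["logp"].to_numpy()

    def peak_index(self, chrom: str | None = None) -> int:
        t = self.table
        if chrom is None:
            return int(t["logp"].idxmax())
        sub = t[t["chrom"] == chrom]
        if sub.empty:
            raise InvalidArgumentError(f"no intervals on chromosome {chrom}")
        return int(sub["logp"].idxmax())


def scan_genome(
    line_values,
    weights,
    probs: DescentProbabilities,
    trait: str = "trait",
) -> ScanResult:
    """Weighted founder-probability regression at every interval.

    ``line_values`` are (corrected, normalized) line means, ``weights`` the
    number of animals per line; both align with ``probs.line_ids`` (pass a
    Series indexed by line ID for name-based alignment).
    """
    L = probs.n_lines
    if L < MIN_LINES:
        raise InvalidArgumentError(f"scan requires >= {MIN_LINES} lines")
    y = _align(line_values, probs.line_ids)
    w = (
        np.ones(L)
        if weights is None
        else _align(weights, probs.line_ids)
    )
    engine = _ScanEngine(probs, w)
    if np.ptp(y) == 0:
        warnings.warn("zero-variance line means; LogP is 0 everywhere")
        logp = np.zeros(probs.n_intervals)
    else:
        logp = engine.logp(y)
    table = probs.intervals.copy()
    table["logp"] = logp
    table["df_num"] = engine.df_num
    table["reduced"] = engine.reduced
    return ScanResult(table, trait, probs.line_ids, w, engine)


@dataclass
class PermutationResult:
    """Null distribution of the genome-wide maximum LogP."""

    n_perm: int
    maxima: np.ndarray
    alphas: tuple[float, ...]
    seed: int | None

    def threshold(self, alpha: float) -> float:
        """Empirical (1-alpha) quantile: order statistic at
        ceil((1-alpha) * n_perm)."""
        srt = np.sort(self.maxima)
        idx = min(max(math.ceil((1 - alpha) * self.n_perm), 1), self.n_perm)
        return float(srt[idx - 1])

    @property
    def thresholds(self) -> dict[float, float]:
        return {a: self.threshold(a) for a in self.alphas}

    def permuted_p(self, observed_logp: float) -> float:
        """Add-one permutation P of an observed genome-wide peak."""
        count = int((self.maxima >= observed_logp - 1e-12).sum())
        return (1 + count) / (self.n_perm + 1)


def permutation_threshold(
    line_values,
    weights,
    probs: DescentProbabilities,
    n_perm: int = 1000,
    alphas: tuple[float, ...] = (0.05, 0.1, 0.5),
    seed: int | None = None,
    engine: _ScanEngine | None = None,
) -> PermutationResult:
    """Genome-wide significance thresholds by permuting line means.

    Means are shuffled across lines while the per-line weights stay
    attached to the lines; each permutation's genome-wide maximum LogP is
    recorded and thresholds are empirical quantiles of those maxima.
    """
    if n_perm < 100:
        raise InvalidArgumentError(
            "n_perm < 100 makes the threshold quantile too unstable"
        )
    y = _align(line_values, probs.line_ids)
    w = (
        np.ones(probs.n_lines)
        if weights is None
        else _align(weights, probs.line_ids)
    )
    rng = np.random.default_rng(seed)
    engine = engine or _ScanEngine(probs, w)
    Y = np.empty((probs.n_lines, n_perm))
    for k in range(n_perm):
        Y[:, k] = rng.permutation(y)
    logp = engine.logp_many(Y)
    return PermutationResult(
        n_perm=n_perm,
        maxima=logp.max(axis=0),
        alphas=tuple(alphas),
        seed=seed,
    )


@dataclass(frozen=True)
class QtlInterval:
    """A QTL peak with its LogP-drop support interval (0-based half-open)."""

    trait: str
    chrom: str
    peak_index: int
    peak_start_bp: int
    peak_end_bp: int
    start_bp: int
    end_bp: int
    peak_logp: float
    member_indices: tuple[int, ...]
    permuted_p: float | None = None

    def __post_init__(self):
        if not (self.start_bp <= self.peak_start_bp and
                self.peak_end_bp <= self.end_bp):
            raise InvalidArgumentError("support interval must contain the peak")


def define_qtl_interval(
    scan: ScanResult, peak: int, drop: float = 1.0
) -> QtlInterval:
    """Support interval: the maximal contiguous run of intervals on the
    peak's chromosome, containing the peak, with LogP >= peak LogP - drop."""
    t = scan.table
    if not 0 <= peak < len(t):
        raise InvalidArgumentError("peak not on scan")
    chrom = t.at[peak, "chrom"]
    logp = t["logp"].to_numpy()
    on_chrom = np.flatnonzero((t["chrom"] == chrom).to_numpy())
    pos = int(np.searchsorted(on_chrom, peak))
    cutoff = logp[peak] - drop
    lo = pos
    while lo > 0 and logp[on_chrom[lo - 1]] >= cutoff:
        lo -= 1
    hi = pos
    while hi < len(on_chrom) - 1 and logp[on_chrom[hi + 1]] >= cutoff:
        hi += 1
    members = on_chrom[lo : hi + 1]
    return QtlInterval(
        trait=scan.trait,
        chrom=str(chrom),
        peak_index=peak,
        peak_start_bp=int(t.at[peak, "start_bp"]),
        peak_end_bp=int(t.at[peak, "end_bp"]),
        start_bp=int(t.loc[members[0], "start_bp"]),
        end_bp=int(t.loc[members[-1], "end_bp"]),
        peak_logp=float(logp[peak]),
        member_indices=tuple(int(i) for i in members),
    )


def significant_qtls(
    scan: ScanResult,
    perm: PermutationResult,
    alpha: float = 0.05,
    drop: float = 1.0,
) -> list[QtlInterval]:
    """One QTL per chromosome whose peak reaches genome-wide permuted
    P < alpha, each with its LogP-drop support interval."""
    out = []
    for chrom in dict.fromkeys(scan.table["chrom"]):
        peak = scan.peak_index(chrom)
        p = perm.permuted_p(float(scan.table.at[peak, "logp"]))
        if p < alpha:
            qtl = define_qtl_interval(scan, peak, drop)
            out.append(
                QtlInterval(
                    **{
                        **qtl.__dict__,
                        "permuted_p": p,
                    }
                )
            )
    return out
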