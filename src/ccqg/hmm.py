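"""Founder-mosaic reconstruction by a hidden Markov model.

Each near-inbred CC line's genome is modelled as a Markov chain over 8
hidden states, one per homozygous founder.  At a marker with observed
dosage call g and founder allele a_f, the emission is 1-eps when
g == 2*a_f and eps/2 for each of the two other calls; a missing call emits
1 for every state.  Heterozygous calls therefore only surface through eps,
which is how residual heterozygosity appears as local ambiguity rather
than as extra states.  Between adjacent markers at map distance d cM the
chain stays on its founder with probability 1 - r_eff and switches to each
specific other founder with probability r_eff / 7, where

    r_eff = (1 - exp(-a * d / 50)) / 2      (capped at 7/8)

and a is a map-expansion factor that inflates single-meiosis recombination
into the effective recombination accumulated by inbred lines.  Posterior
descent probabilities come from the scaled forward-backward recursion;
an optional Viterbi pass yields a hard founder labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InconsistentInputError, InvalidArgumentError
from .genmap import GeneticMap, interval_frame
from .simulate import FounderHaplotypes, GenotypeMatrix, MosaicGenome

N_FOUNDERS = 8


@dataclass(frozen=True)
class HmmParams:
    """Tunable reconstruction parameters.

    error_rate
        Genotyping error eps in [0, 0.5); also absorbs residual
        heterozygosity.  Default 0.01.
    expansion
        Map-expansion factor a > 0 scaling cM distances into RIL-effective
        recombination.  Default 2 (between an F2 and the full RIL limit).
    init
        Initial distribution over the 8 founders (default uniform 1/8).
    """

    error_rate: float = 0.01
    expansion: float = 2.0
    init: tuple[float, ...] | None = None

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 0.5:
            raise InvalidArgumentError("error_rate must lie in [0, 0.5)")
        if self.expansion <= 0:
            raise InvalidArgumentError("expansion must be > 0")
        if self.init is not None:
            init = np.asarray(self.init, dtype=float)
            if init.shape != (N_FOUNDERS,) or abs(init.sum() - 1.0) > 1e-8:
                raise InvalidArgumentError(
                    "init must be 8 probabilities summing to 1"
                )
            object.__setattr__(self, "init", tuple(init))

    @property
    def init_array(self) -> np.ndarray:
        if self.init is None:
            return np.full(N_FOUNDERS, 1.0 / N_FOUNDERS)
        return np.asarray(self.init, dtype=float)


@dataclass
class DescentProbabilities:
    """Posterior probability of descent from each founder per interval.

    ``p[l, m, f]`` is the probability that line ``l`` descends from founder
    ``f`` at interval ``m``; rows sum to 1.  ``intervals`` carries
    chromosome, 0-based half-open bp bounds, the cM midpoint and the cM
    width of each interval.
    """

    line_ids: tuple[str, ...]
    intervals: pd.DataFrame
    p: np.ndarray  # (L, M, 8)
    founders: tuple[str, ...]
    viterbi: np.ndarray | None = None  # (L, M) founder indices, optional

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        L, M = len(self.line_ids), len(self.intervals)
        if p.shape != (L, M, N_FOUNDERS):
            raise InvalidArgumentError(
                f"p shape {p.shape} does not match ({L}, {M}, 8)"
            )
        if p.size:
            if p.min() < -1e-10 or p.max() > 1 + 1e-10:
                raise InconsistentInputError("probabilities outside [0, 1]")
            sums = p.sum(axis=2)
            if np.abs(sums - 1.0).max() > 1e-8:
                raise InconsistentInputError(
                    "descent probabilities must sum to 1 per (line, interval)"
                )
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        object.__setattr__(self, "founders", tuple(self.founders))

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def subset_intervals(self, idx: np.ndarray) -> "DescentProbabilities":
        idx = np.sort(np.asarray(idx, dtype=int))
        sub = self.intervals.iloc[idx]
        frames = []
        for chrom, grp in sub.groupby("chrom", sort=False):
            # rebuild cM widths so retained intervals tile the chromosome's
            # original extent
            span = self.intervals.loc[
                self.intervals["chrom"] == chrom, "cm_width"
            ].sum()
            frames.append(
                interval_frame(
                    chrom,
                    grp["end_bp"].to_numpy(),  # placeholder, replaced below
                    grp["cm"].to_numpy(),
                    span,
                )
            )
        new = pd.concat(frames, ignore_index=True)
        # keep original bp bounds of the retained intervals (identity of the
        # member markers), but use retiled cM widths for weighting
        new["start_bp"] = sub["start_bp"].to_numpy()
        new["end_bp"] = sub["end_bp"].to_numpy()
        vit = None if self.viterbi is None else self.viterbi[:, idx]
        return DescentProbabilities(
            self.line_ids, new, self.p[:, idx, :], self.founders, vit
        )


# ---------------------------------------------------------------------------
# forward-backward / Viterbi core
# ---------------------------------------------------------------------------


def recomb_fraction(d_cm: np.ndarray, expansion: float) -> np.ndarray:
    """Effective founder-switch probability across a gap of d cM."""
    r = (1.0 - np.exp(-expansion * np.asarray(d_cm, dtype=float) / 50.0)) / 2.0
    return np.minimum(r, 7.0 / 8.0)


def _emissions(obs: np.ndarray, alleles: np.ndarray, eps: float) -> np.ndarray:
    """(M, 8) emission probabilities for one line on one chromosome."""
    expected = 2 * alleles.astype(np.int16)  # (8, M)
    m = obs.shape[0]
    e = np.where(obs[None, :] == expected, 1.0 - eps, eps / 2.0).T  # (M, 8)
    e[obs == -1] = 1.0
    return e


def _forward_backward(e: np.ndarray, r: np.ndarray, init: np.ndarray):
    """Scaled forward-backward for the symmetric 8-state chain.

    Exploits the exchangeable transition structure: for a normalized
    distribution v, (v @ T) = (1 - r - r/7) * v + r/7.
    Returns (posterior (M,8), log-likelihood).
    """
    m, k = e.shape
    alpha = np.empty((m, k))
    c = np.empty(m)
    a = init * e[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, m):
        rt = r[t - 1]
        pred = (1.0 - rt - rt / 7.0) * alpha[t - 1] + rt / 7.0
        a = pred * e[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((m, k))
    beta[-1] = 1.0
    for t in range(m - 2, -1, -1):
        rt = r[t]
        nb = e[t + 1] * beta[t + 1]
        beta[t] = ((1.0 - rt - rt / 7.0) * nb + (rt / 7.0) * nb.sum()) / c[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, float(np.log(c).sum())


def _viterbi(e: np.ndarray, r: np.ndarray, init: np.ndarray) -> np.ndarray:
    """Most probable founder path (log space, top-2 trick for the
    exchangeable transition)."""
    m, k = e.shape
    with np.errstate(divide="ignore"):
        loge = np.log(e)
        delta = np.log(init) + loge[0]
    psi = np.zeros((m, k), dtype=np.int8)
    for t in range(1, m):
        rt = r[t - 1]
        with np.errstate(divide="ignore"):
            stay = np.log1p(-rt) if rt < 1 else -np.inf
            move = np.log(rt / 7.0) if rt > 0 else -np.inf
        order = np.argsort(delta)
        best, second = order[-1], order[-2]
        cand_stay = delta + stay
        cand_move = np.full(k, delta[best] + move)
        cand_move_arg = np.full(k, best, dtype=np.int8)
        cand_move[best] = delta[second] + move
        cand_move_arg[best] = second
        take_stay = cand_stay >= cand_move
        psi[t] = np.where(take_stay, np.arange(k, dtype=np.int8), cand_move_arg)
        delta = np.where(take_stay, cand_stay, cand_move) + loge[t]
    path = np.empty(m, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(m - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def reconstruct_descent(
    genotypes: GenotypeMatrix,
    founders: FounderHaplotypes,
    params: HmmParams | None = None,
    return_viterbi: bool = False,
) -> DescentProbabilities:
    """Posterior founder-descent probabilities for every line and interval.

    Runs the scaled forward-backward recursion independently per line and
    chromosome (numerically stable for arbitrarily long marker runs); an
    all-missing chromosome yields the uniform prior 1/8.
    """
    params = params or HmmParams()
    if not genotypes.gmap.same_markers(founders.gmap):
        raise InconsistentInputError(
            "genotypes and founders must share the same marker map"
        )
    gmap = founders.gmap
    L = len(genotypes.line_ids)
    M = gmap.n_markers
    if M == 0:
        warnings.warn("map has zero markers; returning uniform priors")
        return DescentProbabilities(
            genotypes.line_ids,
            gmap.intervals,
            np.empty((L, 0, N_FOUNDERS)),
            founders.founders,
        )
    eps = params.error_rate
    init = params.init_array
    p = np.empty((L, M, N_FOUNDERS))
    vit = np.empty((L, M), dtype=np.int8) if return_viterbi else None
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        cm = gmap.markers["cM"].to_numpy()[sl]
        r = recomb_fraction(np.diff(cm), params.expansion)
        alleles = founders.alleles[:, sl]
        for i in range(L):
            e = _emissions(genotypes.calls[i, sl], alleles, eps)
            if eps == 0.0:
                # guard against all-zero emission rows (an impossible call
                # under every founder): treat such markers as missing
                bad = e.sum(axis=1) == 0
                e[bad] = 1.0
            p[i, sl], _ = _forward_backward(e, r, init)
            if return_viterbi:
                vit[i, sl] = _viterbi(e, r, init)
    return DescentProbabilities(
        genotypes.line_ids, gmap.intervals, p, founders.founders, vit
    )


def descent_from_truth(
    mosaics: Sequence[MosaicGenome],
    gmap: GeneticMap,
    founders: tuple[str, ...] | None = None,
) -> DescentProbabilities:
    """Noiseless descent probabilities read directly off true mosaics
    (each haplotype contributes 1/2 to its founder); the simulation-truth
    counterpart of :func:`reconstruct_descent`."""
    from .simulate import CC_FOUNDERS

    L, M = len(mosaics), gmap.n_markers
    p = np.zeros((L, M, N_FOUNDERS))
    idx = np.arange(M)
    for i, mos in enumerate(mosaics):
        labels = mos.founder_labels(gmap)
        p[i, idx, labels[0]] += 0.5
        p[i, idx, labels[1]] += 0.5
    return DescentProbabilities(
        tuple(m.line_id for m in mosaics),
        gmap.intervals,
        p,
        founders or CC_FOUNDERS,
    )


def prune_intervals(
    probs: DescentProbabilities, target_count: int
) -> DescentProbabilities:
    """Thin intervals to ~``target_count``, approximately evenly spaced in
    cM, always retaining the first and last interval per chromosome."""
    M = probs.n_intervals
    chroms = list(dict.fromkeys(probs.intervals["chrom"]))
    if target_count > M:
        raise InvalidArgumentError("target_count exceeds interval count")
    if target_count < len(chroms):
        raise InvalidArgumentError(
            "target_count smaller than the number of chromosomes"
        )
    if target_count == M:
        return probs
    counts = {
        c: int((probs.intervals["chrom"] == c).sum()) for c in chroms
    }
    # proportional allocation with a floor of min(2, available)
    alloc = {
        c: min(counts[c], max(2 if counts[c] > 1 else 1,
                              int(round(target_count * counts[c] / M))))
        for c in chroms
    }
    while sum(alloc.values()) > target_count:
        c = max(alloc, key=lambda x: alloc[x])
        if alloc[c] <= 2:
            break
        alloc[c] -= 1
    keep = []
    offset = 0
    for c in chroms:
        sub = probs.intervals[probs.intervals["chrom"] == c]
        cm = sub["cm"].to_numpy()
        n_c = alloc[c]
        if n_c >= len(cm):
            sel = np.arange(len(cm))
        else:
            # greedy walk: jump to the marker nearest to one step ahead,
            # re-deriving the step from the remaining span and budget so
            # the total lands on ~n_c; first/last always retained
            picks = [0]
            while picks[-1] < len(cm) - 1 and len(picks) < n_c - 1:
                remaining = n_c - len(picks)
                target = cm[picks[-1]] + (cm[-1] - cm[picks[-1]]) / remaining
                i = int(np.searchsorted(cm, target))
                i = min(max(i, picks[-1] + 1), len(cm) - 1)
                j = i - 1 if (
                    i - 1 > picks[-1]
                    and abs(cm[i - 1] - target) <= abs(cm[i] - target)
                ) else i
                picks.append(j)
            if picks[-1] != len(cm) - 1:
                picks.append(len(cm) - 1)
            sel = np.asarray(picks)
        keep.append(sel + offset)
        offset += len(cm)
    return probs.subset_intervals(np.concatenate(keep))


@dataclass(frozen=True)
class FounderContributions:
    """Genome-wide and per-interval founder shares plus absence flags."""

    overall: pd.Series  # cM-weighted mean share per founder
    per_interval: pd.DataFrame  # (M, 8) mean over lines
    per_line: pd.DataFrame  # (L, 8) cM-weighted mean over intervals
    absent: pd.DataFrame  # (interval, founder) pairs with zero share


def founder_contributions(
    probs: DescentProbabilities, zero_tol: float = 1e-12
) -> FounderContributions:
    """Founder-share accounting from descent probabilities.

    Overall shares are the cM-weighted average of per-interval shares (mean
    over lines); intervals at which a founder's share is exactly zero are
    flagged, mirroring the panel-level check for locally missing founder
    haplotypes.
    """
    if probs.n_intervals == 0 or probs.n_lines == 0:
        raise InvalidArgumentError("empty descent probabilities")
    w = probs.intervals["cm_width"].to_numpy()
    w = w / w.sum()
    per_interval = probs.p.mean(axis=0)  # (M, 8)
    overall = pd.Series(per_interval.T @ w, index=probs.founders)
    per_line = pd.DataFrame(
        np.tensordot(probs.p, w, axes=(1, 0)),
        index=list(probs.line_ids),
        columns=list(probs.founders),
    )
    zero = np.argwhere(per_interval <= zero_tol)
    absent = pd.DataFrame(
        {
            "interval": zero[:, 0],
            "chrom": probs.intervals["chrom"].to_numpy()[zero[:, 0]],
            "founder": [probs.founders[f] for f in zero[:, 1]],
        }
    )
    return FounderContributions(
        overall=overall,
        per_interval=pd.DataFrame(per_interval, columns=list(probs.founders)),
        per_line=per_line,
        absent=absent,
    )
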