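"""Synthetic Collaborative Cross populations with known ground truth.

The Collaborative Cross (CC) is a panel of recombinant inbred mouse lines
descended from eight founder strains.  Each line is bred through a
three-generation "funnel" that combines all eight founders into a single
pedigree (four pairwise crosses, two four-way crosses, one eight-way cross)
followed by repeated brother-sister mating; lines are conventionally
regarded as fully inbred around generation F20.  This module simulates that
process explicitly, meiosis by meiosis, so that every downstream stage
(mosaic reconstruction, kinship, heritability, QTL mapping) can be tested
against a known truth:

* founder haplotypes at biallelic SNPs on a genetic map,
* true line genomes as founder-labelled segment mosaics (with residual
  heterozygosity from finite inbreeding),
* observed genotype calls with genotyping error and missingness,
* per-animal phenotypes with a chosen QTL architecture, a kinship-structured
  polygenic component, covariate effects and residual noise,
* a synthetic genome-wide gene table and disorder-implication ranking for
  the annotation stage.

Crossovers follow a Poisson process on the cM scale (Haldane model, one
crossover per 100 cM per meiosis, no interference).  Sex chromosomes are
not modelled.  All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InconsistentInputError, InvalidArgumentError
from .genmap import GeneticMap

#: The eight CC founder strains (five classical, three wild-derived).
CC_FOUNDERS = (
    "A/J",
    "C57BL/6J",
    "129S1/SvImJ",
    "NOD/ShiLtJ",
    "NZO/HlLtJ",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
)

#: bp per cM used when laying out synthetic physical coordinates
#: (mouse genome-wide average is roughly 2 Mb per cM).
BP_PER_CM = 2_000_000

# A haplotype is an ordered list of (start_cM, end_cM, founder) segments
# tiling [0, chrom_length).
Segment = tuple[float, float, int]
Haplotype = list[Segment]


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FounderHaplotypes:
    """Alleles of the eight fully inbred founders at mapped SNPs."""

    gmap: GeneticMap
    alleles: np.ndarray  # (8, M) in {0, 1}
    founders: tuple[str, ...] = CC_FOUNDERS

    def __post_init__(self):
        a = np.asarray(self.alleles, dtype=np.uint8)
        if len(self.founders) != 8:
            raise InvalidArgumentError("exactly 8 founders required")
        if a.shape != (8, self.gmap.n_markers):
            raise InvalidArgumentError(
                f"alleles shape {a.shape} does not match 8 founders x "
                f"{self.gmap.n_markers} markers"
            )
        if a.size and not np.isin(a, (0, 1)).all():
            raise InvalidArgumentError("founder alleles must be 0/1")
        object.__setattr__(self, "alleles", a)
        object.__setattr__(self, "founders", tuple(self.founders))

    @property
    def n_markers(self) -> int:
        return self.gmap.n_markers


def simulate_founders(
    n_markers_per_chr: Sequence[int] | int,
    chr_lengths_cM: Sequence[float] | float,
    allele_freq: float = 0.5,
    seed: int | None = None,
    chrom_names: Sequence[str] | None = None,
    founders: Sequence[str] = CC_FOUNDERS,
) -> FounderHaplotypes:
    """Simulate 8 inbred founder strains genotyped on a fresh genetic map.

    Markers are spread uniformly at random in cM along each chromosome and
    each founder's allele is an independent Bernoulli(``allele_freq``) draw.
    Physical positions are laid out at ``BP_PER_CM`` bp per cM.
    """
    if np.isscalar(chr_lengths_cM):
        chr_lengths_cM = [float(chr_lengths_cM)]
    chr_lengths_cM = [float(x) for x in chr_lengths_cM]
    if np.isscalar(n_markers_per_chr):
        n_markers_per_chr = [int(n_markers_per_chr)] * len(chr_lengths_cM)
    n_markers_per_chr = [int(x) for x in n_markers_per_chr]
    if len(n_markers_per_chr) != len(chr_lengths_cM):
        raise InvalidArgumentError(
            "n_markers_per_chr and chr_lengths_cM must have equal length"
        )
    if not chr_lengths_cM:
        raise InvalidArgumentError("at least one chromosome required")
    if any(n < 0 for n in n_markers_per_chr):
        raise InvalidArgumentError("marker counts must be non-negative")
    if any(x <= 0 for x in chr_lengths_cM):
        raise InvalidArgumentError("chromosome lengths must be positive")
    if not 0.0 < allele_freq < 1.0:
        raise InvalidArgumentError("allele_freq must lie in (0, 1)")
    if chrom_names is None:
        chrom_names = [str(i + 1) for i in range(len(chr_lengths_cM))]

    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for chrom, n, length in zip(chrom_names, n_markers_per_chr, chr_lengths_cM):
        cm = np.sort(rng.uniform(0.0, length, size=n))
        bp = np.maximum(1, (cm * BP_PER_CM).astype(np.int64))
        # force strictly increasing bp so cM ties cannot land on distinct bp
        bp = np.maximum.accumulate(bp + np.arange(n))
        for j in range(n):
            rows.append((f"M{k + j:06d}", chrom, bp[j], cm[j]))
        k += n
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"])
    if markers.empty:
        markers = pd.DataFrame(columns=["marker", "chrom", "bp", "cM"])
    gmap = GeneticMap(
        markers, chrom_lengths=dict(zip(chrom_names, chr_lengths_cM))
    )
    alleles = (rng.random((8, gmap.n_markers)) < allele_freq).astype(np.uint8)
    return FounderHaplotypes(gmap, alleles, tuple(founders))


# ---------------------------------------------------------------------------
# funnel breeding
# ---------------------------------------------------------------------------


def _merge(segs: Haplotype) -> Haplotype:
    out = [segs[0]]
    for s in segs[1:]:
        if s[2] == out[-1][2]:
            out[-1] = (out[-1][0], s[1], s[2])
        else:
            out.append(s)
    return out


def _clip(hap: Haplotype, lo: float, hi: float, out: Haplotype) -> None:
    for a, b, f in hap:
        if b <= lo:
            continue
        if a >= hi:
            break
        out.append((max(a, lo), min(b, hi), f))


def _meiosis(h1: Haplotype, h2: Haplotype, length: float, rng) -> Haplotype:
    """One gamete from a parent's two haplotypes (Haldane crossovers)."""
    pick = int(rng.integers(2))
    if length <= 0:
        return list((h1, h2)[pick])
    n_xo = int(rng.poisson(length / 100.0))
    if n_xo == 0:
        return list((h1, h2)[pick])
    bounds = np.empty(n_xo + 2)
    bounds[0], bounds[-1] = 0.0, length
    bounds[1:-1] = np.sort(rng.uniform(0.0, length, size=n_xo))
    out: Haplotype = []
    for i in range(n_xo + 1):
        _clip((h1, h2)[(pick + i) % 2], bounds[i], bounds[i + 1], out)
    return _merge(out)


# an individual is a pair of {chrom: Haplotype} dicts
def _gamete(ind, lengths, rng):
    return {c: _meiosis(ind[0][c], ind[1][c], L, rng) for c, L in lengths.items()}


def _cross(mother, father, lengths, rng):
    return (_gamete(mother, lengths, rng), _gamete(father, lengths, rng))


def _founder_individual(f: int, lengths):
    haps = {c: [(0.0, L, f)] for c, L in lengths.items()}
    return (haps, {c: list(h) for c, h in haps.items()})


def _label_at(hap: Haplotype, pos: float) -> int:
    ends = [s[1] for s in hap]
    i = int(np.searchsorted(ends, pos, side="right"))
    return hap[min(i, len(hap) - 1)][2]


@dataclass
class MosaicGenome:
    """A CC line's true genome as founder-labelled segments (two haplotypes)."""

    line_id: str
    funnel: tuple[int, ...]
    hap1: dict[str, Haplotype]
    hap2: dict[str, Haplotype]
    chrom_lengths: dict[str, float]
    n_inbreeding_gens: int = 0
    seed: int | None = None

    def __post_init__(self):
        if sorted(self.funnel) != list(range(8)):
            raise InvalidArgumentError("funnel must be a permutation of 0..7")
        for haps in (self.hap1, self.hap2):
            for c, segs in haps.items():
                L = self.chrom_lengths[c]
                pos = 0.0
                for a, b, f in segs:
                    if not (0 <= f <= 7):
                        raise InvalidArgumentError("founder index out of range")
                    if abs(a - pos) > 1e-9 or b < a:
                        raise InvalidArgumentError(
                            f"segments do not tile chromosome {c}"
                        )
                    pos = b
                if abs(pos - L) > 1e-9:
                    raise InvalidArgumentError(
                        f"segments do not tile chromosome {c}"
                    )

    # -- queries ---------------------------------------------------------

    def founder_at(self, chrom: str, pos_cm: float) -> tuple[int, int]:
        """Founder index of each haplotype at a cM position."""
        return (
            _label_at(self.hap1[chrom], pos_cm),
            _label_at(self.hap2[chrom], pos_cm),
        )

    def founder_labels(self, gmap: GeneticMap) -> np.ndarray:
        """(2, M) founder index of each haplotype at every marker."""
        out = np.empty((2, gmap.n_markers), dtype=np.int8)
        for chrom in gmap.chromosomes:
            sl = gmap.chrom_slice(chrom)
            cm = gmap.markers["cM"].to_numpy()[sl]
            for h, haps in enumerate((self.hap1, self.hap2)):
                segs = haps[chrom]
                ends = np.array([s[1] for s in segs])
                labels = np.array([s[2] for s in segs], dtype=np.int8)
                idx = np.minimum(
                    np.searchsorted(ends, cm, side="right"), len(segs) - 1
                )
                out[h, sl] = labels[idx]
        return out

    def founder_shares(self) -> np.ndarray:
        """cM-weighted genome share of each founder (both haplotypes; sums to 1)."""
        shares = np.zeros(8)
        total = 0.0
        for haps in (self.hap1, self.hap2):
            for c, segs in haps.items():
                for a, b, f in segs:
                    shares[f] += b - a
                total += self.chrom_lengths[c]
        if total == 0:
            raise InvalidArgumentError("genome has zero genetic length")
        return shares / total

    def heterozygous_fraction(self) -> float:
        """cM fraction of the genome where the two haplotypes carry
        different founders."""
        het = 0.0
        total = 0.0
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                continue
            total += L
            bounds = sorted(
                {b for _, b, _ in self.hap1[c]}
                | {b for _, b, _ in self.hap2[c]}
                | {0.0}
            )
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                mid = (lo + hi) / 2.0
                if _label_at(self.hap1[c], mid) != _label_at(self.hap2[c], mid):
                    het += hi - lo
        return het / total if total else 0.0

    def n_junctions(self) -> int:
        """Total founder switch points over both haplotypes."""
        return sum(
            len(haps[c]) - 1
            for haps in (self.hap1, self.hap2)
            for c in self.chrom_lengths
        )

    def to_frame(self, bp_per_cm: int = BP_PER_CM) -> pd.DataFrame:
        """BED-like table (chrom, start_bp, end_bp, founder, haplotype),
        0-based half-open bp at ``bp_per_cm`` resolution."""
        rows = []
        for h, haps in enumerate((self.hap1, self.hap2), start=1):
            for c in self.chrom_lengths:
                for a, b, f in haps[c]:
                    rows.append(
                        (
                            self.line_id,
                            c,
                            int(round(a * bp_per_cm)),
                            int(round(b * bp_per_cm)),
                            f,
                            h,
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["line", "chrom", "start_bp", "end_bp", "founder", "haplotype"],
        )


def breed_cc_line(
    founders: FounderHaplotypes,
    funnel: Sequence[int] | None = None,
    n_inbreeding_gens: int = 20,
    seed: int | None = None,
    line_id: str = "CC001",
) -> MosaicGenome:
    """Breed one CC line: funnel cross of 8 founders, then sib mating.

    G1 makes four pairwise crosses in funnel order, G2 two four-way crosses,
    and their offspring form the eight-way G2:F1 sibling pair from which
    ``n_inbreeding_gens`` generations of brother-sister mating descend.  The
    final individual's two haplotypes are returned as founder segments; with
    20+ generations the two haplotypes agree over >99% of the genome in
    expectation (residual heterozygosity is retained, not forced away).
    """
    rng = np.random.default_rng(seed)
    if funnel is None:
        funnel = tuple(int(x) for x in rng.permutation(8))
    funnel = tuple(int(x) for x in funnel)
    if sorted(funnel) != list(range(8)):
        raise InvalidArgumentError("funnel must be a permutation of 0..7")
    if n_inbreeding_gens < 0:
        raise InvalidArgumentError("n_inbreeding_gens must be >= 0")
    lengths = founders.gmap.chrom_lengths

    g1 = [
        _cross(
            _founder_individual(funnel[2 * i], lengths),
            _founder_individual(funnel[2 * i + 1], lengths),
            lengths,
            rng,
        )
        for i in range(4)
    ]
    g2a = _cross(g1[0], g1[1], lengths, rng)
    g2b = _cross(g1[2], g1[3], lengths, rng)
    sib1 = _cross(g2a, g2b, lengths, rng)
    sib2 = _cross(g2a, g2b, lengths, rng)
    for _ in range(n_inbreeding_gens):
        child1 = _cross(sib1, sib2, lengths, rng)
        child2 = _cross(sib1, sib2, lengths, rng)
        sib1, sib2 = child1, child2
    return MosaicGenome(
        line_id=line_id,
        funnel=funnel,
        hap1=sib1[0],
        hap2=sib1[1],
        chrom_lengths=dict(lengths),
        n_inbreeding_gens=n_inbreeding_gens,
        seed=seed,
    )


def balanced_funnels(n_lines: int, seed: int | None = None) -> list[tuple[int, ...]]:
    """Randomized funnels balanced so every founder occupies every funnel
    position equally often (per block of 8 lines: cyclic rotations of a
    random permutation)."""
    rng = np.random.default_rng(seed)
    out: list[tuple[int, ...]] = []
    while len(out) < n_lines:
        base = rng.permutation(8)
        for r in range(8):
            out.append(tuple(int(x) for x in np.roll(base, r)))
    return out[:n_lines]


def breed_cc_panel(
    founders: FounderHaplotypes,
    n_lines: int,
    n_inbreeding_gens: int = 20,
    seed: int | None = None,
    funnels: Sequence[Sequence[int]] | str | None = None,
) -> list[MosaicGenome]:
    """Breed a panel of CC lines with independent per-line seeds.

    ``funnels`` may be explicit, ``"balanced"`` (position-balanced rotations)
    or None (random permutation per line).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_lines + 1)
    if funnels == "balanced":
        funnels = balanced_funnels(
            n_lines, seed=int(child[-1].generate_state(1)[0] % 2**31)
        )
    lines = []
    for i in range(n_lines):
        fun = None if funnels is None else funnels[i]
        lines.append(
            breed_cc_line(
                founders,
                funnel=fun,
                n_inbreeding_gens=n_inbreeding_gens,
                seed=child[i],
                line_id=f"CC{i + 1:03d}",
            )
        )
    return lines


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeMatrix:
    """Observed alternate-allele dosages per line; -1 encodes missing."""

    gmap: GeneticMap
    line_ids: tuple[str, ...]
    calls: np.ndarray  # (L, M) int8 in {-1, 0, 1, 2}

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.shape != (len(self.line_ids), self.gmap.n_markers):
            raise InvalidArgumentError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.line_ids)} lines x {self.gmap.n_markers} markers"
            )
        if calls.size and not np.isin(calls, (-1, 0, 1, 2)).all():
            raise InvalidArgumentError("calls must be in {-1, 0, 1, 2}")
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "line_ids", tuple(self.line_ids))

    @property
    def missing_rate(self) -> float:
        return float((self.calls == -1).mean()) if self.calls.size else 0.0


def genotype_line(
    mosaic: MosaicGenome,
    founders: FounderHaplotypes,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Observed calls for one line: true dosage = sum of the two haplotypes'
    founder alleles, then symmetric genotyping error and missingness."""
    if not 0.0 <= error_rate < 0.5:
        raise InvalidArgumentError("error_rate must lie in [0, 0.5)")
    if not 0.0 <= missing_rate < 1.0 + 1e-12:
        raise InvalidArgumentError("missing_rate must lie in [0, 1]")
    for c, L in founders.gmap.chrom_lengths.items():
        if c not in mosaic.chrom_lengths or abs(mosaic.chrom_lengths[c] - L) > 1e-6:
            raise InconsistentInputError(
                f"mosaic and founders disagree on chromosome {c}"
            )
    rng = np.random.default_rng(seed)
    labels = mosaic.founder_labels(founders.gmap)
    m = founders.n_markers
    idx = np.arange(m)
    true = (
        founders.alleles[labels[0], idx].astype(np.int8)
        + founders.alleles[labels[1], idx].astype(np.int8)
    )
    calls = true.copy()
    if error_rate > 0 and m:
        flip = rng.random(m) < error_rate
        # replace by a uniformly chosen *different* value in {0,1,2}
        shift = rng.integers(1, 3, size=m).astype(np.int8)
        calls[flip] = (calls[flip] + shift[flip]) % 3
    if missing_rate > 0 and m:
        calls[rng.random(m) < missing_rate] = -1
    return calls


def genotype_panel(
    mosaics: Sequence[MosaicGenome],
    founders: FounderHaplotypes,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Genotype a panel of lines with independent per-line randomness."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(mosaics))
    calls = np.empty((len(mosaics), founders.n_markers), dtype=np.int8)
    for i, mos in enumerate(mosaics):
        calls[i] = genotype_line(
            mos, founders, error_rate, missing_rate, seed=children[i]
        )
    return GenotypeMatrix(
        founders.gmap, tuple(m.line_id for m in mosaics), calls
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QtlEffect:
    """Additive founder-allelic effect at one genomic position."""

    chrom: str
    pos_cm: float
    effects: tuple[float, ...]  # length 8, phenotype units

    def __post_init__(self):
        if len(self.effects) != 8:
            raise InvalidArgumentError("QTL effect vector must have length 8")
        object.__setattr__(self, "effects", tuple(float(x) for x in self.effects))


@dataclass(frozen=True)
class QtlSpec:
    """Ground-truth phenotype architecture for the simulator."""

    qtls: tuple[QtlEffect, ...] = ()
    sigma_g2: float = 0.0  # polygenic variance, structured by kinship
    sigma_e2: float = 1.0  # residual variance per animal
    intercept: float = 0.0
    age_effect: float = 0.0  # phenotype units per day of age
    batch_effects: dict[str, float] = field(default_factory=dict)
    origin_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise InvalidArgumentError("variance components must be >= 0")
        object.__setattr__(self, "qtls", tuple(self.qtls))

    @property
    def true_h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


DEFAULT_COVARIATE_LEVELS = {
    "age_days": (56, 112),
    "batch": ("B1", "B2", "B3"),
    "origin": ("ILRI", "GND", "UNC"),
}


def simulate_phenotypes(
    mosaics: Sequence[MosaicGenome],
    kinship,
    spec: QtlSpec,
    n_per_line: int | tuple[int, int] = 5,
    covariate_levels: dict | None = None,
    seed: int | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Per-animal phenotype table with known heritability and QTL effects.

    animal value = intercept + QTL effects (mean of the two haplotypes'
    founder effects at each QTL, read from the true mosaic) + a line-level
    polygenic draw with covariance sigma_g2 * K + covariate effects +
    N(0, sigma_e2) residual noise.  ``kinship`` is a KinshipMatrix or plain
    (L, L) array aligned with ``mosaics``; it may be None when sigma_g2 = 0.
    True parameters are recorded in the returned frame's ``attrs``.
    """
    rng = np.random.default_rng(seed)
    levels = dict(DEFAULT_COVARIATE_LEVELS)
    if covariate_levels:
        levels.update(covariate_levels)
    n_lines = len(mosaics)
    if n_lines == 0:
        raise InvalidArgumentError("at least one line required")

    kvals = None
    if kinship is not None:
        kvals = np.asarray(getattr(kinship, "values", kinship), dtype=float)
        if kvals.shape != (n_lines, n_lines):
            raise InvalidArgumentError(
                f"kinship shape {kvals.shape} does not match {n_lines} lines"
            )
    if spec.sigma_g2 > 0:
        if kvals is None:
            raise InvalidArgumentError("sigma_g2 > 0 requires a kinship matrix")
        w = np.linalg.eigvalsh(kvals)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise InvalidArgumentError("kinship is not positive semidefinite")
        chol = np.linalg.cholesky(kvals + 1e-10 * np.eye(n_lines))
        poly = np.sqrt(spec.sigma_g2) * chol @ rng.standard_normal(n_lines)
    else:
        poly = np.zeros(n_lines)

    qtl_value = np.zeros(n_lines)
    for q in spec.qtls:
        eff = np.asarray(q.effects)
        for i, mos in enumerate(mosaics):
            f1, f2 = mos.founder_at(q.chrom, q.pos_cm)
            qtl_value[i] += 0.5 * (eff[f1] + eff[f2])

    lo, hi = levels["age_days"] if not np.isscalar(levels["age_days"]) else (
        levels["age_days"],
        levels["age_days"],
    )
    batches = list(levels["batch"])
    origins = list(levels["origin"])
    origin_of_line = rng.choice(origins, size=n_lines)  # origin is a line property

    rows = []
    k = 0
    mean_age = (lo + hi) / 2.0
    for i, mos in enumerate(mosaics):
        if np.isscalar(n_per_line):
            n_animals = int(n_per_line)
        else:
            n_animals = int(rng.integers(n_per_line[0], n_per_line[1] + 1))
        if n_animals < 1:
            raise InvalidArgumentError("n_per_line must be >= 1")
        for _ in range(n_animals):
            age = int(rng.integers(lo, hi + 1))
            batch = str(rng.choice(batches))
            origin = str(origin_of_line[i])
            value = (
                spec.intercept
                + qtl_value[i]
                + poly[i]
                + spec.age_effect * (age - mean_age)
                + spec.batch_effects.get(batch, 0.0)
                + spec.origin_effects.get(origin, 0.0)
                + np.sqrt(spec.sigma_e2) * rng.standard_normal()
            )
            rows.append((f"A{k:04d}", mos.line_id, age, batch, origin, value))
            k += 1
    df = pd.DataFrame(
        rows, columns=["animal", "line", "age", "batch", "origin", trait]
    )
    df.attrs.update(
        {
            "trait": trait,
            "true_h2": spec.true_h2,
            "sigma_g2": spec.sigma_g2,
            "sigma_e2": spec.sigma_e2,
            "qtls": [(q.chrom, q.pos_cm, q.effects) for q in spec.qtls],
            "seed": seed,
        }
    )
    return df


# ---------------------------------------------------------------------------
# gene table and ranking (annotation-stage inputs)
# ---------------------------------------------------------------------------


def simulate_gene_table(
    gmap: GeneticMap,
    n_genes: int = 500,
    seed: int | None = None,
    bp_per_cm: int = BP_PER_CM,
) -> pd.DataFrame:
    """Synthetic genome-wide gene table (0-based half-open bp coordinates).

    Genes are placed uniformly along each chromosome's physical extent with
    log-normal lengths (median ~20 kb), mimicking the pre-resolved
    ortholog tables the annotation stage consumes.
    """
    rng = np.random.default_rng(seed)
    chroms = gmap.chromosomes
    lengths_bp = {
        c: int(gmap.chrom_lengths[c] * bp_per_cm) for c in chroms
    }
    total = sum(lengths_bp.values())
    rows = []
    gid = 0
    for c in chroms:
        n_c = max(1, int(round(n_genes * lengths_bp[c] / total)))
        starts = np.sort(rng.integers(0, max(lengths_bp[c] - 1, 1), size=n_c))
        glen = np.exp(rng.normal(np.log(20_000), 0.8, size=n_c)).astype(np.int64)
        for s, ln in zip(starts, glen):
            end = min(int(s) + max(int(ln), 100), lengths_bp[c])
            rows.append(
                (
                    f"G{gid:05d}",
                    f"Gene{gid}",
                    c,
                    int(s),
                    end,
                    "+" if rng.random() < 0.5 else "-",
                )
            )
            gid += 1
    return pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"]
    )


def simulate_gene_ranking(gene_ids: Sequence[str], seed: int | None = None):
    """Random disorder-implication ranking (rank 1 = most implicated)."""
    from .annotate import GeneRanking

    rng = np.random.default_rng(seed)
    ranks = rng.permutation(len(gene_ids)) + 1
    return GeneRanking(
        pd.Series(ranks, index=list(gene_ids)), genome_size=len(gene_ids)
    )
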