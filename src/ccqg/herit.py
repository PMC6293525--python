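"""Kinship and heritability estimation.

Kinship between two lines is the probability, averaged over genomic
intervals, that both descend from the same founder:

    K[i, j] = (1/M) * sum_m sum_f p[i, m, f] * p[j, m, f]

Narrow-sense heritability comes from the animal-level mixed model with
phenotypic covariance V = sigma_g^2 * Z K Z' + sigma_e^2 * I (Z expands
lines to animals), fitted by maximum likelihood via one eigendecomposition
and a 1-D profile over h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Broad-sense heritability comes from a one-way ANOVA over lines:
Ve = MS_within, Vg = (MS_between - MS_within) / n with n the average number
of animals per line, and H^2 = Vg / (Vg + Ve) (negative Vg clamped to 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InconsistentInputError, InvalidArgumentError
from .hmm import DescentProbabilities
from .pheno import TraitVector


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric L x L expected founder-haplotype sharing between lines."""

    line_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        L = len(self.line_ids)
        if v.shape != (L, L):
            raise InvalidArgumentError(f"kinship shape {v.shape} != ({L},{L})")
        if L and np.abs(v - v.T).max() > 1e-8:
            raise InvalidArgumentError("kinship must be symmetric")
        object.__setattr__(self, "values", (v + v.T) / 2.0)
        object.__setattr__(self, "line_ids", tuple(self.line_ids))

    @cached_property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())

    def check_psd(self, tol: float = 1e-8) -> None:
        scale = max(np.abs(self.values).max(), 1.0)
        if self.min_eigenvalue < -tol * scale:
            raise InvalidArgumentError(
                f"kinship is not PSD (min eigenvalue {self.min_eigenvalue:.3g})"
            )

    def rescaled(self) -> "KinshipMatrix":
        """Copy rescaled to unit mean diagonal."""
        d = np.trace(self.values) / len(self.line_ids)
        return KinshipMatrix(self.line_ids, self.values / d)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.line_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


def kinship_from_descent(probs: DescentProbabilities) -> KinshipMatrix:
    """Expected founder sharing averaged over intervals (unweighted mean,
    matching the descent-probability dot-product definition)."""
    if probs.n_lines < 2 or probs.n_intervals < 1:
        raise InvalidArgumentError("need >= 2 lines and >= 1 interval")
    p = probs.p
    K = np.einsum("imf,jmf->ij", p, p) / probs.n_intervals
    return KinshipMatrix(probs.line_ids, K)


# ---------------------------------------------------------------------------
# narrow-sense: mixed-model ML
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    """ML variance components of V = K*sigma_g2 + I*sigma_e2."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    boundary: bool  # h2 pinned at 0 or 1
    method: str = "ML"

    def __post_init__(self):
        if not -1e-12 <= self.h2 <= 1 + 1e-12:
            raise InvalidArgumentError("h2 must lie in [0, 1]")


def _profile_negll(h, s, yt, xt, n, reml):
    v = h * s + (1.0 - h)
    xv = (xt * xt / v).sum()
    beta = (xt * yt / v).sum() / xv
    r = yt - xt * beta
    q = (r * r / v).sum()
    if reml:
        sp2 = q / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(2 * np.pi * sp2)
            + np.log(v).sum()
            + np.log(xv)
            + (n - 1)
        )
    else:
        sp2 = q / n
        ll = -0.5 * (n * np.log(2 * np.pi * sp2) + np.log(v).sum() + n)
    return -ll, sp2, beta


def fit_variance_components(
    trait: TraitVector | np.ndarray,
    lines,
    kinship: KinshipMatrix,
    reml: bool = False,
    grid_points: int = 101,
) -> VarianceComponents:
    """Maximum-likelihood variance components at the animal level.

    Animals of lines i and j share genetic covariance sigma_g2 * K[i, j];
    the expanded relationship matrix is eigendecomposed once and the
    likelihood profiled over h2 on a grid refined by bounded 1-D
    optimization (tolerance 1e-6 in h2).  Boundary solutions are allowed
    and flagged.  ``reml=True`` switches to residual ML.
    """
    y = trait.values if isinstance(trait, TraitVector) else np.asarray(trait, float)
    lines = np.asarray(lines, dtype=object)
    if lines.shape != y.shape:
        raise InvalidArgumentError("lines must align with trait values")
    mask = ~np.isnan(y)
    y, lines = y[mask], lines[mask]
    n = len(y)
    if n < 3:
        raise InvalidArgumentError("need >= 3 non-missing animals")
    if np.ptp(y) == 0:
        raise InvalidArgumentError("trait is constant; h2 undefined")
    index = {lid: i for i, lid in enumerate(kinship.line_ids)}
    try:
        li = np.array([index[l] for l in lines])
    except KeyError as exc:
        raise InconsistentInputError(f"line {exc} missing from kinship") from None
    kinship.check_psd(tol=1e-6)
    A = kinship.values[np.ix_(li, li)]
    s, U = np.linalg.eigh(A)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def f(h):
        return _profile_negll(h, s, yt, xt, n, reml)[0]

    upper = 1.0 - 1e-9
    grid = np.linspace(0.0, upper, grid_points)
    vals = np.array([f(h) for h in grid])
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
    )
    h = float(res.x) if res.fun <= vals[j] else float(grid[j])
    negll, sp2, _ = _profile_negll(h, s, yt, xt, n, reml)
    boundary = h < 1e-5 or h > 1 - 1e-5
    if boundary and h < 1e-5:
        h = 0.0
    return VarianceComponents(
        sigma_g2=h * sp2,
        sigma_e2=(1.0 - h) * sp2,
        h2=h,
        loglik=-float(negll),
        boundary=bool(boundary),
        method="REML" if reml else "ML",
    )


# ---------------------------------------------------------------------------
# broad-sense: one-way ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaH2:
    """One-way ANOVA broad-sense heritability over lines."""

    ms_between: float
    ms_within: float
    n_bar: float  # average animals per line
    vg: float
    ve: float
    H2: float
    F: float
    p_value: float
    clamped: bool  # negative Vg clamped to 0

    def __post_init__(self):
        if not 0.0 <= self.H2 <= 1.0:
            raise InvalidArgumentError("H2 must lie in [0, 1]")


def anova_broad_h2(trait: TraitVector | np.ndarray, lines) -> AnovaH2:
    """Broad-sense heritability from one-way ANOVA mean squares.

    H2 = Vg / (Vg + Ve) with Ve = MS_within and
    Vg = (MS_between - MS_within) / n_bar, n_bar the arithmetic mean number
    of animals per line; negative Vg is clamped to 0 (flagged).
    """
    y = trait.values if isinstance(trait, TraitVector) else np.asarray(trait, float)
    lines = np.asarray(lines, dtype=object)
    mask = ~np.isnan(y)
    y, lines = y[mask], lines[mask]
    df = pd.DataFrame({"line": lines, "y": y})
    g = df.groupby("line")["y"]
    k = g.ngroups
    if k < 2:
        raise InvalidArgumentError("ANOVA needs >= 2 lines")
    counts = g.count().to_numpy(float)
    means = g.mean().to_numpy()
    grand = y.mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((y - g.transform("mean").to_numpy()) ** 2).sum())
    df_b = k - 1
    df_w = len(y) - k
    if df_w <= 0:
        raise InvalidArgumentError("no within-line degrees of freedom")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    n_bar = float(counts.mean())
    vg = (ms_b - ms_w) / n_bar
    clamped = vg < 0
    vg = max(vg, 0.0)
    ve = ms_w
    if vg + ve > 0:
        H2 = vg / (vg + ve)
    else:
        H2 = 0.0  # all animals identical
    if ms_w > 0:
        F = ms_b / ms_w
        p = float(stats.f.sf(F, df_b, df_w))
    else:
        F = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    return AnovaH2(ms_b, ms_w, n_bar, vg, ve, min(H2, 1.0), F, p, clamped)
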