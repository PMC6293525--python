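"""Behavioral readouts and the phenotype preprocessing chain.

Raw per-animal measurements are first corrected for age, batch and origin
by ordinary least squares (residuals), then quantile normalized by a
rank-based inverse-normal (Blom) transform; line-level summaries are
computed from whichever stage the caller asks for.  Provenance is tracked
explicitly and only the transitions raw -> corrected -> normalized are
allowed, so the chain order is enforced, not just documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDesignError, InvalidArgumentError

_PROVENANCE_ORDER = ("raw", "corrected", "normalized")


@dataclass(frozen=True)
class TraitVector:
    """One trait across animals; NaN marks missing values."""

    ids: tuple[str, ...]
    values: np.ndarray
    name: str = "trait"
    provenance: str = "raw"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.ids),):
            raise InvalidArgumentError("ids and values must align")
        if self.provenance not in _PROVENANCE_ORDER:
            raise InvalidArgumentError(
                f"unknown provenance {self.provenance!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, trait: str, id_col: str = "animal"
    ) -> "TraitVector":
        return cls(tuple(df[id_col].astype(str)), df[trait].to_numpy(float), trait)

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.ids), name=self.name)


class DiscriminationResult(NamedTuple):
    ratio: float | np.ndarray
    discriminated: bool | np.ndarray


def discrimination_ratio(t_novel, t_familiar) -> DiscriminationResult:
    """Social discrimination ratio tN / (tN + tF).

    tN and tF are exploration times (seconds, >= 0) of the novel and
    familiar conspecific.  Values above 0.5 flag successful discrimination.
    A zero total leaves the ratio undefined (NaN, not flagged).
    """
    tn = np.asarray(t_novel, dtype=float)
    tf = np.asarray(t_familiar, dtype=float)
    if np.nanmin(tn, initial=0.0) < 0 or np.nanmin(tf, initial=0.0) < 0:
        raise InvalidArgumentError("exploration times must be >= 0")
    total = tn + tf
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, tn / total, np.nan)
    flag = np.where(np.isnan(ratio), False, ratio > 0.5)
    if np.isscalar(t_novel) and np.isscalar(t_familiar):
        return DiscriminationResult(float(ratio), bool(flag))
    return DiscriminationResult(ratio, flag)


class ExceedanceResult(NamedTuple):
    fraction: float
    exceeders: tuple[str, ...]


def exceedance_fraction(trait: TraitVector, threshold: float) -> ExceedanceResult:
    """Fraction of non-missing animals strictly above ``threshold`` (same
    units as the trait), plus their IDs."""
    mask = trait.mask
    if not mask.any():
        raise InvalidArgumentError("all trait values missing")
    over = mask & (trait.values > threshold)
    ids = tuple(np.asarray(trait.ids, dtype=object)[over])
    return ExceedanceResult(float(over.sum() / mask.sum()), ids)


def _build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric columns enter linearly; object/categorical columns as
    treatment-coded dummies.  Returns (design without intercept, the list
    of source-factor names per column)."""
    cols = []
    owners = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(float)
            if np.ptp(x) == 0:
                continue  # constant covariate carries no information
            cols.append(x[:, None])
            owners.append([name])
        else:
            d = pd.get_dummies(col.astype(str), drop_first=True)
            if d.shape[1]:
                cols.append(d.to_numpy(float))
                owners.append([name] * d.shape[1])
    if not cols:
        return np.empty((len(covariates), 0)), []
    return np.hstack(cols), [o for sub in owners for o in sub]


def adjust_covariates(
    trait: TraitVector, covariates: pd.DataFrame
) -> TraitVector:
    """Residuals of an OLS fit of the trait on its covariates.

    ``covariates`` must align with ``trait.ids`` (either positionally or by
    an ``animal`` column / index) and be complete for every non-missing
    animal.  Residuals have mean zero; missing trait values stay missing.
    A singular design raises :class:`DegenerateDesignError` naming the
    offending factor.
    """
    if trait.provenance == "normalized":
        raise InvalidArgumentError(
            "cannot correct a normalized trait (chain is raw->corrected->normalized)"
        )
    cov = covariates
    if "animal" in cov.columns:
        cov = cov.set_index("animal")
    if not cov.index.equals(pd.RangeIndex(len(cov))):
        try:
            cov = cov.loc[list(trait.ids)]
        except KeyError as exc:
            raise InvalidArgumentError(
                f"covariates missing for some animals: {exc}"
            ) from None
    if len(cov) != len(trait.ids):
        raise InvalidArgumentError("covariates must align with trait animals")
    mask = trait.mask
    if cov.iloc[np.flatnonzero(mask)].isna().any().any():
        raise InvalidArgumentError(
            "covariates incomplete for non-missing animals"
        )
    X, owners = _build_design(cov.iloc[np.flatnonzero(mask)])
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a factor whose removal restores full rank
        for factor in dict.fromkeys(owners):
            keep = [0] + [
                j + 1 for j, o in enumerate(owners) if o != factor
            ]
            Xr = X[:, keep]
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                raise DegenerateDesignError(
                    f"covariate design is singular; factor '{factor}' is "
                    "confounded (e.g. one level per animal or aliased levels)"
                )
        raise DegenerateDesignError("covariate design is singular")
    y = trait.values[mask]
    res = sm.OLS(y, X).fit()
    out = np.full_like(trait.values, np.nan)
    out[mask] = res.resid
    return replace(trait, values=out, provenance="corrected")


def quantile_normalize(trait: TraitVector) -> TraitVector:
    """Rank-based inverse-normal transform with Blom offsets.

    score = Phi^-1((rank - 0.375) / (n + 0.25)), ties get average ranks,
    missing values propagate.  The output is a monotone transform of the
    input, so any strictly monotone pre-transform yields identical scores.
    """
    if trait.provenance == "normalized":
        raise InvalidArgumentError("trait is already normalized")
    mask = trait.mask
    n = int(mask.sum())
    if n < 3:
        raise InvalidArgumentError(
            "quantile normalization needs >= 3 non-missing values"
        )
    vals = trait.values[mask]
    out = np.full_like(trait.values, np.nan)
    if np.ptp(vals) == 0:
        warnings.warn(
            f"trait {trait.name!r} is constant; normalized scores are all 0"
        )
        out[mask] = 0.0
    else:
        ranks = stats.rankdata(vals, method="average")
        out[mask] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return replace(trait, values=out, provenance="normalized")


def line_summaries(trait: TraitVector, lines) -> pd.DataFrame:
    """Per-line mean, SEM and n, sorted ascending by mean (ties broken by
    line ID).  SEM is NaN when a line has a single animal."""
    lines = np.asarray(lines, dtype=object)
    if lines.shape != (len(trait.ids),):
        raise InvalidArgumentError("every animal needs a line assignment")
    df = pd.DataFrame({"line": lines, "value": trait.values}).dropna()
    g = df.groupby("line")["value"]
    out = pd.DataFrame(
        {
            "line": g.mean().index,
            "mean": g.mean().to_numpy(),
            "sem": (g.std(ddof=1) / np.sqrt(g.count())).to_numpy(),
            "n": g.count().to_numpy(),
        }
    )
    out.loc[out["n"] == 1, "sem"] = np.nan
    return out.sort_values(["mean", "line"], kind="mergesort").reset_index(
        drop=True
    )
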