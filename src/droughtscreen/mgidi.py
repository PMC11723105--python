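"""Multi-trait genotype-ideotype distance index (MGIDI).

The index ranks genotypes by their Euclidean distance, in rotated factor
score space, from an *ideotype* — a hypothetical genotype attaining the
desired extreme of every trait.  The pipeline is

1. direction-aware 0-100 rescaling of genotype trait means, so the best
   observed genotype scores 100 on every trait regardless of whether high
   or low raw values are wanted;
2. exploratory factor analysis of the rescaled matrix: eigen decomposition
   of the trait correlation matrix, Kaiser retention (eigenvalue >= 1),
   varimax rotation, and regression factor scores B = R^-1 Λ*;
3. scoring of the genotypes and of the all-100 ideotype with the same
   coefficients;
4. MGIDI_i = sqrt( sum_j (gamma_ij − gamma_j)^2 ) over the retained
   factors, plus genotype selection at a given selection pressure,
   per-trait selection differentials of the selected set, and the
   per-factor "strengths and weaknesses" decomposition of each genotype's
   distance.

Because factor scores transform covariantly under any orthogonal rotation
of the loadings, the index itself is rotation invariant; the rotation only
shapes the per-factor decomposition used for interpretation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import LOWER_BETTER_DEFAULT

__all__ = [
    "MGIDI",
    "MGIDIResults",
    "FactorModel",
    "rescale_trait_means",
    "varimax",
    "factor_analysis",
    "ideotype_scores",
    "mgidi_index",
    "select_genotypes",
    "selection_differentials",
    "factor_contributions",
]


def _directions_vector(traits, directions) -> pd.Series:
    """Normalise a direction spec to a trait-indexed Series of {+1 higher
    better, −1 lower better}."""
    if directions is None:
        directions = {t: ("lower" if t in LOWER_BETTER_DEFAULT else "higher")
                      for t in traits}
    out = {}
    for t in traits:
        d = directions[t] if not isinstance(directions, pd.Series) else directions[t]
        if isinstance(d, str):
            d = d.lower()
            if d in ("higher", "higher_better", "increase", "+"):
                out[t] = 1
            elif d in ("lower", "lower_better", "decrease", "-"):
                out[t] = -1
            else:
                raise ValueError(f"unknown direction {d!r} for trait {t!r}")
        else:
            out[t] = 1 if d >= 0 else -1
    return pd.Series(out, name="direction")


def rescale_trait_means(means: pd.DataFrame, directions=None) -> pd.DataFrame:
    """Direction-aware linear rescaling of genotype means to [0, 100].

    For a higher-better trait the observed minimum maps to 0 and the
    maximum to 100; for a lower-better trait the map is reversed.  Either
    way the most desirable observed genotype scores 100.  Constant traits
    (max == min) are dropped with a warning.
    """
    const = (means.max() - means.min()) <= 0
    if const.any():
        warnings.warn("dropping constant traits: "
                      + ", ".join(map(str, means.columns[const])), stacklevel=2)
        means = means.loc[:, ~const]
    dirs = _directions_vector(means.columns, directions)
    lo, hi = means.min(), means.max()
    frac = (means - lo) / (hi - lo)
    resc = frac * 100.0
    flip = dirs < 0
    resc.loc[:, flip] = 100.0 - resc.loc[:, flip]
    return resc


def varimax(loadings: np.ndarray, *, normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (Kaiser row-normalized variant).

    Returns ``(rotated_loadings, T)`` with ``rotated = loadings @ T`` and T
    orthonormal.  Column signs are fixed so the largest-magnitude loading
    of each rotated column is positive; columns are ordered by decreasing
    explained variance (sum of squared loadings).
    """
    L = np.asarray(loadings, float)
    p, k = L.shape
    if k < 2:
        T = np.ones((k, k))
        return L.copy(), T
    h = np.sqrt((L**2).sum(axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    A = L / h[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ T
        u, s, vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p))
        T = u @ vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    rotated = (A @ T) * h[:, None]
    # deterministic column order and sign
    order = np.argsort(-(rotated**2).sum(axis=0), kind="stable")
    rotated, T = rotated[:, order], T[:, order]
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    return rotated * signs, T * signs


@dataclass(frozen=True)
class FactorModel:
    """Factor analysis of the rescaled genotype × trait matrix.

    Loadings are the eigenvector columns scaled by sqrt(eigenvalue);
    ``rotated_loadings = loadings @ rotation`` after varimax; communalities
    (row sums of squared loadings over retained factors) are invariant
    under the rotation; ``score_coefficients`` B = R⁻¹Λ* give regression
    factor scores gamma = Z B for any matrix Z standardized with
    ``column_means`` / ``column_sds``.
    """

    correlation: pd.DataFrame
    eigenvalues: np.ndarray
    n_factors: int
    loadings: pd.DataFrame
    rotation: np.ndarray
    rotated_loadings: pd.DataFrame
    communalities: pd.Series
    score_coefficients: pd.DataFrame
    genotype_scores: pd.DataFrame
    ideotype_scores_: pd.Series
    column_means: pd.Series = field(repr=False)
    column_sds: pd.Series = field(repr=False)

    def standardize(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Standardize new rows with the fitted column means/SDs."""
        return (matrix[self.column_means.index] - self.column_means) / self.column_sds

    def score(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Regression factor scores for new rows on the rescaled-trait scale."""
        z = self.standardize(matrix)
        out = z.to_numpy(float) @ self.score_coefficients.to_numpy(float)
        return pd.DataFrame(out, index=matrix.index,
                            columns=self.score_coefficients.columns)


def factor_analysis(rescaled: pd.DataFrame, *, ridge: float = 1e-8) -> FactorModel:
    """Fit the factor model on the 0-100 rescaled genotype × trait matrix.

    Retains every factor with eigenvalue >= 1 (Kaiser criterion) and
    rotates with normalized varimax.  When the correlation matrix is
    rank-deficient (more traits than genotypes) its inverse is taken as a
    ridge-stabilized pseudo-inverse with a logged warning.
    """
    if rescaled.shape[0] < 3:
        raise ValueError("factor analysis needs at least 3 genotypes")
    if rescaled.shape[1] < 2:
        raise ValueError("factor analysis needs at least 2 traits")
    mu = rescaled.mean()
    sd = rescaled.std(ddof=1)
    if (sd <= 0).any():
        raise ValueError("constant trait column reached factor analysis")
    Z = ((rescaled - mu) / sd).to_numpy(float)
    R = np.corrcoef(Z, rowvar=False)
    traits = list(rescaled.columns)

    lam, vec = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    f = max(int(np.sum(lam >= 1.0)), 1)
    lam_f = np.clip(lam[:f], 0.0, None)
    L = vec[:, :f] * np.sqrt(lam_f)
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(f)])
    signs[signs == 0] = 1.0
    L = L * signs

    Lrot, T = varimax(L)
    factors = [f"FA{j + 1}" for j in range(f)]

    rank = np.linalg.matrix_rank(R, tol=1e-10)
    if rank < R.shape[0]:
        warnings.warn(
            f"correlation matrix is rank-deficient (rank {rank} < {R.shape[0]}); "
            "using ridge-stabilized pseudo-inverse for the score coefficients",
            stacklevel=2)
        R_inv = np.linalg.pinv(R + ridge * np.eye(R.shape[0]))
    else:
        R_inv = np.linalg.inv(R)
    B = R_inv @ Lrot
    scores = Z @ B

    ideo = pd.DataFrame(100.0, index=["ideotype"], columns=traits)
    z_ideo = ((ideo - mu) / sd).to_numpy(float)
    gamma_ideo = (z_ideo @ B).ravel()

    return FactorModel(
        correlation=pd.DataFrame(R, index=traits, columns=traits),
        eigenvalues=lam,
        n_factors=f,
        loadings=pd.DataFrame(L, index=traits, columns=factors),
        rotation=T,
        rotated_loadings=pd.DataFrame(Lrot, index=traits, columns=factors),
        communalities=pd.Series((Lrot**2).sum(axis=1), index=traits,
                                name="communality"),
        score_coefficients=pd.DataFrame(B, index=traits, columns=factors),
        genotype_scores=pd.DataFrame(scores, index=rescaled.index,
                                     columns=factors),
        ideotype_scores_=pd.Series(gamma_ideo, index=factors, name="ideotype"),
        column_means=mu,
        column_sds=sd,
    )


def ideotype_scores(model: FactorModel) -> pd.Series:
    """Factor scores of the all-100 ideotype under the fitted model."""
    return model.ideotype_scores_


def mgidi_index(model: FactorModel) -> pd.Series:
    """Euclidean genotype-ideotype distance over the retained factors."""
    diff = model.genotype_scores - model.ideotype_scores_
    return pd.Series(np.sqrt((diff**2).sum(axis=1)),
                     index=model.genotype_scores.index, name="MGIDI")


def select_genotypes(index: pd.Series, pressure: float = 0.15) -> tuple[list, float]:
    """Smallest-index genotypes at the given selection pressure.

    Returns ``(selected ids, cutpoint)`` where ``ceil(pressure * t)``
    genotypes are taken and the cutpoint is the largest selected index
    value.  Ties at the boundary are broken by genotype identifier order.
    """
    if not 0 < pressure <= 1:
        raise ValueError("selection pressure must lie in (0, 1]")
    n_sel = math.ceil(pressure * len(index))
    ordered = (index.to_frame("MGIDI").assign(_id=index.index.astype(str))
               .sort_values(["MGIDI", "_id"], kind="stable"))
    selected = list(ordered.index[:n_sel])
    cutpoint = float(ordered["MGIDI"].iloc[n_sel - 1])
    return selected, cutpoint


def selection_differentials(raw_means: pd.DataFrame, selected,
                            directions=None) -> pd.DataFrame:
    """Per-trait selection differentials of the selected set, %.

    SD%_j = (mean_selected − mean_all)/mean_all × 100 on the original trait
    scale; ``success`` flags whether the sign matches the trait's desired
    direction.  Traits with zero grand mean are flagged and excluded from
    the per-direction totals (rows kept, ``excluded`` = True).
    """
    if len(list(selected)) == 0:
        raise ValueError("selected set must be non-empty")
    dirs = _directions_vector(raw_means.columns, directions)
    mean_all = raw_means.mean()
    mean_sel = raw_means.loc[list(selected)].mean()
    excluded = mean_all == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sd_pct = (mean_sel - mean_all) / mean_all * 100.0
    sd_pct[excluded] = np.nan
    out = pd.DataFrame({
        "mean_all": mean_all,
        "mean_selected": mean_sel,
        "sd_percent": sd_pct,
        "direction": np.where(dirs > 0, "higher", "lower"),
        "success": np.sign(sd_pct) * dirs.to_numpy() >= 0,
        "excluded": excluded,
    })
    out.loc[excluded, "success"] = False
    out.index.name = "trait"
    return out


def sd_totals(differentials: pd.DataFrame) -> dict[str, float]:
    """Summed selection differentials per direction group."""
    ok = ~differentials["excluded"]
    return {
        "total_higher": float(differentials.loc[
            ok & (differentials["direction"] == "higher"), "sd_percent"].sum()),
        "total_lower": float(differentials.loc[
            ok & (differentials["direction"] == "lower"), "sd_percent"].sum()),
    }


def factor_contributions(model: FactorModel, index: pd.Series) -> pd.DataFrame:
    """Per-genotype share of each factor in the squared ideotype distance.

    Shares sum to 1 per genotype; a genotype at zero distance gets uniform
    shares and is flagged in ``attrs['degenerate']``.
    """
    diff2 = (model.genotype_scores - model.ideotype_scores_) ** 2
    total = diff2.sum(axis=1)
    degenerate = total[total == 0].index.tolist()
    shares = diff2.div(total.where(total > 0), axis=0)
    if degenerate:
        shares.loc[degenerate] = 1.0 / model.n_factors
    shares.attrs["degenerate"] = degenerate
    return shares


class MGIDI:
    """Model object for the multi-trait genotype-ideotype distance index.

    Parameters
    ----------
    means : genotype × trait matrix of means on the original scale
        (typically drought-condition genotype means).
    directions : optional mapping trait -> "higher"/"lower" (or ±1); by
        default the eight drought-response traits where a decrease is
        desirable (ELWR, Ci, VPD_LA, WUE_L, NPQ, MDA, H2O2, MG) are
        lower-better and all others higher-better.
    pressure : selection pressure, fraction of genotypes to retain.

    Examples
    --------
    >>> res = MGIDI(drought_means, pressure=0.3).fit()
    >>> res.ranking.head(); res.selected; print(res.summary())
    """

    def __init__(self, means: pd.DataFrame, directions=None,
                 pressure: float = 0.15):
        if means.isna().any().any():
            raise ValueError("trait means contain missing values")
        self.means = means
        self.directions = _directions_vector(means.columns, directions)
        if not 0 < pressure <= 1:
            raise ValueError("selection pressure must lie in (0, 1]")
        self.pressure = pressure

    def fit(self) -> "MGIDIResults":
        rescaled = rescale_trait_means(self.means, self.directions)
        model = factor_analysis(rescaled)
        index = mgidi_index(model)
        selected, cutpoint = select_genotypes(index, self.pressure)
        diffs = selection_differentials(
            self.means[rescaled.columns], selected,
            self.directions[rescaled.columns])
        contrib = factor_contributions(model, index)
        return MGIDIResults(self, rescaled, model, index, selected, cutpoint,
                            diffs, contrib)


class MGIDIResults:
    """Fitted MGIDI: index, ranking, selection and decompositions."""

    def __init__(self, model_spec: MGIDI, rescaled, factor_model, index,
                 selected, cutpoint, differentials, contributions):
        self.model = model_spec
        self.rescaled = rescaled
        self.factor_model: FactorModel = factor_model
        self.index: pd.Series = index
        self.selected: list = selected
        self.cutpoint: float = cutpoint
        self.differentials: pd.DataFrame = differentials
        self.contributions: pd.DataFrame = contributions

    @property
    def ranking(self) -> pd.DataFrame:
        out = (self.index.to_frame("MGIDI")
               .assign(_id=self.index.index.astype(str))
               .sort_values(["MGIDI", "_id"], kind="stable")
               .drop(columns="_id"))
        out["rank"] = np.arange(1, len(out) + 1)
        out["selected"] = out.index.isin(self.selected)
        out.index.name = "genotype"
        return out

    @property
    def n_factors(self) -> int:
        return self.factor_model.n_factors

    def sd_totals(self) -> dict[str, float]:
        return sd_totals(self.differentials)

    def score(self, means: pd.DataFrame) -> pd.Series:
        """MGIDI of new rows given on the original trait scale.

        The rows are rescaled with the *fitted* per-trait min/max and
        directions, then scored and measured against the fitted ideotype.
        """
        cols = self.rescaled.columns
        base = self.model.means[cols]
        lo, hi = base.min(), base.max()
        frac = (means[cols] - lo) / (hi - lo)
        resc = frac * 100.0
        flip = self.model.directions[cols] < 0
        resc.loc[:, flip] = 100.0 - resc.loc[:, flip]
        gamma = self.factor_model.score(resc)
        diff = gamma - self.factor_model.ideotype_scores_
        return pd.Series(np.sqrt((diff**2).sum(axis=1)), index=means.index,
                         name="MGIDI")

    def summary(self) -> str:
        totals = self.sd_totals()
        lam = self.factor_model.eigenvalues
        lines = [
            "MGIDI — multi-trait genotype-ideotype distance index",
            f"genotypes: {len(self.index)}   traits: {self.rescaled.shape[1]}   "
            f"retained factors (eigenvalue >= 1): {self.n_factors}",
            f"leading eigenvalues: "
            + ", ".join(f"{v:.3f}" for v in lam[: min(5, len(lam))]),
            "",
            self.ranking.to_string(float_format=lambda x: f"{x:.4f}"),
            "",
            f"selection pressure {self.model.pressure:.2f} -> "
            f"{len(self.selected)} selected (cutpoint {self.cutpoint:.4f})",
            f"selection differential totals: "
            f"{totals['total_higher']:+.2f}% (higher-better), "
            f"{totals['total_lower']:+.2f}% (lower-better)",
        ]
        return "\n".join(lines)
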