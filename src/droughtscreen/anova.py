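"""Balanced factorial-RCBD variance analysis and broad-sense heritability.

The model is

    y_ijk = mu + a_i + c_j + b_k(j) + (ac)_ij + e_ijk

with genotype *i*, growing condition *j* (control/drought), block *k* nested
within condition, and normal iid errors.  Because the design is balanced by
construction, variance components are estimated exactly by equating observed
to expected mean squares (EMS); unbalanced data is rejected rather than
approximated.  Broad-sense heritability on a genotype-mean basis across both
conditions is

    H^2 = s2_g / (s2_g + s2_ge/e + s2_eps/(e*r))

with e conditions and r blocks; negative component estimates are truncated
at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorialRCBD",
    "FactorialRCBDResults",
    "VarianceDecomposition",
    "anova_factorial_rcbd",
    "heritability",
    "heritability_table",
    "paired_t",
    "pearson_correlation",
    "correlation_table",
    "significance_stars",
]

_KEY = ["genotype", "condition", "block"]

SOURCES = ("condition", "block(condition)", "genotype",
           "genotype:condition", "residual")


class UnbalancedDesignError(ValueError):
    """The observations do not form a complete balanced factorial RCBD."""


class DegenerateDataError(ValueError):
    """Statistic undefined for the supplied data (e.g. zero variance)."""


def _to_cube(obs: pd.DataFrame, trait: str) -> tuple[np.ndarray, list[str]]:
    """Pivot the long table for one trait into a (genotype, condition, block)
    cube, enforcing balance."""
    sub = obs[obs["trait"] == trait] if "trait" in obs.columns else obs
    if sub.empty:
        raise UnbalancedDesignError(f"no observations for trait {trait!r}")
    if sub.duplicated(_KEY).any():
        raise UnbalancedDesignError("duplicate (genotype, condition, block) cells")
    wide = sub.pivot_table(index="genotype", columns=["condition", "block"],
                           values="value", aggfunc="first", sort=True)
    if wide.isna().any().any():
        raise UnbalancedDesignError("missing cells: design must be complete")
    conditions = wide.columns.get_level_values(0).unique()
    blocks = wide.columns.get_level_values(1).unique()
    if len(conditions) != 2:
        raise UnbalancedDesignError("expected exactly 2 growing conditions")
    cube = np.empty((wide.shape[0], len(conditions), len(blocks)))
    for j, c in enumerate(conditions):
        cube[:, j, :] = wide[c].to_numpy()
    return cube, list(wide.index)


def _anova_from_cube(y: np.ndarray) -> pd.DataFrame:
    g, e, r = y.shape
    grand = y.mean()
    gm = y.mean(axis=(1, 2))
    cm = y.mean(axis=(0, 2))
    bm = y.mean(axis=0)           # (e, r) block-within-condition means
    cellm = y.mean(axis=2)        # (g, e)

    ss_g = e * r * np.sum((gm - grand) ** 2)
    ss_c = g * r * np.sum((cm - grand) ** 2)
    ss_b = g * np.sum((bm - cm[:, None]) ** 2)
    ss_ge = r * np.sum((cellm - gm[:, None] - cm[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_res = ss_tot - ss_g - ss_c - ss_b - ss_ge

    df = {
        "condition": e - 1,
        "block(condition)": e * (r - 1),
        "genotype": g - 1,
        "genotype:condition": (g - 1) * (e - 1),
        "residual": (g - 1) * e * (r - 1),
    }
    ss = {
        "condition": ss_c,
        "block(condition)": ss_b,
        "genotype": ss_g,
        "genotype:condition": ss_ge,
        "residual": max(ss_res, 0.0),
    }
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in df}
    ms_res = ms["residual"]
    table = []
    for src in SOURCES:
        if src == "residual" or not np.isfinite(ms_res) or ms_res <= 0:
            f = p = np.nan
        else:
            f = ms[src] / ms_res
            p = stats.f.sf(f, df[src], df["residual"])
        table.append({"source": src, "df": df[src], "sum_sq": ss[src],
                      "mean_sq": ms[src], "F": f, "p": p})
    out = pd.DataFrame(table).set_index("source")
    out.attrs["total_ss"] = ss_tot
    out.attrs["design"] = (g, e, r)
    return out


@dataclass(frozen=True)
class VarianceDecomposition:
    """Method-of-moments variance components and broad-sense heritability."""

    trait: str
    sigma2_g: float
    sigma2_ge: float
    sigma2_eps: float
    heritability: float
    n_conditions: int
    n_blocks: int
    truncated: tuple[str, ...] = ()

    def as_series(self) -> pd.Series:
        return pd.Series({
            "sigma2_g": self.sigma2_g, "sigma2_ge": self.sigma2_ge,
            "sigma2_eps": self.sigma2_eps, "H2": self.heritability,
        }, name=self.trait)


class FactorialRCBD:
    """Two-factor RCBD model for one trait of a long observation table.

    Parameters
    ----------
    obs : long DataFrame with columns genotype, condition, block, value and
        (if more than one trait is present) trait.
    trait : name of the trait to analyse.

    Examples
    --------
    >>> res = FactorialRCBD(panel, "Pn").fit()
    >>> res.anova_table; res.variance_components.heritability
    """

    def __init__(self, obs: pd.DataFrame, trait: str = ""):
        self.trait = trait
        self.cube, self.genotypes = _to_cube(obs, trait)

    @classmethod
    def from_cube(cls, cube: np.ndarray, trait: str = "") -> "FactorialRCBD":
        obj = cls.__new__(cls)
        obj.trait = trait
        obj.cube = np.asarray(cube, float)
        obj.genotypes = [f"G{i + 1:02d}" for i in range(obj.cube.shape[0])]
        return obj

    def fit(self) -> "FactorialRCBDResults":
        table = _anova_from_cube(self.cube)
        g, e, r = table.attrs["design"]
        ms = table["mean_sq"]
        s2_eps = ms["residual"]
        truncated = []
        s2_ge = (ms["genotype:condition"] - ms["residual"]) / r
        if s2_ge < 0:
            truncated.append("sigma2_ge")
            s2_ge = 0.0
        s2_g = (ms["genotype"] - ms["genotype:condition"]) / (r * e)
        if s2_g < 0:
            truncated.append("sigma2_g")
            s2_g = 0.0
        denom = s2_g + s2_ge / e + s2_eps / (e * r)
        h2 = s2_g / denom if denom > 0 else 0.0
        if truncated:
            warnings.warn(
                f"trait {self.trait!r}: negative variance-component estimate(s) "
                f"truncated at zero: {', '.join(truncated)}", stacklevel=2)
        vc = VarianceDecomposition(self.trait, s2_g, s2_ge, s2_eps, h2,
                                   e, r, tuple(truncated))
        return FactorialRCBDResults(self, table, vc)


class FactorialRCBDResults:
    """ANOVA table plus variance components for one trait."""

    def __init__(self, model: FactorialRCBD, anova_table: pd.DataFrame,
                 variance_components: VarianceDecomposition):
        self.model = model
        self.anova_table = anova_table
        self.variance_components = variance_components

    @property
    def heritability(self) -> float:
        return self.variance_components.heritability

    def summary(self) -> str:
        vc = self.variance_components
        lines = [f"Factorial RCBD ANOVA — trait {self.model.trait!r}",
                 self.anova_table.to_string(float_format=lambda x: f"{x:.6g}"),
                 (f"sigma2_g={vc.sigma2_g:.6g}  sigma2_ge={vc.sigma2_ge:.6g}  "
                  f"sigma2_eps={vc.sigma2_eps:.6g}  H2={vc.heritability:.4f}")]
        if vc.truncated:
            lines.append(f"truncated components: {', '.join(vc.truncated)}")
        return "\n".join(lines)


def anova_factorial_rcbd(obs: pd.DataFrame, trait: str = "") -> pd.DataFrame:
    """Classical EMS ANOVA table for one trait (see :class:`FactorialRCBD`)."""
    return FactorialRCBD(obs, trait).fit().anova_table


def heritability(obs: pd.DataFrame, trait: str = "") -> VarianceDecomposition:
    """Variance components and broad-sense H² for one trait."""
    return FactorialRCBD(obs, trait).fit().variance_components


def heritability_table(obs: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait variance components / H² table for a long observation table."""
    traits = list(traits) if traits is not None else sorted(obs["trait"].unique())
    rows = [heritability(obs, t).as_series() for t in traits]
    out = pd.DataFrame(rows)
    out.index.name = "trait"
    return out


# ---------------------------------------------------------------------------
# simple paired tests and correlations
# ---------------------------------------------------------------------------

def paired_t(control_means, drought_means) -> dict[str, float]:
    """Two-sided paired t-test between matched genotype means."""
    x = np.asarray(control_means, float)
    y = np.asarray(drought_means, float)
    if x.shape != y.shape or x.size < 2:
        raise DegenerateDataError("paired t needs two equal-length vectors, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise DegenerateDataError("paired t undefined: zero-variance differences")
    t, p = stats.ttest_rel(x, y)
    return {"t": float(t), "df": x.size - 1, "p": float(p)}


def pearson_correlation(x, y) -> dict[str, float]:
    """Pearson r with two-sided p from the t-transform (n − 2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise DegenerateDataError("correlation needs n >= 3")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise DegenerateDataError("correlation undefined for zero variance")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


def significance_stars(p: float) -> str:
    """Conventional star coding: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(means_by_condition: dict[str, pd.DataFrame],
                      trait_pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Star-coded correlations of trait pairs per growing condition.

    ``means_by_condition`` maps condition name to a genotype × trait matrix
    of means; one output row per (pair, condition).
    """
    columns = ["trait_1", "trait_2", "condition", "r", "p", "stars"]
    rows = []
    for (t1, t2) in trait_pairs:
        for cond, means in means_by_condition.items():
            res = pearson_correlation(means[t1], means[t2])
            rows.append({"trait_1": t1, "trait_2": t2, "condition": cond,
                         "r": res["r"], "p": res["p"],
                         "stars": significance_stars(res["p"])})
    return pd.DataFrame(rows, columns=columns)
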