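"""End-to-end orchestration: simulate/ingest -> derive -> ANOVA/H² ->
cluster + validate -> MGIDI, with every stage output persisted as CSV.

The long observation table (genotype, condition, block, trait, value) is the
single interchange format between stages; wide matrices are derived views.
A JSON manifest records the configuration hash, the seed, and the formula
variants in force, so a rerun with the same configuration reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import anova, cluster, mgidi, synthetic, traits

__all__ = ["RunConfig", "run_pipeline", "report_tables", "trait_means"]


@dataclass
class RunConfig:
    """Pipeline configuration (YAML/JSON loadable).

    ``observations`` may point at a long-format CSV; when None the default
    synthetic panel is generated at ``seed``.  ``mgidi_basis`` chooses the
    genotype means fed to the index: drought-condition means (default),
    across-condition means, or relative values.
    """

    seed: int = 0
    observations: str | None = None
    outdir: str = "droughtscreen_out"
    directions: dict[str, str] = field(default_factory=dict)
    k_genotypes: int = 3
    k_traits: int = 2
    pressure: float = 0.15
    mgidi_basis: str = "drought"
    rwl_per_dry_mass: bool = True
    gs_max_air_molar_volume: float = traits.AIR_MOLAR_VOLUME_25C
    gs_max_boundary_factor: float = 1.6
    correlation_targets: tuple[str, ...] = ("BY", "GY")
    correlation_partners: tuple[str, ...] = (
        "LRWC", "CTD", "CMS", "Pn", "gs", "SD", "AS",
        "Fv_Fm", "Phi_PSII", "H2O2", "Pro", "GB",
    )

    def __post_init__(self):
        if self.mgidi_basis not in ("drought", "mean", "relative"):
            raise ValueError("mgidi_basis must be drought, mean or relative")
        if not 0 < self.pressure <= 1:
            raise ValueError("selection pressure must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("correlation_targets", "correlation_partners"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def trait_means(obs: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """Genotype × trait matrix of means, optionally for one condition."""
    sub = obs if condition is None else obs[obs["condition"] == condition]
    return sub.pivot_table(index="genotype", columns="trait", values="value",
                           aggfunc="mean", sort=True)


def _validate_directions(config: RunConfig, trait_names) -> dict:
    unknown = set(config.directions) - set(trait_names)
    if unknown:
        raise ValueError(
            f"directions name trait(s) absent from the data: {sorted(unknown)}")
    base = {t: ("lower" if t in traits.LOWER_BETTER_DEFAULT else "higher")
            for t in trait_names}
    base.update(config.directions)
    return base


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and persist outputs under ``config.outdir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, **kwargs)
        written.append(name)

    stage = "input"
    try:
        if config.observations is None:
            design = synthetic.default_design(seed=config.seed)
            obs = synthetic.simulate_trait_panel(design)
        else:
            obs = pd.read_csv(config.observations)
            need = {"genotype", "condition", "block", "trait", "value"}
            if not need <= set(obs.columns):
                raise ValueError(f"observation CSV must have columns {sorted(need)}")
        trait_names = sorted(obs["trait"].unique())
        directions = _validate_directions(config, trait_names)
        save(obs, "observations.csv", index=False)

        stage = "anova"
        tables = []
        for t in trait_names:
            tab = anova.anova_factorial_rcbd(obs, t).reset_index()
            tab.insert(0, "trait", t)
            tables.append(tab)
        save(pd.concat(tables, ignore_index=True), "anova.csv", index=False)
        h2 = anova.heritability_table(obs, trait_names)
        save(h2, "heritability.csv")

        stage = "means"
        control = trait_means(obs, "control")
        drought = trait_means(obs, "drought")
        save(control, "means_control.csv")
        save(drought, "means_drought.csv")
        rel = traits.relative_values(control, drought)
        save(rel, "relative_values.csv")
        pct = traits.percent_change(control.to_numpy(), drought.to_numpy())
        pct = pd.DataFrame(pct, index=control.index, columns=control.columns)
        save(pct, "percent_change.csv")

        stage = "cluster"
        z = cluster.standardize_columns(rel)
        save(z, "relative_values_standardized.csv")
        tw = cluster.two_way_cluster(z, config.k_genotypes, config.k_traits)
        save(tw.row_tree.as_frame(), "linkage_genotypes.csv", index=False)
        save(tw.col_tree.as_frame(), "linkage_traits.csv", index=False)
        save(tw.row_assignment.to_frame(), "clusters_genotypes.csv")
        save(tw.col_assignment.to_frame(), "clusters_traits.csv")
        save(z.clip(-2, 2).loc[tw.ordered_matrix.index,
                               tw.ordered_matrix.columns],
             "heatmap_matrix.csv")

        stage = "pca"
        pca_model = cluster.pca(rel)
        save(pca_model.scores, "pca_scores.csv")
        save(pca_model.loadings, "pca_loadings.csv")
        save(pd.DataFrame({"eigenvalue": pca_model.eigenvalues,
                           "percent_variance": pca_model.percent_variance},
                          index=pca_model.scores.columns),
             "pca_variance.csv")

        stage = "lda"
        confusion = cluster.lda_crossvalidate(z, tw.row_assignment)
        save(confusion.counts, "lda_confusion.csv")

        stage = "cluster-summary"
        summary = cluster.cluster_summary(pct, tw.row_assignment)
        save(summary, "cluster_percent_change.csv")

        stage = "mgidi"
        if config.mgidi_basis == "drought":
            basis = drought
        elif config.mgidi_basis == "mean":
            basis = trait_means(obs)
        else:
            basis = rel
        fitted = mgidi.MGIDI(basis, directions, config.pressure).fit()
        save(fitted.ranking, "mgidi_ranking.csv")
        save(pd.concat([fitted.factor_model.rotated_loadings,
                        fitted.factor_model.communalities], axis=1),
             "mgidi_loadings.csv")
        contrib = fitted.contributions.reset_index(names="genotype").melt(
            id_vars="genotype", var_name="factor", value_name="share")
        save(contrib, "mgidi_contributions.csv", index=False)
        save(fitted.differentials, "mgidi_selection_differentials.csv")

        stage = "report"
        pairs = [(t, p) for t in config.correlation_targets
                 for p in config.correlation_partners
                 if t in trait_names and p in trait_names]
        corr = anova.correlation_table(
            {"control": control, "drought": drought}, pairs)
        save(corr, "correlation_table.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "formula_variants": {
            "rwl_per_dry_mass": config.rwl_per_dry_mass,
            "gs_max_air_molar_volume": config.gs_max_air_molar_volume,
            "gs_max_boundary_factor": config.gs_max_boundary_factor,
            "mgidi_basis": config.mgidi_basis,
        },
        "n_genotypes": int(control.shape[0]),
        "n_traits": int(len(trait_names)),
        "n_factors": int(fitted.n_factors),
        "selected": [str(s) for s in fitted.selected],
        "lda_accuracy": confusion.accuracy,
        "outputs": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


def report_tables(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Load the publication-style summary tables from a finished run.

    Returns the star-coded correlation table, the per-cluster percent-change
    table and the MGIDI ranking; stages whose output is missing are listed
    under ``"skipped"`` (as an empty DataFrame with a note column).
    """
    out = Path(outdir)
    wanted = {
        "correlations": "correlation_table.csv",
        "cluster_percent_change": "cluster_percent_change.csv",
        "mgidi_ranking": "mgidi_ranking.csv",
    }
    tables: dict[str, pd.DataFrame] = {}
    skipped = []
    for key, name in wanted.items():
        path = out / name
        if path.exists():
            tables[key] = pd.read_csv(path)
        else:
            skipped.append(name)
    if skipped:
        tables["skipped"] = pd.DataFrame({"missing": skipped})
    return tables
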