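"""End-to-end orchestration: filter, fit, estimate, correlate.

The pipeline reproduces the analysis chain on one record table: apply
the record-exclusion filters, fit the growth GLM, derive per-group
curves and allocation integrals, estimate differential mortality from
the dominance hierarchy, assemble the comparative table, and run the
species-level and contrast-level correlation tests plus the plasticity
check — all under one seed, with a manifest that makes a run
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allocation as alloc
from . import comparative_stats as cs
from . import growth_model as gm
from . import mortality as mort
from . import phylo
from .mortality import UNINFECTED_GROUPS

log = logging.getLogger(__name__)

__all__ = ["FilterReport", "RunManifest", "apply_filters", "flag_outliers",
           "local_risk_table", "run_pipeline"]


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of the record-exclusion chain; counts must conserve."""

    input_count: int
    mixed_species: int
    undetermined: int
    outlier: int
    rare_species: int
    retained: int
    retained_per_group: dict[str, int]

    def __post_init__(self) -> None:
        total = (self.mixed_species + self.undetermined + self.outlier
                 + self.rare_species + self.retained)
        assert total == self.input_count, "filter dispositions must sum to input"


def apply_filters(records: pd.DataFrame, min_group_n: int = 20,
                  outlier_col: str = "outlier_flag") -> tuple[pd.DataFrame, FilterReport]:
    """Record-exclusion chain; first matching rule wins.

    In order: surviving mixed-species infections (uncertain original
    status); records with undetermined initial size, gender or infection
    status; flagged outliers; then infections of any species retained
    with ``min_group_n`` or fewer individuals (strictly more than 20 are
    needed by default, because low samples underestimate the mean of
    overdispersed growth).  Uninfected groups are never rare-dropped.
    """
    df = records.copy()
    disposition = pd.Series("retained", index=df.index)

    mixed = df["infection"].astype(str).str.contains(r"\+", na=False)
    disposition[mixed] = "mixed"

    undet = (df["infection"].isna() | df["gender"].isna()
             | df["initial_length"].isna() | df["initial_size"].isna())
    disposition[undet & (disposition == "retained")] = "undetermined"

    if outlier_col in df.columns:
        out = df[outlier_col].fillna(False).astype(bool)
        disposition[out & (disposition == "retained")] = "outlier"

    kept = disposition == "retained"
    infected = kept & (df["infection"] != "none")
    counts = df.loc[infected, "infection"].value_counts()
    rare_species = set(counts[counts <= min_group_n].index)
    rare = infected & df["infection"].isin(rare_species)
    disposition[rare] = "rare"

    retained = df[disposition == "retained"]
    per_group = retained["group"].value_counts().to_dict()
    report = FilterReport(
        input_count=len(df),
        mixed_species=int((disposition == "mixed").sum()),
        undetermined=int((disposition == "undetermined").sum()),
        outlier=int((disposition == "outlier").sum()),
        rare_species=int((disposition == "rare").sum()),
        retained=len(retained),
        retained_per_group={str(k): int(v) for k, v in per_group.items()},
    )
    if report.retained == 0:
        log.warning("all records excluded by the filter chain")
    return retained.reset_index(drop=True), report


def flag_outliers(records: pd.DataFrame, threshold: float = 4.0) -> pd.DataFrame:
    """Flag growth outliers by absolute Studentized deviance residual.

    Runs a preliminary quasi-Poisson fit on the records that pass every
    other filter and marks records whose |Studentized deviance residual|
    exceeds ``threshold`` (4 by default).  Returns a copy with
    ``outlier_flag`` updated; the rule is recorded by the manifest.
    """
    df = records.copy()
    df["outlier_flag"] = False
    clean, _ = apply_filters(df, min_group_n=0)
    if len(clean) < 50:
        return df
    try:
        fit = gm.fit_growth(clean, compute_term_tests=False)
    except ValueError:
        return df
    y = fit.design.response_values(clean)
    X, _, _, _ = gm._build_design(clean, fit.design)
    mu = np.exp(X @ fit.params)
    sign = np.sign(y - mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * (np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
    resid = sign * np.sqrt(np.maximum(dev, 0.0) / fit.dispersion)
    flagged = clean.index[np.abs(resid) > threshold]
    # map back to the original frame by matching retained row order
    key_cols = ["site", "gender", "degrees_growth", "initial_length"]
    flagged_keys = set(map(tuple, clean.loc[flagged, key_cols].itertuples(index=False)))
    mask = df[key_cols].apply(tuple, axis=1).isin(flagged_keys)
    df.loc[mask, "outlier_flag"] = True
    return df


def local_risk_table(records: pd.DataFrame,
                     hierarchy: mort.DominanceHierarchy) -> pd.DataFrame:
    """Per (group, site) mean growth and local differential-mortality risk.

    The local risk of a castrator species at a site is the prevalence of
    its dominants there; for uninfected snails it is the overall
    trematode prevalence (the risk of castration).  Feeds the
    plasticity test.
    """
    tables = {t.site: t for t in mort.tabulate_sites(records)}
    rows = []
    for (group, site), sub in records.groupby(["group", "site"]):
        t = tables[site]
        if group in UNINFECTED_GROUPS:
            risk = sum(bool(inf) for inf in t.infections) / t.n_snails
        else:
            dom = hierarchy.dominants_of(str(group))
            risk = sum(bool(inf & dom) for inf in t.infections) / t.n_snails
        rows.append({"group": str(group), "site": str(site),
                     "mean_growth": float(sub["growth"].mean()),
                     "risk": float(risk), "n": len(sub)})
    return pd.DataFrame(rows)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    statistics: dict[str, dict] = field(default_factory=dict)
    outlier_rule: str = "abs studentized deviance residual > 4"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=float)


def _config_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def run_pipeline(records: pd.DataFrame, hierarchy: mort.DominanceHierarchy,
                 gsi: dict[str, float], seed: int = 0,
                 iterations: int = 10_000,
                 newick: str | None = None,
                 drop_groups: tuple[str, ...] = (),
                 detect_outliers: bool = True,
                 min_group_n: int = 20,
                 reference_site: str | None = None,
                 mean_size: float | None = None) -> tuple[RunManifest, dict]:
    """Run the full analysis chain on one record table.

    Returns ``(manifest, outputs)`` where ``outputs`` carries the filter
    report, growth fit, allocation table, mortality estimates and every
    test result.  ``drop_groups`` re-runs the correlations without the
    named groups (robustness re-runs such as excluding the uninfected
    genders); ``newick`` enables the contrast-level analyses.
    """
    from . import __version__

    rng_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    manifest = RunManifest(config_hash=_config_hash((sorted(gsi.items()),
                                                     hierarchy.edges, seed,
                                                     iterations, drop_groups)),
                           seed=seed, version=__version__)
    outputs: dict = {}
    manifest.stage_counts["input"] = len(records)

    if detect_outliers:
        records = flag_outliers(records)
    retained, report = apply_filters(records, min_group_n=min_group_n)
    outputs["filter_report"] = report
    manifest.stage_counts["retained"] = report.retained

    design = gm.GrowthDesign(reference_site=reference_site)
    fit = gm.fit_growth(retained, design)
    outputs["growth_fit"] = fit
    manifest.statistics["dispersion"] = {"value": fit.dispersion}

    mean_size = mean_size if mean_size is not None else fit.mean_initial_size
    vmin, vmax = gm.common_size_limits(fit)
    growth_rows = []
    for group in fit.groups:
        curve = gm.growth_curve(fit, group)
        growth_rows.append({
            "group": group,
            "growth_at_mean_size": gm.growth_at_mean_size(fit, group, mean_size),
            "total_growth_allocation": gm.total_growth_allocation(curve, vmin, vmax),
            "mean_size": mean_size,
        })
    growth_table = pd.DataFrame(growth_rows)
    outputs["growth_table"] = growth_table
    outputs["contrast_table"] = gm.pairwise_contrasts(fit, mean_size)

    tables = mort.tabulate_sites(retained)
    mort_rows = []
    for sp in sorted(set(fit.groups) - set(UNINFECTED_GROUPS)):
        est = mort.estimate_mortality(tables, hierarchy, sp)
        mort_rows.append({"group": sp, "differential_mortality": est.pooled,
                          "n_sites": est.n_sites})
    for gender in UNINFECTED_GROUPS:
        if gender in fit.groups:
            mort_rows.append({
                "group": gender,
                "differential_mortality": mort.castration_risk(tables, gender),
                "n_sites": len(tables),
            })
    mortality_table = pd.DataFrame(mort_rows)
    outputs["mortality_table"] = mortality_table

    gsi_records = [alloc.GsiRecord(group=g, fraction=f) for g, f in gsi.items()
                   if g in set(fit.groups)]
    table = alloc.build_allocation_table(growth_table, mortality_table,
                                         gsi_records)
    outputs["allocation_table"] = table
    manifest.stage_counts["allocation_groups"] = len(table)

    def correlation_suite(sub: pd.DataFrame, label: str) -> None:
        if len(sub) < 3:
            log.warning("%s: too few groups for correlations", label)
            return
        pairs = {
            "growth_vs_mortality": (sub["total_growth_allocation"],
                                    sub["differential_mortality"]),
            "rra_vs_mortality": (sub["relative_reproductive_allocation"],
                                 sub["differential_mortality"]),
            "gsi_vs_mortality": (sub["gsi"], sub["differential_mortality"]),
            "gsi_vs_rra": (sub["gsi"],
                           sub["relative_reproductive_allocation"]),
        }
        for name, (x, y) in pairs.items():
            res = cs.randomization_correlation(x.to_numpy(), y.to_numpy(),
                                               iterations=iterations,
                                               seed=rng_seed)
            sma = cs.sma_fit(x.to_numpy(), y.to_numpy())
            manifest.statistics[f"{label}:{name}"] = {
                "r": res.statistic, "p": res.p_value, "n": len(sub),
                "sma_slope": sma.slope, "B": iterations,
            }
        guard = cs.two_stage_randomization(
            sub["growth_at_mean_size"].to_numpy(),
            sub["differential_mortality"].to_numpy(),
            sub["gsi"].to_numpy(), iterations=iterations, seed=rng_seed)
        manifest.statistics[f"{label}:rra_two_stage"] = {
            "r": guard.statistic, "p": guard.p_value, "n": len(sub),
            "B": iterations,
        }

    correlation_suite(table, "species")
    if drop_groups:
        correlation_suite(table[~table["group"].isin(drop_groups)],
                          f"species_minus_{'_'.join(sorted(drop_groups))}")

    if newick is not None:
        tree = phylo.read_tree(newick)
        tips = set(tree.tip_labels)
        sub = table[table["group"].isin(tips)]
        if set(sub["group"]) == tips:
            traits = sub.set_index("group")
            for name, col in (("growth_vs_mortality", "total_growth_allocation"),
                              ("rra_vs_mortality",
                               "relative_reproductive_allocation")):
                rand, origin = phylo.contrast_correlation(
                    tree, traits[col].to_dict(),
                    traits["differential_mortality"].to_dict(),
                    iterations=iterations, seed=rng_seed)
                manifest.statistics[f"contrasts:{name}"] = {
                    "r": rand.statistic, "p": rand.p_value,
                    "n": tree.n_tips - 1, "origin_slope": origin.slope,
                    "origin_t": origin.t, "origin_df": origin.df,
                    "origin_p": origin.p_value, "B": iterations,
                }
        else:
            log.warning("tree tips not all present in allocation table; "
                        "contrast analyses skipped")

    risk = local_risk_table(retained, hierarchy)
    outputs["risk_table"] = risk
    try:
        plast = cs.plasticity_test(risk)
        manifest.statistics["plasticity"] = {
            "F": plast.f, "df_num": plast.df_num, "df_den": plast.df_den,
            "p": plast.p_value,
        }
        outputs["plasticity"] = plast
    except ValueError as err:
        log.warning("plasticity test skipped: %s", err)

    try:
        gender = mort.gender_susceptibility_test(retained)
        manifest.statistics["gender_susceptibility"] = gender
    except ValueError as err:
        log.warning("gender susceptibility test skipped: %s", err)

    return manifest, outputs
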