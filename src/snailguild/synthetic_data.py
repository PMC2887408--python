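"""Synthetic mark-recapture worlds with known life-history ground truth.

The generator emulates the statistical structure of a field
mark-recapture study of a parasitic-castrator guild sharing one snail
host: ~10 comparison groups (eight castrator species plus uninfected
males and females), 17 sites nested in three estuaries with fixed site
effects and two growing periods, independent multi-species recruitment
followed by hierarchical within-host killing (dominants remove
subordinates), species-varying prevalence across sites (including a
spatial-refuge species concentrated where dominants are rare and a
tissue-refuge species that tolerates most would-be killers), and
strongly overdispersed non-negative growth with species-by-size
interactions.

Everything latent is kept: the full pre-kill recruitment set per snail,
the realized kill fraction per species, and the generating growth
coefficients — so estimator-recovery tests have an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import shell_geometry as geom
from .mortality import DominanceHierarchy

__all__ = [
    "GroupGrowthParams",
    "WorldConfig",
    "SyntheticWorld",
    "default_config",
    "generate_world",
    "generate_fixture_counts",
]

RECORD_COLUMNS = [
    "site", "estuary", "habitat", "growing_days", "gender", "infection",
    "initial_length", "initial_width", "final_length", "final_width",
    "degrees_growth", "initial_size", "growth", "group", "outlier_flag",
]


@dataclass(frozen=True)
class GroupGrowthParams:
    """Log-scale growth law of one group: mean = exp(intercept + slope*size).

    ``dispersion`` is the quasi-Poisson variance inflation (variance =
    dispersion * mean); 1 is the Poisson limit.
    """

    intercept: float
    slope: float
    dispersion: float = 4.0

    def __post_init__(self) -> None:
        if self.dispersion < 1.0:
            raise ValueError("dispersion factor must be >= 1")


@dataclass(frozen=True)
class WorldConfig:
    """Full parameterization of a synthetic world.

    ``site_layout`` maps estuary -> {site: habitat};
    ``recruitment_prevalence`` maps (site, species) -> probability;
    ``growing_days`` maps estuary -> tuple of period lengths (days)
    sampled per snail; ``site_log_effects`` are fixed site offsets on
    the log-mean scale.
    """

    species_codes: tuple[str, ...]
    dominance_edges: tuple[tuple[str, str], ...]
    site_layout: dict[str, dict[str, str]]
    recruitment_prevalence: dict[tuple[str, str], float]
    growth_params: dict[str, GroupGrowthParams]
    gsi: dict[str, float]
    growing_days: dict[str, tuple[int, ...]]
    site_log_effects: dict[str, float]
    n_snails_per_site: int = 120
    reference_days: float = 105.0   # 3.5 months
    width_ratio: float = 0.39       # shell width as a fraction of length
    male_susceptibility: float = 1.0  # multiplier on recruitment odds for males
    mean_length: float = 26.0
    sd_length: float = 6.0
    length_range: tuple[float, float] = (8.0, 43.0)
    seed: int = 0

    def __post_init__(self) -> None:
        DominanceHierarchy(list(self.dominance_edges),
                           species=list(self.species_codes))  # validates acyclicity
        for p in self.recruitment_prevalence.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("recruitment prevalences must lie in [0, 1]")
        if self.n_snails_per_site <= 0:
            raise ValueError("n_snails_per_site must be positive")

    @property
    def sites(self) -> list[tuple[str, str, str]]:
        """(estuary, site, habitat) triples in a stable order."""
        out = []
        for estuary in sorted(self.site_layout):
            for site in sorted(self.site_layout[estuary]):
                out.append((estuary, site, self.site_layout[estuary][site]))
        return out

    @property
    def hierarchy(self) -> DominanceHierarchy:
        return DominanceHierarchy(list(self.dominance_edges),
                                  species=list(self.species_codes))


@dataclass
class SyntheticWorld:
    """Observed records plus the latent truth that produced them."""

    records: pd.DataFrame
    latent_infections: list[frozenset[str]]
    true_mortality: dict[str, float]
    true_growth: dict[str, GroupGrowthParams]
    config: WorldConfig


# Default guild: eight castrator species ranked from most dominant
# (hime) to most subordinate (smcy), with two deliberate departures from
# a clean rank-mortality relationship: renc tolerates co-infection with
# everything below the top rank (a tissue refuge), and smcy recruits
# mostly where its dominants are rare (a spatial refuge).
DEFAULT_RANKS = ("hime", "echi", "para", "euha", "stic", "pygi", "renc", "smcy")
UNINFECTED = ("male", "female")

# growth at the mean-sized snail (mm^3 per reference period): the
# configured study condition couples growth negatively with the expected
# mortality from the hierarchy and prevalences below, with uninfected
# snails growing least (their castration risk is the guild's highest).
_GROWTH_AT_MEAN = {
    "hime": 28.0, "echi": 24.0, "para": 20.0, "euha": 12.0,
    "stic": 16.0, "pygi": 14.0, "renc": 26.0, "smcy": 32.0,
    "male": 9.0, "female": 11.0,
}
_SIZE_SLOPES = {
    "hime": -0.0012, "echi": -0.0011, "para": -0.0013, "euha": -0.0009,
    "stic": -0.0014, "pygi": -0.0010, "renc": -0.0012, "smcy": -0.0015,
    "male": -0.0010, "female": -0.0013,
}
# reproductive tissue mass fractions: trematode indices rise gently with
# expected mortality so the reproduction-mortality coupling is positive
# beyond what the growth denominator alone induces; uninfected values
# are the host gonadosomatic indices.
_DEFAULT_GSI = {
    "hime": 0.16, "echi": 0.19, "para": 0.21, "euha": 0.23,
    "stic": 0.26, "pygi": 0.28, "renc": 0.17, "smcy": 0.18,
    "male": 0.146, "female": 0.149,
}
_MEAN_SIZE = 705.0  # mm^3, the guild's mean-sized snail


def default_config(n_snails_per_site: int = 120, seed: int = 0,
                   dispersion: float = 4.0,
                   male_susceptibility: float = 1.0) -> WorldConfig:
    """The default study conditions: 17 sites in 3 estuaries, 10 groups.

    Estuary CSM has two habitats (channel and pan; the three pans are
    dominant-poor refuge sites) and only the first growing period; LPL
    and TJE are channel-only with both periods.  One refuge site also
    sits in LPL so the spatial-refuge species is not confined to a
    single estuary.
    """
    layout = {
        "CSM": {f"CSM{i}": ("pan" if i > 4 else "channel") for i in range(1, 8)},
        "LPL": {f"LPL{i}": "channel" for i in range(1, 7)},
        "TJE": {f"TJE{i}": "channel" for i in range(1, 5)},
    }
    refuge_sites = {"CSM5", "CSM6", "CSM7", "LPL6"}

    base_prev = {
        "hime": 0.06, "echi": 0.05, "para": 0.05, "euha": 0.10,
        "stic": 0.03, "pygi": 0.04, "renc": 0.04, "smcy": 0.01,
    }
    prevalence: dict[tuple[str, str], float] = {}
    for estuary, sites in layout.items():
        for site in sites:
            for sp, p in base_prev.items():
                if site in refuge_sites:
                    prevalence[(site, sp)] = 0.15 if sp == "smcy" else 0.1 * p
                else:
                    prevalence[(site, sp)] = p

    # renc is killed only by the top rank; every other pair follows the
    # linear order
    exceptions = [(k, "renc") for k in DEFAULT_RANKS[1:6]]
    edges = tuple(
        (a, b)
        for i, a in enumerate(DEFAULT_RANKS)
        for b in DEFAULT_RANKS[i + 1:]
        if (a, b) not in set(exceptions)
    )

    growth = {
        g: GroupGrowthParams(
            intercept=float(np.log(_GROWTH_AT_MEAN[g]) - _SIZE_SLOPES[g] * _MEAN_SIZE),
            slope=_SIZE_SLOPES[g],
            dispersion=dispersion,
        )
        for g in list(DEFAULT_RANKS) + list(UNINFECTED)
    }

    all_sites = sorted(s for sites in layout.values() for s in sites)
    offsets = np.linspace(-0.3, 0.3, len(all_sites))
    site_effects = {s: float(o) for s, o in zip(all_sites, offsets)}
    for s in layout["CSM"]:
        if layout["CSM"][s] == "pan":
            site_effects[s] -= 0.2  # pans are poorer growing habitat

    return WorldConfig(
        species_codes=DEFAULT_RANKS,
        dominance_edges=edges,
        site_layout=layout,
        recruitment_prevalence=prevalence,
        growth_params=growth,
        gsi=dict(_DEFAULT_GSI),
        growing_days={"CSM": (94,), "LPL": (94, 154), "TJE": (94, 154)},
        site_log_effects=site_effects,
        n_snails_per_site=n_snails_per_site,
        male_susceptibility=male_susceptibility,
        seed=seed,
    )


def default_gsi_table() -> dict[str, float]:
    return dict(_DEFAULT_GSI)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_growth(rng, mean, dispersion):
    """Overdispersed count draw: Poisson mixed over a gamma mean.

    With mean mu and dispersion phi, the latent rate is
    Gamma(mu/(phi-1), phi-1), giving variance phi*mu; phi = 1 collapses
    to plain Poisson.
    """
    if dispersion <= 1.0 + 1e-12:
        return rng.poisson(mean)
    shape = mean / (dispersion - 1.0)
    lam = rng.gamma(shape, dispersion - 1.0)
    return rng.poisson(lam)


def generate_world(config: WorldConfig, seed: int | None = None) -> SyntheticWorld:
    """Simulate one mark-recapture dataset under ``config``.

    Recruitment is independent across species within each snail — the
    assumption the mortality estimator leans on — so the realized kill
    fractions recorded in ``true_mortality`` are the exact estimand.
    Shell measurements are back-computed from the drawn growth volumes
    through the cone and aperture geometry and rounded to 0.1 mm, the
    field measurement resolution.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    hierarchy = config.hierarchy
    species = list(config.species_codes)

    recruited = {sp: 0 for sp in species}
    killed = {sp: 0 for sp in species}
    gender_totals = {g: {} for g in UNINFECTED}   # gender -> site -> [n, infected]

    rows = []
    latent_sets: list[frozenset[str]] = []
    for estuary, site, habitat in config.sites:
        n = config.n_snails_per_site
        days = rng.choice(config.growing_days[estuary], size=n)
        lengths = _truncated_normal(rng, config.mean_length, config.sd_length,
                                    *config.length_range, size=n)
        genders = np.where(rng.random(n) < 0.5, "male", "female")
        site_eff = config.site_log_effects.get(site, 0.0)
        for i in range(n):
            gender = str(genders[i])
            odds_mult = config.male_susceptibility if gender == "male" else 1.0
            latent = set()
            for sp in species:
                p = config.recruitment_prevalence.get((site, sp), 0.0)
                if odds_mult != 1.0:
                    odds = odds_mult * p / (1 - p) if p < 1 else np.inf
                    p = odds / (1 + odds)
                if rng.random() < p:
                    latent.add(sp)
            survivors = {
                sp for sp in latent
                if not any(hierarchy.dominates(k, sp) for k in latent if k != sp)
            }
            for sp in latent:
                recruited[sp] += 1
                if sp not in survivors:
                    killed[sp] += 1

            if not survivors:
                infection, group = "none", gender
                rec = gender_totals[gender].setdefault(site, [0, 0])
                rec[0] += 1
            elif len(survivors) == 1:
                infection = group = next(iter(survivors))
                rec = gender_totals[gender].setdefault(site, [0, 0])
                rec[0] += 1
                rec[1] += 1
            else:
                ordered = sorted(survivors, key=species.index)
                infection, group = "+".join(ordered), ordered[0]
                rec = gender_totals[gender].setdefault(site, [0, 0])
                rec[0] += 1
                rec[1] += 1

            params = config.growth_params[group]
            length0 = float(lengths[i])
            v0 = geom.cone_volume(length0, config.width_ratio * length0)
            mu = np.exp(params.intercept + params.slope * v0 + site_eff)
            mu *= days[i] / config.reference_days
            y = float(_draw_growth(rng, mu, params.dispersion))

            vf = v0 + y
            lengthf = geom.cone_length(vf, config.width_ratio)
            widthf = config.width_ratio * lengthf
            degrees = geom.degrees_from_growth(y, widthf)

            il = round(length0, 1)
            iw = round(config.width_ratio * length0, 1)
            fl = max(round(lengthf, 1), il)
            fw = max(round(widthf, 1), iw)
            m = geom.ShellMeasurement(il, iw, fl, fw, degrees)
            rows.append({
                "site": site, "estuary": estuary, "habitat": habitat,
                "growing_days": int(days[i]), "gender": gender,
                "infection": infection,
                "initial_length": il, "initial_width": iw,
                "final_length": fl, "final_width": fw,
                "degrees_growth": degrees,
                "initial_size": geom.initial_volume(m),
                "growth": geom.growth_volume(m),
                "group": group, "outlier_flag": False,
            })
            latent_sets.append(frozenset(latent))

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    true_mortality = {
        sp: (killed[sp] / recruited[sp]) if recruited[sp] else 0.0
        for sp in species
    }
    # for uninfected snails the analogue is the castration risk: the
    # realized gender-specific infection prevalence averaged across sites
    for gender in UNINFECTED:
        per_site = [inf / tot for tot, inf in gender_totals[gender].values() if tot]
        true_mortality[gender] = float(np.mean(per_site)) if per_site else 0.0

    return SyntheticWorld(records=records, latent_infections=latent_sets,
                          true_mortality=true_mortality,
                          true_growth=dict(config.growth_params),
                          config=config)


def generate_fixture_counts(totals: dict[str, int],
                            seed: int = 0) -> pd.DataFrame:
    """A record table with exact exclusion-category counts.

    ``totals`` may carry keys ``mixed``, ``outlier``, ``undetermined``,
    ``rare`` and ``retained``; each produced record falls into exactly
    one category.  Retained infected records are spread over the default
    eight-species guild with more than 20 individuals each (or made
    uninfected when the budget cannot support a species); rare records
    are split over nine rare species codes with 2-16 individuals each.
    Used to exercise the record-filter arithmetic.
    """
    for k, v in totals.items():
        if v < 0:
            raise ValueError(f"negative count for {k!r}")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def base_row(**kw):
        row = {
            "site": "CSM1", "estuary": "CSM", "habitat": "channel",
            "growing_days": 94, "gender": "female", "infection": "none",
            "initial_length": 25.0, "initial_width": 9.8,
            "final_length": 25.5, "final_width": 10.0,
            "degrees_growth": 90.0, "initial_size": 628.0, "growth": 4.9,
            "group": "female", "outlier_flag": False,
        }
        row.update(kw)
        return row

    retained = totals.get("retained", 0)
    n_inf = int(round(retained * 0.38))
    k = min(len(DEFAULT_RANKS), n_inf // 21)
    per_species = []
    if k > 0:
        each = n_inf // k
        per_species = [each] * k
        per_species[0] += n_inf - each * k
    else:
        n_inf = 0
    n_uninf = retained - sum(per_species)
    for sp, count in zip(DEFAULT_RANKS, per_species):
        for _ in range(count):
            rows.append(base_row(infection=sp, group=sp,
                                 gender=str(rng.choice(["male", "female"]))))
    for i in range(n_uninf):
        g = "male" if i % 2 == 0 else "female"
        rows.append(base_row(gender=g, group=g))

    for _ in range(totals.get("mixed", 0)):
        rows.append(base_row(infection="hime+euha", group="hime"))
    for _ in range(totals.get("outlier", 0)):
        rows.append(base_row(outlier_flag=True, growth=900.0,
                             degrees_growth=16500.0, final_length=31.0,
                             final_width=12.1))
    for i in range(totals.get("undetermined", 0)):
        rows.append(base_row(gender=np.nan, infection=np.nan)
                    if i % 2 == 0 else base_row(gender=np.nan))

    n_rare = totals.get("rare", 0)
    rare_codes = [f"rare{i}" for i in range(1, 10)]
    rare_counts = _split_rare(n_rare, len(rare_codes))
    for sp, count in zip(rare_codes, rare_counts):
        for _ in range(count):
            rows.append(base_row(infection=sp, group=sp))

    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    assert len(df) == sum(totals.values())
    return df


def _split_rare(total: int, n_codes: int, lo: int = 2, hi: int = 16) -> list[int]:
    """Split ``total`` over up to ``n_codes`` species with lo..hi individuals each."""
    if total == 0:
        return []
    counts: list[int] = []
    remaining = total
    while remaining > 0:
        if len(counts) == n_codes:  # spill over the cap rather than invent a code
            counts[-1] += remaining
            break
        take = min(hi, remaining)
        leftover = remaining - take
        if 0 < leftover < lo and take > lo:
            take -= lo - leftover
        counts.append(take)
        remaining -= take
    return counts


def write_world(world: SyntheticWorld, out_dir) -> None:
    """Write records, latent truth and config as delimited text + YAML."""
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.records.to_csv(out / "records.csv", index=False)
    truth = pd.DataFrame({
        "group": list(world.true_mortality),
        "true_mortality": list(world.true_mortality.values()),
    })
    growth = pd.DataFrame([
        {"group": g, "intercept": p.intercept, "slope": p.slope,
         "dispersion": p.dispersion}
        for g, p in world.true_growth.items()
    ])
    truth.merge(growth, on="group", how="outer").to_csv(
        out / "latent_truth.csv", index=False)
    latent = pd.DataFrame({
        "snail": range(len(world.latent_infections)),
        "latent_infections": ["+".join(sorted(s)) for s in world.latent_infections],
    })
    latent.to_csv(out / "latent_infections.csv", index=False)
    cfg = world.config
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({
            "species_codes": list(cfg.species_codes),
            "n_snails_per_site": cfg.n_snails_per_site,
            "seed": cfg.seed,
            "reference_days": cfg.reference_days,
            "width_ratio": cfg.width_ratio,
        }, fh)
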