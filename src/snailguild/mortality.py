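"""Differential extrinsic mortality from a trematode dominance hierarchy.

Within a shared snail host, dominant trematode species kill subordinate
species in co-infections, so the infections we observe are the
survivors.  The estimator reconstructs, per site, how many recruits of a
focal species were killed: the focal's prevalence among snails free of
any of its dominants ("dominant-free" snails, where the focal's
recruitment is undisturbed) is applied to the snails that do carry a
dominant, giving the expected co-recruits; subtracting the co-infections
actually observed gives the kills.  Negative values are meaningful: they
flag species found *with* their dominants more often than independent
recruitment predicts (facilitation, e.g. via a tissue refuge).

For uninfected snails the analogous quantity is the risk of parasitic
castration: the gender-specific trematode prevalence averaged across
sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "DominanceHierarchy",
    "SiteInfectionTable",
    "MortalityEstimate",
    "tabulate_sites",
    "site_mortality",
    "pooled_mortality",
    "estimate_mortality",
    "castration_risk",
    "gender_susceptibility_test",
    "read_hierarchy",
]

UNINFECTED_GROUPS = ("male", "female")


class DominanceHierarchy:
    """Strict directed relation ``dominates(killer, victim)`` over species codes.

    The relation must be irreflexive and acyclic; transitivity is *not*
    assumed, because real hierarchies carry exceptions (a subordinate
    tolerated by particular mid-ranking species, for instance).
    Pair-specific tolerated co-infections are represented simply by
    omitting the edge.
    """

    def __init__(self, edges: list[tuple[str, str]],
                 species: list[str] | None = None):
        self._dominants: dict[str, set[str]] = {}
        seen: set[str] = set(species or [])
        for killer, victim in edges:
            if killer == victim:
                raise ValueError(f"species {killer!r} cannot dominate itself")
            self._dominants.setdefault(victim, set()).add(killer)
            seen.update((killer, victim))
        self.species = sorted(seen)
        self.edges = sorted(set(edges))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS cycle check on the killer -> victim graph
        children: dict[str, set[str]] = {}
        for killer, victim in self.edges:
            children.setdefault(killer, set()).add(victim)
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {s: WHITE for s in self.species}

        def visit(node: str) -> None:
            colour[node] = GREY
            for nxt in children.get(node, ()):  # pragma: no branch
                if colour[nxt] == GREY:
                    raise ValueError("dominance relation contains a cycle")
                if colour[nxt] == WHITE:
                    visit(nxt)
            colour[node] = BLACK

        for s in self.species:
            if colour[s] == WHITE:
                visit(s)

    def dominates(self, killer: str, victim: str) -> bool:
        return killer in self._dominants.get(victim, ())

    def dominants_of(self, victim: str) -> frozenset[str]:
        return frozenset(self._dominants.get(victim, ()))

    @classmethod
    def linear(cls, ranked_species: list[str],
               exceptions: list[tuple[str, str]] | None = None) -> "DominanceHierarchy":
        """Strict linear order (earlier ranks kill later), minus ``exceptions``."""
        drop = set(exceptions or [])
        edges = [
            (a, b)
            for i, a in enumerate(ranked_species)
            for b in ranked_species[i + 1:]
            if (a, b) not in drop
        ]
        return cls(edges, species=list(ranked_species))


def read_hierarchy(path) -> DominanceHierarchy:
    """Read a (killer, victim) edge list from a two-column delimited file."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("hierarchy file needs two columns: killer, victim")
    edges = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return DominanceHierarchy(edges)


@dataclass
class SiteInfectionTable:
    """Per-site infection tabulation feeding the mortality estimator.

    ``infections`` maps each snail index to the frozenset of species
    observed surviving in it (empty set = uninfected); ``genders`` maps
    snail index to "male"/"female" (or None when undetermined).
    """

    site: str
    infections: list[frozenset[str]]
    genders: list[str | None] = field(default_factory=list)

    @property
    def n_snails(self) -> int:
        return len(self.infections)

    def prevalence(self, species: str) -> float:
        """Observed prevalence of ``species`` among all snails at the site."""
        if self.n_snails == 0:
            return 0.0
        return sum(species in inf for inf in self.infections) / self.n_snails


def tabulate_sites(records: pd.DataFrame) -> list[SiteInfectionTable]:
    """Build per-site infection tables from a snail record table.

    Expects columns ``site``, ``gender`` and ``infection`` where
    ``infection`` is "none" for uninfected snails, a species code for a
    single infection, or "+"-joined codes for a surviving mixed-species
    infection.
    """
    tables = []
    for site, sub in records.groupby("site", sort=True):
        infections = []
        genders = []
        for inf, gender in zip(sub["infection"], sub["gender"]):
            if pd.isna(inf) or inf == "none" or inf == "":
                infections.append(frozenset())
            else:
                infections.append(frozenset(str(inf).split("+")))
            genders.append(None if pd.isna(gender) else str(gender))
        tables.append(SiteInfectionTable(site=str(site), infections=infections,
                                         genders=genders))
    return tables


@dataclass(frozen=True)
class MortalityEstimate:
    """Pooled differential mortality of one species with its per-site breakdown."""

    species: str
    pooled: float
    per_site: dict[str, float]
    weights: dict[str, float]
    n_sites: int

    def __post_init__(self) -> None:
        assert -1.0 - 1e-9 <= self.pooled <= 1.0 + 1e-9


def site_mortality(table: SiteInfectionTable, hierarchy: DominanceHierarchy,
                   focal: str) -> float | None:
    """Differential mortality of ``focal`` at one site.

    Let p be the focal's prevalence among snails carrying none of its
    dominants, D the number of snails carrying at least one dominant,
    and C the observed focal-with-dominant co-infections.  Expected
    co-recruits E = p*D; kills K = E - C; total recruits
    R = (observed focal among dominant-free) + E.  Returns K/R, clipped
    to [-1, 1], or None when the site is unusable (no dominant-free
    snails, or no recruits), in which case the site is skipped upstream.
    """
    dominants = hierarchy.dominants_of(focal)
    free = [inf for inf in table.infections if not (inf & dominants)]
    with_dom = table.n_snails - len(free)
    if not free:
        log.warning("site %s: no dominant-free snails for %s; skipped",
                    table.site, focal)
        return None
    observed_free = sum(focal in inf for inf in free)
    p = observed_free / len(free)
    expected_co = p * with_dom
    observed_co = sum(
        focal in inf and bool(inf & dominants) for inf in table.infections
    )
    kills = expected_co - observed_co
    recruits = observed_free + expected_co
    if recruits == 0:
        log.warning("site %s: no recruits of %s; skipped", table.site, focal)
        return None
    return float(np.clip(kills / recruits, -1.0, 1.0))


def pooled_mortality(per_site: dict[str, float],
                     weights: dict[str, float], species: str) -> MortalityEstimate:
    """Prevalence-weighted mean of per-site mortality values.

    ``weights`` are the focal species' observed prevalences at the same
    sites; sites where the species was absent carry zero weight and drop
    out.
    """
    usable = {s: v for s, v in per_site.items() if weights.get(s, 0.0) > 0}
    if not usable:
        raise ValueError(f"no usable site for {species}: all weights zero")
    w = np.array([weights[s] for s in usable])
    v = np.array([usable[s] for s in usable])
    pooled = float(np.average(v, weights=w))
    return MortalityEstimate(species=species, pooled=pooled, per_site=dict(per_site),
                             weights={s: weights[s] for s in usable},
                             n_sites=len(usable))


def estimate_mortality(tables: list[SiteInfectionTable],
                       hierarchy: DominanceHierarchy,
                       focal: str) -> MortalityEstimate:
    """Per-site estimation + prevalence-weighted pooling for one species."""
    per_site: dict[str, float] = {}
    weights: dict[str, float] = {}
    for t in tables:
        prev = t.prevalence(focal)
        if prev == 0:
            continue  # species absent: site not informative for it
        m = site_mortality(t, hierarchy, focal)
        if m is None:
            continue
        per_site[t.site] = m
        weights[t.site] = prev
    return pooled_mortality(per_site, weights, focal)


def castration_risk(tables: list[SiteInfectionTable], gender: str,
                    weight_by_n: bool = False) -> float:
    """Mean gender-specific trematode prevalence across sites.

    This is the differential "mortality" of uninfected snails: the risk
    of being reproductively killed by castration.  The average across
    sites is unweighted by default; ``weight_by_n`` switches to
    sample-size weights.
    """
    prevalences = []
    ns = []
    for t in tables:
        idx = [i for i, g in enumerate(t.genders) if g == gender]
        if not idx:
            continue
        infected = sum(bool(t.infections[i]) for i in idx)
        prevalences.append(infected / len(idx))
        ns.append(len(idx))
    if not prevalences:
        raise ValueError(f"no snails of gender {gender!r} at any site")
    if weight_by_n:
        return float(np.average(prevalences, weights=ns))
    return float(np.mean(prevalences))


def gender_susceptibility_test(records: pd.DataFrame):
    """Likelihood-ratio test of gender in a logistic infection model.

    Fits infected ~ gender + site + growing-time + initial size by
    binomial GLM and compares against the model without gender.  Returns
    a dict with the LR chi-square (1 df), p-value and n.  Records with
    undetermined gender or infection status are dropped.
    """
    import statsmodels.api as sm

    df = records.dropna(subset=["gender", "infection"]).copy()
    df = df[df["gender"].isin(UNINFECTED_GROUPS)]
    y = (df["infection"] != "none").astype(float).to_numpy()
    if len(set(y)) < 2 or df["gender"].nunique() < 2:
        raise ValueError("need both genders and both infection states")

    site_d = pd.get_dummies(df["site"], drop_first=True, dtype=float)
    time_d = pd.get_dummies(df["growing_days"].astype(str), drop_first=True, dtype=float)
    size = df["initial_size"].to_numpy(dtype=float)
    male = (df["gender"] == "male").astype(float).to_numpy()

    base = np.column_stack([np.ones(len(df)), site_d.to_numpy(),
                            time_d.to_numpy(), size])
    full = np.column_stack([base, male])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_full = sm.GLM(y, full, family=sm.families.Binomial()).fit()
        fit_base = sm.GLM(y, base, family=sm.families.Binomial()).fit()
    chi2 = 2.0 * (fit_full.llf - fit_base.llf)
    from scipy import stats as sps
    return {
        "chi2": float(chi2),
        "df": 1,
        "p_value": float(sps.chi2.sf(max(chi2, 0.0), 1)),
        "coef_male": float(fit_full.params[-1]),
        "n": int(len(df)),
    }
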