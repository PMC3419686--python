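"""Seeded synthetic gut-microbiota cohort generator.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised end to end without external data:

* Dirichlet-multinomial genus compositions drawn around three overlapping
  community archetypes (Prevotella-dominated, Bacteroides-dominated with
  near-mutual exclusion of Prevotella, and a diverse-Firmicutes type with
  the highest entropy), mixed at 47/14/39% prevalence;
* sequencing depth ~ N(10,357, 3,764^2) rounded and floored, matching the
  read-depth regime of deep 16S amplicon surveys;
* a bimodal prevalence profile: a fixed 17-genus core that never drops out,
  plus many sporadic genera gated by per-subject presence Bernoullis;
* clinical traits with age/sex baselines and planted taxon-trait
  correlations (effects enter on standardized log relative abundance, with
  the effect size calibrated against the generated cohort so the marginal
  Spearman correlation hits its target);
* family structure built as trees of relative pairs (spouse, sibling,
  parent-offspring) with exact planted concordance probabilities per pair;
* repeat samples with an archetype switch rate, switches landing on the
  Prevotella archetype (the direction of change observed in repeat
  sampling of real cohorts).

Everything is reproducible bit-exactly from (config, seed): the master seed
spawns one child stream per generation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import CountTable, TaxonLineage, relative_abundance
from .exceptions import GutnetError
from .family import RelativePair

__all__ = [
    "ARCHETYPES",
    "SimConfig",
    "SimCohort",
    "TraitEffect",
    "FamilySpec",
    "RepeatSpec",
    "default_taxon_panel",
    "generate_cohort",
    "plant_families",
    "plant_trait_effects",
    "generate_repeats",
    "planted_correlation_profiles",
    "null_profiles_and_traits",
]

ARCHETYPES = ("Prevotella", "Bacteroides", "Firmicutes")

#: The 17-genus core (phylum, genus) planted at prevalence 1.
_CORE_GENERA = [
    ("Firmicutes", "Clostridium", 0.050),
    ("Firmicutes", "Ruminococcus", 0.045),
    ("Firmicutes", "Faecalibacterium", 0.070),
    ("Firmicutes", "Subdoligranulum", 0.018),
    ("Firmicutes", "Oscillospira", 0.050),
    ("Firmicutes", "Coprococcus", 0.035),
    ("Firmicutes", "Blautia", 0.040),
    ("Firmicutes", "Roseburia", 0.030),
    ("Firmicutes", "Lachnospira", 0.020),
    ("Firmicutes", "Incertae_sedis_121", 0.012),
    ("Firmicutes", "Lachnobacterium", 0.012),
    ("Firmicutes", "Dorea", 0.022),
    ("Firmicutes", "Eubacterium", 0.030),
    ("Firmicutes", "Streptococcus", 0.015),
    ("Bacteroidetes", "Bacteroides", 0.080),
    ("Bacteroidetes", "Prevotella", 0.100),
    ("Tenericutes", "Incertae_sedis_32", 0.010),
]

_NAMED_EXTRA = [
    ("Firmicutes", "Anaerotruncus", 0.006, 0.85),
    ("Firmicutes", "Dialister", 0.006, 0.80),
    ("Firmicutes", "Megasphaera", 0.004, 0.60),
    ("Firmicutes", "Veillonella", 0.004, 0.70),
    ("Firmicutes", "Catenibacterium", 0.003, 0.50),
    ("Bacteroidetes", "Parabacteroides", 0.008, 0.85),
    ("Bacteroidetes", "Alistipes", 0.007, 0.85),
    ("Bacteroidetes", "Tenacibaculum", 0.002, 0.30),
    ("Fusobacteria", "Fusobacterium", 0.003, 0.60),
    ("Proteobacteria", "Sutterella", 0.004, 0.70),
    ("Proteobacteria", "Escherichia", 0.005, 0.75),
    ("Proteobacteria", "J2-29", 0.002, 0.30),
    ("Actinobacteria", "Bifidobacterium", 0.008, 0.85),
    ("Actinobacteria", "Collinsella", 0.005, 0.75),
    ("Verrucomicrobia", "Akkermansia", 0.005, 0.60),
    ("Tenericutes", "Anaeroplasma", 0.002, 0.40),
]

_FILLER_PHYLA = (
    "Firmicutes", "Firmicutes", "Firmicutes", "Bacteroidetes",
    "Proteobacteria", "Actinobacteria", "Tenericutes",
)


@dataclass(frozen=True)
class TraitEffect:
    """A planted taxon-trait association with a target Spearman rho."""

    taxon: str
    trait: str
    rho: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise GutnetError("planted |rho| must be < 1")


@dataclass(frozen=True)
class FamilySpec:
    n_spouse: int = 54
    n_sibling: int = 76
    n_parent_offspring: int = 42
    concordance_spouse: float = 0.389
    concordance_first_degree: float = 0.483


@dataclass(frozen=True)
class RepeatSpec:
    n_repeat: int = 19
    switch_rate: float = 0.21


@dataclass
class SimConfig:
    """Study-conditions configuration of the cohort generator.

    Defaults mirror the cohort regime the pipeline targets: 310 subjects,
    ~203 genera, depth 10,357 +/- 3,764 reads, community-type prevalences
    47/14/39%, 54/76/42 relative pairs with concordances 0.389/0.483, and
    19 repeat samples with a 21% archetype switch rate.
    """

    n_subjects: int = 310
    lineages: list[TaxonLineage] = field(default_factory=lambda: default_taxon_panel())
    archetype_means: pd.DataFrame | None = None  # taxa x archetypes; built if None
    presence_prob: pd.Series | None = None  # per-taxon inclusion prob; built if None
    mixing: tuple[float, float, float] = (0.47, 0.14, 0.39)
    theta: float = 55.0  # Dirichlet concentration (separation control)
    floor_mix: float = 0.05  # deterministic archetype-mean admixture
    depth_mean: float = 10_357.0
    depth_sd: float = 3_764.0
    depth_floor: int = 3_000
    trait_effects: list[TraitEffect] = field(
        default_factory=lambda: [
            TraitEffect("Lachnobacterium", "bmi", -0.25),
            TraitEffect("Lachnobacterium", "tg", -0.25),
            TraitEffect("Anaerotruncus", "bmi", -0.20),
            TraitEffect("Anaerotruncus", "tg", -0.20),
            TraitEffect("Fusobacterium", "crp", 0.30),
            TraitEffect("Faecalibacterium", "hdl", 0.25),
        ]
    )
    families: FamilySpec = field(default_factory=FamilySpec)
    repeats: RepeatSpec = field(default_factory=RepeatSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixing) - 1.0) > 1e-9:
            raise GutnetError("mixing prevalences must sum to 1")
        if self.theta <= 0:
            raise GutnetError("theta must be positive")
        if self.archetype_means is None:
            self.archetype_means = _default_archetype_means(self.lineages)
        if self.presence_prob is None:
            self.presence_prob = _default_presence_prob(self.lineages)
        means = self.archetype_means
        if not np.allclose(means.sum(axis=0), 1.0, atol=1e-9):
            raise GutnetError("archetype mean vectors must be on the simplex")

    @classmethod
    def separated(cls, n_subjects: int = 300, seed: int = 0) -> "SimConfig":
        """A well-separated three-archetype configuration (tight clusters)."""
        return cls(
            n_subjects=n_subjects,
            theta=2_000.0,
            families=FamilySpec(0, 0, 0),
            repeats=RepeatSpec(0, 0.0),
            seed=seed,
        )


def default_taxon_panel(n_genera: int = 203) -> list[TaxonLineage]:
    """Deterministic panel of genus lineages with a 17-genus core."""
    panel = []
    for phylum, genus, _w in _CORE_GENERA:
        panel.append(
            TaxonLineage(genus, {"kingdom": "Bacteria", "phylum": phylum,
                                 "genus": genus})
        )
    for phylum, genus, _w, _p in _NAMED_EXTRA:
        panel.append(
            TaxonLineage(genus, {"kingdom": "Bacteria", "phylum": phylum,
                                 "genus": genus})
        )
    i = 0
    while len(panel) < n_genera:
        phylum = _FILLER_PHYLA[i % len(_FILLER_PHYLA)]
        genus = f"Genus{i + 1:03d}"
        panel.append(
            TaxonLineage(genus, {"kingdom": "Bacteria", "phylum": phylum,
                                 "genus": genus})
        )
        i += 1
    return panel[:n_genera]


def _base_weights(lineages: Sequence[TaxonLineage]) -> pd.Series:
    core = {g: w for _p, g, w in _CORE_GENERA}
    named = {g: w for _p, g, w, _pi in _NAMED_EXTRA}
    rng = np.random.default_rng(12345)  # panel construction, not cohort noise
    w = {}
    for lin in lineages:
        if lin.taxon_id in core:
            w[lin.taxon_id] = core[lin.taxon_id]
        elif lin.taxon_id in named:
            w[lin.taxon_id] = named[lin.taxon_id]
        else:
            w[lin.taxon_id] = float(10 ** rng.uniform(-3.45, -2.2))
    return pd.Series(w)


def _default_archetype_means(lineages: Sequence[TaxonLineage]) -> pd.DataFrame:
    base = _base_weights(lineages)
    phylum = {lin.taxon_id: lin.phylum for lin in lineages}
    cols = {}
    for arch in ARCHETYPES:
        w = base.copy()
        if arch == "Prevotella":
            w["Prevotella"] *= 4.0
            w["Bacteroides"] *= 0.15
        elif arch == "Bacteroides":
            w["Bacteroides"] *= 4.5
            w["Prevotella"] *= 0.10
        else:  # diverse Firmicutes
            w["Prevotella"] *= 0.45
            w["Bacteroides"] *= 0.45
            for t in w.index:
                if phylum.get(t) == "Firmicutes" and t != "Oscillospira":
                    w[t] *= 1.5
            w["Oscillospira"] *= 2.2 * 1.5
        cols[arch] = w / w.sum()
    return pd.DataFrame(cols)


def _default_presence_prob(lineages: Sequence[TaxonLineage]) -> pd.Series:
    core = {g for _p, g, _w in _CORE_GENERA}
    named = {g: pi for _p, g, _w, pi in _NAMED_EXTRA}
    rng = np.random.default_rng(54321)
    out = {}
    for lin in lineages:
        if lin.taxon_id in core:
            out[lin.taxon_id] = 1.0
        elif lin.taxon_id in named:
            out[lin.taxon_id] = named[lin.taxon_id]
        else:
            # sporadic genera: bimodal prevalence's low mode
            out[lin.taxon_id] = float(rng.uniform(0.03, 0.60))
    return pd.Series(out)


@dataclass
class SimCohort:
    """A generated cohort with its ground truth."""

    counts: CountTable
    traits: pd.DataFrame
    pairs: list[RelativePair]
    repeat_counts: CountTable | None
    repeat_map: dict[str, str]
    truth: dict

    @property
    def archetypes(self) -> pd.Series:
        return self.truth["archetype"]


# --------------------------------------------------------------------------
# family structure


def plant_families(
    archetypes: pd.Series,
    spec: FamilySpec,
    rng: np.random.Generator,
    mixing: Mapping[str, float] | None = None,
) -> tuple[list[RelativePair], pd.Series]:
    """Build relative pairs as family trees and plant pair concordances.

    Families are trees whose edges are the relative pairs; the "new" member
    of each edge copies the anchor's archetype with the planted concordance
    probability and otherwise draws from the mixing distribution restricted
    to the other archetypes.  Every pair's concordance probability therefore
    equals exactly c_spouse / c_first_degree.
    """
    subjects = list(archetypes.index)
    n_members = 2 * spec.n_spouse + spec.n_parent_offspring + spec.n_sibling
    extra_roots = 0
    if spec.n_spouse == 0 and (spec.n_sibling > 0 or spec.n_parent_offspring > 0):
        extra_roots = 1
        n_members += 1
    if n_members > len(subjects):
        raise GutnetError(
            f"family spec needs {n_members} subjects, cohort has {len(subjects)}"
        )
    arche = archetypes.copy()
    names = list(arche.unique()) if mixing is None else list(mixing)
    if mixing is None:
        probs = {a: (arche == a).mean() for a in names}
    else:
        probs = dict(mixing)

    def discordant_draw(current: str) -> str:
        others = [a for a in names if a != current]
        weights = np.array([probs[a] for a in others], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones(len(others))
        weights = weights / weights.sum()
        return others[rng.choice(len(others), p=weights)]

    def plant(child: str, anchor: str, c: float) -> None:
        if rng.random() < c:
            arche[child] = arche[anchor]
        else:
            arche[child] = discordant_draw(arche[anchor])

    pool = iter(subjects)
    pairs: list[RelativePair] = []
    fam_of: dict[str, str] = {}
    # spouse couples root the families
    couples: list[tuple[str, str]] = []
    for f in range(spec.n_spouse):
        a, b = next(pool), next(pool)
        fid = f"F{f + 1:03d}"
        fam_of[a] = fam_of[b] = fid
        plant(b, a, spec.concordance_spouse)
        pairs.append(RelativePair(a, b, "spouse", fid))
        couples.append((a, b))
    # a rootless family when there are no couples but child pairs are wanted
    roots: list[tuple[str, str | None]] = [(a, fid) for (a, _b), fid in
                                           zip(couples, [p.family_id for p in pairs])]
    if extra_roots:
        a = next(pool)
        fid = f"F{spec.n_spouse + 1:03d}"
        fam_of[a] = fid
        roots.append((a, fid))
    if spec.n_parent_offspring > 0 and not roots:
        raise GutnetError("parent-offspring pairs need at least one parent")
    # first children: parent-offspring edges, cycled over families
    children_of: dict[str, list[str]] = {fid: [] for _a, fid in roots}
    for i in range(spec.n_parent_offspring):
        parent, fid = roots[i % len(roots)]
        child = next(pool)
        fam_of[child] = fid
        plant(child, parent, spec.concordance_first_degree)
        pairs.append(RelativePair(parent, child, "parent-offspring", fid))
        children_of[fid].append(child)
    # additional children: sibling edges chained to the previous child
    sib_fams = [fid for _a, fid in roots if children_of[fid]]
    if spec.n_sibling > 0 and not sib_fams:
        # no parent-offspring edges were requested: seed sibling-only chains
        parent, fid = roots[0]
        children_of[fid].append(parent)
        sib_fams = [fid]
    for i in range(spec.n_sibling):
        fid = sib_fams[i % len(sib_fams)]
        prev = children_of[fid][-1]
        child = next(pool)
        fam_of[child] = fid
        plant(child, prev, spec.concordance_first_degree)
        pairs.append(RelativePair(prev, child, "sibling", fid))
        children_of[fid].append(child)
    return pairs, arche


# --------------------------------------------------------------------------
# composition and counts


def _draw_compositions(
    arche: pd.Series,
    means: pd.DataFrame,
    presence: pd.Series,
    theta: float,
    floor_mix: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    taxa = list(means.index)
    presence = presence.reindex(taxa).fillna(1.0).to_numpy()
    out = np.zeros((len(taxa), len(arche)))
    for j, subject in enumerate(arche.index):
        m = means[arche[subject]].to_numpy(dtype=float).copy()
        include = rng.random(len(taxa)) < presence
        m = m * include
        m = m / m.sum()
        alpha = theta * m[include]
        p = np.zeros(len(taxa))
        p[include] = rng.dirichlet(alpha)
        out[:, j] = (1 - floor_mix) * p + floor_mix * m
    return pd.DataFrame(out, index=taxa, columns=list(arche.index))


def _draw_counts(
    comps: pd.DataFrame,
    depth_mean: float,
    depth_sd: float,
    depth_floor: int,
    lineages: Mapping[str, TaxonLineage],
    rng: np.random.Generator,
) -> CountTable:
    depths = np.maximum(
        np.round(rng.normal(depth_mean, depth_sd, comps.shape[1])), depth_floor
    ).astype(int)
    counts = np.zeros(comps.shape, dtype=np.int64)
    vals = comps.to_numpy()
    for j in range(comps.shape[1]):
        counts[:, j] = rng.multinomial(depths[j], vals[:, j] / vals[:, j].sum())
    frame = pd.DataFrame(counts, index=comps.index, columns=comps.columns)
    frame.index.name = "taxon_id"
    return CountTable(frame, dict(lineages))


# --------------------------------------------------------------------------
# traits


_TRAIT_BASELINES = {
    # trait: (mean_m, sd_m, mean_f, sd_f, age_slope)
    "bmi": (27.2, 4.0, 30.3, 5.9, 0.05),
    "waist": (95.6, 11.2, 90.3, 12.3, 0.10),
    "sbp": (117.3, 12.2, 118.2, 15.9, 0.30),
    "dbp": (71.0, 8.0, 70.8, 9.1, 0.10),
    "tc": (208.7, 42.5, 214.4, 50.2, 0.50),
    "hdl": (54.8, 13.1, 62.0, 14.1, 0.00),
    "glucose": (87.4, 8.0, 87.3, 11.2, 0.10),
}
_TG_PARAMS = {"M": (76.4, 45.5), "F": (88.5, 54.0)}  # lognormal moments


def _lognormal_from_moments(mean: float, sd: float, size, rng) -> np.ndarray:
    var = sd**2
    sigma2 = np.log(1 + var / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def plant_trait_effects(
    rel_abundance: pd.DataFrame,
    effects: Sequence[TraitEffect],
    traits: pd.DataFrame,
    rng: np.random.Generator,
    max_iter: int = 4,
) -> pd.DataFrame:
    """Add planted taxon-trait correlations to a baseline trait table.

    The effect enters on the standardized log relative abundance (a
    pseudocount keeps absent taxa finite), and the coefficient is calibrated
    iteratively against the generated cohort so the realized marginal
    Spearman correlation is within a few hundredths of the target.
    """
    from scipy import stats as _stats

    traits = traits.copy()
    missing = [e.taxon for e in effects if e.taxon not in rel_abundance.index]
    if missing:
        raise GutnetError(f"planted effect on absent taxa: {missing}")
    by_trait: dict[str, list[TraitEffect]] = {}
    for e in effects:
        by_trait.setdefault(e.trait, []).append(e)
    samples = list(rel_abundance.columns)
    for trait_name, effs in by_trait.items():
        if trait_name not in traits.columns:
            raise GutnetError(f"unknown trait {trait_name!r}")
        base = traits.loc[samples, trait_name].to_numpy(dtype=float)
        sd_base = base.std()
        z = {}
        for e in effs:
            logv = np.log(rel_abundance.loc[e.taxon, samples].to_numpy() + 1e-6)
            z[e.taxon] = (logv - logv.mean()) / logv.std()
        # initial gamma from the Pearson<->Spearman relation for Gaussians
        gam = {}
        for e in effs:
            r = 2 * np.sin(np.pi * e.rho / 6)
            gam[e.taxon, e.trait] = sd_base * r / np.sqrt(1 - r**2)
        for _ in range(max_iter):
            vals = base + sum(
                gam[e.taxon, e.trait] * z[e.taxon] for e in effs
            )
            done = True
            for e in effs:
                obs = _stats.spearmanr(
                    vals, rel_abundance.loc[e.taxon, samples]
                ).statistic
                if abs(obs - e.rho) > 0.02 and abs(obs) > 1e-6:
                    gam[e.taxon, e.trait] *= float(
                        np.clip(e.rho / obs, 0.5, 2.0)
                    )
                    done = False
            if done:
                break
        traits.loc[samples, trait_name] = base + sum(
            gam[e.taxon, e.trait] * z[e.taxon] for e in effs
        )
    return traits


def _baseline_traits(
    subjects: Sequence[str],
    arche: pd.Series,
    fam_of: Mapping[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(subjects)
    sex = np.where(rng.random(n) < 198 / 310, "F", "M")
    age = np.clip(
        np.where(
            sex == "F", rng.normal(49.5, 13.4, n), rng.normal(46.0, 12.7, n)
        ),
        20, 80,
    ).round(1)
    frame = pd.DataFrame(index=pd.Index(subjects, name="sample_id"))
    frame["age"] = age
    frame["sex"] = sex
    for trait, (mm, sm, mf, sf, slope) in _TRAIT_BASELINES.items():
        mean = np.where(sex == "F", mf, mm) + slope * (age - 48.0)
        sd = np.where(sex == "F", sf, sm)
        frame[trait] = (mean + sd * rng.standard_normal(n)).round(1)
    frame["hdl"] = frame["hdl"].clip(lower=20)
    frame["glucose"] = frame["glucose"].clip(lower=60)
    tg = np.where(
        sex == "F",
        _lognormal_from_moments(*_TG_PARAMS["F"], n, rng),
        _lognormal_from_moments(*_TG_PARAMS["M"], n, rng),
    )
    frame["tg"] = np.round(tg, 1)
    frame["crp"] = np.round(rng.lognormal(np.log(1.5), 1.0, n), 2)
    # medication flags (sparse, independent)
    frame["med_tg_lowering"] = rng.random(n) < 0.01
    frame["med_hdl_raising"] = rng.random(n) < 0.005
    frame["med_antihypertensive"] = rng.random(n) < 0.05
    frame["med_antidiabetic"] = rng.random(n) < 0.03
    # occupation: archetype-linked for men, near-uniform for women
    occ = []
    men_probs = {
        "Prevotella": (0.45, 0.33, 0.18, 0.04),
        "Bacteroides": (0.00, 0.50, 0.30, 0.20),
        "Firmicutes": (0.40, 0.43, 0.11, 0.06),
    }
    men_classes = ("farmer", "tradesman", "teacher/shopkeeper", "unknown/retired")
    women_classes = ("farmer's wife", "teacher/shopkeeper", "unknown/retired")
    for subject, s in zip(subjects, sex):
        if s == "M":
            p = np.array(men_probs[arche[subject]])
            occ.append(men_classes[rng.choice(4, p=p / p.sum())])
        else:
            occ.append(women_classes[rng.choice(3, p=(0.11, 0.855, 0.035))])
    frame["occupation"] = occ
    frame["menopause"] = (sex == "F") & (age + rng.normal(0, 3, n) >= 51)
    frame["family_id"] = [fam_of.get(s, "") for s in subjects]
    months = rng.integers(0, 30, n)
    start = pd.Timestamp("2008-04-15")
    frame["collection_date"] = [
        (start + pd.DateOffset(months=int(m))).strftime("%Y-%m-%d") for m in months
    ]
    return frame


# --------------------------------------------------------------------------
# repeats


def generate_repeats(
    arche: pd.Series,
    spec: RepeatSpec,
    config: "SimConfig",
    rng: np.random.Generator,
) -> tuple[dict[str, str], CountTable | None, pd.Series, dict[str, bool]]:
    """Second-visit samples for a subset of subjects.

    With probability 1 - switch_rate the subject's archetype persists (a
    fresh Dirichlet-multinomial draw from the same archetype); otherwise the
    archetype changes — to the Prevotella type when the origin differs, else
    to a non-Prevotella archetype — so the change probability is exactly the
    switch rate.
    """
    if spec.n_repeat == 0:
        return {}, None, pd.Series(dtype=object), {}
    if spec.n_repeat > len(arche):
        raise GutnetError("n_repeat exceeds number of subjects")
    chosen = list(
        np.array(arche.index)[
            np.sort(rng.choice(len(arche), spec.n_repeat, replace=False))
        ]
    )
    second_arche = {}
    switched = {}
    mix = {a: p for a, p in zip(ARCHETYPES, config.mixing)}
    for subject in chosen:
        if rng.random() < spec.switch_rate:
            cur = arche[subject]
            if cur != "Prevotella":
                second_arche[subject] = "Prevotella"
            else:
                others = [a for a in ARCHETYPES if a != "Prevotella"]
                w = np.array([mix[a] for a in others])
                second_arche[subject] = others[rng.choice(len(others), p=w / w.sum())]
            switched[subject] = True
        else:
            second_arche[subject] = arche[subject]
            switched[subject] = False
    repeat_ids = {f"{s}_r2": s for s in chosen}
    arche2 = pd.Series(
        {f"{s}_r2": second_arche[s] for s in chosen}, name="archetype"
    )
    comps = _draw_compositions(
        arche2, config.archetype_means, config.presence_prob,
        config.theta, config.floor_mix, rng,
    )
    counts = _draw_counts(
        comps, config.depth_mean, config.depth_sd, config.depth_floor,
        {lin.taxon_id: lin for lin in config.lineages}, rng,
    )
    return repeat_ids, counts, arche2, switched


# --------------------------------------------------------------------------
# top level


def generate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full cohort (counts, traits, pairs, repeats, ground truth)."""
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_arch, rng_fam, rng_comp, rng_trait, rng_rep, rng_eff = streams

    subjects = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
    mix = np.array(config.mixing)
    arche = pd.Series(
        [ARCHETYPES[k] for k in rng_arch.choice(3, config.n_subjects, p=mix)],
        index=subjects,
        name="archetype",
    )
    pairs, arche = plant_families(
        arche, config.families, rng_fam,
        mixing={a: p for a, p in zip(ARCHETYPES, config.mixing)},
    )
    fam_of = {}
    for pair in pairs:
        fam_of[pair.subject_a] = pair.family_id
        fam_of[pair.subject_b] = pair.family_id

    comps = _draw_compositions(
        arche, config.archetype_means, config.presence_prob,
        config.theta, config.floor_mix, rng_comp,
    )
    lineage_map = {lin.taxon_id: lin for lin in config.lineages}
    counts = _draw_counts(
        comps, config.depth_mean, config.depth_sd, config.depth_floor,
        lineage_map, rng_comp,
    )

    traits = _baseline_traits(subjects, arche, fam_of, rng_trait)
    if config.trait_effects:
        rel = relative_abundance(counts)
        traits = plant_trait_effects(rel, config.trait_effects, traits, rng_eff)
    from .phenotype import friedewald_ldl

    with np.errstate(invalid="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            # occasional TG >= 400 draws are a feature of the cohort, not a bug
            _warnings.simplefilter("ignore", UserWarning)
            traits["ldl"] = np.round(
                friedewald_ldl(traits["tc"], traits["hdl"], traits["tg"]), 1
            )

    repeat_map, repeat_counts, arche2, switched = generate_repeats(
        arche, config.repeats, config, rng_rep
    )
    truth = {
        "archetype": arche,
        "repeat_archetype": arche2,
        "switched": switched,
        "effects": list(config.trait_effects),
        "config": config,
    }
    return SimCohort(
        counts=counts,
        traits=traits,
        pairs=pairs,
        repeat_counts=repeat_counts,
        repeat_map=repeat_map,
        truth=truth,
    )


# --------------------------------------------------------------------------
# focused fixtures for network calibration studies


def planted_correlation_profiles(
    n_samples: int = 310,
    n_taxa: int = 40,
    n_pairs: int = 10,
    rho: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str, int]]]:
    """Relative-abundance table with planted pairwise Spearman correlations.

    Taxa are independent lognormals except for ``n_pairs`` disjoint pairs
    whose latent Gaussians are coupled so the Spearman correlation is
    approximately ``rho`` (alternating sign).  Returns the taxa-by-samples
    relative abundance frame and the planted (taxon_a, taxon_b, sign) list.
    """
    if 2 * n_pairs > n_taxa:
        raise GutnetError("too many planted pairs for the taxon count")
    rng = np.random.default_rng(seed)
    r = 2 * np.sin(np.pi * rho / 6)  # Pearson on latent Gaussians
    z = rng.standard_normal((n_taxa, n_samples))
    planted = []
    for k in range(n_pairs):
        i, j = 2 * k, 2 * k + 1
        sign = 1 if k % 2 == 0 else -1
        z[j] = sign * (r * z[i] + np.sqrt(1 - r**2) * rng.standard_normal(n_samples))
        planted.append((f"T{i + 1:02d}", f"T{j + 1:02d}", sign))
    x = np.exp(np.log(0.02) + 0.8 * z)  # comparable-scale lognormals
    x = x / x.sum(axis=0)
    frame = pd.DataFrame(
        x,
        index=[f"T{i + 1:02d}" for i in range(n_taxa)],
        columns=[f"S{j + 1:03d}" for j in range(n_samples)],
    )
    return frame, planted


def null_profiles_and_traits(
    n_samples: int = 310,
    n_taxa: int = 40,
    n_traits: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent taxa profiles and traits: every taxon-trait pair is null."""
    rng = np.random.default_rng(seed)
    x = np.exp(rng.standard_normal((n_taxa, n_samples)))
    x = x / x.sum(axis=0)
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    taxa = pd.DataFrame(
        x, index=[f"T{i + 1:02d}" for i in range(n_taxa)], columns=samples
    )
    traits = pd.DataFrame(
        rng.standard_normal((n_samples, n_traits)),
        index=samples,
        columns=[f"trait{k + 1:02d}" for k in range(n_traits)],
    )
    return taxa, traits
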