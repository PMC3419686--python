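"""End-to-end pipeline runner: simulate -> profile -> enterotype -> networks
-> family -> stats, writing every stage's outputs as plain-text tables.

Used by the command-line interface and by reproducibility checks (the whole
run is a deterministic function of the configuration and master seed).
"""

from __future__ import annotations

import json
from pathlib import Path



from . import abundance, enterotype, family as family_mod, network, phenotype
from .models import (
    CooccurrenceModel,
    EnterotypeModel,
    FamilyConcordanceModel,
    GroupAssociationModel,
    TraitAssociationModel,
)
from .simulate import SimCohort, SimConfig, generate_cohort

TRAIT_NETWORK_TRAITS = ("bmi", "tg", "hdl", "tc", "glucose", "crp")
ASSOC_TRAITS = ("age", "bmi", "waist", "hdl", "tg", "glucose", "sbp", "dbp")


def run_pipeline(
    config: SimConfig | None = None,
    outdir: str | Path = ".",
    k: int = 3,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Run every stage on a (generated) cohort and write outputs to ``outdir``.

    Returns a dict of the headline numbers; all tables land as TSV/JSON
    files.  ``seed`` overrides the config's master seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SimConfig()
    if seed is not None:
        config.seed = seed
    cohort = generate_cohort(config)
    return analyze_cohort(cohort, outdir, k=k, n_perm=n_perm, seed=config.seed)


def analyze_cohort(
    cohort: SimCohort,
    outdir: str | Path,
    k: int = 3,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cohort.counts
    table.to_tsv(outdir / "counts.tsv", down_to="genus")
    cohort.traits.to_csv(outdir / "metadata.tsv", sep="\t")
    family_mod.write_pairs(cohort.pairs, outdir / "pairs.tsv")

    # profile stage
    summary = abundance.sample_summary(table)
    summary.to_csv(outdir / "sample_summary.tsv", sep="\t")
    prev = abundance.prevalence_core(table)
    prev.to_tsv(outdir / "prevalence.tsv")
    _rank, top10 = abundance.rank_abundance(table, min(10, table.n_taxa))

    # enterotype stage
    ent = EnterotypeModel(table).fit(k=k, also_k=(2,))
    ent.model.distance.to_tsv(outdir / "distance_sqrt_jsd.tsv")
    ent.assignments_frame().to_csv(outdir / "assignments.tsv", sep="\t")
    ent.ordination.coordinates.to_csv(outdir / "pcoa.tsv", sep="\t")

    # diversity contrast: diverse-Firmicutes type vs the rest
    sil = summary.join(ent.assignment.labels.rename("group"))
    firm = sil[sil["dominant_category"] == "Firmicutes-other"]["shannon"]
    rest = sil[sil["dominant_category"] != "Firmicutes-other"]["shannon"]
    if len(firm) > 0 and len(rest) > 0:
        _w, div_p = phenotype.wilcoxon_rank_sum(firm, rest)
    else:
        div_p = float("nan")

    # co-occurrence network stage
    cooc = CooccurrenceModel(table, alpha=0.001).fit(seed=seed)
    cooc.network.edges_frame(cooc.partition).to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False
    )
    cooc.network.nodes_frame(cooc.partition).to_csv(
        outdir / "network_nodes.tsv", sep="\t", index=False
    )
    cooc.network.write_graphml(outdir / "network.graphml")

    # taxon-trait network stage
    tra = TraitAssociationModel(
        table, cohort.traits, TRAIT_NETWORK_TRAITS, alpha=0.005
    ).fit(seed=seed)
    tra.network.edges_frame(tra.partition).to_csv(
        outdir / "trait_network_edges.tsv", sep="\t", index=False
    )

    # family stage
    fam_dict = {}
    if cohort.pairs:
        fam = FamilyConcordanceModel(
            cohort.pairs, ent.assignment.labels
        ).fit(n_perm=n_perm, seed=seed)
        fam_dict = fam.to_dict()
        (outdir / "family.json").write_text(json.dumps(fam_dict, indent=2) + "\n")

    # stats stage
    traits = cohort.traits.copy()
    traits["sex_male"] = (traits["sex"] == "M").astype(float)
    assoc = GroupAssociationModel(traits, ent.assignment.labels).fit(ASSOC_TRAITS)
    assoc.table().to_csv(outdir / "group_association.tsv", sep="\t", index=False)
    flags = phenotype.mets_flags(traits)
    flags.to_csv(outdir / "mets_flags.tsv", sep="\t")
    cross = phenotype.occupation_crosstab(ent.assignment.labels, traits)
    for sex_label, frame in cross.items():
        frame.to_csv(outdir / f"occupation_{sex_label}.tsv", sep="\t")

    # B:F ratio vs age/sex-adjusted BMI
    bf = abundance.bf_ratio(table)
    ok = bf.notna() & traits["bmi"].notna()
    bf_r, bf_p = phenotype.adjusted_correlation(
        bf[ok], traits.loc[ok.index[ok], "bmi"],
        traits.loc[ok.index[ok], ["age", "sex_male"]],
    )

    # repeat-sample stability on dominant-taxon categories
    stab = None
    if cohort.repeat_counts is not None and cohort.repeat_map:
        dom1 = abundance.dominant_categories(table)["dominant_category"]
        dom2 = abundance.dominant_categories(cohort.repeat_counts)[
            "dominant_category"
        ]
        stab_res = enterotype.stability(dom1, dom2, cohort.repeat_map)
        stab = stab_res.fraction_unchanged
        stab_res.transitions.to_csv(outdir / "stability_transitions.tsv", sep="\t")

    headline = {
        "n_subjects": table.n_samples,
        "n_taxa": table.n_taxa,
        "mean_depth": float(table.depths().mean()),
        "sd_depth": float(table.depths().std()),
        "top10_share": top10,
        "n_core": len(prev.core_taxa),
        "silhouettes": ent.silhouettes,
        "group_sizes": {int(g): int(s) for g, s in ent.group_sizes().items()},
        "dominant_prevalence": {
            cat: float((ent.dominant["dominant_category"] == cat).mean())
            for cat in sorted(ent.dominant["dominant_category"].unique())
        },
        "agreement": ent.agreement(),
        "diversity_wilcoxon_p": div_p,
        "n_network_edges": cooc.network.n_edges,
        "network_modularity": cooc.partition.q,
        "n_trait_edges": len(tra.taxon_trait_edges()),
        "bf_bmi_adjusted_r": bf_r,
        "bf_bmi_adjusted_p": bf_p,
        "stability_unchanged": stab,
        "family": fam_dict,
    }
    (outdir / "headline.json").write_text(
        json.dumps(headline, indent=2, default=float) + "\n"
    )
    return headline
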