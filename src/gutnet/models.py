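"""Model/Results objects tying the pipeline stages together.

Each model is constructed from data, ``fit()`` runs the analysis, and the
returned results object carries the estimates, their uncertainties and a
``summary()`` table.  The heavy lifting lives in the functional modules
(:mod:`gutnet.abundance`, :mod:`gutnet.enterotype`, :mod:`gutnet.network`,
:mod:`gutnet.family`, :mod:`gutnet.phenotype`); these classes are the
analyst-facing surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import abundance, enterotype, family, network, phenotype
from .abundance import CountTable

__all__ = [
    "EnterotypeModel",
    "EnterotypeResults",
    "CooccurrenceModel",
    "CooccurrenceResults",
    "TraitAssociationModel",
    "TraitAssociationResults",
    "FamilyConcordanceModel",
    "FamilyConcordanceResults",
    "GroupAssociationModel",
    "GroupAssociationResults",
]


class EnterotypeModel:
    """Community typing of a genus-level count table.

    Pipeline: relative abundance -> pairwise sqrt-Jensen-Shannon distances ->
    complete-linkage dendrogram -> k top-level clades, with mean silhouette
    widths for the candidate k values, PCoA coordinates, and the
    dominant-taxon typing for comparison.
    """

    def __init__(self, table: CountTable):
        self.table = table
        rel = abundance.relative_abundance(table)
        self.distance = enterotype.jsd_matrix(rel)
        self.dendrogram = enterotype.hclust_complete(self.distance)

    def fit(self, k: int = 3, also_k: Sequence[int] = (2,), ndim: int = 2) -> "EnterotypeResults":
        assignment = enterotype.cut_top_clades(self.dendrogram, k)
        silhouettes = {k: enterotype.mean_silhouette(self.distance, assignment)}
        for other in also_k:
            if other == k or other < 2:
                continue
            alt = enterotype.cut_top_clades(self.dendrogram, other)
            silhouettes[other] = enterotype.mean_silhouette(self.distance, alt)
        ordination = enterotype.pcoa(self.distance, ndim=ndim)
        dominant = abundance.dominant_categories(self.table)
        return EnterotypeResults(
            model=self,
            assignment=assignment,
            silhouettes=silhouettes,
            ordination=ordination,
            dominant=dominant,
        )


@dataclass
class EnterotypeResults:
    model: EnterotypeModel
    assignment: enterotype.ClusterAssignment
    silhouettes: dict[int, float]
    ordination: enterotype.OrdinationResult
    dominant: pd.DataFrame

    def group_sizes(self) -> pd.Series:
        return self.assignment.labels.value_counts().sort_index()

    def agreement(self) -> float:
        """Fraction of samples whose clade-cut group matches the dominant-taxon
        category under the best label matching."""
        labels = self.assignment.labels
        cats = self.dominant["dominant_category"].reindex(labels.index)
        best = 0
        from itertools import permutations

        cat_names = sorted(cats.unique())
        for perm in permutations(range(1, self.assignment.k + 1), len(cat_names)):
            mapping = dict(zip(cat_names, perm))
            agree = (labels == cats.map(mapping)).mean()
            best = max(best, agree)
        return float(best)

    def assignments_frame(self) -> pd.DataFrame:
        out = self.assignment.to_frame().join(self.dominant)
        return out

    def summary(self) -> str:
        lines = ["Community typing (sqrt-JSD, complete linkage)"]
        lines.append(f"  samples: {self.model.distance.n}")
        for k in sorted(self.silhouettes):
            mark = " *" if k == self.assignment.k else ""
            lines.append(f"  mean silhouette (k={k}): {self.silhouettes[k]:.3f}{mark}")
        sizes = self.group_sizes()
        n = sizes.sum()
        for g, s in sizes.items():
            lines.append(f"  group {g}: {s} samples ({100 * s / n:.1f}%)")
        lines.append(f"  clade-cut vs dominant-taxon agreement: {self.agreement():.1%}")
        return "\n".join(lines)

    def plot_ordination(self, ax=None):  # pragma: no cover - plotting
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        coords = self.ordination.coordinates
        for g, ids in self.assignment.groups().items():
            sub = coords.loc[ids]
            ax.scatter(sub["PC1"], sub["PC2"], label=f"group {g}", s=12)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        return ax


class CooccurrenceModel:
    """Genus co-occurrence network: Spearman edges at p < alpha, Louvain modules."""

    def __init__(
        self,
        table: CountTable,
        alpha: float = 0.001,
        min_prevalence: float = 0.10,
        rule: str = "strict-less",
    ):
        self.table = table
        self.alpha = alpha
        self.rule = rule
        self.profiles = network.filter_taxa(table, min_prevalence=min_prevalence)

    def fit(self, seed: int = 0) -> "CooccurrenceResults":
        rho, p = network.correlation_matrix(self.profiles)
        mean_ab = self.profiles.mean(axis=1)
        node_attrs = {
            t: {"kind": "taxon", "mean_abundance": float(mean_ab[t])}
            for t in self.profiles.index
        }
        net = network.build_network(rho, p, self.alpha, self.rule, node_attrs)
        partition = network.louvain(net, seed=seed)
        return CooccurrenceResults(self, net, partition)


@dataclass
class CooccurrenceResults:
    model: CooccurrenceModel
    network: network.CorrelationNetwork
    partition: network.ModulePartition

    def subnetwork(self, anchor: str) -> network.CorrelationNetwork:
        return network.dominant_subnetwork(self.network, anchor)

    def summary(self) -> str:
        n_mod = len(set(self.partition.modules.values()))
        pos = sum(
            1 for *_e, d in self.network.graph.edges(data=True)
            if d["sign"] == "positive"
        )
        lines = [
            f"Co-occurrence network (Spearman, {self.model.rule} alpha={self.model.alpha})",
            f"  nodes: {len(self.network.nodes)}  edges: {self.network.n_edges} "
            f"({pos} positive, {self.network.n_edges - pos} inverse)",
            f"  Louvain modules: {n_mod}  (Q = {self.partition.q:.3f})",
        ]
        return "\n".join(lines)


class TraitAssociationModel:
    """Integrated taxon-trait Spearman network at p <= alpha."""

    def __init__(
        self,
        table: CountTable,
        traits: pd.DataFrame,
        trait_columns: Sequence[str],
        alpha: float = 0.005,
        min_prevalence: float = 0.10,
        include_taxon_taxon: bool = False,
    ):
        self.table = table
        self.traits = traits[list(trait_columns)]
        self.alpha = alpha
        self.include_taxon_taxon = include_taxon_taxon
        self.profiles = network.filter_taxa(table, min_prevalence=min_prevalence)

    def fit(self, seed: int = 0) -> "TraitAssociationResults":
        net = network.trait_network(
            self.profiles,
            self.traits,
            alpha=self.alpha,
            include_taxon_taxon=self.include_taxon_taxon,
        )
        partition = network.louvain(net, seed=seed)
        return TraitAssociationResults(self, net, partition)


@dataclass
class TraitAssociationResults:
    model: TraitAssociationModel
    network: network.CorrelationNetwork
    partition: network.ModulePartition

    def taxon_trait_edges(self) -> pd.DataFrame:
        frame = self.network.edges_frame(self.partition)
        kinds = dict(self.network.graph.nodes(data="kind"))
        cross = frame[
            [kinds[a] != kinds[b] for a, b in zip(frame.node_a, frame.node_b)]
        ]
        return cross.reset_index(drop=True)

    def summary(self) -> str:
        cross = self.taxon_trait_edges()
        n_mod = len(set(self.partition.modules.values()))
        return "\n".join(
            [
                f"Taxon-trait network (Spearman, p <= {self.model.alpha})",
                f"  nodes: {len(self.network.nodes)}  edges: {self.network.n_edges} "
                f"({len(cross)} taxon-trait)",
                f"  Louvain modules: {n_mod}  (Q = {self.partition.q:.3f})",
            ]
        )


class FamilyConcordanceModel:
    """Pair concordance by relationship class and the heritability contrast."""

    def __init__(
        self,
        pairs: Sequence[family.RelativePair],
        labels: Mapping[str, object] | pd.Series,
    ):
        self.pairs = list(pairs)
        self.labels = labels

    def fit(self, n_perm: int = 10_000, seed: int = 0) -> "FamilyConcordanceResults":
        conc = family.concordance(self.pairs, self.labels)
        h2 = family.heritability(conc)
        p = family.contrast_test(self.pairs, self.labels, n_perm=n_perm, seed=seed)
        return FamilyConcordanceResults(self, conc, h2, p, n_perm, seed)


@dataclass
class FamilyConcordanceResults:
    model: FamilyConcordanceModel
    concordance: family.ConcordanceResult
    heritability: family.HeritabilityEstimate
    contrast_p: float
    n_perm: int
    seed: int

    def summary(self) -> str:
        t = self.concordance.table
        lines = ["Family concordance"]
        for rel in family.RELATIONSHIPS:
            lines.append(
                f"  {rel}: {int(t.loc[rel, 'n_concordant'])}/{int(t.loc[rel, 'n_pairs'])}"
                f" = {100 * t.loc[rel, 'rate']:.1f}%"
            )
        lines.append(
            f"  pooled first-degree: {100 * self.concordance.pooled_first_degree_rate:.1f}%"
        )
        flag = "  [outside [0,1]]" if self.heritability.out_of_range else ""
        lines.append(f"  h2 = 2*(first-degree - spouse) = {self.heritability.h2:.3f}{flag}")
        lines.append(
            f"  spouse vs first-degree permutation p = {self.contrast_p:.3f} "
            f"({self.n_perm} permutations)"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        t = self.concordance.table
        return {
            "rates": {
                rel: {
                    "n_pairs": int(t.loc[rel, "n_pairs"]),
                    "n_concordant": int(t.loc[rel, "n_concordant"]),
                    "rate": float(t.loc[rel, "rate"]),
                }
                for rel in family.RELATIONSHIPS
            },
            "pooled_first_degree_rate": self.concordance.pooled_first_degree_rate,
            "h2": self.heritability.h2,
            "h2_out_of_range": self.heritability.out_of_range,
            "permutation_p": self.contrast_p,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


class GroupAssociationModel:
    """Community-type association with each clinical trait (2-df tests)."""

    def __init__(
        self,
        traits: pd.DataFrame,
        groups: pd.Series,
        covariate_columns: Sequence[str] = ("age", "sex_male"),
    ):
        self.traits = traits
        self.groups = groups
        self.covariate_columns = list(covariate_columns)

    def fit(
        self,
        trait_columns: Sequence[str],
        binary_columns: Sequence[str] = (),
    ) -> "GroupAssociationResults":
        cov = self.traits[self.covariate_columns].astype(float)
        results = {}
        for col in trait_columns:
            results[col] = phenotype.group_association(
                self.traits[col],
                self.groups,
                covariates=cov,
                binary=col in set(binary_columns),
            )
        return GroupAssociationResults(self, results)


@dataclass
class GroupAssociationResults:
    model: GroupAssociationModel
    results: dict[str, phenotype.GroupAssociationResult]

    def table(self) -> pd.DataFrame:
        rows = []
        for trait, res in self.results.items():
            row = {"trait": trait, "kind": res.kind, "p_value": res.p_value, "n": res.n}
            for g in res.adjusted_means.index:
                row[f"group{g}_mean"] = res.adjusted_means.loc[g, "mean"]
                row[f"group{g}_se"] = res.adjusted_means.loc[g, "se"]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Community-type trait associations (2-df, age/sex adjusted)"]
        for trait, res in self.results.items():
            lines.append(f"  {trait}: p = {res.p_value:.3f} ({res.kind}, n={res.n})")
            if res.contrasts is not None:
                for _i, row in res.contrasts.iterrows():
                    lines.append(f"    {row['contrast']}: p = {row['p']:.3g}")
        return "\n".join(lines)
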