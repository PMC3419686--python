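"""Count tables, relative abundance, and compositional community summaries.

The entry point of the pipeline is a taxon-by-sample table of 16S rRNA read
counts in which every row carries a semicolon-delimited lineage string
(``k__Bacteria;p__Firmicutes;...;g__Oscillospira``).  This module holds the
:class:`CountTable` container, rank aggregation, conversion to relative
abundance (per-sample simplex vectors), and the community summaries built on
top of it: prevalence / core-microbiota calls, Shannon diversity, the
Bacteroidetes:Firmicutes ratio, dominant-taxon community typing, and rank
abundance curves.

Conventions
-----------
* Reads that cannot be assigned at the working rank are pooled into a single
  sentinel taxon (``unassigned``).  The sentinel stays in the normalisation
  denominator — profiles remain on the simplex — but is excluded from
  dominance calls and the core-microbiota report.
* Shannon entropy is natural-log by default (``base`` is exposed).
* A taxon is "present" in a sample when it has at least ``detection_min``
  reads (default 1).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateSampleError, FormatError

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "TaxonLineage",
    "CountTable",
    "CommunityProfile",
    "PrevalenceReport",
    "read_count_table",
    "to_relative",
    "relative_abundance",
    "prevalence_core",
    "shannon_diversity",
    "bf_ratio",
    "dominant_taxon",
    "dominant_categories",
    "rank_abundance",
    "sample_summary",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIX = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
           "f": "family", "g": "genus", "s": "species"}
_RANK_TO_PREFIX = {v: k for k, v in _PREFIX.items()}

#: Sentinel taxon id collecting reads unassigned at the working rank.
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TaxonLineage:
    """Taxonomic lineage of one row of a count table.

    ``ranks`` maps rank name -> taxon name for the assigned prefix of the
    lineage; any suffix may be missing (unassigned).  The phylum must be
    present for downstream phylum-level summaries.
    """

    taxon_id: str
    ranks: Mapping[str, str] = field(default_factory=dict)

    def name_at(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.ranks.get(rank)

    @property
    def phylum(self) -> str | None:
        return self.ranks.get("phylum")

    def lineage_string(self, down_to: str = "species") -> str:
        parts = []
        for rank in RANKS[: RANKS.index(down_to) + 1]:
            name = self.ranks.get(rank, "")
            parts.append(f"{_RANK_TO_PREFIX[rank]}__{name}")
        return ";".join(parts)

    @classmethod
    def from_string(cls, lineage: str, taxon_id: str | None = None) -> "TaxonLineage":
        ranks: dict[str, str] = {}
        for token in lineage.split(";"):
            token = token.strip()
            if not token:
                continue
            if len(token) >= 3 and token[1:3] == "__":
                prefix, name = token[0], token[3:]
            else:
                raise FormatError(f"malformed lineage token {token!r}")
            if prefix not in _PREFIX:
                raise FormatError(f"unknown rank prefix {prefix!r} in {lineage!r}")
            if name:
                ranks[_PREFIX[prefix]] = name
        if taxon_id is None:
            # deepest assigned name, else the raw string
            taxon_id = next(
                (ranks[r] for r in reversed(RANKS) if r in ranks), lineage
            )
        return cls(taxon_id=taxon_id, ranks=ranks)


class CountTable:
    """Integer taxon-by-sample read counts with lineage annotations.

    Parameters
    ----------
    counts : DataFrame
        Taxa on the index (taxon ids), samples on the columns, non-negative
        integer entries.
    lineages : mapping of taxon id -> TaxonLineage
    """

    def __init__(self, counts: pd.DataFrame, lineages: Mapping[str, TaxonLineage]):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if values.size == 0:
            raise FormatError("empty count table")
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if np.any(values < 0):
            raise FormatError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise FormatError("non-integer counts")
        self.data = counts.astype(np.int64)
        missing = [t for t in counts.index if t not in lineages]
        if missing:
            raise FormatError(f"taxa without lineage annotation: {missing[:5]}")
        self.lineages = {t: lineages[t] for t in counts.index}

    # -- basic accessors ---------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.data.sum(axis=0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<CountTable {self.n_taxa} taxa x {self.n_samples} samples>"

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path | io.TextIOBase) -> "CountTable":
        if hasattr(path, "read"):
            text = path.read()
        else:
            text = Path(path).read_text()
        header = text.split("\n", 1)[0].rstrip("\r").split("\t")
        if len(set(header)) != len(header):
            raise FormatError("duplicate sample ids in header")
        try:
            frame = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise FormatError("empty count table file") from exc
        if frame.shape[1] < 2 or frame.columns[0] != "lineage":
            raise FormatError(
                "expected a 'lineage' first column and >=1 sample column"
            )
        sample_cols = list(frame.columns[1:])
        if len(set(sample_cols)) != len(sample_cols):
            raise FormatError("duplicate sample ids in header")
        try:
            counts = frame[sample_cols].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric counts: {exc}") from exc
        lineages = {}
        ids = []
        for raw in frame["lineage"]:
            lin = TaxonLineage.from_string(raw)
            tid = lin.taxon_id
            if tid in lineages:  # disambiguate homonyms across lineages
                tid = f"{tid}__{lin.phylum or 'NA'}"
                lin = TaxonLineage(taxon_id=tid, ranks=lin.ranks)
            lineages[tid] = lin
            ids.append(tid)
        counts.index = pd.Index(ids, name="taxon_id")
        return cls(counts, lineages)

    def to_tsv(self, path: str | Path | io.TextIOBase, down_to: str = "species") -> None:
        out = self.data.copy()
        out.insert(
            0, "lineage",
            [self.lineages[t].lineage_string(down_to) for t in out.index],
        )
        out.to_csv(path, sep="\t", index=False)

    # -- rank aggregation --------------------------------------------------
    def aggregate(self, rank: str) -> "CountTable":
        """Sum rows sharing the rank-level lineage; pool unassigned rows.

        Total reads per sample are conserved exactly.
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        depth_idx = RANKS.index(rank)
        groups: dict[tuple, list[str]] = {}
        for tid, lin in self.lineages.items():
            name = lin.ranks.get(rank)
            if name is None:
                key: tuple = (UNASSIGNED,)
            else:
                key = tuple(lin.ranks.get(r, "") for r in RANKS[: depth_idx + 1])
            groups.setdefault(key, []).append(tid)

        rows = {}
        lineages = {}
        for key, members in groups.items():
            if key == (UNASSIGNED,):
                new_id = UNASSIGNED
                new_lin = TaxonLineage(
                    taxon_id=new_id,
                    ranks={r: "Unassigned" for r in RANKS[: depth_idx + 1]},
                )
            else:
                name = key[-1]
                new_id = name
                if new_id in rows:  # same name under a different higher lineage
                    new_id = f"{name}__{key[1] if len(key) > 1 else 'NA'}"
                first = self.lineages[members[0]]
                new_lin = TaxonLineage(
                    taxon_id=new_id,
                    ranks={r: first.ranks[r] for r in RANKS[: depth_idx + 1]
                           if r in first.ranks},
                )
            rows[new_id] = self.data.loc[members].sum(axis=0)
            lineages[new_id] = new_lin
        counts = pd.DataFrame(rows).T
        counts.index.name = "taxon_id"
        counts.columns = self.data.columns
        # deterministic order: abundance descending, then name
        order = sorted(
            counts.index, key=lambda t: (-counts.loc[t].sum(), t)
        )
        counts = counts.loc[order]
        return CountTable(counts, lineages)


def read_count_table(path: str | Path, rank: str | None = None) -> CountTable:
    """Read a lineage-annotated TSV count table, optionally aggregated to a rank."""
    table = CountTable.from_tsv(path)
    if rank is not None:
        table = table.aggregate(rank)
    return table


@dataclass
class CommunityProfile:
    """Per-sample relative-abundance vector on the simplex."""

    sample_id: str
    abundances: pd.Series  # index: taxon ids, values sum to 1

    def __post_init__(self) -> None:
        total = float(self.abundances.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"profile {self.sample_id!r} sums to {total}, expected 1"
            )
        if (self.abundances < -1e-15).any() or (self.abundances > 1 + 1e-12).any():
            raise ValueError(f"profile {self.sample_id!r} leaves [0, 1]")

    @property
    def values(self) -> np.ndarray:
        return self.abundances.to_numpy(dtype=float)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Taxa-by-samples fractions; every column sums to 1."""
    depths = table.depths()
    zero = depths[depths == 0]
    if len(zero) > 0:
        raise DegenerateSampleError(
            f"sample(s) with zero total reads: {list(zero.index)}"
        )
    return table.data / depths


def to_relative(table: CountTable) -> list[CommunityProfile]:
    """Convert a count table into one :class:`CommunityProfile` per sample."""
    rel = relative_abundance(table)
    return [CommunityProfile(s, rel[s]) for s in rel.columns]


@dataclass
class PrevalenceReport:
    """Per-taxon prevalence with core-microbiota flags, sorted descending."""

    table: pd.DataFrame  # columns: prevalence, core (index taxon)
    detection_min: int
    core_cutoff: float

    @property
    def core_taxa(self) -> list[str]:
        return list(self.table.index[self.table["core"]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "taxon", out.index)
        out.to_csv(path, sep="\t", index=False)


def prevalence_core(
    table: CountTable,
    detection_min: int = 1,
    core_cutoff: float = 0.95,
    exclude_unassigned: bool = True,
) -> PrevalenceReport:
    """Prevalence of every taxon and the core set (prevalence >= cutoff).

    A taxon counts as present in a sample when it has at least
    ``detection_min`` reads.  The ``unassigned`` sentinel is excluded from the
    report by default (it is not a biological taxon).
    """
    if detection_min < 1:
        raise ValueError("detection_min must be >= 1")
    if not 0 < core_cutoff <= 1:
        raise ValueError("core_cutoff must be in (0, 1]")
    data = table.data
    if exclude_unassigned and UNASSIGNED in data.index:
        data = data.drop(index=UNASSIGNED)
    prev = (data >= detection_min).sum(axis=1) / table.n_samples
    frame = pd.DataFrame({"prevalence": prev})
    frame["core"] = frame["prevalence"] >= core_cutoff
    frame = frame.sort_values(
        by=["prevalence"], ascending=False, kind="mergesort"
    )
    # stable secondary order by taxon id for determinism among ties
    frame = frame.loc[
        sorted(frame.index, key=lambda t: (-frame.loc[t, "prevalence"], t))
    ]
    return PrevalenceReport(frame, detection_min, core_cutoff)


def shannon_diversity(
    profile: CommunityProfile | Sequence[float] | np.ndarray,
    base: float | None = None,
) -> float:
    """Shannon entropy H = -sum p ln p (nats by default), 0*ln0 == 0."""
    if isinstance(profile, CommunityProfile):
        p = profile.values
    else:
        p = np.asarray(profile, dtype=float)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def bf_ratio(table: CountTable) -> pd.Series:
    """Per-sample Bacteroidetes:Firmicutes read ratio.

    Samples with zero Firmicutes reads get NaN (undefined), never infinity.
    """
    phyla = pd.Series({t: table.lineages[t].phylum for t in table.taxa})
    b_taxa = phyla.index[phyla == "Bacteroidetes"]
    f_taxa = phyla.index[phyla == "Firmicutes"]
    b = table.data.loc[b_taxa].sum(axis=0).astype(float)
    f = table.data.loc[f_taxa].sum(axis=0).astype(float)
    ratio = b.where(f > 0) / f.where(f > 0)
    ratio.name = "bf_ratio"
    return ratio


#: Community-type categories used for dominant-taxon typing.
CATEGORY_PREVOTELLA = "Prevotella"
CATEGORY_BACTEROIDES = "Bacteroides"
CATEGORY_FIRMICUTES = "Firmicutes-other"


def dominant_taxon(
    profile: CommunityProfile, exclude: Iterable[str] = (UNASSIGNED,)
) -> tuple[str, str]:
    """Most abundant genus and its community-type category.

    Category is ``Prevotella`` or ``Bacteroides`` when that genus dominates,
    otherwise ``Firmicutes-other`` (the diverse-Firmicutes type).  Exact ties
    break lexicographically on the genus name so the call is deterministic.
    """
    ab = profile.abundances.drop(labels=[t for t in exclude
                                         if t in profile.abundances.index])
    if len(ab) == 0 or float(ab.sum()) <= 0:
        raise ValueError(f"no assigned abundance in sample {profile.sample_id!r}")
    top = ab.max()
    winner = min(ab.index[ab == top])  # lexicographic tie-break
    if winner == "Prevotella":
        category = CATEGORY_PREVOTELLA
    elif winner == "Bacteroides":
        category = CATEGORY_BACTEROIDES
    else:
        category = CATEGORY_FIRMICUTES
    return winner, category


def dominant_categories(table: CountTable) -> pd.DataFrame:
    """Dominant genus and category for every sample of a genus-level table."""
    rows = {}
    for prof in to_relative(table):
        genus, cat = dominant_taxon(prof)
        rows[prof.sample_id] = {"dominant_genus": genus, "dominant_category": cat}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out.loc[table.samples]


def rank_abundance(table: CountTable, top_n: int) -> tuple[pd.Series, float]:
    """Mean relative abundances sorted descending plus the top-n cumulative share."""
    if top_n > table.n_taxa:
        raise ValueError("top_n exceeds number of taxa")
    mean_rel = relative_abundance(table).mean(axis=1)
    mean_rel = mean_rel.loc[
        sorted(mean_rel.index, key=lambda t: (-mean_rel[t], t))
    ]
    share = float(mean_rel.iloc[:top_n].sum())
    return mean_rel, share


def sample_summary(table: CountTable) -> pd.DataFrame:
    """Per-sample depth, Shannon H, B:F ratio, and dominant genus/category."""
    rel = relative_abundance(table)
    h = rel.apply(lambda col: shannon_diversity(col.to_numpy()), axis=0)
    dom = dominant_categories(table)
    out = pd.DataFrame(
        {
            "depth": table.depths(),
            "shannon": h,
            "bf_ratio": bf_ratio(table),
        }
    ).join(dom)
    out.index.name = "sample_id"
    return out
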