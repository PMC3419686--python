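"""Community-type concordance in relative pairs and concordance-contrast
heritability.

Spouse pairs share a household but not genes; sibling and parent-offspring
pairs share half their genes (and often a household history).  Comparing
community-type concordance rates between the two kinds of pair gives a crude
heritability estimate:

    h2 = 2 * (first-degree concordance - spouse concordance)

The first-degree rate pools sibling and parent-offspring pairs weighted by
pair counts.  The spouse/first-degree contrast is tested by permuting
relationship-class labels across pairs (pairs within families are not
independent, so a plain two-proportion z-test is optimistic; it is available
behind ``method='ztest'`` for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import GutnetError, UndefinedStatisticError

__all__ = [
    "RELATIONSHIPS",
    "FIRST_DEGREE",
    "RelativePair",
    "ConcordanceResult",
    "HeritabilityEstimate",
    "read_pairs",
    "write_pairs",
    "concordance",
    "heritability",
    "contrast_test",
]

RELATIONSHIPS = ("spouse", "sibling", "parent-offspring")
FIRST_DEGREE = ("sibling", "parent-offspring")


@dataclass(frozen=True)
class RelativePair:
    subject_a: str
    subject_b: str
    relationship: str
    family_id: str = ""

    def __post_init__(self) -> None:
        if self.subject_a == self.subject_b:
            raise GutnetError(f"pair with identical members {self.subject_a!r}")
        if self.relationship not in RELATIONSHIPS:
            raise GutnetError(f"unknown relationship {self.relationship!r}")


def read_pairs(path: str | Path) -> list[RelativePair]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_a", "subject_b", "relationship"}
    if not required <= set(frame.columns):
        raise GutnetError(f"pairs file must have columns {sorted(required)}")
    fam = frame["family_id"] if "family_id" in frame.columns else [""] * len(frame)
    return [
        RelativePair(a, b, rel, f or "")
        for a, b, rel, f in zip(
            frame["subject_a"], frame["subject_b"], frame["relationship"], fam
        )
    ]


def write_pairs(pairs: Sequence[RelativePair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_a": p.subject_a,
                "subject_b": p.subject_b,
                "relationship": p.relationship,
                "family_id": p.family_id,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ConcordanceResult:
    """Per-relationship pair counts, concordant counts and rates."""

    table: pd.DataFrame  # index: relationship; columns n_pairs, n_concordant, rate
    pooled_first_degree_rate: float
    pooled_first_degree_n: int

    def rate(self, relationship: str) -> float:
        return float(self.table.loc[relationship, "rate"])


def _concordance_flags(
    pairs: Sequence[RelativePair], labels: Mapping[str, object] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """(relationship array, concordant bool array) for a pair list."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    rels = []
    conc = []
    for pair in pairs:
        for subject in (pair.subject_a, pair.subject_b):
            if subject not in labels:
                raise GutnetError(f"subject {subject!r} has no group label")
        rels.append(pair.relationship)
        conc.append(labels[pair.subject_a] == labels[pair.subject_b])
    return np.array(rels), np.array(conc, dtype=bool)


def concordance(
    pairs: Sequence[RelativePair], labels: Mapping[str, object] | pd.Series
) -> ConcordanceResult:
    """Concordance rates per relationship class plus the pooled first-degree rate.

    A pair is concordant iff both members carry the same community-type
    label.  The pooled first-degree rate weights sibling and
    parent-offspring classes by their pair counts (i.e. total concordant /
    total pairs).
    """
    rels, conc = _concordance_flags(pairs, labels)
    rows = {}
    for rel in RELATIONSHIPS:
        mask = rels == rel
        n = int(mask.sum())
        k = int(conc[mask].sum())
        rows[rel] = {
            "n_pairs": n,
            "n_concordant": k,
            "rate": k / n if n else np.nan,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "relationship"
    fd_mask = np.isin(rels, FIRST_DEGREE)
    fd_n = int(fd_mask.sum())
    fd_rate = float(conc[fd_mask].sum() / fd_n) if fd_n else np.nan
    return ConcordanceResult(table, fd_rate, fd_n)


@dataclass
class HeritabilityEstimate:
    """Concordance-contrast heritability with its components."""

    h2: float
    first_degree_rate: float
    spouse_rate: float
    out_of_range: bool  # True when h2 falls outside [0, 1]


def heritability(conc: ConcordanceResult) -> HeritabilityEstimate:
    """h2 = 2 * (pooled first-degree rate - spouse rate); flagged, not clamped."""
    n_spouse = int(conc.table.loc["spouse", "n_pairs"])
    if n_spouse == 0 or conc.pooled_first_degree_n == 0:
        raise UndefinedStatisticError(
            "heritability undefined: a relationship class has zero pairs"
        )
    spouse_rate = conc.rate("spouse")
    h2 = 2.0 * (conc.pooled_first_degree_rate - spouse_rate)
    return HeritabilityEstimate(
        h2=h2,
        first_degree_rate=conc.pooled_first_degree_rate,
        spouse_rate=spouse_rate,
        out_of_range=not (0.0 <= h2 <= 1.0),
    )


def contrast_test(
    pairs: Sequence[RelativePair],
    labels: Mapping[str, object] | pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "permutation",
) -> float:
    """Two-sided test of spouse vs pooled first-degree concordance.

    ``method='permutation'`` shuffles relationship-class labels across the
    pooled pair list ``n_perm`` times (seeded) and compares the absolute rate
    difference; the p-value uses the add-one estimator.  ``method='ztest'``
    is the classic two-proportion z-test, provided for comparison only.
    """
    rels, conc = _concordance_flags(pairs, labels)
    spouse_mask = rels == "spouse"
    fd_mask = np.isin(rels, FIRST_DEGREE)
    n_s = int(spouse_mask.sum())
    n_f = int(fd_mask.sum())
    if n_s == 0 or n_f == 0:
        raise UndefinedStatisticError(
            "contrast undefined: need both spouse and first-degree pairs"
        )
    obs = conc[spouse_mask].mean() - conc[fd_mask].mean()
    if method == "ztest":
        p_s = conc[spouse_mask].mean()
        p_f = conc[fd_mask].mean()
        pool = conc[spouse_mask | fd_mask].mean()
        se = np.sqrt(pool * (1 - pool) * (1 / n_s + 1 / n_f))
        if se == 0:
            return 1.0
        z = (p_s - p_f) / se
        return float(2 * stats.norm.sf(abs(z)))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 1000:
        raise GutnetError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed)
    vals = conc[spouse_mask | fd_mask].astype(float)
    n_tot = n_s + n_f
    # permuting class labels across pairs == shuffling the concordance values
    u = rng.random((n_perm, n_tot))
    order = np.argsort(u, axis=1)
    permuted = vals[order]
    diffs = permuted[:, :n_s].mean(axis=1) - permuted[:, n_s:].mean(axis=1)
    extreme = np.sum(np.abs(diffs) >= abs(obs) - 1e-12)
    return float((1 + extreme) / (1 + n_perm))
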