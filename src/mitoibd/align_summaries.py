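"""Descriptive alignment summaries: site classification, haplotypes, clade divergences.

A site is *variable* when at least two distinct unambiguous nucleotides
occur among its non-missing characters, and *parsimony informative*
when at least two of those nucleotides each occur in at least two
sequences.  Gaps and ambiguity codes neither create nor suppress
variability.  Haplotypes are collapsed by exact character identity over
all sites, with an optional ambiguity-tolerant mode.  Clade divergence
summaries are means and sample standard deviations of the defined
between-clade cells of a pairwise distance matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import IUPAC_SETS, Alignment, SampleTable
from .distances import DistanceMatrix, encode_alignment

__all__ = [
    "SiteClassification",
    "HaplotypeTable",
    "CladeDivergenceSummary",
    "classify_sites",
    "collapse_haplotypes",
    "clade_divergence",
    "interclade_divergence_table",
]

logger = logging.getLogger(__name__)


@dataclass
class SiteClassification:
    """Per-site categories with totals; parsimony-informative ⊆ variable."""

    categories: list[str]  # per site: 'constant' | 'variable' | 'all-missing'
    parsimony_informative: list[bool]
    n_sites: int = field(init=False)
    n_constant: int = field(init=False)
    n_variable: int = field(init=False)
    n_all_missing: int = field(init=False)
    n_parsimony_informative: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_sites = len(self.categories)
        self.n_constant = self.categories.count("constant")
        self.n_variable = self.categories.count("variable")
        self.n_all_missing = self.categories.count("all-missing")
        if self.n_constant + self.n_variable + self.n_all_missing != self.n_sites:
            raise ValueError("site categories do not partition the sites")
        self.n_parsimony_informative = sum(self.parsimony_informative)
        if any(
            pi and cat != "variable"
            for pi, cat in zip(self.parsimony_informative, self.categories)
        ):
            raise ValueError("parsimony-informative site not marked variable")


def classify_sites(alignment: Alignment) -> SiteClassification:
    """Classify every column as constant, variable, or all-missing."""
    if alignment.n_samples < 2:
        raise ValueError("site classification needs at least 2 sequences")
    codes = encode_alignment(alignment)  # 0..3 for A,C,G,T; 255 otherwise
    categories: list[str] = []
    informative: list[bool] = []
    for j in range(alignment.n_sites):
        col = codes[:, j]
        counts = np.bincount(col[col < 4], minlength=4)
        n_states = int((counts > 0).sum())
        if n_states == 0:
            categories.append("all-missing")
            informative.append(False)
        elif n_states == 1:
            categories.append("constant")
            informative.append(False)
        else:
            categories.append("variable")
            informative.append(int((counts >= 2).sum()) >= 2)
    return SiteClassification(categories, informative)


@dataclass
class HaplotypeTable:
    """Haplotype id -> representative sequence, member ids, frequency."""

    haplotypes: pd.DataFrame = field(repr=False)  # haplotype_id, sequence, members, frequency
    n_samples: int = 0

    def __post_init__(self) -> None:
        if int(self.haplotypes.frequency.sum()) != self.n_samples:
            raise ValueError("haplotype frequencies do not sum to sample count")
        members = list(itertools.chain.from_iterable(self.haplotypes.members))
        if len(members) != len(set(members)):
            raise ValueError("sample assigned to more than one haplotype")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def frequencies(self) -> list[int]:
        return [int(f) for f in self.haplotypes.frequency]

    def representative_alignment(self) -> Alignment:
        return Alignment.from_sequences(
            self.haplotypes.haplotype_id.tolist(), self.haplotypes.sequence.tolist()
        )


def _compatible(seq_a: str, seq_b: str) -> bool:
    """True when the two sequences could be the same haplotype under ambiguity."""
    return all(
        (IUPAC_SETS[a] & IUPAC_SETS[b]) or (a == b)
        for a, b in zip(seq_a, seq_b)
    )


def collapse_haplotypes(
    alignment: Alignment,
    sample_subset=None,
    *,
    ambiguity_tolerant: bool = False,
) -> HaplotypeTable:
    """Group samples into haplotypes, numbered by first occurrence.

    The default identity rule is exact character-string equality over
    all sites (ambiguity codes count as distinct characters).  With
    ``ambiguity_tolerant=True`` a sample joins the first established
    haplotype whose representative is site-wise IUPAC-compatible.
    """
    ids = list(sample_subset) if sample_subset is not None else list(alignment.sample_ids)
    if not ids:
        raise ValueError("empty sample subset")
    sub = alignment.subset(ids)
    reps: list[str] = []
    members: list[list[str]] = []
    for sid in sub.sample_ids:
        seq = sub.sequence(sid)
        for k, rep in enumerate(reps):
            same = _compatible(seq, rep) if ambiguity_tolerant else seq == rep
            if same:
                members[k].append(sid)
                break
        else:
            reps.append(seq)
            members.append([sid])
    df = pd.DataFrame(
        {
            "haplotype_id": [f"H{k + 1}" for k in range(len(reps))],
            "sequence": reps,
            "members": members,
            "frequency": [len(m) for m in members],
        }
    )
    return HaplotypeTable(df, n_samples=len(ids))


def _between_clade_entries(
    matrix: DistanceMatrix, table: SampleTable, clade_a: str, clade_b: str
) -> np.ndarray:
    ids_a = [s for s in table.subset_clades([clade_a]).sample_ids if s in matrix.labels]
    ids_b = [s for s in table.subset_clades([clade_b]).sample_ids if s in matrix.labels]
    if not ids_a or not ids_b:
        raise ValueError(f"clade {clade_a!r} or {clade_b!r} has no samples in matrix")
    if set(ids_a) & set(ids_b):
        raise ValueError(f"clades {clade_a!r} and {clade_b!r} share samples")
    ia = [matrix.labels.index(s) for s in ids_a]
    ib = [matrix.labels.index(s) for s in ids_b]
    return matrix.values[np.ix_(ia, ib)].ravel()


def clade_divergence(
    matrix: DistanceMatrix, table: SampleTable, clade_a: str, clade_b: str
) -> tuple[float, float, int]:
    """Mean, sample SD, and count of defined between-clade pairwise distances."""
    entries = _between_clade_entries(matrix, table, clade_a, clade_b)
    defined = entries[~np.isnan(entries)]
    n_skipped = entries.size - defined.size
    if defined.size == 0:
        raise ValueError(
            f"all {entries.size} distances between clades {clade_a!r} and {clade_b!r} undefined"
        )
    if n_skipped:
        logger.warning(
            "skipped %d undefined distances between clades %s and %s",
            n_skipped, clade_a, clade_b,
        )
    sd = float(np.std(defined, ddof=1)) if defined.size > 1 else 0.0
    return float(np.mean(defined)), sd, int(defined.size)


@dataclass
class CladeDivergenceSummary:
    """Between-clade divergence means/SDs for all unordered clade pairs."""

    table: pd.DataFrame = field(repr=False)  # clade_a, clade_b, mean, sd, n_pairs, n_skipped
    minimum_mean: float = float("nan")

    def pair(self, clade_a: str, clade_b: str) -> pd.Series:
        t = self.table
        hit = t[((t.clade_a == clade_a) & (t.clade_b == clade_b))
                | ((t.clade_a == clade_b) & (t.clade_b == clade_a))]
        if hit.empty:
            raise KeyError(f"no clade pair ({clade_a}, {clade_b})")
        return hit.iloc[0]


def interclade_divergence_table(
    matrix: DistanceMatrix, table: SampleTable, clade_labels
) -> CladeDivergenceSummary:
    """Summarize all unordered clade pairs; the minimum of the pair means is kept."""
    clades = [str(c) for c in clade_labels]
    if len(clades) < 2:
        raise ValueError("need at least 2 clades")
    rows = []
    for a, b in itertools.combinations(clades, 2):
        entries = _between_clade_entries(matrix, table, a, b)
        defined = entries[~np.isnan(entries)]
        if defined.size == 0:
            raise ValueError(f"all distances between clades {a!r} and {b!r} undefined")
        rows.append(
            {
                "clade_a": a,
                "clade_b": b,
                "mean": float(np.mean(defined)),
                "sd": float(np.std(defined, ddof=1)) if defined.size > 1 else 0.0,
                "n_pairs": int(defined.size),
                "n_skipped": int(entries.size - defined.size),
            }
        )
    df = pd.DataFrame(rows)
    return CladeDivergenceSummary(df, minimum_mean=float(df["mean"].min()))
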