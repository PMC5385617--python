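"""Repertoire statistics: gene usage, Morisita-Horn similarity,
unsupervised clustering, and clonotype-overlap measures.

The Morisita-Horn index between repertoires with clonotype counts x_i,
y_i (totals X, Y) is

    MH = 2 * sum_i x_i y_i / ((sum_i x_i^2 / X^2 + sum_i y_i^2 / Y^2) * X * Y)

— an abundance-weighted similarity in [0, 1] that is 0 for disjoint
repertoires, 1 for identical relative frequencies, and invariant to
uniform rescaling of either count vector.  Repertoires are clustered by
agglomerative linkage on the distance 1 - MH; overlap statistics report
the bidirectional shared-unique-clonotype fractions (optionally within a
fixed V-J rearrangement) with cohort mean +/- SEM and Student's t tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .tables import ClonotypeTable, KEY_COLUMNS

__all__ = [
    "UsageProfile",
    "SimilarityMatrix",
    "DendrogramTree",
    "OverlapResult",
    "gene_usage",
    "order_genes",
    "morisita_horn",
    "similarity_matrix",
    "cluster_repertoires",
    "overlap_profile",
    "vj_restricted_overlap",
    "cohort_overlap_summary",
    "compare_overlap_groups",
]


# ---------------------------------------------------------------------------
# gene usage


@dataclass(frozen=True)
class UsageProfile:
    """Per-gene read-frequency profile of one repertoire."""

    labels: tuple[str, ...]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("usage labels must be unique")
        f = np.asarray(self.frequencies, dtype=float)
        if len(f) and (f.min() < 0 or abs(f.sum() - 1.0) > 1e-9):
            raise ValueError("frequencies must be >= 0 and sum to 1")
        object.__setattr__(self, "frequencies", f)

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=list(self.labels))


def gene_usage(table: ClonotypeTable, axis: str = "V") -> UsageProfile:
    """Read-frequency of each V (or J) gene call in a table."""
    if axis not in {"V", "J"}:
        raise ValueError("axis must be 'V' or 'J'")
    if len(table) == 0:
        raise ValueError(f"gene_usage: table {table.sample_id} is empty")
    col = "v_call" if axis == "V" else "j_call"
    counts = table.df.groupby(col, sort=True)["duplicate_count"].sum()
    freq = counts / counts.sum()
    return UsageProfile(tuple(freq.index), freq.to_numpy())


def order_genes(profile: UsageProfile, reference: UsageProfile) -> UsageProfile:
    """Reorder `profile` by the reference profile's descending frequency
    (genes absent from the reference follow, by their own frequency)."""
    ref = reference.as_series().sort_values(ascending=False, kind="stable")
    own = profile.as_series()
    ordered = [g for g in ref.index if g in own.index]
    rest = own.drop(ordered).sort_values(ascending=False, kind="stable")
    ordered += list(rest.index)
    return UsageProfile(tuple(ordered), own.loc[ordered].to_numpy())


# ---------------------------------------------------------------------------
# Morisita-Horn similarity


def _count_series(table: ClonotypeTable | pd.Series | UsageProfile) -> pd.Series:
    if isinstance(table, ClonotypeTable):
        return table.counts().astype(float)
    if isinstance(table, UsageProfile):
        return table.as_series().astype(float)
    return table.astype(float)


def morisita_horn(a, b) -> float:
    """Morisita-Horn similarity between two count vectors.

    Accepts :class:`ClonotypeTable` (counts keyed by clonotype),
    :class:`UsageProfile` (gene-level comparison), or a pandas Series.
    """
    x = _count_series(a)
    y = _count_series(b)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("morisita_horn: both repertoires must be non-empty")
    x, y = x.align(y, fill_value=0.0)
    # frequency form 2*sum(f*g) / (sum(f^2) + sum(g^2)): algebraically equal
    # to the count form but exact (1.0) for identical count vectors
    fv = x.to_numpy() / x.to_numpy().sum()
    gv = y.to_numpy() / y.to_numpy().sum()
    numerator = 2.0 * float(fv @ gv)
    if numerator == 0.0:
        return 0.0
    return numerator / (float(fv @ fv) + float(gv @ gv))


@dataclass
class SimilarityMatrix:
    """Symmetric label x label Morisita-Horn matrix, diagonal 1."""

    labels: tuple[str, ...]
    values: np.ndarray
    level: str = "clonotype"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def off_diagonal_ranking(self, label: str) -> list[tuple[str, float]]:
        """Other labels sorted by descending similarity to `label`."""
        i = self.labels.index(label)
        pairs = [
            (other, float(self.values[i, k]))
            for k, other in enumerate(self.labels)
            if other != label
        ]
        return sorted(pairs, key=lambda t: (-t[1], t[0]))


def similarity_matrix(
    tables: dict[str, ClonotypeTable], level: str = "clonotype", usage_axis: str = "V"
) -> SimilarityMatrix:
    """All-pairs Morisita-Horn over named repertoires.

    ``level='clonotype'`` compares clonotype count vectors (default);
    ``level='vgene'`` compares V-gene usage profiles — both readings of
    "repertoire similarity" are supported.  Labels are sorted so the
    matrix (and any downstream tie-breaking) is deterministic.
    """
    if len(tables) < 2:
        raise ValueError("similarity_matrix needs at least 2 repertoires")
    labels = tuple(sorted(tables))
    if level == "clonotype":
        vectors = {k: tables[k].counts().astype(float) for k in labels}
    elif level == "vgene":
        vectors = {k: gene_usage(tables[k], usage_axis).as_series() for k in labels}
    else:
        raise ValueError("level must be 'clonotype' or 'vgene'")
    n = len(labels)
    m = np.eye(n)
    for i in range(n):
        for k in range(i + 1, n):
            m[i, k] = m[k, i] = morisita_horn(vectors[labels[i]], vectors[labels[k]])
    return SimilarityMatrix(labels, m, level=level)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class DendrogramTree:
    """Agglomerative merge tree over repertoire labels."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    newick: str

    def tree(self) -> TreeNode:
        return TreeNode.read([self.newick])

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def _cluster_leaves(self) -> dict[int, set[str]]:
        leaves = {i: {lab} for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        for r, (i, k, _, _) in enumerate(self.linkage_matrix):
            leaves[n + r] = leaves[int(i)] | leaves[int(k)]
        return leaves

    def first_merge_partners(self, label: str) -> set[str]:
        """Leaf labels of the cluster `label` is first merged with."""
        idx = self.labels.index(label)
        leaves = self._cluster_leaves()
        current = idx
        n = len(self.labels)
        for r, (i, k, _, _) in enumerate(self.linkage_matrix):
            if int(i) == current:
                return leaves[int(k)]
            if int(k) == current:
                return leaves[int(i)]
        return set()


def cluster_repertoires(
    matrix: SimilarityMatrix, linkage: str = "average"
) -> DendrogramTree:
    """Hierarchical clustering on the distance 1 - MH.

    Ties are broken deterministically: labels are in lexicographic order
    (SimilarityMatrix sorts them) and scipy merges the lowest-index pair
    among equal distances first.
    """
    if linkage not in {"average", "complete", "single"}:
        raise ValueError("linkage must be average, complete or single")
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    tree = TreeNode.from_linkage_matrix(Z, list(matrix.labels))
    newick = str(tree).strip()
    return DendrogramTree(matrix.labels, Z, newick)


# ---------------------------------------------------------------------------
# clonotype overlap


def overlap_profile(
    reference: ClonotypeTable, others: dict[str, ClonotypeTable]
) -> pd.DataFrame:
    """Fig-1D-style profile: for every clonotype of the reference table
    (rows, ordered by descending reference frequency), its relative
    frequency in each other repertoire (0 when absent)."""
    if len(reference) == 0:
        raise ValueError("overlap_profile: empty reference table")
    ref = reference.frequencies().sort_values(ascending=False, kind="stable")
    ref = ref.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    out = pd.DataFrame({"reference": ref})
    for name in sorted(others):
        freq = others[name].frequencies()
        out[name] = freq.reindex(ref.index, fill_value=0.0)
    out.index.names = KEY_COLUMNS
    return out


@dataclass(frozen=True)
class OverlapResult:
    """Bidirectional shared-clonotype proportions between two repertoires."""

    sample_a: str
    sample_b: str
    shared_unique: int
    unique_a: int
    unique_b: int
    fraction_a: float  # shared / unique clonotypes of A
    fraction_b: float
    weighted_fraction_a: float  # summed A-frequency of the shared clonotypes
    weighted_fraction_b: float
    v_gene: str | None = None
    j_gene: str | None = None
    empty: bool = False


def vj_restricted_overlap(
    a: ClonotypeTable,
    b: ClonotypeTable,
    v_gene: str | None = None,
    j_gene: str | None = None,
    level: str = "nt",
) -> OverlapResult:
    """Shared-clonotype fractions, optionally within one V-J rearrangement.

    With ``v_gene``/``j_gene`` given, both tables are first restricted to
    clonotypes carrying that rearrangement and sharing is assessed on the
    junction sequence (``level='nt'``, default) or its translation
    (``level='aa'``).  If the restriction empties either table, a flagged
    all-zero result is returned rather than an error.
    """
    ra = a.restrict(v_gene, j_gene)
    rb = b.restrict(v_gene, j_gene)
    if len(ra) == 0 or len(rb) == 0:
        return OverlapResult(
            a.sample_id, b.sample_id, 0, len(ra), len(rb),
            0.0, 0.0, 0.0, 0.0, v_gene, j_gene, empty=True,
        )
    key_col = "junction" if level == "nt" else "junction_aa"
    ka = ra.df.groupby(key_col)["duplicate_count"].sum()
    kb = rb.df.groupby(key_col)["duplicate_count"].sum()
    shared = ka.index.intersection(kb.index)
    fa = ka / ka.sum()
    fb = kb / kb.sum()
    return OverlapResult(
        a.sample_id,
        b.sample_id,
        shared_unique=len(shared),
        unique_a=len(ka),
        unique_b=len(kb),
        fraction_a=len(shared) / len(ka),
        fraction_b=len(shared) / len(kb),
        weighted_fraction_a=float(fa.loc[shared].sum()),
        weighted_fraction_b=float(fb.loc[shared].sum()),
        v_gene=v_gene,
        j_gene=j_gene,
    )


_SUMMARY_FIELDS = (
    "fraction_a",
    "fraction_b",
    "weighted_fraction_a",
    "weighted_fraction_b",
)


def cohort_overlap_summary(results: Sequence[OverlapResult | float]) -> dict:
    """Mean, SEM (sd/sqrt(n), n-1 denominator) and n across patients.

    Accepts OverlapResults (summarised per direction) or raw fractions
    (summarised under 'fraction').
    """
    if len(results) < 2:
        raise ValueError("cohort summary needs n >= 2 patients (SEM undefined)")
    if all(isinstance(r, OverlapResult) for r in results):
        out = {}
        for fld in _SUMMARY_FIELDS:
            vals = np.array([getattr(r, fld) for r in results], dtype=float)
            out[fld] = {
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                "n": len(vals),
            }
        return out
    vals = np.asarray(results, dtype=float)
    return {
        "fraction": {
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))),
            "n": len(vals),
        }
    }


def compare_overlap_groups(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided Student's t-test on per-patient fractions.

    Welch (unequal-variance) by default; ``equal_var=True`` gives the
    pooled-variance test.  Returns (t statistic, raw p-value) — no
    multiple-testing correction is applied.
    """
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
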