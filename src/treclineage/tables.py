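"""Clonotype tables — the central currency of the repertoire statistics.

A clonotype is keyed by (v_call, j_call, junction-nucleotide-sequence);
a :class:`ClonotypeTable` holds the counted clonotypes of one sample (or
of a pool of samples) as a pandas DataFrame in AIRR Rearrangement column
conventions, and is what every downstream statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

_CODON = dict(standard_dna_table.forward_table)
_CODON.update({c: "*" for c in standard_dna_table.stop_codons})

__all__ = ["Clonotype", "ClonotypeTable", "translate_junction", "KEY_COLUMNS"]

KEY_COLUMNS = ["v_call", "j_call", "junction"]

#: columns every AIRR table written by this package carries
AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
]


class Clonotype(NamedTuple):
    """A single counted TCR rearrangement."""

    v_call: str
    j_call: str
    junction: str
    junction_aa: str
    productive: bool
    count: int

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_call, self.j_call, self.junction)


def translate_junction(junction_nt: str) -> tuple[str, bool]:
    """Return (junction_aa, productive) for a junction nucleotide string.

    Productive means: in frame (length divisible by 3), no stop codon, and
    the translation starts with C (2nd-CYS) and ends with F (J-PHE).
    Out-of-frame junctions get an empty junction_aa.
    """
    if not junction_nt or len(junction_nt) % 3 != 0:
        return "", False
    aa = "".join(
        _CODON.get(junction_nt[i : i + 3], "X") for i in range(0, len(junction_nt), 3)
    )
    productive = "*" not in aa and aa.startswith("C") and aa.endswith("F")
    return aa, productive


@dataclass
class ClonotypeTable:
    """Counted clonotypes of one sample.

    ``df`` uses AIRR Rearrangement column names; the (v_call, j_call,
    junction) keys are unique and ``duplicate_count`` >= 1 everywhere.
    ``meta`` carries free-form per-table annotations (filter tallies,
    junction-collision counts, provenance notes).
    """

    sample_id: str
    df: pd.DataFrame
    patient: str = ""
    site: str = ""
    subset: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS + ["duplicate_count"] if c not in self.df.columns]
        if missing:
            raise ValueError(f"table {self.sample_id}: missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df.duplicated(KEY_COLUMNS).any():
            raise ValueError(f"table {self.sample_id}: duplicate clonotype keys")
        if len(self.df) and (self.df["duplicate_count"] < 1).any():
            raise ValueError(f"table {self.sample_id}: duplicate_count must be >= 1")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_clonotypes(
        cls,
        clonotypes: Iterable[Clonotype],
        sample_id: str,
        patient: str = "",
        site: str = "",
        subset: str = "",
        **meta,
    ) -> "ClonotypeTable":
        rows = list(clonotypes)
        df = pd.DataFrame(
            {
                "v_call": [c.v_call for c in rows],
                "j_call": [c.j_call for c in rows],
                "junction": [c.junction for c in rows],
                "junction_aa": [c.junction_aa for c in rows],
                "productive": [bool(c.productive) for c in rows],
                "duplicate_count": np.asarray([c.count for c in rows], dtype=np.int64),
            }
        )
        return cls(sample_id, df, patient=patient, site=site, subset=subset, meta=meta)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_count(self) -> int:
        return int(self.df["duplicate_count"].sum())

    @property
    def n_unique(self) -> int:
        return len(self.df)

    def counts(self) -> pd.Series:
        """Counts indexed by the (v_call, j_call, junction) key."""
        s = pd.Series(
            self.df["duplicate_count"].to_numpy(),
            index=pd.MultiIndex.from_frame(self.df[KEY_COLUMNS]),
        )
        return s

    def frequencies(self) -> pd.Series:
        c = self.counts()
        return c / c.sum()

    def keys(self) -> set[tuple[str, str, str]]:
        return set(map(tuple, self.df[KEY_COLUMNS].itertuples(index=False)))

    def restrict(self, v_call: str | None = None, j_call: str | None = None) -> "ClonotypeTable":
        """Sub-table of clonotypes using the given V and/or J gene."""
        mask = pd.Series(True, index=self.df.index)
        if v_call is not None:
            mask &= self.df["v_call"] == v_call
        if j_call is not None:
            mask &= self.df["j_call"] == j_call
        return ClonotypeTable(
            self.sample_id,
            self.df[mask].copy(),
            patient=self.patient,
            site=self.site,
            subset=self.subset,
            meta=dict(self.meta),
        )

    # -- AIRR Rearrangement TSV -------------------------------------------

    def to_airr_tsv(self, path) -> None:
        out = self.df.copy()
        if "sequence_id" not in out.columns:
            out.insert(0, "sequence_id", [f"{self.sample_id}:{i}" for i in range(len(out))])
        if "junction_aa" not in out.columns:
            aa_prod = [translate_junction(j) for j in out["junction"]]
            out["junction_aa"] = [a for a, _ in aa_prod]
            out["productive"] = [p for _, p in aa_prod]
        out["productive"] = out["productive"].map({True: "T", False: "F"})
        for col, val in (("patient", self.patient), ("site", self.site), ("subset", self.subset)):
            if col not in out.columns:
                out[col] = val
        cols = AIRR_COLUMNS + [c for c in out.columns if c not in AIRR_COLUMNS]
        out[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_airr_tsv(cls, path, sample_id: str | None = None) -> "ClonotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"junction": str, "junction_aa": str})
        df["junction_aa"] = df.get("junction_aa", "").fillna("")
        if "productive" in df.columns:
            df["productive"] = df["productive"].map(
                lambda x: x in (True, "T", "TRUE", "true", "True")
            )
        meta_cols = {c: "" for c in ("patient", "site", "subset")}
        for c in meta_cols:
            if c in df.columns and len(df):
                meta_cols[c] = str(df[c].iloc[0])
        if sample_id is None:
            sample_id = Path(str(path)).stem
        return cls(
            sample_id,
            df,
            patient=meta_cols["patient"],
            site=meta_cols["site"],
            subset=meta_cols["subset"],
        )
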