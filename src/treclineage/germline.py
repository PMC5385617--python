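"""Germline V/J/C segment references for TCR amplicon analysis.

A :class:`GermlineReference` is the coordinate frame shared by the read
simulator and the annotation pipeline: V segments carry the conserved
2nd-CYS anchor codon (TGT/TGC), J segments the first codon of the
"FGXG" motif (TTY GGN NNN GGN), and the constant-region primer strings
mark where amplicons end.  Synthetic references are generated by
:func:`build_germline_reference`; real-data mode loads an IMGT-style
FASTA with anchor offsets encoded in the description line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GermlineSegment",
    "GermlineReference",
    "build_germline_reference",
    "read_reference_fasta",
    "write_reference_fasta",
    "TCRA_C_PRIMER",
    "TCRB_C_PRIMER",
    "UNIVERSAL_ADAPTER",
    "InvalidConfiguration",
]

# Second-round (semi-nested) constant-region reverse primers of the
# 5'RACE protocol, and the SMART universal adapter appended to cDNA
# 5' ends by template switching.
TCRA_C_PRIMER = "CAGGGTCAGGGTTCTGGAT"
TCRB_C_PRIMER = "CACAGCGACCTCGGGTGGGAA"
UNIVERSAL_ADAPTER = "AAGCAGTGGTATCAACGCAGAGT"

_BASES = np.array(list("ACGT"))


class InvalidConfiguration(ValueError):
    """Raised when a reference, model or parameter set violates its contract."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment.

    ``anchor_offset`` is the 0-based position of the conserved junction
    anchor: the first base of the 2nd-CYS codon for V segments, the first
    base of the J-PHE codon (start of the FGXG motif) for J segments.
    """

    name: str
    kind: str  # "V", "J" or "C"
    sequence: str
    anchor_offset: int = -1

    def __post_init__(self) -> None:
        if self.kind not in {"V", "J", "C"}:
            raise InvalidConfiguration(f"unknown segment kind {self.kind!r}")
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise InvalidConfiguration(
                f"segment {self.name}: sequence must be non-empty over ACGT"
            )
        if self.kind in {"V", "J"} and not (
            0 <= self.anchor_offset <= len(self.sequence) - 3
        ):
            raise InvalidConfiguration(
                f"segment {self.name}: anchor_offset {self.anchor_offset} "
                f"outside sequence of length {len(self.sequence)}"
            )

    @property
    def anchor_codon(self) -> str:
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]


@dataclass(frozen=True)
class GermlineReference:
    """V and J segment collections plus constant-region primer strings."""

    v_segments: tuple[GermlineSegment, ...]
    j_segments: tuple[GermlineSegment, ...]
    c_primers: tuple[str, ...] = (TCRA_C_PRIMER, TCRB_C_PRIMER)
    adapter: str = UNIVERSAL_ADAPTER

    def __post_init__(self) -> None:
        if len(self.v_segments) < 2 or len(self.j_segments) < 2:
            raise InvalidConfiguration("reference needs at least 2 V and 2 J segments")
        if not self.c_primers:
            raise InvalidConfiguration("c_primers must be non-empty")
        names = [s.name for s in self.v_segments + self.j_segments]
        if len(set(names)) != len(names):
            raise InvalidConfiguration("segment names must be unique")

    def v_by_name(self, name: str) -> GermlineSegment:
        return self._index()[name]

    def j_by_name(self, name: str) -> GermlineSegment:
        return self._index()[name]

    def _index(self) -> dict[str, GermlineSegment]:
        return {s.name: s for s in self.v_segments + self.j_segments}

    @property
    def c_primer_sites(self) -> tuple[str, ...]:
        """Reverse-complemented primer sequences as they appear on the read."""
        return tuple(str(Seq(p).reverse_complement()) for p in self.c_primers)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _v_names(n: int) -> list[str]:
    # TRBV12-4 always present so V/J-restricted overlap works out of the box
    return ["TRBV12-4"] + [f"TRBV{i}-1" for i in range(1, n)]


def _j_names(n: int) -> list[str]:
    return ["TRBJ1-2"] + [f"TRBJ2-{i}" for i in range(1, n)]


def build_germline_reference(
    n_v: int, n_j: int, seed: int, j_anchor_offset: int = 18
) -> GermlineReference:
    """Generate a synthetic germline reference.

    Each V segment ends in a TGT/TGC (Cys) anchor codon; each J segment
    carries a TTY GGN NNN GGN ("FGXG") motif at ``j_anchor_offset``, so
    the minimal junction (zero N-insertion) is ``3 + j_anchor_offset + 3``
    nt — 24 nt at the default offset, long enough that accidental junction
    collisions are negligible.  Deterministic for a fixed seed.
    """
    if n_v < 2 or n_j < 2:
        raise InvalidConfiguration("n_v and n_j must both be >= 2")
    rng = np.random.default_rng(seed)
    v_segments = []
    for name in _v_names(n_v):
        body_len = int(48 + 3 * rng.integers(0, 6))
        anchor = "TGT" if rng.random() < 0.5 else "TGC"
        seq = _random_seq(rng, body_len) + anchor
        v_segments.append(
            GermlineSegment(name=name, kind="V", sequence=seq, anchor_offset=body_len)
        )
    j_segments = []
    for name in _j_names(n_j):
        prefix = _random_seq(rng, j_anchor_offset)
        phe = "TTT" if rng.random() < 0.5 else "TTC"
        motif = phe + "GG" + _random_seq(rng, 4) + "GG" + _random_seq(rng, 1)
        tail = _random_seq(rng, int(12 + 3 * rng.integers(0, 3)))
        j_segments.append(
            GermlineSegment(
                name=name,
                kind="J",
                sequence=prefix + motif + tail,
                anchor_offset=j_anchor_offset,
            )
        )
    return GermlineReference(tuple(v_segments), tuple(j_segments))


def write_reference_fasta(reference: GermlineReference, path) -> None:
    """Write segments (and primers, kind=C) with anchors in the description."""
    records = []
    for seg in reference.v_segments + reference.j_segments:
        records.append(
            SeqRecord(
                Seq(seg.sequence),
                id=seg.name,
                description=f"kind={seg.kind} anchor={seg.anchor_offset}",
            )
        )
    for i, primer in enumerate(reference.c_primers):
        records.append(
            SeqRecord(Seq(primer), id=f"C-primer-{i+1}", description="kind=C anchor=-1")
        )
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path) -> GermlineReference:
    v, j, c = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        kind = fields.get("kind")
        anchor = int(fields.get("anchor", -1))
        if kind == "V":
            v.append(GermlineSegment(rec.id, "V", str(rec.seq), anchor))
        elif kind == "J":
            j.append(GermlineSegment(rec.id, "J", str(rec.seq), anchor))
        elif kind == "C":
            c.append(str(rec.seq))
        else:
            raise InvalidConfiguration(
                f"record {rec.id}: description must carry kind=V|J|C"
            )
    primers = tuple(c) if c else (TCRA_C_PRIMER, TCRB_C_PRIMER)
    return GermlineReference(tuple(v), tuple(j), primers)
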