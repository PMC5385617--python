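"""Synthetic multi-patient TCR repertoire cohorts with planted lineage sharing.

Emulates the study design the statistics are meant to interrogate: per
patient, nine T-cell compartments (PB/LN/TI sites x naive/memory/Treg
subsets), each a pool of clonotypes with power-law clone sizes; a
:class:`SharingModel` plants cross-compartment clone sharing (the
lineage signal, e.g. tumor-infiltrating Tregs seeded from naive CD4+
cells) whose fractions the overlap statistics must recover.  Reads are
emitted in 5'RACE amplicon structure: sample barcode, universal adapter,
V segment, junction, J segment, reverse-complemented constant-region
primer site, with i.i.d. substitution errors.

Everything is deterministic for a fixed seed; ground truth (clonotype
tables with per-clone sharing provenance, per-read sample/clonotype
labels) is retained so every downstream stage is testable without
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .germline import GermlineReference, InvalidConfiguration, _random_seq
from .tables import Clonotype, ClonotypeTable, translate_junction

__all__ = [
    "SITES",
    "SUBSETS",
    "COMPARTMENTS",
    "SharingModel",
    "ReadRecord",
    "default_sharing_fractions",
    "simulate_cohort",
    "emit_reads",
    "design_barcodes",
    "write_fastq",
    "write_barcode_tsv",
    "read_barcode_tsv",
]

SITES = ("PB", "LN", "TI")
SUBSETS = ("naive", "memory", "Treg")
#: the nine (site, subset) compartments sampled per patient
COMPARTMENTS = tuple(f"{site}_{subset}" for site in SITES for subset in SUBSETS)

_BASES = "ACGT"


def default_sharing_fractions() -> dict[tuple[str, str], float]:
    """The planted lineage structure under test.

    TI Tregs draw a large clone fraction from naive CD4+ pools (tumor and
    blood) and only a trace fraction from blood Tregs and memory cells.
    Only these hypothesis edges are planted, so the raw shared-unique
    fraction of each (source, TI_Treg) pair is an unbiased estimate of
    its theta (no two-hop sharing paths).
    """
    return {
        ("TI_naive", "TI_Treg"): 0.13,
        ("PB_naive", "TI_Treg"): 0.13,
        ("PB_Treg", "TI_Treg"): 0.01,
        ("PB_memory", "TI_Treg"): 0.01,
        ("TI_memory", "TI_Treg"): 0.01,
    }


@dataclass
class SharingModel:
    """Design of a synthetic cohort.

    Parameters
    ----------
    patients : number of patients; each gets independent clone pools.
    compartments : (site, subset) labels simulated per patient.
    clone_pool_size : clonotypes per compartment (int, or per-compartment dict).
    powerlaw_alpha : exponent of the discrete power-law clone-size
        distribution P(size=k) ~ k**(-alpha), truncated at the pool size.
    cells_per_compartment : clone counts are rescaled to this fixed total,
        mirroring sequencing of equal cell numbers per sample.
    sharing_fractions : (source, target) -> theta, the fraction of the
        target's clone pool copied from the source.
    seed : master seed; all randomness derives from it.
    """

    patients: int = 5
    compartments: tuple[str, ...] = COMPARTMENTS
    clone_pool_size: int | dict[str, int] = 1000
    powerlaw_alpha: float = 2.5
    cells_per_compartment: int = 50_000
    sharing_fractions: dict[tuple[str, str], float] = field(
        default_factory=default_sharing_fractions
    )
    seed: int = 0

    def pool_size(self, compartment: str) -> int:
        if isinstance(self.clone_pool_size, dict):
            return int(self.clone_pool_size[compartment])
        return int(self.clone_pool_size)

    def validate(self) -> None:
        if self.patients < 1:
            raise InvalidConfiguration("patients must be >= 1")
        if self.powerlaw_alpha <= 0:
            raise InvalidConfiguration("powerlaw_alpha must be > 0")
        incoming: dict[str, float] = {}
        for (src, tgt), theta in self.sharing_fractions.items():
            if src not in self.compartments or tgt not in self.compartments:
                raise InvalidConfiguration(f"unknown compartment in edge {src}->{tgt}")
            if not 0.0 <= theta <= 1.0:
                raise InvalidConfiguration(f"theta({src}->{tgt})={theta} outside [0,1]")
            incoming[tgt] = incoming.get(tgt, 0.0) + theta
        for tgt, total in incoming.items():
            if total > 1.0 + 1e-12:
                raise InvalidConfiguration(
                    f"total incoming sharing for {tgt} is {total:.3f} > 1"
                )
        self._topological_order()

    def _topological_order(self) -> list[str]:
        """Compartments ordered so every sharing source precedes its targets."""
        edges = [(s, t) for (s, t), th in self.sharing_fractions.items() if th > 0]
        indeg = {c: 0 for c in self.compartments}
        for _, t in edges:
            indeg[t] += 1
        order, ready = [], [c for c in self.compartments if indeg[c] == 0]
        while ready:
            c = ready.pop(0)
            order.append(c)
            for s, t in edges:
                if s == c:
                    indeg[t] -= 1
                    if indeg[t] == 0:
                        ready.append(t)
        if len(order) != len(self.compartments):
            raise InvalidConfiguration("sharing_fractions contains a cycle")
        return order


@dataclass(frozen=True)
class ReadRecord:
    """One simulated read with its ground truth."""

    read_id: str
    sequence: str
    qualities: str  # Phred+33
    true_sample: str = ""
    true_clonotype: str = ""  # "v_call|j_call|junction"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")


# ---------------------------------------------------------------------------
# clone pools


def _powerlaw_sizes(rng: np.random.Generator, n: int, alpha: float, kmax: int) -> np.ndarray:
    """n i.i.d. draws from P(k) ~ k**(-alpha) on 1..kmax (Zipf truncated)."""
    k = np.arange(1, max(kmax, 2) + 1, dtype=float)
    pmf = k ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(len(k), size=n, p=pmf) + 1


def _scale_counts(sizes: np.ndarray, total: int) -> np.ndarray:
    """Rescale integer sizes to sum exactly to `total`, keeping every count >= 1."""
    sizes = np.asarray(sizes, dtype=float)
    counts = np.maximum(1, np.rint(sizes * total / sizes.sum())).astype(np.int64)
    diff = total - counts.sum()
    order = np.argsort(-counts, kind="stable")
    i = 0
    while diff != 0 and len(counts):
        idx = order[i % len(order)]
        step = 1 if diff > 0 else -1
        if counts[idx] + step >= 1:
            counts[idx] += step
            diff -= step
        i += 1
    return counts


def _novel_clonotypes(
    rng: np.random.Generator,
    reference: GermlineReference,
    used_keys: set,
    n: int,
    max_insert: int = 12,
) -> tuple[list[Clonotype], int]:
    """Draw n new (V, J, junction) clonotypes not colliding with `used_keys`.

    Returns the clonotypes and the number of accidental key collisions
    encountered (redrawn, and reported in the table metadata).
    """
    v_suffix = [s.sequence[s.anchor_offset :] for s in reference.v_segments]
    j_prefix = [s.sequence[: s.anchor_offset + 3] for s in reference.j_segments]
    v_names = [s.name for s in reference.v_segments]
    j_names = [s.name for s in reference.j_segments]
    out: list[Clonotype] = []
    collisions = 0
    while len(out) < n:
        m = n - len(out)
        vi = rng.integers(len(v_suffix), size=m)
        ji = rng.integers(len(j_prefix), size=m)
        ins_len = rng.integers(0, max_insert + 1, size=m)
        pool = "".join(_BASES[b] for b in rng.integers(0, 4, size=int(ins_len.sum())))
        offset = 0
        for k in range(m):
            L = int(ins_len[k])
            insert = pool[offset : offset + L]
            offset += L
            junction = v_suffix[vi[k]] + insert + j_prefix[ji[k]]
            key = (v_names[vi[k]], j_names[ji[k]], junction)
            if key in used_keys:
                collisions += 1
                continue
            used_keys.add(key)
            aa, productive = translate_junction(junction)
            out.append(Clonotype(key[0], key[1], junction, aa, productive, 1))
    return out, collisions


def simulate_cohort(
    model: SharingModel, reference: GermlineReference
) -> dict[str, ClonotypeTable]:
    """Generate per-(patient, compartment) clonotype tables with planted sharing.

    Each compartment pool is built by first copying floor(theta * pool_size)
    clonotypes from every sharing source (provenance recorded per clone),
    then filling with novel clonotypes; clone counts follow a truncated
    power law rescaled to ``cells_per_compartment``.  Keys are unique
    across the whole cohort by construction (collisions redrawn + counted),
    so set intersections equal the planted provenance exactly.
    """
    model.validate()
    order = model._topological_order()
    root = np.random.SeedSequence(model.seed)
    patient_seeds = root.spawn(model.patients)
    used_keys: set = set()
    tables: dict[str, ClonotypeTable] = {}
    for p in range(model.patients):
        rng = np.random.default_rng(patient_seeds[p])
        patient = f"P{p + 1}"
        pools: dict[str, list[Clonotype]] = {}
        prov: dict[str, list[str]] = {}
        collisions = 0
        for comp in order:
            pool_size = model.pool_size(comp)
            clones: list[Clonotype] = []
            provenance: list[str] = []
            seen_here: set = set()
            for (src, tgt), theta in sorted(model.sharing_fractions.items()):
                if tgt != comp or theta <= 0:
                    continue
                n_copy = math.floor(theta * pool_size)
                src_pool = pools[src]
                idx = rng.choice(len(src_pool), size=min(n_copy, len(src_pool)), replace=False)
                for i in idx:
                    c = src_pool[i]
                    if c.key in seen_here:  # copied via two sources
                        collisions += 1
                        continue
                    seen_here.add(c.key)
                    clones.append(c)
                    provenance.append(src)
            novel, n_coll = _novel_clonotypes(
                rng, reference, used_keys, pool_size - len(clones)
            )
            collisions += n_coll
            for c in novel:
                seen_here.add(c.key)
                clones.append(c)
                provenance.append("novel")
            sizes = _powerlaw_sizes(rng, len(clones), model.powerlaw_alpha, pool_size)
            counts = _scale_counts(sizes, model.cells_per_compartment)
            clones = [c._replace(count=int(n)) for c, n in zip(clones, counts)]
            pools[comp] = clones
            prov[comp] = provenance
        for comp in model.compartments:  # stable output order
            site, subset = comp.split("_", 1)
            table = ClonotypeTable.from_clonotypes(
                pools[comp],
                sample_id=f"{patient}_{comp}",
                patient=patient,
                site=site,
                subset=subset,
                junction_collisions=collisions,
            )
            table.df["provenance"] = prov[comp]
            tables[table.sample_id] = table
    return tables


# ---------------------------------------------------------------------------
# barcodes and reads


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def design_barcodes(
    n: int, length: int = 8, min_distance: int = 3, seed: int = 0
) -> list[str]:
    """Random barcode set with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        cand = _random_seq(rng, length)
        if all(_hamming(cand, b) >= min_distance for b in barcodes):
            barcodes.append(cand)
        attempts += 1
        if attempts > 200_000:
            raise InvalidConfiguration(
                f"cannot place {n} barcodes of length {length} at distance {min_distance}"
            )
    return barcodes


def _validate_barcodes(barcodes: Iterable[str], min_distance: int = 3) -> None:
    barcodes = list(barcodes)
    if len(set(barcodes)) != len(barcodes):
        raise InvalidConfiguration("duplicate barcodes")
    if len({len(b) for b in barcodes}) > 1:
        raise InvalidConfiguration("barcodes must have equal length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if _hamming(a, b) < min_distance:
                raise InvalidConfiguration(
                    f"barcodes {a} and {b} closer than Hamming distance {min_distance}"
                )


def _read_core(clonotype_row, reference: GermlineReference) -> str:
    """Amplicon body for a clonotype: V + junction-insert + J (anchors shared)."""
    v = reference.v_by_name(clonotype_row.v_call)
    j = reference.j_by_name(clonotype_row.j_call)
    return (
        v.sequence[: v.anchor_offset]
        + clonotype_row.junction
        + j.sequence[j.anchor_offset + 3 :]
    )


def emit_reads(
    tables: dict[str, ClonotypeTable],
    reference: GermlineReference,
    barcode_map: dict[str, str],
    depth_per_clonotype_cell: float = 1.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> Iterator[ReadRecord]:
    """Yield barcoded 5'RACE-style reads for every clonotype table.

    Read layout: barcode + universal adapter + V + junction + J +
    reverse-complemented constant-region primer site.  Each clonotype
    emits round(count * depth_per_clonotype_cell) reads; substitution
    errors are i.i.d. per base at ``error_rate``.
    """
    if not 0.0 <= error_rate < 0.5:
        raise InvalidConfiguration("error_rate must be in [0, 0.5)")
    _validate_barcodes([barcode_map[s] for s in tables], min_distance=3)
    rng = np.random.default_rng(seed)
    primer_site = reference.c_primer_sites[-1]  # beta-chain constant primer
    q = 40 if error_rate == 0 else int(min(40, max(2, round(-10 * math.log10(error_rate)))))
    qchar = chr(33 + q)
    for sample_id, table in tables.items():
        prefix = barcode_map[sample_id] + reference.adapter
        serial = 0
        for row in table.df.itertuples(index=False):
            n_reads = round(row.duplicate_count * depth_per_clonotype_cell)
            if n_reads <= 0:
                continue
            seq = prefix + _read_core(row, reference) + primer_site
            L = len(seq)
            truth = f"{row.v_call}|{row.j_call}|{row.junction}"
            n_err = rng.binomial(L, error_rate, size=n_reads) if error_rate else None
            for r in range(n_reads):
                s = seq
                if n_err is not None and n_err[r]:
                    pos = rng.choice(L, size=n_err[r], replace=False)
                    chars = list(s)
                    for pidx in pos:
                        alt = _BASES.replace(chars[pidx], "")
                        chars[pidx] = alt[rng.integers(3)]
                    s = "".join(chars)
                yield ReadRecord(
                    read_id=f"{sample_id}.{serial}",
                    sequence=s,
                    qualities=qchar * L,
                    true_sample=sample_id,
                    true_clonotype=truth,
                )
                serial += 1


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    """Write records as Phred+33 FASTQ, ground truth in the description."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"@{rec.read_id} {rec.true_sample}|{rec.true_clonotype}\n"
                f"{rec.sequence}\n+\n{rec.qualities}\n"
            )
            n += 1
    return n


def write_barcode_tsv(barcode_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tbarcode\n")
        for sample, bc in barcode_map.items():
            fh.write(f"{sample}\t{bc}\n")


def read_barcode_tsv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                sample, bc = line.rstrip("\n").split("\t")
                out[sample] = bc
    return out
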