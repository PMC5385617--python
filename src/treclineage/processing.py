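"""From barcoded 5'RACE amplicon FASTQ to per-sample clonotype tables.

Stages, in pipeline order: demultiplex on the sample barcode prefix,
trim the universal adapter and the constant-region primer site, assign
V and J germline segments by semi-global alignment (segment fully
aligned, read overhangs free), extract the CDR3 junction between the
conserved anchors, and count clonotypes keyed by
(v_call, j_call, junction nucleotide sequence).

``process_run`` streams a whole FASTQ through these stages with exact
read-count conservation; identical sequences are collapsed before
alignment so deep error-free samples cost one alignment per clonotype.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .germline import GermlineReference, InvalidConfiguration
from .synthetic import ReadRecord, _hamming
from .tables import Clonotype, ClonotypeTable, translate_junction

__all__ = [
    "Scoring",
    "DEFAULT_SCORING",
    "AssignmentResult",
    "TrimResult",
    "JunctionResult",
    "DemuxResult",
    "read_fastq",
    "demultiplex",
    "trim_race_ends",
    "assign_vj",
    "extract_junction",
    "build_clonotype_table",
    "subsample_table",
    "pool_tables",
    "process_run",
    "parse_sample_id",
]


@dataclass(frozen=True)
class Scoring:
    """Alignment scores; a gap of length k costs gap_open + (k-1)*gap_extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


def make_aligner(scoring: Scoring = DEFAULT_SCORING) -> Align.PairwiseAligner:
    """Fit aligner: query (segment) aligned end to end, read overhangs free."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # gaps in the query (segment) strand at either end consume read bases
    # for free -> semi-global with free end gaps on the read
    aligner.end_deletion_score = 0.0
    return aligner


class TrimResult(NamedTuple):
    sequence: str
    status: str  # "ok" | "no_c_primer" | "too_short"


class JunctionResult(NamedTuple):
    junction: str
    junction_aa: str
    productive: bool
    status: str  # "ok" | "anchor_missing"


@dataclass(frozen=True)
class AssignmentResult:
    """Best V/J calls with scores; ``passed`` is False on ties or weak hits."""

    v_call: str
    j_call: str
    v_score: float
    j_score: float
    v_second_score: float
    j_second_score: float
    passed: bool


@dataclass
class DemuxResult:
    by_sample: dict[str, list[ReadRecord]]
    undetermined: list[ReadRecord]

    @property
    def counts(self) -> dict[str, int]:
        out = {s: len(reads) for s, reads in self.by_sample.items()}
        out["undetermined"] = len(self.undetermined)
        return out


# ---------------------------------------------------------------------------
# FASTQ input


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a FASTQ; simulator ground truth in the description is kept."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            read_id, _, desc = title.partition(" ")
            true_sample, true_clone = "", ""
            if "|" in desc:
                true_sample, _, true_clone = desc.partition("|")
            yield ReadRecord(read_id, seq, qual, true_sample, true_clone)


# ---------------------------------------------------------------------------
# demultiplexing


def _check_barcode_set(barcode_map: dict[str, str], max_mismatch: int) -> int:
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise InvalidConfiguration("duplicate barcodes")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise InvalidConfiguration("barcodes must have equal length")
    if len(barcodes) > 1:
        min_dist = min(
            _hamming(a, b)
            for i, a in enumerate(barcodes)
            for b in barcodes[i + 1 :]
        )
        if not max_mismatch < min_dist / 2:
            raise InvalidConfiguration(
                f"max_mismatch={max_mismatch} not below half the minimum "
                f"pairwise barcode distance ({min_dist})"
            )
    return lengths.pop()


def _match_barcode(
    prefix: str,
    exact: dict[str, str],
    barcode_map: dict[str, str],
    max_mismatch: int,
) -> str | None:
    sample = exact.get(prefix)
    if sample is not None:
        return sample
    if max_mismatch == 0:
        return None
    hits = [
        s for s, b in barcode_map.items() if _hamming(prefix, b) <= max_mismatch
    ]
    return hits[0] if len(hits) == 1 else None


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_map: dict[str, str],
    max_mismatch: int = 1,
) -> DemuxResult:
    """Assign each read to the unique barcode within ``max_mismatch`` of its
    prefix (else route to undetermined) and trim the barcode."""
    bc_len = _check_barcode_set(barcode_map, max_mismatch)
    exact = {b: s for s, b in barcode_map.items()}
    result = DemuxResult({s: [] for s in barcode_map}, [])
    for read in reads:
        sample = _match_barcode(read.sequence[:bc_len], exact, barcode_map, max_mismatch)
        if sample is None:
            result.undetermined.append(read)
        else:
            result.by_sample[sample].append(
                ReadRecord(
                    read.read_id,
                    read.sequence[bc_len:],
                    read.qualities[bc_len:],
                    read.true_sample,
                    read.true_clonotype,
                )
            )
    return result


# ---------------------------------------------------------------------------
# adapter / primer trimming


def _find_primer_site(seq: str, site: str, max_mismatch: int) -> int:
    """Rightmost start of `site` in `seq` with <= max_mismatch substitutions, or -1."""
    pos = seq.rfind(site)
    if pos >= 0 or max_mismatch == 0:
        return pos
    m = len(site)
    for start in range(len(seq) - m, -1, -1):
        window = seq[start : start + m]
        mism = 0
        for a, b in zip(window, site):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return start
    return -1


def trim_race_ends(
    sequence: str, reference: GermlineReference, max_primer_mismatch: int = 1
) -> TrimResult:
    """Strip the 5' universal-adapter stub and everything from the
    constant-region primer site (reverse-complement match, tolerant to
    ``max_primer_mismatch`` substitutions) to the 3' end.

    Reads without a detectable primer site are flagged ``no_c_primer``
    but retained; reads shorter than adapter + primer are ``too_short``.
    """
    adapter_len = len(reference.adapter)
    min_primer = min(len(p) for p in reference.c_primers)
    if len(sequence) < adapter_len + min_primer:
        return TrimResult(sequence, "too_short")
    body = sequence[adapter_len:]
    best = -1
    for site in reference.c_primer_sites:
        pos = _find_primer_site(body, site, max_primer_mismatch)
        best = max(best, pos)
    if best < 0:
        return TrimResult(body, "no_c_primer")
    return TrimResult(body[:best], "ok")


# ---------------------------------------------------------------------------
# V/J assignment and junction extraction


def _best_two(
    aligner: Align.PairwiseAligner, sequence: str, segments
) -> tuple[str, float, float, int]:
    """Top segment name, its score, the runner-up score, and the top length.

    Ties broken toward the lexicographically smaller name so results are
    deterministic; a surviving tie is reported via equal scores.
    """
    scored = sorted(
        ((float(aligner.score(sequence, seg.sequence)), seg.name, len(seg.sequence)) for seg in segments),
        key=lambda t: (-t[0], t[1]),
    )
    top_score, top_name, top_len = scored[0]
    second = scored[1][0] if len(scored) > 1 else float("-inf")
    return top_name, top_score, second, top_len


def assign_vj(
    sequence: str,
    reference: GermlineReference,
    scoring: Scoring = DEFAULT_SCORING,
    min_score_fraction: float = 0.6,
) -> AssignmentResult:
    """Call the best-scoring V and J segment by semi-global alignment.

    ``passed`` is False if either top score falls below
    ``min_score_fraction * match * segment_length`` or ties the runner-up
    (ambiguous call).
    """
    if not reference.v_segments or not reference.j_segments:
        raise InvalidConfiguration("empty germline reference")
    aligner = make_aligner(scoring)
    v_call, v_score, v_second, v_len = _best_two(aligner, sequence, reference.v_segments)
    j_call, j_score, j_second, j_len = _best_two(aligner, sequence, reference.j_segments)
    ok = (
        v_score >= min_score_fraction * scoring.match * v_len
        and j_score >= min_score_fraction * scoring.match * j_len
        and v_score != v_second
        and j_score != j_second
    )
    return AssignmentResult(v_call, j_call, v_score, j_score, v_second, j_second, ok)


def _segment_to_read_map(
    aligner: Align.PairwiseAligner, sequence: str, segment_seq: str
) -> dict[int, int]:
    """Map aligned segment positions to read positions (gapped ones absent)."""
    aln = aligner.align(sequence, segment_seq)[0]
    target_blocks, query_blocks = aln.aligned
    mapping: dict[int, int] = {}
    for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
        for offset in range(q1 - q0):
            mapping[q0 + offset] = t0 + offset
    return mapping


def extract_junction(
    sequence: str,
    assignment: AssignmentResult,
    reference: GermlineReference,
    scoring: Scoring = DEFAULT_SCORING,
) -> JunctionResult:
    """CDR3 junction between the V-anchor Cys codon and the J-anchor Phe
    codon, both inclusive, in read coordinates of the assigned segments."""
    v = reference.v_by_name(assignment.v_call)
    j = reference.j_by_name(assignment.j_call)
    aligner = make_aligner(scoring)
    v_map = _segment_to_read_map(aligner, sequence, v.sequence)
    j_map = _segment_to_read_map(aligner, sequence, j.sequence)
    start = v_map.get(v.anchor_offset)
    end = j_map.get(j.anchor_offset + 2)
    if start is None or end is None or end < start:
        return JunctionResult("", "", False, "anchor_missing")
    junction = sequence[start : end + 1]
    aa, productive = translate_junction(junction)
    return JunctionResult(junction, aa, productive, "ok")


# ---------------------------------------------------------------------------
# table construction and manipulation


def build_clonotype_table(
    clonotypes: Iterable[Clonotype],
    sample_id: str,
    min_count: int = 1,
    patient: str = "",
    site: str = "",
    subset: str = "",
    **meta,
) -> ClonotypeTable:
    """Group by (v_call, j_call, junction), sum counts, drop below min_count."""
    agg: dict[tuple, list] = {}
    for c in clonotypes:
        if c.key in agg:
            agg[c.key][5] += c.count
        else:
            agg[c.key] = list(c)
    merged = [
        Clonotype(*row) for row in agg.values() if row[5] >= min_count
    ]
    if not merged:
        meta["empty_table"] = True
    return ClonotypeTable.from_clonotypes(
        merged, sample_id, patient=patient, site=site, subset=subset, **meta
    )


def subsample_table(table: ClonotypeTable, depth: int, seed: int = 0) -> ClonotypeTable:
    """Draw ``depth`` reads without replacement (multivariate hypergeometric)."""
    total = table.total_count
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total_count {total}")
    if depth == total:
        return table
    rng = np.random.default_rng(seed)
    counts = table.df["duplicate_count"].to_numpy()
    drawn = rng.multivariate_hypergeometric(counts, depth)
    df = table.df.copy()
    df["duplicate_count"] = drawn
    df = df[df["duplicate_count"] > 0]
    return ClonotypeTable(
        table.sample_id,
        df,
        patient=table.patient,
        site=table.site,
        subset=table.subset,
        meta={**table.meta, "subsampled_to": depth},
    )


def pool_tables(
    tables: Iterable[ClonotypeTable], sample_id: str | None = None, force: bool = False
) -> ClonotypeTable:
    """Union clonotype keys and sum counts across tables.

    Inputs are expected to share (site, subset) — the pooling the study
    applies across patients — unless ``force`` is given.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("nothing to pool")
    groups = {(t.site, t.subset) for t in tables if len(t)}
    if len(groups) > 1 and not force:
        raise ValueError(
            f"tables span multiple (site, subset) groups {sorted(groups)}; "
            "pass force=True to pool anyway"
        )
    frames = [t.df for t in tables if len(t)]
    if not frames:
        return ClonotypeTable(sample_id or "pool", tables[0].df.iloc[0:0].copy())
    cat = pd.concat(frames, ignore_index=True)
    keep_first = [
        c
        for c in cat.columns
        if c not in ("duplicate_count", "v_call", "j_call", "junction", "sequence_id")
    ]
    agg_spec = {"duplicate_count": "sum", **{c: "first" for c in keep_first}}
    pooled = (
        cat.groupby(["v_call", "j_call", "junction"], sort=True, as_index=False)
        .agg(agg_spec)
    )
    site, subset = (groups.pop() if len(groups) == 1 else ("", ""))
    if sample_id is None:
        sample_id = f"pool_{site}_{subset}" if site else "pool"
    return ClonotypeTable(sample_id, pooled, site=site, subset=subset)


# ---------------------------------------------------------------------------
# whole-run driver


def parse_sample_id(sample_id: str) -> tuple[str, str, str]:
    """Split 'P1_TI_Treg' into (patient, site, subset); blanks if unparseable."""
    parts = sample_id.split("_")
    if len(parts) >= 3:
        return parts[0], parts[1], "_".join(parts[2:])
    return "", "", ""


def process_run(
    fastq_path,
    barcode_map: dict[str, str],
    reference: GermlineReference,
    max_mismatch: int = 1,
    scoring: Scoring = DEFAULT_SCORING,
    min_score_fraction: float = 0.6,
    min_count: int = 1,
    productive_only: bool = False,
    subsample_depth: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, ClonotypeTable], dict]:
    """Run the full chain on one FASTQ, returning per-sample tables and a
    per-stage count report (reads in == assigned + undetermined, exactly).

    Identical read sequences are collapsed up front and V/J assignment is
    cached per unique trimmed sequence, so cost scales with sequence
    diversity rather than depth.
    """
    bc_len = _check_barcode_set(barcode_map, max_mismatch)
    exact = {b: s for s, b in barcode_map.items()}
    per_sample: dict[str, Counter] = {s: Counter() for s in barcode_map}
    n_reads = 0
    n_undetermined = 0
    for read in read_fastq(fastq_path):
        n_reads += 1
        sample = _match_barcode(read.sequence[:bc_len], exact, barcode_map, max_mismatch)
        if sample is None:
            n_undetermined += 1
        else:
            per_sample[sample][read.sequence[bc_len:]] += 1

    assignment_cache: dict[str, tuple] = {}

    def annotate(trimmed: str):
        hit = assignment_cache.get(trimmed)
        if hit is None:
            assignment = assign_vj(trimmed, reference, scoring, min_score_fraction)
            if not assignment.passed:
                hit = ("assignment_failed", None)
            else:
                jr = extract_junction(trimmed, assignment, reference, scoring)
                if jr.status != "ok":
                    hit = (jr.status, None)
                else:
                    hit = (
                        "ok",
                        (assignment.v_call, assignment.j_call, jr.junction,
                         jr.junction_aa, jr.productive),
                    )
            assignment_cache[trimmed] = hit
        return hit

    tables: dict[str, ClonotypeTable] = {}
    report: dict = {
        "reads_in": n_reads,
        "undetermined": n_undetermined,
        "samples": {},
    }
    for sample, seq_counts in per_sample.items():
        tallies = Counter()
        clonotypes: list[Clonotype] = []
        for seq, count in seq_counts.items():
            trimmed = trim_race_ends(seq, reference)
            tallies[f"trim_{trimmed.status}"] += count
            if trimmed.status == "too_short":
                continue
            status, fields = annotate(trimmed.sequence)
            tallies[status] += count
            if fields is None:
                continue
            v_call, j_call, junction, aa, productive = fields
            if productive_only and not productive:
                tallies["nonproductive_dropped"] += count
                continue
            clonotypes.append(Clonotype(v_call, j_call, junction, aa, productive, count))
        patient, site, subset = parse_sample_id(sample)
        table = build_clonotype_table(
            clonotypes, sample, min_count=min_count,
            patient=patient, site=site, subset=subset,
        )
        dropped = sum(seq_counts.values()) - sum(tallies[k] for k in ("trim_too_short",)) \
            - table.total_count - tallies["assignment_failed"] - tallies["anchor_missing"] \
            - tallies["nonproductive_dropped"]
        tallies["min_count_dropped"] = dropped
        if subsample_depth is not None and table.total_count >= subsample_depth:
            table = subsample_table(table, subsample_depth, seed=seed)
        tables[sample] = table
        report["samples"][sample] = {
            "reads": int(sum(seq_counts.values())),
            "unique_sequences": len(seq_counts),
            "clonotypes": table.n_unique,
            "tallies": dict(tallies),
        }
    report["assigned"] = int(sum(r["reads"] for r in report["samples"].values()))
    return tables, report
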