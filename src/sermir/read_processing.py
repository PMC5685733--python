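"""Adapter trimming, read collapsing and exact-match genome alignment.

The aligner is a deliberately simple exact-substring search over toy
genomes with a bounded 3' soft-clip (candidate non-templated tails).
Downstream rules only ever use perfect alignments plus <= 3 clipped 3'
bases, so a scoring aligner would add nothing here; full-genome-scale
alignment is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from . import io
from ._seq import normalize, revcomp

TRIMMED = "trimmed"
UNTRIMMED = "untrimmed"
TOO_SHORT = "too_short"


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    min_insert: int = 10,
) -> tuple[str, str]:
    """Remove a 3' adapter from one read.

    Scans for the longest read suffix matching a prefix of the adapter
    (overlap >= `min_overlap`, mismatch rate <= `max_error_rate`), i.e.
    the earliest cut position wins. Returns (insert, status) with status
    one of ``trimmed`` / ``untrimmed`` / ``too_short``. Untrimmed reads
    are returned unchanged; inserts shorter than `min_insert` after
    trimming are flagged ``too_short``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = normalize(read)
    adapter = normalize(adapter)
    n = len(read)
    for i in range(0, n - min_overlap + 1):
        m = min(n - i, len(adapter))
        if m < min_overlap:
            break
        allowed = int(m * max_error_rate)
        mism = 0
        for a, b in zip(read[i:i + m], adapter[:m]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            insert = read[:i]
            return (insert, TOO_SHORT if len(insert) < min_insert else TRIMMED)
    return read, UNTRIMMED


def collapse_reads(
    fastq_by_sample: Mapping[str, object],
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    min_insert: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trim and collapse per-sample FASTQ into a unique-sequence table.

    `fastq_by_sample` maps sample id to either a FASTQ path or an
    iterable of (read_id, sequence). Returns (counts, stats): counts is
    a DataFrame indexed by sequence with one integer column per sample;
    stats counts reads per trimming status per sample.
    """
    counts: dict[str, dict[str, int]] = {}
    stats_rows = []
    samples = list(fastq_by_sample)
    for sid in samples:
        src = fastq_by_sample[sid]
        reads: Iterable[tuple[str, str]]
        if isinstance(src, (str, bytes)) or hasattr(src, "__fspath__"):
            reads = io.iter_fastq(src)
        else:
            reads = src
        tallied = {TRIMMED: 0, UNTRIMMED: 0, TOO_SHORT: 0}
        col = counts
        for _rid, seq in reads:
            insert, status = trim_adapter(seq, adapter, min_overlap, max_error_rate, min_insert)
            tallied[status] += 1
            if status == TOO_SHORT:
                continue
            row = col.setdefault(insert, {})
            row[sid] = row.get(sid, 0) + 1
        stats_rows.append({"sample": sid, **tallied})
    mat = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=samples).fillna(0).astype(int)
    mat.index.name = "sequence"
    mat = mat.sort_index()
    stats = pd.DataFrame(stats_rows).set_index("sample")
    return mat, stats


def match_calibrators(
    unique_sequences: pd.DataFrame,
    calibrators: Sequence,
    max_distance: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split unique sequences into calibrator counts and the remainder.

    Exact matches count toward their calibrator; sequences within edit
    distance <= `max_distance` of a calibrator are tallied as variants
    of the closest one (ties broken toward the lowest calibrator index)
    and withheld from genomic annotation. Returns
    (calibrator_counts, variant_table, remainder).
    """
    cal_names = [c.name for c in calibrators]
    cal_seqs = [normalize(c.sequence) for c in calibrators]
    exact = {s: i for i, s in enumerate(cal_seqs)}

    cal_counts = pd.DataFrame(
        0, index=pd.Index(cal_names, name="calibrator"), columns=unique_sequences.columns
    )
    variant_rows = []
    keep = []
    for seq in unique_sequences.index:
        hit = exact.get(seq)
        dist = 0
        if hit is None:
            best = None
            for i, cs in enumerate(cal_seqs):
                if abs(len(seq) - len(cs)) > max_distance:
                    continue
                d = edlib.align(seq, cs, task="distance", k=max_distance)["editDistance"]
                if d >= 0 and (best is None or d < best[0]):
                    best = (d, i)  # first index wins ties (lowest calibrator)
            if best is not None:
                dist, hit = best
        if hit is None:
            keep.append(seq)
            continue
        cal_counts.loc[cal_names[hit]] += unique_sequences.loc[seq]
        if dist > 0:
            variant_rows.append(
                {"calibrator": cal_names[hit], "sequence": seq, "distance": dist,
                 "total_count": int(unique_sequences.loc[seq].sum())}
            )
    variants = pd.DataFrame(
        variant_rows, columns=["calibrator", "sequence", "distance", "total_count"]
    )
    remainder = unique_sequences.loc[keep]
    return cal_counts, variants, remainder


@dataclass(frozen=True)
class AlignmentRecord:
    """One perfect genome alignment, possibly with a clipped 3' tail."""

    sequence: str
    contig: str
    start: int   # 0-based, genome coordinates of the aligned core
    end: int     # half-open
    strand: str
    clipped_tail: str  # 3' read bases not matching the genome ("" if none)
    saturated: bool = False


class GenomeIndex:
    """Exact-occurrence lookup over a small genome (both strands)."""

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs = {name: normalize(seq) for name, seq in contigs.items()}

    def find(self, core: str) -> list[tuple[str, int, str]]:
        """All (contig, start, strand) where `core` matches perfectly.

        A minus-strand hit means the read matches the reverse complement
        of the genome at [start, start+len(core)).
        """
        hits = []
        rc = revcomp(core)
        for contig, seq in self.contigs.items():
            for probe, strand in ((core, "+"), (rc, "-")):
                p = seq.find(probe)
                while p != -1:
                    hits.append((contig, p, strand))
                    p = seq.find(probe, p + 1)
        if rc == core:  # palindromic: drop duplicated strand listing
            seen = set()
            hits = [h for h in hits if (h[0], h[1]) not in seen and not seen.add((h[0], h[1]))]
        return hits


def align_unique_sequences(
    sequences: Iterable[str],
    genome: Mapping[str, str] | GenomeIndex,
    max_hits: int = 10,
    max_tail: int = 3,
    min_core: int = 10,
) -> pd.DataFrame:
    """Align unique sequences to the genome, allowing a short 3' soft-clip.

    A sequence is reported where it matches the genome perfectly, or
    perfectly except for at most `max_tail` trailing 3' bases (recorded
    as `clipped_tail`, the non-templated-addition candidate). Clipping is
    greedy template-first: the smallest clip with at least one perfect
    hit is used. Internal mismatches are never allowed. If more than
    `max_hits` placements exist, the `max_hits` leftmost are kept and
    flagged saturated. Sequences with no placement get a single row with
    empty contig and status ``unmapped``.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    rows = []
    for seq in sequences:
        seq = normalize(seq)
        placed = False
        for tail_len in range(0, max_tail + 1):
            core = seq[: len(seq) - tail_len] if tail_len else seq
            if len(core) < min_core:
                break
            hits = index.find(core)
            if not hits:
                continue
            hits.sort(key=lambda h: (h[0], h[1], h[2]))
            saturated = len(hits) > max_hits
            for contig, start, strand in hits[:max_hits]:
                rows.append(
                    {
                        "sequence": seq, "contig": contig, "start": start,
                        "end": start + len(core), "strand": strand,
                        "clipped_tail": seq[len(core):], "saturated": saturated,
                        "status": "aligned",
                    }
                )
            placed = True
            break
        if not placed:
            rows.append(
                {"sequence": seq, "contig": "", "start": -1, "end": -1,
                 "strand": "", "clipped_tail": "", "saturated": False,
                 "status": "unmapped"}
            )
    return pd.DataFrame(
        rows,
        columns=["sequence", "contig", "start", "end", "strand",
                 "clipped_tail", "saturated", "status"],
    )


def length_distribution(
    unique_sequences: pd.DataFrame,
    class_of_sequence: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read-count length histogram, optionally split by RNA class.

    Counts reads (not unique sequences) per insert length; sequences
    missing from `class_of_sequence` are labelled ``unassigned``.
    """
    lengths = unique_sequences.index.str.len()
    totals = unique_sequences.sum(axis=1)
    if class_of_sequence is None:
        cls = pd.Series("all", index=unique_sequences.index)
    else:
        cls = pd.Series(
            [class_of_sequence.get(s, "unassigned") for s in unique_sequences.index],
            index=unique_sequences.index,
        )
    df = pd.DataFrame({"length": lengths, "rna_class": cls, "reads": totals})
    out = df.groupby(["rna_class", "length"], sort=True)["reads"].sum().reset_index()
    return out
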