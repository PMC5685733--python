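"""Hierarchical annotation of unique sequences and count-matrix assembly.

Sequences are first assigned to mature-miRNA loci by strand-aware
genomic overlap (htseq-style); only sequences untouched by that stage
are then matched against the ncRNA database by exact sense-strand
substring containment. Multi-assigned counts are duplicated per
feature, not split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Priority used to resolve multi-class sequences in the composition
#: summary (a declared convention; the cascade itself never mixes
#: miRNA with ncRNA assignments).
CLASS_PRIORITY = ("miRNA", "scRNA", "tRNA", "snoRNA", "snRNA", "rRNA", "Y-RNA", "lncRNA")


def assign_mirna(alignments: pd.DataFrame, mirna_loci) -> pd.DataFrame:
    """Assign sequences to every mature locus any alignment overlaps.

    Overlap is >= 1 base of the aligned core, on the same contig and
    strand. Returns one row per (sequence, locus) with the locus and
    mature names.
    """
    rows = []
    aligned = alignments[alignments["status"] == "aligned"]
    for _, aln in aligned.iterrows():
        for loc in mirna_loci:
            if loc.contig != aln["contig"] or loc.strand != aln["strand"]:
                continue
            if aln["start"] < loc.end and loc.start < aln["end"]:
                rows.append(
                    {
                        "sequence": aln["sequence"],
                        "feature": loc.mature_name,
                        "locus": loc.name,
                        "kind": "miRNA",
                        "via": "genome-overlap",
                    }
                )
    df = pd.DataFrame(rows, columns=["sequence", "feature", "locus", "kind", "via"])
    return df.drop_duplicates(ignore_index=True)


def assign_ncrna(sequences, ncrna_db) -> pd.DataFrame:
    """Assign non-miRNA sequences to ncRNA entries containing them.

    Sense-strand exact substring containment; a fragment contained in
    several entries is assigned to each and flagged multi.
    """
    rows = []
    for seq in sequences:
        hits = [e for e in ncrna_db if seq in e.sequence]
        for e in hits:
            rows.append(
                {
                    "sequence": seq,
                    "feature": e.entry_id,
                    "kind": f"ncRNA:{e.rna_class}",
                    "via": "db-substring",
                    "multi": len(hits) > 1,
                }
            )
    return pd.DataFrame(rows, columns=["sequence", "feature", "kind", "via", "multi"])


def annotate(alignments: pd.DataFrame, mirna_loci, ncrna_db) -> pd.DataFrame:
    """Run the full cascade: miRNA loci first, ncRNA database second."""
    mirna = assign_mirna(alignments, mirna_loci)
    assigned = set(mirna["sequence"])
    rest = [s for s in alignments["sequence"].unique() if s not in assigned]
    ncrna = assign_ncrna(rest, ncrna_db)
    if not ncrna.empty:
        ncrna = ncrna.drop(columns=["multi"])
        ncrna["locus"] = ""
    return pd.concat([mirna, ncrna], ignore_index=True)


def summarize_classes(
    assignments: pd.DataFrame,
    unique_sequences: pd.DataFrame,
    priority=CLASS_PRIORITY,
) -> pd.DataFrame:
    """Read-count fraction per RNA class per sample.

    Sequences assigned to entries of several ncRNA classes are resolved
    by the priority list; the remainder (unassigned reads) makes the
    fractions sum to <= 1.
    """
    cls_by_seq: dict[str, str] = {}
    rank = {c: i for i, c in enumerate(priority)}
    for seq, grp in assignments.groupby("sequence"):
        classes = {k.split(":", 1)[-1] if k.startswith("ncRNA:") else k for k in grp["kind"]}
        cls_by_seq[seq] = min(classes, key=lambda c: rank.get(c, len(rank)))

    totals = unique_sequences.sum(axis=0).astype(float)
    frames = {}
    for cls in list(priority):
        seqs = [s for s, c in cls_by_seq.items() if c == cls]
        sub = unique_sequences.loc[unique_sequences.index.intersection(seqs)]
        frames[cls] = sub.sum(axis=0) / totals.replace(0, pd.NA)
    out = pd.DataFrame(frames).T
    out.index.name = "rna_class"
    return out.fillna(0.0)


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample library sizes
    and normalization factors (default 1)."""

    counts: pd.DataFrame
    kind: str
    lib_sizes: pd.Series
    norm_factors: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors

    def cpm(self) -> pd.DataFrame:
        from .normalization import cpm_normalize

        return cpm_normalize(self.counts, self.norm_factors, self.lib_sizes)


def build_matrices(
    assignments: pd.DataFrame,
    unique_sequences: pd.DataFrame,
    alignments: pd.DataFrame,
    calibrator_counts: pd.DataFrame,
    isomir_labels: pd.DataFrame | None = None,
) -> dict[str, CountMatrix]:
    """Assemble {mirna, ncrna, calibrator} count matrices (isomir too when
    classified records are supplied).

    The mature-miRNA matrix sums, per mature name, the counts of every
    sequence assigned to any locus of that mature (multi-locus counts
    are added once per assigned locus). Library size is the total count
    of aligned biological sequences — calibrators are spike-ins, not
    library content, and are excluded so cpm stays comparable when the
    spike ratio varies.
    """
    samples = list(unique_sequences.columns)
    if list(calibrator_counts.columns) != samples:
        raise ValueError("sample sets of count inputs are inconsistent")

    aligned_seqs = alignments.loc[alignments["status"] == "aligned", "sequence"].unique()
    lib_sizes = unique_sequences.loc[
        unique_sequences.index.intersection(aligned_seqs)
    ].sum(axis=0)
    if (lib_sizes == 0).any():
        empty = lib_sizes.index[lib_sizes == 0].tolist()
        raise ValueError(f"samples with zero aligned reads: {empty}")

    mirna_asn = assignments[assignments["kind"] == "miRNA"]
    # one row per (sequence, locus): counts duplicated per locus, then
    # summed into the mature name
    m = (
        mirna_asn.merge(unique_sequences, left_on="sequence", right_index=True)
        .groupby("feature")[samples]
        .sum()
    )
    mirna = CountMatrix(m.astype(int), "miRNA", lib_sizes)

    nc_asn = assignments[assignments["kind"].str.startswith("ncRNA:")]
    if not nc_asn.empty:
        nc = nc_asn.merge(unique_sequences, left_on="sequence", right_index=True)
        nc = nc.set_index(
            pd.MultiIndex.from_frame(nc[["feature", "sequence"]], names=["entry", "fragment"])
        )[samples]
        nc = nc.groupby(level=["entry", "fragment"]).sum()
    else:
        nc = pd.DataFrame(columns=samples)
    ncrna = CountMatrix(nc.astype(int), "ncRNA", lib_sizes)

    calibrator = CountMatrix(
        calibrator_counts.astype(int), "calibrator", calibrator_counts.sum(axis=0)
    )

    out = {"mirna": mirna, "ncrna": ncrna, "calibrator": calibrator}
    if isomir_labels is not None:
        from .isomir import isomir_count_matrix

        iso_counts, _tally = isomir_count_matrix(isomir_labels, unique_sequences)
        out["isomir"] = CountMatrix(iso_counts, "isomiR", lib_sizes)
    return out
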