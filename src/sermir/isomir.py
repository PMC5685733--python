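"""IsomiR classification.

A miRNA-assigned sequence is described relative to the canonical mature
ends of its locus: a signed 5' offset (positive = trimmed, negative =
templated extension), 3' trimming or templated tailing, and a
non-templated 3' addition (NTA — the clipped tail the aligner could not
place on the genome). Reads with internal mismatches never align under
the perfect-match rule and therefore never produce a record, matching
the filter that discards mismatched isomiRs as possible sequencing
errors while keeping 3'-NTA ones.

Labels follow the boxplot-facet convention: lower case marks trimmed
bases, upper case marks tailed bases, rendered in the RNA alphabet,
e.g. ``3p:gu`` (two bases trimmed), ``3p:GU`` (templated tail),
``nta:AU`` (non-templated tail), ``5p:a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import revcomp, to_rna

MAX_FIVE_OFFSET = 5
MAX_THREE_TRIM = 5
MAX_THREE_TAIL = 5
MAX_NTA = 3


@dataclass(frozen=True)
class IsomiRRecord:
    mature_name: str
    sequence: str
    locus: str
    five_prime_offset: int  # positive = trimmed, negative = extended
    five_ext: str           # templated 5' extension bases (read orientation)
    three_prime_trim: int
    three_prime_tail: str   # templated 3' extension bases
    nta: str                # non-templated 3' bases

    @property
    def is_canonical(self) -> bool:
        return (
            self.five_prime_offset == 0
            and self.three_prime_trim == 0
            and not self.three_prime_tail
            and not self.nta
        )

    @property
    def types(self) -> tuple[str, ...]:
        t = []
        if self.five_prime_offset != 0:
            t.append("5p-mod")
        if self.three_prime_trim > 0:
            t.append("3p-trim")
        if self.three_prime_tail:
            t.append("3p-tail")
        if self.nta:
            t.append("nta")
        return tuple(t)

    @property
    def label(self) -> str:
        if self.is_canonical:
            return "canonical"
        parts = []
        if self.five_prime_offset > 0:
            parts.append("5p:" + to_rna(self._mature_prefix.lower()))
        elif self.five_prime_offset < 0:
            parts.append("5p:" + to_rna(self.five_ext.upper()))
        if self.three_prime_trim > 0:
            parts.append("3p:" + to_rna(self._mature_suffix.lower()))
        elif self.three_prime_tail:
            parts.append("3p:" + to_rna(self.three_prime_tail.upper()))
        if self.nta:
            parts.append("nta:" + to_rna(self.nta.upper()))
        return "|".join(parts)

    # The trimmed bases themselves are recoverable from the mature
    # sequence; they are attached at construction for labelling.
    _mature_prefix: str = ""
    _mature_suffix: str = ""


def classify_isomir(alignment, locus, ref) -> IsomiRRecord | None:
    """Classify one aligned sequence against one mature locus.

    `alignment` carries genome coordinates of the perfectly aligned core
    plus any clipped 3' tail; `locus` is the mature locus it overlaps;
    `ref` supplies genomic context for templated-extension bases.
    Returns None (reject) when an offset exceeds the isomiR window —
    such a sequence overlaps the locus but is not an isomiR of it.
    """
    g = ref.contigs[locus.contig]
    mature = ref.mature_sequence(locus)
    if locus.strand == "+":
        five_off = alignment["start"] - locus.start
        three_delta = alignment["end"] - locus.end
    else:
        five_off = locus.end - alignment["end"]
        three_delta = locus.start - alignment["start"]

    trim = max(0, -three_delta)
    ext = max(0, three_delta)
    nta = alignment["clipped_tail"]
    if abs(five_off) > MAX_FIVE_OFFSET or trim > MAX_THREE_TRIM:
        return None
    if ext > MAX_THREE_TAIL or len(nta) > MAX_NTA:
        return None

    if ext:
        if locus.strand == "+":
            tail = g[locus.end:locus.end + ext]
        else:
            tail = revcomp(g[locus.start - ext:locus.start])
    else:
        tail = ""
    if five_off < 0:
        if locus.strand == "+":
            five_ext = g[alignment["start"]:locus.start]
        else:
            five_ext = revcomp(g[locus.end:alignment["end"]])
    else:
        five_ext = ""

    return IsomiRRecord(
        mature_name=locus.mature_name,
        sequence=alignment["sequence"],
        locus=locus.name,
        five_prime_offset=int(five_off),
        five_ext=five_ext,
        three_prime_trim=int(trim),
        three_prime_tail=tail,
        nta=nta,
        _mature_prefix=mature[:five_off] if five_off > 0 else "",
        _mature_suffix=mature[len(mature) - trim:] if trim > 0 else "",
    )


def classify_all(alignments: pd.DataFrame, assignments: pd.DataFrame, ref) -> pd.DataFrame:
    """Classify every miRNA-assigned sequence at every assigned locus.

    Multi-locus sequences are classified independently per locus.
    Returns a DataFrame of record fields plus the composed label and
    one boolean column per modification type.
    """
    loci = {loc.name: loc for loc in ref.mirna_loci}
    mirna_asn = assignments[assignments["kind"] == "miRNA"]
    aln_by_seq: dict[str, list] = {}
    aligned = alignments[alignments["status"] == "aligned"]
    for _, aln in aligned.iterrows():
        aln_by_seq.setdefault(aln["sequence"], []).append(aln)

    rows = []
    for _, asn in mirna_asn.iterrows():
        loc = loci[asn["locus"]]
        for aln in aln_by_seq.get(asn["sequence"], []):
            if aln["contig"] != loc.contig or aln["strand"] != loc.strand:
                continue
            if not (aln["start"] < loc.end and loc.start < aln["end"]):
                continue
            rec = classify_isomir(aln, loc, ref)
            if rec is None:
                continue
            rows.append(
                {
                    "sequence": rec.sequence,
                    "mature": rec.mature_name,
                    "locus": rec.locus,
                    "five_prime_offset": rec.five_prime_offset,
                    "five_ext": rec.five_ext,
                    "three_prime_trim": rec.three_prime_trim,
                    "three_prime_tail": rec.three_prime_tail,
                    "nta": rec.nta,
                    "label": rec.label,
                    "is_canonical": rec.is_canonical,
                    "is_5p_mod": "5p-mod" in rec.types,
                    "is_3p_trim": "3p-trim" in rec.types,
                    "is_3p_tail": "3p-tail" in rec.types,
                    "is_nta": "nta" in rec.types,
                }
            )
    cols = [
        "sequence", "mature", "locus", "five_prime_offset", "five_ext",
        "three_prime_trim", "three_prime_tail", "nta", "label", "is_canonical",
        "is_5p_mod", "is_3p_trim", "is_3p_tail", "is_nta",
    ]
    return pd.DataFrame(rows, columns=cols).drop_duplicates(
        subset=["sequence", "mature", "locus"], ignore_index=True
    )


def reconstruct_read(mature_seq: str, record: IsomiRRecord) -> str:
    """Rebuild the read sequence implied by a record (round-trip check)."""
    seq = mature_seq
    if record.five_prime_offset > 0:
        seq = seq[record.five_prime_offset:]
    elif record.five_prime_offset < 0:
        seq = record.five_ext + seq
    if record.three_prime_trim:
        seq = seq[: len(seq) - record.three_prime_trim]
    return seq + record.three_prime_tail + record.nta


def isomir_type_composition(records: pd.DataFrame) -> pd.Series:
    """Fractions of unique isomiRs per modification type.

    Unique isomiRs are distinct (mature, label) pairs, canonical
    excluded; a record carrying several modifications counts once per
    type, so fractions can sum to more than 1.
    """
    uniq = records.loc[~records["is_canonical"]].drop_duplicates(subset=["mature", "label"])
    n = len(uniq)
    flags = {"3p-trim": "is_3p_trim", "nta": "is_nta",
             "3p-tail": "is_3p_tail", "5p-mod": "is_5p_mod"}
    if n == 0:
        return pd.Series({t: float("nan") for t in flags}, name="fraction")
    return pd.Series({t: uniq[c].sum() / n for t, c in flags.items()}, name="fraction")


def isomir_count_matrix(
    records: pd.DataFrame, unique_sequences: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-(mature, label) count matrix plus unique-isomiR tally.

    Distinct sequences mapping to the same (mature, label) are merged
    with counts summed. The tally counts distinct non-canonical labels
    per mature name.
    """
    samples = list(unique_sequences.columns)
    if records.empty:
        empty = pd.DataFrame(
            columns=samples,
            index=pd.MultiIndex.from_arrays([[], []], names=["mature", "label"]),
        )
        return empty, pd.Series(dtype=int, name="unique_isomirs")
    merged = records.drop_duplicates(subset=["sequence", "mature", "label"]).merge(
        unique_sequences, left_on="sequence", right_index=True
    )
    mat = merged.groupby(["mature", "label"])[samples].sum().astype(int)
    tally = (
        records.loc[~records["is_canonical"]]
        .drop_duplicates(subset=["mature", "label"])
        .groupby("mature")["label"]
        .size()
        .rename("unique_isomirs")
    )
    return mat, tally
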