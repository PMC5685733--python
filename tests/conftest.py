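import pandas as pd
import pytest

from sermir import annotation, isomir
from sermir import read_processing as rp
from sermir import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_ref():
    return sd.build_toy_reference(seed=1)


@pytest.fixture(scope="session")
def cohort():
    meta, truth = sd.simulate_cohort(seed=1)
    return meta, truth


@pytest.fixture(scope="session")
def large_library(toy_ref, cohort):
    """One deeply sequenced sample (~5e4 miRNA reads) pushed through the
    whole read-level pipeline, with ground truth attached."""
    meta, _ = cohort
    profile = sd.SampleProfile(library_size=150_000)
    catalogue = sd.build_catalogue(toy_ref, profile, seed=2)
    reads, truth = sd.simulate_sample_reads(
        toy_ref, profile, meta.iloc[0], catalogue=catalogue, seed=3, sample_id="S1"
    )
    unique, trim_stats = rp.collapse_reads({"S1": reads}, profile.adapter)
    cal_counts, cal_variants, remainder = rp.match_calibrators(unique, toy_ref.calibrators)
    alignments = rp.align_unique_sequences(remainder.index, toy_ref.contigs)
    assignments = annotation.annotate(alignments, toy_ref.mirna_loci, toy_ref.ncrna_db)
    records = isomir.classify_all(alignments, assignments, toy_ref)
    return {
        "ref": toy_ref,
        "profile": profile,
        "catalogue": catalogue,
        "reads": reads,
        "truth": truth,
        "unique": unique,
        "trim_stats": trim_stats,
        "cal_counts": cal_counts,
        "cal_variants": cal_variants,
        "remainder": remainder,
        "alignments": alignments,
        "assignments": assignments,
        "records": records,
    }


def unique_truth_agreement(library) -> tuple[int, int]:
    """(agreeing, total) unique miRNA inserts whose classified type at the
    true mature equals the generator's truth label."""
    records = library["records"]
    truth = library["truth"]
    key = records.set_index(["sequence", "mature"]).sort_index()
    mt = truth[truth["rna_class"] == "miRNA"].drop_duplicates(subset=["insert", "feature"])
    flag_cols = (
        ("5p-mod", "is_5p_mod"), ("3p-trim", "is_3p_trim"),
        ("3p-tail", "is_3p_tail"), ("nta", "is_nta"),
    )
    agree = total = 0
    for _, row in mt.iterrows():
        total += 1
        try:
            rec = key.loc[(row["insert"], row["feature"])]
        except KeyError:
            continue
        if isinstance(rec, pd.DataFrame):
            rec = rec.iloc[0]
        types = [t for t, c in flag_cols if rec[c]]
        if row["itype"] == "canonical":
            agree += bool(rec["is_canonical"])
        else:
            agree += types == [row["itype"]]
    return agree, total
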