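"""Synthetic serum small-RNA data with known ground truth.

This module generates everything the analysis consumes: a toy reference
(genome, mature-miRNA loci, a class-tagged ncRNA database, and ten
22-nt spike-in calibrators), a 96-patient rectal-cancer-like cohort
with TNM staging, serum-sampling timing, and stage-dependent survival,
and per-sample FASTQ reads whose class mixture, isomiR composition and
planted expression effects are fully recorded as ground truth.

The defaults encode the study conditions the analysis assumes:

* reads are 50-bp single-end with a ligated 3' adapter;
* insert lengths form three modes (~13 nt degradation fragments,
  ~22 nt miRNAs, ~31 nt full-length small ncRNAs);
* the library is dominated by scRNA, miRNA and lncRNA reads;
* unique isomiRs split 32% 3'-trimming, 39% non-templated addition
  (NTA), 15% templated 3' tailing and 14% 5' modification;
* ten equimolar calibrators are spiked into every library, each
  occasionally read with a single terminal deletion;
* the cohort has 96 patients (stage 0/I/II/III/IV = 1/13/38/23/21,
  53 sampled before and 43 after preoperative treatment, 53 male and
  43 female, 21 M1), with stage IV carrying the highest hazard.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from ._seq import normalize, random_seq, revcomp

#: 3' adapter ligated during library preparation (Illumina small-RNA style).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

#: Fixed bases a sequencer would read past the end of a short fragment
#: (index/flow-cell sequence); used to pad simulated reads to 50 bp.
_POST_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTGAAAAA"

READ_LENGTH = 50

NCRNA_CLASSES = ("scRNA", "lncRNA", "rRNA", "tRNA", "snoRNA", "snRNA", "Y-RNA")

ISOMIR_TYPES = ("3p-trim", "nta", "3p-tail", "5p-mod")


# ---------------------------------------------------------------------------
# Reference


@dataclass(frozen=True)
class MirnaLocus:
    """A mature-miRNA locus on the toy genome (0-based half-open)."""

    name: str
    mature_name: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class NcrnaEntry:
    entry_id: str
    rna_class: str
    sequence: str


@dataclass(frozen=True)
class Calibrator:
    name: str
    sequence: str
    concentration: float = 1.0


@dataclass
class ToyReference:
    contigs: dict[str, str]
    mirna_loci: list[MirnaLocus]
    ncrna_db: list[NcrnaEntry]
    calibrators: list[Calibrator]

    def mature_sequence(self, locus: MirnaLocus) -> str:
        seg = self.contigs[locus.contig][locus.start:locus.end]
        return revcomp(seg) if locus.strand == "-" else seg

    @property
    def mature_seqs(self) -> dict[str, str]:
        """mature name -> sequence (first locus wins for paralog pairs)."""
        out: dict[str, str] = {}
        for loc in self.mirna_loci:
            out.setdefault(loc.mature_name, self.mature_sequence(loc))
        return out

    def transcript_context(self, locus: MirnaLocus, n: int = 6) -> tuple[str, str]:
        """Genomic bases flanking the mature locus, in transcript orientation.

        Returns (upstream of the 5' end, downstream of the 3' end).
        """
        g = self.contigs[locus.contig]
        if locus.strand == "+":
            return g[max(0, locus.start - n):locus.start], g[locus.end:locus.end + n]
        return revcomp(g[locus.end:locus.end + n]), revcomp(g[max(0, locus.start - n):locus.start])

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "mirna_gff3": outdir / "mirna.gff3",
            "mature_fasta": outdir / "mature.fa",
            "ncrna_fasta": outdir / "ncrna.fa",
            "calibrator_fasta": outdir / "calibrators.fa",
            "calibrator_tsv": outdir / "calibrators.tsv",
        }
        io.write_fasta(paths["genome"], self.contigs.items())
        io.write_mirna_gff3(paths["mirna_gff3"], self.mirna_loci)
        io.write_fasta(paths["mature_fasta"], self.mature_seqs.items())
        io.write_fasta(
            paths["ncrna_fasta"],
            [(e.entry_id, e.sequence) for e in self.ncrna_db],
            descriptions={e.entry_id: f"class={e.rna_class}" for e in self.ncrna_db},
        )
        io.write_fasta(
            paths["calibrator_fasta"],
            [(c.name, c.sequence) for c in self.calibrators],
            descriptions={c.name: f"conc={c.concentration}" for c in self.calibrators},
        )
        cal = pd.DataFrame(
            {"sequence": [c.sequence for c in self.calibrators],
             "concentration": [c.concentration for c in self.calibrators]},
            index=pd.Index([c.name for c in self.calibrators], name="calibrator"),
        )
        io.write_tsv(cal, paths["calibrator_tsv"])
        return paths


def load_reference(refdir) -> ToyReference:
    refdir = Path(refdir)
    contigs = io.read_fasta(refdir / "genome.fa")
    loci = io.read_mirna_gff3(refdir / "mirna.gff3")
    ncrna = []
    from Bio import SeqIO

    for rec in SeqIO.parse(str(refdir / "ncrna.fa"), "fasta"):
        cls = dict(
            kv.split("=") for kv in rec.description.split()[1:] if "=" in kv
        ).get("class", "ncRNA")
        ncrna.append(NcrnaEntry(rec.id, cls, str(rec.seq).upper()))
    cal = io.read_tsv(refdir / "calibrators.tsv", index_col=0)
    calibrators = [
        Calibrator(name, row["sequence"], float(row["concentration"]))
        for name, row in cal.iterrows()
    ]
    return ToyReference(contigs, loci, ncrna, calibrators)


@dataclass
class ReferenceConfig:
    n_mirna_loci: int = 20          # distinct mature miRNAs
    duplicated_matures: int = 2     # matures planted at two genomic loci
    minus_strand_fraction: float = 0.3
    mature_length: tuple[int, int] = (21, 23)
    n_ncrna_per_class: int = 5
    ncrna_classes: tuple[str, ...] = NCRNA_CLASSES
    ncrna_length: tuple[int, int] = (34, 90)
    n_calibrators: int = 10
    calibrator_length: int = 22
    spacer_length: int = 40
    contig_name: str = "chr1"
    calibrator_sequences: tuple[str, ...] | None = None


def build_toy_reference(config: ReferenceConfig | None = None, seed: int = 0) -> ToyReference:
    """Construct a deterministic toy reference.

    Mature loci are spliced into a random genome; the base immediately
    downstream of every mature 3' end (transcript orientation) is forced
    to C so that A/U non-templated tails are always distinguishable from
    templated extension.
    """
    cfg = config or ReferenceConfig()
    if cfg.n_mirna_loci < 10:
        raise ValueError("at least 10 miRNA loci are required")
    if len(cfg.ncrna_classes) < 5:
        raise ValueError("at least 5 ncRNA classes are required")
    rng = np.random.default_rng(seed)
    adapter8 = DEFAULT_ADAPTER[:8]

    for _attempt in range(50):
        matures: list[str] = []
        while len(matures) < cfg.n_mirna_loci:
            s = random_seq(rng, int(rng.integers(cfg.mature_length[0], cfg.mature_length[1] + 1)))
            if adapter8 not in s and s not in matures:
                matures.append(s)

        parts: list[str] = []
        pos = 0

        def add(seq: str) -> None:
            nonlocal pos
            parts.append(seq)
            pos += len(seq)

        add(random_seq(rng, cfg.spacer_length))
        loci: list[MirnaLocus] = []
        for i, mat in enumerate(matures):
            n_copies = 2 if i < cfg.duplicated_matures else 1
            mature_name = f"miR-sim-{i + 1:02d}"
            for c in range(n_copies):
                strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
                if strand == "-":
                    # transcript-downstream base sits just before the locus
                    parts[-1] = parts[-1][:-1] + "G"
                name = mature_name if n_copies == 1 else f"{mature_name}-{c + 1}"
                start = pos
                add(mat if strand == "+" else revcomp(mat))
                loci.append(MirnaLocus(name, mature_name, cfg.contig_name, start, pos, strand))
                if strand == "+":
                    add("C" + random_seq(rng, cfg.spacer_length - 1))
                else:
                    add(random_seq(rng, cfg.spacer_length))

        ncrna: list[NcrnaEntry] = []
        for cls in cfg.ncrna_classes:
            for j in range(cfg.n_ncrna_per_class):
                while True:
                    s = random_seq(
                        rng, int(rng.integers(cfg.ncrna_length[0], cfg.ncrna_length[1] + 1))
                    )
                    if adapter8 not in s:
                        break
                start = pos
                add(s)
                ncrna.append(NcrnaEntry(f"{cls}-sim-{j + 1}", cls, s))
                add(random_seq(rng, cfg.spacer_length))

        genome = "".join(parts)
        # every mature must occur exactly where (and as often as) planted
        counts_ok = True
        planted = {}
        for loc in loci:
            planted[loc.mature_name] = planted.get(loc.mature_name, 0) + 1
        for mat, n_copies in zip(matures, (planted[f"miR-sim-{i + 1:02d}"] for i in range(len(matures)))):
            if genome.count(mat) + genome.count(revcomp(mat)) != n_copies:
                counts_ok = False
                break
        if not counts_ok:
            continue

        if cfg.calibrator_sequences is not None:
            cals = [normalize(s) for s in cfg.calibrator_sequences]
            for s in cals:
                if s in matures:
                    raise ValueError(f"calibrator sequence collides with a mature miRNA: {s}")
            if len(set(cals)) != len(cals):
                raise ValueError("calibrator sequences must be distinct")
        else:
            cals = []
            while len(cals) < cfg.n_calibrators:
                s = random_seq(rng, cfg.calibrator_length)
                if s in genome or revcomp(s) in genome or s in cals or s in matures:
                    continue
                if adapter8 in s:
                    continue
                cals.append(s)
        calibrators = [Calibrator(f"cal-{k + 1:02d}", s) for k, s in enumerate(cals)]
        return ToyReference({cfg.contig_name: genome}, loci, ncrna, calibrators)
    raise RuntimeError("could not build a self-consistent toy reference")


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class DEEffect:
    """A planted expression effect: `feature` is scaled by 2**lfc in the
    affected group (`condition` is "m1" or "after")."""

    feature: str
    lfc: float
    condition: str = "m1"


def _default_de_effects() -> tuple[DEEffect, ...]:
    up = tuple(DEEffect(f"miR-sim-{i:02d}", 1.0, "m1") for i in (1, 2, 3, 4))
    down = tuple(DEEffect(f"miR-sim-{i:02d}", -1.0, "m1") for i in (5, 6))
    treat = (DEEffect("miR-sim-07", 1.0, "after"),)
    return up + down + treat


@dataclass
class CohortSpec:
    """Cohort marginals; the defaults reproduce the 96-patient study table."""

    n_patients: int = 96
    stage_counts: Mapping[str, int] = field(
        default_factory=lambda: {"0": 1, "I": 13, "II": 38, "III": 23, "IV": 21}
    )
    n_before_treatment: int = 53
    n_after_treatment: int = 43
    sex_counts: Mapping[str, int] = field(default_factory=lambda: {"male": 53, "female": 43})
    #: after-treatment patients by the treatment they received
    after_treatments: Mapping[str, int] = field(
        default_factory=lambda: {"crt": 34, "surgery": 2, "surgery_crt": 6, "surgery_adjuvant": 1}
    )
    #: how the 21 M1 (= stage IV) patients split across sampling groups
    n_m1_before: int = 10
    n_m1_after_crt: int = 7
    t_counts: Mapping[str, int] = field(
        default_factory=lambda: {"Tis": 1, "T1": 5, "T2": 11, "T3": 43, "T4": 36}
    )
    n_counts: Mapping[str, int] = field(
        default_factory=lambda: {"N0": 57, "N1": 14, "N2": 23, "NX": 2}
    )
    age_bins: tuple[tuple[int, int, int], ...] = (
        (25, 39, 3), (40, 49, 5), (50, 59, 19), (60, 69, 32),
        (70, 79, 19), (80, 89, 17), (90, 94, 1),
    )
    #: five-year overall survival per stage; exponential hazard is derived
    #: from these (stage IV worst, matching published rectal-cancer rates)
    five_year_survival: Mapping[str, float] = field(
        default_factory=lambda: {"0": 0.95, "I": 0.90, "II": 0.75, "III": 0.60, "IV": 0.12}
    )
    followup_months: tuple[float, float] = (60.0, 108.0)
    later_metastasis_rate: float = 0.22
    de_effects: tuple[DEEffect, ...] = field(default_factory=_default_de_effects)

    def validate(self) -> None:
        if sum(self.stage_counts.values()) != self.n_patients:
            raise ValueError("stage counts must sum to n_patients")
        if self.n_before_treatment + self.n_after_treatment != self.n_patients:
            raise ValueError("before + after treatment must equal n_patients")
        if sum(self.sex_counts.values()) != self.n_patients:
            raise ValueError("sex counts must sum to n_patients")
        if sum(self.after_treatments.values()) != self.n_after_treatment:
            raise ValueError("after_treatments must sum to n_after_treatment")


def stage_hazard(spec: CohortSpec) -> dict[str, float]:
    """Per-stage exponential hazard (per month) implied by 5-year survival."""
    return {
        s: 0.0 if v >= 1.0 else -np.log(v) / 60.0
        for s, v in spec.five_year_survival.items()
    }


def simulate_cohort(spec: CohortSpec | None = None, seed: int = 0):
    """Draw a patient metadata table plus ground truth.

    Returns (metadata DataFrame indexed by patient_id, truth DataFrame with
    the per-patient hazard used to draw survival).
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    ids = [f"P{i + 1:03d}" for i in range(n)]

    n_m1 = spec.stage_counts.get("IV", 0)
    n_m1_after_other = n_m1 - spec.n_m1_before - spec.n_m1_after_crt
    if n_m1_after_other < 0:
        raise ValueError("M1 split exceeds the number of stage-IV patients")

    # sampling timing and treatment received
    timing = ["before"] * spec.n_before_treatment + ["after"] * spec.n_after_treatment
    after_types = [t for t, c in spec.after_treatments.items() for _ in range(c)]
    rng.shuffle(after_types)
    treatment = ["none"] * spec.n_before_treatment + after_types

    # metastasis status: stage IV <=> M1, allocated across sampling groups
    m1 = np.zeros(n, dtype=bool)
    before_idx = [i for i in range(n) if timing[i] == "before"]
    after_crt_idx = [i for i in range(n) if timing[i] == "after" and treatment[i] == "crt"]
    after_other_idx = [i for i in range(n) if timing[i] == "after" and treatment[i] != "crt"]
    for idx, count in (
        (before_idx, spec.n_m1_before),
        (after_crt_idx, spec.n_m1_after_crt),
        (after_other_idx, n_m1_after_other),
    ):
        if count:
            m1[rng.choice(idx, count, replace=False)] = True

    # stage: M1 patients are IV; remaining stages shuffled among M0
    m0_stages = [s for s, c in spec.stage_counts.items() if s != "IV" for _ in range(c)]
    rng.shuffle(m0_stages)
    stages = np.empty(n, dtype=object)
    stages[m1] = "IV"
    stages[~m1] = m0_stages

    sexes = [s for s, c in spec.sex_counts.items() for _ in range(c)]
    rng.shuffle(sexes)
    t_stage = [t for t, c in spec.t_counts.items() for _ in range(c)]
    rng.shuffle(t_stage)
    n_stage = [t for t, c in spec.n_counts.items() for _ in range(c)]
    rng.shuffle(n_stage)
    ages = [int(rng.integers(lo, hi + 1)) for lo, hi, c in spec.age_bins for _ in range(c)]
    rng.shuffle(ages)

    hz = stage_hazard(spec)
    hazard = np.array([hz[s] for s in stages])
    with np.errstate(divide="ignore"):
        t_event = np.where(hazard > 0, rng.exponential(1.0, n) / np.where(hazard > 0, hazard, 1.0), np.inf)
    censor = rng.uniform(*spec.followup_months, n)
    os_months = np.minimum(t_event, censor)
    os_event = (t_event <= censor).astype(int)

    later = np.where(
        m1, 1, (rng.random(n) < spec.later_metastasis_rate).astype(int)
    )

    meta = pd.DataFrame(
        {
            "age": ages,
            "sex": sexes,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "m_stage": np.where(m1, "M1", "M0"),
            "stage_group": stages,
            "serum_timing": timing,
            "treatment": treatment,
            "os_months": np.round(os_months, 2),
            "os_event": os_event,
            "later_metastasis": later,
        },
        index=pd.Index(ids, name="patient_id"),
    )
    truth = pd.DataFrame(
        {"stage_group": stages, "hazard_per_month": hazard},
        index=meta.index,
    )
    return meta, truth


# ---------------------------------------------------------------------------
# Reads


@dataclass
class SampleProfile:
    """Per-sample read-generation parameters.

    `class_mixture` fractions emulate a serum library dominated by
    scRNA/miRNA/lncRNA; `isomir_mix` gives per-read modification
    probabilities whose non-canonical part splits 32/39/15/14 across
    3'-trim / NTA / templated 3'-tail / 5'-mod.
    """

    library_size: int = 20000
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "miRNA": 0.35, "scRNA": 0.28, "lncRNA": 0.15, "rRNA": 0.05,
            "tRNA": 0.06, "snoRNA": 0.04, "snRNA": 0.02, "Y-RNA": 0.05,
        }
    )
    isomir_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.30, "3p-trim": 0.224, "nta": 0.273,
            "3p-tail": 0.105, "5p-mod": 0.098,
        }
    )
    adapter: str = DEFAULT_ADAPTER
    calibrator_fraction: float = 0.05
    calibrator_variant_rate: float = 0.02
    fragment_fraction: float = 0.45
    fragment_length: tuple[int, int] = (10, 16)
    full_length: tuple[int, int] = (29, 33)
    n_variants_per_locus: int = 15
    seed: int | None = None

    def validate(self) -> None:
        for name, mix in (("class_mixture", self.class_mixture), ("isomir_mix", self.isomir_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} fractions must sum to 1")


@dataclass(frozen=True)
class IsomirVariant:
    """A planted isomiR: the read insert plus its true classification."""

    mature_name: str
    sequence: str
    itype: str          # canonical | 3p-trim | nta | 3p-tail | 5p-mod
    five_off: int = 0   # positive = 5'-trimmed, negative = 5'-extended
    five_ext: str = ""  # templated 5' extension bases (read orientation)
    trim: int = 0       # 3' bases trimmed
    tail: str = ""      # templated 3' extension bases
    nta: str = ""       # non-templated 3' bases


@dataclass
class SimCatalogue:
    """The fixed variant catalogue and abundance weights shared by all
    samples of one simulated cohort."""

    variants: dict[str, dict[str, list[IsomirVariant]]]
    mature_weights: pd.Series
    entry_weights: pd.Series

    def unique_isomir_type_counts(self) -> dict[str, int]:
        out = {t: 0 for t in ISOMIR_TYPES}
        for pools in self.variants.values():
            for t in ISOMIR_TYPES:
                out[t] += len(pools.get(t, []))
        return out


def _enumerate_variants(mature_name: str, m: str, up: str, dn: str) -> dict[str, list[IsomirVariant]]:
    pools: dict[str, list[IsomirVariant]] = {t: [] for t in ISOMIR_TYPES}
    seen = {m}

    def push(t: str, v: IsomirVariant) -> None:
        if v.sequence not in seen and DEFAULT_ADAPTER[:8] not in v.sequence:
            seen.add(v.sequence)
            pools[t].append(v)

    for k in range(1, 6):
        if len(m) - k >= 16:
            push("3p-trim", IsomirVariant(mature_name, m[:-k], "3p-trim", trim=k))
    for k in range(1, 4):
        if len(dn) >= k:
            push("3p-tail", IsomirVariant(mature_name, m + dn[:k], "3p-tail", tail=dn[:k]))
    for ln in range(1, 4):
        for bases in itertools.product("AT", repeat=ln):
            t = "".join(bases)
            if dn and t[0] == dn[0]:
                continue  # must be non-templated at the first tail base
            push("nta", IsomirVariant(mature_name, m + t, "nta", nta=t))
    for k in range(1, 6):
        if len(m) - k >= 16:
            push("5p-mod", IsomirVariant(mature_name, m[k:], "5p-mod", five_off=k))
        if len(up) >= k:
            push("5p-mod", IsomirVariant(
                mature_name, up[-k:] + m, "5p-mod", five_off=-k, five_ext=up[-k:]
            ))
    return pools


def build_catalogue(ref: ToyReference, profile: SampleProfile, seed: int = 0) -> SimCatalogue:
    """Build the per-cohort isomiR catalogue and abundance weights.

    The number of unique isomiRs of each modification type is planted
    deterministically in the ratios of `profile.isomir_mix` (non-canonical
    part), subject to the per-locus variant space; allocation cycles over
    loci so every mature carries at least one variant of each type.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    matures = list(dict.fromkeys(loc.mature_name for loc in ref.mirna_loci))
    first_locus = {}
    for loc in ref.mirna_loci:
        first_locus.setdefault(loc.mature_name, loc)

    full_pools = {}
    for mat in matures:
        loc = first_locus[mat]
        up, dn = ref.transcript_context(loc, 6)
        pools = _enumerate_variants(mat, ref.mature_sequence(loc), up, dn)
        for p in pools.values():
            rng.shuffle(p)
        full_pools[mat] = pools

    noncanon = {t: profile.isomir_mix.get(t, 0.0) for t in ISOMIR_TYPES}
    tot = sum(noncanon.values())
    n_total = profile.n_variants_per_locus * len(matures)
    if tot > 0:
        targets = {t: int(round(n_total * f / tot)) for t, f in noncanon.items()}
    else:
        targets = {t: 0 for t in ISOMIR_TYPES}

    chosen: dict[str, dict[str, list[IsomirVariant]]] = {
        mat: {"canonical": [IsomirVariant(mat, ref.mature_sequence(first_locus[mat]), "canonical")]}
        for mat in matures
    }
    for t in ISOMIR_TYPES:
        order = itertools.cycle(matures)
        taken = 0
        stalled = 0
        while taken < targets[t] and stalled < len(matures):
            mat = next(order)
            pool = full_pools[mat][t]
            if pool:
                chosen[mat].setdefault(t, []).append(pool.pop())
                taken += 1
                stalled = 0
            else:
                stalled += 1

    mat_w = pd.Series(rng.lognormal(0.0, 1.0, len(matures)), index=matures)
    entries = [e.entry_id for e in ref.ncrna_db]
    ent_w = pd.Series(rng.lognormal(0.0, 1.0, len(entries)), index=entries)
    return SimCatalogue(chosen, mat_w, ent_w)


def _effect_applies(eff: DEEffect, patient: Mapping) -> bool:
    if eff.condition == "m1":
        return patient["m_stage"] == "M1"
    if eff.condition == "after":
        return patient["serum_timing"] == "after"
    raise ValueError(f"unknown DE condition {eff.condition!r}")


def expected_mirna_fractions(
    catalogue: SimCatalogue, de_effects: Sequence[DEEffect], patient: Mapping
) -> pd.Series:
    """Per-mature expected read fraction within the miRNA class."""
    w = catalogue.mature_weights.copy()
    for eff in de_effects:
        if eff.feature in w.index and _effect_applies(eff, patient):
            w[eff.feature] *= 2.0 ** eff.lfc
    return w / w.sum()


def simulate_sample_reads(
    ref: ToyReference,
    profile: SampleProfile,
    patient: Mapping,
    de_effects: Sequence[DEEffect] = (),
    catalogue: SimCatalogue | None = None,
    seed: int = 0,
    sample_id: str = "S1",
    library_size: int | None = None,
):
    """Simulate one sample's 50-bp reads.

    Returns (reads, truth): reads is a list of (read_id, sequence) and
    truth a DataFrame with one row per read recording its class, feature
    and true isomiR coordinates.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    catalogue = catalogue or build_catalogue(ref, profile, seed)
    lib = int(library_size if library_size is not None else profile.library_size)
    adapter = normalize(profile.adapter)
    if not adapter:
        raise ValueError("adapter must be non-empty")

    n_cal = int(round(lib * profile.calibrator_fraction))
    n_bio = lib - n_cal
    classes = list(profile.class_mixture)
    class_counts = rng.multinomial(n_bio, np.array([profile.class_mixture[c] for c in classes]))

    inserts: list[tuple[str, str, str, IsomirVariant | None]] = []  # (class, feature, insert, variant)

    # --- miRNA reads
    n_mirna = int(class_counts[classes.index("miRNA")]) if "miRNA" in classes else 0
    if n_mirna:
        fracs = expected_mirna_fractions(catalogue, de_effects, patient)
        mat_counts = rng.multinomial(n_mirna, fracs.to_numpy())
        type_names = list(profile.isomir_mix)
        for mat, cnt in zip(fracs.index, mat_counts):
            if cnt == 0:
                continue
            pools = catalogue.variants[mat]
            avail = [t for t in type_names if pools.get(t)]
            p = np.array([profile.isomir_mix[t] for t in avail])
            p /= p.sum()
            tcounts = rng.multinomial(cnt, p)
            for t, tc in zip(avail, tcounts):
                pool = pools[t]
                for j in rng.integers(0, len(pool), size=tc):
                    v = pool[int(j)]
                    inserts.append(("miRNA", mat, v.sequence, v))

    # --- ncRNA reads
    by_class: dict[str, list[NcrnaEntry]] = {}
    for e in ref.ncrna_db:
        by_class.setdefault(e.rna_class, []).append(e)
    for cls, cnt in zip(classes, class_counts):
        if cls == "miRNA" or cnt == 0:
            continue
        entries = by_class.get(cls)
        if not entries:
            raise ValueError(f"class mixture requests {cls!r} but the reference has none")
        w = catalogue.entry_weights.loc[[e.entry_id for e in entries]].to_numpy()
        ecounts = rng.multinomial(int(cnt), w / w.sum())
        for e, ec in zip(entries, ecounts):
            for _ in range(int(ec)):
                if rng.random() < profile.fragment_fraction:
                    ln = int(rng.integers(profile.fragment_length[0], profile.fragment_length[1] + 1))
                    for _try in range(20):
                        st = int(rng.integers(0, len(e.sequence) - ln + 1))
                        frag = e.sequence[st:st + ln]
                        if adapter[:8] not in frag:
                            break
                else:
                    ln = min(
                        int(rng.integers(profile.full_length[0], profile.full_length[1] + 1)),
                        len(e.sequence),
                    )
                    frag = e.sequence[:ln]
                inserts.append((cls, e.entry_id, frag, None))

    # --- calibrator reads
    cal_counts = rng.multinomial(n_cal, np.full(len(ref.calibrators), 1.0 / len(ref.calibrators)))
    for cal, cc in zip(ref.calibrators, cal_counts):
        for _ in range(int(cc)):
            s = cal.sequence
            if rng.random() < profile.calibrator_variant_rate:
                s = s[1:] if rng.random() < 0.5 else s[:-1]  # terminal deletion
            inserts.append(("calibrator", cal.name, s, None))

    reads = []
    rows = []
    for i, (cls, feature, insert, var) in enumerate(inserts):
        rid = f"{sample_id}:r{i:06d}"
        read = (insert + adapter + _POST_ADAPTER)[:READ_LENGTH]
        reads.append((rid, read))
        rows.append(
            {
                "read_id": rid,
                "sample": sample_id,
                "rna_class": cls,
                "feature": feature,
                "insert": insert,
                "itype": var.itype if var else "",
                "five_off": var.five_off if var else 0,
                "five_ext": var.five_ext if var else "",
                "trim": var.trim if var else 0,
                "tail": var.tail if var else "",
                "nta": var.nta if var else "",
            }
        )
    truth = pd.DataFrame(rows)
    return reads, truth


@dataclass
class SimulatedCohort:
    metadata: pd.DataFrame
    cohort_truth: pd.DataFrame
    read_truth: pd.DataFrame
    expected_mirna: pd.DataFrame      # mature x sample expected fractions
    catalogue: SimCatalogue
    reads: dict[str, list[tuple[str, str]]] | None = None
    fastq_paths: dict[str, Path] | None = None


def simulate_cohort_reads(
    ref: ToyReference,
    metadata: pd.DataFrame,
    cohort_truth: pd.DataFrame | None = None,
    profile: SampleProfile | None = None,
    de_effects: Sequence[DEEffect] | None = None,
    outdir=None,
    seed: int = 0,
    library_sizes: Mapping[str, int] | None = None,
) -> SimulatedCohort:
    """Simulate FASTQ reads for every patient in `metadata`.

    All randomness flows from `seed` through per-sample derived seeds;
    the variant catalogue and abundance weights are shared cohort-wide.
    """
    profile = profile or SampleProfile()
    de_effects = tuple(de_effects) if de_effects is not None else _default_de_effects()
    ss = np.random.SeedSequence(seed)
    cat_seed, *sample_seeds = ss.generate_state(len(metadata) + 1) % (2 ** 31)
    catalogue = build_catalogue(ref, profile, int(cat_seed))

    all_truth = []
    expected = {}
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    for sid, sseed in zip(metadata.index, sample_seeds):
        patient = metadata.loc[sid]
        lib = library_sizes.get(sid) if library_sizes else None
        reads, truth = simulate_sample_reads(
            ref, profile, patient, de_effects, catalogue,
            seed=int(sseed), sample_id=sid, library_size=lib,
        )
        reads_by_sample[sid] = reads
        all_truth.append(truth)
        expected[sid] = expected_mirna_fractions(catalogue, de_effects, patient)

    read_truth = pd.concat(all_truth, ignore_index=True)
    expected_df = pd.DataFrame(expected)
    out = SimulatedCohort(
        metadata=metadata,
        cohort_truth=cohort_truth if cohort_truth is not None else pd.DataFrame(index=metadata.index),
        read_truth=read_truth,
        expected_mirna=expected_df,
        catalogue=catalogue,
        reads=reads_by_sample,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sid, reads in reads_by_sample.items():
            p = outdir / f"{sid}.fastq"
            io.write_fastq(p, reads)
            paths[sid] = p
        out.fastq_paths = paths
    return out


# ---------------------------------------------------------------------------
# Feature-level simulators for the statistical modules


def simulate_count_matrix(
    n_features: int = 1000,
    group_sizes: tuple[int, int] = (43, 21),
    n_de: int = 30,
    lfc: float = 1.0,
    dispersion: float = 0.2,
    lib_size_range: tuple[float, float] = (0.5e6, 1.5e6),
    seed: int = 0,
):
    """Gamma-Poisson counts with planted two-group effects.

    Half the planted features go up, half down, by |lfc| in group B.
    Returns (counts DataFrame features x samples, groups Series,
    de_truth DataFrame of planted features and their lfc).
    """
    rng = np.random.default_rng(seed)
    n1, n2 = group_sizes
    n = n1 + n2
    features = [f"feat-{i + 1:04d}" for i in range(n_features)]
    samples = [f"S{j + 1:03d}" for j in range(n)]
    groups = pd.Series(["A"] * n1 + ["B"] * n2, index=samples, name="group")

    base_cpm = 2.0 ** rng.normal(5.0, 2.0, n_features)
    lfc_vec = np.zeros(n_features)
    de_idx = rng.choice(n_features, n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    lfc_vec[de_idx] = signs * abs(lfc)

    libs = rng.uniform(*lib_size_range, n)
    mu = np.outer(base_cpm / 1e6, libs)
    mu[:, n1:] *= 2.0 ** lfc_vec[:, None]
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=features, columns=samples)
    de_truth = pd.DataFrame(
        {"feature": [features[i] for i in de_idx], "lfc": lfc_vec[de_idx]}
    ).set_index("feature")
    return counts_df, groups, de_truth


def simulate_survival_data(
    n: int = 300,
    hr: float = 2.0,
    baseline_hazard: float = 0.03,
    censoring: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with a binary covariate of true hazard ratio `hr`.

    Censoring times are exponential with per-subject rate chosen so the
    expected censored fraction equals `censoring` exactly.
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    lam = baseline_hazard * hr ** x
    t = rng.exponential(1.0 / lam)
    if censoring > 0:
        lam_c = lam * censoring / (1.0 - censoring)
        c = rng.exponential(1.0 / lam_c)
    else:
        c = np.full(n, np.inf)
    return pd.DataFrame(
        {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
    )


def simulate_reference_gene_matrix(
    n_genes: int = 200,
    group_sizes: tuple[int, int] = (30, 30),
    n_stable: int = 3,
    group_effect_sd: float = 0.5,
    stable_noise_sd: float = 0.1,
    noise_sd_range: tuple[float, float] = (0.4, 1.0),
    seed: int = 0,
):
    """Log2 expression with a few designed-stable genes among variable ones.

    Stable genes have zero between-group effect and low within-group
    noise; the rest carry random group effects and larger noise. Returns
    (matrix genes x samples, groups Series, list of stable gene names).
    """
    rng = np.random.default_rng(seed)
    n1, n2 = group_sizes
    genes = [f"gene-{i + 1:03d}" for i in range(n_genes)]
    samples = [f"S{j + 1:03d}" for j in range(n1 + n2)]
    groups = pd.Series(["A"] * n1 + ["B"] * n2, index=samples, name="group")
    stable = genes[:n_stable]

    base = rng.normal(8.0, 2.0, n_genes)
    delta = rng.normal(0.0, group_effect_sd, n_genes)
    sd = rng.uniform(*noise_sd_range, n_genes)
    delta[:n_stable] = 0.0
    sd[:n_stable] = stable_noise_sd

    g2 = (groups == "B").to_numpy()
    mean = base[:, None] + np.where(g2[None, :], delta[:, None], 0.0)
    x = mean + rng.normal(0.0, 1.0, (n_genes, len(samples))) * sd[:, None]
    return pd.DataFrame(x, index=genes, columns=samples), groups, stable


def simulate_ct_table(
    targets: Sequence[str],
    controls: Sequence[str],
    group_sizes: tuple[int, int] = (10, 10),
    ct_shift: Mapping[str, float] | None = None,
    n_replicates: int = 2,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format qPCR Ct table (sample, group, gene, replicate, Ct).

    `ct_shift[target]` lowers the metastatic group's Ct by that many
    cycles (lower Ct = higher expression). Controls are unshifted.
    """
    rng = np.random.default_rng(seed)
    ct_shift = ct_shift or {}
    rows = []
    for g, ng, gname in (("M0", group_sizes[0], "non_metastatic"), ("M1", group_sizes[1], "metastatic")):
        for j in range(ng):
            sid = f"{g}-{j + 1:02d}"
            sample_effect = rng.normal(0.0, 0.3)
            for gene in list(controls) + list(targets):
                base = 24.0 if gene in controls else 25.0
                shift = ct_shift.get(gene, 0.0) if g == "M1" else 0.0
                for rep in range(1, n_replicates + 1):
                    ct = base - shift + sample_effect + rng.normal(0.0, noise_sd)
                    rows.append(
                        {"sample": sid, "group": gname, "gene": gene,
                         "replicate": rep, "Ct": round(ct, 3)}
                    )
    return pd.DataFrame(rows)
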