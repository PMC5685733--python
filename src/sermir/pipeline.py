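"""End-to-end pipeline: simulate -> process -> annotate -> classify ->
normalize -> differential expression -> survival -> reference genes.

A single seeded configuration drives every stage; each output file is
checksummed into a manifest so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, diffexp, io, isomir, normalization, qpcr
from . import read_processing as rp
from . import survival as surv
from . import synthetic_data as sd

log = logging.getLogger("sermir.pipeline")


@dataclass
class PipelineConfig:
    outdir: str = "sermir_run"
    seed: int = 0
    n_patients: int = 96
    library_size: int = 8000
    n_mirna_loci: int = 20
    n_variants_per_locus: int = 15
    de_min_cpm: float = 1.0
    de_min_fraction: float = 0.5
    surv_min_cpm: float = 100.0
    surv_min_fraction: float = 0.5
    alpha: float = 0.05
    run_de: bool = True
    run_survival: bool = True
    run_normfinder: bool = True
    run_qpcr: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("de_min_cpm", "surv_min_cpm", "library_size", "n_mirna_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.de_min_fraction < 1 or not 0 < self.surv_min_fraction < 1:
            raise ValueError("filter fractions must lie in (0, 1)")


def _alloc(counts: dict, total: int) -> dict:
    """Largest-remainder allocation of `total` over the given marginals."""
    keys = list(counts)
    weights = [counts[k] for k in keys]
    s = sum(weights)
    quotas = [total * w / s for w in weights]
    out = {k: int(q) for k, q in zip(keys, quotas)}
    rem = total - sum(out.values())
    order = sorted(range(len(keys)), key=lambda i: quotas[i] - int(quotas[i]), reverse=True)
    for i in order[:rem]:
        out[keys[i]] += 1
    return out


def scaled_cohort_spec(n_patients: int) -> sd.CohortSpec:
    """Shrink the default 96-patient cohort to `n_patients`, preserving
    the marginal proportions (largest-remainder rounding)."""
    base = sd.CohortSpec()
    if n_patients == base.n_patients:
        return base
    if n_patients < 8:
        raise ValueError("cohorts below 8 patients cannot preserve the group structure")
    stage = _alloc(dict(base.stage_counts), n_patients)
    before = _alloc({"b": base.n_before_treatment, "a": base.n_after_treatment}, n_patients)
    n_before, n_after = before["b"], before["a"]
    at = _alloc(dict(base.after_treatments), n_after)
    n_iv = stage["IV"]
    # keep at least two M1 patients in the before-treatment (metastasis
    # contrast) arm so two-group statistics stay defined
    m1_before = min(n_before, n_iv, max(2, round(n_iv * base.n_m1_before / 21)))
    m1_after_crt = min(at["crt"], n_iv - m1_before)
    m1_other = n_iv - m1_before - m1_after_crt
    non_crt_after = n_after - at["crt"]
    if m1_other > non_crt_after:
        m1_after_crt += m1_other - non_crt_after
    age = tuple((lo, hi, c) for (lo, hi, _), c in zip(
        base.age_bins, _alloc({i: c for i, (_, _, c) in enumerate(base.age_bins)}, n_patients).values()
    ))
    spec = sd.CohortSpec(
        n_patients=n_patients,
        stage_counts=stage,
        n_before_treatment=n_before,
        n_after_treatment=n_after,
        sex_counts=_alloc(dict(base.sex_counts), n_patients),
        after_treatments=at,
        n_m1_before=m1_before,
        n_m1_after_crt=min(at["crt"], n_iv - m1_before),
        t_counts=_alloc(dict(base.t_counts), n_patients),
        n_counts=_alloc(dict(base.n_counts), n_patients),
        age_bins=age,
    )
    spec.validate()
    return spec


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result bundle of DataFrames.

    Writes all stage outputs plus a checksum manifest under
    `config.outdir`. A stage failure aborts with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    outputs: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        io.write_tsv(df, path, index=index)
        outputs.append(path)

    log.info("config: %s", asdict(config))
    stage = "simulate"
    try:
        ref = sd.build_toy_reference(
            sd.ReferenceConfig(n_mirna_loci=config.n_mirna_loci), seed=config.seed
        )
        refpaths = ref.write(outdir / "reference")
        outputs.extend(refpaths.values())
        spec = scaled_cohort_spec(config.n_patients)
        meta, cohort_truth = sd.simulate_cohort(spec, seed=config.seed)
        profile = sd.SampleProfile(
            library_size=config.library_size,
            n_variants_per_locus=config.n_variants_per_locus,
        )
        sim = sd.simulate_cohort_reads(
            ref, meta, cohort_truth, profile, spec.de_effects,
            outdir=outdir / "fastq", seed=config.seed,
        )
        save(meta, "metadata.tsv")
        save(cohort_truth, "cohort_truth.tsv")
        outputs.extend(sim.fastq_paths.values())
        log.info("simulated %d samples, %d reads total", len(meta), len(sim.read_truth))

        stage = "process"
        unique, trim_stats = rp.collapse_reads(sim.fastq_paths, profile.adapter)
        cal_counts, cal_variants, remainder = rp.match_calibrators(unique, ref.calibrators)
        alignments = rp.align_unique_sequences(remainder.index, ref.contigs)
        save(unique, "unique_sequences.tsv")
        save(trim_stats, "trim_stats.tsv")
        save(cal_counts, "calibrator_counts.tsv")
        save(cal_variants, "calibrator_variants.tsv", index=False)
        save(alignments, "alignments.tsv", index=False)
        log.info("%d unique sequences, %d calibrator variants", len(unique), len(cal_variants))

        stage = "annotate"
        assignments = annotation.annotate(alignments, ref.mirna_loci, ref.ncrna_db)
        composition = annotation.summarize_classes(assignments, remainder)
        cls_of_seq = dict(zip(assignments["sequence"], assignments["kind"]))
        lengths = rp.length_distribution(
            remainder, {s: k.split(":", 1)[-1] for s, k in cls_of_seq.items()}
        )
        save(assignments, "assignments.tsv", index=False)
        save(composition, "class_composition.tsv")
        save(lengths, "length_distribution.tsv", index=False)

        stage = "isomir"
        records = isomir.classify_all(alignments, assignments, ref)
        iso_comp = isomir.isomir_type_composition(records)
        matrices = annotation.build_matrices(
            assignments, remainder, alignments, cal_counts, isomir_labels=records
        )
        save(records, "isomir_records.tsv", index=False)
        save(iso_comp.to_frame(), "isomir_composition.tsv")
        save(matrices["mirna"].counts, "mirna_counts.tsv")
        save(matrices["isomir"].counts, "isomir_counts.tsv")
        save(matrices["ncrna"].counts, "ncrna_counts.tsv")
        results.update(
            reference=ref, metadata=meta, sim=sim, matrices=matrices,
            records=records, isomir_composition=iso_comp, composition=composition,
        )

        stage = "normalize"
        factors = normalization.tmm_factors(matrices["calibrator"].counts)
        lib = matrices["mirna"].lib_sizes
        for mat in ("mirna", "isomir", "ncrna"):
            matrices[mat].norm_factors = factors
        cal_cpm = normalization.cpm_normalize(
            matrices["calibrator"].counts, factors, lib
        )
        qc_cal, qc_sample = normalization.calibrator_qc(cal_cpm)
        norm_tbl = pd.DataFrame({"norm_factor": factors, "library_size": lib})
        save(norm_tbl, "norm_factors.tsv")
        save(matrices["mirna"].cpm(), "mirna_cpm.tsv")
        save(qc_cal, "calibrator_qc.tsv")
        save(qc_sample, "calibrator_qc_samples.tsv")
        results.update(norm_factors=factors, calibrator_qc=qc_cal)

        if config.run_de:
            stage = "de"
            de_results = {}
            for cname in ("metastasis", "treatment"):
                contrast = diffexp.define_contrast(meta, cname)
                for mname in ("mirna", "isomir"):
                    m = matrices[mname]
                    res = diffexp.run_de(
                        m.counts, m.lib_sizes, m.norm_factors, contrast,
                        min_cpm=config.de_min_cpm, min_fraction=config.de_min_fraction,
                    )
                    de_results[f"{cname}_{mname}"] = res
                    save(res, f"de_{cname}_{mname}.tsv")
                if cname == "metastasis" and len(matrices["ncrna"].counts):
                    m = matrices["ncrna"]
                    res = diffexp.run_de(
                        m.counts, m.lib_sizes, m.norm_factors, contrast,
                        min_cpm=config.de_min_cpm, require_all=True,
                    )
                    de_results[f"{cname}_ncrna"] = res
                    save(res, f"de_{cname}_ncrna.tsv")
            results["de"] = de_results
            for key, res in de_results.items():
                log.info("DE %s: %d significant at BH<%.2f", key,
                         int((res["p_adj"] < config.alpha).sum()), config.alpha)

        if config.run_survival:
            stage = "survival"
            screen, km_curves = surv.survival_screen(
                matrices["mirna"].cpm(), meta,
                min_cpm=config.surv_min_cpm, min_fraction=config.surv_min_fraction,
                alpha=config.alpha,
            )
            save(screen, "survival_screen.tsv")
            for feat, curves in km_curves.items():
                save(curves, f"km_{feat}.tsv", index=False)
            results["survival_screen"] = screen

        if config.run_normfinder and config.run_de:
            stage = "normfinder"
            contrast = diffexp.define_contrast(meta, "metastasis")
            cpm = matrices["mirna"].cpm()[contrast.samples]
            logcpm = pd.DataFrame(
                np.log2(cpm.to_numpy() + 0.5), index=cpm.index, columns=cpm.columns
            )
            stab = qpcr.normfinder(logcpm, contrast.groups)
            refs = qpcr.select_references(
                results["de"]["metastasis_mirna"], stab, cpm.mean(axis=1),
                min_expression=100.0,
            )
            save(stab, "normfinder.tsv")
            save(pd.DataFrame({"reference_gene": refs}), "reference_genes.tsv", index=False)
            results.update(normfinder=stab, reference_genes=refs)

            if config.run_qpcr:
                stage = "qpcr"
                target = results["de"]["metastasis_mirna"].index[0]
                ct = sd.simulate_ct_table(
                    [target], refs, ct_shift={target: 1.0}, seed=config.seed
                )
                per_sample = qpcr.delta_ct(ct, target, refs)
                cmp = qpcr.qpcr_compare(per_sample)
                qdf = pd.DataFrame([{"target": target, **cmp}])
                save(ct, "qpcr_ct.tsv", index=False)
                save(qdf, "qpcr_results.tsv", index=False)
                results["qpcr"] = qdf
    except Exception:
        log.exception("stage %r failed", stage)
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None
    finally:
        if handler in log.handlers:
            log.removeHandler(handler)
            handler.close()

    stage = "manifest"
    config.to_yaml(outdir / "run_config.yaml")
    outputs.append(outdir / "run_config.yaml")
    manifest = pd.DataFrame(
        sorted(
            [{"file": str(p.relative_to(outdir)), "sha256": _sha256(p)} for p in outputs],
            key=lambda r: r["file"],
        )
    )
    io.write_tsv(manifest, outdir / "manifest.tsv", index=False)
    results["manifest"] = manifest
    return results
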