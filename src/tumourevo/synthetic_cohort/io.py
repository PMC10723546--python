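"""On-disk cohort emission in the formats the pipeline readers consume."""

from __future__ import annotations

import json
from pathlib import Path

from ..cohort_io.model import InvalidInputError
from ..cohort_io.tables import write_bedpe, write_clinical, write_segments
from ..cohort_io.vcf import write_snv_vcf


def write_cohort(samples, ground_truth, out_dir) -> dict:
    """Write per-sample VCF/segment-TSV/BEDPE, cohort clinical TSV and
    ground-truth JSON; returns (and writes) a deterministic manifest."""
    if not samples:
        raise InvalidInputError("cannot write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {"samples": {}, "cohort": {}}
    chrom_order = None
    for sample in samples:
        sid = sample.sample_id
        vcf_path = out / f"{sid}.vcf"
        seg_path = out / f"{sid}_segments.tsv"
        bedpe_path = out / f"{sid}.bedpe"
        chrom_order = sorted({s.chrom for s in sample.segments})
        write_snv_vcf(sample.variants, vcf_path, chrom_order=chrom_order)
        write_segments(sample.segments, seg_path)
        write_bedpe(sample.svs, bedpe_path)
        manifest["samples"][sid] = {
            "vcf": vcf_path.name,
            "segments": seg_path.name,
            "bedpe": bedpe_path.name,
            "n_variants": len(sample.variants),
            "n_segments": len(sample.segments),
            "n_svs": len(sample.svs),
        }

    clinical_path = out / "clinical.tsv"
    write_clinical(samples, clinical_path)
    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(ground_truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest["cohort"] = {
        "clinical": clinical_path.name,
        "ground_truth": truth_path.name,
        "n_samples": len(samples),
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
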