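"""Tumour-cohort simulation with known mutation multiplicities and gain times.

Mutation placement follows the timing algebra used by the estimators: for a
clonal gain to (2,1) at molecular time t with per-copy clonal intensity mu,
mutations duplicated by the gain are Poisson(mu*t) at multiplicity 2 and the
remaining clonal mutations Poisson(mu*(3-2t)) at multiplicity 1; (2,0) gives
Poisson(mu*t) / Poisson(2*mu*(1-t)) and (2,2) gives Poisson(2*mu*t) /
Poisson(4*mu*(1-t)). Read counts are binomial at Poisson depth with the
purity-diluted expected VAF.
"""

from __future__ import annotations

import numpy as np

from ..cohort_io.model import CopyNumberSegment, InvalidInputError, SVRecord, TumourSample, VariantRecord
from ..event_timing.chronology import RateModel, chronological_lead_time
from ..event_timing.estimators import expected_vaf
from .config import CohortGroundTruth, SampleGroundTruth, SimulationConfig

_SAMPLE_STREAM = 1
_SV_STREAM = 2


def rate_model(config: SimulationConfig) -> RateModel:
    return RateModel(
        clock_rate=config.clock_rate_per_year,
        acceleration=config.acceleration_factor,
        initiation_lead=config.initiation_lead_years,
    )


def _multiplicity_counts(state: str, mu: float, t: float, rng) -> tuple:
    """(n2, n1) Poisson draws for a gained segment at molecular time t."""
    if state == "2+1":
        return rng.poisson(mu * t), rng.poisson(mu * (3.0 - 2.0 * t))
    if state == "2+0":
        return rng.poisson(mu * t), rng.poisson(2.0 * mu * (1.0 - t))
    if state == "2+2":
        return rng.poisson(2.0 * mu * t), rng.poisson(4.0 * mu * (1.0 - t))
    raise InvalidInputError(f"unsupported state {state}")


def _build_segments(config: SimulationConfig, wgd: bool, escape) -> list:
    """Non-overlapping clonal segments: diploid baseline, configured gains,
    WGD override, and HLA-locus LOH carve-out when requested."""
    carves = []  # (chrom, start, end, major, minor, time or None)
    if not wgd:
        for gain in config.gain_events:
            carves.append((gain.chrom, gain.start, gain.end, gain.major_cn, gain.minor_cn, gain.time))
    if escape is not None and escape.hla_loh:
        chrom, start, end = config.hla_locus
        major = 2 if wgd else 1
        carves.append((chrom, start, end, major, 0, None))

    segments = []
    base_major, base_minor = (2, 2) if wgd else (1, 1)
    for chrom, length, _ in config.genome:
        chrom_carves = sorted([c for c in carves if c[0] == chrom], key=lambda c: c[1])
        for a, b in zip(chrom_carves, chrom_carves[1:]):
            if b[1] <= a[2]:
                raise InvalidInputError(f"overlapping configured events on {chrom}")
        cursor = 1
        for _, start, end, major, minor, _t in chrom_carves:
            if start > cursor:
                segments.append(CopyNumberSegment(chrom, cursor, start - 1, base_major, base_minor))
            segments.append(CopyNumberSegment(chrom, start, end, major, minor))
            cursor = end + 1
        if cursor <= length:
            segments.append(CopyNumberSegment(chrom, cursor, length, base_major, base_minor))
    return segments


def _segment_event_time(config: SimulationConfig, segment, wgd: bool):
    """(state, t) if the segment corresponds to a configured timed event."""
    if wgd and segment.major_cn == 2 and segment.minor_cn == 2:
        return "2+2", config.wgd_time
    for gain in config.gain_events:
        if (
            gain.chrom == segment.chrom
            and gain.start == segment.start
            and gain.end == segment.end
        ):
            return gain.state, gain.time
    return None, None


def _draw_reads(rng, depth_mean: float, vaf: float) -> tuple:
    depth = max(1, int(rng.poisson(depth_mean)))
    alt = int(rng.binomial(depth, min(max(vaf, 0.0), 1.0)))
    return depth - alt, alt


def _class_sampler(config: SimulationConfig):
    classes = sorted(config.context_rates)
    probs = np.array([config.context_rates[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    return classes, probs


def _make_variant(rng, chrom, pos, cls, purity, segment, m, ccf, depth_mean, **kw) -> VariantRecord:
    tri, sub = cls.split(":")
    ref, alt = sub.split(">")
    v_exp = ccf * expected_vaf(m, purity, segment.total_cn)
    ref_depth, alt_depth = _draw_reads(rng, depth_mean, v_exp)
    return VariantRecord(
        chrom=chrom,
        pos=int(pos),
        ref=ref,
        alt=alt,
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        trinucleotide_context=cls,
        **kw,
    )


def simulate_sample(config: SimulationConfig, sample_index: int) -> tuple:
    """Generate one tumour sample plus its ground truth."""
    if sample_index >= config.n_samples:
        raise InvalidInputError("sample_index must be < n_samples")
    if config.total_rate_per_site <= 0 or config.depth_mean <= 0:
        raise InvalidInputError("non-positive mutation intensity or depth")

    rng = np.random.default_rng([config.seed, _SAMPLE_STREAM, sample_index])
    lo, hi = config.purity_range
    purity = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    age = float(config.age_mean + config.age_sd * rng.standard_normal())
    wgd = sample_index < round(config.wgd_fraction * config.n_samples)
    escape = config.escape_specs.get(sample_index)
    model = rate_model(config)

    segments = _build_segments(config, wgd, escape)
    classes, class_probs = _class_sampler(config)
    lam = config.total_rate_per_site  # per-copy per-bp

    variants = []
    truth_variants = []
    gain_times = {}

    def emit(segment, count, m, ccf, clonal):
        if count <= 0:
            return
        positions = rng.integers(segment.start, segment.end + 1, size=count)
        class_idx = rng.choice(len(classes), size=count, p=class_probs)
        for pos, ci in zip(positions, class_idx):
            variant = _make_variant(
                rng, segment.chrom, pos, classes[ci], purity, segment, m, ccf, config.depth_mean
            )
            variants.append(variant)
            truth_variants.append(
                {
                    "chrom": segment.chrom,
                    "pos": int(pos),
                    "multiplicity": int(m),
                    "clonal": bool(clonal),
                    "ccf": float(ccf),
                }
            )

    for segment in segments:
        mu = lam * segment.length
        state, t = _segment_event_time(config, segment, wgd)
        if state is not None:
            n2, n1 = _multiplicity_counts(state, mu, t, rng)
            emit(segment, n2, 2, 1.0, True)
            emit(segment, n1, 1, 1.0, True)
            target = "WGD" if state == "2+2" and wgd else f"{segment.chrom}:{segment.start}-{segment.end}"
            lead = chronological_lead_time(t, age, model)
            entry = gain_times.get(target)
            if entry is None:
                gain_times[target] = {
                    "state": state,
                    "molecular_time": float(t),
                    "lead_years": float(lead),
                }
        else:
            clonal_mean = segment.total_cn * mu
            emit(segment, rng.poisson(clonal_mean), 1, 1.0, True)
        sub_mean = config.subclonal_fraction * segment.total_cn * mu
        emit(segment, rng.poisson(sub_mean), 1, config.subclonal_ccf, False)

    # driver-element mutation enrichment (extra clonal multiplicity-1 hits)
    for spec in config.driver_element_specs:
        extra_mean = (spec.fold - 1.0) * 2.0 * lam * (spec.end - spec.start)
        count = rng.poisson(extra_mean)
        for _ in range(count):
            pos = int(rng.integers(spec.start + 1, spec.end + 1))
            segment = _segment_for(segments, spec.chrom, pos)
            cls = classes[rng.choice(len(classes), p=class_probs)]
            variant = _make_variant(
                rng, spec.chrom, pos, cls, purity, segment, 1, 1.0, config.depth_mean,
                gene=spec.element_id, consequence="non-coding",
            )
            variants.append(variant)
            truth_variants.append(
                {"chrom": spec.chrom, "pos": pos, "multiplicity": 1, "clonal": True, "ccf": 1.0}
            )

    # planted escape alterations
    if escape is not None:
        if escape.hla_mutation:
            gene, (chrom, pos) = "HLA-A", config.hla_gene_positions["HLA-A"]
            variants.append(_escape_variant(rng, config, segments, purity, gene, chrom, pos))
        if escape.apg_mutation:
            gene = sorted(config.apg_gene_positions)[sample_index % len(config.apg_gene_positions)]
            chrom, pos = config.apg_gene_positions[gene]
            variants.append(_escape_variant(rng, config, segments, purity, gene, chrom, pos))

    svs = _sample_svs(config, rng)

    ploidy = sum(s.total_cn * s.length for s in segments) / sum(s.length for s in segments)
    sample = TumourSample(
        sample_id=f"S{sample_index:04d}",
        purity=purity,
        ploidy=float(ploidy),
        age_at_sampling=age,
        grade=int(rng.integers(1, 5)),
        stage=int(rng.integers(1, 5)),
        variants=variants,
        segments=segments,
        svs=svs,
    )
    truth = SampleGroundTruth(
        sample_id=sample.sample_id,
        purity=purity,
        age=age,
        wgd=wgd,
        gain_times=gain_times,
        variant_truth=truth_variants,
        escape={
            "hla_loh": bool(escape and escape.hla_loh),
            "hla_mutation": bool(escape and escape.hla_mutation),
            "apg_mutation": bool(escape and escape.apg_mutation),
        },
    )
    return sample, truth


def _segment_for(segments, chrom, pos):
    for seg in segments:
        if seg.contains(chrom, pos):
            return seg
    raise InvalidInputError(f"position {chrom}:{pos} not covered by any segment")


def _escape_variant(rng, config, segments, purity, gene, chrom, pos) -> VariantRecord:
    segment = _segment_for(segments, chrom, pos)
    v_exp = expected_vaf(1, purity, segment.total_cn)
    ref_depth, alt_depth = _draw_reads(rng, config.depth_mean, v_exp)
    alt_depth = max(alt_depth, 1)  # a planted driver must be observable
    return VariantRecord(
        chrom=chrom, pos=pos, ref="C", alt="A",
        ref_depth=ref_depth, alt_depth=alt_depth,
        gene=gene, consequence="truncating", trinucleotide_context="ACA:C>A",
    )


def simulate_sv_landscape(
    config: SimulationConfig,
    seed: int,
    covariates=(),
    covariate_effects=(),
    bin_width: int = 10_000,
) -> list:
    """Breakpoints from an inhomogeneous Poisson process, paired into SVs.

    Per fine bin, log-intensity = log(background) + sum of covariate effects
    (standardized tracks) + log(fold) inside hotspot intervals. Breakpoint
    positions are preserved exactly by the pairing, so binned end counts
    reproduce the intensity surface.
    """
    if not config.genome:
        raise InvalidInputError("empty genome")
    if config.sv_background_rate <= 0:
        raise InvalidInputError("sv_background_rate must be > 0")
    if len(covariates) != len(covariate_effects):
        raise InvalidInputError("one effect per covariate track required")

    rng = np.random.default_rng([config.seed, _SV_STREAM, seed])
    base = config.sv_background_rate * bin_width / 1e6

    z_by_chrom = {}
    if covariates:
        flats = []
        for cov in covariates:
            flat = cov.concat()
            flats.append((flat - flat.mean()) / (flat.std() or 1.0))
        offsets = {}
        offset = 0
        for chrom in sorted(covariates[0].values):
            n = covariates[0].values[chrom].size
            offsets[chrom] = (offset, offset + n)
            offset += n
        for chrom, (a, b) in offsets.items():
            z_by_chrom[chrom] = sum(
                beta * flat[a:b] for beta, flat in zip(covariate_effects, flats)
            )

    breakpoints = []
    for chrom, length, _ in config.genome:
        n_bins = int(np.ceil(length / bin_width))
        log_lam = np.full(n_bins, np.log(base))
        if chrom in z_by_chrom:
            z = z_by_chrom[chrom]
            if z.size != n_bins:
                raise InvalidInputError("covariate grid does not match genome binning")
            log_lam += z
        centres = (np.arange(n_bins) + 0.5) * bin_width
        for spec in config.hotspot_specs:
            if spec.chrom == chrom:
                inside = (centres >= spec.start) & (centres < spec.end)
                log_lam[inside] += np.log(spec.fold)
        counts = rng.poisson(np.exp(log_lam))
        for i in np.nonzero(counts)[0]:
            lo = i * bin_width
            hi = min((i + 1) * bin_width, length)
            positions = rng.integers(lo + 1, hi + 1, size=counts[i])
            breakpoints.extend((chrom, int(p)) for p in positions)

    order = rng.permutation(len(breakpoints))
    classes = sorted(c for c in config.sv_class_mixture if c != "translocation")
    probs = np.array([config.sv_class_mixture[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    strand_for = {"deletion": ("+", "-"), "tandem-duplication": ("-", "+"), "inversion": ("+", "+")}

    svs = []
    for a, b in zip(order[0::2], order[1::2]):
        (c1, p1), (c2, p2) = breakpoints[a], breakpoints[b]
        if c1 == c2:
            cls = classes[rng.choice(len(classes), p=probs)]
            s1, s2 = strand_for.get(cls, ("+", "-"))
        else:
            cls = "translocation"
            s1 = "+" if rng.random() < 0.5 else "-"
            s2 = "+" if rng.random() < 0.5 else "-"
        svs.append(
            SVRecord(
                chrom1=c1, pos1=p1, strand1=s1,
                chrom2=c2, pos2=p2, strand2=s2,
                sv_class=cls, callers=frozenset({"sim"}),
            )
        )
    return svs


def _sample_svs(config: SimulationConfig, rng) -> list:
    """Small per-sample SV load drawn from the same landscape model."""
    if config.sv_background_rate <= 0:
        return []
    return simulate_sv_landscape(config, seed=int(rng.integers(0, 2**31)))


def simulate_cohort(config: SimulationConfig) -> tuple:
    """All samples plus cohort-level ground truth."""
    samples, truths = [], []
    for i in range(config.n_samples):
        sample, truth = simulate_sample(config, i)
        samples.append(sample)
        truths.append(truth)
    cohort_truth = CohortGroundTruth(
        samples=truths,
        hotspots=[(h.chrom, h.start, h.end, h.fold) for h in config.hotspot_specs],
        driver_elements=[
            (e.element_id, e.chrom, e.start, e.end, e.fold) for e in config.driver_element_specs
        ],
    )
    return samples, cohort_truth
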