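"""End-to-end orchestration of a paired profile comparison.

``run_pair_analysis`` drives normalize → segment → center → call → difference
→ annotate for one resistant/parental pair and assembles a report with
per-sample QC (probe counts, thresholds, centering offsets, scaling fit) plus
the differential region table.  Runs are deterministic given the config and
seed; when an output directory is set, the region TSV, per-sample and
differential SEG files, the report JSON and an echo of the config are written
there.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import probe_io
from .calling import call_segments, calling_threshold, center_profile
from .differential import DifferentialResult, differential_regions
from .normalization import normalize_probeset
from .probe_io import GenomeAnnotation, ProbeSet, load_annotation, write_seg
from .segmentation import CbsParams, cbs_segment, smooth_outliers


@dataclass
class RunConfig:
    test_path: str | None = None
    ref_path: str | None = None
    cytoband_path: str | None = None
    gene_path: str | None = None
    cbs: CbsParams = field(default_factory=CbsParams)
    threshold_source: str = "diff"
    include_junction_pairs: bool = False
    centering_rule: str = "nearest-zero"
    gc_correction: bool = True
    segment_samples: bool = True
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cbs = CbsParams(**raw.pop("cbs", {}))
        return cls(cbs=cbs, **raw)


@dataclass
class PairReport:
    result: DifferentialResult
    qc: dict

    def to_json(self) -> str:
        return json.dumps(self.qc, indent=2, sort_keys=True)


def _prepare_sample(raw: ProbeSet, config: RunConfig, qc: dict):
    profile = normalize_probeset(raw, gc_correction=config.gc_correction)
    cbs = dataclasses.replace(config.cbs, seed=config.seed)
    segmented = cbs_segment(smooth_outliers(profile), cbs) if config.segment_samples else None
    profile, segmented, centering = center_profile(
        profile, segmented, rule=config.centering_rule
    )
    threshold = calling_threshold(profile, include_junctions=config.include_junction_pairs)
    called = call_segments(segmented, threshold, centering) if segmented is not None else None
    qc[raw.sample_id] = {
        "n_probes": len(raw),
        "n_dropped": raw.n_dropped,
        "normalization": profile.normalization_log,
        "centering_offset": round(centering.offset, 6),
        "centering_bandwidth": round(centering.bandwidth, 6),
        "calling_threshold": round(threshold.value, 6),
        "n_segments": len(called.segments) if called else None,
        "n_gain": called.n_gain if called else None,
        "n_loss": called.n_loss if called else None,
    }
    return profile, called


def simulate_and_diff(
    n_probes: int = 180_000,
    seed: int = 0,
    n_shared: int = 5,
    n_acquired: int = 3,
    amplitudes: tuple[float, ...] | None = None,
    noise=None,
    cbs: CbsParams | None = None,
    min_probes: int = 80,
    max_probes: int = 300,
):
    """Simulate a parental/resistant pair and run the differential comparison.

    Returns ``(DifferentialResult, truth table)``.  The pair is normalized
    (dye + GC), centered on the density peak, dynamics-scaled and differenced;
    the truth table allows recovery scoring against the generator's regions.
    """
    from . import synthetic

    design = synthetic.generate_design(n_probes=n_probes, seed=seed)
    kwargs = {} if amplitudes is None else {"amplitudes": amplitudes}
    cna = synthetic.random_cna_spec(
        design, n_shared=n_shared, n_acquired=n_acquired,
        min_probes=min_probes, max_probes=max_probes, seed=seed, **kwargs,
    )
    parental, resistant, truth = synthetic.simulate_pair(design, cna, noise=noise, seed=seed)
    profiles = []
    for raw in (resistant, parental):
        profile = normalize_probeset(raw)
        profile, _, _ = center_profile(profile)
        profiles.append(profile)
    cbs = cbs or CbsParams(seed=seed)
    result = differential_regions(profiles[0], profiles[1], cbs=cbs)
    return result, truth


def run_pair_analysis(
    config: RunConfig,
    test: ProbeSet | None = None,
    ref: ProbeSet | None = None,
    ann: GenomeAnnotation | None = None,
) -> PairReport:
    """Run the full paired comparison; inputs may be paths (via config) or objects."""
    if test is None:
        if config.test_path is None:
            raise ValueError("no test sample given")
        test = probe_io.read_probe_table(config.test_path)
    if ref is None:
        if config.ref_path is None:
            raise ValueError("no reference sample given")
        ref = probe_io.read_probe_table(config.ref_path)
    if ann is None and (config.cytoband_path or config.gene_path):
        ann = load_annotation(config.cytoband_path, config.gene_path)

    qc: dict = {"config": config.to_dict()}
    try:
        test_profile, test_called = _prepare_sample(test, config, qc)
        ref_profile, ref_called = _prepare_sample(ref, config, qc)
        cbs = dataclasses.replace(config.cbs, seed=config.seed)
        result = differential_regions(
            test_profile, ref_profile, cbs=cbs, ann=ann,
            threshold_source=config.threshold_source,
        )
    except Exception as exc:
        raise RuntimeError(f"pair analysis failed: {exc}") from exc

    qc["differential"] = {
        "scaling_slope": round(result.scaling.slope, 6),
        "scaling_intercept": round(result.scaling.intercept, 6),
        "scaled_sample": result.scaling.low_sample,
        "iqr_low": round(result.scaling.iqr_low, 6),
        "iqr_high": round(result.scaling.iqr_high, 6),
        "calling_threshold": round(result.called.threshold.value, 6),
        "n_regions": len(result.regions),
    }
    report = PairReport(result, qc)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.regions_frame().to_csv(outdir / "regions.tsv", sep="\t", index=False)
        if test_called is not None:
            write_seg(test_called, outdir / f"{test.sample_id}.seg")
        if ref_called is not None:
            write_seg(ref_called, outdir / f"{ref.sample_id}.seg")
        write_seg(result.called, outdir / "differential.seg")
        (outdir / "report.json").write_text(report.to_json() + "\n")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return report
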