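"""End-to-end orchestration from a declarative YAML config.

A run config names a reference community, a manifest of sample profiles
(with optional group labels such as library kit and homogenisation
time), and optional SAM / coverage inputs.  :func:`run_evaluation`
executes every applicable stage — per-sample reconstruction metrics,
Bray–Curtis matrix + dendrogram, host-read calibration, spike coverage
assessment, gram ratios, pairwise clade tests and PERMANOVA — and
writes a bundle of TSV/JSON tables plus a provenance sidecar.  Stages
whose inputs are absent are marked absent in the bundle, not errors,
and re-running the same config with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .community_metrics import (
    DissimilarityMatrix,
    cluster_samples,
    dissimilarity_matrix,
    evaluate_sample,
)
from .composition_stats import (
    PairwiseTestTable,
    PermanovaResult,
    gram_ratio,
    pairwise_clade_tests,
    permanova,
)
from .host_calibration import (
    SeedCalibration,
    calibrate,
    host_fraction,
    match_length_distribution,
    read_alignments,
)
from .profile_io import (
    Rank,
    ReferenceCommunity,
    TaxonProfile,
    parse_bracken,
    parse_kraken_report,
    parse_metaphlan,
    read_profile_tsv,
    read_reference_community,
)
from .spike_coverage import (
    compare_spikes,
    coverage_from_alignments,
    intervals_from_bed,
    intervals_from_sam,
    write_coverage_bed,
)

logger = logging.getLogger(__name__)

_PROFILE_READERS = {
    "kraken": parse_kraken_report,
    "kraken_bracken": lambda p: parse_bracken(p),
    "bracken": lambda p: parse_bracken(p),
    "metaphlan": parse_metaphlan,
    "canonical": lambda p: read_profile_tsv(p),
    "synthetic": lambda p: read_profile_tsv(p),
}


@dataclass
class SampleSpec:
    sample_id: str
    profile_path: Optional[Path] = None
    tool: str = "canonical"
    sam_path: Optional[Path] = None
    group: dict[str, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    reference_path: Optional[Path]
    samples: list[SampleSpec]
    outdir: Path
    detection_threshold: float = 0.0
    rmse_mode: str = "tp_only"
    percentile: float = 0.95
    min_read_length: int = 140
    alpha: float = 0.05
    n_permutations: int = 999
    seed: int = 0
    linkage: str = "average"
    permanova_formula: Optional[str] = None
    spikes: Optional[dict[str, dict[str, Any]]] = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(p: Optional[str]) -> Optional[Path]:
            return (base / p).resolve() if p else None

        samples = []
        for s in raw.get("samples", []):
            if "id" not in s:
                raise ValueError("every sample needs an 'id'")
            samples.append(
                SampleSpec(
                    sample_id=str(s["id"]),
                    profile_path=resolve(s.get("profile")),
                    tool=s.get("tool", "canonical"),
                    sam_path=resolve(s.get("sam")),
                    group={k: str(v) for k, v in (s.get("group") or {}).items()},
                )
            )
        thresholds = raw.get("thresholds", {}) or {}
        spikes = raw.get("spikes")
        if spikes:
            for side in spikes.values():
                if "path" in side:
                    side["path"] = str(resolve(side["path"]))
        cfg = cls(
            reference_path=resolve(raw.get("reference")),
            samples=samples,
            outdir=resolve(raw.get("outdir", "gutbench-out")) or Path("gutbench-out"),
            detection_threshold=float(thresholds.get("detection_threshold", 0.0)),
            rmse_mode=str(thresholds.get("rmse_mode", "tp_only")),
            percentile=float(thresholds.get("percentile", 0.95)),
            min_read_length=int(thresholds.get("min_read_length", 140)),
            alpha=float(thresholds.get("alpha", 0.05)),
            n_permutations=int(thresholds.get("n_permutations", 999)),
            seed=int(thresholds.get("seed", 0)),
            linkage=str(thresholds.get("linkage", "average")),
            permanova_formula=raw.get("permanova_formula"),
            spikes=spikes,
            raw=raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config lists no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in manifest")
        for s in self.samples:
            for p in (s.profile_path, s.sam_path):
                if p is not None and not Path(p).exists():
                    raise ValueError(f"sample {s.sample_id}: missing input {p}")
        if self.reference_path is not None and not self.reference_path.exists():
            raise ValueError(f"missing reference {self.reference_path}")

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    evaluation: Optional[pd.DataFrame] = None
    dissimilarity: Optional[DissimilarityMatrix] = None
    newick: Optional[str] = None
    host_fractions: Optional[pd.DataFrame] = None
    seed_calibrations: dict[str, SeedCalibration] = field(default_factory=dict)
    spike_assessment: Optional[dict] = None
    gram_ratios: Optional[pd.DataFrame] = None
    pairwise_tests: Optional[PairwiseTestTable] = None
    permanova_result: Optional[PermanovaResult] = None
    provenance: dict = field(default_factory=dict)


def _load_profile(spec: SampleSpec) -> TaxonProfile:
    reader = _PROFILE_READERS.get(spec.tool)
    if reader is None:
        raise ValueError(f"unknown profile tool {spec.tool!r} for sample {spec.sample_id}")
    profile = reader(spec.profile_path)
    profile.sample_id = spec.sample_id
    return profile


def run_evaluation(config: RunConfig) -> ReportBundle:
    """Execute every applicable stage of the evaluation pipeline."""
    config.validate()
    bundle = ReportBundle()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = (
        read_reference_community(config.reference_path) if config.reference_path else None
    )
    profiles = [_load_profile(s) for s in config.samples if s.profile_path]

    # --- reconstruction metrics
    if reference is not None and profiles:
        rows = []
        for p in profiles:
            res = evaluate_sample(
                p.normalized(),
                reference,
                detection_threshold=config.detection_threshold,
                rmse_mode=config.rmse_mode,  # type: ignore[arg-type]
            )
            rows.append({"sample_id": p.sample_id, **res.to_dict()})
        bundle.evaluation = pd.DataFrame(rows)
        bundle.evaluation.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)

    # --- beta diversity
    if len(profiles) >= 2:
        dm = dissimilarity_matrix([p.normalized() for p in profiles])
        bundle.dissimilarity = dm
        dm.write_tsv(outdir / "bray_curtis.tsv")
        tree = cluster_samples(dm, linkage=config.linkage)
        bundle.newick = tree.to_newick()
        (outdir / "dendrogram.nwk").write_text(bundle.newick + "\n")

    # --- gram ratios
    if reference is not None and profiles and any(
        reference.annotation(t).gram != "not_applicable" for t in reference.taxa
    ):
        rows = []
        for p in profiles:
            r = gram_ratio(p.normalized(), reference)
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "observed_ratio": r.observed_ratio,
                    "expected_ratio": r.expected_ratio,
                    "gram_positive_sum": r.gram_positive_sum,
                    "gram_negative_sum": r.gram_negative_sum,
                }
            )
        bundle.gram_ratios = pd.DataFrame(rows)
        bundle.gram_ratios.to_csv(outdir / "gram_ratios.tsv", sep="\t", index=False)

    # --- host calibration
    host_rows = []
    for s in config.samples:
        if s.sam_path is None:
            continue
        records = read_alignments(s.sam_path, min_read_length=config.min_read_length)
        dist = match_length_distribution(records)
        try:
            cal = calibrate(dist, percentile=config.percentile)
        except ValueError as exc:
            logger.warning("sample %s: host calibration skipped (%s)", s.sample_id, exc)
            continue
        bundle.seed_calibrations[s.sample_id] = cal
        hf = host_fraction(records, cal.recommended_seed, sample_id=s.sample_id)
        host_rows.append(
            {
                "sample_id": s.sample_id,
                "host_fraction_percent": hf.host_fraction,
                "seed_used": hf.seed_used,
                "n_host": hf.n_host,
                "n_total": hf.n_total,
                "split_point": cal.split_point,
            }
        )
    if host_rows:
        bundle.host_fractions = pd.DataFrame(host_rows)
        bundle.host_fractions.to_csv(outdir / "host_fractions.tsv", sep="\t", index=False)
        with open(outdir / "seed_calibration.json", "w") as fh:
            json.dump(
                {sid: c.to_dict() for sid, c in bundle.seed_calibrations.items()},
                fh,
                indent=2,
                sort_keys=True,
            )

    # --- spike coverage
    if config.spikes:
        tracks = {}
        for key in ("genome_a", "genome_b"):
            side = config.spikes[key]
            path = Path(side["path"])
            length = int(side["length"])
            gid = side.get("id", path.stem)
            if path.suffix == ".sam":
                iv = intervals_from_sam(path, min_mapq=int(side.get("min_mapq", 0)))
            else:
                iv = intervals_from_bed(path)
            tracks[key] = coverage_from_alignments(iv, length, genome_id=gid)
            write_coverage_bed(tracks[key], outdir / f"coverage_{gid}.bed")
        assessment = compare_spikes(tracks["genome_a"], tracks["genome_b"])
        bundle.spike_assessment = assessment.to_dict()
        with open(outdir / "spike_assessment.json", "w") as fh:
            json.dump(bundle.spike_assessment, fh, indent=2, sort_keys=True)

    # --- group statistics
    group_keys = sorted({k for s in config.samples for k in s.group})
    if profiles and group_keys:
        factors = pd.DataFrame(
            [{"sample_id": s.sample_id, **s.group} for s in config.samples if s.profile_path]
        ).set_index("sample_id")
        for key in group_keys:
            labels = {
                s.sample_id: s.group[key]
                for s in config.samples
                if s.profile_path and key in s.group
            }
            if len(set(labels.values())) >= 2:
                table = pairwise_clade_tests(
                    [p for p in profiles if p.sample_id in labels], labels
                )
                bundle.pairwise_tests = table
                table.rows.to_csv(
                    outdir / f"pairwise_tests_{key}.tsv", sep="\t", index=False
                )
        if bundle.dissimilarity is not None and config.permanova_formula:
            bundle.permanova_result = permanova(
                bundle.dissimilarity,
                factors.reset_index(),
                config.permanova_formula,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            bundle.permanova_result.to_dataframe().to_csv(
                outdir / "permanova.tsv", sep="\t", index=False
            )

    bundle.provenance = {
        "gutbench_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": len(config.samples),
        "stages": {
            "evaluation": bundle.evaluation is not None,
            "beta_diversity": bundle.dissimilarity is not None,
            "host_calibration": bool(bundle.seed_calibrations),
            "spike_assessment": bundle.spike_assessment is not None,
            "gram_ratios": bundle.gram_ratios is not None,
            "pairwise_tests": bundle.pairwise_tests is not None,
            "permanova": bundle.permanova_result is not None,
        },
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(bundle.provenance, fh, indent=2, sort_keys=True)
    return bundle
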