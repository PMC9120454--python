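"""Synthetic inputs with known ground truth.

Every input the evaluation pipeline consumes can be generated here:

* reference mock communities — 12-species even mixes or log-normal
  staggered mixes, with gram labels, genome lengths and GC content;
* noisy observed profiles — multiplicative abundance noise, per-species
  dropout, and a geometric tail of low-abundance false-positive
  species, mimicking the artifact species a k-mer classifier reports;
* host-alignment record sets — a bimodal mix of full-length true host
  mappings (MAPQ 60) and short-overlap spurious mappings (mostly
  MAPQ 0), writable as SAM;
* spike-genome coverage tracks — the broad-low regime of genuine
  low-abundance presence and the narrow-high regime of shared-region
  artifacts.

All generators are pure functions of their spec (including the seed).
Defaults reflect the study conditions this package evaluates: 12
species with 4 gram-positives, ~8.33% even abundance, 150-base reads
with a >=140-base length filter, short overlaps of 10-26 bases against
full-length ~150-base true mappings, and coverage regimes of breadth
~0.3 at depth 1 vs breadth 0.005 at depth 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .host_calibration import AlignmentRecord
from .profile_io import (
    Rank,
    ReferenceCommunity,
    Taxon,
    TaxonAnnotation,
    TaxonProfile,
)
from .spike_coverage import CoverageTrack

MatchDist = Union[Mapping[int, float], tuple[int, int]]


@dataclass
class CommunitySpec:
    n_species: int = 12
    distribution: str = "even"  # even | lognormal
    lognormal_mu: float = 1.0
    lognormal_sigma: float = 1.0
    n_gram_positive: int = 4
    genome_length_range: tuple[int, int] = (1_800_000, 6_500_000)
    gc_range: tuple[float, float] = (0.28, 0.60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.distribution not in {"even", "lognormal"}:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not (0 <= self.n_gram_positive <= self.n_species):
            raise ValueError("n_gram_positive must be <= n_species")
        if self.genome_length_range[0] > self.genome_length_range[1]:
            raise ValueError("genome_length_range must be ordered")
        if self.gc_range[0] > self.gc_range[1]:
            raise ValueError("gc_range must be ordered")


@dataclass
class ProfileNoiseSpec:
    fp_count: int = 0
    fp_total_abundance: float = 0.0  # percent of the final profile
    fp_decay: float = 0.5
    abundance_cv: float = 0.0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_total_abundance < 100.0):
            raise ValueError("fp_total_abundance must be in [0, 100)")
        if self.fp_count < 0 or self.abundance_cv < 0:
            raise ValueError("fp_count and abundance_cv must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if not (0.0 < self.fp_decay <= 1.0):
            raise ValueError("fp_decay must be in (0, 1]")


def _default_fp_match_dist() -> dict[int, float]:
    # bulk of spurious short overlaps well below the valley, with a sparse
    # 5% tail at 26 bases: the 95th-percentile calibration then clears the
    # bulk entirely, the pattern the seed-length raise is designed to exploit
    dist = {v: 95.0 / 12.0 for v in range(10, 22)}
    dist[26] = 5.0
    return dist


@dataclass
class ReadPopulationSpec:
    n_true_host: int = 1000
    n_short_fp: int = 1000
    n_unmapped: int = 0
    read_length: int = 150
    true_match_dist: MatchDist = (140, 150)
    fp_match_dist: MatchDist = field(default_factory=_default_fp_match_dist)
    fp_mapq0_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for dist in (self.true_match_dist, self.fp_match_dist):
            hi = max(dist) if isinstance(dist, Mapping) else dist[1]
            if hi > self.read_length:
                raise ValueError("match distribution support exceeds read_length")
        if not (0.0 <= self.fp_mapq0_prob <= 1.0):
            raise ValueError("fp_mapq0_prob must be in [0, 1]")


def make_community(spec: CommunitySpec) -> ReferenceCommunity:
    """Generate a reference mock community from a spec.

    ``even`` gives every species 100/n percent; ``lognormal`` draws
    exp(N(mu, sigma^2)) weights and normalises them to sum to 100.
    The first ``n_gram_positive`` species are labelled gram-positive.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.distribution == "even":
        weights = np.full(spec.n_species, 1.0)
    else:
        weights = np.exp(rng.normal(spec.lognormal_mu, spec.lognormal_sigma, spec.n_species))
    abundances = 100.0 * weights / weights.sum()
    lo, hi = spec.genome_length_range
    glo, ghi = spec.gc_range
    entries: dict[Taxon, float] = {}
    annotations: dict[Taxon, TaxonAnnotation] = {}
    for i in range(spec.n_species):
        t = Taxon(name=f"Simulated species {i + 1:02d}", taxid=900_000 + i, rank=Rank.SPECIES)
        entries[t] = float(abundances[i])
        annotations[t] = TaxonAnnotation(
            gram="positive" if i < spec.n_gram_positive else "negative",
            genome_length=int(rng.integers(lo, hi + 1)),
            gc_content=float(rng.uniform(glo, ghi)),
        )
    return ReferenceCommunity(
        community_id=f"synthetic-{spec.distribution}-{spec.n_species}sp-seed{spec.seed}",
        entries=entries,
        annotations=annotations,
    )


def simulate_observed_profile(
    reference: ReferenceCommunity,
    noise: ProfileNoiseSpec,
    sample_id: Optional[str] = None,
) -> TaxonProfile:
    """Simulate a profiler's output for a known community.

    Surviving true species keep their reference abundance times a
    multiplicative log-normal noise factor (mean 1, coefficient of
    variation ``abundance_cv``); each species is independently dropped
    with probability ``dropout``.  ``fp_count`` synthetic false-positive
    species are appended with geometrically decaying abundances whose
    total is ``fp_total_abundance`` percent *of the final profile* (true
    species are scaled to the complement), matching how artifact species
    dilute the mass on correctly identified taxa.  Ground-truth taxon
    sets are kept in ``meta``.
    """
    rng = np.random.default_rng(noise.seed)
    taxa = sorted(reference.entries, key=lambda t: t.key)
    survivors: list[Taxon] = []
    for attempt in range(10):
        survivors = [t for t in taxa if rng.random() >= noise.dropout]
        if survivors:
            break
    if not survivors:
        raise RuntimeError("all species dropped in 10 attempts; lower dropout")
    if noise.abundance_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise.abundance_cv**2))
        factors = np.exp(rng.normal(-(sigma**2) / 2.0, sigma, len(survivors)))
    else:
        factors = np.ones(len(survivors))
    true_raw = np.array([reference.entries[t] for t in survivors]) * factors
    fp_mass = noise.fp_total_abundance if noise.fp_count > 0 else 0.0
    true_abund = true_raw / true_raw.sum() * (100.0 - fp_mass)
    entries: dict[Taxon, float] = {t: float(a) for t, a in zip(survivors, true_abund)}
    fp_taxa: list[Taxon] = []
    if noise.fp_count > 0 and fp_mass > 0:
        w = noise.fp_decay ** np.arange(noise.fp_count)
        fp_abund = fp_mass * w / w.sum()
        for k in range(noise.fp_count):
            t = Taxon(
                name=f"Artifact species {k + 1:03d}",
                taxid=990_000 + k,
                rank=Rank.SPECIES,
            )
            entries[t] = float(fp_abund[k])
            fp_taxa.append(t)
    sid = sample_id or f"sim-{reference.community_id}-seed{noise.seed}"
    return TaxonProfile(
        sample_id=sid,
        entries=entries,
        rank=Rank.SPECIES,
        source_tool="synthetic",
        meta={
            "true_taxa": list(survivors),
            "dropped_taxa": [t for t in taxa if t not in set(survivors)],
            "fp_taxa": fp_taxa,
        },
    )


@dataclass
class SimulatedReadSet:
    records: list[AlignmentRecord]
    labels: list[str]  # true_host | short_fp | unmapped, parallel to records

    def by_label(self, label: str) -> list[AlignmentRecord]:
        return [r for r, l in zip(self.records, self.labels) if l == label]


def _draw_lengths(dist: MatchDist, n: int, rng: np.random.Generator) -> np.ndarray:
    """Dict distributions are deterministic compositions (largest-remainder
    apportionment of n over the weights); tuple (lo, hi) distributions are
    sampled discrete-uniform."""
    if isinstance(dist, Mapping):
        support = np.array(sorted(dist))
        weights = np.array([float(dist[k]) for k in support])
        exact = n * weights / weights.sum()
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        short = n - counts.sum()
        for idx in np.argsort(-remainder)[:short]:
            counts[idx] += 1
        return np.repeat(support, counts)
    lo, hi = dist
    return rng.integers(lo, hi + 1, size=n)


def simulate_alignment_records(spec: ReadPopulationSpec) -> SimulatedReadSet:
    """Generate a bimodal host-mapping read population with labels.

    True host reads map over (nearly) their whole length at MAPQ 60;
    short-overlap false positives map over a short stretch and carry
    MAPQ 0 with probability ``fp_mapq0_prob`` (else 60).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[AlignmentRecord] = []
    labels: list[str] = []
    true_lengths = _draw_lengths(spec.true_match_dist, spec.n_true_host, rng)
    for i, m in enumerate(true_lengths):
        records.append(
            AlignmentRecord(
                read_id=f"host_{i:06d}",
                mapped=True,
                match_length=int(m),
                read_length=spec.read_length,
                mapq=60,
            )
        )
        labels.append("true_host")
    fp_lengths = _draw_lengths(spec.fp_match_dist, spec.n_short_fp, rng)
    fp_mapq = np.where(rng.random(spec.n_short_fp) < spec.fp_mapq0_prob, 0, 60)
    for i, (m, q) in enumerate(zip(fp_lengths, fp_mapq)):
        records.append(
            AlignmentRecord(
                read_id=f"fp_{i:06d}",
                mapped=True,
                match_length=int(m),
                read_length=spec.read_length,
                mapq=int(q),
            )
        )
        labels.append("short_fp")
    for i in range(spec.n_unmapped):
        records.append(
            AlignmentRecord(
                read_id=f"unmapped_{i:06d}",
                mapped=False,
                match_length=0,
                read_length=spec.read_length,
                mapq=0,
            )
        )
        labels.append("unmapped")
    return SimulatedReadSet(records=records, labels=labels)


def write_sam(
    readset: SimulatedReadSet,
    path: str | Path,
    reference_name: str = "host_ref",
    reference_length: int = 1_000_000,
    seed: int = 0,
) -> None:
    """Serialise simulated records as a plain-text SAM file."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference_name}\tLN:{reference_length}\n")
        for rec in readset.records:
            seq = "A" * rec.read_length
            qual = "I" * rec.read_length
            if not rec.mapped:
                fh.write(f"{rec.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                continue
            pos = int(rng.integers(1, reference_length - rec.read_length))
            soft = rec.read_length - rec.match_length
            cigar = f"{rec.match_length}M" + (f"{soft}S" if soft else "")
            fh.write(
                f"{rec.read_id}\t0\t{reference_name}\t{pos}\t{rec.mapq}\t{cigar}"
                f"\t*\t0\t0\t{seq}\t{qual}\n"
            )


def simulate_coverage(
    genome_length: int,
    regime: str,
    p_covered: float = 0.3,
    run_fraction: float = 0.005,
    depth: int = 100,
    seed: int = 0,
    genome_id: Optional[str] = None,
) -> CoverageTrack:
    """Simulate a spike-genome coverage track.

    ``broad_low``: each position independently covered at depth 1 with
    probability ``p_covered`` — genuine low-abundance presence.
    ``narrow_high``: a single run of ``run_fraction`` of the genome at
    ``depth`` — a shared-region mapping artifact.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    rng = np.random.default_rng(seed)
    gid = genome_id or f"sim-{regime}-seed{seed}"
    if regime == "broad_low":
        if not (0.0 < p_covered <= 1.0):
            raise ValueError("p_covered must be in (0, 1]")
        covered = rng.random(genome_length) < p_covered
        edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
        runs = [(int(s), int(e), 1) for s, e in zip(edges[::2], edges[1::2])]
        return CoverageTrack(genome_id=gid, genome_length=genome_length, runs=runs)
    if regime == "narrow_high":
        if depth < 1 or not (0.0 < run_fraction <= 1.0):
            raise ValueError("invalid narrow_high parameters")
        run_len = max(1, int(round(run_fraction * genome_length)))
        start = int(rng.integers(0, genome_length - run_len + 1))
        return CoverageTrack(
            genome_id=gid,
            genome_length=genome_length,
            runs=[(start, start + run_len, depth)],
        )
    raise ValueError(f"unknown regime {regime!r}")
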