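"""Host-read contamination calibration from alignment match lengths.

Reads from a metagenome mapped against a host (human) genome fall into
two populations: true host reads, which align over essentially their
full length, and spurious mappings where only a short stretch of the
read — a region of accidental similarity shared between host and
bacterial genomes — anchors the alignment.  Left unfiltered, the short
population grossly inflates the apparent host fraction.

This module detects the bimodal structure of the match-length
distribution, splits the two populations at the density valley between
the modes (or at a user-fixed boundary), and calibrates a minimum
seed-length threshold at the 95th percentile of the short-overlap
(false-positive) match lengths.  Filtering alignments by
``match_length >= seed`` is the decision-equivalent of re-running the
aligner with the raised minimum seed length.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

DEFAULT_MIN_READ_LENGTH = 140
DEFAULT_PERCENTILE = 0.95
SMOOTH_WINDOW = 5

#: CIGAR operations that consume both query and reference (M, =, X)
_ALIGNED_OPS = {0, 7, 8}


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's mapping summary: match length, read length, MAPQ."""

    read_id: str
    mapped: bool
    match_length: int
    read_length: int
    mapq: int = 0

    def __post_init__(self) -> None:
        if not self.mapped and self.match_length != 0:
            raise ValueError("unmapped record must have match_length 0")
        if not (0 <= self.match_length <= self.read_length):
            raise ValueError(
                f"match_length {self.match_length} outside [0, read_length={self.read_length}]"
            )


@dataclass
class MatchLengthDistribution:
    lengths: list[int]
    n_mapped: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_mapped != len(self.lengths) or self.n_mapped > self.n_total:
            raise ValueError("inconsistent match-length distribution counts")


@dataclass
class SeedCalibration:
    split_point: int
    fp_lengths: list[int]
    tp_lengths: list[int]
    percentile: float
    recommended_seed: int

    def to_dict(self) -> dict:
        return {
            "split_point": self.split_point,
            "n_false_positive": len(self.fp_lengths),
            "n_true_positive": len(self.tp_lengths),
            "percentile": self.percentile,
            "recommended_seed": self.recommended_seed,
        }


@dataclass
class HostFractionResult:
    sample_id: str
    host_fraction: float  # percent of total reads
    seed_used: int
    n_host: int
    n_total: int


@dataclass
class ReadFilterLog:
    n_kept: int = 0
    n_too_short: int = 0
    n_secondary_or_supplementary: int = 0
    n_cigar_errors: int = 0


def read_alignments(
    path: str | Path,
    min_read_length: int = DEFAULT_MIN_READ_LENGTH,
    filter_log: Optional[ReadFilterLog] = None,
) -> list[AlignmentRecord]:
    """Load primary alignments from a SAM file as match-length records.

    Reads shorter than ``min_read_length`` (default 140, mirroring the
    preprocessing length filter) are excluded and counted in
    ``filter_log``.  Secondary and supplementary alignments are skipped:
    fractions are per read, not per alignment.  Match length is the sum
    of CIGAR operations that align query to reference (M/=/X).
    """
    log = filter_log if filter_log is not None else ReadFilterLog()
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_secondary or seg.is_supplementary:
                log.n_secondary_or_supplementary += 1
                continue
            read_length = seg.query_length or seg.infer_read_length() or 0
            if read_length < min_read_length:
                log.n_too_short += 1
                continue
            if seg.is_unmapped:
                records.append(
                    AlignmentRecord(
                        read_id=seg.query_name or "",
                        mapped=False,
                        match_length=0,
                        read_length=read_length,
                        mapq=0,
                    )
                )
                log.n_kept += 1
                continue
            cigar = seg.cigartuples
            if not cigar:
                log.n_cigar_errors += 1
                logger.warning("record %s: missing/unparseable CIGAR, skipped", seg.query_name)
                continue
            match_length = sum(n for op, n in cigar if op in _ALIGNED_OPS)
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name or "",
                    mapped=True,
                    match_length=match_length,
                    read_length=read_length,
                    mapq=seg.mapping_quality,
                )
            )
            log.n_kept += 1
    return records


def match_length_distribution(records: Iterable[AlignmentRecord]) -> MatchLengthDistribution:
    lengths = []
    n_total = 0
    for r in records:
        n_total += 1
        if r.mapped:
            lengths.append(r.match_length)
    return MatchLengthDistribution(lengths=lengths, n_mapped=len(lengths), n_total=n_total)


def split_populations(
    dist: MatchLengthDistribution,
    method: str = "valley",
    fixed_split: Optional[int] = None,
    smooth_window: int = SMOOTH_WINDOW,
    min_valley_depth: float = 0.5,
) -> tuple[list[int], list[int], int]:
    """Separate short-overlap false positives from full-length host reads.

    ``valley``: build a 1-base histogram of match lengths, smooth it with
    a moving average (window 5), pick the pair of modes with the deepest
    valley between them (valley depth at least ``min_valley_depth`` of
    the smaller mode, so twin sub-peaks within one population are never
    mistaken for two populations), and split at the minimum density
    strictly between the chosen modes.  ``fixed``: split at
    ``fixed_split``.  In both cases false positives are lengths strictly
    below the split point.

    Returns ``(fp_lengths, tp_lengths, split_point)``.
    """
    lengths = sorted(dist.lengths)
    if method == "fixed":
        if fixed_split is None:
            raise ValueError("fixed method requires fixed_split")
        split = int(fixed_split)
    elif method == "valley":
        if len(set(lengths)) < 2:
            raise ValueError(
                "valley method needs at least two distinct match lengths; "
                "use method='fixed' with an explicit split"
            )
        counts = np.bincount(np.asarray(lengths))
        kernel = np.ones(smooth_window) / smooth_window
        # zero-pad so a mode at either end of the observed range (e.g. at
        # full read length) is still detectable as a peak
        pad = smooth_window
        padded = np.concatenate([np.zeros(pad), counts, np.zeros(pad)])
        smooth = np.convolve(padded, kernel, mode="same")
        peaks, _ = find_peaks(smooth, prominence=0)
        best = None  # (valley depth, lo peak, hi peak)
        for ai in range(len(peaks)):
            for bi in range(ai + 1, len(peaks)):
                lo, hi = int(peaks[ai]), int(peaks[bi])
                between = smooth[lo + 1 : hi]
                if between.size == 0:
                    continue
                smaller_mode = min(smooth[lo], smooth[hi])
                depth = smaller_mode - float(between.min())
                if depth < min_valley_depth * smaller_mode:
                    continue
                if best is None or depth > best[0]:
                    best = (depth, lo, hi)
        if best is None:
            raise ValueError(
                "smoothed match-length histogram is effectively unimodal; "
                "use method='fixed' with an explicit split"
            )
        _, lo, hi = best
        split = lo + 1 + int(np.argmin(smooth[lo + 1 : hi])) - pad
    else:
        raise ValueError(f"unknown split method {method!r}")
    fp = [x for x in lengths if x < split]
    tp = [x for x in lengths if x >= split]
    return fp, tp, split


def calibrate_seed_length(
    fp_lengths: Sequence[int], percentile: float = DEFAULT_PERCENTILE
) -> int:
    """Percentile of false-positive match lengths, as an integer seed.

    Linear interpolation between order statistics, then ceiling — a seed
    length must be a whole number of bases.
    """
    if not fp_lengths:
        raise ValueError("cannot calibrate seed length from empty false-positive set")
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must be in (0, 1)")
    q = float(np.quantile(np.asarray(fp_lengths, dtype=float), percentile, method="linear"))
    return int(math.ceil(q))


def calibrate(
    dist: MatchLengthDistribution,
    percentile: float = DEFAULT_PERCENTILE,
    method: str = "valley",
    fixed_split: Optional[int] = None,
) -> SeedCalibration:
    """Split the populations and calibrate the seed length in one step."""
    fp, tp, split = split_populations(dist, method=method, fixed_split=fixed_split)
    seed = calibrate_seed_length(fp, percentile)
    return SeedCalibration(
        split_point=split,
        fp_lengths=fp,
        tp_lengths=tp,
        percentile=percentile,
        recommended_seed=seed,
    )


def host_fraction(
    records: Sequence[AlignmentRecord], seed: int, sample_id: str = ""
) -> HostFractionResult:
    """Percent of all reads mapped with match length >= ``seed``."""
    if seed < 1:
        raise ValueError("seed must be >= 1")
    n_total = len(records)
    if n_total == 0:
        raise ValueError("host fraction undefined: no reads")
    n_host = sum(1 for r in records if r.mapped and r.match_length >= seed)
    return HostFractionResult(
        sample_id=sample_id,
        host_fraction=100.0 * n_host / n_total,
        seed_used=seed,
        n_host=n_host,
        n_total=n_total,
    )


def mapq_peak_summary(records: Iterable[AlignmentRecord]) -> dict[str, int]:
    """Counts at the two characteristic MAPQ peaks.

    MAPQ 60 marks reads mapping with high confidence to a unique locus;
    MAPQ 0 marks reads placed ambiguously at multiple loci.
    """
    c = Counter()
    for r in records:
        if not r.mapped:
            continue
        if r.mapq == 60:
            c["mapq60"] += 1
        elif r.mapq == 0:
            c["mapq0"] += 1
        else:
            c["other"] += 1
    return {"mapq60": c["mapq60"], "mapq0": c["mapq0"], "other": c["other"]}
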