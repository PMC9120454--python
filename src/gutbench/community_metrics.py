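"""Community-reconstruction metrics and beta diversity.

An observed profile is scored against the known composition of a mock
community with four metrics: recall (fraction of expected species
detected), traditional precision (TP / (TP + FP) over detected species
counts), weighted precision (summed abundance of the correctly
identified species — robust to swarms of negligible false positives),
and the root-mean-square abundance error between expected and observed
percentages.  Pairwise sample dissimilarity uses the standard
quantitative Bray–Curtis measure, with average-linkage hierarchical
clustering for the dendrogram view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .profile_io import ReferenceCommunity, Taxon, TaxonProfile

RmseMode = Literal["tp_only", "all_expected"]


@dataclass(frozen=True)
class DetectionPartition:
    """TP/FP/FN split of taxa for one observed-vs-expected comparison.

    ``tp`` and ``fn`` hold *expected-side* taxa; ``fp`` holds observed
    taxa with no expected counterpart.  ``matches`` maps each TP
    expected taxon to the observed taxon it matched (taxid match may
    bridge name differences).
    """

    tp: frozenset[Taxon]
    fp: frozenset[Taxon]
    fn: frozenset[Taxon]
    detection_threshold: float = 0.0
    matches: tuple[tuple[Taxon, Taxon], ...] = ()

    def __post_init__(self) -> None:
        if self.tp & self.fn or self.tp & self.fp or self.fn & self.fp:
            raise ValueError("tp, fp, fn must be pairwise disjoint")


@dataclass
class EvaluationResult:
    partition: DetectionPartition
    recall: float
    precision: float
    weighted_precision: float
    rmse: float
    rmse_mode: RmseMode = "tp_only"

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "weighted_precision": self.weighted_precision,
            "rmse": self.rmse,
            "rmse_mode": self.rmse_mode,
            "n_tp": len(self.partition.tp),
            "n_fp": len(self.partition.fp),
            "n_fn": len(self.partition.fn),
        }


def classify_detections(
    observed: TaxonProfile,
    expected: ReferenceCommunity,
    detection_threshold: float = 0.0,
) -> DetectionPartition:
    """Partition taxa into TP/FP/FN.

    A taxon is "detected" iff its observed abundance is strictly greater
    than ``detection_threshold`` (default 0: any positive abundance
    counts, so negligible-abundance artifacts are counted as FP).
    Expected and observed taxa are matched by taxid when both carry one,
    else by normalised name.
    """
    if observed.rank is not expected.rank:
        raise ValueError(
            f"rank mismatch: observed {observed.rank.value} vs expected {expected.rank.value}"
        )
    detected = {t: a for t, a in observed.entries.items() if a > detection_threshold}
    exp_by_taxid = {t.taxid: t for t in expected.entries if t.taxid is not None}
    exp_by_key = {t.key: t for t in expected.entries}
    matches: list[tuple[Taxon, Taxon]] = []
    fp: set[Taxon] = set()
    for obs_t in detected:
        exp_t = None
        if obs_t.taxid is not None and obs_t.taxid in exp_by_taxid:
            exp_t = exp_by_taxid[obs_t.taxid]
        elif obs_t.key in exp_by_key:
            exp_t = exp_by_key[obs_t.key]
        if exp_t is None:
            fp.add(obs_t)
        else:
            matches.append((exp_t, obs_t))
    tp = {e for e, _ in matches}
    fn = expected.taxa - tp
    return DetectionPartition(
        tp=frozenset(tp),
        fp=frozenset(fp),
        fn=frozenset(fn),
        detection_threshold=detection_threshold,
        matches=tuple(matches),
    )


def recall(partition: DetectionPartition) -> float:
    """Percent of expected taxa that were detected: 100·|TP|/(|TP|+|FN|)."""
    denom = len(partition.tp) + len(partition.fn)
    if denom == 0:
        raise ValueError("recall undefined: empty expected set")
    return 100.0 * len(partition.tp) / denom


def precision_traditional(partition: DetectionPartition) -> float:
    """Percent of detected taxa that were expected: 100·|TP|/(|TP|+|FP|)."""
    denom = len(partition.tp) + len(partition.fp)
    if denom == 0:
        raise ValueError("precision undefined: nothing detected")
    return 100.0 * len(partition.tp) / denom


def weighted_precision(observed: TaxonProfile, partition: DetectionPartition) -> float:
    """Summed observed abundance of correctly identified taxa, in percent."""
    matched_obs = {o for _, o in partition.matches}
    return float(sum(observed.entries.get(t, 0.0) for t in matched_obs))


def rmse_abundance(
    observed: TaxonProfile,
    expected: ReferenceCommunity,
    partition: DetectionPartition,
    mode: RmseMode = "tp_only",
) -> float:
    """RMSE between expected and observed abundances, in percent units.

    ``tp_only`` averages over correctly identified taxa only (the
    convention used when a profiler's false negatives should not be
    charged to its abundance accuracy); ``all_expected`` averages over
    every expected taxon, scoring misses as observed 0.
    """
    obs_for = dict(partition.matches)  # expected taxon -> observed taxon
    if mode == "tp_only":
        eval_set = list(partition.tp)
    elif mode == "all_expected":
        eval_set = list(expected.taxa)
    else:
        raise ValueError(f"unknown rmse mode {mode!r}")
    if not eval_set:
        raise ValueError(f"rmse undefined: empty evaluation set in mode {mode!r}")
    sq = 0.0
    for exp_t in eval_set:
        obs_a = observed.entries.get(obs_for[exp_t], 0.0) if exp_t in obs_for else 0.0
        sq += (expected.entries[exp_t] - obs_a) ** 2
    return math.sqrt(sq / len(eval_set))


def evaluate_sample(
    observed: TaxonProfile,
    expected: ReferenceCommunity,
    detection_threshold: float = 0.0,
    rmse_mode: RmseMode = "tp_only",
) -> EvaluationResult:
    """Bundle detection partition + the four reconstruction metrics."""
    part = classify_detections(observed, expected, detection_threshold)
    return EvaluationResult(
        partition=part,
        recall=recall(part),
        precision=precision_traditional(part),
        weighted_precision=weighted_precision(observed, part),
        rmse=rmse_abundance(observed, expected, part, rmse_mode),
        rmse_mode=rmse_mode,
    )


# ---------------------------------------------------------------------------
# beta diversity


def profile_from_reference(
    expected: ReferenceCommunity, sample_id: str = "Expected"
) -> TaxonProfile:
    """View a reference community as a profile, e.g. as an extra sample
    ("Expected") in beta-diversity clustering."""
    return TaxonProfile(
        sample_id=sample_id,
        entries=dict(expected.entries),
        rank=expected.rank,
        source_tool="synthetic",
    )


def bray_curtis(p: TaxonProfile, q: TaxonProfile) -> float:
    """Quantitative Bray–Curtis dissimilarity between two profiles.

    ``1 - 2·Σ min(p_t, q_t) / (Σ p_t + Σ q_t)`` over the union of taxa;
    0 for identical communities, 1 for disjoint supports.
    """
    if p.rank is not q.rank:
        raise ValueError("profiles must be at the same rank")
    sp, sq = p.total(), q.total()
    if sp + sq == 0:
        raise ValueError("Bray-Curtis undefined for two empty profiles")
    shared = 0.0
    for t, a in p.entries.items():
        b = q.entries.get(t)
        if b is not None:
            shared += min(a, b)
    return 1.0 - 2.0 * shared / (sp + sq)


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match sample_ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("Bray-Curtis values must lie in [0, 1]")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def dissimilarity_matrix(profiles: Sequence[TaxonProfile]) -> DissimilarityMatrix:
    """All-pairs Bray–Curtis matrix over a set of profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")
    n = len(profiles)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = bray_curtis(profiles[i], profiles[j])
    return DissimilarityMatrix(sample_ids=ids, values=m)


@dataclass
class ClusterTree:
    """Agglomerative hierarchy over samples, serialisable as newick."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    method: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right}):0;"


def cluster_samples(
    matrix: DissimilarityMatrix, linkage: str = "average"
) -> ClusterTree:
    """Hierarchically cluster samples from a dissimilarity matrix.

    ``linkage`` is one of ``average`` (UPGMA, the default), ``complete``
    or ``single``.  Samples are ordered lexicographically before
    agglomeration so ties break reproducibly.
    """
    if linkage not in {"average", "complete", "single"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("non-finite dissimilarities")
    order = np.argsort(np.asarray(matrix.sample_ids, dtype=object))
    labels = [matrix.sample_ids[i] for i in order]
    values = matrix.values[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(values, checks=False), method=linkage)
    return ClusterTree(labels=labels, linkage=z, method=linkage)
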