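"""Readers, writers and normalisation for taxonomic profiles.

Profiles produced by different profilers are not directly comparable:
Bracken reports species abundance relative to *classified* reads, while
MetaPhlAn reports it relative to the whole sample input.  Every profile
handled by this package is therefore carried on one canonical scale —
percent of classified reads at a fixed taxonomic rank, summing to 100
per sample — and taxa are matched across tools by NCBI taxid when both
sides carry one, falling back to a normalised organism name otherwise.

Supported input dialects:

* Kraken2 report (six-column TSV: percent, clade reads, direct reads,
  rank code, taxid, indented name).  The printed percent column is
  rounded to two decimals, so abundances are recomputed from read
  counts.
* Bracken species table (name, taxid, rank, read counts, fraction).
* MetaPhlAn merged abundance table (pipe-delimited clade lineages with
  ``k__``/``s__`` rank prefixes).
* Expected-community TSV with optional per-taxon gram status, genome
  length and GC content.

The canonical interchange format written by :func:`write_profile_tsv`
has columns ``sample_id, taxid, name, rank, abundance_percent``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

SUM_TOL = 1e-6
#: manufacturer sheets round per-species abundances to 0.1%, so expected
#: tables may drift from 100 by up to this much before it is an error
REFERENCE_SUM_TOL = 0.1


class ProfileParseError(ValueError):
    """A profile file could not be parsed."""


class ProfileConsistencyError(ValueError):
    """A profile violates an abundance-scale invariant."""


class Rank(str, Enum):
    DOMAIN = "domain"
    KINGDOM = "kingdom"
    PHYLUM = "phylum"
    CLASS = "class"
    ORDER = "order"
    FAMILY = "family"
    GENUS = "genus"
    SPECIES = "species"
    STRAIN = "strain"


#: Kraken2 report rank codes -> ranks (suffixed codes like S1 are strains)
_KRAKEN_RANK_CODES = {
    "D": Rank.DOMAIN,
    "K": Rank.KINGDOM,
    "P": Rank.PHYLUM,
    "C": Rank.CLASS,
    "O": Rank.ORDER,
    "F": Rank.FAMILY,
    "G": Rank.GENUS,
    "S": Rank.SPECIES,
}
_RANK_TO_KRAKEN = {v: k for k, v in _KRAKEN_RANK_CODES.items()}

#: MetaPhlAn lineage prefixes -> ranks
_MPA_PREFIXES = {
    "k": Rank.KINGDOM,
    "p": Rank.PHYLUM,
    "c": Rank.CLASS,
    "o": Rank.ORDER,
    "f": Rank.FAMILY,
    "g": Rank.GENUS,
    "s": Rank.SPECIES,
    "t": Rank.STRAIN,
}

_RANK_PREFIX_RE = re.compile(r"^[a-z]__")
_WS_RE = re.compile(r"\s+")


def normalize_taxon_name(raw: str) -> str:
    """Canonicalise an organism name for cross-tool matching.

    Lowercases, strips a leading rank prefix (``s__`` and friends), maps
    underscores to spaces and collapses whitespace.  Idempotent.

    Raises
    ------
    ValueError
        If nothing remains after normalisation.
    """
    s = _RANK_PREFIX_RE.sub("", raw.strip())
    s = s.replace("_", " ").lower()
    s = _WS_RE.sub(" ", s).strip()
    if not s:
        raise ValueError(f"taxon name is empty after normalisation: {raw!r}")
    return s


@dataclass(frozen=True, eq=False)
class Taxon:
    """One taxonomic unit at a fixed rank.

    Equality and hashing use ``(rank, normalised name)`` so that e.g.
    ``s__Escherichia_coli`` and ``Escherichia coli`` are the same key.
    Taxid-aware matching across tools is done at comparison time (see
    :func:`gutbench.community_metrics.classify_detections`).
    """

    name: str
    taxid: Optional[int] = None
    rank: Rank = Rank.SPECIES
    lineage: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "_key", normalize_taxon_name(self.name))

    @property
    def key(self) -> str:
        return self._key  # type: ignore[attr-defined]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxon):
            return NotImplemented
        return self.rank is other.rank and self.key == other.key

    def __hash__(self) -> int:
        return hash((self.rank, self.key))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tid = f", taxid={self.taxid}" if self.taxid is not None else ""
        return f"Taxon({self.name!r}{tid}, rank={self.rank.value})"


@dataclass
class TaxonProfile:
    """A sample's per-taxon relative abundances, in percent."""

    sample_id: str
    entries: dict[Taxon, float]
    rank: Rank = Rank.SPECIES
    source_tool: str = "other"
    classified_reads: Optional[int] = None
    total_reads: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, a in self.entries.items():
            if a < 0:
                raise ProfileConsistencyError(
                    f"negative abundance {a} for {t.name} in {self.sample_id}"
                )
        if (
            self.classified_reads is not None
            and self.total_reads is not None
            and self.classified_reads > self.total_reads
        ):
            raise ProfileConsistencyError(
                f"classified_reads > total_reads in sample {self.sample_id}"
            )

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def abundance(self, taxon: Taxon) -> float:
        return self.entries.get(taxon, 0.0)

    def normalized(self, target: float = 100.0) -> "TaxonProfile":
        """Return a copy rescaled so abundances sum to ``target``."""
        s = self.total()
        if s <= 0:
            raise ProfileConsistencyError(
                f"cannot normalise empty/zero profile {self.sample_id}"
            )
        entries = {t: a * target / s for t, a in self.entries.items()}
        return TaxonProfile(
            sample_id=self.sample_id,
            entries=entries,
            rank=self.rank,
            source_tool=self.source_tool,
            classified_reads=self.classified_reads,
            total_reads=self.total_reads,
            meta=dict(self.meta),
        )


@dataclass
class TaxonAnnotation:
    gram: str = "not_applicable"  # positive | negative | not_applicable
    genome_length: Optional[int] = None
    gc_content: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gram not in {"positive", "negative", "not_applicable"}:
            raise ValueError(f"bad gram status {self.gram!r}")
        if self.genome_length is not None and self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if self.gc_content is not None and not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")


@dataclass
class ReferenceCommunity:
    """Known (expected) composition of a mock community, in percent."""

    community_id: str
    entries: dict[Taxon, float]
    annotations: dict[Taxon, TaxonAnnotation] = field(default_factory=dict)
    rank: Rank = Rank.SPECIES

    def __post_init__(self) -> None:
        s = sum(self.entries.values())
        if abs(s - 100.0) > SUM_TOL:
            raise ProfileConsistencyError(
                f"reference community {self.community_id} sums to {s}, not 100"
            )

    @property
    def taxa(self) -> set[Taxon]:
        return set(self.entries)

    def annotation(self, taxon: Taxon) -> TaxonAnnotation:
        return self.annotations.get(taxon, TaxonAnnotation())


# ---------------------------------------------------------------------------
# parsers


def parse_kraken_report(path: str | Path, rank: Rank = Rank.SPECIES) -> TaxonProfile:
    """Parse a Kraken2 report, returning abundances at one rank.

    Abundances are recomputed as percent of classified reads (clade reads
    at the requested rank / reads under the classified root x 100); the
    rounded percent column in the file is ignored.
    """
    path = Path(path)
    classified = None
    unclassified = 0
    rows: list[tuple[str, int, int]] = []  # (name, taxid, clade_reads)
    skipped = 0
    want_code = _RANK_TO_KRAKEN[rank]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ProfileParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                clade_reads = int(parts[1])
                taxid = int(parts[4])
            except ValueError as exc:
                raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
            code = parts[3].strip()
            name = parts[5].strip()
            if code == "U":
                unclassified = clade_reads
                continue
            if code == "R" or name == "root":
                if classified is None:
                    classified = clade_reads
                continue
            base = code[0] if code else ""
            if base not in _KRAKEN_RANK_CODES:
                skipped += 1
                logger.debug("%s:%d: unknown rank code %r, row skipped", path, lineno, code)
                continue
            if code == want_code:
                rows.append((name, taxid, clade_reads))
    if classified is None:
        raise ProfileParseError(f"{path}: no classified root row found")
    entries: dict[Taxon, float] = {}
    for name, taxid, clade_reads in rows:
        t = Taxon(name=name, taxid=taxid, rank=rank)
        entries[t] = entries.get(t, 0.0) + 100.0 * clade_reads / classified
    if not entries:
        logger.warning("%s: no rows at rank %s; returning empty profile", path, rank.value)
    return TaxonProfile(
        sample_id=path.stem,
        entries=entries,
        rank=rank,
        source_tool="kraken_bracken",
        classified_reads=classified,
        total_reads=classified + unclassified,
        meta={"skipped_rows": skipped},
    )


def parse_bracken(path: str | Path) -> TaxonProfile:
    """Parse a Bracken species table; abundances = fraction column x 100.

    Rows are renormalised to sum to exactly 100; if the raw fractions sum
    outside [0.99, 1.01] a warning is recorded in ``meta``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"name", "fraction_total_reads"}
    if not required.issubset(df.columns):
        raise ProfileParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    count_cols = [c for c in df.columns if c.endswith("_reads") and c != "fraction_total_reads"]
    for c in count_cols:
        if (df[c] < 0).any():
            raise ProfileParseError(f"{path}: negative read count in column {c}")
    raw_sum = float(df["fraction_total_reads"].sum())
    meta: dict = {}
    if not (0.99 < raw_sum < 1.01):
        meta["fraction_sum_warning"] = raw_sum
        logger.warning("%s: fractions sum to %.4f before renormalisation", path, raw_sum)
    entries: dict[Taxon, float] = {}
    for _, row in df.iterrows():
        taxid = int(row["taxonomy_id"]) if "taxonomy_id" in df.columns else None
        t = Taxon(name=str(row["name"]), taxid=taxid, rank=Rank.SPECIES)
        entries[t] = entries.get(t, 0.0) + 100.0 * float(row["fraction_total_reads"]) / raw_sum
    return TaxonProfile(
        sample_id=path.stem,
        entries=entries,
        rank=Rank.SPECIES,
        source_tool="kraken_bracken",
        meta=meta,
    )


def parse_metaphlan(path: str | Path, rank: Rank = Rank.SPECIES) -> TaxonProfile:
    """Parse a MetaPhlAn merged-abundance table at one rank.

    Keeps rows whose deepest clade matches ``rank``; sub-species (``t__``)
    rows are aggregated into their parent species when species rank is
    requested.  Rank prefixes are stripped and underscores mapped to
    spaces in taxon names.
    """
    path = Path(path)
    entries: dict[Taxon, float] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ProfileParseError(f"{path}:{lineno}: expected >=2 columns")
            lineage = parts[0]
            if lineage.lower().startswith("clade_name"):
                continue
            clades = lineage.split("|")
            prefixed = [c for c in clades if len(c) > 3 and c[1:3] == "__"]
            if not prefixed:
                n_skipped += 1
                logger.debug("%s:%d: unrecognised lineage %r", path, lineno, lineage)
                continue
            deepest = prefixed[-1]
            deepest_rank = _MPA_PREFIXES.get(deepest[0])
            if deepest_rank is None:
                n_skipped += 1
                continue
            target = deepest
            if rank is Rank.SPECIES and deepest_rank is Rank.STRAIN:
                # aggregate unresolved sub-species rows into the parent species
                species = [c for c in prefixed if c.startswith("s__")]
                if not species:
                    continue
                target, deepest_rank = species[-1], Rank.SPECIES
            if deepest_rank is not rank:
                continue
            try:
                abundance = float(parts[-1])
            except ValueError as exc:
                raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
            t = Taxon(name=target[3:].replace("_", " "), rank=rank)
            entries[t] = entries.get(t, 0.0) + abundance
    if not entries:
        logger.warning("%s: no rows at rank %s; returning empty profile", path, rank.value)
    return TaxonProfile(
        sample_id=path.stem,
        entries=entries,
        rank=rank,
        source_tool="metaphlan",
        meta={"skipped_rows": n_skipped},
    )


def renormalize_to_classified(
    profile: TaxonProfile, classified_fraction: float
) -> TaxonProfile:
    """Rescale a whole-input-relative profile onto the classified-reads scale.

    MetaPhlAn-style abundances are relative to all input reads; dividing
    by the classified fraction makes them comparable with Bracken's
    classified-relative abundances.
    """
    if not (0.0 < classified_fraction <= 1.0):
        raise ValueError(f"classified_fraction must be in (0, 1], got {classified_fraction}")
    entries = {t: a / classified_fraction for t, a in profile.entries.items()}
    for t, a in entries.items():
        if a > 100.0 + SUM_TOL:
            raise ProfileConsistencyError(
                f"{t.name}: abundance {a:.4f}% exceeds 100% after rescaling by "
                f"classified fraction {classified_fraction}"
            )
    return TaxonProfile(
        sample_id=profile.sample_id,
        entries=entries,
        rank=profile.rank,
        source_tool=profile.source_tool,
        classified_reads=profile.classified_reads,
        total_reads=profile.total_reads,
        meta=dict(profile.meta),
    )


def read_reference_community(path: str | Path) -> ReferenceCommunity:
    """Read an expected-community TSV.

    Mandatory columns ``name`` and ``expected_abundance``; optional
    ``taxid``, ``gram``, ``genome_length``, ``gc_content``.  Abundances
    must sum to 100 within 0.1 (manufacturer tables round) and are then
    renormalised to exactly 100.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "expected_abundance"):
        if col not in df.columns:
            raise ProfileParseError(f"{path}: missing mandatory column {col!r}")
    names = [normalize_taxon_name(str(n)) for n in df["name"]]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ProfileParseError(f"{path}: duplicate taxon names {dupes}")
    s = float(df["expected_abundance"].sum())
    if abs(s - 100.0) > REFERENCE_SUM_TOL:
        raise ProfileParseError(
            f"{path}: expected abundances sum to {s:.4f}, outside 100 +/- {REFERENCE_SUM_TOL}"
        )
    if abs(s - 100.0) > SUM_TOL:
        logger.info("%s: renormalising expected abundances (sum %.4f -> 100)", path, s)
    entries: dict[Taxon, float] = {}
    annotations: dict[Taxon, TaxonAnnotation] = {}
    for _, row in df.iterrows():
        taxid = None
        if "taxid" in df.columns and not pd.isna(row["taxid"]):
            taxid = int(row["taxid"])
        t = Taxon(name=str(row["name"]), taxid=taxid, rank=Rank.SPECIES)
        entries[t] = 100.0 * float(row["expected_abundance"]) / s
        ann = TaxonAnnotation(
            gram=str(row["gram"]) if "gram" in df.columns and not pd.isna(row.get("gram")) else "not_applicable",
            genome_length=int(row["genome_length"])
            if "genome_length" in df.columns and not pd.isna(row.get("genome_length"))
            else None,
            gc_content=float(row["gc_content"])
            if "gc_content" in df.columns and not pd.isna(row.get("gc_content"))
            else None,
        )
        annotations[t] = ann
    return ReferenceCommunity(
        community_id=path.stem, entries=entries, annotations=annotations
    )


# ---------------------------------------------------------------------------
# canonical interchange format


def write_profile_tsv(profile: TaxonProfile, path: str | Path) -> None:
    """Write the canonical profile TSV (the downstream interchange format)."""
    rows = [
        {
            "sample_id": profile.sample_id,
            "taxid": t.taxid if t.taxid is not None else "",
            "name": t.name,
            "rank": t.rank.value,
            "abundance_percent": repr(a),
        }
        for t, a in sorted(profile.entries.items(), key=lambda kv: kv[0].key)
    ]
    pd.DataFrame(rows, columns=["sample_id", "taxid", "name", "rank", "abundance_percent"]).to_csv(
        path, sep="\t", index=False
    )


def read_profile_tsv(path: str | Path) -> TaxonProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ProfileParseError(f"{path}: empty profile table")
    ranks = {Rank(r) for r in df["rank"]}
    if len(ranks) != 1:
        raise ProfileParseError(f"{path}: mixed ranks {sorted(r.value for r in ranks)}")
    rank = ranks.pop()
    entries: dict[Taxon, float] = {}
    for _, row in df.iterrows():
        taxid = None if pd.isna(row["taxid"]) else int(row["taxid"])
        t = Taxon(name=str(row["name"]), taxid=taxid, rank=rank)
        entries[t] = entries.get(t, 0.0) + float(row["abundance_percent"])
    return TaxonProfile(
        sample_id=str(df["sample_id"].iloc[0]), entries=entries, rank=rank
    )


def write_reference_tsv(community: ReferenceCommunity, path: str | Path) -> None:
    rows = []
    for t, a in sorted(community.entries.items(), key=lambda kv: kv[0].key):
        ann = community.annotation(t)
        rows.append(
            {
                "name": t.name,
                "taxid": t.taxid if t.taxid is not None else "",
                "expected_abundance": repr(a),
                "gram": ann.gram,
                "genome_length": ann.genome_length if ann.genome_length is not None else "",
                "gc_content": ann.gc_content if ann.gc_content is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
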