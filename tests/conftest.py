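import textwrap

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gutbench import (
    CommunitySpec,
    Rank,
    ReferenceCommunity,
    Taxon,
    TaxonProfile,
    make_community,
)


def make_profile(entries: dict[str, float], sample_id: str = "s", **kw) -> TaxonProfile:
    """Shorthand: build a species-rank profile from name -> percent."""
    return TaxonProfile(
        sample_id=sample_id,
        entries={Taxon(name=n, rank=Rank.SPECIES): a for n, a in entries.items()},
        rank=Rank.SPECIES,
        **kw,
    )


def make_reference(entries: dict[str, float], community_id: str = "ref") -> ReferenceCommunity:
    return ReferenceCommunity(
        community_id=community_id,
        entries={Taxon(name=n, rank=Rank.SPECIES): a for n, a in entries.items()},
    )


@pytest.fixture
def even12_community():
    """12 species, even abundance, 4 gram-positive — the standard mock mix."""
    return make_community(CommunitySpec(n_species=12, distribution="even", n_gram_positive=4, seed=7))


@pytest.fixture
def kraken_report(tmp_path):
    """Kraken2 report: 900 classified of 1000, two species at 450 reads each."""
    text = textwrap.dedent(
        """\
        10.00\t100\t100\tU\t0\tunclassified
        90.00\t900\t0\tR\t1\troot
        90.00\t900\t0\tD\t2\t  Bacteria
        45.00\t450\t450\tS\t561\t    Escherichia coli
        45.00\t450\t450\tS\t562\t    Salmonella enterica
        """
    )
    p = tmp_path / "sample1.kreport"
    p.write_text(text)
    return p


@pytest.fixture
def bracken_table(tmp_path):
    text = (
        "name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads\tadded_reads\t"
        "new_est_reads\tfraction_total_reads\n"
        "Escherichia coli\t561\tS\t250\t0\t250\t0.25\n"
        "Salmonella enterica\t562\tS\t750\t0\t750\t0.75\n"
    )
    p = tmp_path / "sample1.bracken"
    p.write_text(text)
    return p


@pytest.fixture
def metaphlan_table(tmp_path):
    text = textwrap.dedent(
        """\
        #mpa_v295_CHOCOPhlAn_201901
        clade_name\trelative_abundance
        k__Bacteria\t100.0
        k__Bacteria|p__Proteobacteria\t100.0
        k__Bacteria|p__Proteobacteria|c__Gammaproteobacteria|o__Enterobacterales|f__Enterobacteriaceae|g__Escherichia|s__Escherichia_coli\t12.34
        k__Bacteria|p__Proteobacteria|c__Gammaproteobacteria|o__Enterobacterales|f__Enterobacteriaceae|g__Salmonella|s__Salmonella_enterica\t87.66
        """
    )
    p = tmp_path / "merged_abundance.tsv"
    p.write_text(text)
    return p


@pytest.fixture
def reference_tsv(tmp_path):
    """Manufacturer-style sheet: 12 species rounded to 8.333 each."""
    lines = ["name\ttaxid\texpected_abundance\tgram\tgenome_length\tgc_content"]
    for i in range(12):
        gram = "positive" if i < 4 else "negative"
        lines.append(f"Mock species {i + 1:02d}\t{7000 + i}\t8.333\t{gram}\t{3000000 + i}\t0.45")
    p = tmp_path / "reference.tsv"
    p.write_text("\n".join(lines) + "\n")
    return p
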