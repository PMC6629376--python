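"""Shared fixtures: compact taxonomy factories for hand-written trees.

Leaf-label conventions used throughout the tests:

* ``E_gal*``  - focal *Galdieria* strain (strain name = label suffix)
* ``E_cya*``  - focal *Cyanidioschyzon* strain
* ``E_o*``    - non-focal eukaryote
* ``E_photo*``- non-focal photosynthetic eukaryote
* ``B_cyano*``- cyanobacterium
* ``B_*``     - other bacterium (species = label body, phylum from suffix)
* ``A_*``     - archaeon
"""

from __future__ import annotations

import re

import pytest

from cyanihgt import Kingdom, Lineage, TaxonInfo


def make_taxon(label: str) -> TaxonInfo:
    if label.startswith("E_gal"):
        return TaxonInfo(label, Kingdom.EUKARYOTA, species=label[2:],
                         genus="Galdieria", phylum="Rhodophyta",
                         is_focal=True, lineage=Lineage.GALDIERIA,
                         strain=label[2:])
    if label.startswith("E_cya"):
        return TaxonInfo(label, Kingdom.EUKARYOTA, species=label[2:],
                         genus="Cyanidioschyzon", phylum="Rhodophyta",
                         is_focal=True, lineage=Lineage.CYANIDIOSCHYZON,
                         strain=label[2:])
    if label.startswith("E_photo"):
        return TaxonInfo(label, Kingdom.EUKARYOTA, species=label[2:],
                         genus="Arabidopsis", phylum="Streptophyta",
                         is_photosynthetic_eukaryote=True)
    if label.startswith("E_"):
        return TaxonInfo(label, Kingdom.EUKARYOTA, species=label[2:],
                         genus="Homo", phylum="Opisthokonta")
    if label.startswith("B_cyano"):
        return TaxonInfo(label, Kingdom.BACTERIA, species=label[2:],
                         genus="Synechocystis", phylum="Cyanobacteria",
                         is_cyanobacteria=True)
    if label.startswith("B_"):
        body = label[2:]
        phylum = "Proteobacteria"
        m = re.match(r".*@(\w+)$", body)
        if m:  # explicit phylum tag: B_x@Firmicutes
            phylum = m.group(1)
            body = body.split("@")[0]
        return TaxonInfo(label, Kingdom.BACTERIA, species=body,
                         genus=body[:2] or body, phylum=phylum)
    if label.startswith("A_"):
        return TaxonInfo(label, Kingdom.ARCHAEA, species=label[2:],
                         genus=label[2:4], phylum="Euryarchaeota")
    raise ValueError(f"unrecognized test label {label!r}")


def taxonomy_for(newick: str) -> dict[str, TaxonInfo]:
    labels = re.findall(r"[ABE]_[A-Za-z0-9@]+", newick)
    return {lab: make_taxon(lab) for lab in dict.fromkeys(labels)}


@pytest.fixture
def tax_factory():
    return taxonomy_for
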