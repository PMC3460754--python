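"""The study's taxon panel and accepted species relationships.

The system is the endophytic holoparasite *Rafflesia* (Malpighiales) and its
obligate grapevine-family host *Tetrastigma* (Vitaceae), analysed against
nine reference genomes with *Oryza* as outgroup.  Roles drive the
classification rule sets: a parasite transcript placed with its Malpighiales
relatives is vertically inherited (VGT); one placed with the host-clade
*Vitis* is a candidate horizontal transfer (HGT).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Species",
    "make_species_panel",
    "PANEL_GENOMES",
    "SPECIES_TREE_NEWICK",
    "OUTGROUP",
    "PARASITE",
    "HOST_TAXON",
    "HOST_PROXY",
    "PARASITE_RELATIVES",
]


@dataclass(frozen=True)
class Species:
    """One genome of the panel: its clade and its role in the analysis."""

    name: str
    clade: str
    role: str  # outgroup | parasite | host | host_relative | relative | other


#: Outgroup used to root every gene tree.
OUTGROUP = "Oryza"
#: Focal holoparasite.
PARASITE = "Rafflesia"
#: The host lineage sampled by transcriptome (no genome available).
HOST_TAXON = "Tetrastigma"
#: Sequenced close relative of the host; the HGT "transfer" side for the parasite.
HOST_PROXY = "Vitis"
#: Sequenced close relatives of the parasite (Malpighiales); the VGT side.
PARASITE_RELATIVES = ("Manihot", "Populus", "Ricinus")

_PANEL = (
    Species("Oryza", "Poales", "outgroup"),
    Species("Aquilegia", "Ranunculales", "other"),
    Species("Vitis", "Vitaceae", "host_relative"),
    Species("Tetrastigma", "Vitaceae", "host"),
    Species("Medicago", "Fabales", "other"),
    Species("Arabidopsis", "Brassicales", "other"),
    Species("Populus", "Malpighiales", "relative"),
    Species("Manihot", "Malpighiales", "relative"),
    Species("Ricinus", "Malpighiales", "relative"),
    Species("Rafflesia", "Malpighiales", "parasite"),
    Species("Mimulus", "Lamiales", "other"),
)

#: Genome names accepted in cluster/tip tables.
PANEL_GENOMES = frozenset(s.name for s in _PANEL)

#: Accepted species relationships (rooted on Oryza): Ranunculales sister to
#: core eudicots; rosids = Vitaceae + (fabids incl. Malpighiales, malvids);
#: Rafflesiaceae nested in Malpighiales sister to the Euphorbiaceae pair.
SPECIES_TREE_NEWICK = (
    "(Oryza,(Aquilegia,(((Vitis,Tetrastigma),"
    "((Medicago,(Populus,((Manihot,Ricinus),Rafflesia))),Arabidopsis)),"
    "Mimulus)));"
)


def make_species_panel() -> list[Species]:
    """Return the taxon panel with clade and role tags.

    The panel covers the parasite, its obligate host lineage, the sequenced
    close relatives of each, the outgroup, and the remaining reference
    genomes used only to diagnose "unassigned" placements.
    """
    return list(_PANEL)


def clade_of(genome: str) -> str:
    for s in _PANEL:
        if s.name == genome:
            return s.clade
    raise KeyError(f"unknown genome: {genome!r}")
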