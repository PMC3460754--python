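"""Sister-group classification of focal transcripts as VGT, HGT or unassigned.

A focal (parasite or host) transcript is classified from its rooted gene
tree: ascend from the tip to the first ancestor contributing at least one
non-focal tip; the genomes of those tips form the sister set.  VGT requires
the sister set to lie within the focal taxon's closest organismal relatives,
HGT within the transfer (host-side) set, and either call additionally
requires the bootstrap support of the edge subtending the (focal + sister)
clade to reach the threshold tau (default 50).  Everything else — mixed
sister sets, placements with the remaining reference taxa, sub-threshold
support — is unassigned.

Cluster retention mirrors the study design: a gene cluster enters the
analysis only if it contains the outgroup (for rooting), the focal taxon,
at least one close relative, and at least one transfer-side taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import ValidationError
from .io import GeneCluster
from .taxa import HOST_PROXY, OUTGROUP, PARASITE, PARASITE_RELATIVES
from .tree import SupportTree

__all__ = [
    "ClassifierConfig",
    "TranscriptClassification",
    "ClassificationSummary",
    "filter_clusters",
    "root_on_outgroup",
    "classify_tip",
    "classify_all",
    "sweep_thresholds",
    "rafflesia_config",
    "tetrastigma_config",
    "control_config",
]

DEFAULT_SWEEP = (50, 55, 60, 65, 70)


@dataclass(frozen=True)
class ClassifierConfig:
    """Rule sets and support threshold for one focal taxon."""

    focal_taxon: str = PARASITE
    relative_set: frozenset[str] = frozenset(PARASITE_RELATIVES)
    transfer_set: frozenset[str] = frozenset({HOST_PROXY})
    outgroup: str = OUTGROUP
    bs_threshold: int = 50

    def __post_init__(self):
        if self.relative_set & self.transfer_set:
            raise ValidationError("relative_set and transfer_set must be disjoint")
        if self.focal_taxon in self.relative_set | self.transfer_set:
            raise ValidationError("focal taxon cannot appear in a rule set")
        if not 0 <= self.bs_threshold <= 100:
            raise ValidationError("bs_threshold outside [0, 100]")

    def swapped(self) -> "ClassifierConfig":
        """Rule sets exchanged (VGT and HGT labels swap exactly)."""
        return replace(
            self, relative_set=self.transfer_set, transfer_set=self.relative_set
        )


def rafflesia_config(bs_threshold: int = 50) -> ClassifierConfig:
    return ClassifierConfig(bs_threshold=bs_threshold)


def tetrastigma_config(bs_threshold: int = 50) -> ClassifierConfig:
    return ClassifierConfig(
        focal_taxon="Tetrastigma",
        relative_set=frozenset({HOST_PROXY}),
        transfer_set=frozenset(PARASITE_RELATIVES),
        bs_threshold=bs_threshold,
    )


def control_config(focal: str, bs_threshold: int = 50) -> ClassifierConfig:
    """Background-rate control: a non-parasitic Malpighiales genome
    (Manihot or Ricinus) analysed exactly as the parasite is."""
    relatives = (frozenset(PARASITE_RELATIVES) | {PARASITE}) - {focal}
    return ClassifierConfig(
        focal_taxon=focal,
        relative_set=relatives,
        transfer_set=frozenset({HOST_PROXY}),
        bs_threshold=bs_threshold,
    )


@dataclass(frozen=True)
class TranscriptClassification:
    transcript_id: str
    cluster_id: str
    category: str  # VGT | HGT | unassigned
    sister_genomes: frozenset[str]
    support: int | None
    outgroup_conflict: bool = False


# ---------------------------------------------------------------------------


def filter_clusters(
    clusters: Iterable[GeneCluster], cfg: ClassifierConfig
) -> list[GeneCluster]:
    """Retain clusters containing outgroup, focal taxon, >=1 relative and
    >=1 transfer-side taxon."""
    kept = []
    for cl in clusters:
        genomes = cl.genomes()
        if (
            cfg.outgroup in genomes
            and cfg.focal_taxon in genomes
            and genomes & cfg.relative_set
            and genomes & cfg.transfer_set
        ):
            kept.append(cl)
    return kept


def root_on_outgroup(
    tree: SupportTree, cfg: ClassifierConfig
) -> tuple[SupportTree, bool]:
    """Root a gene tree on its outgroup; see
    :meth:`SupportTree.root_on_outgroup`."""
    return tree.root_on_outgroup(cfg.outgroup)


def _categorize(
    sister: frozenset[str],
    support: int | None,
    cfg: ClassifierConfig,
    tau: int,
) -> str:
    if not sister or support is None or support < tau:
        return "unassigned"
    if sister <= cfg.relative_set:
        return "VGT"
    if sister <= cfg.transfer_set:
        return "HGT"
    return "unassigned"


def _sister_placement(
    tree: SupportTree, tip_label: str, focal_taxon: str
) -> tuple[frozenset[str], int | None]:
    """Ascend from a focal tip to the first ancestor with non-focal
    descendants; return (sister genome set, support of the edge subtending
    the focal+sister clade).  Other focal-taxon tips met on the way are
    treated as part of the focal lineage and skipped."""
    parents = tree.parents()
    node = tree.find_tip(tip_label)
    current = node
    while True:
        anc = parents.get(id(current))
        if anc is None:  # reached the root without a non-focal sister
            return frozenset(), None
        sister_tips = [
            t
            for child in anc.children
            if child is not current
            for t in child.tip_labels()
        ]
        non_focal = [t for t in sister_tips if tree.tip_genome[t] != focal_taxon]
        if non_focal:
            support = anc.support if id(anc) in parents else None
            return frozenset(tree.tip_genome[t] for t in non_focal), support
        current = anc


def classify_tip(
    tree: SupportTree,
    tip_label: str,
    cfg: ClassifierConfig,
    cluster_id: str = "",
    outgroup_conflict: bool = False,
) -> TranscriptClassification:
    """Classify one focal tip on an already-rooted gene tree."""
    sister, support = _sister_placement(tree, tip_label, cfg.focal_taxon)
    category = _categorize(sister, support, cfg, cfg.bs_threshold)
    return TranscriptClassification(
        transcript_id=tip_label,
        cluster_id=cluster_id,
        category=category,
        sister_genomes=sister,
        support=support,
        outgroup_conflict=outgroup_conflict,
    )


@dataclass
class ClassificationSummary:
    """Counts and percentages over all observed focal transcripts."""

    focal_taxon: str
    bs_threshold: int
    n_total: int
    n_vgt: int
    n_hgt: int
    n_unassigned: int

    @property
    def pct_vgt(self) -> float | None:
        return None if self.n_total == 0 else 100.0 * self.n_vgt / self.n_total

    @property
    def pct_hgt(self) -> float | None:
        return None if self.n_total == 0 else 100.0 * self.n_hgt / self.n_total

    @property
    def pct_hgt_resolved(self) -> float | None:
        """HGT percentage among resolved (VGT+HGT) transcripts, the
        denominator used in the threshold sweep."""
        resolved = self.n_vgt + self.n_hgt
        return None if resolved == 0 else 100.0 * self.n_hgt / resolved

    def as_dict(self) -> dict:
        return {
            "focal_taxon": self.focal_taxon,
            "bs_threshold": self.bs_threshold,
            "n_total": self.n_total,
            "n_vgt": self.n_vgt,
            "n_hgt": self.n_hgt,
            "n_unassigned": self.n_unassigned,
            "pct_vgt": self.pct_vgt,
            "pct_hgt": self.pct_hgt,
            "pct_hgt_resolved": self.pct_hgt_resolved,
        }


def classify_all(
    clusters: Sequence[GeneCluster], cfg: ClassifierConfig
) -> tuple[list[TranscriptClassification], ClassificationSummary]:
    """Filter, root and classify every focal transcript.

    Every focal tip in every retained cluster receives exactly one of the
    three categories, so VGT + HGT + unassigned = observed transcripts.
    """
    results: list[TranscriptClassification] = []
    for cl in filter_clusters(clusters, cfg):
        if cl.tree is None:
            raise ValidationError(f"cluster {cl.cluster_id} has no tree")
        rooted, conflict = root_on_outgroup(cl.tree, cfg)
        for tip, genome in rooted.tip_genome.items():
            if genome == cfg.focal_taxon:
                results.append(
                    classify_tip(rooted, tip, cfg, cl.cluster_id, conflict)
                )
    counts = {"VGT": 0, "HGT": 0, "unassigned": 0}
    for r in results:
        counts[r.category] += 1
    summary = ClassificationSummary(
        focal_taxon=cfg.focal_taxon,
        bs_threshold=cfg.bs_threshold,
        n_total=len(results),
        n_vgt=counts["VGT"],
        n_hgt=counts["HGT"],
        n_unassigned=counts["unassigned"],
    )
    return results, summary


def sweep_thresholds(
    clusters: Sequence[GeneCluster],
    cfg: ClassifierConfig,
    thresholds: Sequence[int] = DEFAULT_SWEEP,
) -> dict[int, dict]:
    """HGT percentage among resolved transcripts at each support threshold.

    The sister placement is threshold-free; only the support cut moves, so
    the tree work is done once.  At a threshold with no resolved transcript
    the percentage is reported as ``None`` (undefined), never zero.
    """
    for tau in thresholds:
        if not 0 <= tau <= 100:
            raise ValidationError(f"threshold {tau} outside [0, 100]")
    base, _ = classify_all(clusters, replace(cfg, bs_threshold=0))
    table: dict[int, dict] = {}
    for tau in thresholds:
        n_vgt = n_hgt = n_un = 0
        for r in base:
            cat = _categorize(r.sister_genomes, r.support, cfg, tau)
            if cat == "VGT":
                n_vgt += 1
            elif cat == "HGT":
                n_hgt += 1
            else:
                n_un += 1
        resolved = n_vgt + n_hgt
        table[tau] = {
            "n_vgt": n_vgt,
            "n_hgt": n_hgt,
            "n_unassigned": n_un,
            "n_resolved": resolved,
            "pct_hgt_resolved": (
                None if resolved == 0 else 100.0 * n_hgt / resolved
            ),
        }
    return table
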