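"""Synthetic study generator with planted ground truth.

Emulates the full host–parasite transcriptome study at desk scale so every
downstream stage is testable without the original sequencing data:

* gene trees for the taxon panel, restricted per cluster to a random taxon
  subset that always satisfies the retention filter; a configurable
  fraction of clusters receives a planted HGT (the parasite tip regrafted
  as sister to the host-clade *Vitis* tip) and a configurable fraction
  receives one random ingroup NNI rearrangement (topological noise);
  bootstrap supports are drawn high on undisturbed edges and low on the
  rearranged edge;
* genome-specific codon-usage profiles drawn hierarchically (one draw per
  clade, a concentrated per-genome perturbation around it), giving the
  within-clade/between-clade contrast the coding-affinity analysis relies
  on;
* coding sequences sampled codon-by-codon from those profiles (no internal
  stop codons, length a multiple of three);
* genomic copies of focal transcripts with planted GT..AG introns, and
  error-free fixed-length reads: cDNA reads with per-transcript counts from
  the expression model, gDNA reads from the genomic copies at uniform
  coverage.

All randomness flows from one :class:`numpy.random.Generator` seeded by the
config, so identical configs give identical output.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneCluster, SequenceRecord, write_cluster_table, write_fasta, write_tip_genome_table
from .taxa import (
    HOST_PROXY,
    OUTGROUP,
    PARASITE,
    PARASITE_RELATIVES,
    SPECIES_TREE_NEWICK,
    make_species_panel,
)
from .tree import Node, SupportTree, parse_newick_with_support

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "STOP_CODONS",
    "SENSE_CODONS",
    "simulate_codon_profiles",
    "simulate_cluster_trees",
    "simulate_transcripts_and_reads",
    "simulate_study",
    "write_simulation",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
#: The 61 sense codons, lexicographic.
SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    ``hgt_fraction`` defaults to the parasite HGT rate observed in the real
    system (2.1%); reads are 150 bp (the study's Illumina read length) and
    fragments 25 bp.  ``codon_profile_divergence`` is a Dirichlet
    concentration: larger values pull each genome's codon profile toward
    its clade mean; ``clade_profile_concentration`` controls how distinct
    the clade means themselves are (smaller = more distinct).
    """

    seed: int = 0
    n_clusters: int = 200
    hgt_fraction: float = 0.021
    noise_fraction: float = 0.05
    support_high: tuple[int, int] = (85, 100)
    support_low: tuple[int, int] = (30, 80)
    clade_profile_concentration: float = 30.0
    codon_profile_divergence: float = 500.0
    read_length: int = 150
    fragment_size: int = 25
    intron_rate: float = 0.5
    intron_length_range: tuple[int, int] = (60, 140)
    expression_model: dict = field(
        default_factory=lambda: {"kind": "lognormal", "mean_log": 3.5, "sigma": 1.0}
    )
    host_like_vgt_fraction: float = 0.0
    gdna_reads_per_transcript: int = 20
    taxon_inclusion_prob: float = 0.7
    transcript_codons_range: tuple[int, int] = (150, 400)
    branch_length_shape: float = 2.0
    branch_length_scale: float = 0.05

    def __post_init__(self):
        for name in ("hgt_fraction", "noise_fraction", "intron_rate",
                     "host_like_vgt_fraction", "taxon_inclusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be positive")
        if self.read_length < self.fragment_size:
            raise ValidationError("read_length must be >= fragment_size")
        if self.fragment_size < 1:
            raise ValidationError("fragment_size must be positive")
        if self.codon_profile_divergence <= 0:
            raise ValidationError("codon_profile_divergence must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ClusterTruth:
    """Planted truth for one cluster's focal transcript."""

    cluster_id: str
    label: str  # VGT | HGT
    noise_applied: bool
    realized_sister: frozenset[str]
    realized_support: int | None


@dataclass
class SimulationResult:
    config: SimulationConfig
    clusters: list[GeneCluster]
    transcripts: list[SequenceRecord]
    genomic_copies: dict[str, str]
    cdna_reads: list[SequenceRecord]
    gdna_reads: list[SequenceRecord]
    codon_profiles: dict[str, np.ndarray]
    cluster_truth: pd.DataFrame
    transcript_truth: pd.DataFrame

    def focal_transcripts(self, genome: str = PARASITE) -> list[str]:
        tt = self.transcript_truth
        return list(tt.loc[tt.genome == genome, "transcript_id"])


# ---------------------------------------------------------------------------
# Codon profiles


def simulate_codon_profiles(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Per-genome codon frequency vectors (61 sense codons, summing to 1).

    One Dirichlet draw per clade, then one concentrated Dirichlet draw per
    genome around its clade mean, so genomes within a clade resemble each
    other more than genomes across clades (in expectation).
    """
    rng = cfg.rng() if rng is None else rng
    panel = make_species_panel()
    clades = sorted({s.clade for s in panel})
    base = np.full(len(SENSE_CODONS), cfg.clade_profile_concentration / len(SENSE_CODONS))
    clade_profile = {c: rng.dirichlet(base) for c in clades}
    profiles: dict[str, np.ndarray] = {}
    for sp in panel:
        alpha = np.maximum(clade_profile[sp.clade] * cfg.codon_profile_divergence, 1e-8)
        profiles[sp.name] = rng.dirichlet(alpha)
    return profiles


# ---------------------------------------------------------------------------
# Trees


def _species_tree() -> SupportTree:
    tips = {s.name: s.name for s in make_species_panel()}
    return parse_newick_with_support(SPECIES_TREE_NEWICK, tips)


def _restrict(node: Node, keep: set[str]) -> Node | None:
    if node.is_tip:
        return Node(name=node.name) if node.name in keep else None
    kids = [k for c in node.children if (k := _restrict(c, keep)) is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return Node(children=kids)


def _prune_tip(root: Node, label: str) -> Node:
    """Remove a tip and suppress the resulting unifurcation."""

    def rec(node: Node) -> Node | None:
        if node.is_tip:
            return None if node.name == label else node
        kids = [k for c in node.children if (k := rec(c)) is not None]
        if len(kids) == 1 and node is not root:
            return kids[0]
        node.children = kids
        return node

    new_root = rec(root)
    assert new_root is not None
    if len(new_root.children) == 1:
        new_root = new_root.children[0]
    return new_root


def _graft_sister(root: Node, target_label: str, new_tip: str) -> None:
    """Attach ``new_tip`` as sister to the tip named ``target_label``."""
    for node in root.walk():
        for i, child in enumerate(node.children):
            if child.is_tip and child.name == target_label:
                node.children[i] = Node(
                    children=[child, Node(name=new_tip)]
                )
                return
    raise ValidationError(f"graft target {target_label!r} not found")


def _eligible_nni_edges(root: Node) -> list[tuple[Node, Node]]:
    """(parent, child) pairs for internal edges strictly inside the
    ingroup (the outgroup tip never moves, keeping rooting well-defined)."""
    out: list[tuple[Node, Node]] = []
    ingroup = [c for c in root.children if not (c.is_tip and c.name and c.name.startswith(OUTGROUP))]

    def rec(node: Node):
        for child in node.children:
            if not child.is_tip:
                out.append((node, child))
                rec(child)

    for sub in ingroup:
        if not sub.is_tip:
            rec(sub)
    return out


def _apply_nni(parent: Node, child: Node, rng: np.random.Generator) -> None:
    """Swap one child of ``child`` with one sibling of ``child``."""
    siblings = [c for c in parent.children if c is not child]
    z = siblings[int(rng.integers(len(siblings)))]
    y = child.children[int(rng.integers(len(child.children)))]
    parent.children[parent.children.index(z)] = y
    child.children[child.children.index(y)] = z


def _realized_placement(
    root: Node, focal_tip: str
) -> tuple[frozenset[str], int | None]:
    """Ground-truth sister set and support of the focal tip, read directly
    off the generated topology (independent of the classifier)."""
    parents: dict[int, Node] = {}
    for n in root.walk():
        for c in n.children:
            parents[id(c)] = n
    tip = next(n for n in root.walk() if n.is_tip and n.name == focal_tip)
    anc = parents[id(tip)]
    sister = [
        t
        for c in anc.children
        if c is not tip
        for t in c.tip_labels()
    ]
    genomes = frozenset(t.rsplit(".", 1)[-1] for t in sister)
    support = anc.support if id(anc) in parents else None
    return genomes, support


def simulate_cluster_trees(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, SupportTree]], list[ClusterTruth]]:
    """Simulate one gene tree per cluster with planted HGT and NNI noise.

    Tip labels are ``<cluster_id>.<genome>``; every cluster satisfies the
    retention filter by construction (outgroup, parasite, *Vitis*, and at
    least one Malpighiales relative always present).
    """
    rng = cfg.rng() if rng is None else rng
    species = _species_tree()
    optional = [
        s.name
        for s in make_species_panel()
        if s.name not in (OUTGROUP, PARASITE, HOST_PROXY)
    ]
    trees: list[tuple[str, SupportTree]] = []
    truths: list[ClusterTruth] = []
    width = len(str(cfg.n_clusters))
    for idx in range(cfg.n_clusters):
        cid = f"cl{idx:0{width}d}"
        keep = {OUTGROUP, PARASITE, HOST_PROXY}
        keep |= {t for t in optional if rng.random() < cfg.taxon_inclusion_prob}
        if not keep & set(PARASITE_RELATIVES):
            keep.add(PARASITE_RELATIVES[int(rng.integers(len(PARASITE_RELATIVES)))])
        root = _restrict(species.root.copy(), keep)
        assert root is not None

        is_hgt = rng.random() < cfg.hgt_fraction
        if is_hgt:
            root = _prune_tip(root, PARASITE)
            _graft_sister(root, HOST_PROXY, PARASITE)

        noised = rng.random() < cfg.noise_fraction
        noised_edge: Node | None = None
        if noised:
            edges = _eligible_nni_edges(root)
            if edges:
                p, c = edges[int(rng.integers(len(edges)))]
                _apply_nni(p, c, rng)
                noised_edge = c

        # lengths on every non-root edge; supports on internal non-root edges
        parents: dict[int, Node] = {}
        for n in root.walk():
            for ch in n.children:
                parents[id(ch)] = n
        for n in root.walk():
            if n is root:
                continue
            n.length = float(
                rng.gamma(cfg.branch_length_shape, cfg.branch_length_scale)
            )
            if not n.is_tip:
                lo, hi = (
                    cfg.support_low if n is noised_edge else cfg.support_high
                )
                if parents.get(id(n)) is root:
                    # trivial split (complement of the outgroup): no support
                    n.support = None
                else:
                    n.support = int(rng.integers(lo, hi + 1))

        # rename tips to per-cluster transcript ids
        tip_genome: dict[str, str] = {}
        for n in root.walk():
            if n.is_tip:
                genome = n.name
                n.name = f"{cid}.{genome}"
                tip_genome[n.name] = genome
        tree = SupportTree(root, tip_genome)
        sister, support = _realized_placement(root, f"{cid}.{PARASITE}")
        trees.append((cid, tree))
        truths.append(
            ClusterTruth(
                cluster_id=cid,
                label="HGT" if is_hgt else "VGT",
                noise_applied=noised,
                realized_sister=sister,
                realized_support=support,
            )
        )
    return trees, truths


# ---------------------------------------------------------------------------
# Sequences and reads


def _sample_coding_sequence(
    profile: np.ndarray, n_codons: int, rng: np.random.Generator
) -> str:
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=profile)
    return "".join(SENSE_CODONS[i] for i in idx)


def _draw_read_count(model: dict, rng: np.random.Generator) -> int:
    kind = model.get("kind", "lognormal")
    if kind == "constant":
        return int(model["value"])
    if kind == "lognormal":
        lam = rng.lognormal(model.get("mean_log", 3.5), model.get("sigma", 1.0))
        return int(rng.poisson(lam))
    raise ValidationError(f"unknown expression model kind {kind!r}")


_BASES = np.array(list("ACGT"))


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_transcripts_and_reads(
    cfg: SimulationConfig,
    trees: list[tuple[str, SupportTree]],
    truths: list[ClusterTruth],
    profiles: dict[str, np.ndarray],
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Sample member transcripts, genomic copies with GT..AG introns, and
    error-free cDNA/gDNA reads for the focal transcripts.

    A focal transcript in a truth-HGT cluster is sampled from the host
    (*Vitis*) codon profile — the transferred copy carries the donor's
    coding properties; a truth-VGT focal transcript is sampled from its own
    genome's profile except with probability ``host_like_vgt_fraction``
    (planting host-convergent coding usage for the affinity analysis).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    truth_by_cid = {t.cluster_id: t for t in truths}
    clusters: list[GeneCluster] = []
    transcripts: list[SequenceRecord] = []
    genomic_copies: dict[str, str] = {}
    cdna_reads: list[SequenceRecord] = []
    gdna_reads: list[SequenceRecord] = []
    tx_rows: list[dict] = []
    lo_c, hi_c = cfg.transcript_codons_range
    l = cfg.read_length
    for cid, tree in trees:
        truth = truth_by_cid[cid]
        members: list[SequenceRecord] = []
        genome_of: dict[str, str] = {}
        for tip, genome in tree.tip_genome.items():
            n_codons = int(rng.integers(lo_c, hi_c + 1))
            origin = genome
            if genome == PARASITE:
                if truth.label == "HGT":
                    origin = HOST_PROXY
                elif rng.random() < cfg.host_like_vgt_fraction:
                    origin = HOST_PROXY
            seq = _sample_coding_sequence(profiles[origin], n_codons, rng)
            rec = SequenceRecord(tip, seq)
            members.append(rec)
            transcripts.append(rec)
            genome_of[tip] = genome

            row = {
                "transcript_id": tip,
                "cluster_id": cid,
                "genome": genome,
                "profile_origin": origin,
                "length": len(seq),
                "true_label": truth.label if genome == PARASITE else "",
                "n_cdna_reads": 0,
                "has_intron": False,
                "intron_junction": -1,
                "intron_length": 0,
            }

            if genome == PARASITE:
                # genomic copy, optionally with one planted GT..AG intron
                gseq = seq
                if rng.random() < cfg.intron_rate and len(seq) > 2 * l:
                    j = int(rng.integers(l, len(seq) - l + 1))
                    ilen = int(rng.integers(*cfg.intron_length_range))
                    intron = "GT" + _random_bases(ilen - 4, rng) + "AG"
                    gseq = seq[:j] + intron + seq[j:]
                    row.update(
                        has_intron=True, intron_junction=j, intron_length=ilen
                    )
                genomic_copies[tip] = gseq

                # cDNA reads (expression) from the spliced transcript
                n_reads = _draw_read_count(cfg.expression_model, rng)
                if len(seq) < l:
                    n_reads = 0
                starts = rng.integers(0, len(seq) - l + 1, size=n_reads)
                for i, s in enumerate(sorted(int(x) for x in starts)):
                    cdna_reads.append(
                        SequenceRecord(f"{tip}.c{i}", seq[s : s + l])
                    )
                row["n_cdna_reads"] = n_reads

                # gDNA reads from the genomic copy, uniform coverage
                if len(gseq) >= l:
                    gstarts = rng.integers(
                        0, len(gseq) - l + 1, size=cfg.gdna_reads_per_transcript
                    )
                    for i, s in enumerate(sorted(int(x) for x in gstarts)):
                        gdna_reads.append(
                            SequenceRecord(f"{tip}.g{i}", gseq[s : s + l])
                        )
            tx_rows.append(row)
        clusters.append(
            GeneCluster(cluster_id=cid, members=members, genome_of=genome_of, tree=tree)
        )

    cluster_truth = pd.DataFrame(
        {
            "cluster_id": [t.cluster_id for t in truths],
            "true_label": [t.label for t in truths],
            "noise_applied": [t.noise_applied for t in truths],
            "realized_sister": [
                ";".join(sorted(t.realized_sister)) for t in truths
            ],
            "realized_support": [
                -1 if t.realized_support is None else t.realized_support
                for t in truths
            ],
        }
    )
    transcript_truth = pd.DataFrame(tx_rows)
    return SimulationResult(
        config=cfg,
        clusters=clusters,
        transcripts=transcripts,
        genomic_copies=genomic_copies,
        cdna_reads=cdna_reads,
        gdna_reads=gdna_reads,
        codon_profiles=profiles,
        cluster_truth=cluster_truth,
        transcript_truth=transcript_truth,
    )


def simulate_study(cfg: SimulationConfig) -> SimulationResult:
    """Run the full generator: trees, codon profiles, sequences, reads."""
    rng = cfg.rng()
    profiles = simulate_codon_profiles(cfg, rng)
    trees, truths = simulate_cluster_trees(cfg, rng)
    return simulate_transcripts_and_reads(cfg, trees, truths, profiles, rng)


# ---------------------------------------------------------------------------
# Serialization


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, str]:
    """Write FASTA/newick/TSV outputs plus the config; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": outdir / "sim_config.json",
        "transcripts": outdir / "transcripts.fasta",
        "genomic_copies": outdir / "genomic_copies.fasta",
        "cdna_reads": outdir / "cdna_reads.fasta",
        "gdna_reads": outdir / "gdna_reads.fasta",
        "cluster_table": outdir / "clusters.tsv",
        "tip_genome": outdir / "tip_genome.tsv",
        "trees": outdir / "trees",
        "cluster_truth": outdir / "truth_clusters.tsv",
        "transcript_truth": outdir / "truth_transcripts.tsv",
    }
    with open(paths["config"], "w") as fh:
        json.dump(asdict(result.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_fasta(result.transcripts, paths["transcripts"])
    write_fasta(
        [SequenceRecord(tid, seq) for tid, seq in result.genomic_copies.items()],
        paths["genomic_copies"],
    )
    write_fasta(result.cdna_reads, paths["cdna_reads"])
    write_fasta(result.gdna_reads, paths["gdna_reads"])
    write_cluster_table(
        {
            cl.cluster_id: [(m.id, cl.genome_of[m.id]) for m in cl.members]
            for cl in result.clusters
        },
        paths["cluster_table"],
    )
    tip_genome: dict[str, str] = {}
    paths["trees"].mkdir(exist_ok=True)
    for cl in result.clusters:
        tip_genome.update(cl.tree.tip_genome)
        (paths["trees"] / f"{cl.cluster_id}.nwk").write_text(cl.tree.newick() + "\n")
    write_tip_genome_table(tip_genome, paths["tip_genome"])
    result.cluster_truth.to_csv(paths["cluster_truth"], sep="\t", index=False)
    result.transcript_truth.to_csv(paths["transcript_truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
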