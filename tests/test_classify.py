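"""Classifier: retention filter, sister-group rules, threshold behaviour,
brute-force oracle equivalence, truth recovery on simulations."""

import random

import pytest

from hgtscan.classify import (
    ClassifierConfig,
    classify_all,
    classify_tip,
    control_config,
    filter_clusters,
    rafflesia_config,
    root_on_outgroup,
    sweep_thresholds,
)
from hgtscan.errors import ValidationError
from hgtscan.io import GeneCluster
from hgtscan.tree import parse_newick_with_support

CFG = rafflesia_config()


def _cluster(genomes, cid="c"):
    genome_of = {f"t{i}": g for i, g in enumerate(genomes)}
    return GeneCluster(cluster_id=cid, members=[], genome_of=genome_of)


def _tree(newick, tip_genome):
    tree = parse_newick_with_support(newick, tip_genome)
    rooted, _ = root_on_outgroup(tree, CFG)
    return rooted


TG = {
    "Raf": "Rafflesia", "Vit": "Vitis", "Man": "Manihot", "Ric": "Ricinus",
    "Pop": "Populus", "Ory": "Oryza", "Ara": "Arabidopsis", "Tet": "Tetrastigma",
}


# -- retention filter -------------------------------------------------------


def test_filter_retains_minimal_satisfying_cluster():
    kept = filter_clusters([_cluster(["Oryza", "Rafflesia", "Ricinus", "Vitis"])], CFG)
    assert len(kept) == 1


def test_filter_drops_cluster_without_transfer_taxon():
    kept = filter_clusters([_cluster(["Oryza", "Rafflesia", "Ricinus"])], CFG)
    assert kept == []


def test_filter_empty_input():
    assert filter_clusters([], CFG) == []


@pytest.mark.parametrize(
    "missing", ["Oryza", "Rafflesia", "Vitis"]
)
def test_filter_requires_each_mandatory_taxon(missing):
    genomes = {"Oryza", "Rafflesia", "Ricinus", "Vitis"} - {missing}
    assert filter_clusters([_cluster(sorted(genomes))], CFG) == []


# -- classify_tip rules -----------------------------------------------------


def test_hgt_call_raf_sister_to_vitis():
    tree = _tree("(((Raf,Vit)75,(Man,Ric)90)88,Ory);", TG)
    cls = classify_tip(tree, "Raf", CFG)
    assert cls.category == "HGT"
    assert cls.support == 75
    assert cls.sister_genomes == frozenset({"Vitis"})


def test_low_support_leaves_unassigned():
    tree = _tree("(((Man,Ric)45,Raf)80,(Vit,Ory)90);", TG)
    cls = classify_tip(tree, "Raf", CFG)
    # support of the (Raf,(Man,Ric)) clade is 80 >= 50: VGT; now drop it
    tree2 = _tree("(((Man,Ric)90,Raf)45,(Vit,Ory)90);", TG)
    cls2 = classify_tip(tree2, "Raf", CFG)
    assert cls.category == "VGT"
    assert cls2.category == "unassigned"
    assert cls2.support == 45


def test_mixed_sister_clade_is_unassigned_despite_support():
    tree = _tree("((Raf,(Vit,Man)99)99,Ory);", TG)
    cls = classify_tip(tree, "Raf", CFG)
    assert cls.sister_genomes == frozenset({"Vitis", "Manihot"})
    assert cls.category == "unassigned"


def test_other_reference_taxa_in_sister_set_unassigned():
    tree = _tree("((Raf,Ara)97,(Man,Ory)88);", TG)
    assert classify_tip(tree, "Raf", CFG).category == "unassigned"


def test_focal_paralogs_skipped_while_ascending():
    tg = dict(TG, Raf2="Rafflesia")
    tree = _tree("(((Raf,Raf2)99,Vit)85,(Man,Ory)70);", tg)
    cls = classify_tip(tree, "Raf", CFG)
    assert cls.sister_genomes == frozenset({"Vitis"})
    assert cls.category == "HGT"
    assert cls.support == 85


def test_missing_tip_raises():
    tree = _tree("((Raf,Vit)80,Ory);", TG)
    with pytest.raises(ValidationError):
        classify_tip(tree, "Nope", CFG)


def test_config_validation():
    with pytest.raises(ValidationError):
        ClassifierConfig(relative_set=frozenset({"Vitis"}))
    with pytest.raises(ValidationError):
        ClassifierConfig(focal_taxon="Vitis")
    with pytest.raises(ValidationError):
        ClassifierConfig(bs_threshold=101)


# -- brute-force oracle -----------------------------------------------------


def _oracle_sister(tree, tip_label, focal_taxon):
    """Enumerate all clades (subtree tip sets); the sister set is read from
    the smallest clade that strictly contains the focal tip plus at least
    one non-focal tip."""
    clades = []
    for node in tree.root.walk():
        tips = set(node.tip_labels())
        clades.append((tips, node))
    containing = [
        (tips, node)
        for tips, node in clades
        if tip_label in tips
        and any(tree.tip_genome[t] != focal_taxon for t in tips - {tip_label})
    ]
    tips, node = min(containing, key=lambda c: len(c[0]))
    sister = frozenset(
        tree.tip_genome[t]
        for t in tips - {tip_label}
        if tree.tip_genome[t] != focal_taxon
    )
    parents = tree.parents()
    support = node.support if id(node) in parents else None
    return sister, support


def _random_rooted_tree(rng, n_tips):
    labels = [f"T{i}" for i in range(n_tips)]
    genomes = ["Rafflesia", "Vitis", "Manihot", "Ricinus", "Oryza", "Arabidopsis"]
    tip_genome = {}
    from hgtscan.tree import Node

    nodes = []
    for t in labels:
        tip_genome[t] = rng.choice(genomes)
        nodes.append(Node(name=t, length=round(rng.uniform(0.01, 0.5), 3)))
    while len(nodes) > 2:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        parent = Node(
            length=round(rng.uniform(0.01, 0.5), 3),
            support=rng.randint(0, 100),
            children=[a, b],
        )
        nodes.append(parent)
    root = Node(children=nodes)
    for c in root.children:
        c.support = None
    from hgtscan.tree import SupportTree

    return SupportTree(root, tip_genome)


def test_classify_tip_matches_bipartition_oracle_on_random_trees():
    rng = random.Random(42)
    checked = 0
    for _ in range(300):
        n = rng.randint(4, 8)
        tree = _random_rooted_tree(rng, n)
        focal_tips = [
            t for t, g in tree.tip_genome.items() if g == "Rafflesia"
        ]
        for tip in focal_tips:
            got = classify_tip(tree, tip, CFG)
            sister, support = _oracle_sister(tree, tip, "Rafflesia")
            assert got.sister_genomes == sister
            assert got.support == support
            checked += 1
    assert checked > 100


# -- aggregate behaviour ----------------------------------------------------


def test_partition_invariant_and_exact_truth_recovery(clean_sim):
    results, summary = classify_all(clean_sim.clusters, CFG)
    assert summary.n_vgt + summary.n_hgt + summary.n_unassigned == summary.n_total
    truth = dict(
        zip(clean_sim.cluster_truth.cluster_id, clean_sim.cluster_truth.true_label)
    )
    assert summary.n_total == len(clean_sim.clusters)
    for r in results:
        assert r.category == truth[r.cluster_id]


def test_label_swap_symmetry(small_sim):
    results, summary = classify_all(small_sim.clusters, CFG)
    swapped_results, swapped = classify_all(small_sim.clusters, CFG.swapped())
    assert swapped.n_vgt == summary.n_hgt
    assert swapped.n_hgt == summary.n_vgt
    assert swapped.n_unassigned == summary.n_unassigned
    by_id = {r.transcript_id: r for r in results}
    for r in swapped_results:
        other = by_id[r.transcript_id]
        flip = {"VGT": "HGT", "HGT": "VGT", "unassigned": "unassigned"}
        assert r.category == flip[other.category]


def test_control_background_on_null_noisy_simulation():
    from hgtscan.simulate import SimulationConfig, simulate_study

    sim = simulate_study(
        SimulationConfig(seed=21, n_clusters=300, hgt_fraction=0.0,
                         noise_fraction=0.3)
    )
    _, raf = classify_all(sim.clusters, CFG)
    _, man = classify_all(sim.clusters, control_config("Manihot"))
    # no HGT planted: any call is noise-induced and rare
    assert raf.pct_hgt < 5.0
    assert man.pct_hgt < 5.0


# -- threshold sweep --------------------------------------------------------


def test_sweep_default_thresholds(small_sim):
    table = sweep_thresholds(small_sim.clusters, CFG)
    assert sorted(table) == [50, 55, 60, 65, 70]
    resolved = [table[t]["n_resolved"] for t in sorted(table)]
    assert resolved == sorted(resolved, reverse=True)


def test_sweep_monotone_resolved_and_all_high_supports_flat():
    from hgtscan.simulate import SimulationConfig, simulate_cluster_trees

    cfg = SimulationConfig(seed=13, n_clusters=40, hgt_fraction=0.2,
                           support_high=(100, 100), noise_fraction=0.0)
    trees, _ = simulate_cluster_trees(cfg)
    clusters = [
        GeneCluster(cluster_id=cid, members=[], genome_of=dict(t.tip_genome), tree=t)
        for cid, t in trees
    ]
    table = sweep_thresholds(clusters, CFG, thresholds=(0, 50, 70, 100))
    pcts = {table[t]["pct_hgt_resolved"] for t in table}
    assert len(pcts) == 1  # all supports 100: thresholds cannot matter
    resolved = [table[t]["n_resolved"] for t in sorted(table)]
    assert resolved == sorted(resolved, reverse=True)


def test_sweep_reports_undefined_not_zero_when_nothing_resolved():
    tree = _tree("((Raf,Vit)40,Ory);", TG)
    cl = GeneCluster(
        cluster_id="c1", members=[], genome_of=dict(tree.tip_genome), tree=tree
    )
    # only resolvable call has support 40; at tau=90 nothing is resolved
    table = sweep_thresholds([cl], CFG, thresholds=(90,))
    assert table[90]["n_resolved"] == 0
    assert table[90]["pct_hgt_resolved"] is None
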