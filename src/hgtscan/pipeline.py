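"""End-to-end orchestration: simulate -> classify -> rates -> verify ->
express -> coding, with a run manifest and a JSON report mirroring the
study's figures (HGT rates with control backgrounds, threshold sweep, rate
and expression comparisons, verification stratified by support and length,
intron calls, coding-affinity table).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import coding as _coding
from . import expression as _expression
from . import rates as _rates
from . import verify as _verify
from .errors import HgtscanError
from .io import read_cluster_table, read_fasta, read_tip_genome_table, GeneCluster, SequenceRecord
from .simulate import SimulationConfig, SimulationResult, simulate_study, write_simulation
from .taxa import HOST_PROXY, HOST_TAXON, PARASITE
from .tree import SupportTree, parse_newick_with_support

__all__ = ["StageError", "run_pipeline", "report_verification_stratified"]

STAGES = ("simulate", "classify", "rates", "verify", "express", "coding")


class StageError(HgtscanError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------


def report_verification_stratified(
    counts: dict[str, int],
    classifications,
    supports: dict[str, int | None],
    lengths: dict[str, int],
    min_hits: int = 1,
    tau: int = 50,
) -> dict:
    """Verification percentage binned by bootstrap support (decade bins
    from tau) and by transcript-length quartiles, per category.  Empty bins
    report ``None``."""
    by_cat: dict[str, list[str]] = {"VGT": [], "HGT": []}
    for c in classifications:
        if c.category in by_cat:
            by_cat[c.category].append(c.transcript_id)

    def pct(ids: list[str]) -> dict:
        n = len(ids)
        v = sum(1 for t in ids if counts.get(t, 0) >= min_hits)
        return {"n": n, "n_verified": v,
                "pct_verified": None if n == 0 else 100.0 * v / n}

    support_edges = list(range(tau, 100, 10))
    length_values = sorted(lengths.values())
    if length_values:
        qs = np.percentile(length_values, [25, 50, 75]).tolist()
    else:
        qs = []

    out: dict = {"overall": {}, "by_support": {}, "by_length": {}}
    for cat, ids in by_cat.items():
        out["overall"][cat] = pct(ids)
    for lo in support_edges:
        hi = lo + 10
        label = f"{lo}-{hi}"
        out["by_support"][label] = {}
        for cat, ids in by_cat.items():
            binned = [
                t for t in ids
                if supports.get(t) is not None and lo <= supports[t] < (hi if hi < 100 else 101)
            ]
            out["by_support"][label][cat] = pct(binned)
    if qs:
        edges = [0] + qs + [float("inf")]
        for i in range(4):
            label = f"L_q{i + 1}"
            out["by_length"][label] = {}
            for cat, ids in by_cat.items():
                binned = [
                    t for t in ids
                    if edges[i] <= lengths.get(t, -1) < edges[i + 1]
                    or (i == 3 and lengths.get(t, -1) == edges[4])
                ]
                out["by_length"][label][cat] = pct(binned)
    return out


# ---------------------------------------------------------------------------


def _load_file_inputs(config: dict) -> SimulationResult | tuple:
    """Non-simulation mode: read trees, tables and FASTA from paths."""
    tip_genome = read_tip_genome_table(config["tip_genome"])
    cluster_map = read_cluster_table(config["clusters"])
    tree_dir = Path(config["trees"])
    clusters: list[GeneCluster] = []
    seqs: dict[str, SequenceRecord] = {}
    if config.get("transcripts"):
        p = Path(config["transcripts"])
        if not p.exists():
            raise StageError("verify", f"transcripts file {p} not found")
        seqs = {r.id: r for r in read_fasta(p)}
    for cid, members in cluster_map.items():
        nwk = tree_dir / f"{cid}.nwk"
        tree = parse_newick_with_support(
            nwk.read_text().strip(),
            {m: tip_genome.get(m, g) for m, g in members},
        )
        clusters.append(
            GeneCluster(
                cluster_id=cid,
                members=[seqs[m] for m, _ in members if m in seqs],
                genome_of=dict(members),
                tree=tree,
            )
        )
    return clusters


def run_pipeline(
    config: SimulationConfig | dict | str | Path,
    outdir: str | Path,
    bs_threshold: int = 50,
    min_hits: int = 1,
    binomial_p0: float | None = None,
    force: bool = False,
) -> dict:
    """Run all stages and write ``report.json`` + ``manifest.json``.

    ``config`` is a :class:`SimulationConfig` (simulation mode), a dict of
    input paths (file mode), or a path to a JSON file holding either.  A
    completed run with an identical config snapshot is not recomputed
    unless ``force`` is set.  Any stage failure raises :class:`StageError`
    naming the stage; a FAILED marker is left next to partial outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(config, (str, Path)):
        loaded = json.loads(Path(config).read_text())
        if loaded.get("mode") == "files":
            config = loaded
        else:
            loaded.pop("mode", None)
            for key in ("support_high", "support_low", "intron_length_range",
                        "transcript_codons_range"):
                if key in loaded:
                    loaded[key] = tuple(loaded[key])
            config = SimulationConfig(**loaded)

    snapshot = _jsonable(
        asdict(config) if isinstance(config, SimulationConfig) else dict(config)
    )
    manifest_path = outdir / "manifest.json"
    report_path = outdir / "report.json"
    if not force and manifest_path.exists() and report_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config") == snapshot:  # idempotent re-run
            return json.loads(report_path.read_text())

    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        report = _run_stages(config, outdir, bs_threshold, min_hits, binomial_p0)
    except StageError:
        failed_marker.write_text("pipeline failed; see exception\n")
        raise
    except Exception as exc:
        failed_marker.write_text(f"{exc}\n")
        raise

    report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    files = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": snapshot,
        "seed": snapshot.get("seed"),
        "stages": list(STAGES),
        "outputs": {
            f: _digest(outdir / f) for f in files
        },
        "n_focal_transcripts": report["classification"][PARASITE]["n_total"],
    }
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")
    return json.loads(report_path.read_text())


def _run_stages(config, outdir: Path, bs_threshold, min_hits, binomial_p0) -> dict:
    report: dict = {}

    # -- simulate ----------------------------------------------------------
    if isinstance(config, SimulationConfig):
        try:
            sim = simulate_study(config)
            write_simulation(sim, outdir / "sim")
        except HgtscanError as exc:
            raise StageError("simulate", str(exc)) from exc
        clusters = sim.clusters
        cdna_reads, gdna_reads = sim.cdna_reads, sim.gdna_reads
        k = config.fragment_size
    else:
        try:
            clusters = _load_file_inputs(config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("classify", str(exc)) from exc
        sim = None
        k = int(config.get("fragment_size", 25))
        cdna_reads = read_fasta(config["cdna_reads"]) if config.get("cdna_reads") else []
        gdna_reads = read_fasta(config["gdna_reads"]) if config.get("gdna_reads") else []

    # -- classify ----------------------------------------------------------
    try:
        cfg_focal = _classify.rafflesia_config(bs_threshold)
        results, summary = _classify.classify_all(clusters, cfg_focal)
        report["classification"] = {PARASITE: summary.as_dict()}
        tet_results, tet_summary = _classify.classify_all(
            clusters, _classify.tetrastigma_config(bs_threshold)
        )
        report["classification"][HOST_TAXON] = tet_summary.as_dict()
        for control in ("Manihot", "Ricinus"):
            _, csum = _classify.classify_all(
                clusters, _classify.control_config(control, bs_threshold)
            )
            report["classification"][control] = csum.as_dict()
        report["sweep"] = _classify.sweep_thresholds(clusters, cfg_focal)
    except HgtscanError as exc:
        raise StageError("classify", str(exc)) from exc

    rooted: dict[str, SupportTree] = {}
    for cl in _classify.filter_clusters(clusters, cfg_focal):
        rooted[cl.cluster_id], _ = cl.tree.root_on_outgroup(cfg_focal.outgroup)

    # -- rates -------------------------------------------------------------
    try:
        rate_report = _rates.compare_rates(results, rooted)
        rate_report.pop("records")
        report["rates"] = rate_report
    except HgtscanError as exc:
        raise StageError("rates", str(exc)) from exc

    # -- verify ------------------------------------------------------------
    try:
        focal_tx = [
            m for cl in clusters for m in cl.members
            if cl.genome_of[m.id] == cfg_focal.focal_taxon and m.seq
        ]
        if not focal_tx:
            raise StageError("verify", "no focal transcripts available")
        index = _verify.FragmentIndex(focal_tx, k)
        counts = _verify.verify_transcripts(
            [t.id for t in focal_tx], gdna_reads, index
        )
        intron_calls = []
        for read in gdna_reads:
            intron_calls.extend(_verify.detect_introns(read, index))
        supports = {r.transcript_id: r.support for r in results}
        lengths = {t.id: len(t.seq) for t in focal_tx}
        strat = report_verification_stratified(
            counts, results, supports, lengths, min_hits, bs_threshold
        )
        tx_by_id = {t.id: t for t in focal_tx}
        # parasite-host divergence for classified HGT transcripts with a
        # host-lineage homologue in the same cluster
        divergences = {}
        host_members = {
            cl.cluster_id: [m for m in cl.members if cl.genome_of[m.id] == HOST_TAXON]
            for cl in clusters
        }
        for r in results:
            if r.category != "HGT":
                continue
            partners = host_members.get(r.cluster_id) or []
            if partners and r.transcript_id in tx_by_id:
                divergences[r.transcript_id] = _verify.pairwise_divergence(
                    tx_by_id[r.transcript_id], partners[0]
                )
        complete_calls = [c for c in intron_calls if c.complete]
        report["verification"] = {
            "min_hits": min_hits,
            "stratified": strat,
            "n_intron_calls": len(intron_calls),
            "n_complete_intron_calls": len(complete_calls),
            "transcripts_with_intron_call": sorted(
                {c.transcript_id for c in intron_calls}
            ),
            "complete_calls_gt_ag": sum(
                1 for c in complete_calls
                if c.donor_motif_ok and c.acceptor_motif_ok
            ),
            "divergence": {
                "n": len(divergences),
                "min": min(divergences.values()) if divergences else None,
                "max": max(divergences.values()) if divergences else None,
                "mean": (
                    float(np.mean(list(divergences.values())))
                    if divergences else None
                ),
            },
        }
        verification_counts = counts
    except StageError:
        raise
    except HgtscanError as exc:
        raise StageError("verify", str(exc)) from exc

    # -- express -----------------------------------------------------------
    try:
        records = _expression.build_expression_records(focal_tx, cdna_reads, k=k, l=k)
        report["expression"] = _expression.compare_expression(records, results)
        rpkm_by_tx = {r.transcript_id: r.RPKM for r in records}
    except HgtscanError as exc:
        raise StageError("express", str(exc)) from exc

    # -- coding ------------------------------------------------------------
    try:
        report["coding"] = _run_coding(
            clusters, results, rpkm_by_tx, binomial_p0
        )
    except HgtscanError as exc:
        raise StageError("coding", str(exc)) from exc

    report["partition_check"] = {
        taxon: (
            report["classification"][taxon]["n_vgt"]
            + report["classification"][taxon]["n_hgt"]
            + report["classification"][taxon]["n_unassigned"]
            == report["classification"][taxon]["n_total"]
        )
        for taxon in report["classification"]
    }
    return report


def _run_coding(clusters, focal_results, rpkm_by_tx, binomial_p0) -> dict:
    """Fig. 3 analogue: affinity calls for focal VGTs and the two control
    genomes, the excess-Vitis-likeness binomial test, and the
    expression-affinity correlation."""
    comparators = _coding.MALPIGHIALES_COMPARATORS
    focal_vgt = {
        r.transcript_id for r in focal_results if r.category == "VGT"
    }
    calls_by_genome: dict[str, list] = {PARASITE: [], "Manihot": [], "Ricinus": []}
    for cl in clusters:
        profiles: dict[str, list] = {}
        by_id = {}
        for m in cl.members:
            try:
                prof = _coding.profile_transcript(m)
            except HgtscanError:
                continue
            profiles.setdefault(cl.genome_of[m.id], []).append(prof)
            by_id[m.id] = prof
        for m in cl.members:
            genome = cl.genome_of[m.id]
            if m.id not in by_id:
                continue
            if genome == PARASITE and m.id in focal_vgt:
                sides = (comparators, frozenset({HOST_PROXY}))
            elif genome in comparators:
                sides = (comparators - {genome}, frozenset({HOST_PROXY}))
            else:
                continue
            others = {
                g: [p for p in profs if p.transcript_id != m.id]
                for g, profs in profiles.items()
            }
            call = _coding.classify_affinity(by_id[m.id], others, *sides)
            if call is not None:
                calls_by_genome[genome].append(call)

    rates = _coding.affinity_rates(calls_by_genome)
    out: dict = {"affinity_rates": rates}

    control_rates = [
        rates[g]["pct_vitis_like"]
        for g in ("Manihot", "Ricinus")
        if rates[g]["pct_vitis_like"] is not None
    ]
    p0 = binomial_p0
    if p0 is None and control_rates:
        p0 = max(control_rates) / 100.0
        if p0 == 0.0:
            # Laplace-smoothed control rate so the null stays proper when
            # no control transcript is Vitis-like at desk scale
            p0 = max(
                (rates[g]["n_vitis_like"] + 1) / (rates[g]["n_total"] + 2)
                for g in ("Manihot", "Ricinus")
                if rates[g]["n_total"] > 0
            )
    focal_rate = rates[PARASITE]
    if p0 is not None and 0.0 < p0 < 1.0 and focal_rate["n_total"] > 0:
        out["binomial_test"] = {
            "k": focal_rate["n_vitis_like"],
            "n": focal_rate["n_total"],
            "p0": p0,
            "p_value": _coding.exact_binomial_test(
                focal_rate["n_vitis_like"], focal_rate["n_total"], p0
            ),
        }
    else:
        out["binomial_test"] = {"p_value": None, "reason": "null rate unavailable"}
    out["expression_correlation"] = _coding.expression_affinity_correlation(
        calls_by_genome[PARASITE], rpkm_by_tx
    )
    return out
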