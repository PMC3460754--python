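"""Substitution-rate comparison between HGT and VGT transcripts.

The rate proxy is the focal tip's terminal branch length from its gene
tree (substitutions/site along the tip edge); root-to-tip distance is
available as an alternative.  Group comparisons use Welch's unequal-
variance t test: t = (x̄_a - x̄_b) / sqrt(s²_a/n_a + s²_b/n_b) with
Welch-Satterthwaite degrees of freedom and a two-sided p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import TranscriptClassification
from .errors import ValidationError
from .tree import SupportTree

__all__ = [
    "RateRecord",
    "extract_rate",
    "root_to_tip_distance",
    "welch_t_test",
    "compare_rates",
]


@dataclass(frozen=True)
class RateRecord:
    transcript_id: str
    category: str
    rate: float
    partner_rate: float | None  # mean terminal rate of the sister-set tips


def extract_rate(tree: SupportTree, tip_label: str) -> float:
    """Terminal branch length of a tip (the default rate proxy)."""
    tip = tree.find_tip(tip_label)
    if tip.length is None:
        raise ValidationError(f"tip {tip_label!r} has no branch length")
    return float(tip.length)


def root_to_tip_distance(tree: SupportTree, tip_label: str) -> float:
    """Sum of branch lengths from the root to a tip (alternative proxy)."""
    parents = tree.parents()
    node = tree.find_tip(tip_label)
    total = 0.0
    while node is not None:
        if node.length is not None:
            total += node.length
        elif node is not tree.root:
            raise ValidationError(f"missing branch length above {tip_label!r}")
        node = parents.get(id(node))
    return total


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's two-sample t test; returns (t, df, two-sided p).

    Both samples need n >= 2.  When both variances are zero the statistic
    is 0 with p = 1 for equal means, else infinite with p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least two observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _quartiles(x: Sequence[float]) -> dict:
    arr = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
    }


def compare_rates(
    classifications: Sequence[TranscriptClassification],
    trees: Mapping[str, SupportTree],
    proxy: str = "terminal",
) -> dict:
    """HGT-vs-VGT and focal-vs-sister-partner rate comparisons.

    ``trees`` maps cluster_id to the rooted gene tree.  Partner rate is the
    mean terminal branch length of the sister-set tips (the homologous
    sister-lineage transcripts).  Groups with fewer than two members are
    skipped with a recorded reason.  The rate proxy used is recorded in the
    output metadata.
    """
    if proxy not in ("terminal", "root_to_tip"):
        raise ValidationError(f"unknown rate proxy {proxy!r}")
    get = extract_rate if proxy == "terminal" else root_to_tip_distance
    records: list[RateRecord] = []
    for cls in classifications:
        if cls.category not in ("VGT", "HGT"):
            continue
        tree = trees[cls.cluster_id]
        rate = get(tree, cls.transcript_id)
        partner_rates = [
            get(tree, tip)
            for tip, genome in tree.tip_genome.items()
            if genome in cls.sister_genomes
        ]
        partner = float(np.mean(partner_rates)) if partner_rates else None
        records.append(RateRecord(cls.transcript_id, cls.category, rate, partner))

    report: dict = {"rate_proxy": proxy, "groups": {}, "tests": {}, "skipped": []}
    groups = {
        "HGT": [r.rate for r in records if r.category == "HGT"],
        "VGT": [r.rate for r in records if r.category == "VGT"],
    }
    for name, vals in groups.items():
        if vals:
            report["groups"][name] = _quartiles(vals)
    if len(groups["HGT"]) >= 2 and len(groups["VGT"]) >= 2:
        t, df, p = welch_t_test(groups["HGT"], groups["VGT"])
        report["tests"]["hgt_vs_vgt"] = {"t": t, "df": df, "p": p}
    else:
        report["skipped"].append("hgt_vs_vgt: a group has <2 members")
    for name in ("HGT", "VGT"):
        focal = [r.rate for r in records if r.category == name and r.partner_rate is not None]
        partner = [
            r.partner_rate for r in records if r.category == name and r.partner_rate is not None
        ]
        if len(focal) >= 2:
            t, df, p = welch_t_test(focal, partner)
            report["tests"][f"{name.lower()}_vs_partner"] = {"t": t, "df": df, "p": p}
            report["groups"][f"{name}_partner"] = _quartiles(partner)
        else:
            report["skipped"].append(f"{name.lower()}_vs_partner: <2 members")
    report["records"] = records
    return report
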