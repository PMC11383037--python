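"""Scoring of pipeline output against simulator truth.

Duplicate genes born inside the simulation (e.g. a CASP4LP-like copy) have no
entry in the annotation reference, so predictions name them ``<gene>~copyN``;
scoring therefore compares *gene families*: truth gene ids are mapped through
the duplication events to their source gene, and predicted ids are stripped
of their copy suffix.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .annotate import GeneModel
from .sim import SimulationTruth


def truth_family(truth: SimulationTruth) -> dict[str, str]:
    """Map every truth gene id to its founding gene family."""
    parent: dict[str, str] = {}
    for ev in truth.events:
        if ev["kind"] == "duplication":
            parent[ev["new_id"]] = ev["gene"]
    fam: dict[str, str] = {}
    all_ids = {g for sp in truth.statuses.values() for g in sp}
    for gid in all_ids:
        cur = gid
        while cur in parent:
            cur = parent[cur]
        fam[gid] = cur
    return fam


def predicted_family(model_id: str) -> str:
    return model_id.split("~")[0]


def exon_assignment_f1(
    truth: SimulationTruth,
    models_by_species: Mapping[str, Sequence[GeneModel]],
    min_overlap: float = 0.8,
) -> tuple[float, int, int, int]:
    """Exon-level F1 of (family, interval) assignments vs truth coordinates."""
    fam = truth_family(truth)
    tp = fp = fn = 0
    for sp, models in models_by_species.items():
        true_exons = []
        for rec in truth.exon_coords[sp]:
            for s, e in rec["exons"]:
                true_exons.append((fam[rec["gene_id"]], s, e))
        used: set[int] = set()
        for model in models:
            family = predicted_family(model.gene_id)
            for h in model.exon_hits:
                matched = False
                for i, (tg, ts, te) in enumerate(true_exons):
                    if i in used or tg != family:
                        continue
                    ov = max(0, min(h.end, te) - max(h.start, ts))
                    if ov >= min_overlap * (te - ts):
                        used.add(i)
                        matched = True
                        break
                if matched:
                    tp += 1
                else:
                    fp += 1
        fn += len(true_exons) - len(used)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return f1, tp, fp, fn


def status_agreement(
    truth: SimulationTruth,
    calls_by_species: Mapping[str, Mapping[str, str]],
) -> tuple[float, dict[str, tuple[int, int]]]:
    """Per-class agreement of status calls vs truth.

    Truth genes absent from the calls are scored as called 'absent' (the
    annotation found nothing). Returns overall agreement and per-class
    (correct, total) pairs keyed by the true status.
    """
    fam = truth_family(truth)
    per_class: dict[str, list[int]] = {}
    rank = {"present": 3, "partial_in_frame": 2, "pseudogene": 1, "absent": 0}
    for sp, true_statuses in truth.statuses.items():
        # collapse both sides to family level: a family is present if any copy is
        calls: dict[str, str] = {}
        for k, v in calls_by_species.get(sp, {}).items():
            f = predicted_family(k)
            if f not in calls or rank[v] > rank[calls[f]]:
                calls[f] = v
        fam_truth: dict[str, str] = {}
        for gid, st in true_statuses.items():
            f = fam[gid]
            if f not in fam_truth or rank[st] > rank[fam_truth[f]]:
                fam_truth[f] = st
        for f, true_st in fam_truth.items():
            called = calls.get(f, "absent")
            stats = per_class.setdefault(true_st, [0, 0])
            stats[1] += 1
            if called == true_st:
                stats[0] += 1
    total = sum(v[1] for v in per_class.values())
    correct = sum(v[0] for v in per_class.values())
    overall = correct / total if total else 0.0
    return overall, {k: (v[0], v[1]) for k, v in per_class.items()}
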