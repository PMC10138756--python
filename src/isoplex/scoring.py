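"""Score pipeline outputs against a synthetic corpus's planted truth.

Structural detections (AS events, end flags, poly(A) sites) are matched by
type and coordinates; clustering is scored by adjusted Rand index; filters by
precision/recall over planted labels.  Gene identifiers differ between the
truth (generator gene ids) and the pipeline (locus ids assigned from the
observed transcripts), so loci are mapped back to truth genes through their
member transcripts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .domains import DomainChange, classify_domain_change
from .splicing import ASEvent, anchor_coords

__all__ = [
    "locus_to_truth_gene",
    "score_events",
    "score_end_flags",
    "score_polya_sites",
    "score_lncrnas",
    "score_clusters",
    "score_domains",
    "score_against_truth",
]


def _prf(n_match: int, n_pred: int, n_true: int) -> dict:
    return {
        "precision": n_match / n_pred if n_pred else float("nan"),
        "recall": n_match / n_true if n_true else float("nan"),
        "n_predicted": n_pred,
        "n_true": n_true,
    }


def locus_to_truth_gene(loci, truth: Mapping) -> dict[str, str]:
    """Map each locus id to the truth gene its member transcripts came from."""
    iso2gene = truth["isoforms"]
    out = {}
    for locus in loci:
        genes = {iso2gene.get(t.transcript_id) for t in locus.transcripts}
        genes.discard(None)
        if len(genes) == 1:
            out[locus.locus_id] = genes.pop()
    return out


def score_events(events: Sequence[ASEvent], truth: Mapping) -> pd.DataFrame:
    """Per-type precision/recall of detected events vs planted ones."""
    detected = {(e.event_type, anchor_coords(e.anchor)) for e in events}
    planted = {
        (r["event_type"], tuple(sorted(r["coords"]))) for r in truth["events"]
    }
    types = sorted({t for t, _ in detected | planted})
    rows = []
    for etype in types:
        d = {k for k in detected if k[0] == etype}
        p = {k for k in planted if k[0] == etype}
        rows.append({"event_type": etype, **_prf(len(d & p), len(d), len(p))})
    return pd.DataFrame(rows)


def score_end_flags(end_flag_df: pd.DataFrame, loci,
                    truth: Mapping) -> pd.DataFrame:
    mapping = locus_to_truth_gene(loci, truth)
    pred = end_flag_df.assign(
        truth_gene=end_flag_df["gene_id"].map(mapping)
    ).dropna(subset=["truth_gene"]).set_index("truth_gene")
    rows = []
    for kind, col in (("aTSS", "atss"), ("aTTS", "atts")):
        true_pos = {g for g, f in truth["end_flags"].items() if f[col]}
        pred_pos = set(pred.index[pred[col]])
        scored = set(truth["end_flags"])
        pred_pos &= scored
        rows.append(
            {"end_kind": kind,
             **_prf(len(pred_pos & true_pos), len(pred_pos), len(true_pos))}
        )
    return pd.DataFrame(rows)


def score_polya_sites(sites_df: pd.DataFrame, loci, truth: Mapping,
                      tol_nt: int = 24) -> dict:
    mapping = locus_to_truth_gene(loci, truth)
    truth_sites: dict[str, list[int]] = {}
    for r in truth["polya_sites"]:
        truth_sites.setdefault(r["gene_id"], []).append(r["site_pos"])
    n_true = sum(len(v) for v in truth_sites.values())
    n_pred = len(sites_df)
    n_match = 0
    for row in sites_df.itertuples(index=False):
        gene = mapping.get(row.gene_id)
        cands = truth_sites.get(gene, [])
        hit = next((s for s in cands if abs(s - row.site_pos) <= tol_nt), None)
        if hit is not None:
            n_match += 1
            cands.remove(hit)
    return _prf(n_match, n_pred, n_true)


def score_lncrnas(records, truth: Mapping) -> dict:
    planted = {r["transcript_id"]: r["class"] for r in truth["lncrnas"]}
    predicted = {r.transcript_id: r.positional_class for r in records}
    matched = set(planted) & set(predicted)
    out = _prf(len(matched), len(predicted), len(planted))
    out["class_accuracy"] = (
        sum(planted[t] == predicted[t] for t in matched) / len(matched)
        if matched else float("nan")
    )
    return out


def score_clusters(labels: pd.Series, truth: Mapping) -> float:
    planted = truth["lnc_clusters"]
    common = [t for t in labels.index if t in planted]
    if not common:
        return float("nan")
    return float(
        adjusted_rand_score(
            [planted[t] for t in common], [labels[t] for t in common]
        )
    )


def score_domains(annotations: Mapping, truth: Mapping) -> dict:
    """Accuracy of change classes against the designated truth references."""
    n_ok = 0
    records = truth["domain_changes"]
    for r in records:
        change = classify_domain_change(
            r["isoform_id"], r["reference_isoform_id"], annotations
        )
        if (
            change.change_class == r["change_class"]
            and change.lost == list(r["lost"])
            and change.gained == list(r["gained"])
        ):
            n_ok += 1
    return {"accuracy": n_ok / len(records) if records else float("nan"),
            "n_true": len(records)}


def score_against_truth(outputs: Mapping, truth: Mapping) -> pd.DataFrame:
    """Aggregate per-stage scores into one tidy table.

    ``outputs`` may provide any of: ``events`` (list of ASEvent), ``loci``,
    ``end_flags`` (DataFrame), ``polya_sites`` (DataFrame), ``lncrnas``
    (records), ``lnc_cluster_labels`` (Series), ``domain_annotations``.
    Missing stages are skipped.
    """
    rows = []

    def add(stage, metric, value, n=None):
        rows.append({"stage": stage, "metric": metric, "value": value, "n": n})

    if "events" in outputs:
        ev = score_events(outputs["events"], truth)
        for r in ev.itertuples(index=False):
            add(f"splicing[{r.event_type}]", "precision", r.precision, r.n_predicted)
            add(f"splicing[{r.event_type}]", "recall", r.recall, r.n_true)
    if "end_flags" in outputs and "loci" in outputs:
        ef = score_end_flags(outputs["end_flags"], outputs["loci"], truth)
        for r in ef.itertuples(index=False):
            add(f"ends[{r.end_kind}]", "precision", r.precision, r.n_predicted)
            add(f"ends[{r.end_kind}]", "recall", r.recall, r.n_true)
    if "polya_sites" in outputs and "loci" in outputs:
        s = score_polya_sites(outputs["polya_sites"], outputs["loci"], truth)
        add("polya", "precision", s["precision"], s["n_predicted"])
        add("polya", "recall", s["recall"], s["n_true"])
    if "lncrnas" in outputs:
        s = score_lncrnas(outputs["lncrnas"], truth)
        add("lncrna", "precision", s["precision"], s["n_predicted"])
        add("lncrna", "recall", s["recall"], s["n_true"])
        add("lncrna", "class_accuracy", s["class_accuracy"])
    if "lnc_cluster_labels" in outputs:
        add("expression", "cluster_ari",
            score_clusters(outputs["lnc_cluster_labels"], truth))
    if "domain_annotations" in outputs:
        s = score_domains(outputs["domain_annotations"], truth)
        add("domains", "class_accuracy", s["accuracy"], s["n_true"])
    return pd.DataFrame(rows, columns=["stage", "metric", "value", "n"])
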