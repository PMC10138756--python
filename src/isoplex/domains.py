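"""Isoform-level conserved-domain comparison.

Each gene's isoforms are compared as multisets of domain names against a
reference isoform (by default the one carrying the most domains) and
classified as unchanged / loss / gain / both.  Comparison is at the level of
domain presence, not domain coordinates.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainChange",
    "read_domain_table",
    "select_reference_isoform",
    "classify_domain_change",
    "classify_gene",
    "family_report",
]


@dataclasses.dataclass
class DomainChange:
    isoform_id: str
    reference_isoform_id: str
    lost: list[str]       # multiset, sorted
    gained: list[str]     # multiset, sorted
    change_class: str     # unchanged | loss | gain | both


def read_domain_table(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a TSV of (isoform_id, domain_name, start_aa, end_aa)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.isoform_id, []).append(
            (row.domain_name, int(row.start_aa), int(row.end_aa))
        )
    return out


def select_reference_isoform(
    isoform_ids: Sequence[str],
    annotations: Mapping[str, Sequence[tuple[str, int, int]]],
    orf_lengths: Mapping[str, int] | None = None,
) -> str:
    """The gene's comparison baseline: most domains, then longest ORF, then id."""
    if not isoform_ids:
        raise ValueError("no isoforms to choose a reference from")

    def key(iso):
        n = len(annotations.get(iso, []))
        orf = (orf_lengths or {}).get(iso, 0)
        return (-n, -orf, iso)

    return min(isoform_ids, key=key)


def classify_domain_change(
    isoform_id: str,
    reference_id: str,
    annotations: Mapping[str, Sequence[tuple[str, int, int]]],
) -> DomainChange:
    """Multiset difference of domain names between an isoform and a reference.

    lost = reference - isoform, gained = isoform - reference (duplicate
    domains count per copy); class: both lost and gained non-empty -> both,
    only lost -> loss, only gained -> gain, neither -> unchanged.
    """
    ref = Counter(name for name, *_ in annotations.get(reference_id, []))
    iso = Counter(name for name, *_ in annotations.get(isoform_id, []))
    lost = sorted((ref - iso).elements())
    gained = sorted((iso - ref).elements())
    cls = (
        "both" if lost and gained
        else "loss" if lost
        else "gain" if gained
        else "unchanged"
    )
    return DomainChange(isoform_id, reference_id, lost, gained, cls)


def classify_gene(
    isoform_ids: Sequence[str],
    annotations: Mapping[str, Sequence[tuple[str, int, int]]],
    reference_id: str | None = None,
    orf_lengths: Mapping[str, int] | None = None,
) -> list[DomainChange]:
    if reference_id is None:
        reference_id = select_reference_isoform(isoform_ids, annotations, orf_lengths)
    return [
        classify_domain_change(iso, reference_id, annotations)
        for iso in sorted(isoform_ids)
    ]


def family_report(
    family_isoforms: Mapping[str, Sequence[str]],
    changes: Mapping[str, DomainChange],
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-isoform domain-change calls with log2(FPKM+1) expression.

    ``family_isoforms`` maps family name -> isoform ids; every listed isoform
    needs an expression row.  One row per isoform, ordered by (family,
    isoform id).
    """
    rows = []
    for family in sorted(family_isoforms):
        for iso in sorted(family_isoforms[family]):
            if iso not in expression.index:
                raise KeyError(f"no expression row for isoform {iso}")
            ch = changes.get(iso)
            expr = np.log2(expression.loc[iso].to_numpy(dtype=float) + 1)
            row = {
                "family": family,
                "isoform_id": iso,
                "change_class": ch.change_class if ch else "unchanged",
                "lost_domains": ",".join(ch.lost) if ch else "",
                "gained_domains": ",".join(ch.gained) if ch else "",
            }
            row.update(
                {f"log2fpkm_{s}": float(v) for s, v in zip(expression.columns, expr)}
            )
            rows.append(row)
    return pd.DataFrame(rows)
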