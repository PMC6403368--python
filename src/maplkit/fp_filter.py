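"""False-positive filtering and replicate-consensus detection calls.

Two per-OTU read-count thresholds remove false positives from the
count matrix:

* ``T_CC`` (cross-contamination): the maximum count of the OTU across
  the run's negative controls — any count at or below the worst
  observed contamination is discarded, which guarantees clean negative
  controls after filtering;
* ``T_FA`` (false index-pairing): ``ceil(rate_fa x run total of the
  OTU)`` with a default global false index-pairing rate of 0.2%,
  absorbing reads misassigned between multiplexed samples on the
  flowcell.

A cell survives only if it exceeds both thresholds.  Surviving counts
are then pooled per taxon and converted to presence/absence: a
biological sample is called positive for a taxon when at least
``min_positive`` of its technical PCR replicates (default 2 of 3) are
positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .containers import CountMatrix

__all__ = [
    "FilterThresholds",
    "DetectionMatrix",
    "compute_tcc",
    "compute_tfa",
    "compute_thresholds",
    "apply_thresholds",
    "drop_taxa",
    "consensus_call",
]


@dataclass
class FilterThresholds:
    """Per-OTU cutoffs: ``t_cc`` from negative controls, ``t_fa`` from
    the global false index-pairing rate."""

    t_cc: dict[str, int]
    t_fa: dict[str, int]
    rate_fa: float = 0.002

    def combined(self, otu_id: str) -> int:
        return max(self.t_cc[otu_id], self.t_fa[otu_id])


@dataclass
class DetectionMatrix:
    """Consensus presence/absence calls per biological sample x taxon.

    ``support`` counts positive replicates; ``calls`` is
    ``support >= min_positive``.
    """

    calls: pd.DataFrame
    support: pd.DataFrame
    min_positive: int = 2

    def detected_taxa(self, biological_id: str) -> set[str]:
        row = self.calls.loc[biological_id]
        return set(row.index[row])


def compute_tcc(counts: CountMatrix) -> dict[str, int]:
    """T_CC per OTU: its maximum count across negative-control columns."""
    nc = counts.negative_control_columns
    if not nc:
        raise ValueError(
            "no negative-control columns present: cannot estimate "
            "cross-contamination thresholds"
        )
    return counts.counts[nc].max(axis=1).astype(int).to_dict()


def compute_tfa(counts: CountMatrix, rate_fa: float = 0.002) -> dict[str, int]:
    """T_FA per OTU: ceil(rate_fa x run total of the OTU)."""
    if not 0.0 <= rate_fa <= 1.0:
        raise ValueError("rate_fa must be in [0, 1]")
    totals = counts.counts.sum(axis=1)
    return {otu: math.ceil(rate_fa * int(t)) for otu, t in totals.items()}


def compute_thresholds(
    counts: CountMatrix, rate_fa: float = 0.002
) -> FilterThresholds:
    return FilterThresholds(
        t_cc=compute_tcc(counts), t_fa=compute_tfa(counts, rate_fa), rate_fa=rate_fa
    )


def apply_thresholds(
    counts: CountMatrix, thresholds: FilterThresholds
) -> CountMatrix:
    """Zero every cell at or below max(T_CC, T_FA) of its OTU.

    By construction of T_CC (max over negative controls, discarded with
    "<="), all negative-control columns are identically zero afterwards.
    """
    missing = set(counts.counts.index) - set(thresholds.t_cc) | (
        set(counts.counts.index) - set(thresholds.t_fa)
    )
    if missing:
        raise ValueError(f"thresholds missing OTUs: {sorted(missing)[:5]}")
    out = counts.copy()
    cutoff = pd.Series(
        {otu: thresholds.combined(otu) for otu in out.counts.index}
    )
    mat = out.counts
    out.counts = mat.where(mat.gt(cutoff, axis=0), 0)
    return out


def drop_taxa(counts: CountMatrix, taxa: Iterable[str],
              taxon_of: Mapping[str, str] | None = None) -> CountMatrix:
    """Remove rows affiliated to excluded taxa (e.g. co-collected
    non-host eggs removed after filtering, before detection calls)."""
    taxa = set(taxa)
    out = counts.copy()
    keep = [
        otu for otu in out.counts.index
        if (taxon_of.get(otu, otu) if taxon_of else otu) not in taxa
    ]
    out.counts = out.counts.loc[keep]
    return out


def consensus_call(
    filtered: CountMatrix,
    min_positive: int = 2,
    n_replicates: int = 3,
    taxon_of: Mapping[str, str] | None = None,
    taxa: Iterable[str] | None = None,
) -> DetectionMatrix:
    """Convert filtered replicate counts to consensus detection calls.

    OTU rows are pooled by assigned taxon (``taxon_of``; identity when
    None, i.e. rows already are taxa) before the presence test, so two
    haplotypes of one species support each other.  ``taxa`` optionally
    restricts the output (e.g. parasitoids + host).  Every biological
    sample must have exactly ``n_replicates`` replicate columns.
    """
    if min_positive > n_replicates:
        raise ValueError("min_positive cannot exceed n_replicates")
    meta = filtered.sample_meta
    assay_cols = filtered.assay_columns
    by_taxon = filtered.counts.loc[:, assay_cols].groupby(
        lambda otu: taxon_of.get(otu, otu) if taxon_of else otu
    ).sum()
    if taxa is not None:
        by_taxon = by_taxon.loc[[t for t in by_taxon.index if t in set(taxa)]]

    bios = meta.loc[assay_cols].groupby("biological_id").groups
    support = {}
    for bio, cols in bios.items():
        if len(cols) != n_replicates:
            raise ValueError(
                f"biological sample {bio!r} has {len(cols)} replicate "
                f"columns, expected {n_replicates}"
            )
        support[bio] = (by_taxon[list(cols)] > 0).sum(axis=1)
    support_df = pd.DataFrame(support).T.sort_index()
    support_df.index.name = "biological_id"
    return DetectionMatrix(
        calls=support_df >= min_positive,
        support=support_df,
        min_positive=min_positive,
    )
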