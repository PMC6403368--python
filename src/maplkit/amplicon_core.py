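"""Merged mini-barcode reads -> taxonomically affiliated OTU table.

Simplified, self-contained equivalents of the standard amplicon stages:
primer trimming against the degenerate pair, length filtering
(133 +/- 10 bp), dereplication, two-parent chimera flagging,
single-linkage clustering at edit distance d=1 (swarm-style, grown in
decreasing abundance order), taxonomic affiliation by semi-global
alignment against a COI reference set with a 99% validity threshold,
and assembly of the sample x OTU count matrix.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .containers import CountMatrix, ReferenceDB
from .primers import IUPAC_EQUALITIES, PrimerPair, count_primer_mismatches

__all__ = [
    "MergedRead",
    "Amplicon",
    "OTU",
    "trim_primers",
    "length_filter",
    "dereplicate",
    "flag_chimeras",
    "swarm_cluster",
    "assign_taxonomy",
    "build_count_matrix",
    "process_reads",
]


@dataclass(frozen=True)
class MergedRead:
    """One merged (already pair-assembled) read assigned to a PCR
    replicate; ``abundance`` > 1 encodes pre-dereplicated input."""

    sample_replicate_id: str
    sequence: str
    abundance: int = 1

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"read contains non-ACGTN characters {sorted(bad)}")


@dataclass
class Amplicon:
    """A dereplicated sequence with its per-replicate counts."""

    sequence: str
    abundance: int
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_sample_counts and self.abundance != sum(
            self.per_sample_counts.values()
        ):
            raise ValueError("abundance != sum of per-sample counts")


@dataclass
class OTU:
    otu_id: str
    representative: str
    members: list[Amplicon]
    taxon: str = "unidentified"
    identity: float = 0.0

    @property
    def abundance(self) -> int:
        return sum(a.abundance for a in self.members)


# ---------------------------------------------------------------------------
# read-level stages
# ---------------------------------------------------------------------------

def trim_primers(read: MergedRead, primers: PrimerPair) -> str | None:
    """Return the insert enclosed by the primer pair, or None.

    The forward primer must match the 5' end and the reverse primer's
    reverse complement the 3' end, each with at most
    ``primers.max_mismatch`` IUPAC mismatches.
    """
    seq = read.sequence.upper()
    flen, rlen = len(primers.forward), len(primers.reverse)
    if len(seq) <= flen + rlen:
        return None
    fwd_mm = count_primer_mismatches(seq[:flen], primers.forward, "forward")
    if len(fwd_mm) > primers.max_mismatch:
        return None
    rev_mm = count_primer_mismatches(seq[-rlen:], primers.reverse, "reverse")
    if len(rev_mm) > primers.max_mismatch:
        return None
    return seq[flen:-rlen]


def length_filter(
    inserts: list[str], expected: int = 133, tolerance: int = 10
) -> list[str]:
    """Keep sequences with length in [expected - tolerance,
    expected + tolerance], inclusive."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    lo, hi = expected - tolerance, expected + tolerance
    return [s for s in inserts if lo <= len(s) <= hi]


def dereplicate(inserts: list[tuple[str, str]]) -> list[Amplicon]:
    """Collapse (sample_replicate_id, sequence) pairs into unique
    amplicons with per-replicate counts; sorted by decreasing abundance
    (ties broken lexicographically by sequence)."""
    per_seq: dict[str, Counter] = defaultdict(Counter)
    for sample_id, seq in inserts:
        per_seq[seq.upper()][sample_id] += 1
    amplicons = [
        Amplicon(seq, sum(c.values()), dict(c)) for seq, c in per_seq.items()
    ]
    amplicons.sort(key=lambda a: (-a.abundance, a.sequence))
    return amplicons


def flag_chimeras(
    amplicons: list[Amplicon],
    min_segment: int = 20,
    parent_ratio: float = 2.0,
) -> tuple[list[Amplicon], list[Amplicon]]:
    """Partition amplicons into (kept, flagged) under a simplified
    two-parent chimera model.

    A candidate is flagged iff two distinct parents exist, each with
    abundance >= ``parent_ratio`` x the candidate's, and a breakpoint
    such that the candidate equals parent A's prefix up to the
    breakpoint and parent B's suffix after it, with both segments exact
    matches of at least ``min_segment`` bases.
    """
    kept: list[Amplicon] = []
    flagged: list[Amplicon] = []
    for cand in amplicons:
        parents = [
            a for a in amplicons
            if a.sequence != cand.sequence
            and a.abundance >= parent_ratio * cand.abundance
        ]
        if _is_chimera(cand.sequence, parents, min_segment):
            flagged.append(cand)
        else:
            kept.append(cand)
    return kept, flagged


def _is_chimera(seq: str, parents: list[Amplicon], min_segment: int) -> bool:
    n = len(seq)
    for a in parents:
        for b in parents:
            if a is b:
                continue
            for k in range(min_segment, n - min_segment + 1):
                if len(a.sequence) < k or len(b.sequence) < n - k:
                    continue
                if (
                    seq[:k] == a.sequence[:k]
                    and seq[k:] == b.sequence[len(b.sequence) - (n - k):]
                ):
                    return True
    return False


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _edit_distance_le(a: str, b: str, d: int) -> bool:
    res = edlib.align(a, b, mode="NW", task="distance", k=d)
    return res["editDistance"] != -1


def swarm_cluster(amplicons: list[Amplicon], d: int = 1) -> list[OTU]:
    """Single-linkage OTUs at Levenshtein distance <= d.

    Clusters are grown iteratively from unassigned amplicons in
    decreasing abundance order (the swarm strategy); for any d this
    yields the connected components of the distance-<=d graph.  The
    representative is the most abundant member (ties broken
    lexicographically by sequence).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    order = sorted(amplicons, key=lambda a: (-a.abundance, a.sequence))
    unassigned = list(order)
    otus: list[OTU] = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        frontier = [seed]
        while frontier:
            nxt = []
            still = []
            for cand in unassigned:
                if any(
                    _edit_distance_le(cand.sequence, m.sequence, d)
                    for m in frontier
                ):
                    nxt.append(cand)
                    members.append(cand)
                else:
                    still.append(cand)
            unassigned = still
            frontier = nxt
        rep = min(members, key=lambda a: (-a.abundance, a.sequence))
        otus.append(
            OTU(
                otu_id=f"OTU_{len(otus) + 1:04d}",
                representative=rep.sequence,
                members=members,
            )
        )
    # deterministic ids by decreasing total abundance
    otus.sort(key=lambda o: (-o.abundance, o.representative))
    for i, otu in enumerate(otus):
        otu.otu_id = f"OTU_{i + 1:04d}"
    return otus


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def assign_taxonomy(
    otu: OTU | str, db: ReferenceDB, min_identity: float = 0.99
) -> tuple[str, float]:
    """Affiliate an OTU representative against the reference set.

    Semi-global (infix) alignment of the representative within each
    ~658 bp reference; identity = 1 - edit distance / representative
    length.  Best identity >= ``min_identity`` -> that species; ties at
    equal best identity -> ``"ambiguous:<sp1>,<sp2>,..."``; otherwise
    ``"unidentified"``.
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    query = otu.representative if isinstance(otu, OTU) else otu
    best: float = -1.0
    best_species: list[str] = []
    for rec in db:
        res = edlib.align(
            query,
            rec.sequence,
            mode="HW",
            task="distance",
            additionalEqualities=IUPAC_EQUALITIES,
        )
        identity = 1.0 - res["editDistance"] / len(query)
        if identity > best + 1e-12:
            best = identity
            best_species = [rec.species_name]
        elif abs(identity - best) <= 1e-12:
            best_species.append(rec.species_name)
    if best < min_identity:
        return "unidentified", best
    if len(best_species) > 1:
        return "ambiguous:" + ",".join(sorted(best_species)), best
    return best_species[0], best


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def build_count_matrix(otus: list[OTU], sample_meta: pd.DataFrame) -> CountMatrix:
    """Sum member per-replicate counts into an OTU x replicate matrix;
    row and column order are deterministic (OTU id, metadata order)."""
    referenced = {
        s for otu in otus for a in otu.members for s in a.per_sample_counts
    }
    missing = referenced - set(sample_meta.index)
    if missing:
        raise ValueError(
            f"sample metadata missing replicate ids: {sorted(missing)[:5]}"
        )
    counts = pd.DataFrame(
        0, index=[o.otu_id for o in otus], columns=list(sample_meta.index)
    )
    for otu in otus:
        for a in otu.members:
            for s, n in a.per_sample_counts.items():
                counts.loc[otu.otu_id, s] += n
    return CountMatrix(counts, sample_meta)


def process_reads(
    reads: list[MergedRead],
    db: ReferenceDB,
    sample_meta: pd.DataFrame,
    primers: PrimerPair | None = None,
    expected_length: int = 133,
    length_tolerance: int = 10,
    min_identity: float = 0.99,
    d: int = 1,
) -> tuple[CountMatrix, pd.DataFrame, dict[str, int]]:
    """Full read-to-table pipeline.

    Returns (count matrix, affiliation table with one row per OTU,
    per-stage rejection log).
    """
    primers = primers or PrimerPair()
    log: dict[str, int] = {"input": sum(r.abundance for r in reads)}

    trimmed: list[tuple[str, str]] = []
    for read in reads:
        insert = trim_primers(read, primers)
        if insert is not None:
            trimmed.extend([(read.sample_replicate_id, insert)] * read.abundance)
    log["primer_rejected"] = log["input"] - len(trimmed)

    lo, hi = expected_length - length_tolerance, expected_length + length_tolerance
    sized = [(s, seq) for s, seq in trimmed if lo <= len(seq) <= hi]
    log["length_rejected"] = len(trimmed) - len(sized)

    amplicons = dereplicate(sized)
    kept, flagged = flag_chimeras(amplicons)
    log["chimera_rejected"] = sum(a.abundance for a in flagged)

    otus = swarm_cluster(kept, d=d)
    for otu in otus:
        otu.taxon, otu.identity = assign_taxonomy(otu, db, min_identity)

    cm = build_count_matrix(otus, sample_meta)
    affiliations = pd.DataFrame(
        {
            "otu_id": [o.otu_id for o in otus],
            "taxon": [o.taxon for o in otus],
            "identity": [o.identity for o in otus],
            "abundance": [o.abundance for o in otus],
        }
    )
    log["retained"] = int(cm.counts.to_numpy().sum())
    return cm, affiliations, log
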