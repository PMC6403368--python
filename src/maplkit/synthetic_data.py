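"""Synthetic mock-dilution and field-survey metabarcoding runs.

The generator emulates the statistical structure of a COI mini-barcode
host-parasitoid assay:

* a reference set of one lepidopteran host plus N parasitoid species,
  each ~658 bp with the degenerate primer binding sites flanking a
  133 bp insert (optionally including a cryptic species pair and a
  species whose reverse-primer 3' mismatch kills its amplification);
* mock dilutions: known parasitoid DNA masses (defaults 7, 0.7, 0.07,
  0.007 ng) mixed into 56 ng of host DNA, read counts drawn
  multinomially with weights mass x amplification efficiency at a
  Poisson-distributed depth (~8,000 reads per PCR replicate);
* field surveys: per-specimen parasitism drawn from stage- and
  site-specific prevalences, within-host parasitoid tissue fractions
  from a truncated log-normal (mean ~0.006 of the host's DNA), paired
  rearing outcomes with stage-specific mortality masking rearing-based
  detection;
* two realistic error processes injected after the fact:
  cross-contamination (Poisson stray reads, visible in negative
  controls) and index hopping (a fixed fraction of each OTU's reads
  reassigned uniformly across samples, totals conserved).

Every run keeps its ground truth so downstream detection and
parasitism-rate estimates can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, ReferenceDB, ReferenceRecord, RunArtifacts
from .primers import (
    FORWARD_PRIMER,
    INSERT_LENGTH,
    REVERSE_PRIMER,
    binding_efficiency,
    count_primer_mismatches,
    expand_degenerate,
    reverse_complement,
)

__all__ = [
    "MockDesign",
    "FieldDesign",
    "LogNormalFractions",
    "make_reference_db",
    "simulate_mock_run",
    "simulate_field_run",
    "inject_cross_contamination",
    "inject_index_hopping",
    "emit_reads",
    "VOUCHER_MISMATCH_REGION",
]

REFERENCE_LENGTH = 658
AMPLICON_LENGTH = len(FORWARD_PRIMER) + INSERT_LENGTH + len(REVERSE_PRIMER)
_LEFT_FLANK = (REFERENCE_LENGTH - AMPLICON_LENGTH) // 2

#: Reverse-primer binding region (read orientation) of a voucher whose
#: 3'-proximal mismatch under the reverse primer abolishes
#: amplification.  The critical mismatch sits 10 bases from the primer
#: 3' end (the primer's degenerate Y position).
VOUCHER_MISMATCH_REGION = "CATGCTTTTTTAATAATTTTTTTTTTTGT"

STAGES = ("egg", "early_larva", "late_larva")

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MockDesign:
    """Controlled host-parasitoid DNA dilution series.

    Defaults follow the calibration mixtures: each parasitoid's DNA at
    7, 0.7, 0.07 and 0.007 ng combined with 56 ng of host DNA, three
    technical PCR replicates per mixture, ~8,000 reads per replicate,
    ten negative controls.
    """

    parasitoid_masses_ng: tuple[float, ...] = (7.0, 0.7, 0.07, 0.007)
    host_mass_ng: float = 56.0
    n_replicates: int = 3
    reads_per_sample: int = 8000
    species: tuple[str, ...] | None = None
    n_negative_controls: int = 10

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.parasitoid_masses_ng) or self.host_mass_ng <= 0:
            raise ValueError("DNA masses must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")


@dataclass(frozen=True)
class LogNormalFractions:
    """Truncated log-normal distribution of within-host parasitoid
    tissue fractions.

    Defaults give mean ~0.006 with bulk range ~0.001-0.01
    (exp(mu + sigma^2/2) = 0.006); draws are rejected outside
    (lower, upper), with upper = 0.5 (a parasitoid never outweighs its
    host).
    """

    mu: float = -5.267
    sigma: float = 0.55
    lower: float = 0.0
    upper: float = 0.5

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            x = float(rng.lognormal(self.mu, self.sigma))
            if self.lower < x < self.upper:
                return x
        raise RuntimeError("tissue-fraction rejection sampling did not converge")


@dataclass(frozen=True)
class FieldDesign:
    """A field survey: specimens per field, stage composition,
    parasitism prevalences, tissue fractions, rearing mortality.

    ``prevalence`` maps (species, stage, site) -> probability that a
    specimen of that stage at that site is parasitised by that species;
    absent keys mean 0.  Stage mix and mortality defaults follow a
    400-specimen survey over 4 fields (143 eggs / 257 larvae; egg
    mortality 31.5%, larval mortality 56.3%).
    """

    prevalence: Mapping[tuple[str, str, str], float]
    n_specimens_per_field: int = 100
    fields: tuple[tuple[str, str], ...] = (
        ("Bambey", "B1"), ("Bambey", "B2"), ("Nioro", "N1"), ("Nioro", "N2"),
    )
    stage_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "egg": 0.3575, "early_larva": 0.32125, "late_larva": 0.32125,
        }
    )
    tissue_fraction_dist: LogNormalFractions = field(
        default_factory=LogNormalFractions
    )
    mortality: Mapping[str, float] = field(
        default_factory=lambda: {
            "egg": 0.315, "early_larva": 0.563, "late_larva": 0.563,
        }
    )
    multiparasitism_rate: float = 0.05
    reads_per_sample: int = 8000
    n_replicates: int = 3
    n_negative_controls: int = 10

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.stage_mix.values()), 1.0):
            raise ValueError("stage_mix must sum to 1")
        probs = list(self.prevalence.values()) + list(self.mortality.values())
        probs.append(self.multiparasitism_rate)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if self.n_specimens_per_field < 1:
            raise ValueError("n_specimens_per_field must be >= 1")
        for stage in self.stage_mix:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------

def _random_insert(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=INSERT_LENGTH))


def _mutate(insert: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    seq = list(insert)
    for p in positions:
        seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
    return "".join(seq)


def _assemble(
    insert: str, rev_region: str, rng: np.random.Generator
) -> tuple[str, float]:
    """Embed an insert between primer binding sites inside a 658 bp
    reference; returns (sequence, amp_efficiency)."""
    fwd_region = expand_degenerate(FORWARD_PRIMER, rng)
    left = "".join(rng.choice(_BASES, size=_LEFT_FLANK))
    right_len = REFERENCE_LENGTH - _LEFT_FLANK - AMPLICON_LENGTH
    right = "".join(rng.choice(_BASES, size=right_len))
    seq = left + fwd_region + insert + rev_region + right
    eff = binding_efficiency(
        count_primer_mismatches(fwd_region, FORWARD_PRIMER, "forward")
    ) * binding_efficiency(
        count_primer_mismatches(rev_region, REVERSE_PRIMER, "reverse")
    )
    return seq, eff


def make_reference_db(
    n_parasitoids: int,
    divergence: float = 0.05,
    cryptic_pair: bool = False,
    primer_mismatch: bool = False,
    seed: int = 0,
) -> ReferenceDB:
    """Build a host + parasitoid COI reference set for simulation.

    Each species' 133 bp insert derives from a common ancestral insert
    by mutating a species-specific, pairwise-disjoint set of
    ``m = max(2, round(divergence * 133))`` positions, so every
    non-cryptic pair differs at >= 2 positions (pairwise identity
    < 99%, resolvable at the validity threshold).  With
    ``cryptic_pair`` the last two parasitoids differ at exactly 2
    insert positions (distinct sequences, indistinguishable to a
    morphologist).  With ``primer_mismatch`` the first parasitoid's
    reverse-primer binding site carries a 3'-critical mismatch and its
    amplification efficiency is 0 (the egg-parasitoid failure mode).
    """
    if n_parasitoids < 1:
        raise ValueError("n_parasitoids must be >= 1")
    if not 0.0 < divergence < 0.3:
        raise ValueError("divergence must be in (0, 0.3)")
    if divergence * INSERT_LENGTH < 2:
        raise ValueError(
            "divergence too low to guarantee <99% pairwise identity "
            f"(need >= {2 / INSERT_LENGTH:.3f})"
        )
    if cryptic_pair and n_parasitoids < 2:
        raise ValueError("cryptic_pair needs n_parasitoids >= 2")

    m = max(2, round(divergence * INSERT_LENGTH))
    n_independent = n_parasitoids - (1 if cryptic_pair else 0)
    needed = n_independent * m + (2 if cryptic_pair else 0)
    if needed > INSERT_LENGTH:
        raise ValueError(
            f"cannot place {n_parasitoids} species at divergence {divergence}: "
            f"{needed} mutated positions exceed the {INSERT_LENGTH} bp insert"
        )

    rng = np.random.default_rng(seed)
    ancestral = _random_insert(rng)
    pool = [int(p) for p in rng.permutation(INSERT_LENGTH)]

    def take(k: int) -> list[int]:
        picked = pool[:k]
        del pool[:k]
        return picked

    records: list[ReferenceRecord] = []

    def add(name: str, guild: str, insert: str, rev_region: str) -> None:
        seq, eff = _assemble(insert, rev_region, rng)
        records.append(
            ReferenceRecord(name, guild, seq, eff, amplicon_start=_LEFT_FLANK)
        )

    matched_rev = expand_degenerate(reverse_complement(REVERSE_PRIMER), rng)
    add("Host_moth", "host", ancestral, matched_rev)

    inserts: list[str] = []
    for i in range(n_independent):
        inserts.append(_mutate(ancestral, take(m), rng))
    if cryptic_pair:
        inserts.append(_mutate(inserts[-1], take(2), rng))

    for i, insert in enumerate(inserts):
        rev_region = (
            VOUCHER_MISMATCH_REGION
            if primer_mismatch and i == 0
            else expand_degenerate(reverse_complement(REVERSE_PRIMER), rng)
        )
        add(f"Parasitoid_{i + 1:02d}", "parasitoid", insert, rev_region)

    return ReferenceDB(records)


# ---------------------------------------------------------------------------
# run simulation
# ---------------------------------------------------------------------------

def _meta_frame(rows: list[dict]) -> pd.DataFrame:
    meta = pd.DataFrame(rows).set_index("sample_replicate_id")
    return meta


def _negative_control_rows(n: int) -> list[dict]:
    return [
        {
            "sample_replicate_id": f"NC{i + 1:02d}|R1",
            "biological_id": f"NC{i + 1:02d}",
            "replicate_index": 1,
            "role": "negative_control",
            "stage": "NA",
            "site": "NA",
            "field": "NA",
        }
        for i in range(n)
    ]


def simulate_mock_run(
    db: ReferenceDB, design: MockDesign, seed: int = 0
) -> RunArtifacts:
    """Simulate one dilution-series sequencing run.

    For every (parasitoid species, mass, PCR replicate), reads are a
    multinomial draw between that parasitoid and the host with weights
    mass x amp_efficiency and host_mass x host amp_efficiency, at depth
    Poisson(reads_per_sample).  Negative controls carry zero template;
    contamination appears only via the ``inject_*`` operations.
    """
    rng = np.random.default_rng(seed)
    host = db.host
    species = (
        list(design.species)
        if design.species is not None
        else db.species("parasitoid")
    )
    known = set(db.species())
    unknown = [s for s in species if s not in known]
    if unknown:
        raise ValueError(f"unknown species in design: {unknown}")

    otu_ids = [host.species_name] + species
    meta_rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []

    for sp in species:
        eff = db[sp].amp_efficiency
        w_host = design.host_mass_ng * host.amp_efficiency
        for mass in design.parasitoid_masses_ng:
            bio = f"{sp}|{mass:g}ng"
            w_sp = mass * eff
            total_w = w_sp + w_host
            expected = w_sp / total_w if total_w > 0 else np.nan
            truth_rows.append(
                {
                    "biological_id": bio,
                    "species": sp,
                    "mass_ng": mass,
                    "host_mass_ng": design.host_mass_ng,
                    "expected_proportion": expected,
                }
            )
            for r in range(1, design.n_replicates + 1):
                col_id = f"{bio}|R{r}"
                depth = int(rng.poisson(design.reads_per_sample))
                col = np.zeros(len(otu_ids), dtype=int)
                if total_w > 0 and depth > 0:
                    sp_reads, host_reads = rng.multinomial(
                        depth, [w_sp / total_w, w_host / total_w]
                    )
                    col[otu_ids.index(sp)] = sp_reads
                    col[0] = host_reads
                columns[col_id] = col
                meta_rows.append(
                    {
                        "sample_replicate_id": col_id,
                        "biological_id": bio,
                        "replicate_index": r,
                        "role": "mock",
                        "stage": "NA",
                        "site": "NA",
                        "field": "NA",
                        "species": sp,
                        "mass_ng": mass,
                    }
                )

    for row in _negative_control_rows(design.n_negative_controls):
        columns[row["sample_replicate_id"]] = np.zeros(len(otu_ids), dtype=int)
        meta_rows.append({**row, "species": "NA", "mass_ng": np.nan})

    counts = pd.DataFrame(columns, index=otu_ids)
    cm = CountMatrix(counts, _meta_frame(meta_rows))
    return RunArtifacts(truth=pd.DataFrame(truth_rows), counts=cm)


def simulate_field_run(
    db: ReferenceDB, design: FieldDesign, seed: int = 0
) -> RunArtifacts:
    """Simulate one field-survey sequencing run with paired rearing.

    Each specimen is assigned a stage, a parasitism status per species
    (Bernoulli at the design prevalence, plus optional multiparasitism),
    per-species tissue fractions, and a rearing outcome: it dies with
    the stage's mortality probability (masking rearing detection),
    otherwise the parasitoid with the largest tissue fraction emerges
    (rearing never reveals multiparasitism), or the host emerges.
    """
    rng = np.random.default_rng(seed)
    host = db.host
    parasitoids = db.species("parasitoid")
    bad = [
        sp for (sp, _, _) in design.prevalence
        if sp not in parasitoids
    ]
    if bad:
        raise ValueError(f"prevalence references species absent from db: {bad}")
    for (_, stage, _) in design.prevalence:
        if stage not in STAGES:
            raise ValueError(f"prevalence references unknown stage {stage!r}")

    stages = list(design.stage_mix)
    stage_p = np.array([design.stage_mix[s] for s in stages], dtype=float)
    stage_p = stage_p / stage_p.sum()

    otu_ids = [host.species_name] + parasitoids
    meta_rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []

    for site, field_id in design.fields:
        for i in range(design.n_specimens_per_field):
            bio = f"{field_id}-{i + 1:03d}"
            stage = stages[int(rng.choice(len(stages), p=stage_p))]

            infecting = [
                sp for sp in parasitoids
                if rng.random() < design.prevalence.get((sp, stage, site), 0.0)
            ]
            if infecting and rng.random() < design.multiparasitism_rate:
                others = [sp for sp in parasitoids if sp not in infecting]
                if others:
                    infecting.append(str(rng.choice(others)))
            fractions = {
                sp: design.tissue_fraction_dist.draw(rng) for sp in infecting
            }

            if rng.random() < design.mortality.get(stage, 0.0):
                outcome = "dead"
            elif infecting:
                emerged = max(fractions, key=fractions.get)
                outcome = f"parasitoid_emerged:{emerged}"
            else:
                outcome = "host_emerged"

            truth_rows.append(
                {
                    "biological_id": bio,
                    "stage": stage,
                    "site": site,
                    "field": field_id,
                    "species": ";".join(infecting),
                    "tissue_fractions": ";".join(
                        f"{fractions[sp]:.6g}" for sp in infecting
                    ),
                    "n_species": len(infecting),
                    "rearing_outcome": outcome,
                }
            )

            weights = np.zeros(len(otu_ids))
            weights[0] = (1.0 - sum(fractions.values())) * host.amp_efficiency
            for sp in infecting:
                weights[otu_ids.index(sp)] = fractions[sp] * db[sp].amp_efficiency
            total_w = weights.sum()

            for r in range(1, design.n_replicates + 1):
                col_id = f"{bio}|R{r}"
                depth = int(rng.poisson(design.reads_per_sample))
                if total_w > 0 and depth > 0:
                    col = rng.multinomial(depth, weights / total_w)
                else:
                    col = np.zeros(len(otu_ids), dtype=int)
                columns[col_id] = col
                meta_rows.append(
                    {
                        "sample_replicate_id": col_id,
                        "biological_id": bio,
                        "replicate_index": r,
                        "role": "specimen",
                        "stage": stage,
                        "site": site,
                        "field": field_id,
                    }
                )

    for row in _negative_control_rows(design.n_negative_controls):
        columns[row["sample_replicate_id"]] = np.zeros(len(otu_ids), dtype=int)
        meta_rows.append(row)

    counts = pd.DataFrame(columns, index=otu_ids)
    cm = CountMatrix(counts, _meta_frame(meta_rows))
    return RunArtifacts(truth=pd.DataFrame(truth_rows), counts=cm)


# ---------------------------------------------------------------------------
# error-process injection
# ---------------------------------------------------------------------------

def inject_cross_contamination(
    counts: CountMatrix, rate: float, seed: int = 0
) -> CountMatrix:
    """Add Poisson stray reads to every column (negative controls
    included): for OTU ``o`` and any column, the expected number of
    stray reads is ``rate x run-mean depth x relative abundance of o``.
    Counts never decrease; sample metadata is untouched.
    """
    if rate < 0:
        raise ValueError("contamination rate must be >= 0")
    out = counts.copy()
    if rate == 0:
        return out
    mat = out.counts.to_numpy()
    grand = mat.sum()
    if grand == 0:
        return out
    rng = np.random.default_rng(seed)
    mean_depth = mat.sum(axis=0).mean()
    rel_abund = mat.sum(axis=1) / grand
    lam = rate * mean_depth * rel_abund
    stray = rng.poisson(lam[:, None], size=mat.shape)
    out.counts = pd.DataFrame(
        mat + stray, index=out.counts.index, columns=out.counts.columns
    )
    return out


def inject_index_hopping(
    counts: CountMatrix, rate: float, seed: int = 0
) -> CountMatrix:
    """Reassign a Binomial(OTU run total, rate) number of each OTU's
    reads from their source samples (drawn without replacement,
    proportionally to counts) uniformly across all sample columns.
    Per-OTU run totals are conserved exactly.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("index-hopping rate must be in [0, 1]")
    out = counts.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mat = out.counts.to_numpy().copy()
    n_cols = mat.shape[1]
    uniform = np.full(n_cols, 1.0 / n_cols)
    for i in range(mat.shape[0]):
        total = int(mat[i].sum())
        if total == 0:
            continue
        n_hop = int(rng.binomial(total, rate))
        if n_hop == 0:
            continue
        removed = rng.multivariate_hypergeometric(mat[i], n_hop)
        mat[i] = mat[i] - removed + rng.multinomial(n_hop, uniform)
    out.counts = pd.DataFrame(
        mat, index=out.counts.index, columns=out.counts.columns
    )
    return out


# ---------------------------------------------------------------------------
# optional read-level emission
# ---------------------------------------------------------------------------

def emit_reads(
    db: ReferenceDB,
    counts: CountMatrix,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[tuple[str, str]]:
    """Materialise a count matrix as merged reads.

    Each read is the species' amplicon (forward binding site + 133 bp
    insert + reverse binding site, read orientation), optionally with
    uniform substitution errors.  Returns ``(sample_replicate_id,
    sequence)`` tuples; row ids of ``counts`` must be species present
    in ``db`` with a known amplicon location.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    amplicons: dict[str, str] = {}
    for otu in counts.counts.index:
        rec = db[otu]
        if rec.amplicon_start is None:
            raise ValueError(f"{otu}: amplicon location unknown")
        amplicons[otu] = rec.sequence[
            rec.amplicon_start : rec.amplicon_start + AMPLICON_LENGTH
        ]
    reads: list[tuple[str, str]] = []
    for col in counts.counts.columns:
        for otu, n in counts.counts[col].items():
            template = amplicons[otu]
            for _ in range(int(n)):
                seq = template
                if error_rate > 0:
                    arr = list(seq)
                    n_err = rng.binomial(len(arr), error_rate)
                    for pos in rng.choice(len(arr), size=n_err, replace=False):
                        arr[pos] = str(
                            rng.choice([b for b in "ACGT" if b != arr[pos]])
                        )
                    seq = "".join(arr)
                reads.append((col, seq))
    return reads
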