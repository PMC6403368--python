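"""Parasitism-rate estimation and method comparison.

Estimates parasitism rates from metabarcoding detection calls and from
paired rearing outcomes, under the two denominator conventions used
when rearing mortality is substantial:

* ``total_denominator`` — parasitised / all collected specimens
  (mortality included in the denominator);
* ``survivors_denominator`` — parasitised / hatched or live specimens
  only (mortality excluded).

Metabarcoding assays every specimen (dead or alive), so the two modes
coincide there.  Also computes per-species rates, multiparasitism
frequencies with co-occurring pairs, stage-wise read-proportion
summaries among positives, and the standard comparisons (one-way ANOVA
on per-field rates; Welch t or Wilcoxon paired rank tests on
per-specimen proportions).  Numerators and denominators are always
reported explicitly so the mortality convention cannot mislead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .fp_filter import DetectionMatrix

__all__ = [
    "SpecimenRecord",
    "ParasitismEstimate",
    "TestResult",
    "metabarcoding_records",
    "rearing_records",
    "parasitism_rate",
    "per_species_rates",
    "multiparasitism_frequency",
    "stage_proportions",
    "compare_rates",
    "compare_proportions",
]


@dataclass(frozen=True)
class SpecimenRecord:
    """One assayed specimen under one method."""

    biological_id: str
    stage: str
    site: str
    field: str
    method: str  # "metabarcoding" | "rearing"
    rearing_outcome: str = "NA"  # "parasitoid_emerged:<sp>"|"host_emerged"|"dead"|"NA"
    detected_taxa: frozenset[str] = frozenset()

    @property
    def is_dead(self) -> bool:
        return self.rearing_outcome == "dead"

    @property
    def parasitised(self) -> bool:
        return len(self.detected_taxa) > 0


@dataclass(frozen=True)
class ParasitismEstimate:
    numerator: int
    denominator: int
    rate: float
    mode: str
    scope: tuple

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be > 0")
        if not np.isclose(self.rate, self.numerator / self.denominator):
            raise ValueError("rate != numerator/denominator")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    pvalue: float
    test: str


# ---------------------------------------------------------------------------
# record construction from run artifacts
# ---------------------------------------------------------------------------

def metabarcoding_records(
    detections: DetectionMatrix,
    truth_meta: pd.DataFrame,
    parasitoid_taxa: Iterable[str] | None = None,
) -> list[SpecimenRecord]:
    """Specimen records from consensus calls; ``truth_meta`` supplies
    per-specimen stage/site/field (and rearing outcome when paired).
    ``parasitoid_taxa`` restricts which called taxa count as parasitoid
    detections (default: every called column except obvious host rows
    is counted — pass the guild list for strictness)."""
    taxa = set(parasitoid_taxa) if parasitoid_taxa is not None else None
    records = []
    meta = truth_meta.set_index("biological_id")
    for bio in detections.calls.index:
        if bio not in meta.index:
            continue
        row = meta.loc[bio]
        called = detections.detected_taxa(bio)
        if taxa is not None:
            called &= taxa
        records.append(
            SpecimenRecord(
                biological_id=bio,
                stage=row["stage"],
                site=row["site"],
                field=row["field"],
                method="metabarcoding",
                rearing_outcome=str(row.get("rearing_outcome", "NA")),
                detected_taxa=frozenset(called),
            )
        )
    return records


def rearing_records(truth_meta: pd.DataFrame) -> list[SpecimenRecord]:
    """Specimen records under rearing: a parasitoid is detected only if
    it emerged; dead specimens contribute no detection."""
    records = []
    for _, row in truth_meta.iterrows():
        outcome = str(row["rearing_outcome"])
        detected: frozenset[str] = frozenset()
        if outcome.startswith("parasitoid_emerged:"):
            detected = frozenset([outcome.split(":", 1)[1]])
        records.append(
            SpecimenRecord(
                biological_id=row["biological_id"],
                stage=row["stage"],
                site=row["site"],
                field=row["field"],
                method="rearing",
                rearing_outcome=outcome,
                detected_taxa=detected,
            )
        )
    return records


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def _scoped(
    records: Sequence[SpecimenRecord],
    stage: str | Iterable[str] | None = None,
    site: str | None = None,
    field: str | None = None,
) -> list[SpecimenRecord]:
    stages = None
    if stage is not None:
        stages = {stage} if isinstance(stage, str) else set(stage)
    return [
        r for r in records
        if (stages is None or r.stage in stages)
        and (site is None or r.site == site)
        and (field is None or r.field == field)
    ]


def parasitism_rate(
    records: Sequence[SpecimenRecord],
    mode: str = "total_denominator",
    species: str | None = None,
    stage: str | Iterable[str] | None = None,
    site: str | None = None,
    field: str | None = None,
) -> ParasitismEstimate:
    """Parasitism rate over a scope of specimens.

    Numerator: specimens with >= 1 parasitoid detection (or detection
    of ``species``).  Denominator: all scoped specimens
    (``total_denominator``), or hatched/live ones only
    (``survivors_denominator``).  Rearing detections only exist among
    survivors; metabarcoding assays every specimen, so for a pure
    metabarcoding scope the mode does not change the denominator.
    """
    if mode not in ("total_denominator", "survivors_denominator"):
        raise ValueError(f"unknown mode {mode!r}")
    scoped = _scoped(records, stage=stage, site=site, field=field)
    if not scoped:
        raise ValueError("scope selects no records")

    def detected(r: SpecimenRecord) -> bool:
        return (species in r.detected_taxa) if species else r.parasitised

    if mode == "survivors_denominator":
        denom_records = [
            r for r in scoped
            if not (r.method == "rearing" and r.is_dead)
        ]
    else:
        denom_records = scoped
    if not denom_records:
        raise ValueError(
            "survivors denominator is zero (every scoped rearing specimen died)"
        )
    num = sum(detected(r) for r in denom_records)
    den = len(denom_records)
    return ParasitismEstimate(
        numerator=num,
        denominator=den,
        rate=num / den,
        mode=mode,
        scope=(
            ",".join(sorted({r.method for r in scoped})),
            stage or "all", site or "all", species or "all",
        ),
    )


def per_species_rates(
    records: Sequence[SpecimenRecord],
    species_list: Iterable[str],
    mode: str = "total_denominator",
    **scope,
) -> pd.DataFrame:
    """One rate per parasitoid species (a multiparasitised specimen
    counts once per species); species never detected are listed with
    rate 0."""
    rows = []
    for sp in species_list:
        est = parasitism_rate(records, mode=mode, species=sp, **scope)
        rows.append(
            {
                "species": sp,
                "numerator": est.numerator,
                "denominator": est.denominator,
                "rate": est.rate,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows)


def multiparasitism_frequency(
    records: Sequence[SpecimenRecord], **scope
) -> tuple[float, pd.DataFrame]:
    """Fraction of scoped specimens carrying >= 2 distinct parasitoid
    taxa, plus per-pair co-detection frequencies."""
    scoped = _scoped(records, **scope)
    if not scoped:
        raise ValueError("scope selects no records")
    n = len(scoped)
    multi = [r for r in scoped if len(r.detected_taxa) >= 2]
    pair_counts: dict[tuple[str, str], int] = {}
    for r in multi:
        for pair in combinations(sorted(r.detected_taxa), 2):
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
    pairs = pd.DataFrame(
        [
            {"species_a": a, "species_b": b, "frequency": c / n}
            for (a, b), c in sorted(pair_counts.items())
        ],
        columns=["species_a", "species_b", "frequency"],
    )
    return len(multi) / n, pairs


# ---------------------------------------------------------------------------
# stage-wise proportions
# ---------------------------------------------------------------------------

def stage_proportions(
    filtered: CountMatrix,
    detections: DetectionMatrix,
    species: str,
    host_taxon: str,
    taxon_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per developmental stage, among consensus-positive specimens of
    ``species``: mean and SD of the per-specimen parasitoid read
    proportion (technical replicates averaged) and the number of
    positives.  Stages without positives are reported with NaN
    (no-data marker)."""
    from .calibration import observed_proportion

    meta = filtered.sample_meta
    spec_meta = meta[meta["role"] == "specimen"]
    rows = []
    for stage, stage_meta in spec_meta.groupby("stage"):
        props = []
        for bio, cols in stage_meta.groupby("biological_id").groups.items():
            if (
                bio not in detections.calls.index
                or species not in detections.calls.columns
                or not detections.calls.loc[bio, species]
            ):
                continue
            reps = [
                observed_proportion(filtered, c, host_taxon, species, taxon_of)
                for c in cols
            ]
            reps = [p for p in reps if p is not None]
            if reps:
                props.append(float(np.mean(reps)))
        rows.append(
            {
                "stage": stage,
                "n_positive": len(props),
                "mean_proportion": float(np.mean(props)) if props else np.nan,
                "sd_proportion": float(np.std(props, ddof=1))
                if len(props) > 1
                else (0.0 if props else np.nan),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistical comparisons
# ---------------------------------------------------------------------------

def compare_rates(*groups: Sequence[float]) -> TestResult:
    """One-way ANOVA across >= 2 groups of per-field rates."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    f, p = stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(a) for a in arrays) - len(arrays)
    if not np.isfinite(f):  # zero variance everywhere
        f, p = 0.0, 1.0
    return TestResult(
        statistic=float(f), df=(df_between, df_within), pvalue=float(p),
        test="one-way ANOVA",
    )


def compare_proportions(
    a: Sequence[float], b: Sequence[float], test: str = "welch"
) -> TestResult:
    """Compare two samples of per-specimen read proportions.

    ``test="welch"`` (default): unequal-variance t-test with
    Welch-Satterthwaite fractional df.  ``test="wilcoxon"``: paired
    signed-rank test (samples must be paired and equal length).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return TestResult(
            statistic=float(res.statistic),
            df=float(res.df),
            pvalue=float(res.pvalue),
            test="Welch t-test",
        )
    if test == "wilcoxon":
        if len(a) != len(b):
            raise ValueError("wilcoxon paired test needs equal-length samples")
        res = stats.wilcoxon(a, b)
        return TestResult(
            statistic=float(res.statistic),
            df=None,
            pvalue=float(res.pvalue),
            test="Wilcoxon paired rank test",
        )
    raise ValueError(f"unknown test {test!r}")
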