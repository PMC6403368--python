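"""Dilution-series sensitivity calibration.

Given a mock run (known parasitoid DNA masses mixed into a known host
mass), this module computes observed vs expected parasitoid read
proportions per technical replicate, and reduces the 2-of-3 consensus
calls over the dilution gradient to a per-species detection threshold:
the smallest parasitoid DNA mass at which the species is (and stays,
at every larger mass) reliably detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix, ReferenceDB
from .fp_filter import DetectionMatrix, apply_thresholds, compute_thresholds, consensus_call
from .synthetic_data import MockDesign, RunArtifacts, make_reference_db, simulate_mock_run

__all__ = [
    "DilutionResult",
    "DetectionThreshold",
    "modal_detection_threshold",
    "observed_proportion",
    "expected_proportion",
    "relative_abundance",
    "detection_threshold",
    "dilution_results",
    "calibration_report",
    "run_dilution_series",
]


@dataclass
class DilutionResult:
    """One (species, mass) mixture: per-replicate observed parasitoid
    read proportions and the replicate-consensus call."""

    species: str
    mass_ng: float
    host_mass_ng: float
    replicate_proportions: list[float]
    consensus_positive: bool


@dataclass
class DetectionThreshold:
    """Smallest reliably-detected parasitoid DNA mass for a species;
    fields are None when the species is never detected."""

    species: str
    threshold_mass_ng: float | None
    threshold_relative_abundance: float | None


def observed_proportion(
    filtered: CountMatrix,
    sample_replicate_id: str,
    host_taxon: str,
    parasitoid_taxon: str,
    taxon_of: Mapping[str, str] | None = None,
) -> float | None:
    """Parasitoid reads / (parasitoid + host reads) in one replicate.

    Returns 0.0 when only host reads are present and None (undefined,
    excluded from averages) when both are zero.
    """
    col = filtered.counts[sample_replicate_id]
    if taxon_of:
        taxa = col.groupby(lambda otu: taxon_of.get(otu, otu)).sum()
    else:
        taxa = col
    p = int(taxa.get(parasitoid_taxon, 0))
    h = int(taxa.get(host_taxon, 0))
    if p == 0 and h == 0:
        return None
    return p / (p + h)


def expected_proportion(mass_ng: float, host_mass_ng: float) -> float:
    """Expected parasitoid read proportion under unbiased amplification:
    mass / (mass + host_mass)."""
    if mass_ng <= 0 or host_mass_ng <= 0:
        raise ValueError("masses must be positive")
    return mass_ng / (mass_ng + host_mass_ng)


def relative_abundance(mass_ng: float, host_mass_ng: float) -> float:
    """Relative DNA abundance as conventionally reported alongside the
    threshold: mass / host_mass (0.07 ng in 56 ng -> 0.00125 ~ 0.001)."""
    if mass_ng <= 0 or host_mass_ng <= 0:
        raise ValueError("masses must be positive")
    return mass_ng / host_mass_ng


def detection_threshold(results: list[DilutionResult]) -> DetectionThreshold:
    """Reduce a species' dilution series to its detection threshold.

    The threshold is the smallest mass of the largest all-positive
    suffix of the mass-sorted series (i.e. the smallest mass that is
    positive with every larger mass also positive).  A positive call
    below a negative one (non-monotone series) triggers a warning.
    """
    if not results:
        raise ValueError("empty dilution series")
    species = {r.species for r in results}
    if len(species) > 1:
        raise ValueError(f"mixed species in dilution series: {sorted(species)}")
    ordered = sorted(results, key=lambda r: r.mass_ng)
    positives = [r.consensus_positive for r in ordered]
    if not any(positives):
        return DetectionThreshold(ordered[0].species, None, None)
    # smallest index such that everything from it upward is positive
    idx = len(positives)
    for i in range(len(positives) - 1, -1, -1):
        if not positives[i]:
            break
        idx = i
    if any(positives[:idx]):
        warnings.warn(
            f"{ordered[0].species}: non-monotone positivity over the dilution "
            "gradient; threshold taken at the largest all-positive suffix",
            stacklevel=2,
        )
    if idx == len(positives):  # only non-suffix positives exist
        return DetectionThreshold(ordered[0].species, None, None)
    r = ordered[idx]
    return DetectionThreshold(
        r.species, r.mass_ng, relative_abundance(r.mass_ng, r.host_mass_ng)
    )


def dilution_results(
    filtered: CountMatrix,
    detections: DetectionMatrix,
    host_taxon: str,
    host_mass_ng: float = float("nan"),
    taxon_of: Mapping[str, str] | None = None,
) -> dict[str, list[DilutionResult]]:
    """Assemble per-species dilution series from a filtered mock run.

    Mock columns must carry ``species`` and ``mass_ng`` metadata (as
    written by the mock simulator).  Undefined replicate proportions
    (no reads at all) are recorded as 0.
    """
    meta = filtered.sample_meta
    mock = meta[meta["role"] == "mock"]
    out: dict[str, list[DilutionResult]] = {}
    for (bio, sp, mass), cols in mock.groupby(
        ["biological_id", "species", "mass_ng"]
    ).groups.items():
        props = []
        for col in cols:
            p = observed_proportion(filtered, col, host_taxon, sp, taxon_of)
            props.append(0.0 if p is None else p)
        out.setdefault(sp, []).append(
            DilutionResult(
                species=sp,
                mass_ng=float(mass),
                host_mass_ng=host_mass_ng,
                replicate_proportions=props,
                consensus_positive=bool(detections.calls.loc[bio, sp])
                if sp in detections.calls.columns
                else False,
            )
        )
    return out


def calibration_report(
    series: dict[str, list[DilutionResult]], host_mass_ng: float
) -> pd.DataFrame:
    """Tabulate a dilution run: per species x mass, mean and SD of the
    replicate proportions, the expectation, and the consensus call;
    plus an across-species mean row per mass."""
    rows = []
    for sp, results in series.items():
        for r in sorted(results, key=lambda x: -x.mass_ng):
            props = np.array(r.replicate_proportions, dtype=float)
            rows.append(
                {
                    "species": sp,
                    "mass_ng": r.mass_ng,
                    "mean_proportion": float(props.mean()),
                    "sd_proportion": float(props.std(ddof=0)),
                    "expected_proportion": expected_proportion(
                        r.mass_ng, host_mass_ng
                    ),
                    "n_replicates": len(props),
                    "consensus_positive": r.consensus_positive,
                }
            )
    report = pd.DataFrame(rows)
    overall = (
        report.groupby("mass_ng", as_index=False)
        .agg(
            mean_proportion=("mean_proportion", "mean"),
            sd_proportion=("mean_proportion", "std"),
            expected_proportion=("expected_proportion", "first"),
            n_replicates=("n_replicates", "sum"),
            consensus_positive=("consensus_positive", "all"),
        )
        .assign(species="ALL_SPECIES_MEAN")
    )
    return pd.concat([report, overall], ignore_index=True)


def run_dilution_series(
    db: ReferenceDB | None = None,
    design: MockDesign | None = None,
    seed: int = 0,
    rate_fa: float = 0.002,
    min_positive: int = 2,
) -> tuple[dict[str, DetectionThreshold], pd.DataFrame, RunArtifacts]:
    """Simulate, filter and calibrate one dilution run end to end.

    With no ``db``, a single equal-efficiency parasitoid + host pair is
    generated.  Returns (per-species detection thresholds, calibration
    report, raw artifacts).
    """
    if db is None:
        db = make_reference_db(n_parasitoids=1, divergence=0.05, seed=seed)
    design = design or MockDesign()
    run = simulate_mock_run(db, design, seed=seed)
    thresholds = compute_thresholds(run.counts, rate_fa=rate_fa)
    filtered = apply_thresholds(run.counts, thresholds)
    detections = consensus_call(
        filtered, min_positive=min_positive, n_replicates=design.n_replicates
    )
    series = dilution_results(
        filtered, detections, db.host.species_name, design.host_mass_ng
    )
    report = calibration_report(series, design.host_mass_ng)
    out = {sp: detection_threshold(results) for sp, results in series.items()}
    return out, report, run


def modal_detection_threshold(
    n_seeds: int = 21,
    seed: int = 0,
    design: MockDesign | None = None,
    rate_fa: float = 0.002,
    min_positive: int = 2,
) -> tuple[float | None, dict]:
    """Headline calibration: repeat the single-species equal-efficiency
    dilution simulation over ``n_seeds`` seeds and return the modal
    detection-threshold mass (plus the per-threshold tally)."""
    from collections import Counter

    tally: Counter = Counter()
    for i in range(n_seeds):
        thresholds, _, _ = run_dilution_series(
            design=design, seed=seed + i, rate_fa=rate_fa, min_positive=min_positive
        )
        (th,) = thresholds.values()
        tally[th.threshold_mass_ng] += 1
    modal = tally.most_common(1)[0][0]
    return modal, dict(tally)
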