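"""Shared in-memory containers and their plain-text serialisations.

Three objects travel between pipeline stages:

* :class:`ReferenceDB` — annotated COI reference sequences (species,
  guild, relative amplification efficiency) used both to simulate reads
  and to affiliate OTUs taxonomically.
* :class:`CountMatrix` — an OTU x PCR-replicate read-count table plus
  per-column sample metadata (biological id, replicate index, role,
  developmental stage, site, field).
* :class:`RunArtifacts` — a simulated run: ground truth, counts and
  (optionally) the simulated merged reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .primers import IUPAC_SETS

__all__ = ["ReferenceRecord", "ReferenceDB", "CountMatrix", "RunArtifacts"]

GUILDS = ("host", "parasitoid", "predator", "herbivore")

#: sample_meta columns every CountMatrix carries.
META_COLUMNS = ("biological_id", "replicate_index", "role", "stage", "site", "field")

ROLES = ("specimen", "negative_control", "mock")


@dataclass
class ReferenceRecord:
    """One annotated COI reference sequence (~658 bp)."""

    species_name: str
    guild: str
    sequence: str
    amp_efficiency: float = 1.0
    #: 0-based start of the amplified region (fwd binding site) within
    #: ``sequence``; None when unknown (e.g. external FASTA without a
    #: sidecar).  Only needed for read-level simulation.
    amplicon_start: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"{self.species_name}: non-IUPAC character(s) {sorted(bad)}"
            )
        if self.guild not in GUILDS:
            raise ValueError(f"{self.species_name}: unknown guild {self.guild!r}")
        if not 0.0 <= self.amp_efficiency <= 1.0:
            raise ValueError(
                f"{self.species_name}: amp_efficiency must be in [0,1]"
            )


@dataclass
class ReferenceDB:
    """A set of reference records with unique species names."""

    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.species_name for r in self.records]
        if len(names) != len(set(names)):
            raise ValueError("duplicate species_name in ReferenceDB")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, species_name: str) -> ReferenceRecord:
        for r in self.records:
            if r.species_name == species_name:
                return r
        raise KeyError(species_name)

    def species(self, guild: str | None = None) -> list[str]:
        return [
            r.species_name for r in self.records
            if guild is None or r.guild == guild
        ]

    @property
    def host(self) -> ReferenceRecord:
        hosts = [r for r in self.records if r.guild == "host"]
        if len(hosts) != 1:
            raise ValueError(f"expected exactly 1 host record, found {len(hosts)}")
        return hosts[0]

    # ------------------------------------------------------------------
    # FASTA (+ sidecar TSV) round trip.  Header convention: >species|guild
    # ------------------------------------------------------------------
    def to_fasta(self, fasta_path, sidecar_path=None) -> None:
        records = [
            SeqRecord(Seq(r.sequence), id=f"{r.species_name}|{r.guild}",
                      description="")
            for r in self.records
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        if sidecar_path is not None:
            pd.DataFrame(
                {
                    "species_name": [r.species_name for r in self.records],
                    "amp_efficiency": [r.amp_efficiency for r in self.records],
                    "amplicon_start": [
                        -1 if r.amplicon_start is None else r.amplicon_start
                        for r in self.records
                    ],
                }
            ).to_csv(sidecar_path, sep="\t", index=False)

    @classmethod
    def from_fasta(cls, fasta_path, sidecar_path=None) -> "ReferenceDB":
        side = {}
        if sidecar_path is not None:
            df = pd.read_csv(sidecar_path, sep="\t")
            for _, row in df.iterrows():
                start = int(row["amplicon_start"])
                side[row["species_name"]] = (
                    float(row["amp_efficiency"]),
                    None if start < 0 else start,
                )
        records = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            name, _, guild = rec.id.partition("|")
            eff, start = side.get(name, (1.0, None))
            records.append(
                ReferenceRecord(name, guild or "host", str(rec.seq), eff, start)
            )
        return cls(records)


class CountMatrix:
    """OTU x PCR-replicate read counts with per-column sample metadata.

    ``counts``: DataFrame, index = OTU/taxon ids, columns =
    sample_replicate ids, non-negative integers.
    ``sample_meta``: DataFrame indexed by sample_replicate id with at
    least :data:`META_COLUMNS`; extra columns (e.g. species / mass for
    mock designs) are carried through untouched.
    """

    def __init__(self, counts: pd.DataFrame, sample_meta: pd.DataFrame):
        counts = counts.copy()
        sample_meta = sample_meta.copy()
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if not counts.to_numpy().dtype.kind in "iu":
            if not (counts.to_numpy() == counts.to_numpy().astype(int)).all():
                raise ValueError("read counts must be integers")
            counts = counts.astype(int)
        missing = set(counts.columns) - set(sample_meta.index)
        if missing:
            raise ValueError(f"sample_meta missing columns: {sorted(missing)[:5]}")
        for col in META_COLUMNS:
            if col not in sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
        bad_roles = set(sample_meta["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        self.counts = counts
        self.sample_meta = sample_meta.loc[counts.columns]

    # -- convenience views ---------------------------------------------
    def columns_with_role(self, *roles: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["role"].isin(roles)])

    @property
    def negative_control_columns(self) -> list[str]:
        return self.columns_with_role("negative_control")

    @property
    def assay_columns(self) -> list[str]:
        """Columns that carry template (specimens and mock mixtures)."""
        return self.columns_with_role("specimen", "mock")

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.sample_meta.copy())

    def equals(self, other: "CountMatrix") -> bool:
        return self.counts.equals(other.counts) and self.sample_meta.equals(
            other.sample_meta
        )

    # -- TSV round trip -------------------------------------------------
    def to_tsv(self, counts_path, meta_path) -> None:
        self.counts.rename_axis("otu_id").to_csv(counts_path, sep="\t")
        self.sample_meta.rename_axis("sample_replicate_id").to_csv(
            meta_path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts, meta)


@dataclass
class RunArtifacts:
    """Everything a simulated sequencing run produces.

    ``truth`` is one row per biological sample; for field runs it
    records the parasitism ground truth (species, tissue fractions,
    rearing outcome) that downstream parameter-recovery tests compare
    against.
    """

    truth: pd.DataFrame
    counts: CountMatrix
    reads: list | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_tsv(out / "counts.tsv", out / "sample_meta.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        if self.reads is not None:
            with open(out / "reads.fasta", "w") as fh:
                for i, (sample_id, seq) in enumerate(self.reads):
                    fh.write(f">read{i}|{sample_id}\n{seq}\n")
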