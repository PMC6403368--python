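"""Generator behaviour: reference sets, mock and field runs, error
injection, determinism."""

import numpy as np
import pytest

from maplkit import (
    FieldDesign,
    LogNormalFractions,
    MockDesign,
    inject_cross_contamination,
    inject_index_hopping,
    make_reference_db,
    simulate_field_run,
    simulate_mock_run,
)
from conftest import levenshtein


def _insert(record):
    start = record.amplicon_start + 25
    return record.sequence[start : start + 133]


class TestMakeReferenceDB:
    def test_species_count_and_cryptic_pair_identity(self):
        db = make_reference_db(n_parasitoids=10, cryptic_pair=True, seed=1)
        assert len(db) == 11
        inserts = {r.species_name: _insert(r) for r in db}
        names = sorted(inserts)
        cryptic = {"Parasitoid_09", "Parasitoid_10"}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                dist = levenshtein(inserts[a], inserts[b])
                if {a, b} == cryptic:
                    assert 1 <= dist <= 3  # distinct but nearly identical
                else:
                    assert 1 - dist / 133 < 0.99

    def test_primer_mismatch_species_has_zero_efficiency(self):
        db = make_reference_db(n_parasitoids=2, primer_mismatch=True, seed=3)
        assert db["Parasitoid_01"].amp_efficiency == 0.0
        assert db["Parasitoid_02"].amp_efficiency == 1.0
        assert db.host.amp_efficiency == 1.0

    def test_host_parasitoid_separability_by_alignment(self):
        db = make_reference_db(n_parasitoids=1, divergence=0.05, seed=7)
        identity = 1 - levenshtein(_insert(db.host), _insert(db["Parasitoid_01"])) / 133
        assert identity < 0.99

    def test_low_divergence_rejected(self):
        with pytest.raises(ValueError):
            make_reference_db(n_parasitoids=1, divergence=0.01, seed=0)

    def test_too_many_species_rejected(self):
        with pytest.raises(ValueError):
            make_reference_db(n_parasitoids=30, divergence=0.2, seed=0)

    def test_fasta_roundtrip(self, tmp_path, small_db):
        small_db.to_fasta(tmp_path / "db.fasta", tmp_path / "db.tsv")
        from maplkit import ReferenceDB

        back = ReferenceDB.from_fasta(tmp_path / "db.fasta", tmp_path / "db.tsv")
        assert [r.species_name for r in back] == [r.species_name for r in small_db]
        assert all(
            a.sequence == b.sequence and a.guild == b.guild
            and a.amp_efficiency == b.amp_efficiency
            for a, b in zip(back, small_db)
        )


class TestSimulateMockRun:
    def test_expected_proportion_equal_efficiencies(self, small_db):
        design = MockDesign(
            parasitoid_masses_ng=(7.0,), n_replicates=60,
            species=("Parasitoid_01",),
        )
        run = simulate_mock_run(small_db, design, seed=2)
        counts = run.counts.counts
        cols = run.counts.assay_columns
        prop = counts.loc["Parasitoid_01", cols].sum() / counts[cols].sum().sum()
        expected = 7 / 63
        se = np.sqrt(expected * (1 - expected) / counts[cols].sum().sum())
        assert abs(prop - expected) < 3 * se

    def test_zero_efficiency_species_yields_zero_reads(self):
        db = make_reference_db(n_parasitoids=2, primer_mismatch=True, seed=3)
        run = simulate_mock_run(db, MockDesign(), seed=4)
        mask = run.counts.sample_meta["species"] == "Parasitoid_01"
        cols = run.counts.sample_meta.index[mask]
        assert run.counts.counts.loc["Parasitoid_01", cols].sum() == 0
        # its columns are pure host reads
        assert (run.counts.counts.loc["Host_moth", cols] > 0).all()

    def test_mean_reads_at_low_mass_matches_binomial_expectation(self, small_db):
        # 0.07 ng in 56 ng at 8000 reads -> mean ~ 8000 * 0.07/56.07
        design = MockDesign(
            parasitoid_masses_ng=(0.07,), n_replicates=400,
            species=("Parasitoid_01",),
        )
        run = simulate_mock_run(small_db, design, seed=6)
        cols = run.counts.assay_columns
        observed = run.counts.counts.loc["Parasitoid_01", cols]
        expected = 8000 * 0.07 / 56.07
        se = np.sqrt(expected / len(cols))  # ~Poisson counts
        assert abs(observed.mean() - expected) < 4 * se

    def test_unknown_species_rejected(self, small_db):
        with pytest.raises(ValueError):
            simulate_mock_run(
                small_db, MockDesign(species=("Nessie",)), seed=0
            )

    def test_negative_controls_have_zero_template(self, small_db):
        run = simulate_mock_run(small_db, MockDesign(), seed=0)
        nc = run.counts.negative_control_columns
        assert len(nc) == 10
        assert run.counts.counts[nc].to_numpy().sum() == 0

    def test_determinism(self, small_db):
        a = simulate_mock_run(small_db, MockDesign(), seed=9)
        b = simulate_mock_run(small_db, MockDesign(), seed=9)
        assert a.counts.equals(b.counts) and a.truth.equals(b.truth)


class TestSimulateFieldRun:
    def _design(self, db, p=0.5, **kw):
        prevalence = {
            (sp, stage, site): p
            for sp in db.species("parasitoid")[:1]
            for stage in ("egg", "early_larva", "late_larva")
            for site in ("Bambey", "Nioro")
        }
        return FieldDesign(prevalence=prevalence, **kw)

    def test_zero_prevalence_means_host_only(self, small_db):
        design = self._design(small_db, p=0.0, reads_per_sample=500)
        run = simulate_field_run(small_db, design, seed=1)
        cols = run.counts.assay_columns
        parasitoid_rows = small_db.species("parasitoid")
        assert run.counts.counts.loc[parasitoid_rows, cols].to_numpy().sum() == 0
        assert (run.truth["n_species"] == 0).all()

    def test_realised_prevalence_within_binomial_ci(self, small_db):
        design = self._design(small_db, p=0.5, reads_per_sample=200,
                              multiparasitism_rate=0.0)
        run = simulate_field_run(small_db, design, seed=42)
        n = len(run.truth)
        assert n == 400
        k = (run.truth["species"].str.contains("Parasitoid_01")).sum()
        half_width = 2.576 * np.sqrt(0.25 / n)
        assert abs(k / n - 0.5) < half_width

    def test_tissue_fraction_mean_near_point_six_percent(self, small_db):
        design = self._design(small_db, p=1.0, reads_per_sample=200,
                              multiparasitism_rate=0.0)
        run = simulate_field_run(small_db, design, seed=7)
        fractions = [
            float(x)
            for s in run.truth["tissue_fractions"]
            if s
            for x in s.split(";")
        ]
        assert len(fractions) == 400
        assert np.mean(fractions) == pytest.approx(0.006, abs=0.001)
        assert all(0 < f < 0.5 for f in fractions)

    def test_dead_specimens_mask_rearing_detection(self, small_db):
        design = self._design(small_db, p=1.0, reads_per_sample=100)
        run = simulate_field_run(small_db, design, seed=3)
        dead = run.truth[run.truth["rearing_outcome"] == "dead"]
        assert len(dead) > 0
        assert not dead["rearing_outcome"].str.contains("emerged").any()
        alive_parasitised = run.truth[
            (run.truth["n_species"] > 0)
            & (run.truth["rearing_outcome"] != "dead")
        ]
        assert alive_parasitised["rearing_outcome"].str.startswith(
            "parasitoid_emerged:"
        ).all()

    def test_unknown_species_in_prevalence_rejected(self, small_db):
        with pytest.raises(ValueError):
            simulate_field_run(
                small_db,
                FieldDesign(prevalence={("Nessie", "egg", "Bambey"): 0.1}),
                seed=0,
            )

    def test_determinism(self, small_db):
        design = self._design(small_db, p=0.3, reads_per_sample=100)
        a = simulate_field_run(small_db, design, seed=11)
        b = simulate_field_run(small_db, design, seed=11)
        assert a.counts.equals(b.counts) and a.truth.equals(b.truth)


class TestInjectCrossContamination:
    def test_rate_zero_is_identity(self, small_db):
        run = simulate_mock_run(small_db, MockDesign(), seed=1)
        assert inject_cross_contamination(run.counts, 0.0, seed=1).equals(run.counts)

    def test_counts_never_decrease_and_controls_gain_reads(self, small_db):
        run = simulate_mock_run(small_db, MockDesign(), seed=1)
        out = inject_cross_contamination(run.counts, 0.01, seed=2)
        assert (out.counts.to_numpy() >= run.counts.counts.to_numpy()).all()
        assert out.counts[out.negative_control_columns].to_numpy().sum() > 0

    def test_stray_read_mean_matches_poisson_arithmetic(self):
        # one OTU at 80% run abundance, depth 8000, rate 0.001 -> lambda 6.4
        from conftest import toy_count_matrix

        cols = {f"S{i}|R1": [6400, 1600] for i in range(1, 101)}
        cols.update({f"NC{i:02d}|R1": [0, 0] for i in range(1, 101)})
        cm = toy_count_matrix(cols, ["otuA", "otuB"])
        out = inject_cross_contamination(cm, 0.001, seed=5)
        stray = out.counts.loc["otuA", out.negative_control_columns]
        lam = 0.001 * 4000 * 0.8  # run-mean depth is 4000 (half the columns empty)
        assert stray.mean() == pytest.approx(lam, abs=3 * np.sqrt(lam / 100))

    def test_negative_rate_rejected(self, small_db):
        run = simulate_mock_run(small_db, MockDesign(), seed=1)
        with pytest.raises(ValueError):
            inject_cross_contamination(run.counts, -0.1, seed=0)


class TestInjectIndexHopping:
    def test_rate_zero_is_identity(self, small_db):
        run = simulate_mock_run(small_db, MockDesign(), seed=1)
        assert inject_index_hopping(run.counts, 0.0, seed=1).equals(run.counts)

    def test_per_otu_totals_conserved(self, small_db):
        run = simulate_mock_run(small_db, MockDesign(), seed=1)
        out = inject_index_hopping(run.counts, 0.002, seed=2)
        assert (
            out.counts.sum(axis=1).to_numpy()
            == run.counts.counts.sum(axis=1).to_numpy()
        ).all()

    def test_expected_hopped_reads(self):
        # 10,000 reads in one source column, rate 0.002 -> ~20 hops
        from conftest import toy_count_matrix

        moved = []
        for seed in range(40):
            cols = {"SRC|R1": [10000]}
            cols.update({f"S{i}|R1": [0] for i in range(99)})
            cm = toy_count_matrix(cols, ["otuA"])
            out = inject_index_hopping(cm, 0.002, seed=seed)
            moved.append(10000 - int(out.counts.loc["otuA", "SRC|R1"]))
        # hops land back in the source 1% of the time -> expect 20 * 0.99
        assert np.mean(moved) == pytest.approx(19.8, abs=3 * np.sqrt(19.8 / 40))

    def test_bad_rate_rejected(self, small_db):
        run = simulate_mock_run(small_db, MockDesign(), seed=1)
        for rate in (-0.1, 1.5):
            with pytest.raises(ValueError):
                inject_index_hopping(run.counts, rate, seed=0)


def test_truncated_lognormal_respects_bounds(rng):
    dist = LogNormalFractions(mu=-5.267, sigma=0.55, lower=0.001, upper=0.5)
    draws = [dist.draw(rng) for _ in range(500)]
    assert all(0.001 < x < 0.5 for x in draws)
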