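"""Simulator calibration against closed-form coalescent expectations,
determinism, event semantics, degradation and VCF round-tripping."""

import numpy as np
import pytest

from introflow import coalsim, genotypes

MU = 1e-8
NE = 10_000.0


def single_deme(ne=NE, mu=MU):
    return coalsim.DemographicModel(demes={"X": ne}, mutation_rate=mu)


class TestNeutralCalibration:
    def test_pairwise_coalescence_time_is_2ne(self):
        model = single_deme()
        t2 = np.array([nt.max() for _, nt, _ in
                       coalsim.simulate_trees(model, {"X": 1}, 2000, seed=1)])
        se = t2.std(ddof=1) / np.sqrt(len(t2))
        assert abs(t2.mean() - 2 * NE) <= 3 * se

    def test_pairwise_diversity_is_theta(self):
        model = single_deme()
        ds = coalsim.simulate(model, {"X": 2}, n_loci=2000, locus_length=1000, seed=2)
        # per-locus pi for an MC standard error
        theta = 4 * NE * MU
        pi = ds.mean_pairwise_diversity()
        # SE of mean pi over loci: approximate from per-site variance of S
        n_hap = 4
        a1 = sum(1.0 / i for i in range(1, n_hap))
        s_per_locus = np.array([
            ((ds.site_contig == c).sum()) for c in ds.contigs
        ])
        se = theta / np.sqrt(2000) * 2  # conservative MC bound
        assert abs(pi - theta) <= 3 * max(se, 1e-5)

    def test_segregating_sites_follow_watterson(self):
        model = single_deme()
        n_dip, loci, L = 3, 2000, 1000
        ds = coalsim.simulate(model, {"X": n_dip}, n_loci=loci, locus_length=L, seed=3)
        a1 = sum(1.0 / i for i in range(1, 2 * n_dip))
        expected = 4 * NE * MU * a1 * L * loci
        # S is approximately Poisson-dispersed plus genealogy variance; use
        # a generous 3-sigma bound from the observed spread across contigs
        assert ds.n_sites == pytest.approx(expected, rel=0.10)

    def test_two_deme_dxy_matches_2mu_t_plus_2ne(self):
        t_split = 30_000.0
        model = coalsim.DemographicModel(
            demes={"A": NE, "B": NE},
            events=[coalsim.Split(t_split, child="B", parent="A")],
            mutation_rate=MU,
        )
        ds = coalsim.simulate(model, {"A": 1, "B": 1}, n_loci=2000,
                              locus_length=1000, seed=4)
        h = ds.haplotypes
        # mean differences between one haplotype from each deme
        diff = (h[0] != h[2]).sum() + (h[1] != h[3]).sum()
        dxy = diff / 2 / sum(ds.contigs.values())
        expected = 2 * MU * (t_split + 2 * NE)
        assert dxy == pytest.approx(expected, rel=0.10)


class TestDeterminismAndStreams:
    def test_identical_seed_gives_identical_dataset(self):
        model = coalsim.scenario_preset("pair_IM_constant")
        a = coalsim.simulate(model, {"A": 2, "B": 2}, n_loci=30, seed=9)
        b = coalsim.simulate(model, {"A": 2, "B": 2}, n_loci=30, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_zero_proportion_pulse_is_a_null_event(self):
        """A phi=0 pulse leaves the genealogy distribution unchanged (the
        event truncates waiting-time draws, which is distribution-neutral
        by memorylessness; pulse decisions use a separate stream)."""
        base = coalsim.DemographicModel(
            demes={"A": NE, "B": NE},
            events=[coalsim.Split(20_000.0, child="B", parent="A")],
            mutation_rate=MU,
        )
        with_null_pulse = coalsim.DemographicModel(
            demes={"A": NE, "B": NE},
            events=[coalsim.Pulse(1000.0, source="A", dest="B", proportion=0.0),
                    coalsim.Split(20_000.0, child="B", parent="A")],
            mutation_rate=MU,
        )
        n_loci = 1500
        tm_a = np.array([nt.max() for _, nt, _ in
                         coalsim.simulate_trees(base, {"A": 2, "B": 2}, n_loci, seed=5)])
        tm_b = np.array([nt.max() for _, nt, _ in
                         coalsim.simulate_trees(with_null_pulse, {"A": 2, "B": 2},
                                                n_loci, seed=5)])
        se = np.hypot(tm_a.std(ddof=1), tm_b.std(ddof=1)) / np.sqrt(n_loci)
        assert abs(tm_a.mean() - tm_b.mean()) <= 3 * se
        # no lineage was actually moved
        ds = coalsim.simulate(with_null_pulse, {"A": 2, "B": 2}, n_loci=20, seed=5)
        assert all(rec["n_moved"] == 0 for rec in ds.truth["pulses"])

    def test_full_replacement_pulse_moves_every_lineage(self):
        model = coalsim.DemographicModel(
            demes={"A": NE, "B": NE},
            events=[coalsim.Pulse(100.0, source="A", dest="B", proportion=1.0),
                    coalsim.Split(20_000.0, child="B", parent="A")],
            mutation_rate=MU,
        )
        ds = coalsim.simulate(model, {"A": 1, "B": 3}, n_loci=10, seed=6)
        for rec in ds.truth["pulses"]:
            assert rec["n_moved"] == rec["n_in_dest"]


class TestModelValidation:
    def test_isolated_deme_raises_structural_error(self):
        model = coalsim.DemographicModel(
            demes={"A": NE, "B": NE},
            events=[coalsim.Split(1000.0, child="B", parent="A")],
            mutation_rate=MU,
        )
        # sabotage: make B unreachable by removing the split
        model.events = []
        with pytest.raises(coalsim.ModelError, match="isolated"):
            list(coalsim.simulate_trees(model, {"A": 1, "B": 1}, 1, seed=0))

    def test_two_roots_rejected(self):
        with pytest.raises(coalsim.ModelError, match="root"):
            coalsim.DemographicModel(demes={"A": NE, "B": NE}, mutation_rate=MU)

    def test_event_times_must_increase(self):
        with pytest.raises(coalsim.ModelError, match="increasing"):
            coalsim.DemographicModel(
                demes={"A": NE, "B": NE},
                events=[coalsim.Pulse(500.0, "A", "B", 0.1),
                        coalsim.Pulse(500.0, "B", "A", 0.1),
                        coalsim.Split(1000.0, "B", "A")],
                mutation_rate=MU,
            )

    def test_bad_pulse_proportion_rejected(self):
        with pytest.raises(coalsim.ModelError, match="proportion"):
            coalsim.DemographicModel(
                demes={"A": NE, "B": NE},
                events=[coalsim.Pulse(10.0, "A", "B", 1.5),
                        coalsim.Split(1000.0, "B", "A")],
                mutation_rate=MU,
            )


class TestPresets:
    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="study_null"):
            coalsim.scenario_preset("nope")

    def test_study_null_has_no_pulse(self):
        model = coalsim.scenario_preset("study_null")
        assert not any(isinstance(e, coalsim.Pulse) for e in model.events)
        splits = [e for e in model.events if isinstance(e, coalsim.Split)]
        # all four ingroup demes merge before the outgroup join
        assert splits[-1].parent == "J"
        assert max(s.time for s in splits[:-1]) < splits[-1].time

    def test_study_pulse_has_unidirectional_hs_to_tpe_pulse(self):
        model = coalsim.scenario_preset("study_pulse", phi=0.25)
        pulses = [e for e in model.events if isinstance(e, coalsim.Pulse)]
        assert len(pulses) == 1
        assert (pulses[0].source, pulses[0].dest) == ("HS", "TP_E")
        assert pulses[0].proportion == 0.25

    def test_constant_migration_spans_whole_history(self):
        model = coalsim.scenario_preset("pair_IM_constant")
        assert model.migration[("A", "B")] > 0
        assert not any(isinstance(e, coalsim.MigrationChange) for e in model.events)

    def test_early_and_recent_epochs_partition_the_interval(self):
        early = coalsim.scenario_preset("pair_IM_early")
        recent = coalsim.scenario_preset("pair_IM_recent")
        t_split = next(e.time for e in early.events if isinstance(e, coalsim.Split))
        e_change = next(e for e in early.events if isinstance(e, coalsim.MigrationChange))
        r_change = next(e for e in recent.events if isinstance(e, coalsim.MigrationChange))
        # same boundary; early is off then on, recent is on then off
        assert e_change.time == r_change.time < t_split
        assert not early.migration and early.migration != recent.migration
        assert recent.migration[("A", "B")] > 0
        assert dict(e_change.rates) and not dict(r_change.rates)


class TestDegrade:
    def test_zero_rate_is_identity_on_genotypes(self, study_pulse_dataset):
        ds = coalsim.degrade(study_pulse_dataset, 0.0, 60.0, seed=1)
        assert np.array_equal(ds.genotypes(), study_pulse_dataset.genotypes())

    def test_masked_fraction_within_binomial_interval(self):
        model = single_deme()
        ds = coalsim.simulate(model, {"X": 5}, n_loci=2200, locus_length=1000, seed=7)
        n_calls = ds.n_samples * ds.n_sites
        assert n_calls >= 10_000
        deg = coalsim.degrade(ds, 0.5, 60.0, seed=8)
        frac = deg.missing.mean()
        half_width = 2.576 * np.sqrt(0.25 / n_calls)
        assert abs(frac - 0.5) <= half_width

    def test_constant_qual_applies_everywhere(self, study_pulse_dataset):
        ds = coalsim.degrade(study_pulse_dataset, 0.1, 60.0, seed=2)
        assert np.all(ds.qual == 60.0)

    def test_rate_out_of_range_rejected(self, study_pulse_dataset):
        with pytest.raises(ValueError):
            coalsim.degrade(study_pulse_dataset, 1.0, 60.0, seed=0)


class TestVcfRoundTrip:
    def test_write_then_read_preserves_genotypes(self, tmp_path, study_pulse_dataset):
        ds = coalsim.degrade(study_pulse_dataset, 0.2, 55.0, seed=3)
        vcf, pop = tmp_path / "x.vcf", tmp_path / "x.pop"
        coalsim.write_vcf(ds, vcf, pop)
        gm = genotypes.read_vcf(vcf, pop)
        assert np.array_equal(gm.calls, ds.genotypes())
        assert np.array_equal(gm.positions, ds.positions)
        assert np.all(gm.qual == 55.0)
        assert gm.sample_pops == ds.sample_pops

    def test_missing_genotype_written_as_dot_slash_dot(self, tmp_path, study_pulse_dataset):
        ds = coalsim.degrade(study_pulse_dataset, 0.3, 60.0, seed=4)
        vcf, pop = tmp_path / "m.vcf", tmp_path / "m.pop"
        coalsim.write_vcf(ds, vcf, pop)
        assert "./." in vcf.read_text()

    def test_study_layout_has_19_contig_header_lines(self, tmp_path, study_pulse_dataset):
        vcf, pop = tmp_path / "c.vcf", tmp_path / "c.pop"
        coalsim.write_vcf(study_pulse_dataset, vcf, pop)
        lines = [l for l in vcf.read_text().splitlines() if l.startswith("##contig")]
        assert len(lines) == 19


@pytest.mark.parametrize("n_dip", [2, 4])
def test_derived_counts_stay_polymorphic(n_dip):
    """Infinite-sites output never contains monomorphic columns."""
    ds = coalsim.simulate(single_deme(), {"X": n_dip}, n_loci=200,
                          locus_length=500, seed=13)
    counts = ds.haplotypes.sum(axis=0)
    assert counts.min() >= 1
    assert counts.max() <= 2 * n_dip - 1
    for c in ds.contigs:
        pos = ds.positions[ds.site_contig == c]
        assert np.all(np.diff(pos) > 0)


def test_cross_check_against_msprime_single_and_split():
    """Summary statistics match an independent coalescent engine."""
    msprime = pytest.importorskip("msprime")
    n_loci, L = 800, 2000
    # one deme, 3 diploids
    ds = coalsim.simulate(single_deme(), {"X": 3}, n_loci=n_loci,
                          locus_length=L, seed=21)
    s_mine = ds.n_sites / n_loci
    s_ref = []
    for i, rep in enumerate(msprime.sim_ancestry(
            samples=3, population_size=NE, sequence_length=L,
            num_replicates=n_loci, random_seed=7)):
        mts = msprime.sim_mutations(rep, rate=MU, random_seed=i + 1)
        s_ref.append(mts.num_sites)
    s_ref = np.array(s_ref, dtype=float)
    se = s_ref.std(ddof=1) / np.sqrt(n_loci) * np.sqrt(2)  # both sides noisy
    assert abs(s_mine - s_ref.mean()) <= 3 * max(se, 0.05)
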