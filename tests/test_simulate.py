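import filecmp
import json

import numpy as np
import pytest

from spliceratio.io import read_cohort_table, read_gtf_exons, read_star_junctions
from spliceratio.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_cohort,
    simulate_gene_models,
    simulate_isoform_expression,
    simulate_junction_counts,
)


class TestGeneModels:
    def test_requested_event_counts(self):
        config = SimulationConfig(events_per_type={"CA": 10}, n_planted=0, seed=1)
        annotation, planted = simulate_gene_models(config)
        assert len(planted) == 10
        assert all(g.event_type == "CA" for g in planted)
        # each cassette gene annotates a skippable middle exon in one isoform
        for gene in planted:
            incl = {((e.exon_start, e.exon_end)) for e in gene.exons
                    if e.transcript_id == gene.inclusion_isoform}
            skip = {((e.exon_start, e.exon_end)) for e in gene.exons
                    if e.transcript_id == gene.skipping_isoform}
            assert len(incl - skip) == 1

    def test_annotation_roundtrips_through_gtf(self, tmp_path):
        from spliceratio.io import write_gtf_exons

        config = SimulationConfig(
            events_per_type={"CA": 3, "MXE": 3}, n_planted=0, seed=1
        )
        annotation, _ = simulate_gene_models(config)
        write_gtf_exons(annotation, tmp_path / "a.gtf")
        assert read_gtf_exons(tmp_path / "a.gtf") == annotation

    def test_deterministic_layout(self):
        config = SimulationConfig(events_per_type={"A5SS": 5}, n_planted=0, seed=9)
        assert simulate_gene_models(config) == simulate_gene_models(config)


class TestJunctionCounts:
    def test_same_seed_byte_identical_files(self, tmp_path):
        config = SimulationConfig(events_per_type={"CA": 20}, n_planted=5, seed=4)
        _, planted = simulate_gene_models(config)
        for d in ("a", "b"):
            simulate_junction_counts(
                planted, config, np.random.default_rng(config.seed),
                out_dir=tmp_path / d,
            )
        for f in (tmp_path / "a").iterdir():
            assert filecmp.cmp(f, tmp_path / "b" / f.name, shallow=False)

    def test_inclusion_fraction_tracks_psi_at_high_depth(self):
        config = SimulationConfig(
            events_per_type={"CA": 200}, n_planted=0, depth=10_000, seed=6
        )
        _, planted = simulate_gene_models(config)
        sim = simulate_junction_counts(planted, config)
        sample = sim.control_ids[0]
        devs = []
        for i, gene in enumerate(planted):
            inc = sim.counts[sample][gene.inclusion_key]
            skip = sim.counts[sample][gene.skipping_key]
            psi = sim.psi.loc[gene.event_id, sample]
            # NB noise: 3 standard errors of the observed inclusion fraction
            se = np.sqrt(
                psi * (1 - psi) / config.depth
                + 2 * config.dispersion * psi**2 * (1 - psi) ** 2
            )
            devs.append(abs(inc / (inc + skip) - psi) <= 3 * se + 3 / config.depth)
        assert np.mean(devs) > 0.95

    def test_truth_ids_subset_of_generated_events(self):
        config = SimulationConfig(events_per_type={"CA": 30}, n_planted=10, seed=2)
        _, planted = simulate_gene_models(config)
        sim = simulate_junction_counts(planted, config)
        assert set(sim.truth.differential) <= {g.event_id for g in planted}
        assert len(sim.truth.differential) == 10

    def test_generated_files_parse_cleanly(self, tmp_path):
        config = SimulationConfig(events_per_type={"CA": 10, "MXE": 5},
                                  n_planted=3, seed=11)
        _, planted = simulate_gene_models(config)
        sim = simulate_junction_counts(
            planted, config, np.random.default_rng(config.seed), out_dir=tmp_path
        )
        for sample in sim.treatment_ids + sim.control_ids:
            records = read_star_junctions(tmp_path / f"{sample}.SJ.out.tab", sample)
            assert {r.key for r in records} == set(sim.counts[sample])


class TestIsoformExpression:
    def test_expression_proportional_to_psi(self):
        config = SimulationConfig(
            events_per_type={"CA": 300}, n_planted=0, seed=13,
            isoform_noise_sigma=0.05,
        )
        _, planted = simulate_gene_models(config)
        sim = simulate_junction_counts(planted, config)
        expr = simulate_isoform_expression(planted, sim, config)
        sample = sim.control_ids[0]
        ratios = []
        for gene in planted:
            psi = sim.psi.loc[gene.event_id, sample]
            inc = expr[sample][gene.inclusion_isoform]
            skip = expr[sample][gene.skipping_isoform]
            ratios.append((inc / (inc + skip)) - psi)
        assert abs(np.mean(ratios)) < 0.02  # centred on the planted PSI

    def test_planted_events_show_larger_expression_shifts(self):
        config = SimulationConfig(events_per_type={"CA": 300}, n_planted=60, seed=14)
        _, planted = simulate_gene_models(config)
        sim = simulate_junction_counts(planted, config)
        expr = simulate_isoform_expression(planted, sim, config)

        def shift(gene):
            dt = np.mean([expr[s][gene.inclusion_isoform] for s in sim.treatment_ids])
            dc = np.mean([expr[s][gene.inclusion_isoform] for s in sim.control_ids])
            return abs(dt - dc)

        planted_ids = set(sim.truth.differential)
        planted_shift = np.mean([shift(g) for g in planted if g.event_id in planted_ids])
        null_shift = np.mean([shift(g) for g in planted if g.event_id not in planted_ids])
        assert planted_shift > 2 * null_shift


class TestCohortSimulation:
    def test_occurrence_frequency_within_three_se(self):
        config = SimulationConfig(cohort_size=500, n_assoc_planted=0,
                                  n_hr_planted=0, seed=5)
        cohort, _ = simulate_cohort(config)
        f = config.ase_frequency
        se = np.sqrt(f * (1 - f) / 500)
        freqs = cohort[[c for c in cohort.columns if c.startswith("ASE_")]].mean()
        assert (abs(freqs - f) < 3 * se + 0.01).mean() > 0.9

    def test_null_hazard_ratio_centres_on_one(self):
        from spliceratio.cohort import survival_association

        estimates = []
        for seed in range(5):
            config = SimulationConfig(cohort_size=400, n_assoc_planted=0,
                                      n_hr_planted=0, seed=seed)
            cohort, _ = simulate_cohort(config)
            res = survival_association(
                cohort["ASE_001"], cohort["time"], cohort["event"]
            )
            estimates.append(np.log(res.hazard_ratio))
        assert abs(np.mean(estimates)) < 0.15

    def test_same_seed_identical_cohort(self):
        config = SimulationConfig(seed=31)
        a, _ = simulate_cohort(config)
        b, _ = simulate_cohort(config)
        assert a.equals(b)


class TestFullBundle:
    def test_simulate_all_emits_valid_inputs(self, tmp_path):
        config = SimulationConfig(
            events_per_type={"CA": 20}, n_planted=5, n_ases=10,
            n_proteins=40, n_binders=4, cohort_size=50, seed=19,
        )
        truth = simulate_all(config, tmp_path)
        assert (tmp_path / "annotation.gtf").exists()
        assert len(read_gtf_exons(tmp_path / "annotation.gtf")) > 0
        cohort = read_cohort_table(tmp_path / "cohort.tsv")
        assert len(cohort) == 50
        saved = json.loads((tmp_path / "truth.json").read_text())
        assert sorted(saved["differential"]) == sorted(truth.differential)
        assert saved["binders"] == truth.binders
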