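import numpy as np
import pytest

from proximatome import enrichment, timecourse
from proximatome.errors import ConfigError
from proximatome.synthetic import (
    SimulationConfig,
    simulate_dataset,
    simulate_peptides,
    simulate_qpcr_plate,
    simulate_timecourse_dataset,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(class_fractions=(0.5, 0.5, 0.5)),
            dict(class_fractions=(1.2, -0.1, -0.1)),
            dict(baseline_mean=0),
            dict(nb_dispersion=-1),
            dict(effect_fc_stable=0),
            dict(mito_fraction_among_flux=1.5),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestSimulateDataset:
    def test_same_seed_bit_identical(self):
        config = SimulationConfig(n_proteins=50, seed=42)
        m1, d1, a1, t1 = simulate_dataset(config)
        m2, d2, a2, t2 = simulate_dataset(config)
        assert m1.counts.tolist() == m2.counts.tolist()
        assert t1.equals(t2)
        assert a1 == a2

    def test_different_seeds_differ(self):
        m1 = simulate_dataset(SimulationConfig(n_proteins=50, seed=1))[0]
        m2 = simulate_dataset(SimulationConfig(n_proteins=50, seed=2))[0]
        assert m1.counts.tolist() != m2.counts.tolist()

    def test_all_background_has_fc_near_one(self):
        """class_fractions (1,0,0): the empirical FC is unbiased, i.e. the
        mean log2 FC over 1000 proteins is within 0.2 of zero (per-protein
        |log2 FC| is a noise property, ~0.38 at baseline 10, and is checked
        only for lack of bias here)."""
        config = SimulationConfig(
            n_proteins=1000, class_fractions=(1.0, 0.0, 0.0), seed=3
        )
        matrix, design, _, _ = simulate_dataset(config)
        fc = enrichment.compute_fold_change(matrix, design)
        assert abs(fc["log2_fc"].mean()) < 0.2

    def test_control_marginal_matches_baseline(self):
        """Empirical control mean within 5% of baseline_mean for >= 3000 draws."""
        config = SimulationConfig(n_proteins=1000, seed=4)
        matrix, design, _, _ = simulate_dataset(config)
        ctrl = matrix.columns(design.control_ids())
        assert ctrl.size >= 3000
        assert abs(ctrl.mean() - config.baseline_mean) / config.baseline_mean < 0.05

    def test_poisson_limit_reduces_variance(self):
        config = SimulationConfig(
            n_proteins=2000, nb_dispersion=float("inf"), seed=5,
            class_fractions=(1.0, 0.0, 0.0),
        )
        matrix, design, _, _ = simulate_dataset(config)
        ctrl = matrix.columns(design.control_ids()).ravel()
        # Poisson: variance ~ mean; NB default would give ~2x mean
        assert ctrl.var() / ctrl.mean() < 1.3

    def test_ground_truth_consistent_with_annotations(self):
        _, _, annotations, truth = simulate_dataset(SimulationConfig(n_proteins=80, seed=6))
        by_id = {a.protein_id: a for a in annotations}
        for _, row in truth.iterrows():
            ann = by_id[row["protein_id"]]
            assert ann.length_aa == row["length_aa"]
            assert ann.is_mitochondrial == row["is_mitochondrial"]
            assert (ann.mts_interval is not None) == bool(row["is_mitochondrial"])


class TestSimulateTimecourse:
    def test_planted_ratio_classes_straddle_boundary(self):
        _, _, _, truth = simulate_timecourse_dataset(
            SimulationConfig(n_proteins=2000, seed=7,
                             class_fractions=(0.0, 0.5, 0.5))
        )
        stable = truth[truth["true_class"] == "stable_interactor"]["true_ratio"]
        flux = truth[truth["true_class"] == "transient_flux"]["true_ratio"]
        assert (stable < 0.5).mean() > 0.95
        assert (flux >= 0.5).mean() > 0.95

    def test_all_flux_mito_gives_pure_group2_share(self):
        config = SimulationConfig(
            n_proteins=300, seed=8, mito_fraction_among_flux=1.0,
            mito_fraction_among_stable=0.0,
        )
        (early, d_early), (late, d_late), ann, truth = \
            simulate_timecourse_dataset(config)
        rec_early = enrichment.build_records(early, d_early)
        rec_late = enrichment.build_records(late, d_late)
        paired, _, _ = timecourse.pair_timepoints(rec_early, rec_late)
        classified = timecourse.classify_groups(paired)
        comp = timecourse.group_composition(classified, ann)
        assert comp["groups"]["group2"]["share_percent"] >= 95.0

    def test_no_transient_class_keeps_group2_small(self):
        """With the transient class absent only noise/boundary cases reach
        group 2: <= 10% of all proteins at default noise."""
        config = SimulationConfig(n_proteins=500, seed=9,
                                  class_fractions=(0.9, 0.1, 0.0))
        (early, d_early), (late, d_late), _, _ = simulate_timecourse_dataset(config)
        rec_early = enrichment.build_records(early, d_early)
        rec_late = enrichment.build_records(late, d_late)
        paired, _, _ = timecourse.pair_timepoints(rec_early, rec_late)
        classified = timecourse.classify_groups(paired)
        n_group2 = int((classified["group"] == "group2").sum())
        assert n_group2 <= 0.10 * config.n_proteins


class TestSimulatePeptides:
    def _annotations(self, n=50, length=300, mts_end=24, seed=10):
        config = SimulationConfig(
            n_proteins=n, seed=seed, mito_fraction_among_flux=1.0,
            class_fractions=(0.0, 0.0, 1.0),
            protein_length_range=(length, length),
            mts_length_range=(mts_end, mts_end),
        )
        return simulate_dataset(config)[2]

    def test_mature_only_never_covers_mts(self):
        from proximatome.coverage_mts import coverage_table

        ann = {a.protein_id: a for a in self._annotations()}
        hits = simulate_peptides(list(ann.values()), "mature_only", seed=1)
        table = coverage_table(hits, ann)
        assert (table["mts_covered"] == False).all()  # noqa: E712

    def test_zero_peptides_empty(self):
        ann = self._annotations(n=5)
        assert simulate_peptides(ann, "full_length", peptides_per_protein=0) == []

    def test_full_length_detection_matches_closed_form(self):
        """Uniform starts over 1..L-len+1: a length-10 peptide overlaps an
        N-terminal [1,24] MTS iff start <= 24, so per-protein detection
        probability is 1 - (1 - 24/291)^n_peptides; Monte Carlo over 1000
        proteins must agree within sampling error."""
        from proximatome.coverage_mts import coverage_table

        ann = {a.protein_id: a
               for a in self._annotations(n=1000, length=300, mts_end=24)}
        hits = simulate_peptides(list(ann.values()), "full_length",
                                 peptides_per_protein=30, peptide_length=10,
                                 seed=2)
        table = coverage_table(hits, ann)
        observed = table["mts_covered"].mean()
        expected = 1 - (1 - 24 / 291) ** 30
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert abs(observed - expected) < 4 * se

    def test_short_protein_skipped_with_warning(self):
        from proximatome.io_model import ProteinAnnotation

        short = ProteinAnnotation("S", "S", 5)
        with pytest.warns(UserWarning, match="too short"):
            hits = simulate_peptides([short], "full_length", peptide_length=10)
        assert hits == []


class TestSimulateQpcr:
    def test_zero_noise_cts_encode_quantities(self):
        table = simulate_qpcr_plate({("T", "s"): 0.5}, ct_noise_sd=0.0,
                                    baseline_ct=20.0)
        assert np.allclose(table["ct"], 21.0)

    def test_nonpositive_quantity_rejected(self):
        from proximatome.errors import ValidationError

        with pytest.raises(ValidationError):
            simulate_qpcr_plate({("T", "s"): 0.0})

    def test_roles_and_timepoints_filled(self):
        table = simulate_qpcr_plate(
            {("T", "ip"): 1.0}, roles={"ip": "IP"}, timepoints={"ip": "30min"}
        )
        assert set(table["role"]) == {"IP"}
        assert set(table["timepoint"]) == {"30min"}
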