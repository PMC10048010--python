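"""Synthetic cohort generator: reference crowns, dimorphism, repeat rounds."""

import numpy as np
import pytest

import crownmorph as cm


class TestReferenceCrowns:
    @pytest.mark.parametrize(
        "tooth,total,counts",
        [
            (cm.Tooth.FP, 63, {"fixed": 4, "curve": 9, "surface": 50}),
            (cm.Tooth.SP, 63, {"fixed": 4, "curve": 9, "surface": 50}),
            (cm.Tooth.M, 265, {"fixed": 4, "curve": 51, "surface": 210}),
        ],
    )
    def test_counts_match_templates(self, tooth, total, counts):
        config, _ = cm.make_reference_crown(tooth)
        assert config.n_points == total
        assert config.role_counts() == counts

    def test_landmarks_lie_on_mesh(self, fp_reference, molar_reference):
        for config, geometry in (fp_reference, molar_reference):
            _, _, d = geometry.project_to_surface(config.points)
            assert d.max() < 0.02  # mm; analytic points vs triangulated surface

    def test_curve_semilandmarks_lie_on_their_curves(self, fp_reference):
        config, geometry = fp_reference
        names = list(geometry.curves)
        for cid in (0, 1):
            sel = (config.roles == "curve") & (config.curve_id == cid)
            proj, _, _ = geometry.polyline(names[cid]).project(config.points[sel])
            assert np.allclose(proj, config.points[sel], atol=1e-9)

    def test_fixed_landmarks_are_apices_and_fossae(self, fp_reference):
        config, _ = fp_reference
        z = config.points[:, 2]
        # cusp tips stand above the fossae
        assert z[0] > z[2] and z[1] > z[3]


class TestGenerateCohort:
    def test_same_seed_reproduces_cohort(self):
        spec = cm.DimorphismSpec(teeth=("FP",), n_f=3, n_m=3, seed=21)
        a = cm.generate_cohort(spec)
        b = cm.generate_cohort(spec)
        assert a.specimen_ids == b.specimen_ids
        pa = a.specimens[2].configs[cm.Tooth.FP].points
        pb = b.specimens[2].configs[cm.Tooth.FP].points
        assert np.array_equal(pa, pb)

    def test_null_spec_gives_identical_shapes(self):
        spec = cm.DimorphismSpec(
            teeth=("FP",), n_f=4, n_m=4, shape_effect=0.0, size_ratio=1.0,
            individual_shape_sd=0.0, digitization_sd=0.0, seed=5,
        )
        cohort = cm.generate_cohort(spec, include_meshes=False)
        aligned = cm.generalized_procrustes(cohort.configs_for(cm.Tooth.FP))
        assert aligned.residual_history[-1] < 1e-12

    def test_sex_counts_and_labels(self):
        spec = cm.DimorphismSpec(teeth=("FP",), n_f=5, n_m=3, shape_effect=0.05, seed=1)
        cohort = cm.generate_cohort(spec, include_meshes=False)
        labels = cohort.labels()
        assert sum(v == "F" for v in labels.values()) == 5
        assert sum(v == "M" for v in labels.values()) == 3

    def test_sex_means_separated_by_requested_effect(self):
        """With noise off, the Procrustes distance between the sexes equals
        the requested shape effect."""
        effect = 0.06
        spec = cm.DimorphismSpec(
            teeth=("FP",), n_f=1, n_m=1, shape_effect=effect, size_ratio=1.0,
            individual_shape_sd=0.0, digitization_sd=0.0, size_log_sd=0.0, seed=2,
        )
        cohort = cm.generate_cohort(spec, include_meshes=False)
        d = cm.procrustes_distance(
            cohort.specimens[0].configs[cm.Tooth.FP].points,
            cohort.specimens[1].configs[cm.Tooth.FP].points,
        )
        assert d == pytest.approx(effect, rel=0.02)

    def test_size_ratio_reflected_in_centroid_sizes(self):
        spec = cm.DimorphismSpec(
            teeth=("FP",), n_f=40, n_m=40, shape_effect=0.0, size_ratio=1.1,
            individual_shape_sd=0.0, digitization_sd=0.0, size_log_sd=0.01, seed=3,
        )
        cohort = cm.generate_cohort(spec, include_meshes=False)
        sizes = {s.sex: [] for s in cohort.specimens}
        for s in cohort.specimens:
            sizes[s.sex].append(cm.centroid_size(s.configs[cm.Tooth.FP]))
        ratio = np.mean(sizes["M"]) / np.mean(sizes["F"])
        assert ratio == pytest.approx(1.1, abs=0.01)


class TestRepeatRound:
    def test_zero_sd_reproduces_round_one(self, small_cohort):
        round2 = cm.generate_repeat_round(small_cohort, 0.0, seed=9)
        sp = small_cohort.specimens[0]
        assert np.array_equal(
            round2[sp.specimen_id][cm.Tooth.FP].points, sp.configs[cm.Tooth.FP].points
        )

    def test_noise_keeps_surface_semilandmarks_on_mesh(self, small_cohort):
        round2 = cm.generate_repeat_round(small_cohort, 0.05, seed=10)
        sp = small_cohort.specimens[1]
        cfg = round2[sp.specimen_id][cm.Tooth.FP]
        _, _, d = sp.geometries[cm.Tooth.FP].project_to_surface(cfg.points[cfg.surface_mask])
        assert d.max() < 1e-9

    def test_repeatability_degrades_with_digitization_noise(self, small_cohort):
        """The estimated measurement-error share grows monotonically with the
        repeat-round digitization noise."""
        fractions = []
        r1 = cm.generalized_procrustes(small_cohort.configs_for(cm.Tooth.FP))
        for sd in (0.005, 0.02, 0.05, 0.1, 0.2):
            round2 = cm.generate_repeat_round(small_cohort, sd, seed=17)
            r2 = cm.generalized_procrustes(
                [round2[s][cm.Tooth.FP] for s in small_cohort.specimen_ids]
            )
            fractions.append(cm.repeatability(r1, r2).error_variance_fraction)
        assert all(b > a for a, b in zip(fractions, fractions[1:]))


class TestDoseResponse:
    def test_accuracy_non_decreasing_in_shape_effect(self):
        """Test accuracy rises with the sex shape effect (within one pooled
        binomial standard error between adjacent levels)."""
        base = cm.calibrate_shape_effect(
            cm.DimorphismSpec(teeth=("FP",), n_f=25, n_m=25, seed=0)
        )
        accs = []
        level_n = 0
        for level in (0.0, 0.5, 1.0, 2.0):
            correct = total = 0
            for seed in (101, 202):
                spec = cm.DimorphismSpec(
                    teeth=("FP",), n_f=25, n_m=25, shape_effect=level * base, seed=seed
                )
                cohort = cm.generate_cohort(spec, include_meshes=False)
                aligned = cm.generalized_procrustes(cohort.configs_for(cm.Tooth.FP))
                labels = cohort.labels()
                split = cm.set_aside_split(labels, {"F": 18, "M": 18}, seed=seed)
                idx = {s: i for i, s in enumerate(aligned.specimen_ids)}
                tr = [idx[s] for s in split.train_ids]
                te = [idx[s] for s in split.test_ids]
                import dataclasses

                train_sample = dataclasses.replace(
                    aligned,
                    specimen_ids=split.train_ids,
                    aligned=aligned.aligned[tr],
                    centroid_sizes=aligned.centroid_sizes[tr],
                )
                pca = cm.shape_pca(train_sample, n_components=10)
                table = cm.assemble_predictors(
                    {cm.Tooth.FP: pca}, {cm.Tooth.FP: aligned}, labels=labels
                )
                ztr = table.table.loc[split.train_ids]
                mu, sd = ztr.mean(), ztr.std(ddof=1).replace(0, 1)
                model = cm.train_ann(
                    (ztr - mu) / sd, table.labels.loc[split.train_ids].to_numpy(),
                    hidden=3, decay=0.1, epochs=200, seed=seed,
                )
                zte = (table.table.loc[split.test_ids] - mu) / sd
                _, pred = cm.predict_sex(model, zte)
                truth = table.labels.loc[split.test_ids].to_numpy()
                correct += int(np.sum(pred == truth))
                total += len(truth)
            accs.append(correct / total)
            level_n = total
        for lo, hi in zip(accs, accs[1:]):
            # one pooled binomial standard error of the difference
            se = np.sqrt(max(lo * (1 - lo) + hi * (1 - hi), 0.04) / level_n)
            assert hi >= lo - se, f"accuracy sequence {accs} not non-decreasing"
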