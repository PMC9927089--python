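"""Synthetic-data generators: determinism, truth fidelity, study structure."""

import numpy as np
import pandas as pd
import pytest

from biofilmmech import (
    analyze_indentation_curve,
    analyze_torque_curve,
    biofilm_momentum_coefficient,
    default_study_spec,
    generate_image_stack,
    generate_indentation_curve,
    generate_study,
    generate_torque_curve,
    quantify_stack,
)
from biofilmmech.errors import DomainError
from biofilmmech.synth import GroupSpec, StudySpec


class TestTorqueGenerator:
    def test_same_seed_identical(self):
        c1, _ = generate_torque_curve(0.05, noise_sd=0.01, seed=7)
        c2, _ = generate_torque_curve(0.05, noise_sd=0.01, seed=7)
        np.testing.assert_array_equal(c1.torque, c2.torque)
        np.testing.assert_array_equal(c1.omega, c2.omega)

    def test_event_outside_ramp_rejected(self):
        with pytest.raises(DomainError):
            generate_torque_curve(0.05, events=((500.0, 0.5),))

    def test_event_produces_detectable_drop(self):
        curve, _ = generate_torque_curve(0.05, events=((50.0, 0.5),), noise_sd=0.0)
        metrics = analyze_torque_curve(curve)
        assert len(metrics.events) >= 1
        assert min(e.omega for e in metrics.events) == pytest.approx(50.0, rel=0.12)

    def test_truth_fidelity_noise_free(self):
        curve, truth = generate_torque_curve(0.063, noise_sd=0.0)
        cf = biofilm_momentum_coefficient(curve)
        assert cf == pytest.approx(truth["cf0"], rel=1e-9)


class TestIndentationGenerator:
    def test_stiffness_inverse_of_modulus_relation(self):
        _, truth = generate_indentation_curve(93.75)
        assert truth["stiffness_n_per_m"] == pytest.approx(1.0, rel=1e-12)

    def test_same_seed_identical(self):
        c1, _ = generate_indentation_curve(10e3, noise_sd=0.02, seed=3)
        c2, _ = generate_indentation_curve(10e3, noise_sd=0.02, seed=3)
        np.testing.assert_array_equal(c1.force, c2.force)

    def test_truth_fidelity_noise_free(self):
        curve, truth = generate_indentation_curve(10e3, noise_sd=0.0)
        res = analyze_indentation_curve(curve)
        assert res.modulus_pa == pytest.approx(truth["modulus_pa"], rel=1e-9)
        assert res.contact.thickness == pytest.approx(truth["thickness_m"], rel=0.02)


class TestStackGenerator:
    def test_layer_eps_has_zero_roughness(self):
        stack, _ = generate_image_stack(eps_style="layer", seed=1)
        assert quantify_stack(stack)["eps"].roughness == 0.0

    def test_punctate_rougher_than_layer_paired_seed(self):
        for seed in range(5):
            layer, _ = generate_image_stack(eps_style="layer", seed=seed)
            punct, _ = generate_image_stack(
                eps_style="punctate", eps_coverage=0.3, seed=seed)
            ra_layer = quantify_stack(layer)["eps"].roughness
            ra_punct = quantify_stack(punct)["eps"].roughness
            assert ra_punct > ra_layer

    def test_biomass_equals_truth_count(self):
        stack, truth = generate_image_stack(seed=2)
        dz, dy, dx = stack.voxel_size
        ny, nx = stack.shape[1:]
        res = quantify_stack(stack)
        assert res["cells"].biomass == pytest.approx(
            truth["cells_voxels"] * dz * dy * dx / (ny * dy * nx * dx), rel=1e-12)

    def test_bad_coverage_rejected(self):
        with pytest.raises(DomainError):
            generate_image_stack(eps_style="punctate", eps_coverage=0.0)


class TestStudyGenerator:
    def test_manifest_counts(self, tmp_path):
        spec = default_study_spec(seed=1)
        data = generate_study(spec, out_dir=tmp_path / "study")
        n_groups, n_bio, n_tech = len(spec.groups), spec.n_biological, spec.n_technical
        assert len(data.torque) == n_groups * n_bio
        assert len(data.indentation) == n_groups * n_bio * n_tech
        assert len(data.stacks) == n_groups * n_bio
        manifest = pd.read_csv(tmp_path / "study" / "manifest.csv")
        assert len(manifest) == n_groups * n_bio * (1 + n_tech + 1)

    def test_zero_sd_recovers_group_means(self):
        groups = [
            GroupSpec("untreated", 27.28, 0.0, 0.063, 0.0, 150.0, 0.0, "layer", 1.0, 10.0),
            GroupSpec("dza", 9.29, 0.0, 0.037, 0.0, 40.0, 0.0, "punctate", 0.3, 4.0),
        ]
        spec = StudySpec(groups=groups, n_biological=2, n_technical=2,
                         seed=0, torque_noise=0.0, force_noise=0.0,
                         include_stacks=False)
        data = generate_study(spec)
        for rec in data.indentation:
            res = analyze_indentation_curve(rec["curve"])
            expected = {"untreated": 27.28e3, "dza": 9.29e3}[rec["group"]]
            assert res.modulus_pa == pytest.approx(expected, rel=1e-6)

    def test_reproducible_and_seed_sensitive(self):
        d1 = generate_study(default_study_spec(seed=5))
        d2 = generate_study(default_study_spec(seed=5))
        d3 = generate_study(default_study_spec(seed=6))
        t1 = d1.torque[0]["curve"].torque
        np.testing.assert_array_equal(t1, d2.torque[0]["curve"].torque)
        assert not np.array_equal(t1, d3.torque[0]["curve"].torque)
        assert len(d3.torque) == len(d1.torque)


class TestEndToEndContrasts:
    def test_dza_weaker_than_untreated_in_most_studies(self):
        """DZA-treated biofilms come out softer, less adherent, detaching at
        lower shear, with rougher EPS, in nearly all generated studies."""
        wins = {"modulus": 0, "cf": 0, "tau": 0, "roughness": 0}
        n_studies = 5
        for s in range(n_studies):
            data = generate_study(default_study_spec(seed=100 + s))
            by_group = {"untreated": [], "dza": []}
            cf = {"untreated": [], "dza": []}
            tau = {"untreated": [], "dza": []}
            ra = {"untreated": [], "dza": []}
            for rec in data.indentation:
                if rec["group"] in by_group:
                    by_group[rec["group"]].append(
                        analyze_indentation_curve(rec["curve"]).modulus_pa)
            for rec in data.torque:
                if rec["group"] in cf:
                    m = analyze_torque_curve(rec["curve"])
                    cf[rec["group"]].append(m.momentum_coefficient)
                    if m.critical_shear_stress is not None:
                        tau[rec["group"]].append(m.critical_shear_stress)
            for rec in data.stacks:
                if rec["group"] in ra:
                    r = quantify_stack(rec["stack"])["eps"].roughness
                    ra[rec["group"]].append(r if r is not None else 0.0)
            wins["modulus"] += np.mean(by_group["dza"]) < np.mean(by_group["untreated"])
            wins["cf"] += np.mean(cf["dza"]) < np.mean(cf["untreated"])
            if tau["dza"] and tau["untreated"]:
                wins["tau"] += np.mean(tau["dza"]) < np.mean(tau["untreated"])
            wins["roughness"] += np.mean(ra["dza"]) > np.mean(ra["untreated"])
        for key, count in wins.items():
            assert count >= n_studies - 1, f"{key}: {count}/{n_studies}"
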