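"""Model builders, parameter counting and RAM compilation."""

import numpy as np
import pytest

from lcmsr.model_spec import (
    PathSpec,
    add_time_varying_covariate,
    build_bivariate,
    build_univariate,
    canonical_bivariate,
    compile_spec,
    decompile,
    normalized_paths,
    split_groups,
)


class TestUnivariateLadder:
    def test_level2_14_waves_has_32_free_parameters(self):
        spec = build_univariate("FI", 2, 14)
        # 14 residual variances + 13 autoregressions + 2 intercept means
        # + 2 intercept variances + 1 intercept covariance
        assert spec.n_free == 32

    def test_level1_3_waves_has_8_free_parameters(self):
        spec = build_univariate("LS", 1, 3, bursts=[[1, 2, 3]])
        # 2 autoregressions + 3 residual variances + 3 observed means
        assert spec.n_free == 8

    def test_level_progression_adds_slope_parameters(self):
        counts = [build_univariate("FI", lv, 14).n_free for lv in (1, 2, 3, 4)]
        assert counts == [41, 32, 34, 41]  # level 4: +2 svar, +1 scov, +4 sicov

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            build_univariate("FI", 5, 14)

    def test_bursts_must_partition_waves(self):
        with pytest.raises(ValueError):
            build_univariate("FI", 2, 14, bursts=[[1, 2, 3], [5, 6, 7]])


class TestBivariate:
    def test_canonical_bivariate_counts(self):
        spec = canonical_bivariate()
        assert spec.n_free == 110
        assert spec.structural_df() == 324

    def test_minimal_two_wave_additions(self):
        a = build_univariate("FI", 1, 2, bursts=[[1, 2]])
        b = build_univariate("LS", 1, 2, bursts=[[1, 2]])
        biv = build_bivariate(a, b)
        added = set(biv.free_labels()) - set(a.free_labels()) - set(b.free_labels())
        # 1 gamma + 1 delta + 2 within-wave covariances, no intercepts at level 1
        assert len(added) == 4

    def test_no_direct_observed_to_observed_paths(self):
        spec = canonical_bivariate()
        obs = set(spec.observed_vars)
        for p in spec.paths:
            if p.kind == "regression":
                assert not (p.src in obs and p.dst in obs)

    def test_mismatched_wave_counts_rejected(self):
        a = build_univariate("FI", 2, 14)
        b = build_univariate("LS", 2, 6, bursts=[[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            build_bivariate(a, b)

    def test_dynamics_connect_adjacent_waves_only(self):
        spec = canonical_bivariate()
        for p in spec.paths:
            if p.kind == "regression" and p.src.startswith("R_"):
                t_src = int(p.src.split("FI")[-1] if "FI" in p.src else p.src.split("LS")[-1])
                t_dst = int(p.dst.split("FI")[-1] if "FI" in p.dst else p.dst.split("LS")[-1])
                assert t_dst == t_src + 1


class TestCovariates:
    def test_both_targets_add_28_paths(self):
        spec = canonical_bivariate()
        ext = add_time_varying_covariate(spec, "bedrest", "both")
        new = set(ext.free_labels()) - set(spec.free_labels())
        tvc = [l for l in new if l.startswith("tvc_")]
        assert len(tvc) == 28

    def test_single_target_adds_14_paths(self):
        spec = canonical_bivariate()
        ext = add_time_varying_covariate(spec, "falls", "FI")
        tvc = [l for l in ext.free_labels() if l.startswith("tvc_")]
        assert len(tvc) == 14

    def test_extended_spec_still_compiles_acyclically(self):
        spec = add_time_varying_covariate(canonical_bivariate(), "bedrest", "both")
        ram = compile_spec(spec)  # raises on cycles
        assert ram.n_free == spec.n_free

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            add_time_varying_covariate(canonical_bivariate(), "x", "NOPE")


class TestGroups:
    def test_two_groups_double_parameters(self):
        spec = canonical_bivariate()
        gs = split_groups(spec, ["m", "w"])
        assert sum(s.n_free for s in gs.values()) == 220
        assert len(set(gs["m"].free_labels()) & set(gs["w"].free_labels())) == 0

    def test_equality_constraint_shares_family(self):
        spec = canonical_bivariate()
        gs = split_groups(spec, ["a", "b", "c"], equal=["wcov"])
        labels = set()
        for s in gs.values():
            labels |= set(s.free_labels())
        assert len(labels) == 3 * 110 - 2 * 14

    def test_single_group_is_identity(self):
        spec = canonical_bivariate()
        gs = split_groups(spec, ["all"])
        assert gs["all"].free_labels() == spec.free_labels()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            split_groups(canonical_bivariate(), ["a", ""])


class TestCompile:
    def test_canonical_dimensions_and_free_cells(self):
        ram = compile_spec(canonical_bivariate())
        assert ram.A0.shape == (62, 62)  # 28 observed + 28 residuals + 4 RI + 2 slopes
        assert sum(len(c) for c in ram.free.values()) == 110

    def test_degenerate_single_variable_model(self):
        from lcmsr.model_spec import ModelSpec

        spec = ModelSpec(
            ["y1"],
            [],
            [
                PathSpec("y1", "y1", "variance", label="v"),
                PathSpec("y1", "y1", "mean", label="m"),
            ],
            meta={"constructs": ["y"], "n_waves": 1, "bursts": [[1]]},
        )
        ram = compile_spec(spec)
        mu, sigma = ram.implied_moments(np.array([2.5, 1.0]))
        assert mu[0] == pytest.approx(1.0)
        assert sigma[0, 0] == pytest.approx(2.5)

    def test_shared_label_maps_one_parameter_to_many_cells(self):
        spec = build_univariate("FI", 2, 14)
        shared = [
            PathSpec(p.src, p.dst, p.kind, label="ar_shared")
            if (p.free and p.label.startswith("ar_"))
            else p
            for p in spec.paths
        ]
        spec.paths = shared
        ram = compile_spec(spec)
        assert len(ram.free["ar_shared"]) == 13
        assert ram.n_free == 32 - 13 + 1

    def test_cycle_detection(self):
        from lcmsr.model_spec import ModelSpec

        spec = ModelSpec(
            ["y1", "y2"],
            [],
            [
                PathSpec("y1", "y2", "regression", label="a"),
                PathSpec("y2", "y1", "regression", label="b"),
                PathSpec("y1", "y1", "variance", label="v1"),
                PathSpec("y2", "y2", "variance", label="v2"),
            ],
        )
        with pytest.raises(ValueError, match="cyclic"):
            compile_spec(spec)

    def test_conflicting_duplicate_paths_rejected(self):
        spec = build_univariate("FI", 2, 4, bursts=[[1, 2], [3, 4]])
        spec.paths.append(PathSpec("R_FI1", "FI1", "loading", value=2.0))
        with pytest.raises(ValueError, match="conflicting"):
            compile_spec(spec)

    @pytest.mark.parametrize("builder", ["univariate", "bivariate", "covariate"])
    def test_compile_decompile_round_trip(self, builder):
        if builder == "univariate":
            spec = build_univariate("FI", 4, 14)
        elif builder == "bivariate":
            spec = canonical_bivariate()
        else:
            spec = add_time_varying_covariate(canonical_bivariate(), "bedrest", "both")
        ram = compile_spec(spec)
        assert decompile(ram) == normalized_paths(spec)

    def test_emitted_A_is_nilpotent(self, canonical_ram, theta_true):
        A, _, _ = canonical_ram.realize(theta_true)
        P = A.copy()
        for _ in range(A.shape[0]):
            P = P @ A
            if not P.any():
                break
        assert not P.any()
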