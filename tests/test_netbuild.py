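import numpy as np
import pandas as pd
import pytest

from avalanchekit import netbuild
from avalanchekit.netbuild import (
    AdjustmentError,
    ColumnGeometry,
    ConnectionRule,
    NetworkConfig,
    RuleSet,
    apply_class_adjustments,
    border_correction_factor,
    build_network,
    conduction_delay,
    cylinder_volume,
    default_adjustments,
    export_network,
    import_network,
    lateral_prob,
    nmda_factor,
    pcon_from_scon,
    place_cells,
    split_unitary_weight,
    threshold_vcon,
)


class TestGeometry:
    def test_electrode_volume(self):
        assert cylinder_volume(40, 1350) == pytest.approx(1_696_460, abs=1)

    def test_column_volume(self):
        # pi * 150^2 * 1350 = 95,425,876.85 um^3
        assert cylinder_volume(300, 1350) == pytest.approx(95_425_877, abs=1)

    def test_zero_depth(self):
        assert cylinder_volume(10.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cylinder_volume(-1.0, 10.0)

    def test_stimulated_fraction_is_about_1_8_percent(self):
        frac = cylinder_volume(40, 1350) / cylinder_volume(300, 1350)
        assert 100 * frac == pytest.approx(1.8, abs=0.05)


class TestPlaceCells:
    def _one_layer(self, count):
        geom = ColumnGeometry(layer_bands={"L5B": (0.47, 0.80)})
        thickness_mm = 0.33 * 1.35
        area_mm2 = np.pi * 0.15**2
        density = count / (thickness_mm * area_mm2)
        comp = {"L5B": ({"IT5B": 1.0}, {"PV5B": 2 / 3, "SOM5B": 1 / 3})}
        return place_cells(geom, {"L5B": density}, comp, seed=0)

    def test_ei_and_pv_som_apportionment(self):
        tab = self._one_layer(100)
        counts = tab["population"].value_counts().to_dict()
        assert counts == {"IT5B": 80, "PV5B": 13, "SOM5B": 7}

    def test_positions_inside_cylinder_band(self):
        tab = self._one_layer(200)
        r = np.hypot(tab["x"], tab["y"])
        assert (r <= 150.0 + 1e-9).all()
        assert tab["ncd"].between(0.47, 0.80).all()

    def test_zero_density_layer_is_empty(self):
        geom = ColumnGeometry()
        tab = place_cells(geom, {k: 0.0 for k in geom.layer_bands}, seed=0)
        assert tab.empty

    def test_default_config_total_matches_column(self):
        tab = place_cells(
            ColumnGeometry(), netbuild.DEFAULT_DENSITIES, seed=0
        )
        assert abs(len(tab) - 10_073) / 10_073 < 0.01

    def test_overlapping_bands_rejected(self):
        geom = ColumnGeometry(
            layer_bands={"A": (0.1, 0.5), "B": (0.4, 0.8)}
        )
        with pytest.raises(ValueError, match="overlap"):
            place_cells(geom, {"A": 1e5, "B": 1e5}, seed=0)


class TestScalarRules:
    def test_pcon_from_scon(self):
        assert pcon_from_scon(0.25, 0.5) == 0.5
        assert pcon_from_scon(0.0, 0.7) == 0.0
        with pytest.warns(UserWarning, match="clip"):
            assert pcon_from_scon(1.5, 1.0) == 1.0
        with pytest.raises(ValueError):
            pcon_from_scon(0.5, 0.0)

    @pytest.mark.parametrize("raw, expected",
                             [(0.1, 0.3), (0.7, 0.7), (1.4, 1.0)])
    def test_threshold_vcon(self, raw, expected):
        assert threshold_vcon(raw) == expected

    def test_threshold_vcon_negative_rejected(self):
        with pytest.raises(ValueError):
            threshold_vcon(-0.1)

    def test_lateral_decay(self):
        assert lateral_prob(0.2, 0.0) == pytest.approx(0.2)
        assert lateral_prob(0.2, 100.0, 100.0) == pytest.approx(
            0.2 / np.e, rel=1e-9
        )
        assert lateral_prob(0.2, 100.0, 100.0, border_correction=1.1) == \
            pytest.approx(0.2 / np.e * 1.1, rel=1e-9)
        with pytest.raises(ValueError):
            lateral_prob(0.2, -1.0)

    def test_border_correction_grows_toward_edge(self):
        factors = border_correction_factor(
            np.array([0.0, 75.0, 150.0]), radius_um=150.0
        )
        assert factors[0] >= 1.0
        assert factors[0] < factors[1] < factors[2]

    @pytest.mark.parametrize("d_mm, expected",
                             [(0.0, 2.0), (0.5, 3.0), (0.1, 2.2)])
    def test_conduction_delay(self, d_mm, expected):
        assert conduction_delay(d_mm) == pytest.approx(expected)

    def test_delay_monotone_and_bounded_below(self):
        d = np.linspace(0.0, 2.0, 100)
        delays = conduction_delay(d)
        assert (np.diff(delays) > 0).all()
        assert (delays >= 2.0).all()

    def test_nmda_factor_values(self):
        assert nmda_factor(0.0, 1.0) == pytest.approx(1 / 1.28)
        assert nmda_factor(-70.0, 1.0) == pytest.approx(
            1.0 / (1.0 + 0.28 * np.exp(0.062 * 70.0)), rel=1e-9
        )
        assert nmda_factor(-70.0, 1.0) == pytest.approx(0.0446, abs=5e-4)

    def test_nmda_factor_monotone_and_mg_free_unity(self):
        v = np.linspace(-90.0, 40.0, 200)
        f = nmda_factor(v, 1.0)
        assert (np.diff(f) > 0).all()
        assert (f > 0).all() and (f <= 1.0).all()
        np.testing.assert_allclose(nmda_factor(v, 0.0), 1.0)


class TestWeightSplit:
    def test_detailed_excitatory(self):
        n, w = split_unitary_weight(0.5, "detailed", "excitatory")
        assert n == 5
        assert w == {"AMPA": pytest.approx(0.05), "NMDA": pytest.approx(0.05)}

    def test_reduced_excitatory(self):
        n, w = split_unitary_weight(0.6, "reduced", "excitatory")
        assert n == 1
        assert w == {"AMPA": pytest.approx(0.3), "NMDA": pytest.approx(0.3)}

    def test_som_onto_excitatory_90_10(self):
        n, w = split_unitary_weight(0.5, "reduced", "SOM", "excitatory")
        assert w == {"GABAA_slow": pytest.approx(0.45),
                     "GABAB": pytest.approx(0.05)}

    def test_som_onto_inhibitory_pure_slow_gabaa(self):
        _, w = split_unitary_weight(0.5, "reduced", "SOM", "inhibitory")
        assert w == {"GABAA_slow": pytest.approx(0.5)}

    def test_pv_pure_fast_gabaa(self):
        _, w = split_unitary_weight(0.4, "detailed", "PV")
        assert w == {"GABAA_fast": pytest.approx(0.08)}

    @pytest.mark.parametrize("detail", ["detailed", "reduced"])
    @pytest.mark.parametrize("pre", ["excitatory", "PV", "SOM"])
    def test_split_conserves_vcon(self, detail, pre):
        vcon = 0.7312
        n, w = split_unitary_weight(vcon, detail, pre)
        assert sum(w.values()) * n == pytest.approx(vcon, abs=1e-12)

    def test_unknown_detail_rejected(self):
        with pytest.raises(ValueError):
            split_unitary_weight(0.5, "mystery", "excitatory")


class TestAdjustments:
    def _rules(self):
        pops = ["IT2/3", "IT4", "CT6", "PV5A", "SOM5A"]
        rules = {}
        for a in pops:
            for b in pops:
                rules[(a, b)] = ConnectionRule(a, b, scon=1.0, vcon_raw=0.5)
        rules[("IT4", "IT2/3")].scon = 0.8
        return RuleSet(rules)

    def test_ct_inputs_reduced_to_62_percent(self):
        rs = apply_class_adjustments(self._rules())
        assert rs.get("IT2/3", "CT6").scon == pytest.approx(0.62)

    def test_l23_to_l4_quarter_of_reverse(self):
        rs = apply_class_adjustments(self._rules())
        assert rs.get("IT2/3", "IT4").scon == pytest.approx(0.25 * 0.8)

    def test_pv_som_probability_biases(self):
        rs = apply_class_adjustments(self._rules())
        assert rs.get("IT2/3", "SOM5A").pcon_scale == pytest.approx(1.5)
        assert rs.get("IT2/3", "PV5A").pcon_scale == pytest.approx(0.5)
        assert rs.get("IT4", "PV5A").pcon_scale == pytest.approx(1.5)
        assert rs.get("IT4", "SOM5A").pcon_scale == pytest.approx(0.5)

    def test_inhibitory_rules_become_same_layer(self):
        rs = apply_class_adjustments(self._rules())
        assert rs.get("PV5A", "IT2/3").same_layer_only
        assert rs.get("SOM5A", "CT6").same_layer_only
        assert not rs.get("IT2/3", "IT4").same_layer_only

    def test_double_application_guarded(self):
        rs = apply_class_adjustments(self._rules())
        with pytest.raises(AdjustmentError):
            apply_class_adjustments(rs, default_adjustments())


def toy_config(p=0.3, decay=1e12, same_layer=False, n=30):
    geom = ColumnGeometry(layer_bands={"L5B": (0.47, 0.80)})
    thickness_mm = 0.33 * 1.35
    area_mm2 = np.pi * 0.15**2
    density = 2 * n / (thickness_mm * area_mm2)
    comp = {"L5B": ({"IT5B": 0.5, "PT5B": 0.5}, {})}
    rules = {}
    for a in ("IT5B", "PT5B"):
        for b in ("IT5B", "PT5B"):
            rules[(a, b)] = ConnectionRule(
                a, b, scon=p * 0.5, vcon_raw=0.5, decay_um=decay,
                same_layer_only=same_layer,
            )
    return NetworkConfig(
        geometry=geom,
        densities={"L5B": density},
        e_fraction=1.0,
        composition=comp,
        rules=RuleSet(rules, adjusted=True),
        border_correction=False,
    )


class TestBuildNetwork:
    def test_full_probability_gives_complete_bipartite(self):
        spec = build_network(toy_config(p=1.0, n=15), seed=0)
        n = len(spec.neurons)
        assert spec.n_edges == n * (n - 1)
        assert not (spec.edges["pre_id"] == spec.edges["post_id"]).any()

    def test_zero_probability_gives_no_edges(self):
        spec = build_network(toy_config(p=0.0, n=15), seed=0)
        assert spec.n_edges == 0

    def test_empirical_connection_frequency_binomial(self):
        p = 0.3
        spec = build_network(toy_config(p=p, n=120), seed=1)
        n = len(spec.neurons)
        trials = n * (n - 1)
        freq = spec.n_edges / trials
        sd = np.sqrt(p * (1 - p) / trials)
        assert abs(freq - p) < 3 * sd

    def test_seeded_reproducibility_edge_for_edge(self):
        a = build_network(toy_config(p=0.4, n=40), seed=9)
        b = build_network(toy_config(p=0.4, n=40), seed=9)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_delays_at_least_2ms_and_monotone_with_distance(self):
        spec = build_network(toy_config(p=0.5, n=40), seed=2)
        pos = spec.neurons[["x", "y", "z"]].to_numpy()
        pre = spec.edges["pre_id"].to_numpy()
        post = spec.edges["post_id"].to_numpy()
        d = np.linalg.norm(pos[pre] - pos[post], axis=1) / 1000.0
        delays = spec.edges["delay_ms"].to_numpy()
        assert (delays >= 2.0).all()
        np.testing.assert_allclose(delays, conduction_delay(d), rtol=1e-9)

    def test_weight_columns_conserve_vcon(self):
        spec = build_network(toy_config(p=0.5, n=20), seed=3)
        receptor_sum = spec.edges[
            ["AMPA", "NMDA", "GABAA_fast", "GABAA_slow", "GABAB"]
        ].sum(axis=1)
        total = receptor_sum * spec.edges["n_synapses"]
        np.testing.assert_allclose(total, 0.5, atol=1e-12)

    def test_detailed_targets_get_five_synapses(self):
        spec = build_network(toy_config(p=0.5, n=20), seed=4)
        per_target = spec.edges.copy()
        per_target["post_pop"] = spec.neurons["population"].reindex(
            per_target["post_id"]
        ).to_numpy()
        assert (
            per_target.loc[per_target["post_pop"] == "PT5B", "n_synapses"]
            == 5
        ).all()
        assert (
            per_target.loc[per_target["post_pop"] == "IT5B", "n_synapses"]
            == 1
        ).all()


class TestExport:
    def test_round_trip_identity(self, tmp_path):
        spec = build_network(toy_config(p=0.4, n=25), seed=5)
        export_network(spec, tmp_path / "net.json")
        back = import_network(tmp_path / "net.json")
        assert back.n_edges == spec.n_edges
        pd.testing.assert_frame_equal(back.edges, spec.edges)
        assert len(back.neurons) == len(spec.neurons)

    def test_empty_network_round_trips(self, tmp_path):
        spec = build_network(toy_config(p=0.0, n=10), seed=6)
        export_network(spec, tmp_path / "net.json")
        back = import_network(tmp_path / "net.json")
        assert back.n_edges == 0
        assert len(back.neurons) == len(spec.neurons)
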