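import numpy as np
import pytest

from togglesim import SimulationConfig, enumerate_fixed_points
from togglesim import workflows
from togglesim.netgen import SELF_ACTIVATION, SELF_NONE


class TestThelperFixture:
    def test_sixteen_inhibitory_edges(self):
        net = workflows.thelper_network()
        assert net.node_names == ["TBX21", "GATA3", "RORC", "FOXP3", "BCL6"]
        assert (net.adjacency < 0).sum() == 16
        assert (net.adjacency > 0).sum() == 0

    def test_unreported_interactions_are_absent(self):
        net = workflows.thelper_network()
        bcl6 = net.index("BCL6")
        for tf in ("GATA3", "RORC", "FOXP3"):
            assert net.adjacency[net.index(tf), bcl6] == 0
        assert net.adjacency[bcl6, net.index("FOXP3")] == 0
        # the reported inhibitions onto/by BCL6 are present
        assert net.adjacency[net.index("TBX21"), bcl6] == -1
        assert net.adjacency[bcl6, net.index("TBX21")] == -1
        assert net.adjacency[bcl6, net.index("GATA3")] == -1
        assert net.adjacency[bcl6, net.index("RORC")] == -1

    def test_self_activation_variant_diagonal(self):
        net = workflows.thelper_network(self_activation=True)
        diag = np.diag(net.adjacency)
        assert diag.tolist() == [1, 1, 1, 1, 0]


class TestHybridLabels:
    @pytest.mark.parametrize(
        "state, label",
        [
            ((1, 1, -1, -1, -1), "Th1/Th2"),
            ((1, -1, 1, -1, -1), "Th1/Th17"),
            ((-1, -1, -1, 1, 1), "Treg/TFH"),
            ((-1, -1, -1, -1, -1), "(none)"),
            ((1, 1, 1, 1, 1), "Th1/Th2/Th17/Treg/TFH"),
        ],
    )
    def test_canonical_names(self, state, label):
        names = ["TBX21", "GATA3", "RORC", "FOXP3", "BCL6"]
        assert workflows.hybrid_label(np.array(state), names) == label


class TestThelperCaseStudy:
    def test_base_support_is_2_and_3_high(self, replicate_config):
        report = workflows.run_thelper_case_study("base", config=replicate_config)
        assert set(report["k"]) <= {2, 3}
        assert report["frequency"].sum() == pytest.approx(1.0)

    def test_base_dominant_2high_hybrids(self, replicate_config):
        report = workflows.run_thelper_case_study("base", config=replicate_config)
        two_high = report[report.k == 2].sort_values(
            "frequency", ascending=False
        )
        assert set(two_high.label.iloc[:2]) == {"Th1/Th2", "Th1/Th17"}

    def test_self_activation_adds_tfh_hybrids(self, replicate_config):
        report = workflows.run_thelper_case_study(
            "self_activation", config=replicate_config
        )
        assert {"Th2/TFH", "Th17/TFH"} <= set(report.label)

    def test_random_weights_variant_runs(self, fast_config):
        # frequencies are across-network means; weight sets whose network
        # never converges contribute zero, so the total can fall below 1
        report = workflows.run_thelper_case_study(
            "random_weights", config=fast_config, n_sets=5, seed=3
        )
        assert 0.0 < report.frequency.sum() <= 1.0 + 1e-9
        assert len(report)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            workflows.run_thelper_case_study("nope")


class TestFkSweep:
    def test_single_positive_frequency_drops_with_size(self, fast_config):
        table = workflows.run_fk_sweep(
            n_range=[2, 3, 4], config=fast_config
        )
        f1 = {
            row.n: row.F
            for row in table[table.k == 1].itertuples()
        }
        assert f1[2] == pytest.approx(1.0)
        assert f1[3] == pytest.approx(0.5, abs=0.04)
        assert f1[4] == pytest.approx(0.0)

    def test_self_activation_rescues_toggle4(self, fast_config):
        table = workflows.run_fk_sweep(
            n_range=[4],
            self_regulation_modes=(SELF_NONE, SELF_ACTIVATION),
            config=fast_config,
        )
        sa = table[(table.self_regulation == SELF_ACTIVATION)]
        none = table[(table.self_regulation == SELF_NONE)]
        assert sa[sa.k == 1].F.iloc[0] > 0
        assert none[none.k == 1].F.iloc[0] == 0
        # flanking states around n/2 appear symmetrically
        f1 = sa[sa.k == 1].F.iloc[0]
        f3 = sa[sa.k == 3].F.iloc[0]
        assert f1 == pytest.approx(f3, abs=0.04)


class TestImpuritySweep:
    def test_endpoints_and_f1_cap(self, fast_config):
        table = workflows.run_impurity_sweep(3, config=fast_config)
        pure = table[table.n_imp == 0]
        assert pure[pure.k == 1].F.iloc[0] == pytest.approx(0.5, abs=0.04)
        assert pure[pure.k == 2].F.iloc[0] == pytest.approx(0.5, abs=0.04)
        full = table[table.n_imp == 6]
        assert full[full.k == 0].F.iloc[0] == pytest.approx(0.5, abs=0.04)
        assert full[full.k == 3].F.iloc[0] == pytest.approx(0.5, abs=0.04)
        assert (table[table.k == 1].F <= 0.5 + 0.04).all()


class TestThelperCytokines:
    def test_t2_and_t3_differentiate_at_baseline(self, fast_config):
        for n, lineage in [(2, "Th1"), (2, "Th2"), (3, "Th17"), (3, "Th1")]:
            table = workflows.run_thelper_cytokines(
                n, lineage, config=fast_config
            )
            assert table.F_lineage_1.iloc[0] == pytest.approx(1.0)

    def test_t4_th1_needs_higher_edge_weight(self, fast_config):
        """IFN-gamma's activation of FOXP3 blocks Th1 differentiation at
        baseline weight; strengthening TBX21's inhibitions overcomes it."""
        table = workflows.run_thelper_cytokines(
            4, "Th1", w_range=[1, 2, 3], config=fast_config
        )
        by_w = dict(zip(table.W, table.F_lineage_1))
        assert by_w[1] < 1.0
        assert by_w[3] == pytest.approx(1.0)

    def test_manifest_reproducibility(self, tmp_path):
        m = workflows.ExperimentManifest(
            experiment="impurity",
            seed=5,
            params={"n": 3, "n_initial_conditions": 500, "n_replicates": 1},
        )
        first = m.run(tmp_path / "a")[0].read_text()
        second = m.run(tmp_path / "b")[0].read_text()
        assert first == second


def test_subnetwork_nodes():
    assert workflows.thelper_subnetwork(3).node_names == [
        "TBX21", "GATA3", "RORC",
    ]
    with pytest.raises(ValueError):
        workflows.thelper_subnetwork(5)
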