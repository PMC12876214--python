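"""Cross-kingdom network inference: correlation primitives, FDR filtering,
topology summaries and planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from codysbiosis import (
    PipelineConfig,
    PlantedEdge,
    SyntheticSpec,
    bh_adjust,
    build_cross_kingdom_network,
    compare_networks,
    simulate_cohort,
    spearman_pvalue,
    spearman_rho,
    summarize_network,
    to_graphml,
)
from codysbiosis.network import ConstantInputError, CrossKingdomNetworkInference


class TestSpearmanRho:
    def test_hand_worked_example(self):
        # sum d^2 = 4 -> 1 - 6*4/(5*24) = 0.8
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 22, 100]) == pytest.approx(1.0)

    def test_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-100, 100), min_size=5, max_size=20,
                    unique=True),
           st.sampled_from(["exp", "cube", "affine"]))
    def test_invariant_under_monotone_transform(self, xs, kind):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.permutation(len(xs)).astype(float)
        x = np.array(xs, dtype=float)
        fx = {"exp": lambda v: np.exp(v / 50.0),
              "cube": lambda v: v ** 3,
              "affine": lambda v: 2.0 * v + 7.0}[kind](x)
        assert spearman_rho(fx, y) == pytest.approx(spearman_rho(x, y),
                                                    abs=1e-12)


class TestSpearmanPvalue:
    @pytest.mark.parametrize("rho,n,expected", [
        (-0.75, 17, 0.0005),
        (0.71, 19, 0.0007),
        (0.66, 17, 0.0039),
    ])
    def test_printed_anchor_triples(self, rho, n, expected):
        assert round(spearman_pvalue(rho, n), 4) == expected

    def test_null_is_one(self):
        assert spearman_pvalue(0.0, 20) == 1.0

    def test_decreasing_in_magnitude_and_n(self):
        ps = [spearman_pvalue(r, 15) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        pn = [spearman_pvalue(0.5, n) for n in (8, 12, 20, 40)]
        assert all(a > b for a, b in zip(pn, pn[1:]))

    def test_perfect_correlation_floor(self):
        import math

        assert spearman_pvalue(1.0, 5) == 2.0 / math.factorial(5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_pvalue(0.5, 3)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_worked_step_up(self):
        got = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(got, [0.02, 0.04, 0.04, 0.02])

    def test_q_at_least_p_and_at_most_one(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_null_calibration(self):
        """On all-null uniform p (m=200), discoveries at q<0.05 average
        at or below 0.05 over 500 replicates."""
        rng = np.random.default_rng(3)
        fracs = [(bh_adjust(rng.random(200)) < 0.05).mean()
                 for _ in range(500)]
        assert np.mean(fracs) <= 0.05

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _toy_network_table(n=20, seed=0):
    """One strictly monotone positive pair, one negative pair (independent
    bases), rest noise.  Values are small fractions (compositionally valid
    without closure) so the planted monotone couplings are exact."""
    rng = np.random.default_rng(seed)
    x1 = rng.permutation(n).astype(float) + 1.0
    x2 = rng.permutation(n).astype(float) + 1.0
    data = pd.DataFrame(index=[f"s{i}" for i in range(n)])
    data["BactPos"] = x1 / 1000.0
    data["BactNeg"] = x2 / 1000.0
    for i in range(4):
        data[f"BactNoise{i}"] = rng.lognormal(size=n) / 1000.0
    data["FungPos"] = np.exp(x1 / 5.0) / 1000.0
    data["FungNeg"] = (np.max(x2) + 1.0 - x2) / 1000.0
    for i in range(4):
        data[f"FungNoise{i}"] = rng.lognormal(size=n) / 1000.0
    kingdom = pd.Series(
        ["bacteria" if c.startswith("Bact") else "fungi" for c in data.columns],
        index=data.columns,
    )
    from codysbiosis import AbundanceTable

    return AbundanceTable(data, kingdom,
                          pd.Series("genus", index=data.columns),
                          normalized=True)


class TestBuildNetwork:
    def test_planted_pairs_recovered_with_signs(self):
        t = _toy_network_table()
        net = build_cross_kingdom_network(t, config=PipelineConfig())
        pairs = {(e.bacterial_taxon, e.fungal_taxon): e.sign for e in net.edges}
        assert pairs[("BactPos", "FungPos")] == "positive"
        assert pairs[("BactNeg", "FungNeg")] == "negative"
        # noise pairs stay out
        assert len(pairs) == 2
        assert net.n_pairs_tested == 36

    def test_cross_kingdom_only(self):
        t = _toy_network_table()
        net = build_cross_kingdom_network(t, config=PipelineConfig())
        for e in net.edges:
            assert t.kingdom[e.bacterial_taxon] == "bacteria"
            assert t.kingdom[e.fungal_taxon] == "fungi"

    def test_all_below_threshold_empty(self):
        rng = np.random.default_rng(10)
        from codysbiosis import AbundanceTable, to_relative_abundance

        data = pd.DataFrame(rng.lognormal(size=(30, 8)),
                            index=[f"s{i}" for i in range(30)],
                            columns=[f"T{i}" for i in range(8)])
        kingdom = pd.Series(["bacteria"] * 4 + ["fungi"] * 4,
                            index=data.columns)
        t = to_relative_abundance(AbundanceTable(
            data, kingdom, pd.Series("genus", index=data.columns)))
        net = build_cross_kingdom_network(t, config=PipelineConfig())
        assert net.n_edges == 0

    def test_raw_p_passing_but_q_failing_excluded(self):
        """A borderline pair (|rho| just over 0.6, raw p < 0.05) among many
        null pairs is excluded once BH adjustment pushes its q above 0.05."""
        rng = np.random.default_rng(17)
        n = 19
        from codysbiosis import AbundanceTable, to_relative_abundance

        data = pd.DataFrame(rng.lognormal(size=(n, 40)) / 1000.0,
                            index=[f"s{i}" for i in range(n)],
                            columns=[f"T{i}" for i in range(40)])
        # mix ranks of T0 into T20 until the coupling lands in the
        # borderline band |rho| in [0.60, 0.68] (raw p ~ 0.002-0.007)
        base = np.argsort(np.argsort(data["T0"])).astype(float)
        planted = None
        for _ in range(200):
            w = rng.uniform(0.5, 0.85)
            mix = w * base + (1 - w) * rng.permutation(n)
            rho = spearman_rho(base, mix)
            if 0.60 <= rho <= 0.68:
                planted = mix
                break
        assert planted is not None
        data["T20"] = np.exp(planted / 5.0) / 1000.0
        kingdom = pd.Series(["bacteria"] * 20 + ["fungi"] * 20,
                            index=data.columns)
        t = AbundanceTable(data, kingdom,
                           pd.Series("genus", index=data.columns),
                           normalized=True)
        rec = [r for r in _all_pairs(t) if r[:2] == ("T0", "T20")][0]
        assert abs(rec[2]) >= 0.6 and rec[3] < 0.05  # construction holds
        net = build_cross_kingdom_network(t, config=PipelineConfig())
        pairs = {(e.bacterial_taxon, e.fungal_taxon) for e in net.edges}
        assert ("T0", "T20") not in pairs

    def test_unnormalized_table_rejected(self, small_table, small_metadata):
        with pytest.raises(ValueError, match="normalized"):
            build_cross_kingdom_network(small_table, small_metadata, "ARFC")


def _all_pairs(table):
    from scipy.stats import rankdata

    out = []
    bact = table.taxa_of("bacteria")
    fung = table.taxa_of("fungi")
    n = table.n_samples
    for b in bact:
        for f in fung:
            r = spearman_rho(table.data[b], table.data[f])
            out.append((b, f, r, spearman_pvalue(r, n)))
    return out


class TestSummaryAndComparison:
    def _net(self, edges, seed=0):
        t = _toy_network_table(seed=seed)
        net = build_cross_kingdom_network(t, config=PipelineConfig())
        return net

    def test_positivity_fraction_arithmetic(self):
        net = self._net(None)
        s = summarize_network(net)
        assert s.n_positive + s.n_negative == s.n_edges
        assert s.positivity_fraction == pytest.approx(0.5)

    def test_empty_network_undefined_flag(self):
        rng = np.random.default_rng(10)
        from codysbiosis import AbundanceTable, to_relative_abundance

        data = pd.DataFrame(rng.lognormal(size=(30, 8)),
                            index=[f"s{i}" for i in range(30)],
                            columns=[f"T{i}" for i in range(8)])
        kingdom = pd.Series(["bacteria"] * 4 + ["fungi"] * 4,
                            index=data.columns)
        t = to_relative_abundance(AbundanceTable(
            data, kingdom, pd.Series("genus", index=data.columns)))
        s = summarize_network(
            build_cross_kingdom_network(t, config=PipelineConfig()))
        assert s.undefined and s.positivity_fraction is None

    def test_star_hub_degree(self):
        """A fungus linked to 7 bacteria is the top hub with degree 7."""
        from codysbiosis import CorrelationEdge
        from codysbiosis.network import CrossKingdomNetwork

        bacteria = [f"B{i}" for i in range(7)]
        edges = [CorrelationEdge(b, "FungHub", 0.8, 1e-5, 1e-4)
                 for b in bacteria]
        nodes = pd.DataFrame(
            {"kingdom": ["bacteria"] * 7 + ["fungi"],
             "mean_abundance": [0.01] * 7 + [0.2],
             "degree": [1] * 7 + [7]},
            index=bacteria + ["FungHub"],
        )
        net = CrossKingdomNetwork(
            group="ARFC", nodes=nodes, edges=edges, rho_min=0.6,
            q_alpha=0.05, prevalence_min=0.25, n_pairs_tested=7, n_samples=19,
        )
        s = summarize_network(net, n_hubs=3)
        assert s.hubs[0] == ("FungHub", 7)
        assert s.positivity_fraction == 1.0

    def test_identical_networks_compare_clean(self):
        net = self._net(None)
        rep = compare_networks(net, net)
        assert rep["sign_flips"] == []
        assert rep["positivity_difference"] == 0.0
        assert rep["hub_turnover"] == 0.0

    def test_threshold_mismatch_rejected(self):
        a = self._net(None)
        t = _toy_network_table()
        b = build_cross_kingdom_network(t, config=PipelineConfig(rho_min=0.7))
        with pytest.raises(ValueError, match="threshold mismatch"):
            compare_networks(a, b)

    def test_sign_flip_detected(self):
        """A shared pair positive in one group and negative in the other is
        reported as a flip."""
        spec = SyntheticSpec(
            n_per_group={"ARFC": 40, "HC": 40}, n_bacteria=10, n_fungi=10,
            depleted_taxa=[], ige_coupling=[], zero_inflation=0.0, seed=4,
        )
        b, f = "Bacterium_006", "Fungus_010"
        spec.planted_edges = {
            "ARFC": [PlantedEdge(b, f, 0.9)],
            "HC": [PlantedEdge(b, f, -0.9)],
        }
        table, meta = simulate_cohort(spec)
        cfg = PipelineConfig()
        net_a = build_cross_kingdom_network(table, meta, "ARFC", cfg)
        net_h = build_cross_kingdom_network(table, meta, "HC", cfg)
        rep = compare_networks(net_h, net_a)
        assert (b, f) in rep["sign_flips"]


class TestRecovery:
    def _spec(self, seed):
        spec = SyntheticSpec(
            n_per_group={"ARFC": 19}, n_bacteria=18, n_fungi=17,
            depleted_taxa=[], ige_coupling=[], seed=seed,
        )
        b, f = spec.bacteria, spec.fungi
        edges = [PlantedEdge(b[0], f[0], 0.8), PlantedEdge(b[1], f[1], 0.8),
                 PlantedEdge(b[2], f[2], -0.8), PlantedEdge(b[3], f[3], -0.8),
                 PlantedEdge(b[4], f[4], -0.8)]
        spec.planted_edges = {"ARFC": edges}
        planted = {(e.bacterial_taxon, e.fungal_taxon):
                   np.sign(e.target_spearman) for e in edges}
        return spec, planted

    def test_planted_signs_and_spurious_rate(self):
        """Planted |rho_s|=0.8 couplings at n=19 over seeds 1..20: every
        discovered planted edge carries its planted sign in >= 19/20 runs,
        and spurious edges from ~300 null pairs average < 0.5 per run."""
        sign_ok_runs = 0
        spurious_total = 0
        for seed in range(1, 21):
            spec, planted = self._spec(seed)
            table, meta = simulate_cohort(spec)
            net = build_cross_kingdom_network(table, meta, "ARFC",
                                              PipelineConfig())
            assert net.n_pairs_tested >= 300
            ok = True
            for e in net.edges:
                key = (e.bacterial_taxon, e.fungal_taxon)
                if key in planted:
                    ok &= np.sign(e.rho) == planted[key]
                else:
                    spurious_total += 1
            sign_ok_runs += ok
        assert sign_ok_runs >= 19
        assert spurious_total / 20 < 0.5


class TestGraphmlExport:
    def test_attributes_round_trip(self, tmp_path):
        import networkx as nx

        t = _toy_network_table()
        net = build_cross_kingdom_network(t, config=PipelineConfig())
        path = tmp_path / "net.graphml"
        to_graphml(net, path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == net.n_edges
        node = g.nodes["BactPos"]
        assert node["kingdom"] == "bacteria"
        assert node["color"] == "yellow" and node["shape"] == "circle"
        edge = g.edges[("BactNeg", "FungNeg")]
        assert edge["sign"] == "negative" and edge["color"] == "blue"


class TestEstimatorApi:
    def test_clone_and_params_round_trip(self):
        from sklearn.base import clone

        est = CrossKingdomNetworkInference(rho_min=0.7, q_alpha=0.01)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(rho_min=0.5)
        assert est.rho_min == 0.5
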