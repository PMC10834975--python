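import numpy as np
import pandas as pd
import pytest

from mirflux.config import OTHER_SOURCE
from mirflux.pitt import (
    build_trafficking_network,
    classify_pitt,
    flow_summary,
    network_from_sets,
    permutation_flow_test,
)

from .conftest import make_te_frames

TISSUES = ("Neu", "Int", "BWM", "Hyp", "Coel")


def all_tissues(value, ages=("D1", "D8")):
    return {(t, a): value for t in TISSUES for a in ages}


class TestClassifyPitt:
    def test_muscle_transcribed_mirna_is_pitt_elsewhere(self):
        # transcribed only in body wall muscle, detected in all five tissues
        E, T = make_te_frames(
            {"miR-1-3p": all_tissues(True)},
            {"miR-1-3p": {("BWM", "D1"): True, ("BWM", "D8"): True}},
        )
        pitt_set, table = classify_pitt(E, T)
        assert pitt_set == {"miR-1-3p"}
        for t in ("Neu", "Int", "Hyp", "Coel"):
            assert table.loc["miR-1-3p", (t, "D1")]
        assert not table.loc["miR-1-3p", ("BWM", "D1")]

    def test_ubiquitous_transcription_never_pitt(self):
        E, T = make_te_frames(
            {"m": all_tissues(True)}, {"m": all_tissues(True)}
        )
        pitt_set, _ = classify_pitt(E, T)
        assert pitt_set == set()

    def test_matches_bruteforce_double_loop(self, rng):
        matures = [f"m{i}" for i in range(25)]
        calls_e = {m: {k: bool(rng.random() < 0.5) for k in all_tissues(True)} for m in matures}
        calls_t = {m: {k: bool(rng.random() < 0.4) for k in all_tissues(True)} for m in matures}
        E, T = make_te_frames(calls_e, calls_t)
        pitt_set, table = classify_pitt(E, T)
        expect = set()
        for m in matures:
            for k in calls_e[m]:
                if calls_e[m][k] and not calls_t[m][k]:
                    expect.add(m)
                    assert table.loc[m, k]
        assert pitt_set == expect

    def test_monotone_in_t_and_e(self, rng):
        calls_e = {f"m{i}": {k: bool(rng.random() < 0.5) for k in all_tissues(True)} for i in range(10)}
        calls_t = {f"m{i}": {k: bool(rng.random() < 0.3) for k in all_tissues(True)} for i in range(10)}
        E, T = make_te_frames(calls_e, calls_t)
        base, _ = classify_pitt(E, T)
        T2 = T.copy()
        T2.loc["m0", ("Neu", "D1")] = True
        more_t, _ = classify_pitt(E, T2)
        assert more_t <= base
        E2 = E.copy()
        E2.loc["m1", ("Hyp", "D8")] = True
        more_e, _ = classify_pitt(E2, T)
        assert base <= more_e

    def test_mature_absent_from_t_map_excluded(self):
        E, T = make_te_frames({"known": all_tissues(True), "orphan": all_tissues(True)}, {})
        T = T.drop(index="orphan")
        pitt_set, table = classify_pitt(E, T)
        assert "orphan" not in pitt_set and "orphan" not in table.index


class TestBuildNetwork:
    def test_single_source_single_receiver(self):
        E, T = make_te_frames(
            {"m": {("BWM", "D1"): True, ("Int", "D1"): True}},
            {"m": {("BWM", "D1"): True}},
        )
        net = build_trafficking_network(E, T, "D1")
        assert len(net.edges) == 1
        row = net.edges.iloc[0]
        assert (row["source"], row["target"], row["weight"]) == ("BWM", "Int", 1)

    def test_product_rule_multi_source_multi_receiver(self):
        E, T = make_te_frames(
            {"m": {(t, "D1"): True for t in ("Neu", "Int", "BWM", "Coel")}},
            {"m": {("Neu", "D1"): True, ("Int", "D1"): True}},
        )
        net = build_trafficking_network(E, T, "D1")
        assert len(net.edges) == 4
        assert set(zip(net.edges["source"], net.edges["target"])) == {
            ("Neu", "BWM"), ("Neu", "Coel"), ("Int", "BWM"), ("Int", "Coel"),
        }

    def test_orphan_source_becomes_other(self):
        E, T = make_te_frames({"m": {("Hyp", "D1"): True}}, {"m": {}})
        net = build_trafficking_network(E, T, "D1")
        assert list(net.edges["source"]) == [OTHER_SOURCE]

    def test_membership_count_invariant(self, rng):
        calls_e = {f"m{i}": {k: bool(rng.random() < 0.6) for k in all_tissues(True)} for i in range(20)}
        calls_t = {f"m{i}": {k: bool(rng.random() < 0.3) for k in all_tissues(True)} for i in range(20)}
        E, T = make_te_frames(calls_e, calls_t)
        net = build_trafficking_network(E, T, "D1")
        # total edge memberships of m equal |S|*|R| (or |R| for Other source)
        member_count: dict[str, int] = {}
        for _, row in net.edges.iterrows():
            assert row["source"] != row["target"]  # no self-edges
            assert row["weight"] == len(row["mirnas"])
            for m in row["mirnas"]:
                member_count[m] = member_count.get(m, 0) + 1
        for m, S in net.sources.items():
            n_src = 1 if S == frozenset({OTHER_SOURCE}) else len(S)
            assert member_count[m] == n_src * len(net.receivers[m])

    def test_tissue_relabeling_equivariance(self, rng):
        calls_e = {f"m{i}": {k: bool(rng.random() < 0.6) for k in all_tissues(True)} for i in range(15)}
        calls_t = {f"m{i}": {k: bool(rng.random() < 0.3) for k in all_tissues(True)} for i in range(15)}
        E, T = make_te_frames(calls_e, calls_t)
        net = build_trafficking_network(E, T, "D1")
        perm = {"Neu": "Int", "Int": "BWM", "BWM": "Hyp", "Hyp": "Coel", "Coel": "Neu"}
        relabel = lambda df: df.rename(columns=perm, level=0)
        net2 = build_trafficking_network(relabel(E), relabel(T), "D1")
        mapped = {
            (perm.get(s, s), perm[t]): tuple(ms)
            for s, t, ms in zip(net.edges["source"], net.edges["target"], net.edges["mirnas"])
        }
        got = {
            (s, t): tuple(ms)
            for s, t, ms in zip(net2.edges["source"], net2.edges["target"], net2.edges["mirnas"])
        }
        assert mapped == got


class TestPermutationTest:
    def _net(self, rng, n=40):
        sources, receivers = {}, {}
        for i in range(n):
            perm = rng.permutation(5)
            s = int(rng.integers(1, 3))
            r = int(rng.integers(1, 3))
            sources[f"m{i}"] = frozenset(TISSUES[j] for j in perm[:s])
            receivers[f"m{i}"] = frozenset(TISSUES[j] for j in perm[s : s + r])
        return network_from_sets(sources, receivers, TISSUES, "D1")

    def test_fixed_seed_reproducible(self, rng):
        net = self._net(rng)
        a = permutation_flow_test(net, n_perm=100, seed=5)
        b = permutation_flow_test(net, n_perm=100, seed=5)
        np.testing.assert_array_equal(a["z"].to_numpy(), b["z"].to_numpy())

    def test_concentrated_edge_over_represented(self):
        # every miRNA on one edge: that edge enriched, others depleted
        sources = {f"m{i}": frozenset({"Neu"}) for i in range(30)}
        receivers = {f"m{i}": frozenset({"Hyp"}) for i in range(30)}
        net = network_from_sets(sources, receivers, TISSUES, "D1")
        out = permutation_flow_test(net, n_perm=300, seed=0)
        hot = out[(out["source"] == "Neu") & (out["target"] == "Hyp")]
        assert float(hot["z"].iloc[0]) > 0

    def test_z_stable_across_seeds_at_1000_perms(self, rng):
        net = self._net(rng, n=50)
        zs = []
        for seed in range(4):
            out = permutation_flow_test(net, n_perm=1000, seed=seed)
            big = out[out["weight"] >= 5].set_index(["source", "target"])["z"]
            zs.append(big)
        z = pd.concat(zs, axis=1)
        assert float(z.std(axis=1).max()) < 0.25

    def test_degenerate_null_flagged(self):
        # an Other-source miRNA received by all five tissues: every
        # permutation reproduces the identical edges, so the null is constant
        sources = {"m": frozenset()}
        receivers = {"m": frozenset(TISSUES)}
        net = network_from_sets(sources, receivers, TISSUES, "D1")
        out = permutation_flow_test(net, n_perm=50, seed=1)
        assert (out["p_normal"] == 1.0).all()
        assert out["z"].isna().all()


class TestFlowSummary:
    def test_single_edge_counts(self):
        E, T = make_te_frames(
            {f"m{i}": {("BWM", "D1"): True, ("Int", "D1"): True} for i in range(3)},
            {f"m{i}": {("BWM", "D1"): True} for i in range(3)},
        )
        flows = flow_summary({1: E}, T, ages=("D1",))
        flows = flows.set_index("tissue")
        assert flows.loc["BWM", "out_count"] == 3
        assert flows.loc["Int", "in_count"] == 3
        assert flows.loc["Neu", "out_count"] == 0

    def test_shape_tissues_by_ages_by_replicates(self, dataset, cfg):
        from mirflux.normalize import call_detection_reads
        from mirflux.pitt import replicate_expression_calls

        det = call_detection_reads(dataset.tissue_counts, 5)
        t_mature = dataset.transcription_map.to_mature(dataset.annotation)
        e_by_rep = replicate_expression_calls(
            det, dataset.tissue_counts.samples, cfg.tissues
        )
        flows = flow_summary(e_by_rep, t_mature, cfg.ages)
        assert len(flows) == 5 * 2 * 3

    def test_totals_match_bruteforce_recount(self, rng):
        calls_e = {f"m{i}": {k: bool(rng.random() < 0.6) for k in all_tissues(True)} for i in range(12)}
        calls_t = {f"m{i}": {k: bool(rng.random() < 0.3) for k in all_tissues(True)} for i in range(12)}
        E, T = make_te_frames(calls_e, calls_t)
        flows = flow_summary({1: E}, T, ages=("D1", "D8")).set_index(
            ["tissue", "age"]
        )
        for a in ("D1", "D8"):
            for t in TISSUES:
                out_expect = in_expect = 0
                for m in calls_e:
                    S = {x for x in TISSUES if calls_e[m][(x, a)] and calls_t[m][(x, a)]}
                    R = {x for x in TISSUES if calls_e[m][(x, a)] and not calls_t[m][(x, a)]}
                    if t in S and R:
                        out_expect += 1
                    if t in R:
                        in_expect += 1
                assert flows.loc[(t, a), "out_count"] == out_expect
                assert flows.loc[(t, a), "in_count"] == in_expect


class TestAlternativeNull:
    def test_pair_shuffle_null_runs_and_differs(self, rng):
        sources = {f"m{i}": frozenset({"Neu"}) for i in range(20)}
        receivers = {f"m{i}": frozenset({"Int"}) for i in range(20)}
        net = network_from_sets(sources, receivers, TISSUES, "D1")
        dp = permutation_flow_test(net, n_perm=300, seed=3)
        ps = permutation_flow_test(net, n_perm=300, seed=3, null="pair_shuffle")
        # same observed edge, different reference distributions
        assert dp["null_mean"].iloc[0] != ps["null_mean"].iloc[0]
        with pytest.raises(ValueError, match="unknown null"):
            permutation_flow_test(net, n_perm=10, seed=0, null="bogus")
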