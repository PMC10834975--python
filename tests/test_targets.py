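import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirflux.config import AnalysisConfig
from mirflux.targets import (
    SeedSite,
    anticorrelation,
    build_site_table,
    call_targets,
    category_enrichment,
    find_seed_sites,
    genage_fraction,
    pairwise_pcc,
    reverse_complement,
)

from .conftest import make_te_frames

MIR1 = "UGGAAUGUAAAGAAGUAUGUAU"  # miR-1-3p


def oracle_sites(utr: str, mirna: str) -> list[tuple[str, int, int]]:
    """Independent sliding-window oracle: compare substrings to explicit
    site strings, strongest type per seed-core locus; 1-based inclusive."""
    site8 = reverse_complement(mirna[1:8]) + "A"
    site7m8 = reverse_complement(mirna[1:8])
    site7a1 = reverse_complement(mirna[1:7]) + "A"
    out = []
    core = reverse_complement(mirna[1:7])
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core:
            continue
        if i >= 1 and utr[i - 1 : i + 7] == site8:
            out.append(("8mer", i, i + 7))
        elif i >= 1 and utr[i - 1 : i + 6] == site7m8:
            out.append(("7mer-m8", i, i + 6))
        elif utr[i : i + 7] == site7a1:
            out.append(("7mer-A1", i + 1, i + 7))
    return out


class TestSeedSites:
    def test_mir1_8mer_site_in_daf16_style_utr(self):
        # the seed match of miR-1 (positions 2-8 = GGAAUGU) is ACAUUCCA
        utr = "GGGG" + "ACAUUCCA" + "GGGG"
        sites = find_seed_sites(utr, MIR1)
        assert len(sites) == 1
        site = sites[0]
        assert site.site_type == "8mer"
        assert (site.utr_start, site.utr_end) == (5, 12)
        assert utr[site.utr_start - 1 : site.utr_end] == "ACAUUCCA"

    @pytest.mark.parametrize(
        "insert,expected",
        [("ACAUUCCA", "8mer"), ("ACAUUCCG", "7mer-m8"), ("CCAUUCCA", "7mer-A1")],
    )
    def test_site_type_classification(self, insert, expected):
        sites = find_seed_sites("GG" + insert + "GG", MIR1)
        assert [s.site_type for s in sites] == [expected]

    def test_no_complementarity_gives_empty_list(self):
        assert find_seed_sites("G" * 40, MIR1) == []

    def test_bare_core_without_flanks_not_reported(self):
        # seed core CAUUCC with neither an m8 match nor an A1 anchor
        assert find_seed_sites("GG" + "CCAUUCCG" + "GG", MIR1) == []

    def test_matches_independent_oracle_on_random_utrs(self, rng):
        mirna = "".join(rng.choice(list("ACGU"), 22))
        for _ in range(1000):
            utr = "".join(rng.choice(list("ACGU"), 30))
            got = [(s.site_type, s.utr_start, s.utr_end) for s in find_seed_sites(utr, mirna)]
            assert got == oracle_sites(utr, mirna)

    def test_alphabet_violation_rejected(self):
        with pytest.raises(ValueError, match="invalid RNA"):
            find_seed_sites("ACGTN", MIR1)

    def test_build_site_table_columns(self):
        table = build_site_table({"g": "GGACAUUCCAGG"}, {"miR-1-3p": MIR1})
        assert list(table.columns) == ["mature_id", "gene_id", "site_type", "utr_start", "utr_end"]
        assert len(table) == 1 and table["site_type"].iloc[0] == "8mer"


class TestAnticorrelation:
    def test_perfect_anticorrelation(self, rng):
        x = rng.random(10)
        assert anticorrelation(x, -x + 3.0) == pytest.approx(-1.0)

    def test_identical_profiles_positive(self, rng):
        x = rng.random(10)
        assert anticorrelation(x, x) == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.random(10), rng.random(10)
        expect = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
        assert anticorrelation(x, y) == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_returns_nan(self, rng):
        assert np.isnan(anticorrelation(np.ones(5), rng.random(5)))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            anticorrelation(rng.random(5), rng.random(6))

    def test_pairwise_matches_scalar(self, rng):
        M = pd.DataFrame(rng.random((4, 10)), index=list("abcd"))
        G = pd.DataFrame(rng.random((3, 10)), index=list("xyz"))
        C = pairwise_pcc(M, G)
        for m in M.index:
            for g in G.index:
                assert C.loc[m, g] == pytest.approx(
                    anticorrelation(M.loc[m], G.loc[g]), abs=1e-12
                )


def _target_setup(pcc_value):
    """Two conditions of data where pair (m, g) has a fixed profile PCC."""
    conditions = [("Neu", "D1"), ("Neu", "D8"), ("Int", "D1"), ("Int", "D8"), ("BWM", "D1")]
    rng = np.random.default_rng(0)
    x = rng.random(len(conditions) * 2).reshape(-1)[: len(conditions)]
    mirna_prof = x
    gene_prof = -x if pcc_value < 0 else x
    samples = pd.DataFrame(
        {
            "tissue": [c[0] for c in conditions],
            "age": [c[1] for c in conditions],
            "replicate": 1,
            "count_unit": "reads",
        },
        index=[f"s{i}" for i in range(len(conditions))],
    )
    mirna_values = pd.DataFrame([mirna_prof], index=["m"], columns=samples.index)
    gene_values = pd.DataFrame([gene_prof + 2.0], index=["g"], columns=samples.index)
    cols = pd.MultiIndex.from_tuples(conditions, names=["tissue", "age"])
    detection = pd.DataFrame(True, index=["m"], columns=cols)
    sites = pd.DataFrame(
        [{"mature_id": "m", "gene_id": "g", "site_type": "8mer", "utr_start": 1, "utr_end": 8}]
    )
    return mirna_values, samples, gene_values, sites, detection


class TestCallTargets:
    def test_site_with_weak_anticorrelation_rejected(self):
        mv, samples, gv, sites, det = _target_setup(+1.0)
        pitt = det & False
        calls = call_targets(mv, samples, gv, samples, sites, det, pitt, AnalysisConfig())
        assert calls.empty

    def test_anticorrelated_site_called_with_autonomy(self):
        mv, samples, gv, sites, det = _target_setup(-1.0)
        pitt = det & False
        pitt.loc["m", ("Int", "D1")] = True  # PITT in intestine at day 1
        calls = call_targets(mv, samples, gv, samples, sites, det, pitt, AnalysisConfig())
        assert len(calls) == 5
        by_cond = calls.set_index(["tissue", "age"])["autonomy"]
        assert by_cond.loc[("Int", "D1")] == "non_autonomous"
        assert by_cond.loc[("Neu", "D1")] == "autonomous"

    def test_autonomy_is_a_partition(self, dataset, cfg):
        from mirflux import normalize, pitt as pitt_mod
        from mirflux.targets import build_site_table

        tpm = normalize.compute_tpm(dataset.tissue_counts)
        qnorm = normalize.log2_and_quantile_normalize(tpm)
        det = normalize.call_detection_reads(dataset.tissue_counts, 5)
        t_mature = dataset.transcription_map.to_mature(dataset.annotation)
        e_calls = pitt_mod.expression_calls(det, cfg.tissues)
        _, pitt_table = pitt_mod.classify_pitt(e_calls, t_mature)
        sites = build_site_table(dataset.utr_seqs, dataset.mirna_seqs)
        calls = call_targets(
            qnorm.values, qnorm.samples, dataset.mrna_values, dataset.mrna_samples,
            sites, e_calls, pitt_table, cfg,
        )
        assert len(calls) > 0
        assert set(calls["autonomy"]) <= {"autonomous", "non_autonomous"}
        for _, sub in calls.groupby(["tissue", "age"]):
            n_a = (sub["autonomy"] == "autonomous").sum()
            n_n = (sub["autonomy"] == "non_autonomous").sum()
            assert n_a + n_n == len(sub)


class TestGenageFraction:
    def test_disjoint_list_gives_zero(self):
        calls = pd.DataFrame({"gene_id": ["g1", "g2"]})
        assert genage_fraction(calls, {"other"})[0] == 0.0

    def test_superset_list_gives_one(self):
        calls = pd.DataFrame({"gene_id": ["g1", "g2", "g1"]})
        assert genage_fraction(calls, {"g1", "g2", "g3"})[0] == 1.0

    def test_matches_set_arithmetic(self, rng):
        genes = [f"g{i}" for i in range(50)]
        calls = pd.DataFrame({"gene_id": rng.choice(genes, 80)})
        listed = set(rng.choice(genes, 20, replace=False))
        frac, _ = genage_fraction(calls, listed)
        uniq = set(calls["gene_id"])
        assert frac == pytest.approx(len(uniq & listed) / len(uniq))


def hypergeom_tail(a, b, c, d):
    """P(X >= a) for the 2x2 table margins, by direct summation."""
    N, K, n = a + b + c + d, a + c, a + b
    return sum(stats.hypergeom.pmf(k, N, K, n) for k in range(a, min(K, n) + 1))


class TestCategoryEnrichment:
    def _annot(self, members, background):
        rows = []
        for g in background:
            c1 = "InCat" if g in members else "Out"
            rows.append({"gene_id": g, "Category1": c1, "Category2": f"{c1}:s", "Category3": f"{c1}:s:l"})
        return pd.DataFrame(rows)

    def test_matches_hypergeometric_tail_oracle(self):
        # 8 targets in category, 2 outside; background adds 10 in, 80 out
        targets = {f"t{i}" for i in range(10)}
        bg_extra = {f"b{i}" for i in range(90)}
        members = {f"t{i}" for i in range(8)} | {f"b{i}" for i in range(10)}
        background = targets | bg_extra
        annot = self._annot(members, background)
        out = category_enrichment(targets, background, annot)
        row = out[(out["level"] == "Category1") & (out["category"] == "InCat")].iloc[0]
        assert row["p"] == pytest.approx(hypergeom_tail(8, 2, 10, 80), abs=1e-12)

    def test_targets_equal_background_gives_p_one(self):
        background = {f"g{i}" for i in range(30)}
        members = {f"g{i}" for i in range(10)}
        out = category_enrichment(background, background, self._annot(members, background))
        np.testing.assert_allclose(out["p"].to_numpy(), 1.0, rtol=1e-12)

    def test_doubling_cells_sharpens_enrichment(self):
        p = []
        for mult in (1, 2):
            a, b, c, d = 8 * mult, 2 * mult, 10 * mult, 80 * mult
            p.append(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        assert p[1] < p[0]

    def test_background_must_contain_targets(self):
        with pytest.raises(ValueError, match="background"):
            category_enrichment({"x"}, {"y"}, self._annot(set(), {"y"}))


class TestReplicateProfileMode:
    def test_replicate_mode_recovers_planted_pairs(self, dataset, cfg):
        from mirflux import normalize, pitt as pitt_mod

        tpm = normalize.compute_tpm(dataset.tissue_counts)
        qnorm = normalize.log2_and_quantile_normalize(tpm)
        det = normalize.call_detection_reads(dataset.tissue_counts, 5)
        t_mature = dataset.transcription_map.to_mature(dataset.annotation)
        e_calls = pitt_mod.expression_calls(det, cfg.tissues)
        _, pitt_table = pitt_mod.classify_pitt(e_calls, t_mature)
        sites = build_site_table(dataset.utr_seqs, dataset.mirna_seqs)
        calls = call_targets(
            qnorm.values, qnorm.samples, dataset.mrna_values, dataset.mrna_samples,
            sites, e_calls, pitt_table, cfg, profile="replicates",
        )
        planted = set(dataset.truth.target_pairs)
        got = set(zip(calls["mature_id"], calls["gene_id"]))
        assert len(got & planted) / len(planted) >= 0.8
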