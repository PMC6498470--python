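"""Differential methylation: probe calls, promoter summaries, persistence,
and flank-expanded CpG/off-target intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimem import methylation as meth
from epimem import synthetic as syn
from epimem.offtarget import OffTargetSite


def small_matrix(values, samples_meta):
    """values: dict probe -> dict sample -> beta."""
    betas = pd.DataFrame(values).T
    betas.index.name = "probe"
    samples = pd.DataFrame(samples_meta, columns=["sample", "condition",
                                                  "timepoint_days", "replicate"])
    return betas, samples


META_2V2 = [("t1", "treated", 17, 1), ("t2", "treated", 17, 2),
            ("c1", "dCas9", 17, 1), ("c2", "dCas9", 17, 2)]


class TestComputeBeta:
    def test_symmetry(self):
        assert meth.compute_beta(5.0, 5.0) == 0.5

    def test_boundaries(self):
        assert meth.compute_beta(0.0, 7.0) == 0.0
        assert meth.compute_beta(7.0, 0.0) == 1.0

    def test_direct_arithmetic(self):
        assert meth.compute_beta(48.0, 52.0) == pytest.approx(0.48)

    def test_zero_total_is_missing_not_zero(self):
        assert np.isnan(meth.compute_beta(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            meth.compute_beta(-1.0, 1.0)

    def test_vectorized(self):
        out = meth.compute_beta([1, 0, 0], [1, 1, 0])
        assert out[0] == 0.5 and out[1] == 0.0 and np.isnan(out[2])


class TestCallDifferentialProbes:
    def test_paper_scale_delta(self):
        betas, samples = small_matrix(
            {"p1": {"t1": 0.48, "t2": 0.48, "c1": 0.07, "c2": 0.07}}, META_2V2)
        res = meth.call_differential_probes(betas, samples, "treated", "dCas9")
        row = res.calls.iloc[0]
        assert row["delta_beta"] == pytest.approx(0.41)
        assert row["direction"] == "hyper"

    def test_null_comparison(self):
        betas, samples = small_matrix(
            {f"p{i}": {s: 0.3 for s, *_ in META_2V2} for i in range(10)}, META_2V2)
        res = meth.call_differential_probes(betas, samples, "treated", "dCas9")
        assert (res.calls["direction"] == "unchanged").all()

    def test_planted_probes_exactly_recovered(self):
        cfg = syn.SimConfig(seed=3, contig_length=120_000, n_genes=24,
                            planted_dmr_genes=tuple(f"GENE{i:04d}" for i in (1, 2, 3, 4)))
        genome = syn.make_genome(cfg)
        _, manifest = syn.make_annotation(genome, cfg)
        betas, samples, truth = syn.simulate_beta_matrix(manifest, cfg)
        sheet = samples[samples["timepoint_days"] == 17]
        res = meth.call_differential_probes(betas, sheet, "treated", "dCas9")
        assert len(truth.per_probe_planted_delta) == 56
        assert res.hyper_probes == set(truth.per_probe_planted_delta)

    def test_missing_probe_excluded_and_tallied(self):
        betas, samples = small_matrix(
            {"p1": {"t1": 0.5, "t2": 0.5, "c1": 0.1, "c2": 0.1},
             "p2": {"t1": np.nan, "t2": 0.5, "c1": 0.1, "c2": 0.1}}, META_2V2)
        res = meth.call_differential_probes(betas, samples, "treated", "dCas9")
        assert res.n_excluded == 1 and res.excluded_probes == ("p2",)
        assert list(res.calls["probe"]) == ["p1"]

    def test_partition_conservation(self):
        rng = np.random.default_rng(0)
        n = 500
        vals = rng.random((n, 4))
        vals[rng.random(n) < 0.1, 0] = np.nan
        betas = pd.DataFrame(vals, columns=[m[0] for m in META_2V2],
                             index=[f"p{i}" for i in range(n)])
        samples = pd.DataFrame(META_2V2, columns=["sample", "condition",
                                                  "timepoint_days", "replicate"])
        res = meth.call_differential_probes(betas, samples, "treated", "dCas9")
        counts = res.calls["direction"].value_counts()
        total = (counts.get("hyper", 0) + counts.get("hypo", 0)
                 + counts.get("unchanged", 0) + res.n_excluded)
        assert total == n

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        betas = pd.DataFrame(rng.random((300, 4)),
                             columns=[m[0] for m in META_2V2],
                             index=[f"p{i}" for i in range(300)])
        samples = pd.DataFrame(META_2V2, columns=["sample", "condition",
                                                  "timepoint_days", "replicate"])
        prev_hyper = prev_hypo = None
        for thr in (0.1, 0.2, 0.3, 0.5, 0.8):
            res = meth.call_differential_probes(betas, samples, "treated",
                                                "dCas9", threshold=thr)
            n_hyper = len(res.hyper_probes)
            n_hypo = len(res.hypo_probes)
            if prev_hyper is not None:
                assert n_hyper <= prev_hyper and n_hypo <= prev_hypo
            prev_hyper, prev_hypo = n_hyper, n_hypo

    def test_hyper_hypo_symmetry(self):
        rng = np.random.default_rng(2)
        betas = pd.DataFrame(rng.random((300, 4)),
                             columns=[m[0] for m in META_2V2],
                             index=[f"p{i}" for i in range(300)])
        samples = pd.DataFrame(META_2V2, columns=["sample", "condition",
                                                  "timepoint_days", "replicate"])
        res = meth.call_differential_probes(betas, samples, "treated", "dCas9")
        flipped = meth.call_differential_probes(1.0 - betas, samples,
                                                "treated", "dCas9")
        assert res.hyper_probes == flipped.hypo_probes
        assert res.hypo_probes == flipped.hyper_probes

    def test_unknown_condition(self):
        betas, samples = small_matrix(
            {"p1": {"t1": 0.5, "t2": 0.5, "c1": 0.1, "c2": 0.1}}, META_2V2)
        with pytest.raises(ValueError, match="condition"):
            meth.call_differential_probes(betas, samples, "nope", "dCas9")

    def test_out_of_range_beta_rejected(self):
        betas, samples = small_matrix(
            {"p1": {"t1": 1.5, "t2": 0.5, "c1": 0.1, "c2": 0.1}}, META_2V2)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            meth.call_differential_probes(betas, samples, "treated", "dCas9")


def make_calls(hyper_probes, all_probes):
    return pd.DataFrame({
        "probe": all_probes,
        "mean_beta_treated": [0.5 if p in hyper_probes else 0.1 for p in all_probes],
        "mean_beta_control": [0.1] * len(all_probes),
        "delta_beta": [0.4 if p in hyper_probes else 0.0 for p in all_probes],
        "direction": ["hyper" if p in hyper_probes else "unchanged"
                      for p in all_probes],
    })


def make_manifest(gene_probes, region_group="TSS200"):
    rows = []
    pos = 100
    for gene, probes in gene_probes.items():
        for p in probes:
            rows.append((p, "c1", pos, gene, region_group))
            pos += 50
    return pd.DataFrame(rows, columns=["probe", "contig", "pos_1based",
                                       "gene", "region_group"])


class TestSummarizePromoters:
    def test_four_probes_is_dmp(self):
        probes = [f"p{i}" for i in range(6)]
        manifest = make_manifest({"SHOX2like": probes})
        calls = make_calls(set(probes[:4]), probes)
        s = meth.summarize_promoters(calls, manifest)
        assert s.loc[s["gene"] == "SHOX2like", "is_dmp"].iloc[0]
        assert s.loc[s["gene"] == "SHOX2like", "n_hyper_probes"].iloc[0] == 4

    def test_exactly_three_is_not_dmp(self):
        probes = [f"p{i}" for i in range(6)]
        manifest = make_manifest({"g": probes})
        s = meth.summarize_promoters(make_calls(set(probes[:3]), probes), manifest)
        assert not s["is_dmp"].iloc[0]

    def test_twelve_probe_gene_ranks_first(self):
        gp = {"HER2like": [f"a{i}" for i in range(12)],
              "other": [f"b{i}" for i in range(12)]}
        manifest = make_manifest(gp)
        hyper = set(gp["HER2like"]) | set(gp["other"][:4])
        s = meth.summarize_promoters(make_calls(hyper, gp["HER2like"] + gp["other"]),
                                     manifest)
        assert s.iloc[0]["gene"] == "HER2like"
        assert s.iloc[0]["n_hyper_probes"] == 12
        assert s["is_dmp"].all()

    def test_non_promoter_probes_ignored(self):
        probes = [f"p{i}" for i in range(8)]
        manifest = make_manifest({"g": probes}, region_group="other")
        s = meth.summarize_promoters(make_calls(set(probes), probes), manifest,
                                     include_all=True)
        assert s.empty

    def test_multi_gene_probe_counts_for_each(self):
        probes = [f"p{i}" for i in range(4)]
        manifest = make_manifest({"gA;gB": probes})
        s = meth.summarize_promoters(make_calls(set(probes), probes), manifest)
        assert set(s["gene"]) == {"gA", "gB"}
        assert (s["n_hyper_probes"] == 4).all() and s["is_dmp"].all()

    def test_zero_hyper_genes_omitted_unless_flagged(self):
        manifest = make_manifest({"g1": ["p1"], "g2": ["p2"]})
        calls = make_calls({"p1"}, ["p1", "p2"])
        assert set(meth.summarize_promoters(calls, manifest, min_probes=0)["gene"]) == {"g1"}
        full = meth.summarize_promoters(calls, manifest, include_all=True)
        assert set(full["gene"]) == {"g1", "g2"}

    def test_min_probes_monotonicity(self):
        probes = [f"p{i}" for i in range(20)]
        manifest = make_manifest({f"g{i}": probes[2 * i: 2 * i + 2]
                                  for i in range(10)})
        calls = make_calls(set(probes[:14]), probes)
        prev = None
        for mp in range(0, 6):
            n = int(meth.summarize_promoters(calls, manifest, min_probes=mp,
                                             include_all=True)["is_dmp"].sum())
            if prev is not None:
                assert n <= prev
            prev = n

    def test_unknown_probe_rejected(self):
        manifest = make_manifest({"g": ["p1"]})
        with pytest.raises(ValueError, match="absent from manifest"):
            meth.summarize_promoters(make_calls({"zz"}, ["zz"]), manifest)


class TestPersistenceOverlap:
    def test_printed_counts_give_93pct(self):
        a = {f"cg{i}" for i in range(2966)}
        b = {f"cg{i}" for i in range(1876)} | {f"x{i}" for i in range(2018 - 1876)}
        res = meth.persistence_overlap(a, b)
        assert len(res.overlap) == 1876
        assert (res.size_a, res.size_b) == (2966, 2018)
        assert res.concordance_pct == pytest.approx(92.96, abs=0.01)
        assert round(res.concordance_pct) == 93

    def test_identity_100pct(self):
        a = {"x", "y", "z"}
        assert meth.persistence_overlap(a, a).concordance_pct == 100.0

    def test_disjoint_0pct(self):
        assert meth.persistence_overlap({"a"}, {"b"}).concordance_pct == 0.0

    def test_empty_flagged_undefined(self):
        res = meth.persistence_overlap(set(), {"a"})
        assert res.undefined and res.concordance_pct is None

    def test_symmetric(self):
        a = {f"a{i}" for i in range(30)}
        b = {f"a{i}" for i in range(20)} | {"q"}
        r1 = meth.persistence_overlap(a, b)
        r2 = meth.persistence_overlap(b, a)
        assert r1.concordance_pct == r2.concordance_pct
        assert r1.overlap == r2.overlap

    def test_alternative_denominators(self):
        a, b = {"1", "2", "3", "4"}, {"3", "4", "5"}
        assert meth.persistence_overlap(a, b, "a").concordance_pct == pytest.approx(50.0)
        assert meth.persistence_overlap(a, b, "union").concordance_pct == pytest.approx(40.0)

    @given(st.sets(st.integers(0, 50), min_size=1),
           st.sets(st.integers(0, 50), min_size=1))
    @settings(max_examples=100, deadline=None)
    def test_concordance_bounds_property(self, a, b):
        res = meth.persistence_overlap({str(x) for x in a}, {str(x) for x in b})
        assert 0.0 <= res.concordance_pct <= 100.0


class TestVenn:
    def summaries(self, genes):
        return pd.DataFrame({"gene": list(genes), "n_hyper_probes": 5,
                             "n_promoter_probes": 14,
                             "mean_beta_treated": 0.5, "mean_beta_control": 0.1,
                             "is_dmp": True})

    def test_identical_all_shared(self):
        s = self.summaries(["a", "b"])
        v = meth.venn_dmps(s, s)
        assert v.shared == {"a", "b"} and not v.a_only and not v.b_only

    def test_shared_subset_property(self):
        va = self.summaries(["a", "b", "c"])
        vb = self.summaries(["b", "c", "d"])
        v = meth.venn_dmps(va, vb)
        assert v.shared <= set(va["gene"]) and v.shared <= set(vb["gene"])
        assert v.a_only == {"a"} and v.b_only == {"d"}

    def test_planted_persistent_vs_transient(self):
        cfg = syn.SimConfig(seed=5, planted_dmr_genes=("GENE0001",),
                            transient_dmr_genes=("GENE0002",))
        genome = syn.make_genome(cfg)
        _, manifest = syn.make_annotation(genome, cfg)
        betas, samples, _ = syn.simulate_beta_matrix(manifest, cfg)
        summaries = {}
        for tp in (17, 24):
            sheet = samples[samples["timepoint_days"] == tp]
            res = meth.call_differential_probes(betas, sheet, "treated", "dCas9")
            summaries[tp] = meth.summarize_promoters(res, manifest)
        v = meth.venn_dmps(summaries[17], summaries[24])
        assert v.shared == {"GENE0001"}
        assert v.a_only == {"GENE0002"} and not v.b_only


def site(contig, start, end, strand="+"):
    return OffTargetSite(contig, start, end, strand, 1, "A" * (end - start), "AGG")


class TestHyperCpgsNearOfftargets:
    manifest = pd.DataFrame({
        "probe": ["p1", "p2"],
        "contig": ["c1", "c1"],
        "pos_1based": [1000, 5000],
        "gene": ["g1", "g2"],
        "region_group": ["TSS200", "TSS200"],
    })

    def calls(self, hyper):
        return make_calls(set(hyper), ["p1", "p2"])

    def test_beyond_flank_empty(self):
        sites = [site("c1", 1300, 1319)]  # 300 bp from the CpG at 1000
        assert meth.hyper_cpgs_near_offtargets(self.calls(["p1"]),
                                               self.manifest, sites) == []

    def test_within_flank_one_pair(self):
        sites = [site("c1", 1099, 1118)]  # 100 bp away
        pairs = meth.hyper_cpgs_near_offtargets(self.calls(["p1"]),
                                                self.manifest, sites)
        assert len(pairs) == 1 and pairs[0][0] == "p1"

    def test_non_hyper_probe_ignored(self):
        sites = [site("c1", 4990, 5009)]
        assert meth.hyper_cpgs_near_offtargets(self.calls(["p1"]),
                                               self.manifest, sites) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_randomized_against_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_probes, n_sites, flank = 60, 80, 146
        manifest = pd.DataFrame({
            "probe": [f"p{i}" for i in range(n_probes)],
            "contig": rng.choice(["c1", "c2"], n_probes),
            "pos_1based": rng.integers(200, 20_000, n_probes),
            "gene": "g",
            "region_group": "TSS200",
        })
        sites = []
        for _ in range(n_sites):
            start = int(rng.integers(0, 20_000))
            sites.append(site(str(rng.choice(["c1", "c2"])), start, start + 19))
        calls = make_calls(set(manifest["probe"]), list(manifest["probe"]))
        got = {(p, s.contig, s.start) for p, s in
               meth.hyper_cpgs_near_offtargets(calls, manifest, sites, flank)}
        expected = set()
        for r in manifest.itertuples():
            lo, hi = max(0, r.pos_1based - 1 - flank), r.pos_1based + flank
            for s in sites:
                if s.contig == r.contig and s.start < hi and s.end > lo:
                    expected.add((r.probe, s.contig, s.start))
        assert got == expected


class TestIO:
    def test_beta_matrix_roundtrip(self, tmp_path):
        betas, _ = small_matrix(
            {"p1": {"t1": 0.5, "t2": np.nan, "c1": 0.1, "c2": 0.1}}, META_2V2)
        path = tmp_path / "b.tsv"
        betas.to_csv(path, sep="\t", na_rep="NA")
        back = meth.read_beta_matrix(path)
        pd.testing.assert_frame_equal(back, betas)

    def test_sample_sheet_validation(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample\tfoo\nx\t1\n")
        with pytest.raises(ValueError, match="missing columns"):
            meth.read_sample_sheet(p)
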