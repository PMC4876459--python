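"""The ultra-rare functional-variant filter cascade."""

import itertools

import numpy as np
import pytest

from pedprio.intervals import RegionSet
from pedprio.variants import (
    CascadeConfig,
    FUNCTIONAL_CLASSES,
    VariantRecord,
    filter_carrier,
    filter_consequence,
    filter_conservation,
    filter_frequency,
    filter_regions,
    read_variant_table,
    run_cascade,
    write_variant_table,
)


def V(pos=100, chrom="chr1", ref="A", alt="T", gene="G1", consequence="missense_snv",
      frequencies=None, gerp=5.0, genotypes=None):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, consequence=consequence,
        frequencies=frequencies or {}, gerp=gerp, genotypes=genotypes or {},
    )


# Table-anchored records: a conserved missense SNV that survives the cascade
# and a frameshift insertion not carried by the proband.
TTR_LIKE = VariantRecord(
    chrom="18", pos=29172937, ref="G", alt="T", gene="TTR",
    consequence="missense_snv", frequencies={}, gerp=5.71,
    genotypes={"proband": 1},
)
NEDD4_LIKE = VariantRecord(
    chrom="15", pos=56207937, ref="C", alt="CA", gene="NEDD4",
    consequence="frameshift", frequencies={}, gerp=None,
    genotypes={"proband": 0},
)


def random_table(rng, n=60):
    classes = sorted(FUNCTIONAL_CLASSES | {"other"})
    out = []
    for i in range(n):
        cls = classes[rng.integers(len(classes))]
        gerp = None if rng.random() < 0.2 else float(rng.uniform(-3, 6.18))
        freqs = {}
        for panel in ("a", "b"):
            if rng.random() < 0.5:
                freqs[panel] = float(rng.uniform(0, 0.02))
        gt = {}
        if rng.random() < 0.8:
            gt["proband"] = int(rng.integers(0, 3))
        out.append(
            V(pos=int(rng.integers(1, 10_000)), gene=f"g{rng.integers(20)}",
              consequence=cls, frequencies=freqs, gerp=gerp, genotypes=gt)
        )
    return out


class TestRecordValidation:
    def test_rejects_bad_fields(self):
        with pytest.raises(ValueError, match="1-based"):
            V(pos=0)
        with pytest.raises(ValueError, match="ref == alt"):
            V(ref="A", alt="A")
        with pytest.raises(ValueError, match="consequence"):
            V(consequence="stop_gained")
        with pytest.raises(ValueError, match="frequency"):
            V(frequencies={"a": 1.5})


class TestFrequencyFilter:
    def test_below_threshold_and_absent_panels_pass(self):
        v = V(frequencies={"a": 0.004})
        assert filter_frequency([v]) == [v]
        v2 = V(frequencies={})
        assert filter_frequency([v2]) == [v2]

    def test_boundary_is_exclusion(self):
        # the rule is >= 0.5%, so exactly 0.005 is removed
        assert filter_frequency([V(frequencies={"a": 0.005})]) == []

    def test_any_panel_at_threshold_excludes(self):
        assert filter_frequency([V(frequencies={"a": 0.0001, "b": 0.01})]) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_frequency([], threshold=-0.1)

    def test_matches_brute_force_rescan(self, rng):
        table = random_table(rng, 200)
        got = {v.key for v in filter_frequency(table, 0.005)}
        want = {
            v.key for v in table
            if not any(f >= 0.005 for f in v.frequencies.values())
        }
        assert got == want


class TestConsequenceFilter:
    def test_whitelist_membership(self, rng):
        table = random_table(rng, 200)
        got = filter_consequence(table)
        assert {v.key for v in got} == {
            v.key for v in table if v.consequence in FUNCTIONAL_CLASSES
        }
        assert all(v.consequence != "other" for v in got)

    def test_frameshift_is_functional(self):
        assert filter_consequence([NEDD4_LIKE]) == [NEDD4_LIKE]

    def test_synonymous_like_removed(self):
        assert filter_consequence([V(consequence="other")]) == []


class TestConservationFilter:
    def test_conserved_missense_kept(self):
        assert filter_conservation([TTR_LIKE]) == [TTR_LIKE]

    def test_weakly_conserved_snv_removed(self):
        assert filter_conservation([V(gerp=1.5)]) == []

    def test_boundary_gerp_kept(self):
        # the removal rule is GERP < 2.0, so exactly 2.0 stays
        assert filter_conservation([V(gerp=2.0)]) != []

    def test_indels_exempt_missing_snv_gerp_removed(self):
        indel = V(consequence="frameshift", alt="AT", gerp=None)
        snv_no_gerp = V(gerp=None)
        assert filter_conservation([indel, snv_no_gerp]) == [indel]

    def test_matches_brute_force(self, rng):
        table = random_table(rng, 200)
        got = {v.key for v in filter_conservation(table)}
        want = {
            v.key for v in table
            if v.consequence in ("frameshift", "inframe_indel")
            or (v.gerp is not None and v.gerp >= 2.0)
        }
        assert got == want


class TestRegionAndCarrierFilters:
    def test_empty_regions_remove_everything(self, rng):
        assert filter_regions(random_table(rng), RegionSet()) == []

    def test_covering_region_keeps_everything(self, rng):
        table = random_table(rng)
        all_cover = RegionSet({"chr1": [(0, 10_001)]})
        assert filter_regions(table, all_cover) == table

    def test_membership_matches_oracle(self, rng):
        table = random_table(rng, 200)
        regions = RegionSet({"chr1": [(100, 2_000), (5_000, 7_500)]})
        got = {v.key for v in filter_regions(table, regions)}
        want = {
            v.key for v in table
            if (100 <= v.pos - 1 < 2_000) or (5_000 <= v.pos - 1 < 7_500)
        }
        assert got == want

    def test_non_carrier_removed_carrier_kept(self):
        # mirrors excluding a variant the proband does not share
        assert filter_carrier([NEDD4_LIKE], "proband") == []
        assert filter_carrier([TTR_LIKE], "proband") == [TTR_LIKE]

    def test_require_ref_inverts(self):
        assert filter_carrier([NEDD4_LIKE], "proband", require_alt=False) == [NEDD4_LIKE]

    def test_missing_genotype_retained_and_flagged(self):
        v = V(genotypes={})
        flagged = []
        assert filter_carrier([v], "proband", flagged=flagged) == [v]
        assert flagged == [v.key]

    def test_matches_oracle(self, rng):
        table = random_table(rng, 200)
        got = {v.key for v in filter_carrier(table, "proband")}
        want = {
            v.key for v in table
            if v.genotypes.get("proband") is None or v.genotypes["proband"] >= 1
        }
        assert got == want


class TestCascade:
    def test_empty_input(self):
        report = run_cascade([], CascadeConfig(regions=RegionSet(), carrier_sample="p"))
        assert all(n_in == 0 and n_out == 0 for _, n_in, n_out in report.stages)
        assert report.survivors == [] and report.genes == []

    def test_hand_traced_toy(self):
        """Six variants, each stage removes exactly one; one survivor."""
        regions = RegionSet({"chr1": [(0, 1_000)]})
        common = V(pos=10, gene="g_common", frequencies={"a": 0.01})
        synon = V(pos=20, gene="g_syn", consequence="other")
        drift = V(pos=30, gene="g_drift", gerp=0.5)
        outside = V(pos=5_000, gene="g_out")
        notshared = V(pos=40, gene="g_ns", genotypes={"pb": 0})
        causal = V(pos=50, gene="g_causal", genotypes={"pb": 1})
        table = [common, synon, drift, outside, notshared, causal]
        report = run_cascade(
            table, CascadeConfig(regions=regions, carrier_sample="pb")
        )
        assert [(s, a, b) for s, a, b in report.stages] == [
            ("frequency", 6, 5), ("consequence", 5, 4), ("conservation", 4, 3),
            ("regions", 3, 2), ("carrier", 2, 1),
        ]
        assert report.survivors == [causal]
        assert report.genes == ["g_causal"]

    def test_counts_non_increasing_and_gene_bound(self, rng):
        for _ in range(20):
            report = run_cascade(random_table(rng), CascadeConfig(carrier_sample="proband"))
            counts = [report.stages[0][1]] + [b for _, _, b in report.stages]
            assert counts == sorted(counts, reverse=True)
            assert len(report.genes) <= report.n_survivors

    def test_stage_order_invariance(self, rng):
        """All filters are pointwise, so any stage permutation agrees."""
        regions = RegionSet({"chr1": [(0, 5_000)]})
        filters = [
            lambda vs: filter_frequency(vs, 0.005),
            filter_consequence,
            lambda vs: filter_conservation(vs, 2.0),
            lambda vs: filter_regions(vs, regions),
            lambda vs: filter_carrier(vs, "proband"),
        ]
        for _ in range(10):
            table = random_table(rng, 80)
            reference = None
            for perm in itertools.permutations(range(5)):
                cur = table
                for i in perm:
                    cur = filters[i](cur)
                keys = {v.key for v in cur}
                if reference is None:
                    reference = keys
                assert keys == reference


class TestVariantIO:
    def test_round_trip(self, tmp_path, rng):
        table = random_table(rng, 50) + [TTR_LIKE, NEDD4_LIKE]
        path = tmp_path / "variants.tsv"
        write_variant_table(table, path)
        back = read_variant_table(path)
        assert len(back) == len(table)
        for a, b in zip(table, back):
            assert a.key == b.key and a.gene == b.gene
            assert a.consequence == b.consequence
            assert (a.gerp is None) == (b.gerp is None)
            if a.gerp is not None:
                assert b.gerp == pytest.approx(a.gerp, abs=1e-5)
            assert dict(a.genotypes) == dict(b.genotypes)
            assert dict(b.frequencies) == pytest.approx(dict(a.frequencies), abs=1e-7)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\n1\t2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_variant_table(path)
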