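import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonotrace.io_formats import ValidationError
from clonotrace.somatic import (
    FilterThresholds,
    annotate_consequences,
    call_somatic,
    classify_consequence,
    compute_tmb,
    filter_variant_calls,
    merge_caller_sets,
    SomaticVariant,
)
from clonotrace.synthetic import CohortConfig, simulate_paired_variants

from conftest import make_call, random_calls
from oracles import consequence_by_retranslation, somatic_row_check


class TestFilter:
    @pytest.mark.parametrize(
        "gq,alt,depth,kept",
        [
            (29, 5, 50, False),   # GQ below 30
            (30, 3, 10, True),    # GQ, alt reads and depth at inclusive boundaries
            (99, 2, 40, False),   # alt reads below 3
            (99, 4, 9, False),    # depth below 10
            (99, 4, 100, False),  # VAF 0.04 below 0.05
        ],
    )
    def test_boundaries(self, gq, alt, depth, kept):
        call = make_call(depth=depth, alt_reads=alt, gq=gq)
        assert (call in filter_variant_calls([call])) == kept

    def test_exact_boundary_retained(self):
        # all four predicates at their inclusive boundary
        call = make_call(depth=60, alt_reads=3, gq=30, vaf=0.05)
        assert filter_variant_calls([call]) == [call]

    def test_5000_random_calls_match_row_oracle(self):
        calls = random_calls(5000, seed=3)
        t = FilterThresholds()
        kept = set(id(c) for c in filter_variant_calls(calls, t))
        for c in calls:
            expected = (
                c.genotype_quality >= 30 and c.alt_reads >= 3
                and c.vaf >= 0.05 and c.depth >= 10
            )
            assert (id(c) in kept) == expected

    def test_empty_input(self):
        assert filter_variant_calls([]) == []


class TestMerge:
    def test_single_caller_provenance(self):
        a = make_call(pos=1)
        merged = merge_caller_sets({"callerA": [a], "callerB": [], "callerC": []})
        assert len(merged) == 1 and merged[0].callers == frozenset({"callerA"})

    def test_three_caller_union(self):
        a = make_call(pos=1, depth=40, alt_reads=10)
        b = make_call(pos=1, depth=80, alt_reads=20)
        c = make_call(pos=1, depth=60, alt_reads=15)
        merged = merge_caller_sets({"callerA": [a], "callerB": [b], "callerC": [c]})
        assert len(merged) == 1
        assert merged[0].callers == frozenset({"callerA", "callerB", "callerC"})
        assert merged[0].depth == 80  # numeric fields from deepest caller

    def test_union_matches_set_oracle(self):
        sets = {
            f"caller{x}": random_calls(300, seed=i)
            for i, x in enumerate("ABC")
        }
        merged = merge_caller_sets(sets)
        expected = set()
        for calls in sets.values():
            expected |= {c.key for c in calls}
        assert {c.key for c in merged} == expected

    def test_conflicting_ref_rejected(self):
        a = make_call(pos=5, ref="A", alt="T")
        b = make_call(pos=5, ref="C", alt="T")
        with pytest.raises(ValidationError, match="conflicting REF"):
            merge_caller_sets({"callerA": [a], "callerB": [b]})


class TestCallSomatic:
    def _pooled(self, key, vafs):
        idx = pd.MultiIndex.from_tuples([key], names=["chrom", "pos", "ref", "alt"])
        return pd.DataFrame([vafs], index=idx, columns=[f"N{i}" for i in range(len(vafs))])

    def test_clean_somatic_retained(self):
        t = make_call(pos=9, depth=50, alt_reads=20)  # vaf 0.40
        n = make_call(pos=9, depth=30, alt_reads=0)
        out = call_somatic([t], [n], None)
        assert len(out) == 1 and out[0].normal_vaf == 0.0

    def test_normal_vaf_above_cap_rejected(self):
        t = make_call(pos=9, depth=100, alt_reads=40)
        n = make_call(pos=9, depth=100, alt_reads=6)  # normal vaf 0.06 > 0.05
        assert call_somatic([t], [n], None) == []

    def test_three_pooled_hits_rejected(self):
        t = make_call(pos=9, depth=100, alt_reads=40)
        n = make_call(pos=9, depth=100, alt_reads=0)
        pooled = self._pooled(t.key, [0.25, 0.25, 0.25, 0.0])
        assert call_somatic([t], [n], pooled) == []
        pooled2 = self._pooled(t.key, [0.25, 0.25, 0.0, 0.0])
        assert len(call_somatic([t], [n], pooled2)) == 1

    def test_normal_rule_variants(self):
        t = make_call(pos=9, depth=100, alt_reads=8)  # tumour vaf 0.08
        n = make_call(pos=9, depth=100, alt_reads=5)  # normal vaf 0.05
        # stringent: 0.05 >= 0.5*0.08 -> reject; literal: 0.05 < 0.16 -> keep
        assert call_somatic([t], [n], None, FilterThresholds()) == []
        lit = FilterThresholds(normal_vaf_rule="twice_tumour")
        assert len(call_somatic([t], [n], None, lit)) == 1

    def test_missing_normal_coverage_rejected(self):
        t = make_call(pos=9, depth=100, alt_reads=40)
        assert call_somatic([t], [], None) == []

    def test_truth_recovery_on_simulated_cohort(self):
        cfg = CohortConfig(
            seed=42, n_clonal=800, n_subclonal=300, n_germline=600, n_artifact=100
        )
        ps = simulate_paired_variants(cfg)
        filtered = filter_variant_calls(ps.tumour_calls)
        called = {v.key for v in call_somatic(filtered, ps.normal_calls, ps.pooled_vafs)}
        assert called == ps.keys_with_label("clonal_somatic")
        assert not called & ps.keys_with_label("germline")
        assert not called & ps.keys_with_label("artifact")

    @settings(deadline=None, max_examples=30)
    @given(
        d_gq=st.floats(0, 30),
        d_alt=st.integers(0, 5),
        d_vaf=st.floats(0, 0.2),
        d_depth=st.integers(0, 20),
    )
    def test_monotone_in_thresholds(self, d_gq, d_alt, d_vaf, d_depth):
        """Tightening any threshold never adds a variant."""
        calls = random_calls(200, seed=9)
        normals = [
            make_call(pos=c.locus.start, depth=100, alt_reads=0, sample="N")
            for c in calls
        ]
        loose = FilterThresholds()
        tight = FilterThresholds(
            min_gq=loose.min_gq + d_gq,
            min_alt_reads=loose.min_alt_reads + d_alt,
            min_vaf=min(1.0, loose.min_vaf + d_vaf),
            min_depth=loose.min_depth + d_depth,
        )
        got_loose = {v.key for v in call_somatic(filter_variant_calls(calls, loose), normals, None, loose)}
        got_tight = {v.key for v in call_somatic(filter_variant_calls(calls, tight), normals, None, tight)}
        assert got_tight <= got_loose


class TestConsequence:
    def test_known_codons(self, mini_gene):
        genome, gene = mini_gene
        # CDS: ATG CTT GGT AAA CCC at positions 11..25
        silent = make_call(chrom="mini", pos=16, ref="T", alt="C")  # CTT->CTC Leu
        assert classify_consequence(silent, [gene], genome)[0] == "silent"
        non_silent = make_call(chrom="mini", pos=18, ref="G", alt="A")  # GGT->GAT Gly->Asp
        assert classify_consequence(non_silent, [gene], genome)[0] == "non_silent"

    def test_outside_genes_non_coding(self, mini_gene):
        genome, gene = mini_gene
        call = make_call(chrom="mini", pos=3, ref="T", alt="A")
        assert classify_consequence(call, [gene], genome) == ("non_coding", None)

    def test_coding_indel_non_silent(self, mini_gene):
        genome, gene = mini_gene
        indel = make_call(chrom="mini", pos=14, ref="CT", alt="C")
        assert classify_consequence(indel, [gene], genome)[0] == "non_silent"

    def test_300_random_snvs_match_retranslation_oracle(self, toy_world):
        genome, genes = toy_world
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 300:
            gene = genes[rng.integers(len(genes))]
            idx = int(rng.integers(gene.cds_length))
            pos = gene.genomic_position(idx)
            ref = genome[gene.chrom][pos - 1]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            call = make_call(chrom=gene.chrom, pos=pos, ref=ref, alt=alt)
            got, _gene_id = classify_consequence(call, genes, genome)
            expected = consequence_by_retranslation(call, gene, genome)
            assert got == expected, (gene.gene_id, pos, ref, alt)
            checked += 1


class TestTmb:
    def _somatic(self, n_non_silent, n_silent=5):
        out = []
        for i in range(n_non_silent + n_silent):
            v = SomaticVariant(
                call=make_call(pos=100 + i),
                normal_depth=50,
                normal_vaf=0.0,
                pooled_hit_count=0,
            )
            v.consequence = "non_silent" if i < n_non_silent else "silent"
            out.append(v)
        return out

    def test_zero(self):
        assert compute_tmb(self._somatic(0)) == 0.0

    def test_forced_arithmetic(self):
        assert compute_tmb(self._somatic(153)) == pytest.approx(3.0)

    def test_bad_target(self):
        with pytest.raises(ValidationError):
            compute_tmb([], target_mb=0)


def test_full_cascade_matches_row_oracle():
    """Filter + somatic predicates agree with a one-pass independent check."""
    rng = np.random.default_rng(23)
    calls = random_calls(1000, seed=23)
    normals = []
    pooled_rows = {}
    for c in calls:
        nd = int(rng.integers(0, 150))
        na = int(rng.integers(0, max(nd // 4, 1) + 1)) if nd else 0
        normals.append(
            make_call(pos=c.locus.start, ref=c.ref, alt=c.alt, depth=max(nd, 1),
                      alt_reads=min(na, max(nd, 1)), sample="N")
        )
        pooled_rows[c.key] = rng.uniform(0, 0.4, size=6)
    pooled = pd.DataFrame(
        list(pooled_rows.values()),
        index=pd.MultiIndex.from_tuples(pooled_rows, names=["chrom", "pos", "ref", "alt"]),
        columns=[f"N{i}" for i in range(6)],
    )
    t = FilterThresholds()
    got = {v.key for v in call_somatic(filter_variant_calls(calls, t), normals, pooled, t)}
    normal_by_pos = {n.locus.start: n for n in normals}
    for c in calls:
        n = normal_by_pos[c.locus.start]
        hits = int((pooled_rows[c.key] >= 0.20).sum())
        assert (c.key in got) == somatic_row_check(c, n.depth, n.vaf, hits, t)
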