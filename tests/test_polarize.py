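"""Filtering, outgroup polarization, mutation classes, ancestral genome."""

import numpy as np
import pytest

from gbgc import polarize as pol
from conftest import make_variant


class TestClassifyMutation:
    def test_exhaustive_category_counts(self):
        """Over all 12 ordered base pairs: 4 W->S, 4 S->W, 2 S->S, 2 W->W."""
        bases = "ACGT"
        cats = [pol.classify_mutation(a, d) for a in bases for d in bases if a != d]
        assert sorted(cats).count("WS") == 4
        assert cats.count("SW") == 4
        assert cats.count("SS") == 2
        assert cats.count("WW") == 2

    @pytest.mark.parametrize("anc,der,cat", [
        ("A", "T", "WW"), ("G", "A", "SW"), ("A", "G", "WS"), ("G", "C", "SS")])
    def test_examples(self, anc, der, cat):
        assert pol.classify_mutation(anc, der) == cat

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            pol.classify_mutation("A", "A")


@pytest.mark.parametrize("tri,prone", [
    ("ACG", True),   # CG
    ("ATA", False),  # AT, TA not in the prone list
    ("TTG", True),   # TG
    ("NAC", True),   # NA
    ("GTN", True),   # TN
    ("GGG", False),
])
def test_cpg_prone_contexts(tri, prone):
    assert pol.flag_cpg_prone(tri) is prone


class TestFiltering:
    def test_toy_vcf_filters(self, toy_paths):
        """Of the 3 clean biallelic SNPs one is exonic and one half-called:
        a single site survives; triallelic and repeat records also drop."""
        records = pol.load_variants(
            toy_paths["vcf"], ["ing_01", "ing_02"],
            {"og1": ["og1_1"], "og2": ["og2_1"]})
        assert len(records) == 5
        rep = pol.read_bed(toy_paths["repeats"])
        ex = pol.read_bed(toy_paths["exons"])
        kept = pol.filter_variants(records, rep, ex)
        assert [(v.chrom, v.pos) for v in kept] == [("toy_chr", 10)]
        # without the masks, the triallelic and half-called records still drop
        kept_nomask = pol.filter_variants(records)
        assert {v.pos for v in kept_nomask} == {10, 20, 50}

    def test_overlapping_unsorted_bed_merged(self):
        import pandas as pd
        bed = pd.DataFrame({"chrom": ["c", "c"], "start": [50, 10], "end": [70, 60]})
        merged = pol.merge_intervals(bed)
        assert merged.values.tolist() == [["c", 10, 70]]


class TestStrictPolarization:
    def test_alt_ancestral_orientation(self):
        """ref=G alt=A, outgroups hom alt, ingroup alt 17/20: the derived
        allele is G with count 3 and the mutation is W->S."""
        site = pol.polarize_strict(make_variant())
        assert isinstance(site, pol.PolarizedSite)
        assert site.ancestral_allele == "A"
        assert site.derived_allele == "G"
        assert site.category == "WS"
        assert site.derived_count == 3

    def test_ref_ancestral_orientation(self):
        v = make_variant(ing_alt=5, out_gts={"og1": [(0, 0)], "og2": [(0, 0)]})
        site = pol.polarize_strict(v)
        assert site.ancestral_allele == "G"
        assert site.derived_count == 5

    def test_heterozygous_outgroup_rejected(self):
        v = make_variant(out_gts={"og1": [(0, 1)], "og2": [(0, 0)]})
        assert pol.polarize_strict(v).reason == "outgroup_polymorphic"

    def test_missing_outgroup_rejected(self):
        v = make_variant(out_gts={"og1": [(None, 1)], "og2": [(1, 1)]})
        assert pol.polarize_strict(v).reason == "outgroup_missing"

    def test_cross_population_disagreement_rejected(self):
        v = make_variant(out_gts={"og1": [(0, 0)], "og2": [(1, 1)]})
        assert pol.polarize_strict(v).reason == "outgroup_polymorphic"


class TestLiberalPolarization:
    def test_half_called_tolerated(self):
        v = make_variant(out_gts={"og1": [(1, None)], "og2": [(1, 1)]})
        site = pol.polarize_liberal(v, {"og1": 0, "og2": 0})
        assert site.ancestral_allele == "A"

    def test_heterozygous_designated_rejected(self):
        v = make_variant(out_gts={"og1": [(0, 1)], "og2": [(1, 1)]})
        assert pol.polarize_liberal(v, {"og1": 0, "og2": 0}).reason == "outgroup_polymorphic"

    def test_liberal_superset_of_strict(self, small_dataset, tmp_path):
        """With one individual per outgroup and varying missingness, every
        strictly polarized site is also liberally polarized."""
        from gbgc import simulate as sim
        paths = sim.write_dataset(tmp_path, small_dataset)
        records = pol.load_variants(paths["vcf"], small_dataset.ingroup,
                                    small_dataset.outgroups)
        strict, _ = pol.polarize_all(records, "strict")
        liberal, _ = pol.polarize_all(records, "liberal",
                                      {pop: 0 for pop in small_dataset.outgroups})
        strict_keys = {(s.chrom, s.pos) for s in strict}
        liberal_keys = {(s.chrom, s.pos) for s in liberal}
        assert strict_keys <= liberal_keys


class TestAncestralGenome:
    def _write_ref(self, tmp_path, seq):
        p = tmp_path / "ref.fa"
        p.write_text(">c\n" + seq + "\n")
        return p

    def test_substitution_and_identity(self, tmp_path):
        ref = self._write_ref(tmp_path, "AAAAGAAAAA")
        sites = [
            pol.PolarizedSite("c", 5, "A", "G", "WS", 3, 20),   # ref derived -> A
            pol.PolarizedSite("c", 1, "A", "T", "WW", 2, 20),   # ref ancestral -> kept
        ]
        ag = pol.build_ancestral_genome(ref, sites)
        assert ag.seqs["c"].tobytes().decode() == "AAAAAAAAAA"
        assert ag.substituted == [("c", 5)]

    def test_gc_by_direct_base_counting(self, tmp_path):
        """The ancestral GC equals hand-counted GC of the expected sequence."""
        seq = "ACGTACGTACGTACGTACGT"
        ref = self._write_ref(tmp_path, seq)
        sites = [
            pol.PolarizedSite("c", 3, "A", "G", "WS", 1, 20),   # ref G -> A: -1 GC
            pol.PolarizedSite("c", 7, "T", "G", "WS", 1, 20),   # ref G -> T: -1 GC
            pol.PolarizedSite("c", 12, "G", "T", "SW", 1, 20),  # ref T -> G: +1 GC
        ]
        ag = pol.build_ancestral_genome(ref, sites)
        expected = list(seq)
        expected[2], expected[6], expected[11] = "A", "T", "G"
        expected = "".join(expected)
        assert ag.seqs["c"].tobytes().decode() == expected
        manual_gc = sum(b in "GC" for b in expected) / len(expected)
        assert ag.gc_content() == pytest.approx(manual_gc, abs=0)

    def test_two_counting_routines_agree(self, polarized_pipeline):
        """GC from base_counts equals GC recounted from the emitted FASTA."""
        ag = polarized_pipeline["genome"]
        L_W, L_S = ag.base_counts()
        total_s = total_w = 0
        for chrom in ag.seqs:
            for p0, ch in enumerate(ag.seqs[chrom].tobytes().decode()):
                if ag.mask[chrom][p0] or ch == "N":
                    continue
                if ch in "GC":
                    total_s += 1
                elif ch in "AT":
                    total_w += 1
        assert (total_w, total_s) == (L_W, L_S)

    def test_masked_substitution_warns(self, tmp_path):
        import pandas as pd
        ref = self._write_ref(tmp_path, "AAAAGAAAAA")
        bed = pd.DataFrame({"chrom": ["c"], "start": [4], "end": [5]})
        sites = [pol.PolarizedSite("c", 5, "A", "G", "WS", 3, 20)]
        with pytest.warns(UserWarning, match="masked"):
            ag = pol.build_ancestral_genome(ref, sites, repeat_bed=bed)
        assert ag.mask["c"][4]

    def test_context_padding_at_sequence_ends(self, tmp_path):
        ref = self._write_ref(tmp_path, "ACG")
        ag = pol.build_ancestral_genome(ref, [])
        assert ag.context("c", 1) == "NAC"
        assert ag.context("c", 3) == "CGN"

    def test_context_annotation_consistency(self, polarized_pipeline):
        sites = polarized_pipeline["sites"][:200]
        pol.annotate_contexts(sites, polarized_pipeline["genome"])
        for s in sites:
            assert s.context[1] == s.ancestral_allele
            assert s.cpg_prone == pol.flag_cpg_prone(s.context)


class TestPipelineRecovery:
    def test_all_ancestral_states_recovered(self, polarized_pipeline):
        """With error-free outgroups the injected ancestral states are
        recovered for every site, and each category matches its alleles."""
        ds = polarized_pipeline["ds"]
        truth = ds.truth.set_index(["chrom", "pos"])
        sites = polarized_pipeline["sites"]
        assert len(sites) == len(ds.truth)
        for s in sites[::7]:
            row = truth.loc[(s.chrom, s.pos)]
            assert s.ancestral_allele == row["anc"]
            assert s.derived_allele == row["der"]
            assert s.derived_count == row["i"]
            assert s.category == pol.classify_mutation(s.ancestral_allele,
                                                       s.derived_allele)
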