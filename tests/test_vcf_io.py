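"""Pedigree/VCF parsing, filters and output round-trips."""

from collections import Counter

import pysam
import pytest

from denovotrio.genotypes import Sex
from denovotrio.model import TrioCall, combo_table
from denovotrio.genotypes import InheritanceMode
from denovotrio.pipeline import CallerConfig, call_sites
from denovotrio.simulate import SimulationConfig, simulate_trios, write_dataset
from denovotrio.vcf_io import (
    FAIL,
    NOT_EVALUATED,
    PASS,
    SiteRecord,
    Trio,
    parent_alt_read_filter,
    read_pedigree,
    read_region_exclusions,
    read_sites,
    write_calls_vcf,
    write_dnm_table,
)


def write_ped(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestPedigree:
    def test_basic_trio_with_female_child(self, tmp_path):
        ped = write_ped(
            tmp_path / "t.ped",
            [
                "FAM1 FATHER 0 0 1 -9",
                "FAM1 MOTHER 0 0 2 -9",
                "FAM1 CHILD FATHER MOTHER 2 -9",
            ],
        )
        trios = read_pedigree(ped)
        assert len(trios) == 1
        assert trios[0] == Trio(
            family="FAM1",
            mother="MOTHER",
            father="FATHER",
            child="CHILD",
            child_sex=Sex.FEMALE,
        )

    def test_child_with_missing_parent_is_skipped(self, tmp_path):
        ped = write_ped(
            tmp_path / "t.ped",
            ["FAM1 MOTHER 0 0 2 -9", "FAM1 CHILD 0 MOTHER 1 -9"],
        )
        assert read_pedigree(ped) == []

    def test_dizygotic_twins_give_two_trios(self, tmp_path):
        ped = write_ped(
            tmp_path / "t.ped",
            [
                "FAM1 DAD 0 0 1 -9",
                "FAM1 MUM 0 0 2 -9",
                "FAM1 TWIN1 DAD MUM 1 -9",
                "FAM1 TWIN2 DAD MUM 2 -9",
            ],
        )
        trios = read_pedigree(ped)
        assert [t.child for t in trios] == ["TWIN1", "TWIN2"]

    def test_duplicate_individual_is_an_error(self, tmp_path):
        ped = write_ped(
            tmp_path / "t.ped", ["FAM1 A 0 0 1 -9", "FAM1 A 0 0 1 -9"]
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_pedigree(ped)

    def test_malformed_line_reports_line_number(self, tmp_path):
        ped = write_ped(tmp_path / "t.ped", ["FAM1 A 0 0 1 -9", "FAM1 B 0"])
        with pytest.raises(ValueError, match=":2"):
            read_pedigree(ped)


@pytest.fixture()
def small_dataset(tmp_path):
    cfg = SimulationConfig(n_trios=2, n_sites=20, dnm_rate=0.1, seed=3)
    ds = simulate_trios(cfg)
    vcf = tmp_path / "trios.vcf"
    ped = tmp_path / "trios.ped"
    truth = tmp_path / "truth.tsv"
    write_dataset(ds, vcf, ped, truth)
    return ds, vcf, ped


class TestReadSites:
    def test_round_trip_preserves_pl_ad_gt(self, small_dataset):
        ds, vcf, _ = small_dataset
        samples = [s for t in ds.trios for s in t.samples]
        sites = list(read_sites(vcf, samples))
        assert len(sites) == len(ds.sites)
        for orig, back in zip(ds.sites, sites):
            assert back.pos == orig.pos
            assert back.pls == orig.pls
            assert back.ads == orig.ads
            assert back.gts == orig.gts

    def test_unknown_sample_is_a_startup_error(self, small_dataset):
        _, vcf, _ = small_dataset
        with pytest.raises(ValueError, match="absent from VCF header"):
            list(read_sites(vcf, ["NOBODY"]))

    def test_multiallelic_sites_are_skipped_and_counted(self, tmp_path):
        header = pysam.VariantHeader()
        header.contigs.add("1")
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("PL", "G", "Integer", "PL")
        header.add_sample("S1")
        path = tmp_path / "multi.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as out:
            rec = out.new_record(contig="1", start=9, alleles=("A", "C"))
            rec.samples["S1"]["GT"] = (0, 1)
            rec.samples["S1"]["PL"] = (10, 0, 40)
            out.write(rec)
            rec = out.new_record(contig="1", start=19, alleles=("A", "C", "G"))
            rec.samples["S1"]["GT"] = (1, 2)
            out.write(rec)
        counter = Counter()
        sites = list(read_sites(path, ["S1"], skip_counter=counter))
        assert [s.pos for s in sites] == [10]
        assert counter["multiallelic"] == 1

    def test_bed_exclusion_is_half_open(self, small_dataset, tmp_path):
        ds, vcf, _ = small_dataset
        bed = tmp_path / "excl.bed"
        # 0-based half-open [0, 5) excludes VCF positions 1..5 only
        bed.write_text("1\t0\t5\n")
        exclusions = read_region_exclusions(bed)
        samples = [s for t in ds.trios for s in t.samples]
        counter = Counter()
        sites = list(
            read_sites(vcf, samples, exclusions=exclusions, skip_counter=counter)
        )
        assert min(s.pos for s in sites) == 6
        assert counter["excluded_region"] == 5


class TestParentAltReadFilter:
    trio = Trio(family="F", mother="M", father="D", child="C")

    def make_site(self, ad_mother, ad_father):
        site = SiteRecord(contig="1", pos=1, ref="A", alt="C")
        site.ads = {"M": ad_mother, "D": ad_father, "C": (10, 10)}
        return site

    def make_call(self):
        table = combo_table(InheritanceMode.AUTOSOMAL, 1e-5)
        return TrioCall(
            best_combination=table.combos[1],
            posterior=0.9,
            q_score=10.0,
            is_denovo=True,
            mode=InheritanceMode.AUTOSOMAL,
            family="F",
        )

    def test_clean_parents_pass(self):
        site = self.make_site((20, 0), (18, 0))
        assert parent_alt_read_filter(self.make_call(), site, self.trio) == PASS

    def test_single_alt_read_in_mother_fails(self):
        site = self.make_site((19, 1), (18, 0))
        assert parent_alt_read_filter(self.make_call(), site, self.trio) == FAIL

    def test_missing_father_ad_is_not_evaluated(self):
        site = self.make_site((20, 0), None)
        assert (
            parent_alt_read_filter(self.make_call(), site, self.trio)
            == NOT_EVALUATED
        )


class TestOutputs:
    def test_vcf_round_trip_preserves_phase_and_annotations(
        self, small_dataset, tmp_path
    ):
        ds, _, _ = small_dataset
        result = call_sites(ds.sites, ds.trios, CallerConfig(mu=1e-5))
        out = tmp_path / "calls.vcf"
        write_calls_vcf(ds.sites, result.calls, ds.trios, out)

        calls_by_key = {c.key: c for c in result.calls}
        with pysam.VariantFile(str(out)) as vcf:
            recs = list(vcf)
        assert len(recs) == len(ds.sites)
        n_phased = 0
        for rec in recs:
            for trio in ds.trios:
                call = calls_by_key.get((rec.contig, rec.pos, trio.family))
                if call is None:
                    continue
                child = rec.samples[trio.child]
                assert child["TP"] == round(call.q_score)
                if call.phase_ambiguous is False:
                    assert child.phased
                    assert tuple(child["GT"]) == call.phased_child
                    n_phased += 1
                if call.is_denovo:
                    assert "DNM" in rec.info
        assert n_phased > 0

    def test_dnm_table_is_ranked_and_thresholded(self, small_dataset, tmp_path):
        ds, _, _ = small_dataset
        result = call_sites(ds.sites, ds.trios, CallerConfig(mu=1e-5))
        path = tmp_path / "dnm.tsv"
        n = write_dnm_table(result.calls, path, min_q=5.0)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == n + 1
        qs = [float(line.split("\t")[7]) for line in lines[1:]]
        assert qs == sorted(qs, reverse=True)
        assert all(q >= 5.0 for q in qs)
        expected = sum(
            1 for c in result.calls if c.is_denovo and c.q_score >= 5.0
        )
        assert n == expected

    def test_empty_call_list_still_writes_headers(self, small_dataset, tmp_path):
        ds, _, _ = small_dataset
        out_vcf = tmp_path / "empty.vcf"
        out_tsv = tmp_path / "empty.tsv"
        write_calls_vcf(ds.sites, [], ds.trios, out_vcf)
        assert write_dnm_table([], out_tsv) == 0
        assert out_tsv.read_text().startswith("contig\t")
        with pysam.VariantFile(str(out_vcf)) as vcf:
            assert len(list(vcf)) == len(ds.sites)
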