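"""Venn-sector classification, specific-region calling, gene assignment, spacing."""

import numpy as np
import pytest

from pantrio.intervals import Gene, IntervalSet, Transcript, AnnotationSet
from pantrio.kmers import CoverageProfile
from pantrio.pangenome import (SpecificRegionCriteria, assign_gene_sector,
                               call_genic_specific_regions,
                               call_specific_regions, classify_bases,
                               spacing_stats, venn_summary, assign_all_genes)

K = 21
LEN = {"g": 10_000}


def labeling(u1=None, u2=None, lengths=LEN):
    return classify_bases(lengths,
                          IntervalSet(u1 or {}), IntervalSet(u2 or {}),
                          "A", ("B", "C"))


def prof(values, name="g"):
    return {name: CoverageProfile(name, K, np.asarray(values))}


def flat(level, length=10_000):
    return prof(np.full(length - K + 1, level))


class TestClassifyBases:
    def test_everything_core_when_fully_aligned(self):
        lab = labeling()
        assert lab.core.total_bp() == 10_000
        assert lab.specific.total_bp() == 0

    def test_specific_definition(self):
        lab = labeling({"g": [(100, 300)]}, {"g": [(200, 400)]})
        assert lab.specific["g"].tolist() == [[200, 300]]
        assert lab.shared_1["g"].tolist() == [[300, 400]]   # aligned to B only
        assert lab.shared_2["g"].tolist() == [[100, 200]]   # aligned to C only

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            labeling({"g": [(0, 20_000)]})
        with pytest.raises(ValueError):
            labeling({"zz": [(0, 10)]})

    def test_partition_random_inputs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mk = lambda: {"g": [(int(s), int(s) + int(w))
                                for s, w in zip(rng.integers(0, 9_900, 30),
                                                rng.integers(1, 100, 30))]}
            lab = labeling(mk(), mk())
            lab.verify_partition()   # raises on overlap or gap
            assert sum(p.total_bp() for p in lab.parts().values()) == 10_000

    def test_sector_names(self):
        lab = labeling()
        assert lab.by_sector().keys() == {"A", "AB", "AC", "ABC"}


def two_exon_gene(seqid="g", exons=((100, 400), (600, 1000))):
    t = Transcript(id="t", exons=list(exons),
                   span=(exons[0][0], exons[-1][1]))
    return Gene(id="gene1", seqid=seqid, start=exons[0][0], end=exons[-1][1],
                strand="+", transcripts=[t])


class TestGeneAssignment:
    def test_majority_rule_90_10(self):
        # 90% of exonic bases core, 10% specific -> core sector
        lab = labeling({"g": [(100, 170)]}, {"g": [(100, 170)]})
        gene = two_exon_gene()   # 700 exonic bp, 70 specific
        sector, support = assign_gene_sector(gene, lab)
        assert sector == "ABC"
        assert support["A"] == 70
        assert support["ABC"] == 630

    def test_pure_specific(self):
        lab = labeling({"g": [(0, 2000)]}, {"g": [(0, 2000)]})
        sector, _ = assign_gene_sector(two_exon_gene(), lab)
        assert sector == "A"

    def test_tie_resolves_to_more_shared(self):
        # exactly half the exonic bases specific, half core
        lab = labeling({"g": [(100, 400), (600, 650)]},
                       {"g": [(100, 400), (600, 650)]})
        gene = two_exon_gene()   # 350 specific vs 350 core
        sector, support = assign_gene_sector(gene, lab)
        assert support["A"] == support["ABC"] == 350
        assert sector == "ABC"

    def test_transcripts_counted_cumulatively(self):
        lab = labeling({"g": [(0, 500)]}, {"g": [(0, 500)]})
        t1 = Transcript(id="t1", exons=[(100, 400)], span=(100, 400))
        t2 = Transcript(id="t2", exons=[(100, 400), (600, 1400)], span=(100, 1400))
        gene = Gene(id="gX", seqid="g", start=100, end=1400, strand="+",
                    transcripts=[t1, t2])
        sector, support = assign_gene_sector(gene, lab)
        assert support["A"] == 600      # shared exon counted once per transcript
        assert support["ABC"] == 800
        assert sector == "ABC"

    def test_no_exons_error(self):
        lab = labeling()
        gene = Gene(id="g0", seqid="g", start=0, end=10, strand="+",
                    transcripts=[Transcript(id="t", exons=[], span=(0, 10))])
        with pytest.raises(ValueError):
            assign_gene_sector(gene, lab)


class TestVennSummary:
    def test_identity_trio_all_core(self):
        labs = {g: classify_bases(LEN, IntervalSet(), IntervalSet(), g,
                                  tuple(h for h in "ABC" if h != g))
                for g in "ABC"}
        ann = {g: AnnotationSet([two_exon_gene()]) for g in "ABC"}
        assigns = {g: assign_all_genes(ann[g], labs[g]) for g in "ABC"}
        rows = {r.sector: r for r in venn_summary(labs, ann, assigns)}
        assert rows["ABC"].bp == 10_000
        assert rows["ABC"].gene_count == 1
        assert rows["ABC"].exonic_bp == 700
        assert all(rows[s].bp == 0 for s in rows if s != "ABC")

    def test_sector_conservation_per_genome(self, exact_trio):
        labs = exact_trio.labelings
        for g, lab in labs.items():
            total = sum(s.total_bp() for s in lab.by_sector().values())
            assert total == sum(lab.lengths.values())


class TestSpecificRegions:
    def crit(self):
        return SpecificRegionCriteria()

    def test_short_region_rejected(self):
        lab = labeling({"g": [(100, 199)]}, {"g": [(100, 199)]})
        out = call_specific_regions(lab, flat(50), [flat(0), flat(0)], self.crit())
        assert out.count() == 0

    def test_repetitive_region_rejected(self):
        lab = labeling({"g": [(100, 600)]}, {"g": [(100, 600)]})
        out = call_specific_regions(lab, flat(150), [flat(0), flat(0)], self.crit())
        assert out.count() == 0

    def test_valid_region_accepted(self):
        lab = labeling({"g": [(100, 600)]}, {"g": [(100, 600)]})
        out = call_specific_regions(lab, flat(50), [flat(2), flat(0)], self.crit())
        assert out["g"].tolist() == [[100, 600]]

    def test_cross_coverage_rejects(self):
        lab = labeling({"g": [(100, 600)]}, {"g": [(100, 600)]})
        out = call_specific_regions(lab, flat(50), [flat(12), flat(0)], self.crit())
        assert out.count() == 0

    def test_inclusive_self_band_bounds(self):
        lab = labeling({"g": [(100, 600)]}, {"g": [(100, 600)]})
        for level, expect in ((10, 1), (100, 1), (9, 0), (101, 0)):
            out = call_specific_regions(lab, flat(level), [flat(0), flat(0)],
                                        self.crit())
            assert out.count() == expect, level

    def test_missing_profile_named(self):
        lab = labeling({"g": [(100, 600)]}, {"g": [(100, 600)]})
        with pytest.raises(ValueError, match="g"):
            call_specific_regions(lab, {}, [flat(0), flat(0)], self.crit())

    def test_monotone_in_cross_cutoff(self):
        rng = np.random.default_rng(42)
        spots = sorted(set(int(x) for x in rng.integers(0, 9_000, 12)))
        ivs = {"g": [(s, s + 300) for s in spots]}
        lab = labeling(ivs, ivs)
        cross = prof(rng.integers(0, 20, 10_000 - K + 1))
        counts = []
        for cmax in (2, 5, 10, 20, 40):
            crit = SpecificRegionCriteria(cross_cov_max=cmax)
            out = call_specific_regions(lab, flat(50), [cross, flat(0)], crit)
            counts.append(out.count())
        assert counts == sorted(counts)


class TestGenicSpecific:
    def test_kept_whole_and_dropped(self):
        ann = AnnotationSet([two_exon_gene()])   # gene span 100-1000
        regions = IntervalSet({"g": [(900, 1500), (5000, 6000)]})
        out = call_genic_specific_regions(regions, ann, min_overlap=100)
        assert out["g"].tolist() == [[900, 1500]]   # 100 bp overlap, kept whole


class TestSpacing:
    def test_regular_spacing(self):
        regions = IntervalSet({"g": [(i * 10_000, i * 10_000 + 100)
                                     for i in range(20)]})
        sp = spacing_stats(regions)
        assert sp.mean_gap == 10_000
        assert sp.sd_gap == 0.0

    def test_poisson_placement_dispersion_near_one(self):
        rng = np.random.default_rng(77)
        starts = np.sort(rng.integers(0, 5_000_000, size=400))
        starts = starts[np.diff(np.concatenate([[-100], starts])) > 60]
        regions = IntervalSet({"g": [(int(s), int(s) + 50) for s in starts]})
        sp = spacing_stats(regions)
        assert 0.8 <= sp.dispersion <= 1.2

    def test_too_few_regions(self):
        with pytest.raises(ValueError, match="[Ii]nsufficient"):
            spacing_stats(IntervalSet({"g": [(0, 10), (50, 60)]}))


class TestBoundaryGenes:
    def test_boundary_gene_assigned_by_majority(self):
        """A gene planted across a sector junction goes to the sector holding
        most of its exonic bases."""
        from pantrio.simulate import SimConfig, simulate_trio
        from pantrio.align import AlignerConfig, ReferenceIndex, align_genomes
        cfg = SimConfig(seed=30, core_length=60_000, core_segments=6,
                        sector_segment_lengths={"A": [3000]},
                        repeat_family_specs=[], snp_rate=0.0,
                        small_indel_rate=0.0, gene_density=0.0,
                        boundary_genes=2)
        genomes, _ann, truth = simulate_trio(cfg)
        bnd = [gp for gp in truth.gene_placements["A"] if gp.sector == "boundary"]
        assert len(bnd) == 2
        acfg = AlignerConfig()
        idx = ReferenceIndex(genomes["A"], acfg)
        uns = [align_genomes(genomes["A"], genomes[h], acfg, index=idx)
               .unaligned(genomes["A"]) for h in ("B", "C")]
        lab = classify_bases(genomes["A"].lengths(), uns[0], uns[1],
                             "A", ("B", "C"))
        sectors = lab.by_sector()
        for gp in bnd:
            gene = Gene(id=gp.gene_id, seqid=gp.seqid, start=gp.start,
                        end=gp.end, strand="+",
                        transcripts=[Transcript(id="t",
                                                exons=[(gp.start, gp.end)],
                                                span=(gp.start, gp.end))])
            sector, support = assign_gene_sector(gene, lab)
            # majority rule: the winning sector holds the plurality of bases
            assert support[sector] == max(support.values())
            assert sum(support.values()) == gp.end - gp.start
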