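"""Guide enumeration, scoring, off-target scanning, pairing and library assembly.

Brute-force oracles here are deliberately naive re-implementations (explicit
loops over every offset/strand/site) kept independent of the package code.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pgscreen as pg
from pgscreen.annotation import GeneModel, revcomp
from pgscreen.pgrna_design import (
    DEFAULT_INSERT1_TEMPLATE,
    Insert1Template,
    PositionWeightScorer,
    rank_pairs_pc,
)

dna = st.text(alphabet="ACGT", min_size=23, max_size=300)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_protospacers(seq):
    """Every offset/strand tested explicitly against the 20-mer + NGG rule."""
    hits = []
    for i in range(len(seq)):
        w = seq[i : i + 23]
        if len(w) == 23 and w[21:23] == "GG":
            hits.append(("+", i, w[:20], w[20:23]))
        rc = revcomp(w)
        if len(w) == 23 and rc[21:23] == "GG":
            hits.append(("-", i + 3, rc[:20], rc[20:23]))
    return sorted(hits)


def brute_force_offtargets(proto, seq, exclude=None):
    """Hamming-distance histogram over every NGG-adjacent site of ``seq``."""
    counts = [0] * 5
    for strand, start, site, _pam in brute_force_protospacers(seq):
        if exclude and (strand, start) == exclude:
            continue
        d = sum(1 for a, b in zip(proto, site) if a != b)
        if d <= 4:
            counts[d] += 1
    return counts


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

class TestEnumerate:
    def test_forward_hit(self):
        hits = pg.enumerate_protospacers("A" * 20 + "AGG")
        assert len(hits) == 1
        p = hits[0]
        assert (p.sequence, p.strand, p.start, p.pam) == ("A" * 20, "+", 0, "AGG")
        assert p.cut_site == 17

    def test_reverse_hit(self):
        hits = pg.enumerate_protospacers("CCT" + "T" * 20)
        assert len(hits) == 1
        p = hits[0]
        assert (p.sequence, p.strand, p.start, p.pam) == ("A" * 20, "-", 3, "AGG")
        assert p.cut_site == 6

    def test_ambiguous_bases_skipped_with_warning(self):
        # an NGG-adjacent window containing an N is skipped, not emitted
        with pytest.warns(UserWarning, match="non-ACGT"):
            hits = pg.enumerate_protospacers("AAAAA" + "N" + "A" * 14 + "AGG")
        assert all("N" not in p.sequence for p in hits)

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        got = sorted(
            (p.strand, p.start, p.sequence, p.pam)
            for p in pg.enumerate_protospacers(seq)
        )
        assert got == brute_force_protospacers(seq)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna)
    def test_brute_force_equivalence_property(self, seq):
        got = sorted(
            (p.strand, p.start, p.sequence, p.pam)
            for p in pg.enumerate_protospacers(seq)
        )
        assert got == brute_force_protospacers(seq)

    def test_offset_shifts_coordinates(self):
        hits = pg.enumerate_protospacers("A" * 20 + "AGG", offset=100)
        assert hits[0].start == 100 and hits[0].cut_site == 117


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class TestScoring:
    def test_deterministic(self):
        s = PositionWeightScorer()
        ctx = "ACGT" + "A" * 20 + "AGG" + "TTT"
        assert s(ctx) == s(ctx)

    def test_composition_is_distinguished(self):
        s = PositionWeightScorer()
        assert s("ACGT" + "A" * 20 + "AGG" + "TTT") != s("ACGT" + "G" * 20 + "AGG" + "TTT")

    def test_scores_bounded(self):
        rng = np.random.default_rng(7)
        s = PositionWeightScorer()
        for _ in range(200):
            ctx = "".join(rng.choice(list("ACGT"), size=30))
            assert 0.0 <= s(ctx) <= 1.0

    def test_constant_scorer_gives_pair_score_one(self, toy_world, ot_index):
        _, genome, models = toy_world
        gene = next(m for m in models if m.biotype == "protein_coding")
        designs = pg.design_pc_target(
            gene, genome, ot_index, scorer=lambda ctx: 0.5, n=3
        )
        assert designs and all(d.pair_score == 1.0 for d in designs)

    def test_truncated_context_warns(self):
        genome = {"c": "A" * 20 + "AGG"}
        p = pg.enumerate_protospacers(genome["c"], chrom="c")[0]
        with pytest.warns(UserWarning, match="truncated context"):
            pg.score_protospacer(p, genome)


# ---------------------------------------------------------------------------
# off-targets
# ---------------------------------------------------------------------------

def planted_genome(rng, extra=""):
    return "".join(rng.choice(list("ACGT"), size=3000)) + extra


class TestOffTargets:
    def test_unique_protospacer_passes(self):
        rng = np.random.default_rng(0)
        seq = planted_genome(rng)
        genome = {"c": seq}
        p = pg.enumerate_protospacers(seq, chrom="c")[0]
        ok, counts = pg.count_offtargets(p, genome)
        oracle = brute_force_offtargets(
            p.sequence, seq, exclude=(p.strand, p.start)
        )
        assert counts[:3] == oracle[:3]

    def test_planted_exact_duplicate_fails(self):
        rng = np.random.default_rng(1)
        core = "".join(rng.choice(list("ACGT"), size=20))
        seq = planted_genome(rng, "TTTT" + core + "TGG" + "TTTT" + core + "AGG")
        genome = {"c": seq}
        p = next(
            q for q in pg.enumerate_protospacers(seq, chrom="c") if q.sequence == core
        )
        ok, counts = pg.count_offtargets(p, genome)
        assert not ok and counts[0] >= 1

    def test_one_mismatch_site_relaxation(self):
        rng = np.random.default_rng(2)
        core = "".join(rng.choice(list("ACGT"), size=20))
        mm = ("A" if core[0] != "A" else "C") + core[1:]
        seq = planted_genome(rng, "TTTT" + core + "TGG" + "TTTT" + mm + "AGG")
        genome = {"c": seq}
        p = next(
            q for q in pg.enumerate_protospacers(seq, chrom="c") if q.sequence == core
        )
        ok_default, counts = pg.count_offtargets(p, genome)
        assert counts[1] >= 1 and not ok_default
        ok_relaxed, _ = pg.count_offtargets(p, genome, thresholds=(0, 1, None, None, None))
        assert ok_relaxed

    def test_histogram_matches_brute_force_for_many_queries(self):
        rng = np.random.default_rng(3)
        seq = planted_genome(rng)
        genome = {"c": seq}
        index = pg.OffTargetIndex(genome)
        protos = pg.enumerate_protospacers(seq, chrom="c")[:50]
        for p in protos:
            _, counts = pg.count_offtargets(p, index)
            oracle = brute_force_offtargets(p.sequence, seq, exclude=(p.strand, p.start))
            assert counts == oracle


# ---------------------------------------------------------------------------
# pairing / ranking
# ---------------------------------------------------------------------------

def proto(start, score, exon_index=0, cut_shift=0):
    p = pg.Protospacer(
        sequence="ACGT" * 5, strand="+", start=start, pam="AGG", chrom="c"
    )
    p.score = score
    p.exon_index = exon_index
    return p


class TestRanking:
    def test_higher_pair_score_first(self):
        a, b = proto(0, 0.9), proto(100, 0.8)  # pair score 1.7
        c, d = proto(300, 0.6), proto(400, 0.6)  # pair score 1.2
        pairs = rank_pairs_pc([a, b, c, d])
        assert pairs[0] == (a, b)

    def test_out_of_frame_breaks_score_ties(self):
        # same exon, same summed score; deletion 98 (out of frame) vs 99
        g = [proto(0, 0.5), proto(98, 0.5), proto(1, 0.5), proto(100, 0.5)]
        pairs = rank_pairs_pc(g)
        first = pairs[0]
        dlen = first[1].cut_site - first[0].cut_site
        assert dlen % 3 != 0

    def test_earlier_orf_exon_dominates_score(self):
        early = (proto(0, 0.1, exon_index=0), proto(60, 0.1, exon_index=0))
        late = (proto(500, 0.9, exon_index=1), proto(600, 0.9, exon_index=1))
        pairs = rank_pairs_pc([*early, *late])
        assert pairs[0][0].start == 0

    def test_full_ranking_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        protos = [
            proto(int(s), float(round(rng.uniform(0, 1), 3)), exon_index=int(e))
            for s, e in zip(rng.choice(2000, size=8, replace=False), rng.integers(0, 3, 8))
        ]
        got = rank_pairs_pc(protos)

        def oracle():
            cands = []
            for a, b in itertools.combinations(protos, 2):
                g1, g2 = (a, b) if a.cut_site < b.cut_site else (b, a)
                if g1.cut_site == g2.cut_site:
                    continue
                dlen = g2.cut_site - g1.cut_site
                cands.append(
                    (
                        (
                            min(g1.exon_index, g2.exon_index),
                            -(g1.score + g2.score),
                            0 if dlen % 3 else 1,
                            g1.start,
                            g2.start,
                        ),
                        (g1, g2),
                    )
                )
            return [p for _, p in sorted(cands, key=lambda t: t[0])]

        assert got == oracle()

    def test_ranking_is_deterministic_total_order(self):
        rng = np.random.default_rng(6)
        protos = [proto(int(s), 0.5) for s in rng.choice(1000, size=6, replace=False)]
        a = rank_pairs_pc(protos)
        b = rank_pairs_pc(list(reversed(protos)))
        assert a == b


# ---------------------------------------------------------------------------
# per-target design and library assembly
# ---------------------------------------------------------------------------

class TestDesignTargets:
    def test_pc_designs_validate_against_genome(self, toy_world, ot_index):
        _, genome, models = toy_world
        gene = next(m for m in models if m.biotype == "protein_coding")
        designs = pg.design_pc_target(gene, genome, ot_index, n=6)
        assert designs
        seq = genome[gene.chrom]
        for d in designs:
            for g in (d.guide1, d.guide2):
                if g.strand == "+":
                    assert seq[g.start : g.start + 20] == g.sequence
                    assert seq[g.start + 21 : g.start + 23] == "GG"
                else:
                    assert revcomp(seq[g.start : g.start + 20]) == g.sequence
                    assert seq[g.start - 3 : g.start - 1] == "CC"
            assert d.deletion_len == d.guide2.cut_site - d.guide1.cut_site
            expect = "out_of_frame" if d.deletion_len % 3 else "in_frame"
            assert d.frame_status == expect

    def test_min_separation_enforced_within_target(self, toy_world, ot_index):
        _, genome, models = toy_world
        gene = next(m for m in models if m.biotype == "protein_coding")
        designs = pg.design_pc_target(gene, genome, ot_index, n=10, min_sep=50)
        cuts = [c for d in designs for c in (d.guide1.cut_site, d.guide2.cut_site)]
        for a, b in itertools.combinations(cuts, 2):
            assert abs(a - b) >= 50

    def test_window_extends_beyond_first_exon_when_needed(self, toy_world, ot_index):
        _, genome, models = toy_world
        gene = next(m for m in models if m.biotype == "protein_coding")
        designs = pg.design_pc_target(gene, genome, ot_index, n=10, min_sep=50)
        first = gene.cds_in_orf_order()[0]
        in_first = [
            d
            for d in designs
            if all(first[0] <= g.start and g.end <= first[1] for g in (d.guide1, d.guide2))
        ]
        # exon 1 alone cannot host 10 x 50-bp-separated pairs here
        if len(designs) > len(in_first):
            exons = gene.cds_in_orf_order()[:3]
            for d in designs:
                for g in (d.guide1, d.guide2):
                    assert any(s <= g.start and g.end <= e for s, e in exons)

    def test_lnc_pairs_straddle_tss(self, toy_world, ot_index):
        _, genome, models = toy_world
        lnc = next(m for m in models if m.biotype == "lncRNA")
        designs = pg.design_lnc_target(lnc, genome, ot_index, pc_models=models)
        assert designs
        for d in designs:
            assert d.guide1.cut_site < lnc.tss < d.guide2.cut_site

    def test_lnc_guides_avoid_pc_genes(self, ot_index):
        # pc gene planted right next to the TSS: no guide may overlap it
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=12_000))
        genome = {"c": seq}
        lnc = GeneModel("lnc", "c", "+", "lncRNA", ((6000, 6400),))
        pc = GeneModel("pc", "c", "+", "protein_coding", ((5600, 5950),), ((5600, 5950),))
        designs = pg.design_lnc_target(lnc, genome, pc_models=[pc, lnc])
        for d in designs:
            for g in (d.guide1, d.guide2):
                assert not (g.start < 5950 and 5600 < g.end)

    def test_no_cds_raises(self, toy_world):
        _, genome, models = toy_world
        lnc = next(m for m in models if m.biotype == "lncRNA")
        with pytest.raises(ValueError, match="no annotated CDS"):
            pg.design_pc_target(lnc, genome)


class TestInsert1:
    def test_default_is_165nt(self):
        a = pg.Protospacer("A" * 20, "+", 0, "AGG")
        b = pg.Protospacer("C" * 20, "+", 100, "TGG")
        assert len(pg.emit_insert1(a, b)) == 165

    def test_round_trip(self):
        a = pg.Protospacer("ACGTACGTACGTACGTACGT", "+", 0, "AGG")
        b = pg.Protospacer("TTGCATTGCATTGCATTGCA", "-", 100, "CGG")
        oligo = pg.emit_insert1(a, b)
        assert pg.parse_insert1(oligo) == (a.sequence, b.sequence)

    def test_inconsistent_template_rejected(self):
        with pytest.raises(ValueError, match="template"):
            Insert1Template(arm5="A" * 10, cloning_site="C" * 10, arm3="G" * 10, total=165)


@pytest.fixture(scope="module")
def library(toy_world):
    cfg, genome, models = toy_world
    targets = [m for m in models if m.biotype == "protein_coding"][:2]
    spec = pg.ControlSpec(
        positive_genes={models[2].gene_id: 3},
        n_intergenic=4,
        intergenic_designs=2,
        region_size=600,
    )
    table = pg.build_library(
        targets, genome, control_spec=spec, models=models, n_designs=4, seed=1
    )
    return table, genome, models


class TestBuildLibrary:
    def test_composition_arithmetic(self, library):
        table, _, _ = library
        by_class = table.groupby("class").size().to_dict()
        assert by_class.get("intergenic_control", 0) == 4 * 2
        assert by_class.get("positive_control", 0) == 3
        assert table.construct_id.is_unique

    def test_intergenic_regions_clear_of_genes(self, library):
        table, _, models = library
        inter = table[table["class"] == "intergenic_control"]
        for _, row in inter.iterrows():
            for m in models:
                assert row.cut2 < m.start - 1000 or row.cut1 > m.end + 1000

    def test_guide_columns_have_screen_lengths(self, library):
        table, _, _ = library
        assert (table.guide1.str.len() == 21).all()
        assert (table.guide2.str.len() == 20).all()
        assert (table.guide1.str[0] == "G").all()
        assert (table.insert1.str.len() == 165).all()

    def test_same_seed_identical_tables(self, toy_world, tmp_path):
        cfg, genome, models = toy_world
        targets = [m for m in models if m.biotype == "protein_coding"][:1]
        for run in ("a", "b"):
            t = pg.build_library(targets, genome, models=models, n_designs=3, seed=7)
            pg.pgrna_design.write_library(t, tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
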