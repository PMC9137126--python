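"""Paired-guide (pgRNA) library design for CRISPR deletion screens.

Protein-coding genes are targeted inside their first coding exons (window
extended to exons 2 and 3 when needed) so that the two Cas9 cuts excise an
ORF fragment, preferring out-of-frame deletions. lncRNAs are targeted with
pairs straddling the TSS inside a symmetric window grown stepwise from 500
to 5,000 bp. Candidate guides are 20-mers followed by an NGG PAM, scored by
a pluggable on-target scorer, filtered by a genome-wide Hamming off-target
scan, and emitted as 165-nt DECKO-style insert-1 oligos.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, revcomp

GUIDE_LEN = 20
PAM_LEN = 3
#: Blunt Cas9 cut 3 bp 5' of the PAM, i.e. between protospacer positions 17/18.
CUT_OFFSET = 17

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i + 1  # 0 = anything non-ACGT, never matches


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class Protospacer:
    """A 20-nt Cas9 target site with its NGG PAM context.

    ``start`` is the 0-based genomic start of the protospacer span;
    ``cut_site`` the genomic coordinate of the blunt cut (inside the span).
    ``exon_index`` is the 0-based ORF-exon index used for ranking
    protein-coding pairs (0 outside ORF-directed design).
    """

    sequence: str
    strand: str
    start: int
    pam: str
    chrom: str = ""
    score: float | None = None
    exon_index: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != GUIDE_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must be NGG, got {self.pam!r}")

    @property
    def end(self) -> int:
        return self.start + GUIDE_LEN

    @property
    def cut_site(self) -> int:
        return self.start + CUT_OFFSET if self.strand == "+" else self.start + 3

    @property
    def guide1_seq(self) -> str:
        """21-nt guide-1 segment: transcription-start G + protospacer."""
        return "G" + self.sequence


@dataclass
class PgRNADesign:
    """One ranked guide pair against one target, with its insert-1 oligo."""

    target_id: str
    cls: str  # pc | lnc | positive_control | intergenic_control | fluorophore
    guide1: Protospacer
    guide2: Protospacer
    pair_score: float
    rank: int
    insert1: str
    construct_id: str = ""

    def __post_init__(self) -> None:
        if self.guide1.cut_site >= self.guide2.cut_site:
            raise ValueError("guide1 must cut upstream of guide2")
        if not self.construct_id:
            self.construct_id = f"{self.target_id}_pg{self.rank}"

    @property
    def deletion_len(self) -> int:
        return self.guide2.cut_site - self.guide1.cut_site

    @property
    def frame_status(self) -> str:
        if self.cls != "pc" and self.cls != "positive_control":
            return "n/a"
        return "out_of_frame" if self.deletion_len % 3 else "in_frame"


# ---------------------------------------------------------------------------
# protospacer enumeration
# ---------------------------------------------------------------------------

def enumerate_protospacers(
    seq: str,
    chrom: str = "",
    offset: int = 0,
    strands: str = "+-",
) -> list[Protospacer]:
    """All 20-mers followed by NGG, on the requested strands, sorted by cut site.

    ``offset`` shifts reported coordinates so that ``seq`` may be a genomic
    sub-region. Windows containing non-ACGT characters are skipped (warning).
    """
    if len(seq) < GUIDE_LEN + PAM_LEN:
        return []
    seq = seq.upper()
    had_ambiguous = False
    out: list[Protospacer] = []
    enc = _encode(seq)
    valid = enc > 0
    L = len(seq)
    if "+" in strands:
        for i in range(L - 22):
            if seq[i + 21 : i + 23] == "GG":
                if not valid[i : i + 23].all():
                    had_ambiguous = True
                    continue
                out.append(
                    Protospacer(
                        sequence=seq[i : i + 20],
                        strand="+",
                        start=offset + i,
                        pam=seq[i + 20 : i + 23],
                        chrom=chrom,
                    )
                )
    if "-" in strands:
        for j in range(L - 22):
            if seq[j : j + 2] == "CC":
                if not valid[j : j + 23].all():
                    had_ambiguous = True
                    continue
                span = seq[j + 3 : j + 23]
                out.append(
                    Protospacer(
                        sequence=revcomp(span),
                        strand="-",
                        start=offset + j + 3,
                        pam=revcomp(seq[j : j + 3]),
                        chrom=chrom,
                    )
                )
    if had_ambiguous:
        warnings.warn("skipped protospacer windows containing non-ACGT characters")
    out.sort(key=lambda p: (p.cut_site, p.strand, p.start))
    return out


# ---------------------------------------------------------------------------
# on-target scoring
# ---------------------------------------------------------------------------

class PositionWeightScorer:
    """Deterministic surrogate on-target scorer.

    The score is a sum of position-specific nucleotide weights over the 30-nt
    context (4 nt upstream + protospacer + PAM + 3 nt downstream) minus a
    penalty for protospacer GC content far from 10/20, affine-rescaled to
    [0, 1]. The weight table is a fixed, documented stand-in that encodes
    coarse Cas9 preferences (G favoured adjacent to the PAM, T disfavoured in
    the seed, PAM-variable-base preference); it is not a trained model, and
    any scorer with the same call signature can be plugged in instead.
    """

    #: (position in 30-nt context, nucleotide) -> weight
    WEIGHTS: Mapping[tuple[int, str], float] = {
        (3, "C"): 0.08,   # base directly 5' of the protospacer
        (4, "G"): 0.06, (4, "T"): -0.08,
        (9, "A"): 0.05,
        (14, "G"): 0.07, (14, "C"): 0.04,
        (19, "T"): -0.12, (19, "G"): 0.09,   # seed region
        (20, "T"): -0.14,
        (21, "C"): 0.06, (21, "T"): -0.10,
        (22, "T"): -0.12,
        (23, "G"): 0.20, (23, "C"): 0.10, (23, "T"): -0.18,  # PAM-proximal base
        (24, "C"): 0.12, (24, "T"): -0.10,  # PAM N
        (27, "G"): 0.05,  # first downstream base
    }
    GC_PENALTY = 0.03
    _BASELINE = 0.55
    _SPAN = 1.6  # affine rescale denominator

    def __call__(self, context: str) -> float:
        context = context.upper()
        raw = sum(
            w for (pos, nt), w in self.WEIGHTS.items()
            if pos < len(context) and context[pos] == nt
        )
        proto = context[4:24] if len(context) >= 24 else context
        gc = sum(1 for b in proto if b in "GC")
        raw -= self.GC_PENALTY * abs(gc - 10)
        return float(np.clip((raw + self._BASELINE) / self._SPAN, 0.0, 1.0))


def get_context(p: Protospacer, genome: Mapping[str, str]) -> str:
    """30-nt scoring context around a protospacer, in guide orientation.

    Truncated (with a warning) when the site is too close to a sequence end.
    """
    seq = genome[p.chrom]
    if p.strand == "+":
        lo, hi = p.start - 4, p.start + GUIDE_LEN + PAM_LEN + 3
        ctx = seq[max(0, lo) : min(len(seq), hi)]
    else:
        lo, hi = p.start - PAM_LEN - 3, p.start + GUIDE_LEN + 4
        ctx = revcomp(seq[max(0, lo) : min(len(seq), hi)])
    if len(ctx) < 30:
        warnings.warn(
            f"protospacer at {p.chrom}:{p.start} scored on truncated context"
        )
    return ctx


def score_protospacer(
    p: Protospacer,
    genome: Mapping[str, str],
    scorer: Callable[[str], float] | None = None,
) -> float:
    """Score a protospacer on its 30-nt genomic context; stores the score."""
    scorer = scorer or PositionWeightScorer()
    p.score = float(scorer(get_context(p, genome)))
    return p.score


# ---------------------------------------------------------------------------
# off-target counting
# ---------------------------------------------------------------------------

DEFAULT_OFFTARGET_THRESHOLDS: tuple[int | None, ...] = (0, 0, 0, None, None)


class OffTargetIndex:
    """All NGG-adjacent 20-mer sites of a genome, both strands, for Hamming scans."""

    def __init__(self, genome: Mapping[str, str]):
        mats, chroms, strands, starts = [], [], [], []
        comp = np.array([0, 4, 3, 2, 1], dtype=np.uint8)  # complement in code space
        for chrom, seq in genome.items():
            enc = _encode(seq.upper())
            L = len(enc)
            if L < 23:
                continue
            win = np.lib.stride_tricks.sliding_window_view(enc, GUIDE_LEN)
            i = np.arange(L - 22)
            fwd = i[(enc[i + 21] == 3) & (enc[i + 22] == 3)]  # G == 3
            if len(fwd):
                mats.append(win[fwd])
                starts.append(fwd)
                strands.append(np.zeros(len(fwd), dtype=np.uint8))
                chroms.extend([chrom] * len(fwd))
            rev = i[(enc[i] == 2) & (enc[i + 1] == 2)]  # C == 2
            if len(rev):
                mats.append(comp[win[rev + 3]][:, ::-1])
                starts.append(rev + 3)
                strands.append(np.ones(len(rev), dtype=np.uint8))
                chroms.extend([chrom] * len(rev))
        if mats:
            self.mat = np.ascontiguousarray(np.vstack(mats))
            self.start = np.concatenate(starts)
            self.strand = np.concatenate(strands)
            self.chrom = np.array(chroms)
        else:
            self.mat = np.empty((0, GUIDE_LEN), dtype=np.uint8)
            self.start = np.empty(0, dtype=int)
            self.strand = np.empty(0, dtype=np.uint8)
            self.chrom = np.empty(0, dtype=object)

    def distances(self, protospacer: str) -> np.ndarray:
        q = _encode(protospacer.upper())
        return (self.mat != q).sum(axis=1)


def count_offtargets(
    p: Protospacer,
    index: OffTargetIndex | Mapping[str, str],
    thresholds: Sequence[int | None] = DEFAULT_OFFTARGET_THRESHOLDS,
    max_distance: int = 4,
) -> tuple[bool, list[int]]:
    """Count NGG-adjacent genomic sites within Hamming distance 0..4.

    The on-target locus itself is excluded. Returns ``(passed, counts)``
    where ``counts[d]`` is the number of off-target sites at distance d and
    pass requires counts[d] <= thresholds[d] for every d (None = unlimited).
    """
    if not isinstance(index, OffTargetIndex):
        if index is None:
            raise ValueError("a genome or off-target index is required")
        index = OffTargetIndex(index)
    d = index.distances(p.sequence)
    own = (
        (index.chrom == p.chrom)
        & (index.start == p.start)
        & (index.strand == (0 if p.strand == "+" else 1))
    )
    d = d[~own]
    counts = [int((d == k).sum()) for k in range(max_distance + 1)]
    passed = all(
        t is None or counts[k] <= t
        for k, t in enumerate(thresholds[: max_distance + 1])
    )
    return passed, counts


# ---------------------------------------------------------------------------
# pairing and ranking
# ---------------------------------------------------------------------------

def _frame_rank(deletion_len: int) -> int:
    return 0 if deletion_len % 3 else 1  # out-of-frame first


def rank_pairs_pc(
    protospacers: Sequence[Protospacer],
) -> list[tuple[Protospacer, Protospacer]]:
    """All guide pairs (cut1 < cut2) in design priority order.

    Sort key: earlier ORF location first (the lower ORF-exon index of the
    pair), then higher summed pair score, then out-of-frame deletions before
    in-frame ones, with a deterministic (start1, start2) tie-break.
    """
    cands = []
    for a, b in itertools.combinations(sorted(protospacers, key=lambda p: p.cut_site), 2):
        if a.cut_site == b.cut_site:
            continue
        g1, g2 = (a, b) if a.cut_site < b.cut_site else (b, a)
        dlen = g2.cut_site - g1.cut_site
        pair_score = (g1.score or 0.0) + (g2.score or 0.0)
        key = (
            min(g1.exon_index, g2.exon_index),
            -pair_score,
            _frame_rank(dlen),
            g1.start,
            g2.start,
        )
        cands.append((key, g1, g2))
    cands.sort(key=lambda t: t[0])
    return [(g1, g2) for _, g1, g2 in cands]


def _min_separation_ok(
    g1: Protospacer,
    g2: Protospacer,
    accepted: Sequence[PgRNADesign],
    min_sep: int,
    enforce_within_pair: bool = True,
) -> bool:
    """Both readings of the 50-bp rule: every two guide cut sites among a
    target's accepted designs differ by >= min_sep, and the pair's own guides
    are >= min_sep apart."""
    if enforce_within_pair and g2.cut_site - g1.cut_site < min_sep:
        return False
    for d in accepted:
        for new in (g1, g2):
            for old in (d.guide1, d.guide2):
                if abs(new.cut_site - old.cut_site) < min_sep:
                    return False
    return True


# ---------------------------------------------------------------------------
# insert-1 emission
# ---------------------------------------------------------------------------

def _make_default_template() -> "Insert1Template":
    arm5 = "GTATCCCTTGGAGAACCACCTTGTT"  # 25 nt
    core = "GTTTAAGAGCTATGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCCGAATTCGGATCC"
    cloning = (core + "GT" * 6)[:75]  # 75 nt, carries EcoRI/BamHI sites
    arm3 = "TTTTAGAGCTAGAAATAGCAAGTTA"  # 25 nt
    return Insert1Template(arm5=arm5, cloning_site=cloning, arm3=arm3)


@dataclass(frozen=True)
class Insert1Template:
    """Fixed segments of the insert-1 oligo: arm5 + guide1(20) + cloning site
    + guide2(20) + arm3, totalling ``total`` nt.

    The default arms are synthetic placeholders; only the structure (165 nt,
    two 20-nt targeting regions around a central cloning site) is contractual.
    """

    arm5: str
    cloning_site: str
    arm3: str
    total: int = 165

    def __post_init__(self) -> None:
        fixed = len(self.arm5) + len(self.cloning_site) + len(self.arm3)
        if fixed + 2 * GUIDE_LEN != self.total:
            raise ValueError(
                f"template fixed segments ({fixed} nt) + 40 nt guides != "
                f"declared total {self.total}"
            )

    @property
    def guide1_slice(self) -> slice:
        a = len(self.arm5)
        return slice(a, a + GUIDE_LEN)

    @property
    def guide2_slice(self) -> slice:
        a = len(self.arm5) + GUIDE_LEN + len(self.cloning_site)
        return slice(a, a + GUIDE_LEN)


DEFAULT_INSERT1_TEMPLATE = _make_default_template()


def emit_insert1(
    guide1: Protospacer,
    guide2: Protospacer,
    template: Insert1Template = DEFAULT_INSERT1_TEMPLATE,
) -> str:
    """The cloning oligo carrying both protospacers (165 nt by default)."""
    oligo = (
        template.arm5
        + guide1.sequence
        + template.cloning_site
        + guide2.sequence
        + template.arm3
    )
    assert len(oligo) == template.total
    return oligo


def parse_insert1(
    oligo: str, template: Insert1Template = DEFAULT_INSERT1_TEMPLATE
) -> tuple[str, str]:
    """Recover the two protospacers from an insert-1 oligo (inverse of emit)."""
    if len(oligo) != template.total:
        raise ValueError(f"oligo length {len(oligo)} != template total {template.total}")
    return oligo[template.guide1_slice], oligo[template.guide2_slice]


# ---------------------------------------------------------------------------
# per-target design
# ---------------------------------------------------------------------------

def _score_and_filter(
    cands: Iterable[Protospacer],
    genome: Mapping[str, str],
    index: OffTargetIndex,
    scorer: Callable[[str], float],
    thresholds: Sequence[int | None],
) -> list[Protospacer]:
    out = []
    for p in cands:
        ok, _ = count_offtargets(p, index, thresholds)
        if ok:
            score_protospacer(p, genome, scorer)
            out.append(p)
    return out


def _greedy_fill(
    pairs: Sequence[tuple[Protospacer, Protospacer]],
    accepted: list[PgRNADesign],
    target_id: str,
    cls: str,
    n: int,
    min_sep: int,
    template: Insert1Template,
) -> None:
    for g1, g2 in pairs:
        if len(accepted) >= n:
            return
        if _min_separation_ok(g1, g2, accepted, min_sep):
            accepted.append(
                PgRNADesign(
                    target_id=target_id,
                    cls=cls,
                    guide1=g1,
                    guide2=g2,
                    pair_score=(g1.score or 0.0) + (g2.score or 0.0),
                    rank=len(accepted) + 1,
                    insert1=emit_insert1(g1, g2, template),
                )
            )


def design_pc_target(
    gene: GeneModel,
    genome: Mapping[str, str],
    index: OffTargetIndex | None = None,
    scorer: Callable[[str], float] | None = None,
    n: int = 10,
    min_sep: int = 50,
    thresholds: Sequence[int | None] = DEFAULT_OFFTARGET_THRESHOLDS,
    template: Insert1Template = DEFAULT_INSERT1_TEMPLATE,
    cls: str = "pc",
) -> list[PgRNADesign]:
    """ORF-directed designs: first coding exon preferred, window extended to
    exons 2 and 3 while fewer than ``n`` designs are placed."""
    if not gene.cds:
        raise ValueError(f"gene {gene.gene_id} has no annotated CDS")
    index = index if index is not None else OffTargetIndex(genome)
    scorer = scorer or PositionWeightScorer()
    seq = genome[gene.chrom]
    orf_exons = gene.cds_in_orf_order()[:3]

    per_exon: list[list[Protospacer]] = []
    for ei, (s, e) in enumerate(orf_exons):
        lo = max(0, s - 25)
        cands = [
            p
            for p in enumerate_protospacers(seq[lo : e + 25], gene.chrom, offset=lo)
            if p.start >= s and p.end <= e
        ]
        for p in cands:
            p.exon_index = ei
        per_exon.append(
            _score_and_filter(cands, genome, index, scorer, thresholds)
        )

    accepted: list[PgRNADesign] = []
    for w in range(1, len(per_exon) + 1):
        pool = [p for ex in per_exon[:w] for p in ex]
        if len(pool) < 2:
            continue
        _greedy_fill(
            rank_pairs_pc(pool), accepted, gene.gene_id, cls, n, min_sep, template
        )
        if len(accepted) >= n:
            break
    if not accepted:
        warnings.warn(f"no valid design for target {gene.gene_id}")
    return accepted


LNC_WINDOW_STEPS = (500, 1000, 2000, 3000, 4000, 5000)


def relaxed_thresholds(step: int) -> tuple[int | None, ...]:
    """Off-target thresholds after ``step`` window expansions: one extra
    2-mismatch site allowed per expansion (exact and 1-mismatch duplicates
    never allowed)."""
    return (0, 0, step, None, None)


def design_lnc_target(
    gene: GeneModel,
    genome: Mapping[str, str],
    index: OffTargetIndex | None = None,
    pc_models: Sequence[GeneModel] = (),
    scorer: Callable[[str], float] | None = None,
    n: int = 10,
    min_sep: int = 50,
    template: Insert1Template = DEFAULT_INSERT1_TEMPLATE,
    cls: str = "lnc",
) -> list[PgRNADesign]:
    """TSS-deletion designs: pairs straddle the TSS inside a symmetric window
    grown through 500..5,000 bp, relaxing off-target thresholds one step per
    expansion; guides overlapping protein-coding genes are discarded."""
    index = index if index is not None else OffTargetIndex(genome)
    scorer = scorer or PositionWeightScorer()
    seq = genome[gene.chrom]
    tss = gene.tss
    pc = [m for m in pc_models if m.biotype == "protein_coding" and m.chrom == gene.chrom]

    accepted: list[PgRNADesign] = []
    for step, width in enumerate(LNC_WINDOW_STEPS):
        lo = max(0, tss - width // 2)
        hi = min(len(seq), tss + width // 2)
        cands = [
            p
            for p in enumerate_protospacers(seq[lo:hi], gene.chrom, offset=lo)
            if not any(m.overlaps(p.start, p.end) for m in pc)
        ]
        cands = _score_and_filter(
            cands, genome, index, scorer, relaxed_thresholds(step)
        )
        up = [p for p in cands if p.cut_site < tss]
        down = [p for p in cands if p.cut_site > tss]
        pairs = sorted(
            itertools.product(up, down),
            key=lambda gg: (
                -((gg[0].score or 0.0) + (gg[1].score or 0.0)),
                gg[0].start,
                gg[1].start,
            ),
        )
        _greedy_fill(pairs, accepted, gene.gene_id, cls, n, min_sep, template)
        if len(accepted) >= n:
            break
    if len(accepted) < n:
        warnings.warn(
            f"lncRNA target {gene.gene_id}: only {len(accepted)}/{n} designs "
            "after the 5 kb window"
        )
    return accepted


# ---------------------------------------------------------------------------
# library assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlSpec:
    """Positive-control genes (with per-gene design depth) and the number /
    size of intergenic negative-control regions."""

    positive_genes: Mapping[str, int] = field(default_factory=dict)
    n_intergenic: int = 100
    intergenic_designs: int = 10
    region_size: int = 1000
    min_gene_distance: int = 1000


def sample_intergenic_regions(
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    spec: ControlSpec,
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Seeded uniform sample of non-overlapping annotation-free regions at
    least ``min_gene_distance`` from every gene; fewer (with a warning) when
    the genome lacks space."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    regions: list[tuple[str, int, int]] = []
    for chrom, seq in genome.items():
        blocked = sorted(
            (max(0, m.start - spec.min_gene_distance), m.end + spec.min_gene_distance)
            for m in models
            if m.chrom == chrom
        )
        free, pos = [], 0
        for s, e in blocked:
            if s - pos >= spec.region_size:
                free.append((pos, s))
            pos = max(pos, e)
        if len(seq) - pos >= spec.region_size:
            free.append((pos, len(seq)))
        for lo, hi in free:
            regions.extend(
                (chrom, int(s), int(s) + spec.region_size)
                for s in range(lo, hi - spec.region_size + 1, spec.region_size)
            )
    if len(regions) < spec.n_intergenic:
        warnings.warn(
            f"only {len(regions)} intergenic regions available "
            f"(requested {spec.n_intergenic})"
        )
        return regions
    idx = rng.choice(len(regions), size=spec.n_intergenic, replace=False)
    return [regions[i] for i in sorted(idx)]


def design_intergenic_region(
    region: tuple[str, int, int],
    region_id: str,
    genome: Mapping[str, str],
    index: OffTargetIndex,
    scorer: Callable[[str], float],
    n: int,
    min_sep: int = 50,
    template: Insert1Template = DEFAULT_INSERT1_TEMPLATE,
) -> list[PgRNADesign]:
    chrom, lo, hi = region
    cands = enumerate_protospacers(genome[chrom][lo:hi], chrom, offset=lo)
    cands = _score_and_filter(
        cands, genome, index, scorer, DEFAULT_OFFTARGET_THRESHOLDS
    )
    pairs = []
    for a, b in itertools.combinations(sorted(cands, key=lambda p: p.cut_site), 2):
        if a.cut_site < b.cut_site:
            pairs.append((a, b))
    pairs.sort(
        key=lambda gg: (
            -((gg[0].score or 0.0) + (gg[1].score or 0.0)),
            gg[0].start,
            gg[1].start,
        )
    )
    accepted: list[PgRNADesign] = []
    _greedy_fill(pairs, accepted, region_id, "intergenic_control", n, min_sep, template)
    return accepted


def designs_to_table(designs: Sequence[PgRNADesign]) -> pd.DataFrame:
    """Flatten designs into the on-disk library schema."""
    rows = []
    for d in designs:
        rows.append(
            {
                "construct_id": d.construct_id,
                "target_id": d.target_id,
                "class": d.cls,
                "guide1": d.guide1.guide1_seq,
                "guide2": d.guide2.sequence,
                "chrom": d.guide1.chrom,
                "strand1": d.guide1.strand,
                "strand2": d.guide2.strand,
                "start1": d.guide1.start,
                "start2": d.guide2.start,
                "cut1": d.guide1.cut_site,
                "cut2": d.guide2.cut_site,
                "deletion_len": d.deletion_len,
                "frame_status": d.frame_status,
                "pair_score": d.pair_score,
                "rank": d.rank,
                "insert1": d.insert1,
            }
        )
    return pd.DataFrame(rows)


def build_library(
    targets: Sequence[GeneModel],
    genome: Mapping[str, str],
    control_spec: ControlSpec | None = None,
    models: Sequence[GeneModel] = (),
    scorer: Callable[[str], float] | None = None,
    n_designs: int = 10,
    min_sep: int = 50,
    seed: int = 0,
    extra_constructs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Design the full construct collection: targets + controls.

    ``models`` is the complete annotation (used for lncRNA/pc overlap checks
    and intergenic placement); ``extra_constructs`` rows (e.g. fluorophore
    controls) are appended as-is. Construct ids are unique; identical seeds
    give byte-identical tables.
    """
    control_spec = control_spec or ControlSpec(n_intergenic=0)
    scorer = scorer or PositionWeightScorer()
    index = OffTargetIndex(genome)
    models = models or targets
    by_id = {m.gene_id: m for m in models}

    designs: list[PgRNADesign] = []
    for g in targets:
        if g.biotype == "protein_coding":
            designs += design_pc_target(
                g, genome, index, scorer, n=n_designs, min_sep=min_sep
            )
        else:
            designs += design_lnc_target(
                g, genome, index, pc_models=models, scorer=scorer,
                n=n_designs, min_sep=min_sep,
            )
    for gid, n_pos in control_spec.positive_genes.items():
        g = by_id[gid]
        designs += design_pc_target(
            g, genome, index, scorer, n=n_pos, min_sep=min_sep,
            cls="positive_control",
        )
    regions = (
        sample_intergenic_regions(genome, models, control_spec, seed=seed)
        if control_spec.n_intergenic
        else []
    )
    for i, region in enumerate(regions):
        designs += design_intergenic_region(
            region, f"intergenic{i:03d}", genome, index, scorer,
            n=control_spec.intergenic_designs, min_sep=min_sep,
        )

    table = designs_to_table(designs)
    if extra_constructs is not None and len(extra_constructs):
        table = pd.concat([table, extra_constructs], ignore_index=True)
    if table["construct_id"].duplicated().any():
        raise ValueError("construct ids are not unique")
    return table


def write_library(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_library(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_oligo_fasta(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            fh.write(f">{row['construct_id']}\n{row['insert1']}\n")
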