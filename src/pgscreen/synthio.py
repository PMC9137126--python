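"""Synthetic inputs for the paired-guide screen pipeline.

Everything the pipeline consumes can be generated here with a fixed seed:

* a toy genome + gene annotation (multi-exon protein-coding genes with CDS,
  isolated lncRNAs with a usable TSS, and intergenic space),
* two-replicate 12-timepoint FPKM matrices with planted profile classes
  (peaking / upregulated / flat / down),
* a paired-guide library table and sorted-population paired-end screen reads
  with stagger prefixes, vector anchors, sequencing errors and
  negative-binomial counts, with configurable enrichment spiked into the
  delayed fraction of chosen targets.

Identical :class:`SimConfig` (including seed) yields byte-identical outputs.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, revcomp, write_fasta, write_gtf

PROFILE_CLASSES = ("peaking", "upregulated", "flat", "down")

#: Hours sampled along the transdifferentiation time course.
DEFAULT_TIMEPOINTS_H = (0, 3, 6, 9, 12, 18, 24, 36, 48, 72, 120, 168)

# Fixed vector-context placeholders flanking the two cloning anchors. Only the
# "ACCG"/"AAAC" anchors and the window geometry are contractual; the true
# backbone sequence is not reproduced here. Neither context contains a spurious
# in-window anchor match.
READ2_CONTEXT = "GTGGAAAGGACGAAAC"  # 16 nt, precedes "ACCG" + guide-1 on read 2
READ1_CONTEXT = ("ACGTTGCA" * 14)[:105]  # 105 nt, precedes "AAAC" + rc(guide-2) on read 1
ANCHOR1 = "ACCG"
ANCHOR2 = "AAAC"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults encode the screen's stated conditions: 12 sampling timepoints,
    150-bp paired-end reads, anchor windows at positions 15-55 of read 2 and
    100-150 of read 1, and over-dispersed counts for the sorted fractions.
    """

    seed: int = 0
    # time-course
    pc_genes_per_class: int = 10
    lnc_genes_per_class: int = 3
    n_pc_genes: int | None = None  # explicit totals override the per-class counts
    n_lnc_genes: int | None = None
    timepoints_h: tuple[int, ...] = DEFAULT_TIMEPOINTS_H
    noise_sd: float = 0.1  # gaussian sd on log10(FPKM + 0.01)
    # genome
    genome_length: int | None = None  # None -> auto-sized to fit the genes
    # screen
    read_len_1: int = 150
    read_len_2: int = 150
    stagger_range: tuple[int, int] = (0, 7)
    error_rate: float = 0.001  # per-base substitution probability
    depth: float = 100.0  # mean reads per construct per sample
    nb_dispersion: float = 0.2
    spike_targets: tuple[tuple[str, float], ...] = ()
    spike_construct_sd: float = 1.0  # ln-scale construct-level fold heterogeneity

    def __post_init__(self) -> None:
        tp = tuple(self.timepoints_h)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints_h must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


# ---------------------------------------------------------------------------
# toy genome + annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_toy_annotation(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a random genome and a gene annotation laid out on it.

    Protein-coding genes are multi-exon with an in-frame CDS; lncRNAs are
    placed with >= 5 kb clearance to any neighbour so that the downstream TSS
    isolation filter retains them. An annotation-free tail of >= 5 kb is
    always left for intergenic controls.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_pc = (
        config.n_pc_genes
        if config.n_pc_genes is not None
        else config.pc_genes_per_class * len(PROFILE_CLASSES)
    )
    n_lnc = (
        config.n_lnc_genes
        if config.n_lnc_genes is not None
        else config.lnc_genes_per_class * len(PROFILE_CLASSES)
    )

    models: list[GeneModel] = []
    cursor = 500
    chrom = "chrS"

    def place_pc(idx: int) -> int:
        nonlocal cursor
        strand = "+" if idx % 2 == 0 else "-"
        n_ex = int(rng.integers(2, 4))
        exons, cds = [], []
        pos = cursor
        total = 0
        for j in range(n_ex):
            elen = int(rng.integers(150, 300))
            if j == n_ex - 1:  # pad the last exon so the CDS is a codon multiple
                elen += (-(total + elen)) % 3
            exons.append((pos, pos + elen))
            cds.append((pos, pos + elen))
            total += elen
            pos += elen + int(rng.integers(120, 300))
        end = exons[-1][1]
        models.append(
            GeneModel(
                gene_id=f"pc{idx:04d}",
                chrom=chrom,
                strand=strand,
                biotype="protein_coding",
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
        cursor = end + 300
        return end

    def place_lnc(idx: int) -> int:
        nonlocal cursor
        cursor += 5200  # upstream clearance for the TSS isolation filter
        strand = "+" if idx % 2 == 0 else "-"
        n_ex = int(rng.integers(1, 3))
        exons = []
        pos = cursor
        for _ in range(n_ex):
            elen = int(rng.integers(200, 400))
            exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(150, 300))
        end = exons[-1][1]
        models.append(
            GeneModel(
                gene_id=f"lnc{idx:04d}",
                chrom=chrom,
                strand=strand,
                biotype="lncRNA",
                exons=tuple(exons),
            )
        )
        cursor = end + 5200  # downstream clearance
        return end

    for i in range(n_pc):
        place_pc(i)
    for i in range(n_lnc):
        place_lnc(i)

    needed = cursor + 5000  # intergenic tail for negative controls
    glen = config.genome_length if config.genome_length is not None else needed
    if glen < 10_000:
        raise ValueError("genome_length must be at least 10 kb")
    if glen < needed:
        raise ValueError(
            f"genome too small to place the requested genes: need >= {needed} bp, "
            f"got {glen}"
        )
    genome = {chrom: _random_seq(rng, glen)}
    return genome, models


# ---------------------------------------------------------------------------
# time-course FPKM matrices
# ---------------------------------------------------------------------------

def _class_template(
    cls: str, lo: float, hi: float, n_tp: int, peak_index: int
) -> np.ndarray:
    """Log-linear FPKM template for one profile class (peak fixed at 36 h)."""
    llo, lhi = np.log10(lo), np.log10(hi)
    idx = np.arange(n_tp)
    if cls == "upregulated":
        logv = llo + (lhi - llo) * idx / (n_tp - 1)
    elif cls == "down":
        logv = lhi - (lhi - llo) * idx / (n_tp - 1)
    elif cls == "peaking":
        up = llo + (lhi - llo) * idx[: peak_index + 1] / peak_index
        down = lhi - (lhi - llo) * (idx[peak_index + 1 :] - peak_index) / (
            n_tp - 1 - peak_index
        )
        logv = np.concatenate([up, down])
    elif cls == "flat":
        logv = np.full(n_tp, (llo + lhi) / 2)
    else:
        raise ValueError(f"unknown profile class {cls!r}")
    return 10.0 ** logv


def make_timecourse(
    models: Sequence[GeneModel], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-replicate FPKM matrices with planted profile classes.

    Classes are assigned round-robin over each biotype's genes (shuffled with
    the config seed). Replicates are independent Gaussian noise draws (sd
    ``noise_sd`` on log10 FPKM) around the same per-gene template. Protein
    coding templates run 0.5 -> 4.0 FPKM (8-fold); lncRNA templates
    0.15 -> 1.5 FPKM, so upregulated/peaking genes clear the expression
    filters while flat genes do not.

    Returns ``(rep1, rep2, truth)``; the matrices have columns
    ``gene_id, biotype, <one column per timepoint-hour>``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    tp = list(config.timepoints_h)
    n_tp = len(tp)
    peak_index = tp.index(36) if 36 in tp else n_tp // 2

    scales = {"protein_coding": (0.5, 4.0), "lncRNA": (0.15, 1.5)}
    rows_truth, profiles, gene_ids, biotypes = [], [], [], []
    for biotype in ("protein_coding", "lncRNA"):
        genes = [m for m in models if m.biotype == biotype]
        order = rng.permutation(len(genes))
        for rank, gi in enumerate(order):
            cls = PROFILE_CLASSES[rank % len(PROFILE_CLASSES)]
            lo, hi = scales[biotype]
            base = _class_template(cls, lo, hi, n_tp, peak_index)
            base = base * 10.0 ** rng.uniform(-0.1, 0.1)  # per-gene baseline jitter
            g = genes[gi]
            gene_ids.append(g.gene_id)
            biotypes.append(biotype)
            profiles.append(base)
            rows_truth.append((g.gene_id, biotype, cls))

    truth = pd.DataFrame(rows_truth, columns=["gene_id", "biotype", "profile_class"])
    prof = np.asarray(profiles)

    def one_rep() -> pd.DataFrame:
        noisy = 10.0 ** (np.log10(prof + 0.01) + rng.normal(0, config.noise_sd, prof.shape))
        df = pd.DataFrame(noisy, columns=[str(h) for h in tp])
        df.insert(0, "biotype", biotypes)
        df.insert(0, "gene_id", gene_ids)
        return df

    rep1, rep2 = one_rep(), one_rep()
    return rep1, rep2, truth


def write_fpkm_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fpkm_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# screen library / counts / reads
# ---------------------------------------------------------------------------

def make_random_library(
    n_targets: int,
    designs_per_target: int = 10,
    seed: int = 0,
    target_class: str = "pc",
    target_prefix: str = "T",
    start_index: int = 0,
) -> pd.DataFrame:
    """A library table with random (genome-free) guide sequences.

    Convenience generator for screen-level simulations where the guides'
    genomic provenance is irrelevant; columns match the designed-library
    contract (construct_id, target_id, class, guide1 21 nt, guide2 20 nt).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    rows = []
    seen: set[str] = set()
    for t in range(start_index, start_index + n_targets):
        tid = f"{target_prefix}{t:04d}"
        for d in range(designs_per_target):
            while True:
                g1 = "G" + _random_seq(rng, 20)
                g2 = _random_seq(rng, 20)
                if g1 + g2 not in seen:
                    seen.add(g1 + g2)
                    break
            rows.append((f"{tid}_pg{d + 1}", tid, target_class, g1, g2))
    return pd.DataFrame(
        rows, columns=["construct_id", "target_id", "class", "guide1", "guide2"]
    )


def screen_samples() -> pd.DataFrame:
    """The sorted-population sample layout: per-replicate T0 plus
    (T3, T6) x (delayed, differentiated) x 2 replicates."""
    rows = [("T0", "initial", r) for r in (1, 2)]
    rows += [
        (tp, frac, rep)
        for tp in ("T3", "T6")
        for frac in ("delayed", "differentiated")
        for rep in (1, 2)
    ]
    df = pd.DataFrame(rows, columns=["timepoint", "fraction", "replicate"])
    df.insert(0, "sample_id", [f"{t}_{f}_rep{r}" for t, f, r in rows])
    return df


def simulate_counts(
    library: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Negative-binomial construct counts for every sorted sample.

    Counts are Gamma-Poisson draws with mean ``depth`` (times the construct's
    delayed-fraction fold in delayed samples) and dispersion
    ``nb_dispersion`` (var = m + a m^2). Spiked targets get per-construct
    folds drawn once from a log-normal centred on the configured fold
    (ln-scale sd ``spike_construct_sd``), shared across replicates and
    timepoints — the construct-to-construct heterogeneity that makes
    replicate DDE values correlate for true effects.

    Returns ``(counts, samples, construct_folds)``.
    """
    if library.empty:
        raise ValueError("library must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    samples = screen_samples()
    constructs = library["construct_id"].to_numpy()
    spike_map = dict(config.spike_targets)

    folds = np.ones(len(library))
    for i, tid in enumerate(library["target_id"]):
        if tid in spike_map:
            folds[i] = spike_map[tid] * np.exp(
                rng.normal(0.0, config.spike_construct_sd)
            )
    construct_folds = pd.Series(folds, index=constructs, name="delayed_fold")

    alpha = config.nb_dispersion
    counts = {}
    for _, s in samples.iterrows():
        mean = np.full(len(constructs), config.depth)
        if s["fraction"] == "delayed":
            mean = mean * folds
        lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
        counts[s["sample_id"]] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(constructs, name="construct_id"))
    return counts_df, samples, construct_folds


_STAGGER = "TCTGTTGT"  # prefix pool for staggered read-2 starts (no in-window ACCG)


def _mutate(rng: np.random.Generator, read: str, k: int) -> str:
    """Apply k substitution errors at distinct positions."""
    pos = rng.choice(len(read), size=k, replace=False)
    chars = list(read)
    for p in pos:
        cur = chars[p]
        alts = [b for b in "ACGT" if b != cur]
        chars[p] = alts[int(rng.integers(3))]
    return "".join(chars)


def make_screen_reads(
    library: pd.DataFrame,
    config: SimConfig,
    outdir: str | os.PathLike,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Emit per-sample gzipped paired FASTQ plus the truth count table.

    Read 2 carries ``stagger + context + "ACCG" + guide1(21) + filler`` with
    the anchor-match start (1-based) inside [15, 55]; read 1 carries
    ``context + "AAAC" + revcomp(guide2) + filler`` with the anchor start
    inside [100, 150]. Substitution errors hit every base at ``error_rate``.
    Read names encode ``sample|construct_id|serial`` so each read maps to
    exactly one truth record.

    Returns ``(sample_sheet, counts_truth, construct_folds)`` where the
    sample sheet has columns sample_id, fastq1, fastq2, timepoint, fraction,
    replicate.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s_lo, s_hi = config.stagger_range
    anchor2_start = s_hi + len(READ2_CONTEXT) + 1  # worst case, 1-based
    if anchor2_start + 3 + 21 > config.read_len_2 or anchor2_start > 55:
        raise ValueError("read_len_2 too short for the read-2 anchor window")
    if len(READ1_CONTEXT) + 4 + 1 > config.read_len_1 + 4:
        raise ValueError("read_len_1 too short for the read-1 anchor window")

    counts_df, samples, folds = simulate_counts(library, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 71]))

    g1s = library["guide1"].to_numpy()
    g2rc = np.array([revcomp(g) for g in library["guide2"]])
    constructs = library["construct_id"].to_numpy()

    sheet_rows = []
    for _, s in samples.iterrows():
        sid = s["sample_id"]
        f1 = outdir / f"{sid}_R1.fastq.gz"
        f2 = outdir / f"{sid}_R2.fastq.gz"
        n_per_construct = counts_df[sid].to_numpy()
        total = int(n_per_construct.sum())
        staggers = rng.integers(s_lo, s_hi + 1, size=total)
        err1 = rng.binomial(config.read_len_1, config.error_rate, size=total)
        err2 = rng.binomial(config.read_len_2, config.error_rate, size=total)
        # bulk random filler, sliced per read (cheap vs per-read draws)
        core1_len = len(READ1_CONTEXT) + 4 + 20
        f1_len = max(0, config.read_len_1 - core1_len)
        f2_len = max(0, config.read_len_2 - (len(READ2_CONTEXT) + 4 + 21))
        fill1 = _random_seq(rng, total * f1_len) if f1_len else ""
        fill2 = _random_seq(rng, total * f2_len) if f2_len else ""

        buf1, buf2 = [], []
        r = 0
        for ci in range(len(constructs)):
            core1 = READ1_CONTEXT + ANCHOR2 + g2rc[ci]
            core2_tail = READ2_CONTEXT + ANCHOR1 + g1s[ci]
            for j in range(n_per_construct[ci]):
                st = int(staggers[r])
                read2 = _STAGGER[:st] + core2_tail
                read2 = (read2 + fill2[r * f2_len : (r + 1) * f2_len])[
                    : config.read_len_2
                ]
                read1 = (core1 + fill1[r * f1_len : (r + 1) * f1_len])[
                    : config.read_len_1
                ]
                if err1[r]:
                    read1 = _mutate(rng, read1, int(err1[r]))
                if err2[r]:
                    read2 = _mutate(rng, read2, int(err2[r]))
                name = f"{sid}|{constructs[ci]}|{j}"
                buf1.append(f"@{name}\n{read1}\n+\n{'I' * len(read1)}\n")
                buf2.append(f"@{name}\n{read2}\n+\n{'I' * len(read2)}\n")
                r += 1
        for path, buf in ((f1, buf1), (f2, buf2)):
            with open(path, "wb") as raw:
                with gzip.GzipFile(
                    filename="", mode="wb", fileobj=raw, mtime=0, compresslevel=1
                ) as gz:
                    gz.write("".join(buf).encode())
        sheet_rows.append(
            (sid, str(f1), str(f2), s["timepoint"], s["fraction"], s["replicate"])
        )

    sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "fastq1", "fastq2", "timepoint", "fraction", "replicate"],
    )
    return sheet, counts_df, folds


def simulate_all(config: SimConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every synthetic input (genome, GTF, FPKM, library, FASTQ, truth)
    under ``outdir``; returns a path manifest. Used by the CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models = make_toy_annotation(config)
    rep1, rep2, truth = make_timecourse(models, config)
    paths = {
        "genome": str(outdir / "genome.fa"),
        "gtf": str(outdir / "annotation.gtf"),
        "fpkm_rep1": str(outdir / "fpkm_rep1.tsv"),
        "fpkm_rep2": str(outdir / "fpkm_rep2.tsv"),
        "timecourse_truth": str(outdir / "timecourse_truth.tsv"),
        "library": str(outdir / "library.tsv"),
        "counts_truth": str(outdir / "counts_truth.tsv"),
        "sample_sheet": str(outdir / "samples.tsv"),
    }
    write_fasta(genome, paths["genome"])
    write_gtf(models, paths["gtf"])
    write_fpkm_tsv(rep1, paths["fpkm_rep1"])
    write_fpkm_tsv(rep2, paths["fpkm_rep2"])
    truth.to_csv(paths["timecourse_truth"], sep="\t", index=False)

    library = make_random_library(
        n_targets=20, designs_per_target=10, seed=config.seed
    )
    library.to_csv(paths["library"], sep="\t", index=False)
    sheet, counts_truth, _ = make_screen_reads(library, config, outdir / "fastq")
    counts_truth.to_csv(paths["counts_truth"], sep="\t")
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    return paths
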