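"""Synthetic 3'-end sequencing data with known ground truth.

Generates a random genome, a non-overlapping gene annotation, planted
poly(A) sites (PAS) carrying an upstream polyadenylation signal, planted
internal-priming artifact positions sitting on genomic A-runs, and
per-sample read 3'-end BED files. Gene counts are negative binomial,
reads are split multinomially over a gene's PASs, and cleavage positions
are jittered because cleavage does not occur with single-nucleotide
precision. A configurable fraction of genes are APA "switch" genes whose
proximal/distal usage shifts between the low- and high-temperature
groups, and a fraction are differentially expressed.

Everything is deterministic given the config seed; the returned
:class:`SimTruth` is the recovery oracle for the downstream pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "plant_pas_and_artifacts",
    "simulate_reads",
    "simulate_dataset",
    "write_dataset",
]

# Geometry of one gene "slot" on the simulated chromosome. Each gene owns
# a disjoint slot: body, then a downstream region where its PASs and its
# artifact site live, then spacer. Disjoint slots guarantee genes never
# overlap and that the half-distance 3'UTR extension rule always reaches
# every planted PAS.
GENE_BODY_LEN = 400
DOWNSTREAM_LEN = 300
SPACER_LEN = 400
SLOT_LEN = GENE_BODY_LEN + DOWNSTREAM_LEN + SPACER_LEN

SIGNAL_HEXAMER = "AATAAA"
SIGNAL_OFFSET = -21  # sense-strand start offset of the planted hexamer
ARTIFACT_OFFSET = 25  # sense offset of the artifact site from the 3' end
_A_RUN = 8  # planted artifact run length (>= the filter threshold of 7)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design being emulated: three biological
    replicates per pooled temperature group, negative-binomial gene
    counts with dispersion 0.1 around a mean of 200 reads per gene and
    sample, one to three PASs per gene, and cleavage jitter of up to
    8 nt around the true site.
    """

    n_genes: int = 200
    pas_per_gene_range: tuple[int, int] = (1, 3)
    n_replicates: int = 3
    groups: tuple[str, str] = ("low", "high")
    gene_mean: float = 200.0
    gene_dispersion: float = 0.1
    switch_fraction: float = 0.0
    switch_delta: float = 0.3
    de_fraction: float = 0.0
    de_log2_shift: float = 1.32  # ~2.5-fold planted expression change
    jitter_scale: int = 8
    artifact_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pas_per_gene_range
        if lo < 1 or hi < lo:
            raise ValueError("pas_per_gene_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.switch_fraction <= 1.0):
            raise ValueError("switch_fraction must be in [0, 1]")
        if not (0.0 <= self.switch_delta < 1.0):
            raise ValueError("switch_delta must be in [0, 1)")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be non-negative")
        for name in ("gene_mean", "gene_dispersion"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")
        if not (0.0 <= self.artifact_fraction < 1.0):
            raise ValueError("artifact_fraction must be in [0, 1)")
        if self.n_genes < 0 or self.n_replicates < 1:
            raise ValueError("n_genes >= 0 and n_replicates >= 1 required")


@dataclass
class SimTruth:
    """Planted ground truth tables.

    true_pas: gene_id, chrom, strand, site, rank, plus per-group usage
        proportion columns ``usage_<group>``.
    artifact_sites: gene_id, chrom, strand, site.
    switch_genes: gene_id, apa_class ("I" or "II").
    de_genes: gene_id, log2_shift (low relative to high).
    """

    true_pas: pd.DataFrame
    artifact_sites: pd.DataFrame
    switch_genes: pd.DataFrame
    de_genes: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a random genome and a non-overlapping gene annotation.

    Returns the genome as ``{chrom: sequence}`` (uppercase A/C/G/T) and an
    annotation table with columns gene_id, chrom, start, end (0-based
    half-open body span), strand, annotated_3p_end (0-based coordinate of
    the last transcribed body nucleotide).
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = "chrS1"
    chrom_len = SLOT_LEN * max(cfg.n_genes, 1) + 2 * SLOT_LEN
    seq = _random_seq(rng, chrom_len)

    rows = []
    for i in range(cfg.n_genes):
        slot = SLOT_LEN * i + SLOT_LEN  # leave one empty slot at each end
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start = slot
            end = slot + GENE_BODY_LEN
            three_p = end - 1
        else:
            # body at the far end of the slot so the downstream region
            # (decreasing coordinates) stays inside the slot
            end = slot + SLOT_LEN - SPACER_LEN
            start = end - GENE_BODY_LEN
            three_p = start
        rows.append((f"g{i:04d}", chrom, start, end, strand, three_p))

    ann = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "annotated_3p_end"],
    )
    if chrom_len < SLOT_LEN * cfg.n_genes:
        raise ValueError("genome too short to place requested genes")
    return {chrom: _to_str(seq)}, ann


def _write_sense(seq: np.ndarray, strand: str, site: int, offset: int, motif: str) -> None:
    """Write ``motif`` so that it reads 5'->3' on the sense strand starting
    at the given sense offset from ``site``."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    if strand == "+":
        start = site + offset
        for k, b in enumerate(motif):
            seq[start + k] = idx[b]
    else:
        start = site - offset
        comp = {"A": 3, "C": 2, "G": 1, "T": 0}
        for k, b in enumerate(motif):
            seq[start - k] = comp[b]


def _break_a_runs(seq: np.ndarray, strand: str, site: int, lo: int, hi: int,
                  protected: set[int]) -> None:
    """Destroy sense-strand A-runs of length >= 7 inside offsets lo..hi.

    ``protected`` holds sense offsets that must not be edited (the planted
    signal). A run of >= 7 A always has an editable base because the
    signal's own runs are at most 3 long.
    """
    a_code = 0 if strand == "+" else 3  # sense A is genomic T on the minus strand
    while True:
        run = 0
        edited = False
        for off in range(lo, hi + 1):
            pos = site + off if strand == "+" else site - off
            if seq[pos] == a_code:
                run += 1
                if run >= 7:
                    # break the run at its last unprotected base
                    for back in range(run):
                        o2 = off - back
                        if o2 not in protected:
                            p2 = site + o2 if strand == "+" else site - o2
                            seq[p2] = 1 if strand == "+" else 2  # sense C
                            edited = True
                            break
                    run = 0
            else:
                run = 0
        if not edited:
            return


def plant_pas_and_artifacts(
    genome: dict[str, str], annotation: pd.DataFrame, cfg: SimConfig
) -> tuple[dict[str, str], SimTruth]:
    """Plant true PASs, their signals, and internal-priming artifact sites.

    Per gene, 1-3 PASs are placed downstream of the body at sense offsets
    >= 60 nt apart; each gets the signal hexamer written at sense offset
    -21 and any accidental A-run of >= 7 within -30..+10 is broken. One
    artifact site per gene is placed between the 3' end and the first PAS
    and receives an A-run of 8 covering the site, with the surrounding
    window scrubbed of A/T so no polyadenylation signal can occur there.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    seqs = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy() for c, s in genome.items()}
    # back to 0..3 codes
    code = np.full(256, -1, dtype=np.int8)
    for b, v in idx.items():
        code[ord(b)] = v
    seqs = {c: code[s].astype(np.int8) for c, s in seqs.items()}

    lo_k, hi_k = cfg.pas_per_gene_range
    n_genes = len(annotation)

    # choose switch genes among genes that will get >= 2 PASs
    k_per_gene = rng.integers(lo_k, hi_k + 1, size=n_genes)
    n_switch = int(round(cfg.switch_fraction * n_genes))
    multi = np.flatnonzero(k_per_gene >= 2)
    if n_switch > 0 and len(multi) < n_switch:
        # promote enough genes to 2 PASs
        need = n_switch - len(multi)
        single = np.flatnonzero(k_per_gene < 2)
        k_per_gene[single[:need]] = 2
        multi = np.flatnonzero(k_per_gene >= 2)
    switch_idx = rng.choice(multi, size=n_switch, replace=False) if n_switch else np.array([], int)
    switch_class = {}
    for j, gi in enumerate(np.sort(switch_idx)):
        switch_class[gi] = "I" if j % 2 == 0 else "II"

    n_de = int(round(cfg.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)

    pas_rows, art_rows, sw_rows, de_rows = [], [], [], []
    g_lo, g_hi = cfg.groups

    for gi, rec in enumerate(annotation.itertuples(index=False)):
        seq = seqs[rec.chrom]
        strand = rec.strand
        three_p = rec.annotated_3p_end
        k = int(k_per_gene[gi])

        # sense offsets of the true PASs: >= 60 apart, first at >= 60
        offs = []
        o = 60 + int(rng.integers(0, 21))
        for _ in range(k):
            offs.append(o)
            o += 60 + int(rng.integers(0, 21))
        sites = [three_p + o if strand == "+" else three_p - o for o in offs]
        for s in sites:
            if not (0 <= s < len(seq)):
                raise ValueError("cannot place PAS within chromosome bounds")

        # usage proportions per group
        if gi in switch_class:
            base = np.full(k, (1.0 - 0.8) / (k - 2), dtype=float) if k > 2 else np.zeros(k)
            base[0] = 0.4 if k > 2 else 0.5
            base[-1] = 0.4 if k > 2 else 0.5
            usage = {g_lo: base.copy(), g_hi: base.copy()}
            d = cfg.switch_delta
            if switch_class[gi] == "I":  # distal preferred at low temperature
                usage[g_lo][0] -= d
                usage[g_lo][-1] += d
            else:
                usage[g_lo][0] += d
                usage[g_lo][-1] -= d
        else:
            p = rng.dirichlet(np.full(k, 5.0))
            usage = {g_lo: p, g_hi: p.copy()}

        for r, (o, s) in enumerate(zip(offs, sites)):
            _write_sense(seq, strand, s, SIGNAL_OFFSET, SIGNAL_HEXAMER)
            protected = set(range(SIGNAL_OFFSET, SIGNAL_OFFSET + 6))
            _break_a_runs(seq, strand, s, -30, 10, protected)
            pas_rows.append(
                (rec.gene_id, rec.chrom, strand, s, r, usage[g_lo][r], usage[g_hi][r])
            )

        # artifact site between the 3' end and the first PAS
        a_site = three_p + ARTIFACT_OFFSET if strand == "+" else three_p - ARTIFACT_OFFSET
        # scrub sense window -30..+10 with C/G only (no A-runs, no signals)
        for off in range(-30, 11):
            pos = a_site + off if strand == "+" else a_site - off
            sense_base = "C" if rng.random() < 0.5 else "G"
            _write_sense(seq, strand, a_site, off, sense_base)
        _write_sense(seq, strand, a_site, -3, "A" * _A_RUN)  # run covers offset 0
        art_rows.append((rec.gene_id, rec.chrom, strand, a_site))

        if gi in switch_class:
            sw_rows.append((rec.gene_id, switch_class[gi]))

    for j, gi in enumerate(de_idx):
        de_rows.append((annotation.iloc[gi]["gene_id"], de_sign[j] * cfg.de_log2_shift))

    truth = SimTruth(
        true_pas=pd.DataFrame(
            pas_rows,
            columns=["gene_id", "chrom", "strand", "site", "rank",
                     f"usage_{g_lo}", f"usage_{g_hi}"],
        ),
        artifact_sites=pd.DataFrame(art_rows, columns=["gene_id", "chrom", "strand", "site"]),
        switch_genes=pd.DataFrame(sw_rows, columns=["gene_id", "apa_class"]),
        de_genes=pd.DataFrame(de_rows, columns=["gene_id", "log2_shift"]),
    )
    genome2 = {c: _to_str(s) for c, s in seqs.items()}
    return genome2, truth


def _jitter_pmf(scale: int, p: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Discretized double-geometric pmf on -scale..+scale, P(j) ~ p^|j|."""
    offsets = np.arange(-scale, scale + 1)
    w = p ** np.abs(offsets)
    return offsets, w / w.sum()


def simulate_reads(
    genome: dict[str, str],
    truth: SimTruth,
    cfg: SimConfig,
    annotation: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate per-sample read 3'-end tables.

    Returns ``{sample_id: DataFrame(chrom, site, strand)}`` with one row
    per read. Sample ids are ``<group>_rep<i>``. Per gene and sample the
    read count is negative binomial; reads are split multinomially over
    the gene's PASs with the group's usage proportions; recorded sites
    are jittered by a truncated double-geometric offset; a binomial
    ``artifact_fraction`` share of the gene's reads is emitted exactly at
    the gene's artifact site.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    de_shift = dict(zip(truth.de_genes["gene_id"], truth.de_genes["log2_shift"]))
    g_lo, g_hi = cfg.groups
    art = truth.artifact_sites.set_index("gene_id")

    pas_by_gene = {g: df.sort_values("rank") for g, df in truth.true_pas.groupby("gene_id")}
    offsets, pmf = _jitter_pmf(cfg.jitter_scale) if cfg.jitter_scale > 0 else (np.array([0]), np.array([1.0]))

    samples: dict[str, pd.DataFrame] = {}
    phi = cfg.gene_dispersion
    r_nb = 1.0 / phi
    for group in (g_lo, g_hi):
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{group}_rep{rep}"
            chroms, sites, strands = [], [], []
            for gene_id, pas in pas_by_gene.items():
                mean = cfg.gene_mean
                if group == g_lo and gene_id in de_shift:
                    mean = mean * 2.0 ** de_shift[gene_id]
                n = int(rng.negative_binomial(r_nb, r_nb / (r_nb + mean)))
                if n == 0:
                    continue
                n_art = int(rng.binomial(n, cfg.artifact_fraction)) if cfg.artifact_fraction > 0 else 0
                n_true = n - n_art
                props = pas[f"usage_{group}"].to_numpy(float)
                counts = rng.multinomial(n_true, props / props.sum())
                pas_sites = pas["site"].to_numpy()
                chrom = pas["chrom"].iloc[0]
                strand = pas["strand"].iloc[0]
                for site, c in zip(pas_sites, counts):
                    if c == 0:
                        continue
                    jit = rng.choice(offsets, size=c, p=pmf) if cfg.jitter_scale > 0 else np.zeros(c, int)
                    chroms.extend([chrom] * c)
                    sites.extend((site + jit).tolist())
                    strands.extend([strand] * c)
                if n_art:
                    a = art.loc[gene_id]
                    chroms.extend([a["chrom"]] * n_art)
                    sites.extend([int(a["site"])] * n_art)
                    strands.extend([a["strand"]] * n_art)
            samples[sid] = pd.DataFrame({"chrom": chroms, "site": sites, "strand": strands})
    return samples


def simulate_dataset(cfg: SimConfig):
    """Run the full generator: genome -> planted truth -> reads.

    Returns (genome, annotation, truth, samples, sample_sheet).
    """
    genome, ann = simulate_genome(cfg)
    genome, truth = plant_pas_and_artifacts(genome, ann, cfg)
    samples = simulate_reads(genome, truth, cfg, ann)
    rows = []
    for sid in samples:
        group, rep = sid.rsplit("_rep", 1)
        rows.append((sid, group, int(rep)))
    sheet = pd.DataFrame(rows, columns=["sample", "group", "replicate"])
    return genome, ann, truth, samples, sheet


def write_dataset(cfg: SimConfig, outdir: str) -> None:
    """Write FASTA, annotation TSV, truth TSVs, sample sheet and BED6 files."""
    genome, ann, truth, samples, sheet = simulate_dataset(cfg)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    ann.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    truth.true_pas.to_csv(os.path.join(outdir, "truth_pas.tsv"), sep="\t", index=False)
    truth.artifact_sites.to_csv(os.path.join(outdir, "truth_artifacts.tsv"), sep="\t", index=False)
    truth.switch_genes.to_csv(os.path.join(outdir, "truth_switches.tsv"), sep="\t", index=False)
    truth.de_genes.to_csv(os.path.join(outdir, "truth_de.tsv"), sep="\t", index=False)
    paths = []
    for sid, df in samples.items():
        path = os.path.join(outdir, f"{sid}.bed")
        with open(path, "w") as fh:
            for rec in df.itertuples(index=False):
                fh.write(f"{rec.chrom}\t{rec.site}\t{rec.site + 1}\t{sid}\t1\t{rec.strand}\n")
        paths.append(path)
    sheet2 = sheet.copy()
    sheet2["path"] = [os.path.join(outdir, f"{s}.bed") for s in sheet2["sample"]]
    sheet2.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
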