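"""Poly(A)-site calling from per-read cleavage events.

A cleavage event is the 0-based genomic coordinate of the last
transcribed nucleotide of one read. Events are clustered per
(chromosome, strand) with a greedy, read-support-ordered procedure using
a +/-25 nt window by default, yielding a PAS database with per-sample
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PasCluster",
    "PasCountMatrix",
    "read_events",
    "cluster_events",
    "build_count_matrix",
]

EVENT_COLUMNS = ["chrom", "strand", "site", "sample"]


@dataclass
class PasCluster:
    """A called poly(A) site.

    The seed is the event position with the highest total read count in
    its neighbourhood; the cluster absorbs all positions within ``w`` nt
    of the seed. Filter flags and gene assignment are filled in by the
    downstream stages.
    """

    pas_id: str
    chrom: str
    strand: str
    seed_site: int
    w: int
    counts: dict[str, int] = field(default_factory=dict)
    internal_priming: bool | None = None
    has_signal: bool | None = None
    gene_id: str | None = None
    rank: int | None = None

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class PasCountMatrix:
    """PAS x sample count table plus sample metadata (group, replicate)."""

    counts: pd.DataFrame  # index: pas_id, columns: sample
    sample_meta: pd.DataFrame  # index: sample; columns: group, replicate


def read_events(bed_paths: dict[str, str]) -> pd.DataFrame:
    """Read per-sample BED6 files of read 3' ends into an event table.

    ``bed_paths`` maps sample id -> path. The BED start coordinate is the
    cleavage site. Returns a DataFrame with columns chrom, strand, site,
    sample (one row per read).

    Raises ValueError on malformed lines (with the line number) or on a
    strand other than ``+``/``-``.
    """
    frames = []
    for sample, path in bed_paths.items():
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{ln}: expected >=6 BED fields, got {len(parts)}")
                try:
                    start = int(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-integer start {parts[1]!r}") from exc
                strand = parts[5]
                if strand not in ("+", "-"):
                    raise ValueError(f"{path}:{ln}: invalid strand {strand!r}")
                rows.append((parts[0], strand, start, sample))
        frames.append(pd.DataFrame(rows, columns=EVENT_COLUMNS))
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def cluster_events(events: pd.DataFrame, w: int = 25) -> list[PasCluster]:
    """Greedy clustering of cleavage events into PASs.

    Per (chrom, strand): among unassigned distinct positions pick the one
    with the highest total read count (ties broken toward the smaller
    genomic coordinate), make it a cluster seed, absorb all unassigned
    positions within ``w`` nt, and repeat. Cluster counts are per-sample
    sums over absorbed positions. Different strands never merge.
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    clusters: list[PasCluster] = []
    if len(events) == 0:
        return clusters
    for (chrom, strand), sub in events.groupby(["chrom", "strand"], sort=True):
        # per-position totals and per-position/sample counts
        pos_sample = sub.groupby(["site", "sample"]).size()
        totals = pos_sample.groupby(level="site").sum()
        positions = totals.index.to_numpy()  # sorted ascending
        tot = totals.to_numpy()
        unassigned = np.ones(len(positions), dtype=bool)
        # seeding order: by (-count, position); stable because positions sorted
        order = np.lexsort((positions, -tot))
        for i in order:
            if not unassigned[i]:
                continue
            seed = int(positions[i])
            lo = np.searchsorted(positions, seed - w, side="left")
            hi = np.searchsorted(positions, seed + w, side="right")
            members = [j for j in range(lo, hi) if unassigned[j]]
            unassigned[lo:hi] = False
            counts: dict[str, int] = {}
            for j in members:
                for (_, samp), c in pos_sample.loc[[positions[j]]].items():
                    counts[samp] = counts.get(samp, 0) + int(c)
            clusters.append(
                PasCluster(
                    pas_id=f"{chrom}:{strand}:{seed}",
                    chrom=chrom,
                    strand=strand,
                    seed_site=seed,
                    w=w,
                    counts=counts,
                )
            )
    return clusters


def build_count_matrix(clusters: list[PasCluster], sample_sheet: pd.DataFrame) -> PasCountMatrix:
    """Assemble the PAS x sample count matrix.

    ``sample_sheet`` needs columns sample, group, replicate. Every sample
    observed in a cluster must appear in the sheet; samples without reads
    at a PAS get 0.
    """
    samples = list(sample_sheet["sample"])
    known = set(samples)
    for cl in clusters:
        missing = set(cl.counts) - known
        if missing:
            raise ValueError(f"samples not in sample sheet: {sorted(missing)}")
    mat = pd.DataFrame(
        [[cl.counts.get(s, 0) for s in samples] for cl in clusters],
        index=pd.Index([cl.pas_id for cl in clusters], name="pas_id"),
        columns=samples,
        dtype=np.int64,
    )
    meta = sample_sheet.set_index("sample")[["group", "replicate"]]
    return PasCountMatrix(counts=mat, sample_meta=meta)
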