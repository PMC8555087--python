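"""Gene assignment of filtered PASs via rule-based 3'UTR extension.

Annotated 3'UTRs are conservative, so each gene's 3' end is extended
downstream by up to 5000 nt, capped at half the distance to the start of
the nearest downstream gene on the same strand (or at the chromosome end
when there is none). A PAS is assigned to the gene whose body-plus-
extension contains its seed; overlaps are resolved toward the nearest
annotated 3' end. Per gene, assigned PASs are ranked proximal (0) to
distal along the direction of transcription, and genes with two or more
PASs are the APA genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pas_calling import PasCluster

__all__ = ["ExtendedGene", "extend_3p", "assign_pas", "rank_pas", "EXTENSION_CAP"]

EXTENSION_CAP = 5000  # nt


@dataclass(frozen=True)
class ExtendedGene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # body span, 0-based half-open
    end: int
    annotated_3p_end: int
    extended_3p_end: int  # 0-based coordinate of the furthest covered base

    @property
    def extension(self) -> int:
        if self.strand == "+":
            return self.extended_3p_end - self.annotated_3p_end
        return self.annotated_3p_end - self.extended_3p_end


def extend_3p(
    annotation: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    cap: int = EXTENSION_CAP,
) -> list[ExtendedGene]:
    """Compute the downstream extension for every gene.

    extension = min(cap, floor(d/2)) where d is the sense-strand distance
    from the annotated 3' end to the 5' start of the nearest downstream
    same-strand gene; with no downstream gene, min(cap, distance to the
    chromosome end). Computed once per gene.
    """
    out: list[ExtendedGene] = []
    for (chrom, strand), sub in annotation.groupby(["chrom", "strand"], sort=False):
        sub = sub.sort_values("start")
        if strand == "+":
            starts = sub["start"].to_numpy()
        else:
            five_p = (sub["end"] - 1).to_numpy()  # 5' start coordinate on -
        for row in sub.itertuples(index=False):
            g3p = int(row.annotated_3p_end)
            if strand == "+":
                downstream = [s for s in starts if s >= g3p]  # >=: abutting genes give d=0
                if downstream:
                    d = int(min(downstream)) - g3p
                    ext = min(cap, d // 2)
                elif chrom_lengths is not None:
                    ext = min(cap, max(chrom_lengths[chrom] - 1 - g3p, 0))
                else:
                    ext = cap
                x3p = g3p + ext
            else:
                upstream_coords = [p for p in five_p if p <= g3p]
                if upstream_coords:
                    d = g3p - int(max(upstream_coords))
                    ext = min(cap, d // 2)
                else:
                    ext = min(cap, g3p)
                x3p = g3p - ext
            out.append(
                ExtendedGene(
                    gene_id=row.gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=int(row.start),
                    end=int(row.end),
                    annotated_3p_end=g3p,
                    extended_3p_end=x3p,
                )
            )
    return out


def _region(g: ExtendedGene) -> tuple[int, int]:
    """Inclusive genomic interval covered by body plus extension."""
    if g.strand == "+":
        return g.start, g.extended_3p_end
    return g.extended_3p_end, g.end - 1


def assign_pas(
    clusters: list[PasCluster], extended_genes: list[ExtendedGene]
) -> tuple[list[PasCluster], list[PasCluster]]:
    """Assign each PAS to at most one gene.

    A PAS belongs to gene g iff its seed lies within g's body-plus-
    extension on g's chromosome and strand. When several genes qualify,
    the one whose annotated 3' end is nearest wins (ties toward the
    lexicographically smallest gene_id). Returns (assigned, unassigned).
    """
    by_key: dict[tuple[str, str], list[ExtendedGene]] = {}
    for g in extended_genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)

    assigned, unassigned = [], []
    for cl in clusters:
        candidates = []
        for g in by_key.get((cl.chrom, cl.strand), []):
            lo, hi = _region(g)
            if lo <= cl.seed_site <= hi:
                candidates.append(g)
        if not candidates:
            cl.gene_id = None
            unassigned.append(cl)
            continue
        best = min(candidates, key=lambda g: (abs(cl.seed_site - g.annotated_3p_end), g.gene_id))
        cl.gene_id = best.gene_id
        assigned.append(cl)
    return assigned, unassigned


def rank_pas(assigned: list[PasCluster]) -> tuple[list[PasCluster], list[str]]:
    """Order each gene's PASs proximal (rank 0) to distal.

    Proximity is measured along the direction of transcription: ascending
    coordinates on +, descending on -. Returns the clusters (ranks set)
    and the list of APA genes (>= 2 assigned PASs).
    """
    by_gene: dict[str, list[PasCluster]] = {}
    for cl in assigned:
        if cl.gene_id is None:
            raise ValueError(f"cluster {cl.pas_id} has no gene assignment")
        by_gene.setdefault(cl.gene_id, []).append(cl)
    apa_genes = []
    for gene_id, cls in by_gene.items():
        cls.sort(key=lambda c: c.seed_site, reverse=(cls[0].strand == "-"))
        for r, cl in enumerate(cls):
            cl.rank = r
        if len(cls) >= 2:
            apa_genes.append(gene_id)
    return assigned, sorted(apa_genes)
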