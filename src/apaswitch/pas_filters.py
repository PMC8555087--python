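"""Sequence-context filters for the PAS database.

3'-end libraries primed with oligo-dT produce artifactual peaks where the
primer anneals to a genomic A-rich stretch (internal priming) instead of
a real poly(A) tail. Putative PASs are therefore removed when the
sense-strand window from -30 to +10 around the cleavage site contains a
run of seven or more consecutive A. Independently, sites are removed
when the -30..0 window contains none of the known polyadenylation-signal
hexamers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pas_calling import PasCluster
from .simdata import revcomp

__all__ = [
    "CANONICAL_SIGNALS",
    "FilterParams",
    "sense_context",
    "is_internal_priming",
    "has_polya_signal",
    "filter_pas",
]

# The twelve canonical metazoan polyadenylation-signal hexamer variants.
CANONICAL_SIGNALS = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AAGAAA", "AATATA",
    "AATACA", "CATAAA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA",
)


@dataclass(frozen=True)
class FilterParams:
    """Windows (inclusive sense-strand offsets around the cleavage site)
    and thresholds of the two filters."""

    ip_window: tuple[int, int] = (-30, 10)
    ip_run_length: int = 7
    signal_window: tuple[int, int] = (-30, 0)
    signal_set: tuple[str, ...] = CANONICAL_SIGNALS

    def __post_init__(self) -> None:
        if self.ip_run_length < 1:
            raise ValueError("ip_run_length must be >= 1")
        if not self.signal_set:
            raise ValueError("signal_set must be non-empty")
        for s in self.signal_set:
            if len(s) != 6 or set(s) - set("ACGT"):
                raise ValueError(f"invalid signal hexamer {s!r}")


def sense_context(
    genome: dict[str, str], chrom: str, strand: str, site: int, from_off: int, to_off: int
) -> str:
    """Sense-strand sequence covering offsets from_off..to_off (inclusive)
    around the cleavage site.

    On +, this is genomic [site+from_off, site+to_off]; on -, the reverse
    complement of genomic [site-to_off, site-from_off]. The window is
    clipped at chromosome edges, so the returned string may be shorter
    than to_off - from_off + 1.
    """
    if from_off > to_off:
        raise ValueError("from_off must be <= to_off")
    try:
        seq = genome[chrom]
    except KeyError:
        raise KeyError(f"unknown chromosome {chrom!r}") from None
    if strand == "+":
        a, b = site + from_off, site + to_off
    else:
        a, b = site - to_off, site - from_off
    a = max(a, 0)
    b = min(b, len(seq) - 1)
    if a > b:
        return ""
    sub = seq[a : b + 1].upper()
    return sub if strand == "+" else revcomp(sub)


def _max_a_run(s: str) -> int:
    best = run = 0
    for ch in s:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    return best


def is_internal_priming(genome: dict[str, str], cluster: PasCluster, params: FilterParams) -> bool:
    """True iff the -30..+10 sense context holds >= 7 consecutive A."""
    ctx = sense_context(
        genome, cluster.chrom, cluster.strand, cluster.seed_site, *params.ip_window
    )
    return _max_a_run(ctx) >= params.ip_run_length


def has_polya_signal(genome: dict[str, str], cluster: PasCluster, params: FilterParams) -> bool:
    """True iff a signal hexamer lies fully inside the -30..0 sense context."""
    ctx = sense_context(
        genome, cluster.chrom, cluster.strand, cluster.seed_site, *params.signal_window
    )
    return any(h in ctx for h in params.signal_set)


def filter_pas(
    clusters: list[PasCluster], genome: dict[str, str], params: FilterParams | None = None
) -> tuple[list[PasCluster], pd.DataFrame]:
    """Flag every cluster and keep those that pass both filters.

    Both filters are always evaluated so the removal log can carry both
    reason codes (``IP``, ``NO_SIGNAL``). Decisions are per-cluster, so
    output is independent of input order.
    """
    params = params or FilterParams()
    kept: list[PasCluster] = []
    log_rows = []
    for cl in clusters:
        cl.internal_priming = is_internal_priming(genome, cl, params)
        cl.has_signal = has_polya_signal(genome, cl, params)
        if not cl.internal_priming and cl.has_signal:
            kept.append(cl)
        else:
            reasons = []
            if cl.internal_priming:
                reasons.append("IP")
            if not cl.has_signal:
                reasons.append("NO_SIGNAL")
            log_rows.append((cl.pas_id, ",".join(reasons)))
    log = pd.DataFrame(log_rows, columns=["pas_id", "reason"])
    return kept, log
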