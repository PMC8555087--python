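"""Differential PAS usage between pooled temperature groups and APA-switch
classification.

Counts are CPM-normalized per sample. Each PAS (or gene) is tested for a
difference between the pooled low- and high-temperature groups with a
negative-binomial Wald test: the effect is log2((mean CPM low + 0.5) /
(mean CPM high + 0.5)); the per-feature dispersion is a pooled
within-group method-of-moments estimate, stabilised by shrinkage toward
the median dispersion of all tested features; the standard error follows
from the NB variance by the delta method; p-values use the normal
reference and are Benjamini-Hochberg adjusted.

APA switches are then called per gene by the tiered pair-selection rule:
among PAS pairs with opposing fold-change direction at FDR < 0.05 (tier
"both significant"), or — when only one / no PAS is significant — pairs
completed by the highest-count PASs, the pair with the greatest
fold-change distance is chosen. The sign of log2FC(proximal) -
log2FC(distal) labels the gene enhanced (> 0, class II: proximal
preferred at low temperature) or repressed (< 0, class I: distal
preferred at low temperature).

Differential expression at the gene level uses the same test with the
CoolUp / CoolDown thresholds: |fold change| >= 2 at FDR < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ApaSwitchCall",
    "cpm_normalize",
    "nb_test",
    "select_switch_pair",
    "call_apa_switches",
    "call_de_genes",
]

LOG2 = np.log(2.0)
PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8
# weight (in pseudo-residual-df) of the globally pooled dispersion in the
# per-feature shrinkage estimate; with 3+3 replicates there are only 4
# residual df per feature, so unshrunk moment estimates are too noisy for a
# calibrated Wald test
DISPERSION_PRIOR_DF = 8.0


@dataclass(frozen=True)
class ApaSwitchCall:
    gene_id: str
    proximal_pas: str
    distal_pas: str
    proximal_rank: int
    distal_rank: int
    pair_delta: float  # |log2fc(proximal) - log2fc(distal)|
    label: str  # enhanced / repressed
    apa_class: str  # II / I
    selection_tier: str  # both_significant / one_significant / none_significant


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column scaled by its library total x 1e6."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total for sample(s) {bad}")
    return counts / totals * 1e6


def _moment_dispersion(x: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Pooled within-group method-of-moments NB dispersion.

    Solves sum_g (n_g-1) s2_g = sum_g (n_g-1) (mu_g + phi mu_g^2) for phi
    per feature. Returns (raw per-feature estimates, globally pooled
    estimate over all features); the global one is far less skewed than
    the per-feature estimates at few residual df and serves as the
    shrinkage target.
    """
    num = np.zeros(x.shape[0])
    den = np.zeros(x.shape[0])
    for idx in groups:
        sub = x[:, idx]
        n = len(idx)
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += (n - 1) * (s2 - mu)
        den += (n - 1) * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    pooled = float(num.sum() / den.sum()) if den.sum() > 0 else 0.0
    return raw, pooled


def nb_test(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    group_a: str = "low",
    group_b: str = "high",
    min_total: int = 0,
) -> pd.DataFrame:
    """NB Wald test of group_a vs group_b for every row of ``counts``.

    Rows whose total count across samples is below ``min_total`` are
    dropped before testing (and before BH adjustment). Returns a
    DataFrame indexed like the tested rows with columns base_mean,
    log2fc, se, p, padj.
    """
    for g in (group_a, group_b):
        n = int((sample_meta["group"] == g).sum())
        if n < 2:
            raise ValueError(f"group {g!r} has {n} replicates; >= 2 required")
    keep = counts.sum(axis=1) >= min_total
    counts = counts.loc[keep]
    cpm = cpm_normalize(counts) if len(counts) else counts.astype(float)

    samples = list(counts.columns)
    ia = np.array([i for i, s in enumerate(samples) if sample_meta.loc[s, "group"] == group_a])
    ib = np.array([i for i, s in enumerate(samples) if sample_meta.loc[s, "group"] == group_b])
    x = cpm.to_numpy(float)
    if x.shape[0] == 0:
        return pd.DataFrame(columns=["base_mean", "log2fc", "se", "p", "padj"])

    mu_a = x[:, ia].mean(axis=1)
    mu_b = x[:, ib].mean(axis=1)
    log2fc = np.log2(mu_a + PSEUDOCOUNT) - np.log2(mu_b + PSEUDOCOUNT)

    raw_phi, pooled_phi = _moment_dispersion(x, [ia, ib])
    resid_df = float(len(ia) - 1 + len(ib) - 1)
    prior = max(pooled_phi, DISPERSION_FLOOR)
    phi = np.maximum(
        (resid_df * raw_phi + DISPERSION_PRIOR_DF * prior) / (resid_df + DISPERSION_PRIOR_DF),
        DISPERSION_FLOOR,
    )

    var_mean_a = (mu_a + phi * mu_a**2) / len(ia)
    var_mean_b = (mu_b + phi * mu_b**2) / len(ib)
    se = np.sqrt(
        var_mean_a / (mu_a + PSEUDOCOUNT) ** 2 + var_mean_b / (mu_b + PSEUDOCOUNT) ** 2
    ) / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(log2fc == 0.0, 0.0, log2fc / np.maximum(se, 1e-300))
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1] if len(p) else p

    return pd.DataFrame(
        {
            "base_mean": x.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
        },
        index=counts.index,
    )


def _pair_call(gene_id: str, prox: pd.Series, dist: pd.Series, tier: str) -> ApaSwitchCall | None:
    """Build a call from a (proximal, distal) result pair; None unless the
    two log2 fold changes have strictly opposite signs."""
    if not (prox["log2fc"] * dist["log2fc"] < 0):
        return None
    diff = prox["log2fc"] - dist["log2fc"]
    label = "enhanced" if diff > 0 else "repressed"
    return ApaSwitchCall(
        gene_id=gene_id,
        proximal_pas=str(prox.name),
        distal_pas=str(dist.name),
        proximal_rank=int(prox["rank"]),
        distal_rank=int(dist["rank"]),
        pair_delta=float(abs(diff)),
        label=label,
        apa_class="II" if label == "enhanced" else "I",
        selection_tier=tier,
    )


def select_switch_pair(
    gene_results: pd.DataFrame, alpha: float = 0.05, gene_id: str = "", mode: str = "tiered"
) -> ApaSwitchCall | None:
    """Tiered selection of the most divergently used PAS pair of one gene.

    ``gene_results`` is indexed by pas_id with columns rank, base_mean,
    log2fc, padj, and must hold >= 2 tested PASs. Candidate pairs: with
    >= 2 significant PASs (padj < alpha), all opposite-sign pairs among
    them; with exactly one, that PAS paired with the highest-count other;
    with none, the two highest-count PASs. The candidate with the
    greatest fold-change distance wins (ties toward the smaller proximal
    rank, then smaller distal rank). A call is returned only when the
    chosen pair's fold changes point in opposite directions.

    ``mode="top2"`` instead always compares the two PASs with the highest
    read counts across all conditions, requiring one of them significant.
    """
    if len(gene_results) < 2:
        raise ValueError("select_switch_pair requires >= 2 tested PASs")
    df = gene_results.sort_values("rank")

    def ordered(a: pd.Series, b: pd.Series) -> tuple[pd.Series, pd.Series]:
        return (a, b) if a["rank"] < b["rank"] else (b, a)

    if mode == "top2":
        top = df.sort_values(["base_mean", "rank"], ascending=[False, True]).iloc[:2]
        prox, dist = ordered(top.iloc[0], top.iloc[1])
        if min(prox["padj"], dist["padj"]) >= alpha:
            return None
        return _pair_call(gene_id, prox, dist, "top2")
    if mode != "tiered":
        raise ValueError(f"unknown mode {mode!r}")

    sig = df[df["padj"] < alpha]
    candidates: list[tuple[pd.Series, pd.Series, str]] = []
    if len(sig) >= 2:
        for i, j in combinations(range(len(sig)), 2):
            a, b = sig.iloc[i], sig.iloc[j]
            if a["log2fc"] * b["log2fc"] < 0:
                candidates.append((*ordered(a, b), "both_significant"))
        if not candidates:
            return None
    elif len(sig) == 1:
        s = sig.iloc[0]
        others = df.drop(index=sig.index)
        partner = others.sort_values(["base_mean", "rank"], ascending=[False, True]).iloc[0]
        candidates.append((*ordered(s, partner), "one_significant"))
    else:
        top = df.sort_values(["base_mean", "rank"], ascending=[False, True]).iloc[:2]
        candidates.append((*ordered(top.iloc[0], top.iloc[1]), "none_significant"))

    best = min(
        candidates,
        key=lambda c: (-abs(c[0]["log2fc"] - c[1]["log2fc"]), c[0]["rank"], c[1]["rank"]),
    )
    return _pair_call(gene_id, best[0], best[1], best[2])


def call_apa_switches(
    results: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "tiered",
    require_significant: bool = True,
) -> pd.DataFrame:
    """Apply pair selection to every APA gene.

    ``results`` is the nb_test output joined with gene_id and rank
    columns, indexed by pas_id. Genes with a single tested PAS never
    yield a call. A switch gene must display *significant* usage changes
    in opposite directions, so by default pairs selected without any
    significant PAS (tier ``none_significant``) identify the gene's most
    divergently used pair but are not reported as switches; pass
    ``require_significant=False`` to keep them. Returns one row per
    called switch gene.
    """
    rows = []
    for gene_id, sub in results.groupby("gene_id", sort=True):
        if len(sub) < 2:
            continue
        call = select_switch_pair(sub, alpha=alpha, gene_id=gene_id, mode=mode)
        if call is None:
            continue
        if require_significant and call.selection_tier == "none_significant":
            continue
        rows.append(call.__dict__)
    cols = [
        "gene_id", "proximal_pas", "distal_pas", "proximal_rank", "distal_rank",
        "pair_delta", "label", "apa_class", "selection_tier",
    ]
    return pd.DataFrame(rows, columns=cols)


def call_de_genes(
    gene_counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    fdr: float = 0.01,
    fc: float = 2.0,
    min_total: int = 0,
) -> pd.DataFrame:
    """CoolUp / CoolDown classification of gene-level counts.

    CoolUp: log2fc >= log2(fc) and padj < fdr (higher at the pooled low
    temperatures); CoolDown the mirror image; otherwise NotDE.
    """
    res = nb_test(gene_counts, sample_meta, min_total=min_total)
    lfc_thr = np.log2(fc)
    cat = np.where(
        (res["padj"] < fdr) & (res["log2fc"] >= lfc_thr),
        "CoolUp",
        np.where((res["padj"] < fdr) & (res["log2fc"] <= -lfc_thr), "CoolDown", "NotDE"),
    )
    out = res.copy()
    out["category"] = cat
    return out
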