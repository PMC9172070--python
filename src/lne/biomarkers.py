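"""High-entropy gene selection, DNB extraction and prognostic classes.

Per sample, the top fraction (default 5%) of genes ranked by the local
score |dE| * |dSD| form that sample's gene set. The genes common to all
critical-stage samples are the dynamic-network-biomarker (DNB) module.
A candidate gene is classified optimistic/pessimistic by whether the
samples carrying it in their gene sets live longer/shorter than the
samples that do not (log-rank significance, direction from restricted
mean survival).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lne.entropy import SampleScore
from lne.expression import ExpressionStudy
from lne.network import GeneNetwork, restrict_to_genes, write_graphml, write_sif
from lne.survival import SurvivalRecord, km_curve, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "LneGeneSet",
    "BiomarkerCall",
    "lne_genes",
    "common_lne_genes",
    "classify_biomarkers",
    "dark_genes",
    "export_dnb_subnetwork",
]

OPTIMISTIC = "O-LNE"
PESSIMISTIC = "P-LNE"
NEITHER = "neither"


@dataclass(frozen=True)
class LneGeneSet:
    sample_id: str
    stage: str
    genes: frozenset[str]
    fraction: float


@dataclass(frozen=True)
class BiomarkerCall:
    gene: str
    klass: str              # O-LNE / P-LNE / neither
    with_n: int
    without_n: int
    logrank_stat: float
    logrank_p: float
    direction: str          # longer / shorter / none


def lne_genes(score: SampleScore, fraction: float = 0.05) -> LneGeneSet:
    """Top ceil(fraction * Q) genes by local score |dE| * |dSD|.

    Ties at the cutoff break lexicographically on the gene symbol.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    k = math.ceil(fraction * score.Q)
    ranked = sorted(score.profiles, key=lambda p: (-p.local_score, p.gene))
    return LneGeneSet(
        sample_id=score.sample_id,
        stage=score.stage,
        genes=frozenset(p.gene for p in ranked[:k]),
        fraction=fraction,
    )


def common_lne_genes(
    sets: Sequence[LneGeneSet],
    samples_at: str,
    min_fraction: float = 1.0,
) -> frozenset[str]:
    """Genes shared by the critical-stage samples' gene sets (the DNBs).

    ``min_fraction`` relaxes the strict intersection: a gene qualifies
    when it appears in at least that fraction of the stage's sets
    (default 1.0 = plain intersection).
    """
    stage_sets = [s.genes for s in sets if s.stage == samples_at]
    if not stage_sets:
        raise ValueError(f"no gene sets from stage {samples_at!r}")
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    need = math.ceil(min_fraction * len(stage_sets))
    counts: dict[str, int] = {}
    for gs in stage_sets:
        for g in gs:
            counts[g] = counts.get(g, 0) + 1
    common = frozenset(g for g, c in counts.items() if c >= need)
    if not common:
        logger.warning("common gene set at stage %r is empty (%d samples)", samples_at, len(stage_sets))
    return common


def classify_biomarkers(
    sets: Sequence[LneGeneSet],
    clinical: Sequence[SurvivalRecord],
    alpha: float = 0.05,
    candidates: set[str] | frozenset[str] | None = None,
) -> list[BiomarkerCall]:
    """Classify candidate genes as optimistic / pessimistic biomarkers.

    For each candidate, samples are split by whether the gene belongs to
    their per-sample gene set; the split is compared by log-rank, and
    the prognosis direction comes from the restricted mean survival of
    the two Kaplan-Meier curves.
    """
    by_id = {r.sample_id: r for r in clinical}
    membership = {s.sample_id: s.genes for s in sets}
    usable = [sid for sid in membership if sid in by_id]
    if candidates is None:
        candidates = frozenset().union(*(s.genes for s in sets))
    if not candidates:
        raise ValueError("empty candidate gene set")

    calls = []
    for gene in sorted(candidates):
        with_recs = [by_id[sid] for sid in usable if gene in membership[sid]]
        without_recs = [by_id[sid] for sid in usable if gene not in membership[sid]]
        if not with_recs or not without_recs:
            calls.append(BiomarkerCall(gene, NEITHER, len(with_recs), len(without_recs), 0.0, 1.0, "none"))
            continue
        res = logrank_test(with_recs, without_recs)
        tau = min(max(r.time for r in with_recs), max(r.time for r in without_recs))
        rm_with = km_curve(with_recs).restricted_mean(tau)
        rm_without = km_curve(without_recs).restricted_mean(tau)
        if rm_with > rm_without:
            direction = "longer"
        elif rm_with < rm_without:
            direction = "shorter"
        else:
            direction = "none"
        if res.p_value < alpha and direction == "longer":
            klass = OPTIMISTIC
        elif res.p_value < alpha and direction == "shorter":
            klass = PESSIMISTIC
        else:
            klass = NEITHER
        calls.append(
            BiomarkerCall(gene, klass, len(with_recs), len(without_recs),
                          res.statistic, res.p_value, direction)
        )
    return calls


def biomarker_table(calls: Sequence[BiomarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "class": [c.klass for c in calls],
            "with_n": [c.with_n for c in calls],
            "without_n": [c.without_n for c in calls],
            "logrank_stat": [c.logrank_stat for c in calls],
            "logrank_p": [c.logrank_p for c in calls],
            "direction": [c.direction for c in calls],
        }
    )


def dark_genes(
    study: ExpressionStudy,
    scores: Sequence[SampleScore],
    transition: str,
    stage_order: Sequence[str],
    de_alpha: float = 0.05,
    lne_alpha: float = 0.05,
) -> frozenset[str]:
    """Genes without case-vs-reference expression change but with a
    local-score shift at/after the transition.

    Expression difference: two-sided Wilcoxon rank-sum per gene,
    Benjamini-Hochberg adjusted; "no change" means adjusted p >= de_alpha.
    Local-score difference: rank-sum of per-sample |dE| * |dSD| between
    case samples before the transition stage and those at/after it,
    BH-adjusted p < lne_alpha.
    """
    ref_ids = study.reference_samples
    case_ids = study.case_samples
    if len(ref_ids) < 3 or len(case_ids) < 3:
        raise ValueError(
            f"need >= 3 reference and >= 3 case samples, got {len(ref_ids)} / {len(case_ids)}"
        )
    order = list(stage_order)
    cut = order.index(transition)
    pre = [s for s in scores if order.index(s.stage) < cut]
    post = [s for s in scores if order.index(s.stage) >= cut]
    if not pre or not post:
        raise ValueError("need samples both before and at/after the transition stage")

    genes = sorted(set(scores[0].local_scores()))
    ref_mat = study.expression.loc[genes, ref_ids].to_numpy(dtype=float)
    case_mat = study.expression.loc[genes, case_ids].to_numpy(dtype=float)
    pre_scores = np.array([[s.local_scores()[g] for s in pre] for g in genes])
    post_scores = np.array([[s.local_scores()[g] for s in post] for g in genes])

    de_p = np.array(
        [stats.ranksums(case_mat[i], ref_mat[i]).pvalue for i in range(len(genes))]
    )
    lne_p = np.array(
        [stats.ranksums(post_scores[i], pre_scores[i]).pvalue for i in range(len(genes))]
    )
    de_adj = stats.false_discovery_control(de_p, method="bh")
    lne_adj = stats.false_discovery_control(lne_p, method="bh")
    flagged = [g for i, g in enumerate(genes) if de_adj[i] >= de_alpha and lne_adj[i] < lne_alpha]
    return frozenset(flagged)


def export_dnb_subnetwork(
    net: GeneNetwork,
    genes: frozenset[str] | set[str],
    scores: Sequence[SampleScore],
    expr: pd.DataFrame,
    sif_path,
    graphml_path,
) -> GeneNetwork:
    """Export the induced DNB subnetwork with mean local score per node
    and |PCC| (over the columns of ``expr``) per edge."""
    sub = restrict_to_genes(net, set(genes))
    mean_score: dict[str, float] = {}
    for g in sub.nodes:
        vals = [s.local_scores()[g] for s in scores if g in s.local_scores()]
        mean_score[g] = float(np.mean(vals)) if vals else 0.0
    edge_pcc: dict[tuple[str, str], float] = {}
    for a, b in sub.edges:
        xa = expr.loc[a].to_numpy(dtype=float)
        xb = expr.loc[b].to_numpy(dtype=float)
        if xa.std() == 0 or xb.std() == 0:
            edge_pcc[(a, b)] = 0.0
        else:
            edge_pcc[(a, b)] = float(abs(np.corrcoef(xa, xb)[0, 1]))
    write_sif(sub, sif_path)
    write_graphml(sub, graphml_path,
                  node_attrs={"mean_local_score": mean_score},
                  edge_attrs={"abs_pcc": edge_pcc})
    return sub
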