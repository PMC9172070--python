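"""Per-gene local network entropy and the global differential score.

For a center gene with M first-order neighbors, the local entropy is

    E = -(1/M) * sum_i p_i * ln(p_i),        0 * ln 0 := 0,

where p_i is the absolute Pearson correlation of neighbor i with the
center, normalized over the neighborhood. Each case sample is scored by
mixing it alone into the n reference samples, recomputing the entropy
from n+1 samples, and combining the per-gene entropy change with the
change in the center gene's standard deviation:

    global score = (1/Q) * sum_k |dE_k| * |dSD_k|

over the Q genes of the pruned network.

Conventions (the source method leaves these open):

* natural logarithm — any other base rescales all scores by a constant
  and leaves rankings and the called transition unchanged;
* Pearson correlation of a zero-variance gene is defined as 0; if every
  neighbor weight is 0 the weight vector falls back to uniform
  (maximal disorder rather than undefined);
* standard deviations use the sample (n-1) denominator, matching the
  internal convention of the Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lne.expression import ExpressionStudy
from lne.network import GeneNetwork, LocalNeighborhood

__all__ = [
    "ReferenceCohort",
    "LocalEntropyProfile",
    "SampleScore",
    "correlation_weights",
    "local_entropy",
    "score_sample",
    "score_cohort",
]


@dataclass
class ReferenceCohort:
    """Reference expression matrix (genes x n samples)."""

    expression: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expression.shape[1] < 3:
            raise ValueError(
                f"reference cohort needs n >= 3 samples for Pearson correlation, "
                f"got n = {self.expression.shape[1]}"
            )
        if self.expression.isna().any().any():
            bad = list(self.expression.index[self.expression.isna().any(axis=1)])[:5]
            raise ValueError(f"reference expression has missing values, e.g. genes {bad}")

    @property
    def n(self) -> int:
        return self.expression.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.expression.index


@dataclass(frozen=True)
class LocalEntropyProfile:
    """Entropy bookkeeping for one gene under one case sample."""

    gene: str
    E_ref: float
    E_mixed: float
    dE: float
    dSD: float

    @property
    def local_score(self) -> float:
        """Per-gene contribution |dE| * |dSD| (the global score's summand)."""
        return self.dE * self.dSD


@dataclass
class SampleScore:
    """Global differential-entropy score of one case sample."""

    sample_id: str
    stage: str
    global_dE: float
    profiles: list[LocalEntropyProfile]

    @property
    def Q(self) -> int:
        return len(self.profiles)

    def local_scores(self) -> dict[str, float]:
        return {p.gene: p.local_score for p in self.profiles}

    def to_frame(self) -> pd.DataFrame:
        """Per-gene table: gene, E_ref, E_mixed, dE, dSD, dE_x_dSD, rank."""
        df = pd.DataFrame(
            {
                "gene": [p.gene for p in self.profiles],
                "E_ref": [p.E_ref for p in self.profiles],
                "E_mixed": [p.E_mixed for p in self.profiles],
                "dE": [p.dE for p in self.profiles],
                "dSD": [p.dSD for p in self.profiles],
                "dE_x_dSD": [p.local_score for p in self.profiles],
            }
        )
        df = df.sort_values(["dE_x_dSD", "gene"], ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        return df.reset_index(drop=True)


def _abs_pearson_to_center(center: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """|PCC| of each neighbor row against the center; zero-variance rows give 0."""
    c = center - center.mean()
    nb = neighbors - neighbors.mean(axis=1, keepdims=True)
    c_norm = np.sqrt((c * c).sum())
    nb_norm = np.sqrt((nb * nb).sum(axis=1))
    denom = nb_norm * c_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, nb @ c / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(np.abs(r), 0.0, 1.0)


def correlation_weights(center: str, hood: LocalNeighborhood, expr: pd.DataFrame) -> np.ndarray:
    """Normalized absolute Pearson correlations of neighbors with the center.

    Returns p with p_i = |PCC(g_i, center)| / sum_j |PCC(g_j, center)|,
    computed over the columns of ``expr``. Falls back to the uniform
    vector when every correlation is zero.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples to compute Pearson correlation, got {expr.shape[1]}")
    missing = [g for g in (center, *hood.neighbors) if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    c = expr.loc[center].to_numpy(dtype=float)
    nb = expr.loc[list(hood.neighbors)].to_numpy(dtype=float)
    absr = _abs_pearson_to_center(c, nb)
    total = absr.sum()
    if total <= 0.0:
        return np.full(hood.M, 1.0 / hood.M)
    return absr / total


def local_entropy(p: np.ndarray, M: int) -> float:
    """Shannon-type entropy -(1/M) sum p ln p, with 0 ln 0 := 0.

    Result lies in [0, ln(M)/M]; the maximum is attained at uniform p.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (M,):
        raise ValueError(f"weight vector length {p.shape} does not match M={M}")
    if (p < 0).any():
        raise ValueError("negative weight in entropy input")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / M)


class _NetworkIndex:
    """Precomputed gene ordering, edge arrays and adjacency for fast scoring.

    Correlations are computed per edge (O(|E| * samples)) instead of as a
    dense gene x gene matrix, so large networks stay tractable.
    """

    def __init__(self, net: GeneNetwork):
        self.genes: list[str] = sorted(net.nodes)
        pos = {g: i for i, g in enumerate(self.genes)}
        edges = sorted(net.edges)
        self.e0 = np.array([pos[a] for a, b in edges], dtype=np.int64)
        self.e1 = np.array([pos[b] for a, b in edges], dtype=np.int64)
        # adjacency: per-gene arrays of (edge index, neighbor sign) — for
        # each gene the list of incident edge indices.
        adj: list[list[int]] = [[] for _ in self.genes]
        for ei, (a, b) in enumerate(edges):
            adj[pos[a]].append(ei)
            adj[pos[b]].append(ei)
        self.adj = [np.array(a, dtype=np.int64) for a in adj]

    def edge_abs_corr(self, values: np.ndarray) -> np.ndarray:
        """|PCC| for every edge over the columns of ``values`` (genes x m)."""
        centered = values - values.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered * centered).sum(axis=1))
        safe = np.where(norms > 0, norms, 1.0)
        unit = centered / safe[:, None]
        unit[norms == 0] = 0.0  # zero-variance gene: all its correlations are 0
        r = (unit[self.e0] * unit[self.e1]).sum(axis=1)
        return np.clip(np.abs(r), 0.0, 1.0)

    def entropies(self, edge_corr: np.ndarray) -> np.ndarray:
        """Local entropy per gene given per-edge |PCC| values."""
        out = np.empty(len(self.genes))
        for i, eidx in enumerate(self.adj):
            c = edge_corr[eidx]
            M = len(eidx)
            total = c.sum()
            if total <= 0.0:
                out[i] = np.log(M) / M  # uniform fallback = maximal entropy
                continue
            p = c / total
            nz = p[p > 0]
            out[i] = -(nz * np.log(nz)).sum() / M
        return out


def _score_from_index(
    index: _NetworkIndex,
    ref_values: np.ndarray,
    e_ref: np.ndarray,
    sd_ref: np.ndarray,
    case_values: np.ndarray,
    sample_id: str,
    stage: str,
) -> SampleScore:
    mixed = np.column_stack([ref_values, case_values])
    e_mixed = index.entropies(index.edge_abs_corr(mixed))
    sd_mixed = mixed.std(axis=1, ddof=1)
    dE = np.abs(e_mixed - e_ref)
    dSD = np.abs(sd_ref - sd_mixed)
    profiles = [
        LocalEntropyProfile(gene=g, E_ref=float(e_ref[i]), E_mixed=float(e_mixed[i]),
                            dE=float(dE[i]), dSD=float(dSD[i]))
        for i, g in enumerate(index.genes)
    ]
    return SampleScore(
        sample_id=sample_id,
        stage=stage,
        global_dE=float((dE * dSD).mean()),
        profiles=profiles,
    )


def score_sample(
    case: pd.Series,
    ref: ReferenceCohort,
    net: GeneNetwork,
    sample_id: str = "case",
    stage: str = "",
) -> SampleScore:
    """Score a single case sample against the reference cohort.

    ``case`` must cover every network gene; the reference cohort must
    contain every network gene as well.
    """
    index = _NetworkIndex(net)
    missing_case = [g for g in index.genes if g not in case.index]
    if missing_case:
        raise KeyError(f"case sample lacks network genes: {missing_case[:5]}")
    missing_ref = [g for g in index.genes if g not in ref.genes]
    if missing_ref:
        raise KeyError(f"reference cohort lacks network genes: {missing_ref[:5]}")
    ref_values = ref.expression.loc[index.genes].to_numpy(dtype=float)
    e_ref = index.entropies(index.edge_abs_corr(ref_values))
    sd_ref = ref_values.std(axis=1, ddof=1)
    case_values = case.loc[index.genes].to_numpy(dtype=float)
    return _score_from_index(index, ref_values, e_ref, sd_ref, case_values, sample_id, stage)


def score_cohort(
    study: ExpressionStudy,
    net: GeneNetwork,
    log_transform: bool = False,
) -> list[SampleScore]:
    """Score every case sample of a study, one at a time.

    The reference cohort is fixed; each case sample is mixed in alone.
    Reference-only quantities are computed once (a pure caching
    optimization — results are identical to per-sample scoring).
    ``log_transform`` applies log2(x + 1) to the whole matrix first.
    """
    cases = study.case_samples
    if not cases:
        raise ValueError("study has no case samples")
    expr = study.expression
    if log_transform:
        expr = np.log2(expr + 1.0)
    ref = ReferenceCohort(expr[study.reference_samples])

    index = _NetworkIndex(net)
    missing = [g for g in index.genes if g not in expr.index]
    if missing:
        raise KeyError(f"expression matrix lacks network genes: {missing[:5]}")
    ref_values = ref.expression.loc[index.genes].to_numpy(dtype=float)
    e_ref = index.entropies(index.edge_abs_corr(ref_values))
    sd_ref = ref_values.std(axis=1, ddof=1)

    scores = []
    for sample in cases:
        case_values = expr.loc[index.genes, sample].to_numpy(dtype=float)
        scores.append(
            _score_from_index(index, ref_values, e_ref, sd_ref, case_values,
                              sample_id=sample, stage=study.stage_of(sample))
        )
    return scores
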