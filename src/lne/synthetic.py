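"""Synthetic studies with a planted critical-transition module.

The generator realizes the three hallmarks of a dynamic-network-
biomarker group approaching a tipping point: intra-module correlation
rises, module-to-outside correlation falls, and module-gene standard
deviation rises. Samples are drawn from multivariate normals whose
module block interpolates between baseline and critical parameters
along the stage axis, peaking at the configured critical stage.

Module-to-outside correlation is realized through a one-to-one pairing
of each module gene with a dedicated background "partner" gene (also
wired as a network edge). The pairing keeps every implied correlation
matrix positive semi-definite as long as 1 - rho_in >= rho_out**2,
which is additionally verified numerically at construction.

With ``prognostic_split`` enabled a second, disjoint module is planted
and each case sample is perturbed through exactly one of the two; at or
after the critical stage, samples carrying the first ("pessimistic")
module get an elevated hazard and samples carrying the second
("optimistic") module a reduced one, so both prognostic directions are
recoverable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from lne.expression import CASE_LABEL, REFERENCE_LABEL, ExpressionStudy
from lne.network import GeneNetwork
from lne.survival import SurvivalRecord

__all__ = ["SimConfig", "SimTruth", "simulate_network", "simulate_study", "simulate_survival"]

_BASE_MEAN = 10.0


@dataclass
class SimConfig:
    n_genes: int = 100
    module_size: int = 10
    stages: tuple[str, ...] = ("I", "II", "III", "IV")
    critical_stage: str = "III"
    n_ref: int = 20
    n_per_stage: int = 20
    rho_in_base: float = 0.2
    rho_in_crit: float = 0.7
    rho_out_base: float = 0.3
    rho_out_crit: float = 0.05
    sd_base: float = 1.0
    sd_crit: float = 2.0
    survival_hazard_ratio: float = 4.0
    anchor_sd_boost: float = 3.0    # extra SD gain for each module's anchor gene
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.1
    post_trajectory: str = "peaked"   # "peaked" (fall back after the peak) or "plateau"
    prognostic_split: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.critical_stage not in self.stages:
            raise ValueError(f"critical_stage {self.critical_stage!r} not in stages {self.stages}")
        n_modules = 2 if self.prognostic_split else 1
        needed = 2 * n_modules * self.module_size  # modules plus their partner genes
        if self.module_size < 2:
            raise ValueError("module_size must be >= 2")
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small: need >= {needed} for "
                f"{n_modules} module(s) of size {self.module_size} plus partners"
            )
        for name in ("rho_in_base", "rho_in_crit", "rho_out_base", "rho_out_crit"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0, 1)")
        if self.sd_base <= 0 or self.sd_crit <= 0:
            raise ValueError("standard deviations must be positive")
        if self.post_trajectory not in ("peaked", "plateau"):
            raise ValueError(f"unknown post_trajectory {self.post_trajectory!r}")
        # PSD check at the trajectory extremes (w = 0 and w = 1).
        for w in (0.0, 1.0):
            rho_in = self.rho_in_base + w * (self.rho_in_crit - self.rho_in_base)
            rho_out = self.rho_out_base + w * (self.rho_out_crit - self.rho_out_base)
            corr = _module_block(self.module_size, rho_in, rho_out)
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError(
                    f"implied correlation matrix not PSD at w={w} "
                    f"(rho_in={rho_in}, rho_out={rho_out}, module_size={self.module_size})"
                )

    @property
    def genes(self) -> list[str]:
        width = max(3, len(str(self.n_genes - 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def stage_weight(self, stage: str) -> float:
        """Perturbation strength in [0, 1] along the stage trajectory.

        Quadratic ramp up to the critical stage (early stages stay near
        baseline, then the signal spikes), followed by a partial return
        toward baseline ("peaked") or persistence ("plateau").
        """
        i = self.stages.index(stage)
        c = self.stages.index(self.critical_stage)
        if i <= c:
            return 1.0 if c == 0 else (i / c) ** 2
        return 0.4 if self.post_trajectory == "peaked" else 1.0


@dataclass
class SimTruth:
    module_genes: tuple[str, ...]
    critical_stage: str
    pessimistic_gene: str
    optimistic_module: tuple[str, ...] | None = None
    optimistic_gene: str | None = None
    sample_modules: dict[str, str] = field(default_factory=dict)  # sample -> "P" / "O"


def _module_block(m: int, rho_in: float, rho_out: float) -> np.ndarray:
    """Correlation matrix of one module plus its m partner genes."""
    r = np.eye(2 * m)
    r[:m, :m] = rho_in
    np.fill_diagonal(r[:m, :m], 1.0)
    for i in range(m):
        r[i, m + i] = r[m + i, i] = rho_out
    return r


def _module_layout(cfg: SimConfig) -> dict[str, tuple[list[int], list[int]]]:
    """Gene-index layout: module key -> (module indices, partner indices)."""
    m = cfg.module_size
    layout = {"P": (list(range(m)), None)}
    nxt = m
    if cfg.prognostic_split:
        layout["O"] = (list(range(nxt, nxt + m)), None)
        nxt += m
    out = {}
    for key, (mod, _) in layout.items():
        out[key] = (mod, list(range(nxt, nxt + m)))
        nxt += m
    return out


def simulate_network(cfg: SimConfig) -> GeneNetwork:
    """Deterministic network: each module wired as hub + ring, partner
    bridge edges, and a random background tree with a few extra edges."""
    rng = np.random.default_rng([cfg.seed, 0])
    genes = cfg.genes
    layout = _module_layout(cfg)
    edges: list[tuple[str, str]] = []
    in_module: set[int] = set()
    for mod, partners in layout.values():
        # ring over the whole module, plus a hub tied to every member
        # beyond the anchor; the anchor (mod[0]) keeps a small
        # neighborhood — two module edges and its partner bridge — so
        # its local weight contrast is maximal near the tipping point
        hub = mod[1]
        for g in mod[2:]:
            edges.append((genes[hub], genes[g]))
        for a, b in zip(mod, mod[1:] + mod[:1]):
            if a != b:
                edges.append((genes[a], genes[b]))
        for g, p in zip(mod, partners):
            edges.append((genes[g], genes[p]))
        in_module.update(mod)
    background = [i for i in range(cfg.n_genes) if i not in in_module]
    # random tree over background genes, rooted at a module hub
    for pos, g in enumerate(background):
        if pos == 0:
            edges.append((genes[g], genes[0]))
        else:
            parent = background[rng.integers(0, pos)]
            edges.append((genes[g], genes[parent]))
    # densify the background: very low-degree nodes have volatile
    # two-neighbor entropies that would drown the planted signal
    if len(background) >= 2:
        n_extra = 2 * len(background)
        for _ in range(n_extra):
            a, b = rng.choice(background, size=2, replace=False)
            edges.append((genes[a], genes[b]))
    return GeneNetwork(edges)


def _correlation_matrix(cfg: SimConfig, weights: dict[str, float]) -> np.ndarray:
    r = np.eye(cfg.n_genes)
    for key, (mod, partners) in _module_layout(cfg).items():
        w = weights[key]
        rho_in = cfg.rho_in_base + w * (cfg.rho_in_crit - cfg.rho_in_base)
        rho_out = cfg.rho_out_base + w * (cfg.rho_out_crit - cfg.rho_out_base)
        for i, a in enumerate(mod):
            for b in mod[i + 1:]:
                r[a, b] = r[b, a] = rho_in
            p = partners[i]
            r[a, p] = r[p, a] = rho_out
    return r


def _sd_vector(cfg: SimConfig, weights: dict[str, float]) -> np.ndarray:
    sd = np.full(cfg.n_genes, cfg.sd_base)
    for key, (mod, _) in _module_layout(cfg).items():
        gain = weights[key] * (cfg.sd_crit - cfg.sd_base)
        sd[mod] = cfg.sd_base + gain
        # the module's anchor (hub) gene — the planted prognostic marker —
        # is perturbed hardest, so its per-sample membership is stable
        sd[mod[0]] = cfg.sd_base + cfg.anchor_sd_boost * gain
    return sd


def simulate_study(cfg: SimConfig) -> tuple[ExpressionStudy, SimTruth]:
    """Draw reference and staged case samples; returns study plus truth."""
    rng = np.random.default_rng([cfg.seed, 1])
    genes = cfg.genes
    layout = _module_layout(cfg)
    module_keys = list(layout)

    chol_cache: dict[tuple[float, ...], np.ndarray] = {}

    def draw(weights: dict[str, float], count: int) -> np.ndarray:
        key = tuple(weights[k] for k in module_keys)
        if key not in chol_cache:
            corr = _correlation_matrix(cfg, weights)
            sd = _sd_vector(cfg, weights)
            cov = corr * np.outer(sd, sd)
            try:
                chol_cache[key] = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"covariance not positive definite at module weights {weights}"
                ) from None
        z = rng.standard_normal((count, cfg.n_genes))
        return _BASE_MEAN + z @ chol_cache[key].T

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    stages: dict[str, str] = {}
    sample_modules: dict[str, str] = {}

    baseline = {k: 0.0 for k in module_keys}
    ref = draw(baseline, cfg.n_ref)
    for i in range(cfg.n_ref):
        sid = f"ref{i:03d}"
        columns[sid] = ref[i]
        groups[sid] = REFERENCE_LABEL

    for stage in cfg.stages:
        w = cfg.stage_weight(stage)
        if cfg.prognostic_split:
            assignment = np.array(["P", "O"] * ((cfg.n_per_stage + 1) // 2))[: cfg.n_per_stage]
            rng.shuffle(assignment)
        else:
            assignment = np.array(["P"] * cfg.n_per_stage)
        for i in range(cfg.n_per_stage):
            weights = dict(baseline)
            weights[assignment[i]] = w
            sid = f"case_{stage}_{i:03d}"
            columns[sid] = draw(weights, 1)[0]
            groups[sid] = CASE_LABEL
            stages[sid] = stage
            sample_modules[sid] = str(assignment[i])

    expr = pd.DataFrame({sid: vals for sid, vals in columns.items()}, index=genes)
    study = ExpressionStudy(expression=expr, groups=groups, stages=stages)

    p_mod, _ = layout["P"]
    truth = SimTruth(
        module_genes=tuple(genes[i] for i in p_mod),
        critical_stage=cfg.critical_stage,
        pessimistic_gene=genes[p_mod[0]],
        sample_modules=sample_modules,
    )
    if cfg.prognostic_split:
        o_mod, _ = layout["O"]
        truth.optimistic_module = tuple(genes[i] for i in o_mod)
        truth.optimistic_gene = genes[o_mod[0]]
    return study, truth


def simulate_survival(
    truth: SimTruth,
    samples: Sequence[tuple[str, str]],
    cfg: SimConfig,
    membership: dict[str, frozenset[str] | set[str]] | None = None,
) -> list[SurvivalRecord]:
    """Exponential survival for case samples (``samples`` = (id, stage) pairs).

    Without ``membership``, samples at/after the critical stage have
    their hazard multiplied by ``survival_hazard_ratio`` (pessimistic-
    module samples) or divided by it (optimistic-module samples, when a
    split is planted). With ``membership`` (sample id -> that sample's
    high-entropy gene set), hazards are instead conditioned on whether
    the planted pessimistic/optimistic gene is in the sample's set, so
    biomarker-linked survival can be generated from realized gene sets.
    Censoring is independent; ``censoring_rate >= 1`` censors every
    record.
    """
    if cfg.survival_hazard_ratio <= 0:
        raise ValueError("survival_hazard_ratio must be > 0")
    rng = np.random.default_rng([cfg.seed, 2])
    crit = list(cfg.stages).index(cfg.critical_stage)
    records = []
    for sid, stage in samples:
        hazard = cfg.baseline_hazard
        if membership is not None:
            genes = membership.get(sid, frozenset())
            if truth.pessimistic_gene in genes:
                hazard *= cfg.survival_hazard_ratio
            elif truth.optimistic_gene is not None and truth.optimistic_gene in genes:
                hazard /= cfg.survival_hazard_ratio
        elif list(cfg.stages).index(stage) >= crit:
            module = truth.sample_modules.get(sid, "P")
            if module == "O" and truth.optimistic_module is not None:
                hazard /= cfg.survival_hazard_ratio
            else:
                hazard *= cfg.survival_hazard_ratio
        t_event = rng.exponential(1.0 / hazard)
        if cfg.censoring_rate >= 1.0:
            records.append(SurvivalRecord(sid, float(t_event), 0))
        elif cfg.censoring_rate <= 0.0:
            records.append(SurvivalRecord(sid, float(t_event), 1))
        else:
            c_rate = cfg.baseline_hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
            t_cens = rng.exponential(1.0 / c_rate)
            if t_cens < t_event:
                records.append(SurvivalRecord(sid, float(t_cens), 0))
            else:
                records.append(SurvivalRecord(sid, float(t_event), 1))
    return records
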