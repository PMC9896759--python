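"""Synthetic pooled CRISPR screen generator with ground-truth labels.

A screen is generated in five stages:

1. Per-gene mean lethality in the reference condition, ``z1 ~ Gamma(1, 1)``
   rescaled by the maximum draw so values lie in [0, 1] and most genes look
   non-essential.
2. The second condition's mean is ``z2 = z1 + delta`` for the first
   ``n_effect`` genes and ``z2 = z1`` otherwise.
3. Observed per-guide fold changes ``fc ~ N(z, sigma^2)`` for every guide,
   replicate and condition, collected in a guides x (2R) matrix ``L``.
4. Initial (T=0) counts ``C0 = trunc(f * lambda)`` with transduction
   efficiency ``lambda ~ U(0.05, 1.95)``; under the paired design the two
   conditions of a replicate share one lambda (one transduction, split
   after T=0), under the independent design each arm draws its own.
5. Endpoint counts ``M = C0 - C0 * L``, rounded to the nearest integer and
   clamped below at zero (noise can push ``L`` above 1; counts cannot go
   negative).

Positive/negative assay controls (defaults: 400 + 400 guides, mean
lethality 0.8 / 0.1, sigma 0.05, identical in both conditions) run through
stages 3-5 unchanged and are grouped four guides per synthetic control
gene so they flow through gene-level code like any other gene.

Randomness is split into named child streams of the master seed, one per
stage, so altering one stage's draws never shifts another's.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import ControlSet, CountScreen, SampleSheet

__all__ = [
    "SimulationConfig",
    "SimulatedScreen",
    "simulate_gene_effects",
    "simulate_fold_changes",
    "simulate_initial_counts",
    "compute_endpoint_counts",
    "add_controls",
    "simulate_screen",
]

_STREAMS = ("gene_effects", "fold_changes", "initial_counts",
            "control_fold_changes", "control_initial_counts")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen generator.

    Defaults are the benchmark study conditions: G=1000 genes x S_g=4
    guides, R=3 replicates per condition, the first 100 genes carrying a
    differential effect ``delta``, replicate noise ``sigma=0.1``, mean
    transduction fold ``f=400``, and 400 + 400 control guides with mean
    lethality 0.8 (positive) / 0.1 (negative) at ``control_sigma=0.05``.
    """

    G: int = 1000
    S_g: int = 4
    R: int = 3
    n_effect: int = 100
    delta: float = 0.0
    sigma: float = 0.1
    f: float = 400.0
    design: str = "independent"
    n_pos: int = 400
    n_neg: int = 400
    control_mean_pos: float = 0.8
    control_mean_neg: float = 0.1
    control_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.G, self.S_g, self.R) < 1 or self.f <= 0:
            raise ValueError("G, S_g, R and f must be positive")
        if not (0 <= self.n_effect <= self.G):
            raise ValueError("n_effect must lie in [0, G]")
        if self.delta < 0 or self.sigma < 0 or self.control_sigma < 0:
            raise ValueError("delta and noise levels must be >= 0")
        if self.design not in ("paired", "independent"):
            raise ValueError(f"unknown design {self.design!r}")

    def streams(self) -> dict:
        """Named per-stage random generators derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(child)
                for name, child in zip(_STREAMS, children)}


@dataclass(frozen=True)
class SimulatedScreen:
    """A generated screen plus its ground truth and latent matrices."""

    screen: CountScreen
    sheet: SampleSheet
    controls: ControlSet
    truth: pd.Series          # per library gene: True if differential effect
    config: SimulationConfig
    z1: np.ndarray            # per-gene mean lethality, reference condition
    z2: np.ndarray            # per-gene mean lethality, second condition
    L: np.ndarray             # latent fold changes, guides x 2R (library+controls)
    C0: np.ndarray            # initial counts, guides x 2R
    M: np.ndarray             # endpoint counts, guides x 2R

    @property
    def effect_genes(self) -> tuple:
        return tuple(self.truth.index[self.truth])


def simulate_gene_effects(config: SimulationConfig, rng: np.random.Generator):
    """Stage 1-2: per-gene mean lethality in both conditions.

    Returns ``(z1, z2)``; ``z1`` is rescaled by its maximum so the largest
    effect is exactly 1.
    """
    z1 = rng.gamma(shape=1.0, scale=1.0, size=config.G)
    z1 = z1 / z1.max()
    z2 = z1.copy()
    z2[: config.n_effect] += config.delta
    return z1, z2


def _column_order(R: int):
    """(condition, replicate) pairs in column order: c1 r1..R, then c2."""
    return [(c, r) for c in (1, 2) for r in range(1, R + 1)]


def simulate_fold_changes(z: np.ndarray, config: SimulationConfig,
                          rng: np.random.Generator,
                          sigma: Optional[float] = None) -> np.ndarray:
    """Stage 3: guide-level fold changes ``fc ~ N(z, sigma^2)``.

    ``z`` is guides x 2 (per-condition means, already expanded guide-wise);
    the result has one column per (condition, replicate).
    """
    sigma = config.sigma if sigma is None else sigma
    n_guides = z.shape[0]
    cols = [rng.normal(loc=z[:, c - 1], scale=sigma, size=n_guides)
            for c, _r in _column_order(config.R)]
    return np.column_stack(cols)


def simulate_initial_counts(config: SimulationConfig, rng: np.random.Generator,
                            n_guides: int) -> np.ndarray:
    """Stage 4: T=0 counts ``trunc(f * lambda)``, lambda ~ U(0.05, 1.95).

    Under the paired design the same lambda serves both conditions of a
    replicate; under the independent design every arm draws its own.
    """
    R = config.R
    if config.design == "paired":
        lam = rng.uniform(0.05, 1.95, size=(n_guides, R))
        lam = np.concatenate([lam, lam], axis=1)
    else:
        lam = rng.uniform(0.05, 1.95, size=(n_guides, 2 * R))
    return np.trunc(config.f * lam).astype(np.int64)


def compute_endpoint_counts(C0: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Stage 5: endpoint counts ``M = C0 - C0*L``, rounded, clamped at 0."""
    if C0.shape != L.shape:
        raise ValueError(f"shape mismatch: C0 {C0.shape} vs L {L.shape}")
    M = np.rint(C0 * (1.0 - L))
    return np.maximum(M, 0).astype(np.int64)


def _control_labels(config: SimulationConfig):
    """Control guide ids, gene map and per-guide mean lethality columns."""
    guide_ids, genes, z_rows = [], [], []
    for kind, n, mean in (("pos", config.n_pos, config.control_mean_pos),
                          ("neg", config.n_neg, config.control_mean_neg)):
        per_gene = config.S_g
        for i in range(n):
            gene_idx = i // per_gene + 1
            gene = f"{kind}_ctrl_{gene_idx:04d}"
            guide_ids.append(f"{gene}_sg{i % per_gene + 1}")
            genes.append(gene)
            z_rows.append((mean, mean))  # identical in both conditions
    return guide_ids, genes, np.array(z_rows, dtype=float)


def add_controls(sim: SimulatedScreen, config: SimulationConfig,
                 rng_fc: np.random.Generator,
                 rng_c0: np.random.Generator) -> SimulatedScreen:
    """Append control guides (stages 3-5 with fixed z) to a library screen."""
    guide_ids, genes, z = _control_labels(config)
    if not guide_ids:
        return sim
    L_ctrl = simulate_fold_changes(z, config, rng_fc, sigma=config.control_sigma)
    C0_ctrl = simulate_initial_counts(config, rng_c0, len(guide_ids))
    M_ctrl = compute_endpoint_counts(C0_ctrl, L_ctrl)

    pos_genes = frozenset(g for g in genes if g.startswith("pos_ctrl"))
    neg_genes = frozenset(g for g in genes if g.startswith("neg_ctrl"))
    counts_ctrl = _assemble_counts(C0_ctrl, M_ctrl, config)
    screen = CountScreen(
        guide_ids=sim.screen.guide_ids + tuple(guide_ids),
        gene_of_guide={**dict(sim.screen.gene_of_guide), **dict(zip(guide_ids, genes))},
        counts=np.vstack([sim.screen.counts, counts_ctrl]),
        sample_ids=sim.screen.sample_ids,
    )
    return replace(
        sim,
        screen=screen,
        controls=ControlSet(positive_genes=pos_genes, negative_genes=neg_genes),
        L=np.vstack([sim.L, L_ctrl]),
        C0=np.vstack([sim.C0, C0_ctrl]),
        M=np.vstack([sim.M, M_ctrl]),
    )


def _sample_names(config: SimulationConfig):
    """(T0 names by column, endpoint names by column) for the 2R columns."""
    t0, endpoint = [], []
    for c, r in _column_order(config.R):
        endpoint.append(f"T1_c{c}_r{r}")
        if config.design == "paired":
            t0.append(f"T0_r{r}")
        else:
            t0.append(f"T0_c{c}_r{r}")
    return t0, endpoint


def _assemble_counts(C0: np.ndarray, M: np.ndarray, config: SimulationConfig):
    """Stack T0 and endpoint columns in sample-sheet order."""
    t0_names, _ = _sample_names(config)
    unique_t0 = list(dict.fromkeys(t0_names))
    t0_cols = [C0[:, t0_names.index(name)] for name in unique_t0]
    return np.column_stack(t0_cols + [M[:, j] for j in range(M.shape[1])])


def _build_sheet(config: SimulationConfig) -> SampleSheet:
    t0_names, endpoint_names = _sample_names(config)
    rows = []
    for name in dict.fromkeys(t0_names):
        if config.design == "paired":
            rep = int(name.split("_r")[1])
            cond = ""
        else:
            cond = f"c{name.split('_c')[1].split('_')[0]}"
            rep = int(name.split("_r")[1])
        rows.append((name, cond, rep, "T0", ""))
    for j, (c, r) in enumerate(_column_order(config.R)):
        rows.append((endpoint_names[j], f"c{c}", r, "T1", t0_names[j]))
    table = pd.DataFrame(rows, columns=["sample", "condition", "replicate",
                                        "timepoint", "t0_partner"])
    return SampleSheet(table=table, design=config.design, reference="c1")


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate a complete screen (library + controls) with truth labels."""
    rngs = config.streams()
    z1, z2 = simulate_gene_effects(config, rngs["gene_effects"])
    z_guides = np.repeat(np.column_stack([z1, z2]), config.S_g, axis=0)
    L = simulate_fold_changes(z_guides, config, rngs["fold_changes"])
    C0 = simulate_initial_counts(config, rngs["initial_counts"],
                                 config.G * config.S_g)
    M = compute_endpoint_counts(C0, L)

    gene_names = [f"g{i + 1:04d}" for i in range(config.G)]
    guide_ids = [f"{gene_names[i // config.S_g]}_sg{i % config.S_g + 1}"
                 for i in range(config.G * config.S_g)]
    gene_of_guide = {gid: gene_names[i // config.S_g]
                     for i, gid in enumerate(guide_ids)}

    sheet = _build_sheet(config)
    counts = _assemble_counts(C0, M, config)
    screen = CountScreen(
        guide_ids=tuple(guide_ids),
        gene_of_guide=gene_of_guide,
        counts=counts,
        sample_ids=tuple(sheet.table["sample"]),
    )
    truth = pd.Series(
        [i < config.n_effect and config.delta > 0 for i in range(config.G)],
        index=gene_names, name="is_effect",
    )
    sim = SimulatedScreen(
        screen=screen, sheet=sheet,
        controls=ControlSet(frozenset(), frozenset()),
        truth=truth, config=config, z1=z1, z2=z2, L=L, C0=C0, M=M,
    )
    sim = add_controls(sim, config, rngs["control_fold_changes"],
                       rngs["control_initial_counts"])
    return sim
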