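"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import linalg

from shrinkcrispr import (HyperParameters, ShrinkCrisprModel, SimulationConfig,
                          simulate_screen)
from shrinkcrispr.genemodel import GeneModelSpec

settings.register_profile(
    "suite", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def hp_toy() -> HyperParameters:
    """Fixed hyperparameters for single-gene tests."""
    return HyperParameters(
        v_beta=0.05,
        log_theta_loc=np.log(np.array([0.02, 0.005, 0.005])),
        log_theta_scale=np.array([1.0, 1.5, 1.5]),
    )


@pytest.fixture(scope="session")
def small_screen():
    """A small but complete simulated screen with strong effects."""
    cfg = SimulationConfig(G=80, n_effect=8, delta=0.5, n_pos=40, n_neg=40,
                           seed=11)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def small_screen_fit(small_screen):
    model = ShrinkCrisprModel(small_screen.screen, small_screen.sheet,
                              small_screen.controls)
    return model.fit()


def make_balanced_spec(gene="toy", S=3, R=2, beta=0.0, sigma=0.15,
                       seed=0) -> GeneModelSpec:
    """A complete balanced two-condition gene with a known effect."""
    rng = np.random.default_rng(seed)
    guide = np.repeat(np.arange(S), 2 * R)
    cond = np.tile(np.repeat([0, 1], R), S)
    y = 0.2 + beta * cond + rng.normal(0.0, sigma, size=S * 2 * R)
    return GeneModelSpec(gene=gene, y=y, condition=cond, guide=guide)


def brute_force_logml(spec: GeneModelSpec, hp: HyperParameters,
                      hypothesis: str, n_phi: int = 31, n_beta: int = 81,
                      span: float = 6.0) -> float:
    """Dense-grid quadrature oracle for the per-gene marginal likelihood.

    Integrates the Gaussian marginal (alpha, b, u analytic) over a
    trapezoid grid in the three log variance components and, under the
    alternative, a trapezoid grid over the tested effect.  Independent of
    the package's mode-finding / Gauss-Hermite machinery.
    """
    y = spec.y
    n = len(y)
    cond = spec.condition.astype(float) - 0.5   # centred coding, as the model
    gidx = spec.guide
    Gb = (gidx[:, None] == gidx[None, :]).astype(float)
    Gu = Gb * (spec.condition[:, None] == spec.condition[None, :])
    v_alpha = hp.v_alpha_scale * np.var(y)
    ones = np.ones(n)
    grids, lw = [], []
    for i in range(3):
        g = np.linspace(hp.log_theta_loc[i] - span * hp.log_theta_scale[i],
                        hp.log_theta_loc[i] + span * hp.log_theta_scale[i],
                        n_phi)
        w = np.full(n_phi, g[1] - g[0])
        w[0] *= 0.5
        w[-1] *= 0.5
        grids.append(g)
        lw.append(np.log(w))
    if hypothesis == "Ha":
        bspan = span * np.sqrt(hp.v_beta) + 2.0 * np.std(y)
        bgrid = np.linspace(-bspan, bspan, n_beta)
        wb = np.full(n_beta, bgrid[1] - bgrid[0])
        wb[0] *= 0.5
        wb[-1] *= 0.5
        log_pb = (-0.5 * (bgrid ** 2 / hp.v_beta
                          + np.log(2 * np.pi * hp.v_beta)) + np.log(wb))
    vals = []
    for i, p0 in enumerate(grids[0]):
        for j, p1 in enumerate(grids[1]):
            for k, p2 in enumerate(grids[2]):
                s2, tb, tu = np.exp([p0, p1, p2])
                V0 = (s2 * np.eye(n) + tb * Gb + tu * Gu
                      + v_alpha * np.outer(ones, ones))
                c, low = linalg.cho_factor(V0, lower=True)
                logdet = 2 * np.sum(np.log(np.diag(c)))
                lp_phi = sum(
                    -0.5 * ((p - hp.log_theta_loc[d]) / hp.log_theta_scale[d]) ** 2
                    - 0.5 * np.log(2 * np.pi) - np.log(hp.log_theta_scale[d])
                    for d, p in enumerate((p0, p1, p2)))
                base = -0.5 * (n * np.log(2 * np.pi) + logdet)
                wsum = lw[0][i] + lw[1][j] + lw[2][k]
                if hypothesis == "H0":
                    q = y @ linalg.cho_solve((c, low), y)
                    vals.append(base - 0.5 * q + lp_phi + wsum)
                else:
                    Viy = linalg.cho_solve((c, low), y)
                    Vic = linalg.cho_solve((c, low), cond)
                    yy = y @ Viy
                    cy = cond @ Viy
                    cc = cond @ Vic
                    qs = yy - 2 * bgrid * cy + bgrid ** 2 * cc
                    t = base - 0.5 * qs + log_pb
                    m = t.max()
                    vals.append(m + np.log(np.exp(t - m).sum())
                                + lp_phi + wsum)
    vals = np.array(vals)
    m = vals.max()
    return float(m + np.log(np.exp(vals - m).sum()))


def brute_force_logml_batch(specs, hp: HyperParameters, hypothesis: str,
                            n_phi: int = 31, n_beta: int = 81,
                            span: float = 6.0) -> np.ndarray:
    """Batched dense-grid quadrature oracle.

    All specs must share the same (guide, condition) layout; the dense
    covariance is factorized once per grid point and reused across genes.
    """
    ref = specs[0]
    for s in specs[1:]:
        assert np.array_equal(s.guide, ref.guide)
        assert np.array_equal(s.condition, ref.condition)
    Y = np.stack([s.y for s in specs])                    # (G, n)
    G, n = Y.shape
    cond = ref.condition.astype(float) - 0.5
    gidx = ref.guide
    Gb = (gidx[:, None] == gidx[None, :]).astype(float)
    Gu = Gb * (ref.condition[:, None] == ref.condition[None, :])
    v_alpha = hp.v_alpha_scale * np.var(Y, axis=1)        # per gene
    ones = np.ones(n)
    grids, lw = [], []
    for i in range(3):
        g = np.linspace(hp.log_theta_loc[i] - span * hp.log_theta_scale[i],
                        hp.log_theta_loc[i] + span * hp.log_theta_scale[i],
                        n_phi)
        w = np.full(n_phi, g[1] - g[0])
        w[0] *= 0.5
        w[-1] *= 0.5
        grids.append(g)
        lw.append(np.log(w))
    if hypothesis == "Ha":
        bspan = span * np.sqrt(hp.v_beta) + 2.0 * float(np.std(Y))
        bgrid = np.linspace(-bspan, bspan, n_beta)
        wb = np.full(n_beta, bgrid[1] - bgrid[0])
        wb[0] *= 0.5
        wb[-1] *= 0.5
        log_pb = (-0.5 * (bgrid ** 2 / hp.v_beta
                          + np.log(2 * np.pi * hp.v_beta)) + np.log(wb))
    vals = np.full((G, n_phi ** 3), -np.inf)
    col = 0
    for i, p0 in enumerate(grids[0]):
        for j, p1 in enumerate(grids[1]):
            for k, p2 in enumerate(grids[2]):
                s2, tb, tu = np.exp([p0, p1, p2])
                Vs = s2 * np.eye(n) + tb * Gb + tu * Gu
                c, low = linalg.cho_factor(Vs, lower=True, check_finite=False)
                logdet_s = 2 * np.sum(np.log(np.diag(c)))
                ViY = linalg.cho_solve((c, low), Y.T, check_finite=False)
                Vi1 = linalg.cho_solve((c, low), ones, check_finite=False)
                Vic = linalg.cho_solve((c, low), cond, check_finite=False)
                # Sherman-Morrison for the per-gene diffuse-alpha rank-1
                # term v_alpha * 1 1'
                s11 = ones @ Vi1
                s1y = ones @ ViY           # (G,)
                s1c = ones @ Vic
                denom = 1.0 + v_alpha * s11
                yy = np.einsum("ng,ng->g", Y.T, ViY) - v_alpha * s1y ** 2 / denom
                logdet = logdet_s + np.log(denom)
                lp_phi = sum(
                    -0.5 * ((p - hp.log_theta_loc[d]) / hp.log_theta_scale[d]) ** 2
                    - 0.5 * np.log(2 * np.pi) - np.log(hp.log_theta_scale[d])
                    for d, p in enumerate((p0, p1, p2)))
                wsum = lw[0][i] + lw[1][j] + lw[2][k]
                base = -0.5 * (n * np.log(2 * np.pi) + logdet)
                if hypothesis == "H0":
                    vals[:, col] = base - 0.5 * yy + lp_phi + wsum
                else:
                    cy = cond @ ViY - v_alpha * s1c * s1y / denom   # (G,)
                    cc = cond @ Vic - v_alpha * s1c ** 2 / denom    # (G,)
                    qs = (yy[:, None] - 2 * bgrid[None, :] * cy[:, None]
                          + bgrid[None, :] ** 2 * cc[:, None])
                    t = base[:, None] - 0.5 * qs + log_pb[None, :]
                    m = t.max(axis=1)
                    vals[:, col] = (m + np.log(np.sum(np.exp(t - m[:, None]),
                                                      axis=1))
                                    + lp_phi + wsum)
                col += 1
    m = vals.max(axis=1)
    return m + np.log(np.sum(np.exp(vals - m[:, None]), axis=1))
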