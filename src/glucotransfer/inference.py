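"""Hierarchical Bayesian inference for the response models.

The joint model couples person-specific response parameters through
group-level Gaussian priors: for person ``p``

    alpha_d[p] ~ N(alpha_d_mu, 10)   truncated > 0
    beta_d[p]  ~ N(beta_d_mu, 0.1)
    alpha_e[p] ~ N(alpha_e_mu, alpha_e_sd)  truncated > 0
    beta_e[p]  ~ N(beta_e_mu, beta_e_sd)
    c_syn[p]   ~ N(c_mu, c_sd)
    sigma[p]   ~ HalfNormal(2)

with fixed person-level SDs for the diet block, learned half-normal(1) SDs
for the exercise block, and hyperpriors on the group means given by a
:class:`~glucotransfer.priors.PriorSpec` (flat for the source task,
possibly an informative rescaled Gaussian for the target task; in extended
transfer the shift ``eta`` and shrink ``lambda`` are sampled jointly).

Sampling uses an affine-invariant ensemble MCMC with differential-evolution
moves (emcee), fully vectorised over walkers; independent ensembles serve as
chains for the Gelman-Rubin diagnostic.  The backend sits behind the plain
"draws in, summaries out" contract of :class:`PosteriorSummary`, so other
samplers can be swapped in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

import emcee

from .priors import PriorSpec, exercise_block_size, EXERCISE_COMPONENTS
from .responses import PersonParams
from .segments import SegmentSet, N_POST
from .responses import baseline_glucose

_LOG_FLOOR = 1e-300


@dataclass
class SamplerConfig:
    """MCMC settings: 4 chains of 4000 iterations with 2000 burn-in by default."""

    n_chains: int = 4
    n_iter: int = 4000
    n_burnin: int = 2000
    seed: Optional[int] = None
    n_walkers: Optional[int] = None   # default: max(2*dim + 2, 48), rounded even
    thin: Optional[int] = None        # default: auto (bounded memory)
    backend: str = "emcee-de"

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    def walkers_for(self, ndim: int) -> int:
        n = self.n_walkers if self.n_walkers is not None else max(2 * ndim + 2, 48)
        return n + (n % 2)

    def thin_for(self, ndim: int) -> int:
        if self.thin is not None:
            return self.thin
        kept = self.n_iter - self.n_burnin
        # keep at most ~2e6 scalars per chain
        max_steps = max(25, int(2e6 / max(1, self.walkers_for(ndim) * ndim)))
        return max(1, int(np.ceil(kept / max_steps)))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroupHyper:
    """Posterior-median group-level means and person-level SDs."""

    theta_tilde: dict
    sigma_person: dict


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

class ParamLayout:
    """Maps named model parameters to positions in the sampled vector."""

    def __init__(self, model_kind: str, person_ids: Sequence[str], extended: bool):
        self.model_kind = model_kind
        self.person_ids = list(person_ids)
        self.extended = extended
        self.k = exercise_block_size(model_kind)
        if extended and self.k == 0:
            raise ValueError("extended transfer requires an exercise block")

        names: list[str] = ["alpha_d_mu", "beta_d_mu"]
        comps = EXERCISE_COMPONENTS[:self.k]
        names += [f"{c}_mu" for c in comps]
        names += [f"{c}_sd" for c in comps]
        if extended:
            names += [f"eta_{c}" for c in comps] + ["lam"]
        self.n_hyper = len(names)
        self.person_block = 3 + self.k  # alpha_d, beta_d, (exercise...), sigma
        for pid in self.person_ids:
            names.append(f"alpha_d[{pid}]")
            names.append(f"beta_d[{pid}]")
            names += [f"{c}[{pid}]" for c in comps]
            names.append(f"sigma[{pid}]")
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.ndim = len(names)

    def hyper_mean_names(self) -> list[str]:
        return ["alpha_d_mu", "beta_d_mu"] + [
            f"{c}_mu" for c in EXERCISE_COMPONENTS[:self.k]]

    def person_slice(self, p: int) -> slice:
        start = self.n_hyper + p * self.person_block
        return slice(start, start + self.person_block)

    def person_index(self, p: int, offset: int) -> int:
        return self.n_hyper + p * self.person_block + offset


# ---------------------------------------------------------------------------
# Likelihood bundle: segments flattened to padded numpy blocks per person
# ---------------------------------------------------------------------------

class _PersonData:
    __slots__ = ("y", "base", "m_delta", "m_dose", "m_mask",
                 "e_delta", "e_dose", "e_mask", "n_obs")

    def __init__(self, segments, model_kind):
        S = len(segments)
        self.y = np.array([s.post_glucose for s in segments]) if S else np.zeros((0, N_POST))
        self.base = np.array([baseline_glucose(s) for s in segments]) if S else np.zeros(0)
        self.n_obs = self.y.size

        def pad(event_lists, grids, dose_of):
            K = max((len(ev) for ev in event_lists), default=0)
            K = max(K, 1)
            delta = np.zeros((S, K, N_POST))
            dose = np.zeros((S, K))
            for i, (ev, grid) in enumerate(zip(event_lists, grids)):
                for j, e in enumerate(ev):
                    delta[i, j] = grid - e.time
                    dose[i, j] = dose_of(e)
            return delta, dose, delta >= 0

        grids = [s.post_times.astype(float) for s in segments]
        self.m_delta, self.m_dose, self.m_mask = pad(
            [s.meals_in_window for s in segments], grids, lambda m: m.carbs)
        if model_kind in ("additive", "synergistic"):
            self.e_delta, self.e_dose, self.e_mask = pad(
                [s.exercises_in_window for s in segments], grids, lambda e: e.ee)
        else:
            self.e_delta = self.e_dose = self.e_mask = None


class _Bundle:
    """Segments flattened to event-term arrays for one vectorised likelihood.

    Terms (one per event per segment window) are stored contiguously by
    segment, segments contiguously by person, so per-segment and per-person
    sums are ``np.add.reduceat`` calls.  Segments without exercise carry one
    zero-dose dummy term to keep the reduceat groups non-empty.
    """

    def __init__(self, segment_set: SegmentSet, model_kind: str,
                 person_ids: Sequence[str]):
        by_person = {pid: [] for pid in person_ids}
        for seg in segment_set.segments:
            if seg.person_id in by_person:
                by_person[seg.person_id].append(seg)
        self.persons = [_PersonData(by_person[pid], model_kind)
                        for pid in person_ids]
        self.active = np.array([p.n_obs > 0 for p in self.persons])
        self.n_obs_person = np.array([p.n_obs for p in self.persons], dtype=float)

        has_exercise = model_kind in ("additive", "synergistic")
        resid0, seg_person, p_starts = [], [], []
        m_delta, m_dose, m_person, m_starts = [], [], [], []
        e_delta, e_dose, e_person, e_starts = [], [], [], []
        s_idx = 0
        for p_idx, pid in enumerate(person_ids):
            p_starts.append(s_idx)
            for seg in by_person[pid]:
                grid = seg.post_times.astype(float)
                resid0.append(seg.post_glucose - baseline_glucose(seg))
                seg_person.append(p_idx)
                m_starts.append(len(m_dose))
                for m in seg.meals_in_window:
                    m_delta.append(grid - m.time)
                    m_dose.append(m.carbs)
                    m_person.append(p_idx)
                if has_exercise:
                    e_starts.append(len(e_dose))
                    events = seg.exercises_in_window or ()
                    for e in events:
                        e_delta.append(grid - e.time)
                        e_dose.append(e.ee)
                        e_person.append(p_idx)
                    if not events:
                        e_delta.append(grid)
                        e_dose.append(0.0)
                        e_person.append(p_idx)
                s_idx += 1
        self.n_segments = s_idx
        self.resid0 = np.array(resid0) if s_idx else np.zeros((0, N_POST))
        self.seg_person = np.array(seg_person, dtype=int)
        # clip duplicate/trailing starts from segment-less persons; their
        # (wrong) reduceat groups are zeroed through the active mask
        self.p_starts = np.minimum(np.array(p_starts, dtype=int),
                                   max(s_idx - 1, 0))
        self.m_delta = np.array(m_delta) if m_dose else np.zeros((0, N_POST))
        self.m_mask = self.m_delta >= 0
        self.m_dose = np.array(m_dose)
        self.m_person = np.array(m_person, dtype=int)
        self.m_starts = np.array(m_starts, dtype=int)
        if has_exercise:
            self.e_delta = np.array(e_delta) if e_dose else np.zeros((0, N_POST))
            self.e_mask = self.e_delta >= 0
            self.e_dose = np.array(e_dose)
            self.e_person = np.array(e_person, dtype=int)
            self.e_starts = np.array(e_starts, dtype=int)


def _bundle(segment_set: SegmentSet, model_kind: str,
            person_ids: Sequence[str]) -> _Bundle:
    return _Bundle(segment_set, model_kind, person_ids)


def _bell_sum(delta, dose, mask, alpha):
    """Summed causal bell responses, vectorised over walkers.

    delta/dose/mask: (S, K, T)/(S, K)/(S, K, T); alpha: (W,).
    Returns (W, S, T).
    """
    a = alpha[:, None, None, None]
    z = (delta[None] - 3.0 * a) / a
    bell = np.exp(-0.5 * z * z)
    bell *= mask[None]
    return np.einsum("wskt,sk->wst", bell, dose)


def _term_response(delta, mask, dose, person_of_term, starts, alpha_person):
    """Per-segment summed bell responses from flattened term arrays.

    Returns (W, S, T): each segment's response with unit strength (the
    dose-weighted causal bells summed within the segment).
    """
    a = alpha_person[:, person_of_term, None]          # (W, M, 1)
    z = (delta[None] - 3.0 * a) / a
    bell = np.exp(-0.5 * z * z)
    bell *= (mask * dose[:, None])[None]
    return np.add.reduceat(bell, starts, axis=1)


def _log_likelihood(P: np.ndarray, layout: ParamLayout,
                    bundle: _Bundle) -> np.ndarray:
    """Gaussian log likelihood; ``P`` rows are *physical* parameter vectors."""
    W = P.shape[0]
    if bundle.n_segments == 0:
        return np.zeros(W)
    k = layout.k
    n_hyper, blk = layout.n_hyper, layout.person_block
    cols = n_hyper + blk * np.arange(len(layout.person_ids))
    alpha_d = P[:, cols]
    beta_d = P[:, cols + 1]
    sigma = P[:, cols + 2 + k]
    sp = bundle.seg_person
    r = beta_d[:, sp, None] * _term_response(
        bundle.m_delta, bundle.m_mask, bundle.m_dose, bundle.m_person,
        bundle.m_starts, alpha_d)
    if k:
        re = P[:, cols + 3][:, sp, None] * _term_response(
            bundle.e_delta, bundle.e_mask, bundle.e_dose, bundle.e_person,
            bundle.e_starts, P[:, cols + 2])
        if k == 3:
            r = r + re + P[:, cols + 4][:, sp, None] * r * re
        else:
            r = r + re
    resid = bundle.resid0[None] - r
    ss_seg = np.einsum("wst,wst->ws", resid, resid)
    ss_p = np.add.reduceat(ss_seg, bundle.p_starts, axis=1)
    ss_p[:, ~bundle.active] = 0.0
    safe_sig = np.where(bundle.active[None], sigma, 1.0)
    return np.sum(-0.5 * ss_p / (safe_sig * safe_sig)
                  - bundle.n_obs_person[None] * np.log(safe_sig), axis=1)


# ---------------------------------------------------------------------------
# Prior density
# ---------------------------------------------------------------------------

def _log_prior(P: np.ndarray, layout: ParamLayout, prior: PriorSpec) -> np.ndarray:
    W = P.shape[0]
    lp = np.zeros(W)
    bad = np.zeros(W, dtype=bool)
    k = layout.k
    ex = prior.exercise

    ad_mu = P[:, 0]
    bd_mu = P[:, 1]
    bad |= (ad_mu < prior.diet_alpha_bounds[0]) | (ad_mu > prior.diet_alpha_bounds[1])
    bad |= (bd_mu < prior.diet_beta_bounds[0]) | (bd_mu > prior.diet_beta_bounds[1])

    if k:
        theta_e = P[:, 2:2 + k]
        sds = P[:, 2 + k:2 + 2 * k]
        bad |= np.any(sds <= 0, axis=1)
        safe_sds = np.maximum(sds, _LOG_FLOOR)
        # half-normal hyperpriors on learned person-level SDs
        lp += -0.5 * np.sum((sds / prior.exercise_sd_scale) ** 2, axis=1)

        if ex.mode == "flat":
            for j in range(k):
                lo, hi = ex.bounds[j]
                bad |= (theta_e[:, j] < lo) | (theta_e[:, j] > hi)
        elif ex.mode == "gaussian":
            lp += -0.5 * np.sum((theta_e - ex.mu[None]) ** 2 / ex.var[None], axis=1)
        elif ex.mode == "extended":
            eta = P[:, 2 + 2 * k:2 + 3 * k]
            lam = P[:, 2 + 3 * k]
            bad |= lam <= 0
            safe_lam = np.maximum(lam, _LOG_FLOOR)
            lp += -0.5 * np.sum(((eta - ex.eta_mean[None]) / ex.eta_sd) ** 2, axis=1)
            lp += -0.5 * ((lam - ex.lam_mean) / ex.lam_sd) ** 2
            mu_t = eta * ex.mu[None]
            var_t = safe_lam[:, None] * ex.var[None]
            lp += np.sum(-0.5 * np.log(var_t) - 0.5 * (theta_e - mu_t) ** 2 / var_t,
                         axis=1)

    sd_ad, sd_bd = prior.diet_person_sd
    for p in range(len(layout.person_ids)):
        i0 = layout.person_index(p, 0)
        alpha_d = P[:, i0]
        beta_d = P[:, i0 + 1]
        sigma = P[:, i0 + 2 + k]
        bad |= (alpha_d <= 0) | (sigma <= 0)
        # truncated-at-zero normal for the response speed
        lp += -0.5 * ((alpha_d - ad_mu) / sd_ad) ** 2 \
            - np.log(np.maximum(ndtr(ad_mu / sd_ad), _LOG_FLOOR))
        lp += -0.5 * ((beta_d - bd_mu) / sd_bd) ** 2
        lp += -0.5 * (sigma / prior.sigma_scale) ** 2
        if k:
            alpha_e = P[:, i0 + 2]
            beta_e = P[:, i0 + 3]
            bad |= alpha_e <= 0
            ae_sd = np.maximum(P[:, 2 + k], _LOG_FLOOR)
            be_sd = np.maximum(P[:, 2 + k + 1], _LOG_FLOOR)
            ae_mu = P[:, 2]
            be_mu = P[:, 3]
            lp += -np.log(ae_sd) - 0.5 * ((alpha_e - ae_mu) / ae_sd) ** 2 \
                - np.log(np.maximum(ndtr(ae_mu / ae_sd), _LOG_FLOOR))
            lp += -np.log(be_sd) - 0.5 * ((beta_e - be_mu) / be_sd) ** 2
            if k == 3:
                c_p = P[:, i0 + 4]
                c_sd = np.maximum(P[:, 2 + k + 2], _LOG_FLOOR)
                c_mu = P[:, 4]
                lp += -np.log(c_sd) - 0.5 * ((c_p - c_mu) / c_sd) ** 2

    lp[bad] = -np.inf
    return lp


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def _trunc_pos(rng, mean, sd, size):
    x = rng.normal(mean, sd, size=size)
    for _ in range(50):
        neg = x <= 0
        if not neg.any():
            break
        x[neg] = rng.normal(np.broadcast_to(mean, x.shape)[neg], sd)
    return np.abs(x) + 1e-6


def _init_walkers(rng: np.random.Generator, layout: ParamLayout,
                  prior: PriorSpec, n_walkers: int) -> np.ndarray:
    W = n_walkers
    k = layout.k
    ex = prior.exercise
    P = np.empty((W, layout.ndim))
    P[:, 0] = rng.uniform(*prior.diet_alpha_bounds, size=W)
    P[:, 1] = rng.uniform(*prior.diet_beta_bounds, size=W)
    if k:
        if ex.mode == "flat":
            for j in range(k):
                P[:, 2 + j] = rng.uniform(*ex.bounds[j], size=W)
        elif ex.mode == "gaussian":
            P[:, 2:2 + k] = rng.normal(ex.mu, np.sqrt(ex.var), size=(W, k))
        else:
            eta = rng.normal(ex.eta_mean, ex.eta_sd, size=(W, k))
            lam = np.abs(rng.normal(ex.lam_mean, ex.lam_sd, size=W)) + 1e-4
            P[:, 2 + 2 * k:2 + 3 * k] = eta
            P[:, 2 + 3 * k] = lam
            P[:, 2:2 + k] = rng.normal(eta * ex.mu, np.sqrt(lam[:, None] * ex.var))
        P[:, 2 + k:2 + 2 * k] = np.abs(
            rng.normal(0.0, prior.exercise_sd_scale, size=(W, k))) + 1e-4
    for p in range(len(layout.person_ids)):
        i0 = layout.person_index(p, 0)
        P[:, i0] = _trunc_pos(rng, P[:, 0], prior.diet_person_sd[0], W)
        P[:, i0 + 1] = rng.normal(P[:, 1], prior.diet_person_sd[1])
        if k:
            P[:, i0 + 2] = _trunc_pos(rng, P[:, 2], P[:, 2 + k], W)
            P[:, i0 + 3] = rng.normal(P[:, 3], P[:, 2 + k + 1])
            if k == 3:
                P[:, i0 + 4] = rng.normal(P[:, 4], P[:, 2 + k + 2])
        P[:, i0 + 2 + k] = np.abs(rng.normal(0.0, prior.sigma_scale, size=W)) + 1e-3
    return P


def _optimizer_bounds(layout: ParamLayout, prior: PriorSpec) -> list[tuple]:
    """Box constraints for the MAP search, slightly inside the support."""
    k = layout.k
    ex = prior.exercise
    bounds: list[tuple] = [prior.diet_alpha_bounds, prior.diet_beta_bounds]
    if k:
        if ex.mode == "flat":
            bounds += [tuple(b) for b in ex.bounds[:k]]
        else:
            bounds += [(m - 10 * np.sqrt(v), m + 10 * np.sqrt(v))
                       for m, v in zip(ex.mu, ex.var)]
        bounds += [(1e-3, 10.0)] * k          # learned person-level SDs
        if layout.extended:
            bounds += [(-3.0, 3.0)] * k       # eta
            bounds += [(1e-4, 3.0)]           # lambda
    for _ in layout.person_ids:
        bounds.append((1e-2, 120.0))          # alpha_d
        bounds.append((-2.0, 2.0))            # beta_d
        if k:
            bounds.append((1e-2, 120.0))      # alpha_e
            bounds.append((-2.0, 2.0))        # beta_e
            if k == 3:
                bounds.append((-6.0, 6.0))    # c_syn
        bounds.append((1e-3, 10.0))           # sigma
    return bounds


def _person_curve_fit(data: "_PersonData", k: int) -> tuple:
    """Per-person profile fit: grid over response speeds, OLS over strengths.

    For fixed (alpha_d, alpha_e) the mean trajectory is linear in
    (beta_d, beta_e, beta_d*beta_e*C), so an ordinary least-squares solve on
    the summed bell features profiles out the strengths; the speed pair with
    the smallest residual sum of squares wins.
    """
    resid = (data.y - data.base[:, None]).ravel()
    grid = np.geomspace(3.0, 40.0, 10)
    best = (np.inf, None)
    e_active = k > 0 and np.any(data.e_dose > 0)
    for a_d in grid:
        u = _bell_sum(data.m_delta, data.m_dose, data.m_mask,
                      np.array([a_d]))[0].ravel()
        e_grid = grid if e_active else grid[:1]
        for a_e in e_grid:
            cols = [u]
            if e_active:
                v = _bell_sum(data.e_delta, data.e_dose, data.e_mask,
                              np.array([a_e]))[0].ravel()
                cols.append(v)
                if k == 3:
                    cols.append(u * v)
            X = np.column_stack(cols)
            coef, rss, *_ = np.linalg.lstsq(X, resid, rcond=None)
            r = resid - X @ coef
            rss = float(r @ r)
            if rss < best[0]:
                best = (rss, (a_d, a_e, coef))
    rss, (a_d, a_e, coef) = best
    beta_d = float(coef[0])
    beta_e = float(coef[1]) if e_active else 0.0
    # the synergy weight is weakly identified; start it neutral at zero and
    # let the sampler learn it
    sigma = float(np.sqrt(rss / max(resid.size, 1)))
    # a person whose strongest bout is small carries next to no information
    # on the exercise block; their profiled speed/strength are noise fits
    informed = bool(e_active and np.max(data.e_dose) >= 40.0)
    return a_d, beta_d, a_e, beta_e, 0.0, max(sigma, 0.05), informed


def _structured_center(bundle, layout: ParamLayout, prior: PriorSpec) -> np.ndarray:
    """Data-driven starting point: per-person profile fits, hypers from their
    moments, transfer latents at their hyperprior means."""
    k = layout.k
    ex = prior.exercise
    x = np.empty(layout.ndim)
    fits = []
    for data in bundle.persons:
        fits.append(_person_curve_fit(data, k) if data.n_obs else None)
    got = [f for f in fits if f is not None]
    if got:
        arr = np.array([f[:6] for f in got])  # a_d, b_d, a_e, b_e, c, sigma
        means = arr.mean(axis=0)
    else:
        means = np.array([12.0, 0.05, 10.0, -0.01, 0.0, 0.5])
    x[0] = np.clip(means[0], *prior.diet_alpha_bounds)
    x[1] = np.clip(means[1], *prior.diet_beta_bounds)
    if k:
        # the exercise block is centred on persons whose data can actually
        # identify it; everyone else starts at the group centre
        inf_arr = np.array([f[:6] for f in got if f[6]])
        if ex.mode != "flat":
            theta = np.asarray(ex.mu, dtype=float)
        elif len(inf_arr):
            theta = inf_arr.mean(axis=0)[[2, 3, 4]][:k]
            for j in range(k):
                theta[j] = np.clip(theta[j], ex.bounds[j][0], ex.bounds[j][1])
        else:
            theta = np.array([10.0, -0.01, 0.0])[:k]
        x[2:2 + k] = theta[:k]
        if len(inf_arr) >= 2:
            spread = inf_arr[:, [2, 3, 4]].std(axis=0)[:k]
        else:
            spread = np.zeros(k)
        x[2 + k:2 + 2 * k] = np.maximum(spread, [0.5, 0.003, 0.03][:k])
        if layout.extended:
            x[2 + 2 * k:2 + 3 * k] = ex.eta_mean
            x[2 + 3 * k] = ex.lam_mean
    for p, f in enumerate(fits):
        i0 = layout.person_index(p, 0)
        if f is None:
            f = (x[0], x[1], 0.0, 0.0, 0.0, 0.5, False)
        a_d, b_d, a_e, b_e, c, sigma, informed = f
        x[i0] = max(a_d, 0.1)
        x[i0 + 1] = b_d
        if k:
            x[i0 + 2] = max(a_e, 0.1) if informed else max(x[2], 0.1)
            x[i0 + 3] = b_e if informed else x[3]
            if k == 3:
                x[i0 + 4] = c if informed else x[4]
        x[i0 + 2 + k] = max(sigma, 0.05)
    return x


def _find_map(logpost, layout: ParamLayout, prior: PriorSpec,
              rng: np.random.Generator, x0: Optional[np.ndarray] = None,
              maxiter: int = 300) -> np.ndarray:
    """L-BFGS-B polish of the log posterior from a given starting point.

    The gradient is a central finite difference evaluated in one vectorised
    batch, which keeps the search cheap even for cohort-sized problems.
    """
    from scipy.optimize import minimize

    bounds = _optimizer_bounds(layout, prior)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if x0 is None:
        x0 = _init_walkers(rng, layout, prior, 1)[0]
    x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
    eps = 1e-6 * np.maximum(1.0, np.abs(hi - lo) / 10.0)

    def fun(x):
        v = logpost(x[None])[0]
        return 1e12 if not np.isfinite(v) else -v

    def grad(x):
        batch = np.concatenate([x[None] + np.diag(eps), x[None] - np.diag(eps)])
        vals = logpost(batch)
        g = -(vals[:len(x)] - vals[len(x):]) / (2.0 * eps)
        g[~np.isfinite(g)] = 0.0
        return g

    res = minimize(fun, x0, jac=grad, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter})
    best = res.x if logpost(res.x[None])[0] >= logpost(x0[None])[0] else x0
    return np.clip(best, lo + 1e-9, hi - 1e-9)


def _ball_init(center: np.ndarray, layout: ParamLayout, prior: PriorSpec,
               rng: np.random.Generator, n_walkers: int,
               mult: float = 1.0) -> np.ndarray:
    """Walkers scattered around a MAP point, kept inside the support."""
    k = layout.k
    scales = np.empty(layout.ndim)
    scales[0] = 1.0
    scales[1] = 0.005
    if k:
        scales[2] = 1.0
        scales[3] = 0.005
        if k == 3:
            scales[4] = 0.05
        scales[2 + k:2 + 2 * k] = 0.05
        if layout.extended:
            scales[2 + 2 * k:2 + 3 * k] = 0.05
            scales[2 + 3 * k] = 0.02
    for p in range(len(layout.person_ids)):
        i0 = layout.person_index(p, 0)
        scales[i0] = 0.5
        scales[i0 + 1] = 0.003
        if k:
            scales[i0 + 2] = 0.5
            scales[i0 + 3] = 0.003
            if k == 3:
                scales[i0 + 4] = 0.03
        scales[i0 + 2 + k] = 0.02
    bounds = _optimizer_bounds(layout, prior)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    P = center[None] + mult * scales[None] * rng.standard_normal(
        (n_walkers, layout.ndim))
    return np.clip(P, lo[None] + 1e-9, hi[None] - 1e-9)


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Thinned posterior draws organised as chains x draws x parameters."""

    names: list[str]
    chains: np.ndarray            # (n_chains, n_draws, ndim)
    model_kind: str
    person_ids: list[str]
    extended: bool
    config: SamplerConfig
    prior: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.names)}

    def draws(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains pooled."""
        return self.chains[:, :, self._index[name]].ravel()

    def chain_draws(self, name: str) -> np.ndarray:
        return self.chains[:, :, self._index[name]]

    def median(self, name: str) -> float:
        return float(np.median(self.draws(name)))

    def mean(self, name: str) -> float:
        return float(np.mean(self.draws(name)))

    def sd(self, name: str) -> float:
        return float(np.std(self.draws(name), ddof=1))

    def interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        lo = 50.0 * (1.0 - prob)
        d = self.draws(name)
        return float(np.percentile(d, lo)), float(np.percentile(d, 100.0 - lo))

    @property
    def rhat(self) -> dict:
        if self.chains.shape[0] < 2:
            return {}
        vals = gelman_rubin(np.moveaxis(self.chains, 2, 0))
        return dict(zip(self.names, np.atleast_1d(vals)))

    def hyper_mean_names(self) -> list[str]:
        k = exercise_block_size(self.model_kind)
        return ["alpha_d_mu", "beta_d_mu"] + [
            f"{c}_mu" for c in EXERCISE_COMPONENTS[:k]]

    def group_hyper(self) -> GroupHyper:
        k = exercise_block_size(self.model_kind)
        theta = {n: self.median(n) for n in self.hyper_mean_names()}
        sds = {"alpha_d_sd": 10.0, "beta_d_sd": 0.1}
        for c in EXERCISE_COMPONENTS[:k]:
            sds[f"{c}_sd"] = self.median(f"{c}_sd")
        return GroupHyper(theta_tilde=theta, sigma_person=sds)

    def person_params(self, person_id: str) -> PersonParams:
        k = exercise_block_size(self.model_kind)
        kw = dict(
            alpha_d=self.median(f"alpha_d[{person_id}]"),
            beta_d=self.median(f"beta_d[{person_id}]"),
            sigma=self.median(f"sigma[{person_id}]"),
        )
        if k:
            kw["alpha_e"] = self.median(f"alpha_e[{person_id}]")
            kw["beta_e"] = self.median(f"beta_e[{person_id}]")
        if k == 3:
            kw["c_syn"] = self.median(f"c_syn[{person_id}]")
        return PersonParams(**kw)

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i in range(self.chains.shape[0]):
            pd.DataFrame(self.chains[i], columns=self.names).to_parquet(
                directory / f"chain_{i}.parquet")
        summary = {
            "names": self.names,
            "model_kind": self.model_kind,
            "person_ids": self.person_ids,
            "extended": self.extended,
            "medians": {n: self.median(n) for n in self.names},
            "intervals_95": {n: self.interval(n) for n in self.names},
            "rhat": {n: float(v) for n, v in self.rhat.items()},
        }
        (directory / "summary.json").write_text(json.dumps(summary, indent=1))
        (directory / "config.json").write_text(json.dumps(
            {"sampler": self.config.to_dict(), "prior": self.prior}, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorSummary":
        directory = Path(directory)
        summary = json.loads((directory / "summary.json").read_text())
        cfgs = json.loads((directory / "config.json").read_text())
        chains = []
        i = 0
        while (directory / f"chain_{i}.parquet").exists():
            chains.append(pd.read_parquet(directory / f"chain_{i}.parquet").to_numpy())
            i += 1
        return cls(names=summary["names"], chains=np.stack(chains),
                   model_kind=summary["model_kind"],
                   person_ids=summary["person_ids"],
                   extended=summary["extended"],
                   config=SamplerConfig(**cfgs["sampler"]),
                   prior=cfgs.get("prior", {}))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains) -> np.ndarray | float:
    """Classic (split-free) Gelman-Rubin potential scale reduction factor.

    ``chains`` is an array of shape (n_chains, n_draws) for one parameter or
    (n_params, n_chains, n_draws) for several; chains must have equal
    lengths and there must be at least two of them.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        return float(gelman_rubin(chains[None])[0])
    if chains.ndim != 3:
        raise ValueError("chains must be (n_chains, n_draws) or (n_params, n_chains, n_draws)")
    m = chains.shape[1]
    n = chains.shape[2]
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    means = chains.mean(axis=2)
    variances = chains.var(axis=2, ddof=1)
    w = variances.mean(axis=1)
    b_over_n = means.var(axis=1, ddof=1)
    var_hat = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_hat / w)
    r[~np.isfinite(r)] = 1.0  # degenerate constant chains
    return r


def point_estimates(posterior: PosteriorSummary) -> dict[str, PersonParams]:
    """Per-person marginal posterior medians assembled as PersonParams."""
    return {pid: posterior.person_params(pid) for pid in posterior.person_ids}


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _child_seeds(seed: Optional[int], n: int) -> list[int]:
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _sample_posterior(segment_set: SegmentSet, model_kind: str,
                      prior: PriorSpec, config: SamplerConfig,
                      person_ids: Optional[Sequence[str]] = None) -> PosteriorSummary:
    if person_ids is None:
        person_ids = segment_set.person_ids
    extended = prior.exercise.mode == "extended"
    layout = ParamLayout(model_kind, person_ids, extended)
    if prior.exercise.mu is not None and len(prior.exercise.mu) != layout.k:
        raise ValueError(
            f"exercise prior has {len(prior.exercise.mu)} components but the "
            f"{model_kind} model expects {layout.k}")
    bundle = _bundle(segment_set, model_kind, person_ids)

    def logpost(P):
        P = np.atleast_2d(np.asarray(P, dtype=float))
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp = _log_prior(P, layout, prior)
            out = np.full(P.shape[0], -np.inf)
            ok = np.isfinite(lp)
            if ok.any():
                ll = _log_likelihood(P[ok], layout, bundle)
                out[ok] = lp[ok] + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    n_walkers = config.walkers_for(layout.ndim)
    thin = config.thin_for(layout.ndim)
    seeds = _child_seeds(config.seed, 2 * config.n_chains)
    chains = []
    start = _structured_center(bundle, layout, prior)
    rng0 = np.random.default_rng(_child_seeds(config.seed, 1)[0] ^ 0x5EED)
    maxiter = 300 if layout.ndim <= 64 else 120
    shared = _find_map(logpost, layout, prior, rng0, x0=start, maxiter=maxiter)
    shared_lp = logpost(shared[None])[0]
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[2 * c])
        # for small problems each chain additionally polishes its own
        # perturbed start; it keeps that basin only when it is at least as
        # good as the shared one, so chains can discover better modes but
        # cannot linger in worse ones
        center = shared
        if layout.ndim <= 64:
            x0 = _ball_init(start, layout, prior, rng, 1, mult=8.0)[0]
            cand = _find_map(logpost, layout, prior, rng, x0=x0)
            if logpost(cand[None])[0] >= shared_lp - 2.0:
                center = cand
        p0 = _ball_init(center, layout, prior, rng, n_walkers)
        sampler = emcee.EnsembleSampler(
            n_walkers, layout.ndim, logpost, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.9),
                   (emcee.moves.DESnookerMove(), 0.1)])
        sampler.random_state = np.random.RandomState(seeds[2 * c + 1]).get_state()
        sampler.run_mcmc(p0, config.n_iter, progress=False,
                         skip_initial_state_check=True)
        kept = sampler.get_chain(discard=config.n_burnin, thin=thin)
        chains.append(kept.reshape(-1, layout.ndim))
        if not np.isfinite(sampler.get_log_prob()[-1]).any():
            raise RuntimeError("sampler failed: no walker has finite posterior density")
    n_draws = min(c.shape[0] for c in chains)
    chains = np.stack([c[:n_draws] for c in chains])
    return PosteriorSummary(names=layout.names, chains=chains,
                            model_kind=model_kind,
                            person_ids=list(person_ids), extended=extended,
                            config=config, prior=prior.to_dict())


def fit_source_task(rct_train: SegmentSet, model_kind: str,
                    config: Optional[SamplerConfig] = None,
                    prior: Optional[PriorSpec] = None,
                    summary_stat: str = "moment"):
    """Pretrain on balanced RCT data and summarise the exercise block.

    Returns the posterior and a Gaussian summary of the exercise-block group
    means ready for prior rescaling in the target task: moment matching
    (posterior means, diagonal posterior variances) by default, or the
    outlier-robust median/MAD equivalent with ``summary_stat="robust"``.
    """
    from .transfer import GaussianSourceSummary

    if exercise_block_size(model_kind) == 0:
        raise ValueError("the source task pretrains exercise parameters; "
                         "use the additive or synergistic model")
    if summary_stat not in ("moment", "robust"):
        raise ValueError("summary_stat must be 'moment' or 'robust'")
    if config is None:
        config = SamplerConfig()
    if prior is None:
        prior = PriorSpec.flat()
    if rct_train.n_persons < 2:
        warnings.warn("fewer than 2 persons: group-level hierarchy is weakly "
                      "identified", UserWarning, stacklevel=2)
    posterior = _sample_posterior(rct_train, model_kind, prior, config)
    k = exercise_block_size(model_kind)
    comp_names = [f"{c}_mu" for c in EXERCISE_COMPONENTS[:k]]
    if summary_stat == "moment":
        mu = np.array([posterior.mean(n) for n in comp_names])
        var = np.array([posterior.sd(n) ** 2 for n in comp_names])
    else:
        mu = np.array([posterior.median(n) for n in comp_names])
        mad = np.array([np.median(np.abs(posterior.draws(n) - posterior.median(n)))
                        for n in comp_names])
        var = (1.4826 * mad) ** 2  # MAD of a Gaussian scaled to its SD
    return posterior, GaussianSourceSummary(mu=mu, var=var)


def fit_target_task(patient_train: SegmentSet, model_kind: str,
                    prior: Optional[PriorSpec] = None,
                    config: Optional[SamplerConfig] = None,
                    person_ids: Optional[Sequence[str]] = None) -> PosteriorSummary:
    """Joint posterior over group hyperparameters and per-patient parameters.

    ``prior`` is flat (no transfer) or an informative rescaled Gaussian
    (normal/extended transfer) over the exercise block.
    """
    if config is None:
        config = SamplerConfig()
    if prior is None:
        prior = PriorSpec.flat()
    return _sample_posterior(patient_train, model_kind, prior, config,
                             person_ids=person_ids)
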