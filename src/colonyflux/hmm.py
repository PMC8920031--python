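"""Three-state hidden Markov model for behaviour classification.

States are (flight, colony, water).  Two observation streams per
analysis window, conditionally independent given the state:

* wingbeat frequency (Hz) — zero-inflated gamma: a point mass at 0
  ("no dominant flapping peak") plus a gamma density on positive values;
* near-colony indicator — Bernoulli on the 500 m distance dichotomy.

Missing values in either stream are marginalised out (contribute 0 to
the emission log-likelihood).  Inference is exact: scaled
forward–backward for posteriors and the likelihood, Viterbi for the
decoded path, Baum–Welch (EM) for fitting pooled sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.special import digamma, gammaln, polygamma

from .config import BEHAVIOURS
from .containers import FeatureSeries, StatePath, TimeActivityBudget

N_STATES = 3
_PROB_FLOOR = 1e-6
_SHAPE_BOUNDS = (1e-3, 1e6)


@dataclass
class HmmModel:
    """Parameters; state index order is the canonical (flight, colony, water)
    only after :func:`canonicalize` — a freshly fitted model's indices are
    arbitrary."""

    init: np.ndarray  # (3,) initial distribution
    trans: np.ndarray  # (3,3) row-stochastic
    zero_mass: np.ndarray  # (3,) P(wingbeat == 0 | state)
    shape: np.ndarray  # (3,) gamma shape for positive wingbeat
    rate: np.ndarray  # (3,) gamma rate
    p_near: np.ndarray  # (3,) P(near colony | state)

    def __post_init__(self):
        for name in ("init", "trans", "zero_mass", "shape", "rate", "p_near"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        self.validate()

    def validate(self) -> None:
        if abs(self.init.sum() - 1) > 1e-9 or (self.init < 0).any():
            raise ValueError("initial distribution must be on the simplex")
        if np.abs(self.trans.sum(axis=1) - 1).max() > 1e-9 or (self.trans < 0).any():
            raise ValueError("transition matrix rows must sum to 1")
        for p in (self.zero_mass, self.p_near):
            if ((p < 0) | (p > 1)).any():
                raise ValueError("probabilities must lie in [0, 1]")
        if (self.shape <= 0).any() or (self.rate <= 0).any():
            raise ValueError("gamma parameters must be positive")

    @property
    def mean_wingbeat(self) -> np.ndarray:
        """Mean of the wingbeat emission per state (zero-inflated gamma)."""
        return (1.0 - self.zero_mass) * self.shape / self.rate

    def to_dict(self) -> dict:
        return {
            "init": self.init.tolist(),
            "trans": self.trans.tolist(),
            "zero_mass": self.zero_mass.tolist(),
            "shape": self.shape.tolist(),
            "rate": self.rate.tolist(),
            "p_near": self.p_near.tolist(),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "HmmModel":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---- emissions -----------------------------------------------------------


def emission_loglik(model: HmmModel, wingbeat, near) -> np.ndarray:
    """Per-window, per-state emission log-likelihood, shape (T, 3).

    ``wingbeat`` NaN and ``near`` NaN are missing observations and
    contribute 0 (marginalised).  Negative wingbeat values are invalid.
    """
    w = np.atleast_1d(np.asarray(wingbeat, float))
    nr = np.atleast_1d(np.asarray(near, float))
    if np.nanmin(w, initial=0.0) < 0:
        raise ValueError("wingbeat frequencies must be non-negative")
    T = len(w)
    logB = np.zeros((T, N_STATES))

    with np.errstate(divide="ignore"):
        log_pi = np.log(model.zero_mass)
        log_1mpi = np.log1p(-model.zero_mass)
        log_p = np.log(model.p_near)
        log_1mp = np.log1p(-model.p_near)

    zero = w == 0
    pos = w > 0
    logB[zero] += log_pi
    if pos.any():
        x = w[pos][:, None]
        k, r = model.shape[None, :], model.rate[None, :]
        logB[pos] += log_1mpi + k * np.log(r) - gammaln(k) + (k - 1) * np.log(x) - r * x

    present = ~np.isnan(nr)
    if present.any():
        y = nr[present][:, None]
        logB[present] += y * log_p[None, :] + (1 - y) * log_1mp[None, :]
    return logB


# ---- exact inference -----------------------------------------------------


def _scaled_B(logB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = logB.max(axis=-1)
    if not np.isfinite(m).all():
        raise ValueError("observation impossible under every state; check the model")
    return np.exp(logB - m[..., None]), m


def _forward_backward_core(B: np.ndarray, init: np.ndarray, trans: np.ndarray):
    """Scaled forward-backward, batched over leading sequence axis.

    B: (S, T, K) emission likelihoods (any positive scaling per window).
    Returns alpha, beta, per-window scale factors c, posteriors gamma.
    """
    S, T, K = B.shape
    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = init[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    if (c[:, 0] <= 0).any():
        raise ValueError("zero likelihood at the first window")
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ trans) * B[:, t]
        c[:, t] = a.sum(axis=1)
        if (c[:, t] <= 0).any():
            raise ValueError(f"zero likelihood at window {t}")
        alpha[:, t] = a / c[:, t, None]
    beta = np.empty((S, T, K))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = ((beta[:, t + 1] * B[:, t + 1]) @ trans.T) / c[:, t + 1, None]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return alpha, beta, c, gamma


def forward_backward(model: HmmModel, fs: FeatureSeries):
    """Total log-likelihood and per-window posterior state probabilities."""
    if len(fs) == 0:
        raise ValueError("empty feature series")
    logB = emission_loglik(model, fs.wingbeat, fs.near)
    B, m = _scaled_B(logB)
    _, _, c, gamma = _forward_backward_core(B[None], model.init, model.trans)
    loglik = float(np.log(c[0]).sum() + m.sum())
    return loglik, gamma[0]


def viterbi(model: HmmModel, fs: FeatureSeries, bird_id: Optional[str] = None) -> StatePath:
    """Maximum-probability state path; ties break toward the lowest state
    index in the canonical order (flight, colony, water)."""
    if len(fs) == 0:
        raise ValueError("empty feature series")
    logB = emission_loglik(model, fs.wingbeat, fs.near)
    T = len(fs)
    with np.errstate(divide="ignore"):
        log_init = np.log(model.init)
        log_trans = np.log(model.trans)
    delta = log_init + logB[0]
    psi = np.zeros((T, N_STATES), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        psi[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta = cand[psi[t], np.arange(N_STATES)] + logB[t]
    states = np.empty(T, dtype=np.int64)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1][states[t + 1]]
    _, post = forward_backward(model, fs)
    return StatePath(
        t0=fs.t0,
        midpoints=fs.midpoints,
        states=states,
        posterior=post,
        missing=fs.missing,
        bird_id=bird_id,
    )


def path_logprob(model: HmmModel, fs: FeatureSeries, states: np.ndarray) -> float:
    """Joint log-probability of one complete state path with the data."""
    logB = emission_loglik(model, fs.wingbeat, fs.near)
    with np.errstate(divide="ignore"):
        lp = np.log(model.init[states[0]]) + logB[0, states[0]]
        for t in range(1, len(states)):
            lp += np.log(model.trans[states[t - 1], states[t]]) + logB[t, states[t]]
    return float(lp)


# ---- EM fitting ----------------------------------------------------------


def _solve_gamma_shape(s_stat: float) -> float:
    """Solve log(k) - digamma(k) = s_stat by Newton iteration."""
    lo, hi = _SHAPE_BOUNDS
    if s_stat <= 0:
        return hi
    k = (3 - s_stat + np.sqrt((s_stat - 3) ** 2 + 24 * s_stat)) / (12 * s_stat)
    k = np.clip(k, lo, hi)
    for _ in range(50):
        f = np.log(k) - digamma(k) - s_stat
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = np.clip(k - step, lo, hi)
        if abs(k_new - k) < 1e-12 * max(k, 1.0):
            k = k_new
            break
        k = k_new
    return float(k)


def init_from_features(series: Sequence[FeatureSeries]) -> HmmModel:
    """Deterministic quantile-based initialisation.

    Flight is seeded with top-tercile wingbeat windows, colony with
    near-colony low-wingbeat windows, water with the rest; the
    transition matrix starts sticky (0.9 on the diagonal).
    """
    w = np.concatenate([fs.wingbeat for fs in series])
    nr = np.concatenate([fs.near for fs in series])
    present = ~np.isnan(w)
    q66 = np.nanquantile(w[present], 2 / 3) if present.any() else 0.0
    flight = present & (w > max(q66, 0.0))
    colony = ~flight & (nr == 1.0)
    water = ~flight & ~colony
    masks = (flight, colony, water)

    zero_mass = np.empty(3)
    shape = np.empty(3)
    rate = np.empty(3)
    p_near = np.empty(3)
    for s, mask in enumerate(masks):
        ws = w[mask & present]
        zero_mass[s] = np.clip(
            np.mean(ws == 0) if len(ws) else 0.5, _PROB_FLOOR, 1 - _PROB_FLOOR
        )
        pos = ws[ws > 0]
        if len(pos) >= 2 and pos.var() > 0:
            m, v = pos.mean(), pos.var(ddof=1)
            shape[s] = np.clip(m * m / v, *_SHAPE_BOUNDS)
            rate[s] = shape[s] / m
        else:
            shape[s], rate[s] = 1.0, 1.0
        ns = nr[mask & ~np.isnan(nr)]
        p_near[s] = np.clip(ns.mean() if len(ns) else 0.5, _PROB_FLOOR, 1 - _PROB_FLOOR)
    trans = np.full((3, 3), 0.05)
    np.fill_diagonal(trans, 0.9)
    return HmmModel(
        init=np.full(3, 1 / 3),
        trans=trans,
        zero_mass=zero_mass,
        shape=shape,
        rate=rate,
        p_near=p_near,
    )


def fit_em(
    series: Sequence[FeatureSeries],
    init: Optional[HmmModel] = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[HmmModel, list[float]]:
    """Baum–Welch over pooled sequences.

    Returns the fitted model and the per-iteration total log-likelihood
    trace (non-decreasing).  Stops at relative improvement < ``tol`` or
    ``max_iter``.  A state whose expected occupancy drops below one
    window keeps its previous emission parameters (with a warning)
    rather than collapsing.
    """
    if len(series) == 0:
        raise ValueError("need at least one feature series")
    model = init if init is not None else init_from_features(series)

    obs = [(fs.wingbeat, fs.near) for fs in series]
    # batch sequences of equal length for vectorised forward-backward
    by_len: dict[int, list[int]] = {}
    for i, fs in enumerate(series):
        by_len.setdefault(len(fs), []).append(i)

    trace: list[float] = []
    for iteration in range(max_iter):
        total_ll = 0.0
        init_acc = np.zeros(3)
        xi_acc = np.zeros((3, 3))
        sw_near = np.zeros(3)
        swx_near = np.zeros(3)
        sw_wb = np.zeros(3)  # weight over windows with wingbeat present
        sw_zero = np.zeros(3)
        sw_pos = np.zeros(3)
        swx_pos = np.zeros(3)
        swlx_pos = np.zeros(3)
        occupancy = np.zeros(3)

        for T, idxs in by_len.items():
            logB = np.stack([emission_loglik(model, *obs[i]) for i in idxs])
            B, m = _scaled_B(logB)
            alpha, beta, c, g = _forward_backward_core(B, model.init, model.trans)
            total_ll += float(np.log(c).sum() + m.sum())
            init_acc += g[:, 0].sum(axis=0)
            if T > 1:
                pred = (B[:, 1:] * beta[:, 1:]) / c[:, 1:, None]
                xi_acc += model.trans * np.einsum("sti,stj->ij", alpha[:, :-1], pred)
            for local, i in enumerate(idxs):
                w, nr = obs[i]
                gs = g[local]
                occupancy += gs.sum(axis=0)
                near_p = ~np.isnan(nr)
                sw_near += gs[near_p].sum(axis=0)
                swx_near += (gs[near_p] * nr[near_p, None]).sum(axis=0)
                wb_p = ~np.isnan(w)
                sw_wb += gs[wb_p].sum(axis=0)
                sw_zero += gs[wb_p & (w == 0)].sum(axis=0)
                pos = wb_p & (w > 0)
                gp = gs[pos]
                sw_pos += gp.sum(axis=0)
                swx_pos += (gp * w[pos, None]).sum(axis=0)
                swlx_pos += (gp * np.log(w[pos])[:, None]).sum(axis=0)

        trace.append(total_ll)
        if len(trace) > 1 and tol > 0:
            rel = (trace[-1] - trace[-2]) / max(abs(trace[-2]), 1.0)
            if rel < tol:
                break

        # ---- M-step
        new_init = init_acc / init_acc.sum()
        rows = xi_acc.sum(axis=1, keepdims=True)
        new_trans = np.where(rows > 0, xi_acc / np.where(rows > 0, rows, 1.0), model.trans)
        new_trans /= new_trans.sum(axis=1, keepdims=True)
        zero_mass = model.zero_mass.copy()
        shape = model.shape.copy()
        rate = model.rate.copy()
        p_near = model.p_near.copy()
        for s in range(3):
            if occupancy[s] < 1.0:
                warnings.warn(
                    f"state {s} expected occupancy {occupancy[s]:.3g} < 1 window; "
                    "emission parameters frozen this iteration"
                )
                continue
            if sw_near[s] > 0:
                p_near[s] = np.clip(swx_near[s] / sw_near[s], _PROB_FLOOR, 1 - _PROB_FLOOR)
            if sw_wb[s] > 0:
                zero_mass[s] = np.clip(sw_zero[s] / sw_wb[s], _PROB_FLOOR, 1 - _PROB_FLOOR)
            if sw_pos[s] > 1e-12:
                mean = swx_pos[s] / sw_pos[s]
                s_stat = np.log(mean) - swlx_pos[s] / sw_pos[s]
                shape[s] = _solve_gamma_shape(s_stat)
                rate[s] = shape[s] / mean
        model = HmmModel(
            init=new_init,
            trans=new_trans,
            zero_mass=zero_mass,
            shape=shape,
            rate=rate,
            p_near=p_near,
        )
    return model, trace


# ---- labelling & budgets -------------------------------------------------


def label_states(model: HmmModel) -> dict[int, str]:
    """Map fitted state indices to behaviours.

    Flight is the state with the highest mean wingbeat emission; of the
    remaining two, colony has the higher near-colony probability.
    Exact ties make the fit ambiguous and are an error.
    """
    mu = model.mean_wingbeat
    order = np.argsort(mu)[::-1]
    if mu[order[0]] == mu[order[1]]:
        raise ValueError("ambiguous fit: two states share the highest mean wingbeat")
    flight = int(order[0])
    rest = [s for s in range(3) if s != flight]
    if model.p_near[rest[0]] == model.p_near[rest[1]]:
        raise ValueError("ambiguous fit: remaining states share the near-colony probability")
    colony = rest[0] if model.p_near[rest[0]] > model.p_near[rest[1]] else rest[1]
    water = next(s for s in rest if s != colony)
    return {flight: "flight", colony: "colony", water: "water"}


def canonicalize(model: HmmModel) -> HmmModel:
    """Permute state indices into the canonical (flight, colony, water) order."""
    labels = label_states(model)
    perm = [next(s for s, b in labels.items() if b == beh) for beh in BEHAVIOURS]
    perm = np.asarray(perm)
    return replace(
        model,
        init=model.init[perm],
        trans=model.trans[np.ix_(perm, perm)],
        zero_mass=model.zero_mass[perm],
        shape=model.shape[perm],
        rate=model.rate[perm],
        p_near=model.p_near[perm],
    )


def decode(model: HmmModel, fs: FeatureSeries, method: str = "viterbi",
           bird_id: Optional[str] = None) -> StatePath:
    """Decode one deployment with a canonically ordered model."""
    if method == "viterbi":
        return viterbi(model, fs, bird_id=bird_id)
    if method == "posterior":
        _, post = forward_backward(model, fs)
        return StatePath(
            t0=fs.t0,
            midpoints=fs.midpoints,
            states=np.argmax(post, axis=1),
            posterior=post,
            missing=fs.missing,
            bird_id=bird_id,
        )
    raise ValueError(f"unknown decoding method {method!r}")


def compute_budget(path: StatePath) -> TimeActivityBudget:
    """Time–activity budget: decoded-window counts per behaviour over
    non-missing windows."""
    keep = ~path.missing
    if not keep.any():
        raise ValueError("all windows missing; no budget defined")
    counts = np.bincount(path.states[keep], minlength=N_STATES).astype(float)
    return TimeActivityBudget(proportions=counts / counts.sum(), bird_id=path.bird_id)
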