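"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exhaustive enumeration over
internal-state assignments, quadrature for gamma category means, and a
fixed-step RK4 integrator.  None of it shares code paths with the package
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from paraspec.alignment import AA_INDEX
from paraspec.models import N_STATES


def _tree_arrays(tree):
    flat = tree.flatten()
    internal = [k for k in range(flat.n_nodes) if not flat.is_leaf[k]]
    leaves = [k for k in range(flat.n_nodes) if flat.is_leaf[k]]
    return flat, internal, leaves


def _branch_matrices(flat, model, rate):
    from paraspec.models import build_generator

    q = build_generator(model).matrix
    return [
        expm(q * (flat.branch_lengths[k] * rate)) if flat.parent[k] >= 0 else None
        for k in range(flat.n_nodes)
    ]


def _site_codes(flat, alignment):
    codes = {}
    for k in range(flat.n_nodes):
        if flat.is_leaf[k]:
            seq = alignment.sequence(flat.ids[k])
            codes[k] = [AA_INDEX[ch] for ch in seq]
    return codes


def enumeration_site_likelihoods(tree, alignment, model) -> np.ndarray:
    """Per-site likelihood by summing over all internal-state assignments.

    For every joint assignment of states to internal nodes the probability
    factors into the root prior, internal-branch transition terms, and
    leaf-branch terms looked up per site; missing leaf states (gap/X)
    contribute a sum over the 20 states.  Averages over gamma categories.
    Exponential in the number of internal nodes: tiny trees only.
    """
    flat, internal, leaves = _tree_arrays(tree)
    codes = _site_codes(flat, alignment)
    rates = model.category_rates()
    pi = model.frequencies / model.frequencies.sum()
    n_sites = alignment.n_columns
    total = np.zeros(n_sites)
    root = flat.root
    leaf_cols = {k: np.asarray(codes[k]) for k in leaves}
    for rate in rates:
        mats = _branch_matrices(flat, model, rate)
        # leaf term per (leaf, parent state): vector over sites
        leaf_term = {}
        for k in leaves:
            cols = leaf_cols[k]
            term = np.empty((N_STATES, n_sites))
            for ps in range(N_STATES):
                row = mats[k][ps]
                term[ps] = np.where(cols >= 0, row[np.maximum(cols, 0)], 1.0)
            leaf_term[k] = term
        for assignment in itertools.product(range(N_STATES), repeat=len(internal)):
            state = dict(zip(internal, assignment))
            p = pi[state[root]]
            for k in internal:
                if flat.parent[k] >= 0:
                    p *= mats[k][state[flat.parent[k]], state[k]]
            site_p = np.full(n_sites, p)
            for k in leaves:
                site_p *= leaf_term[k][state[flat.parent[k]]]
            total += site_p / len(rates)
    return total


def enumeration_log_likelihood(tree, alignment, model) -> float:
    return float(np.log(enumeration_site_likelihoods(tree, alignment, model)).sum())


def enumeration_posteriors_all(tree, alignment, model) -> dict:
    """Clamp-and-renormalize marginal posteriors at every internal node.

    For each site, node and state s, fixing the node to s and summing the
    joint probability over all remaining internal states and the rate
    category, then normalizing over s, gives the marginal posterior.
    """
    flat, internal, leaves = _tree_arrays(tree)
    codes = _site_codes(flat, alignment)
    rates = model.category_rates()
    pi = model.frequencies / model.frequencies.sum()
    n_sites = alignment.n_columns
    out = {k: np.zeros((n_sites, N_STATES)) for k in internal}
    root = flat.root
    for rate in rates:
        mats = _branch_matrices(flat, model, rate)
        leaf_term = {}
        for k in leaves:
            cols = np.asarray(codes[k])
            term = np.empty((N_STATES, n_sites))
            for ps in range(N_STATES):
                row = mats[k][ps]
                term[ps] = np.where(cols >= 0, row[np.maximum(cols, 0)], 1.0)
            leaf_term[k] = term
        for assignment in itertools.product(
            range(N_STATES), repeat=len(internal)
        ):
            state = dict(zip(internal, assignment))
            p = pi[state[root]]
            for k in internal:
                if flat.parent[k] >= 0:
                    p *= mats[k][state[flat.parent[k]], state[k]]
            site_p = np.full(n_sites, p)
            for k in leaves:
                site_p *= leaf_term[k][state[flat.parent[k]]]
            for k in internal:
                out[k][:, state[k]] += site_p / len(rates)
    return {
        flat.ids[k]: m / m.sum(axis=1, keepdims=True) for k, m in out.items()
    }


def enumeration_posteriors(tree, alignment, model, node_id) -> np.ndarray:
    return enumeration_posteriors_all(tree, alignment, model)[node_id]


def gamma_rates_by_quadrature(alpha: float, k: int) -> np.ndarray:
    """Category means via numeric integration of x * pdf over each slice."""
    dist = gamma_dist(a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], dist.ppf(np.arange(1, k) / k), [np.inf]])
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        upper = hi if np.isfinite(hi) else dist.ppf(1.0 - 1e-14)
        val, _ = quad(lambda x: x * dist.pdf(x), lo, upper, limit=400)
        means.append(val * k)
    return np.array(means)


def rk4_phosphotransfer(
    kt: float,
    kp: float,
    hk_total: float,
    rr_total: float,
    times: np.ndarray,
    dt: float = 1e-3,
) -> np.ndarray:
    """Fixed-step RK4 integration of the transfer/phosphatase ODEs."""

    def rhs(y):
        hkp, rrp = y
        transfer = kt * hkp * (rr_total - rrp)
        return np.array([-transfer, transfer - kp * (hk_total - hkp) * rrp])

    y = np.array([hk_total, 0.0])
    t = 0.0
    out = []
    for target in times:
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * h * k1)
            k3 = rhs(y + 0.5 * h * k2)
            k4 = rhs(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out.append(y[0])
    return np.array(out)
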