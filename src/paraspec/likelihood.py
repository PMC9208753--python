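"""Felsenstein pruning on a fixed tree, with discrete-gamma rate mixing.

Branch lengths are taken as given (no optimization); gaps and ``X`` are
missing data.  Identical alignment columns are collapsed to weighted site
patterns before any computation; this is exact, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment
from .errors import MissingSequenceError
from .models import (
    N_STATES,
    RateGenerator,
    SubstitutionModel,
    build_generator,
)
from .tree import FlatTree, PhylogeneticTree

_SCALE_EVERY = True  # rescale partials at every internal node


@dataclass
class SitePatterns:
    """Deduplicated alignment columns.

    ``codes`` is (n_leaves, n_patterns) with -1 for missing data; ``weights``
    counts how many alignment columns each pattern represents and
    ``pattern_of_site`` maps every original column (0-based) to its pattern.
    """

    leaf_ids: list[str]
    codes: np.ndarray
    weights: np.ndarray
    pattern_of_site: np.ndarray

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.pattern_of_site)


def compress_alignment(alignment: Alignment, leaf_ids: list[str]) -> SitePatterns:
    missing = [lid for lid in leaf_ids if lid not in alignment]
    if missing:
        raise MissingSequenceError(
            f"alignment lacks sequences for leaves: {missing}"
        )
    mat = alignment.encoded(leaf_ids)  # (n_leaves, n_sites)
    cols, pattern_of_site, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    return SitePatterns(
        leaf_ids=list(leaf_ids),
        codes=cols.T.copy(),
        weights=counts.astype(float),
        pattern_of_site=pattern_of_site.ravel(),
    )


class PruningWorkspace:
    """Shared state for likelihood and marginal-posterior computation.

    Holds, per gamma category: the per-branch transition matrices and the
    postorder ("below") partial likelihoods with their log scaling factors.
    The posterior pass adds the preorder ("above") quantities on demand.
    """

    def __init__(
        self,
        tree: PhylogeneticTree,
        alignment: Alignment,
        model: SubstitutionModel,
    ):
        self.tree = tree
        self.model = model
        self.flat: FlatTree = tree.flatten()
        leaf_ids = [
            self.flat.ids[k] for k in range(self.flat.n_nodes) if self.flat.is_leaf[k]
        ]
        self.patterns = compress_alignment(alignment, leaf_ids)
        self._leaf_row = {lid: r for r, lid in enumerate(self.patterns.leaf_ids)}
        self.generator: RateGenerator = build_generator(model)
        self.rates = model.category_rates()
        self.n_cat = len(self.rates)
        self._run_down_pass()

    # -- down (postorder) pass ----------------------------------------------
    def _leaf_partial(self, node_index: int) -> np.ndarray:
        row = self._leaf_row[self.flat.ids[node_index]]
        codes = self.patterns.codes[row]
        partial = np.zeros((N_STATES, self.patterns.n_patterns))
        observed = codes >= 0
        partial[codes[observed], np.nonzero(observed)[0]] = 1.0
        partial[:, ~observed] = 1.0  # gap / X: sum over states downstream
        return partial

    def _run_down_pass(self) -> None:
        flat = self.flat
        n_pat = self.patterns.n_patterns
        # trans[c][k]: transition matrix over branch above node k, category c
        self.trans = [
            [
                self.generator.transition_matrix(flat.branch_lengths[k] * rate)
                if flat.parent[k] >= 0
                else None
                for k in range(flat.n_nodes)
            ]
            for rate in self.rates
        ]
        self.below = [
            [None] * flat.n_nodes for _ in range(self.n_cat)
        ]  # (20, n_pat) arrays
        self.below_logscale = [
            np.zeros((flat.n_nodes, n_pat)) for _ in range(self.n_cat)
        ]
        for c in range(self.n_cat):
            for k in range(flat.n_nodes):  # postorder by construction
                if flat.is_leaf[k]:
                    self.below[c][k] = self._leaf_partial(k)
                    continue
                partial = np.ones((N_STATES, n_pat))
                scale = np.zeros(n_pat)
                for child in flat.children[k]:
                    partial *= self.trans[c][child] @ self.below[c][child]
                    scale += self.below_logscale[c][child]
                if _SCALE_EVERY:
                    peak = partial.max(axis=0)
                    peak[peak == 0.0] = 1.0
                    partial /= peak
                    scale = scale + np.log(peak)
                self.below[c][k] = partial
                self.below_logscale[c][k] = scale

    def pattern_log_likelihoods(self) -> np.ndarray:
        """Log-likelihood of each site pattern, gamma categories averaged."""
        pi = self.generator.frequencies
        root = self.flat.root
        per_cat = np.stack(
            [
                np.log(np.maximum(pi @ self.below[c][root], 1e-300))
                + self.below_logscale[c][root]
                for c in range(self.n_cat)
            ]
        )
        return logsumexp(per_cat, axis=0) - np.log(self.n_cat)

    def log_likelihood(self) -> float:
        return float(self.pattern_log_likelihoods() @ self.patterns.weights)

    # -- up (preorder) pass ---------------------------------------------------
    def run_up_pass(self) -> None:
        """Compute "above" partials: data outside each node's subtree.

        ``above[c][k][i]`` is the joint probability of everything outside
        node k's subtree and state i at node k (including the root prior),
        for category c, up to the tracked log scale.
        """
        flat = self.flat
        n_pat = self.patterns.n_patterns
        pi = self.generator.frequencies
        self.above = [[None] * flat.n_nodes for _ in range(self.n_cat)]
        self.above_logscale = [
            np.zeros((flat.n_nodes, n_pat)) for _ in range(self.n_cat)
        ]
        for c in range(self.n_cat):
            root = flat.root
            self.above[c][root] = np.repeat(pi[:, None], n_pat, axis=1)
            for k in range(flat.n_nodes - 1, -1, -1):  # preorder = reversed postorder
                if flat.is_leaf[k]:
                    continue
                kids = flat.children[k]
                # messages from each child's subtree up into node k
                msgs = [self.trans[c][ch] @ self.below[c][ch] for ch in kids]
                for pos, child in enumerate(kids):
                    m = self.above[c][k].copy()
                    scale = self.above_logscale[c][k].copy()
                    for other, msg in enumerate(msgs):
                        if other == pos:
                            continue
                        m *= msg
                        scale += self.below_logscale[c][kids[other]]
                    out = self.trans[c][child].T @ m
                    peak = out.max(axis=0)
                    peak[peak == 0.0] = 1.0
                    out /= peak
                    self.above[c][child] = out
                    self.above_logscale[c][child] = scale + np.log(peak)

    def node_posteriors(self, nid: str) -> np.ndarray:
        """Per-site marginal posterior over the 20 states at internal node ``nid``.

        Categories are weighted by their posterior given the whole site
        pattern (empirical-Bayes treatment of the rate mixture).
        """
        if not hasattr(self, "above"):
            self.run_up_pass()
        k = self.flat.index_of(nid)
        n_pat = self.patterns.n_patterns
        log_joint = np.empty((self.n_cat, N_STATES, n_pat))
        for c in range(self.n_cat):
            joint = self.above[c][k] * self.below[c][k]
            log_joint[c] = (
                np.log(np.maximum(joint, 1e-300))
                + self.above_logscale[c][k]
                + self.below_logscale[c][k]
            )
        log_norm = logsumexp(log_joint, axis=(0, 1), keepdims=True)
        post = np.exp(logsumexp(log_joint - log_norm, axis=0))  # (20, n_pat)
        post /= post.sum(axis=0, keepdims=True)
        return post[:, self.patterns.pattern_of_site].T  # (n_sites, 20)


def log_likelihood(
    tree: PhylogeneticTree, alignment: Alignment, model: SubstitutionModel
) -> float:
    """Log-likelihood of ``alignment`` on ``tree`` under ``model``.

    Sum over sites of the log of the gamma-category-averaged pruning
    likelihood; gaps and ``X`` are marginalized as missing data.
    """
    return PruningWorkspace(tree, alignment, model).log_likelihood()


def _fit_gamma_shape(
    tree: PhylogeneticTree,
    alignment: Alignment,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.02, 100.0),
) -> tuple[float, float]:
    """Maximum-likelihood gamma shape (on a log grid refined by Brent)."""

    def neg_lnl(log_alpha: float) -> float:
        m = model.with_gamma(float(np.exp(log_alpha)), model.n_categories)
        return -log_likelihood(tree, alignment, m)

    res = minimize_scalar(
        neg_lnl,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x)), -float(res.fun)


def aic_model_selection(
    tree: PhylogeneticTree,
    alignment: Alignment,
    candidates: list[SubstitutionModel],
) -> pd.DataFrame:
    """Rank candidate models by AIC = 2k - 2 lnL.

    Candidates with ``n_categories > 1`` and an unset gamma shape have the
    shape estimated by maximum likelihood (it is counted as a free
    parameter either way).  The best model minimizes AIC; ties go to the
    model with fewer parameters.
    """
    if not candidates:
        raise ValueError("at least one candidate model is required")
    rows = []
    for model in candidates:
        fitted = model
        if model.has_gamma and model.gamma_shape is None:
            alpha, lnl = _fit_gamma_shape(tree, alignment, model)
            fitted = model.with_gamma(alpha, model.n_categories)
        else:
            lnl = log_likelihood(tree, alignment, fitted)
        k = fitted.n_free_parameters
        rows.append(
            {
                "model": fitted.name,
                "gamma_shape": fitted.gamma_shape,
                "n_categories": fitted.n_categories,
                "lnL": lnl,
                "n_params": k,
                "AIC": 2.0 * k - 2.0 * lnl,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["AIC", "n_params"], kind="stable"
    ).index
    table["best"] = False
    table.loc[order[0], "best"] = True
    return table
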