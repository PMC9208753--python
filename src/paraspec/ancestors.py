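"""Marginal (empirical-Bayes) ancestral sequence reconstruction.

For each requested internal node the per-site posterior distribution over
the 20 residues is computed with one postorder and one preorder pass over
the tree (no per-node re-rooting), marginalizing all other ancestral
states and the gamma rate categories.  From these posteriors come:

* the MAP ancestor (most probable residue per site, with the mean of the
  per-site maxima as the usual confidence summary);
* the list of ambiguously reconstructed sites — those where at least two
  residues each exceed a posterior threshold tau (default 0.2);
* the "AltAll" alternative ancestor, which swaps in the second most likely
  residue at every ambiguous site and is used to check that downstream
  conclusions are robust to reconstruction uncertainty.

Threshold comparisons are strict (``> tau``).  Exact posterior ties at the
MAP site are broken toward the alphabetically smaller residue and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import AMINO_ACIDS, Alignment
from .errors import InvalidArgumentError
from .likelihood import PruningWorkspace
from .models import SubstitutionModel
from .tree import PhylogeneticTree

_POST_TOL = 1e-10


@dataclass
class SitePosteriorMatrix:
    """Per-site posterior distributions over residues at one internal node."""

    node_id: str
    probabilities: np.ndarray  # (n_sites, 20), rows sum to 1
    alphabet: str = AMINO_ACIDS

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != len(self.alphabet):
            raise InvalidArgumentError(
                f"posterior matrix must be (n_sites, {len(self.alphabet)})"
            )
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _POST_TOL) or np.any(p < -_POST_TOL):
            raise InvalidArgumentError("posterior rows must be distributions")
        self.probabilities = p

    @property
    def n_sites(self) -> int:
        return self.probabilities.shape[0]


@dataclass
class AncestorSequence:
    """MAP ancestor with per-site confidence."""

    node_id: str
    map_sequence: str
    site_max_pp: np.ndarray
    mean_pp: float
    ambiguity_threshold: float = 0.2
    tied_sites: list[int] = field(default_factory=list)  # 1-based


@dataclass
class AltAllSequence:
    """Alternative ancestor: second-best residue at every ambiguous site."""

    node_id: str
    sequence: str
    altered_sites: list[tuple[int, str, str]]  # (1-based site, MAP, alt)


def marginal_posteriors(
    tree: PhylogeneticTree,
    alignment: Alignment,
    model: SubstitutionModel,
    nodes: list[str] | None = None,
) -> list[SitePosteriorMatrix]:
    """Marginal posteriors at the requested internal nodes (default: all)."""
    internal = set(tree.internal_ids)
    if nodes is None:
        nodes = tree.internal_ids
    for nid in nodes:
        if nid not in internal:
            if nid in tree.leaf_labels:
                raise InvalidArgumentError(
                    f"node {nid!r} is a leaf; posteriors are defined only "
                    "for internal nodes"
                )
            raise InvalidArgumentError(f"unknown node id {nid!r}")
    ws = PruningWorkspace(tree, alignment, model)
    ws.run_up_pass()
    return [
        SitePosteriorMatrix(node_id=nid, probabilities=ws.node_posteriors(nid))
        for nid in nodes
    ]


def map_ancestor(posteriors: SitePosteriorMatrix) -> AncestorSequence:
    """Most-probable residue per site, with ties broken alphabetically."""
    probs = posteriors.probabilities
    alphabet = np.array(list(posteriors.alphabet))
    # stable argmax over residues sorted alphabetically -> smaller residue wins
    alpha_order = np.argsort(alphabet, kind="stable")
    best_in_sorted = np.argmax(probs[:, alpha_order], axis=1)
    best = alpha_order[best_in_sorted]
    site_max = probs[np.arange(len(best)), best]
    n_at_max = (np.abs(probs - site_max[:, None]) == 0.0).sum(axis=1)
    tied = [int(i) + 1 for i in np.nonzero(n_at_max > 1)[0]]
    return AncestorSequence(
        node_id=posteriors.node_id,
        map_sequence="".join(alphabet[best]),
        site_max_pp=site_max,
        mean_pp=float(site_max.mean()),
        tied_sites=tied,
    )


def ambiguous_sites(posteriors: SitePosteriorMatrix, tau: float = 0.2) -> list[int]:
    """1-based sites where two or more residues each have posterior > tau."""
    if not 0.0 < tau < 0.5:
        warnings.warn(
            f"tau={tau} is outside the recommended (0, 0.5) range",
            stacklevel=2,
        )
    count_over = (posteriors.probabilities > tau).sum(axis=1)
    return [int(i) + 1 for i in np.nonzero(count_over >= 2)[0]]


def altall_ancestor(
    posteriors: SitePosteriorMatrix, tau: float = 0.2
) -> AltAllSequence:
    """MAP sequence with the second most likely residue at ambiguous sites."""
    map_seq = map_ancestor(posteriors)
    seq = list(map_seq.map_sequence)
    probs = posteriors.probabilities
    alphabet = np.array(list(posteriors.alphabet))
    alpha_order = np.argsort(alphabet, kind="stable")
    altered: list[tuple[int, str, str]] = []
    for site in ambiguous_sites(posteriors, tau):
        row = probs[site - 1][alpha_order]
        ranked = np.argsort(-row, kind="stable")  # ties -> smaller residue first
        second = alphabet[alpha_order][ranked[1]]
        altered.append((site, seq[site - 1], str(second)))
        seq[site - 1] = str(second)
    return AltAllSequence(
        node_id=posteriors.node_id,
        sequence="".join(seq),
        altered_sites=altered,
    )
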